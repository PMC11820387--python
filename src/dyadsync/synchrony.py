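"""Per-pair physiological synchrony: correlation of time-matched vmHRV vectors.

For each dyad session that survives quality gating, synchrony is the
correlation between the viewer's and the gameplayer's window-wise pNN50
vectors.  Pearson correlation is the default; Spearman is available behind
the ``method`` switch since rank-based synchrony is a common alternative
reading for short ordinal-ish vectors.  Negative correlations are retained:
clipping them would bias group means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats as sps

from .vmhrv import PairedVmhrv

__all__ = ["SynchronyResult", "synchrony_r", "group_synchrony_summary"]

_METHODS = ("pearson", "spearman")


@dataclass
class SynchronyResult:
    pair_id: int | None
    condition: str | None
    r: float
    method: str
    n_windows: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError(f"|r| must be <= 1, got {self.r}")


def synchrony_r(paired: PairedVmhrv, method: str = "pearson",
                pair_id: int | None = None,
                condition: str | None = None) -> SynchronyResult:
    """Correlation between the two partners' matched pNN50 vectors.

    A zero-variance vector (constant pNN50 in every kept window) yields
    ``r = 0`` with ``degenerate=True`` rather than NaN, keeping group
    summaries computable while staying auditable.

    Raises
    ------
    ValueError
        If the session was dropped (fewer than the minimum matched windows);
        the caller must exclude dropped sessions.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    if paired.dropped:
        raise ValueError(
            "session was dropped by the minimum-window rule; exclude it "
            "from synchrony analysis"
        )
    x, y = paired.viewer_pnn50, paired.player_pnn50
    if np.std(x) == 0 or np.std(y) == 0:
        return SynchronyResult(pair_id, condition, 0.0, method,
                               paired.n_windows, degenerate=True)
    if method == "pearson":
        r = float(sps.pearsonr(x, y).statistic)
    else:
        r = float(sps.spearmanr(x, y).statistic)
    r = float(np.clip(r, -1.0, 1.0))
    return SynchronyResult(pair_id, condition, r, method, paired.n_windows)


def group_synchrony_summary(results: Iterable[SynchronyResult],
                            labels: Mapping[int, str],
                            alpha: float = 0.05) -> dict:
    """Per-group mean synchrony plus a between-group Mann-Whitney test.

    ``labels`` maps pair_id to "HIGH"/"LOW" for the condition at hand.

    Raises
    ------
    ValueError
        If either group contributes fewer than 2 sessions.
    """
    from .stats import mann_whitney_u  # local import avoids a cycle

    rs: dict[str, list[float]] = {"HIGH": [], "LOW": []}
    for res in results:
        lab = labels.get(res.pair_id)
        if lab in rs:
            rs[lab].append(res.r)
    for lab, vals in rs.items():
        if len(vals) < 2:
            raise ValueError(f"group {lab} has fewer than 2 synchrony values")
    test = mann_whitney_u(np.asarray(rs["HIGH"]), np.asarray(rs["LOW"]),
                          alpha=alpha)
    return {
        "mean_r": {lab: float(np.mean(vals)) for lab, vals in rs.items()},
        "n": {lab: len(vals) for lab, vals in rs.items()},
        "test": test,
    }
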