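"""Nonparametric group-comparison battery for dyadic rating and vmHRV data.

Viewers are split into HIGH/LOW closeness groups at the per-condition median
of their closeness ratings.  Between-group contrasts use Mann-Whitney U,
within-group (paired) contrasts use Wilcoxon signed-rank, and associations
use Spearman/Pearson correlations.  Bonferroni-corrected thresholds are
alpha = 0.017 for families of 3 condition tests and alpha = 0.008 for the 6
within-group condition-pair comparisons.  Effect sizes for rank tests follow
r = Z / sqrt(N) with 0.10 / 0.30 / 0.50 as small / medium / large benchmarks.

The U and W statistics are computed directly (with tie-corrected,
continuity-corrected normal Z deviates — required because the effect size is
defined on Z) and small tie-free samples use exact enumeration of the null
distribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb, sqrt
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr, rankdata, spearmanr
from scipy.stats import t as t_dist

from .vmhrv import PairedVmhrv

__all__ = [
    "VasRecord",
    "GroupAssignment",
    "TestResult",
    "median_split",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "effect_size_r",
    "rank_correlation",
    "run_battery",
]

ALPHA_BETWEEN = 0.017   # Bonferroni: 3 condition tests at familywise 0.05
ALPHA_WITHIN = 0.008    # Bonferroni: 6 condition-pair comparisons

CONDITIONS = ("Baseline", "ActiveEasy", "ActiveHard", "Passive")
TEST_CONDITIONS = ("ActiveEasy", "ActiveHard", "Passive")

#: Largest combined sample for exact Mann-Whitney enumeration.
MW_EXACT_MAX_N = 12
#: Largest effective (nonzero-difference) sample for exact Wilcoxon.
WILCOXON_EXACT_MAX_N = 12
#: Largest sample for exact permutation correlation p.
CORR_EXACT_MAX_N = 8

RATING_COLUMNS = ("closeness", "concern", "perceived_stress", "own_stress",
                  "player_stress")


@dataclass
class VasRecord:
    """One viewer's ratings for one condition (all VAS points in [0, 100])."""

    pair_id: int
    condition: str
    closeness: float
    concern: float
    perceived_stress: float
    own_stress: float
    player_stress: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        for name in RATING_COLUMNS:
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside the VAS range [0, 100]")


@dataclass
class GroupAssignment:
    """HIGH/LOW labels from a median split on closeness for one condition."""

    condition: str
    median_closeness: float
    labels: dict[int, str]

    def group(self, label: str) -> list[int]:
        return sorted(p for p, lab in self.labels.items() if lab == label)


@dataclass
class TestResult:
    """One rank test or correlation, with its normal deviate and effect size."""

    test: str
    statistic: float
    z: float
    p: float
    effect_r: float
    n: int
    alpha: float
    significant: bool
    exact: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p={self.p} outside [0, 1]")
        if abs(self.effect_r) > 1.0 + 1e-12:
            raise ValueError(f"|effect_r|={self.effect_r} exceeds 1")


def median_split(pair_ids, closeness, condition: str = "") -> GroupAssignment:
    """Split viewers at the median closeness rating for one condition.

    Viewers strictly above the median are HIGH; all others LOW.  This
    tie-rule is deterministic: with an even count of distinct middle values
    the split is exactly even, but ties at the median can make it uneven —
    callers should report, not assume, evenness.

    Raises
    ------
    ValueError
        With fewer than 2 viewers, or when every rating is identical
        (no between-group contrast exists).
    """
    pair_ids = list(pair_ids)
    vals = np.asarray(closeness, dtype=float)
    if len(pair_ids) != len(vals):
        raise ValueError("pair_ids and closeness must align")
    if len(vals) < 2:
        raise ValueError("median split needs at least 2 viewers")
    if np.ptp(vals) == 0:
        raise ValueError("degenerate split: all closeness ratings identical")
    med = float(np.median(vals))
    labels = {p: ("HIGH" if v > med else "LOW")
              for p, v in zip(pair_ids, vals)}
    return GroupAssignment(condition=condition, median_closeness=med,
                           labels=labels)


def _tie_term(ranks: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled ranks."""
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney_u(x, y, alpha: float = 0.05,
                   exact: bool | None = None) -> TestResult:
    """Mann-Whitney U test (two-sided) between two independent samples.

    The reported statistic is the smaller of the two U orientations.  Z is
    the tie-corrected, continuity-corrected normal deviate of the
    x-orientation U (negative when x ranks lower).  With
    ``n_x + n_y <= 12`` and no ties the p-value is computed by full
    enumeration of rank assignments, ``P(min-orientation U <= observed)``;
    otherwise by the normal approximation.

    Raises
    ------
    ValueError
        On an empty sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    has_ties = len(np.unique(pooled)) < n

    u_x = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    u_min = min(u_x, n1 * n2 - u_x)

    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - _tie_term(ranks) / (n * (n - 1)))
    if var > 0:
        dev = u_x - mu
        cc = 0.5 * np.sign(dev)
        z = (dev - cc) / sqrt(var) if abs(dev) > 0.5 else 0.0
    else:
        z = 0.0
    p_norm = min(1.0, 2.0 * norm.sf(abs(z)))

    if exact is None:
        exact = n <= MW_EXACT_MAX_N and not has_ties
    if exact:
        total = comb(n, n1)
        count = 0
        prefix = n1 * (n1 + 1) / 2.0
        for subset in itertools.combinations(range(n), n1):
            u = ranks[list(subset)].sum() - prefix
            if min(u, n1 * n2 - u) <= u_min + 1e-9:
                count += 1
        p = count / total
    else:
        p = p_norm

    return TestResult(test="mann_whitney_u", statistic=u_min, z=float(z),
                      p=float(p), effect_r=effect_size_r(z, n), n=n,
                      alpha=alpha, significant=p < alpha, exact=bool(exact))


def wilcoxon_signed_rank(x, y, alpha: float = 0.05,
                         exact: bool | None = None) -> TestResult:
    """Wilcoxon signed-rank test (two-sided) between two paired samples.

    Zero differences are dropped before ranking; the statistic is the
    smaller of the positive- and negative-rank sums.  Z is the tie-corrected
    continuity-corrected deviate of the positive-rank sum (negative when
    x < y on balance), so swapping the samples negates it.  With effective
    n <= 12 the p-value enumerates all sign patterns of the observed
    absolute-difference ranks.  N for the effect size is the number of pairs
    supplied (before zero-difference removal), following common statistical
    software output.

    Raises
    ------
    ValueError
        On unequal lengths, fewer than 2 pairs, or all-zero differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"paired samples differ in length: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    n_supplied = len(x)
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("no nonzero pairs: the samples are identical")

    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 \
        - float(np.sum(counts.astype(float) ** 3 - counts)) / 48.0
    if var > 0:
        dev = w_plus - mu
        cc = 0.5 * np.sign(dev)
        z = (dev - cc) / sqrt(var) if abs(dev) > 0.5 else 0.0
    else:
        z = 0.0
    p_norm = min(1.0, 2.0 * norm.sf(abs(z)))

    if exact is None:
        exact = n <= WILCOXON_EXACT_MAX_N
    if exact:
        total = 2 ** n
        w_sum = float(ranks.sum())
        count = 0
        for bits in itertools.product((0, 1), repeat=n):
            wp = float(np.dot(bits, ranks))
            if min(wp, w_sum - wp) <= w + 1e-9:
                count += 1
        p = count / total
    else:
        p = p_norm

    return TestResult(test="wilcoxon_signed_rank", statistic=w, z=float(z),
                      p=float(p), effect_r=effect_size_r(z, n_supplied),
                      n=n_supplied, alpha=alpha, significant=p < alpha,
                      exact=bool(exact))


def effect_size_r(z: float, n: int) -> float:
    """Standardized effect size r = Z / sqrt(N), sign preserved."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(z) / sqrt(n)


def rank_correlation(x, y, method: str = "spearman", alpha: float = 0.05,
                     exact: bool | None = None) -> TestResult:
    """Spearman or Pearson correlation with a two-sided p-value.

    p comes from the t approximation ``t = r sqrt((n-2)/(1-r^2))`` on n - 2
    degrees of freedom, or, for n <= 8 tie-free samples, from exact
    enumeration of all n! pairings.  The reported effect size is the
    correlation coefficient itself; Z is the normal deviate matching p
    (carried for table uniformity).

    Raises
    ------
    ValueError
        On unequal lengths or n < 3.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance sample: correlation undefined")

    if method == "pearson":
        r = float(pearsonr(x, y).statistic)
    else:
        r = float(spearmanr(x, y).statistic)
    r = float(np.clip(r, -1.0, 1.0))

    if abs(r) >= 1.0 - 1e-12:
        p_t = 0.0
    else:
        t = r * sqrt((n - 2) / (1.0 - r * r))
        p_t = 2.0 * t_dist.sf(abs(t), n - 2)

    if exact is None:
        exact = n <= CORR_EXACT_MAX_N
    if exact:
        xs = x if method == "pearson" else rankdata(x)
        ys = y if method == "pearson" else rankdata(y)
        xn = (xs - xs.mean())
        xn /= np.linalg.norm(xn)
        yn = (ys - ys.mean())
        yn /= np.linalg.norm(yn)
        r_obs = abs(float(np.dot(xn, yn)))
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(float(np.dot(xn, yn[list(perm)]))) >= r_obs - 1e-9:
                count += 1
        p = count / total
    else:
        p = p_t
    p = float(min(1.0, p))

    z = float(np.sign(r) * norm.isf(max(p, 1e-300) / 2.0))
    z = float(np.clip(z, -37.0, 37.0))
    return TestResult(test=method, statistic=r, z=z, p=p, effect_r=r, n=n,
                      alpha=alpha, significant=p < alpha, exact=bool(exact))


# --------------------------------------------------------------------------
# The full battery
# --------------------------------------------------------------------------

_STRESS_PAIRS = (("ActiveHard", "ActiveEasy"), ("ActiveHard", "Passive"),
                 ("ActiveEasy", "Passive"))
_WITHIN_PAIRS = tuple(itertools.combinations(CONDITIONS, 2))


def _result_cell(res: TestResult) -> dict:
    return {
        "test": res.test, "statistic": round(float(res.statistic), 6),
        "z": round(float(res.z), 6), "p": round(float(res.p), 6),
        "effect_r": round(float(res.effect_r), 6), "n": int(res.n),
        "alpha": float(res.alpha), "significant": bool(res.significant),
        "exact": bool(res.exact), "note": "",
    }


def _insufficient(reason: str) -> dict:
    return {"test": None, "statistic": None, "z": None, "p": None,
            "effect_r": None, "n": 0, "alpha": None, "significant": False,
            "exact": False, "note": f"insufficient data: {reason}"}


def _ratings_wide(ratings: pd.DataFrame, column: str) -> pd.DataFrame:
    return ratings.pivot(index="pair_id", columns="condition", values=column)


def overall_split(ratings: pd.DataFrame) -> GroupAssignment:
    """Stable split on each viewer's mean closeness across all conditions.

    Used for paired (across-condition) tests, where per-condition group
    membership would make pairing ill-defined.
    """
    mean_close = ratings.groupby("pair_id")["closeness"].mean()
    return median_split(mean_close.index.tolist(), mean_close.values,
                        condition="overall")


def _matched_windows(a: PairedVmhrv, b: PairedVmhrv
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Viewer pNN50 values on window start times kept in both sessions."""
    common, ia, ib = np.intersect1d(a.window_start_s, b.window_start_s,
                                    return_indices=True)
    return a.viewer_pnn50[ia], b.viewer_pnn50[ib]


def run_battery(ratings: pd.DataFrame,
                paired: Mapping[tuple[int, str], PairedVmhrv] | None = None,
                alpha_between: float = ALPHA_BETWEEN,
                alpha_within: float = ALPHA_WITHIN,
                synchrony_method: str = "pearson") -> dict:
    """Run the full comparison battery and return a structured report.

    Sections
    --------
    stress_within
        Wilcoxon contrasts of gameplayer own-stress and viewer
        perceived-stress across condition pairs, within each (stable)
        closeness group; alpha_between (3 comparisons).
    concern_between
        Mann-Whitney HIGH vs LOW empathic concern per condition
        (per-condition split); alpha_between.
    empathy_correlations
        Pearson perceived-stress x own-stress per group per condition
        (affective empathy), plus Spearman closeness x concern per condition
        over all viewers.
    vmhrv_between
        Mann-Whitney HIGH vs LOW on pooled window-level viewer pNN50 per
        condition; alpha_between.  Requires ``paired``.
    vmhrv_within
        Wilcoxon on window-start-matched viewer pNN50 between every pair of
        the four conditions, pooled over each (stable) group's viewers;
        alpha_within (6 comparisons).
    synchrony
        Per-group mean pair synchrony per condition plus a between-group
        Mann-Whitney test.

    Cells whose inputs were excluded report ``insufficient data`` rather
    than aborting the run.  The report is a plain-JSON-serializable dict and
    is byte-deterministic for a given cohort.
    """
    from .synchrony import synchrony_r

    report: dict = {"schema_version": 1, "sections": {}}
    n_pairs = ratings["pair_id"].nunique()
    report["n_pairs"] = int(n_pairs)

    # --- groupings -------------------------------------------------------
    splits: dict[str, GroupAssignment | None] = {}
    for cond in CONDITIONS:
        sub = ratings[ratings["condition"] == cond]
        try:
            splits[cond] = median_split(sub["pair_id"].tolist(),
                                        sub["closeness"].values, cond)
        except ValueError:
            splits[cond] = None
    try:
        stable = overall_split(ratings)
    except ValueError:
        stable = None
    report["groups"] = {
        cond: ({"median_closeness": round(g.median_closeness, 6),
                "HIGH": g.group("HIGH"), "LOW": g.group("LOW")}
               if g else "degenerate")
        for cond, g in splits.items()
    }
    if stable is not None:
        report["groups"]["overall"] = {
            "median_closeness": round(stable.median_closeness, 6),
            "HIGH": stable.group("HIGH"), "LOW": stable.group("LOW"),
        }

    # --- (a) stress contrasts across conditions, within groups ----------
    cells = []
    for measure in ("player_stress", "perceived_stress"):
        wide = _ratings_wide(ratings, measure)
        for label in ("HIGH", "LOW"):
            members = stable.group(label) if stable else []
            for c1, c2 in _STRESS_PAIRS:
                cell = {"measure": measure, "group": label,
                        "conditions": [c1, c2]}
                sub = wide.loc[wide.index.isin(members), [c1, c2]].dropna()
                try:
                    if len(sub) < 2:
                        raise ValueError("fewer than 2 pairs")
                    res = wilcoxon_signed_rank(sub[c1].values, sub[c2].values,
                                               alpha=alpha_between)
                    cell.update(_result_cell(res))
                except ValueError as e:
                    cell.update(_insufficient(str(e)))
                cells.append(cell)
    report["sections"]["stress_within"] = cells

    # --- (b) between-group empathic concern ------------------------------
    cells = []
    wide_concern = _ratings_wide(ratings, "concern")
    for cond in TEST_CONDITIONS:
        cell = {"measure": "concern", "condition": cond}
        g = splits[cond]
        try:
            if g is None:
                raise ValueError("degenerate closeness split")
            hi = wide_concern.loc[wide_concern.index.isin(g.group("HIGH")), cond].dropna()
            lo = wide_concern.loc[wide_concern.index.isin(g.group("LOW")), cond].dropna()
            if len(hi) < 2 or len(lo) < 2:
                raise ValueError("fewer than 2 viewers per group")
            res = mann_whitney_u(hi.values, lo.values, alpha=alpha_between)
            cell.update(_result_cell(res))
        except ValueError as e:
            cell.update(_insufficient(str(e)))
        cells.append(cell)
    report["sections"]["concern_between"] = cells

    # --- (c) empathy correlations ----------------------------------------
    cells = []
    for cond in TEST_CONDITIONS:
        sub = ratings[ratings["condition"] == cond].set_index("pair_id")
        g = splits[cond]
        for label in ("HIGH", "LOW"):
            cell = {"measure": "affective_empathy", "condition": cond,
                    "group": label}
            try:
                if g is None:
                    raise ValueError("degenerate closeness split")
                members = sub.loc[sub.index.isin(g.group(label))]
                if len(members) < 3:
                    raise ValueError("fewer than 3 viewers")
                res = rank_correlation(members["perceived_stress"].values,
                                       members["own_stress"].values,
                                       method="pearson", alpha=0.05)
                cell.update(_result_cell(res))
            except ValueError as e:
                cell.update(_insufficient(str(e)))
            cells.append(cell)
        cell = {"measure": "closeness_vs_concern", "condition": cond,
                "group": "ALL"}
        try:
            res = rank_correlation(sub["closeness"].values,
                                   sub["concern"].values,
                                   method="spearman", alpha=0.05)
            cell.update(_result_cell(res))
        except ValueError as e:
            cell.update(_insufficient(str(e)))
        cells.append(cell)
    report["sections"]["empathy_correlations"] = cells

    if paired is not None:
        kept = {k: v for k, v in paired.items() if not v.dropped}

        # --- (d) between-group vmHRV on pooled windows -------------------
        cells = []
        for cond in TEST_CONDITIONS:
            cell = {"measure": "pnn50_windows", "condition": cond}
            g = splits[cond]
            try:
                if g is None:
                    raise ValueError("degenerate closeness split")
                pools = {}
                for label in ("HIGH", "LOW"):
                    vals = [kept[(p, cond)].viewer_pnn50
                            for p in g.group(label) if (p, cond) in kept]
                    pools[label] = (np.concatenate(vals) if vals
                                    else np.empty(0))
                if min(len(pools["HIGH"]), len(pools["LOW"])) < 2:
                    raise ValueError("fewer than 2 windows per group")
                res = mann_whitney_u(pools["HIGH"], pools["LOW"],
                                     alpha=alpha_between)
                cell.update(_result_cell(res))
            except ValueError as e:
                cell.update(_insufficient(str(e)))
            cells.append(cell)
        report["sections"]["vmhrv_between"] = cells

        # --- (e) within-group vmHRV across conditions --------------------
        cells = []
        for label in ("HIGH", "LOW"):
            members = stable.group(label) if stable else []
            for c1, c2 in _WITHIN_PAIRS:
                cell = {"measure": "pnn50_windows", "group": label,
                        "conditions": [c1, c2]}
                xs, ys = [], []
                for p in members:
                    if (p, c1) in kept and (p, c2) in kept:
                        a, b = _matched_windows(kept[(p, c1)], kept[(p, c2)])
                        xs.append(a)
                        ys.append(b)
                try:
                    if stable is None:
                        raise ValueError("degenerate closeness split")
                    x = np.concatenate(xs) if xs else np.empty(0)
                    y = np.concatenate(ys) if ys else np.empty(0)
                    if len(x) < 2:
                        raise ValueError("fewer than 2 matched windows")
                    res = wilcoxon_signed_rank(x, y, alpha=alpha_within)
                    cell.update(_result_cell(res))
                except ValueError as e:
                    cell.update(_insufficient(str(e)))
                cells.append(cell)
        report["sections"]["vmhrv_within"] = cells

        # --- (f) synchrony summary ---------------------------------------
        cells = []
        for cond in TEST_CONDITIONS:
            cell = {"measure": f"synchrony_{synchrony_method}",
                    "condition": cond}
            g = splits[cond]
            try:
                if g is None:
                    raise ValueError("degenerate closeness split")
                means = {}
                groups_r = {}
                for label in ("HIGH", "LOW"):
                    rs = [synchrony_r(kept[(p, cond)], method=synchrony_method,
                                      pair_id=p, condition=cond).r
                          for p in g.group(label) if (p, cond) in kept]
                    groups_r[label] = np.asarray(rs)
                    means[label] = (round(float(np.mean(rs)), 6)
                                    if rs else None)
                cell["mean_r"] = means
                cell["n_pairs"] = {lab: int(len(v))
                                   for lab, v in groups_r.items()}
                if min(len(groups_r["HIGH"]), len(groups_r["LOW"])) < 2:
                    raise ValueError("fewer than 2 pairs per group")
                res = mann_whitney_u(groups_r["HIGH"], groups_r["LOW"],
                                     alpha=alpha_between)
                cell.update(_result_cell(res))
            except ValueError as e:
                cell.update(_insufficient(str(e)))
            cells.append(cell)
        report["sections"]["synchrony"] = cells

    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten a battery report into one row per cell."""
    rows = []
    for section, cells in report["sections"].items():
        for cell in cells:
            row = {"section": section}
            for key, val in cell.items():
                row[key] = (",".join(val) if isinstance(val, list)
                            and key == "conditions" else val)
            rows.append(row)
    df = pd.DataFrame(rows)
    front = [c for c in ("section", "measure", "group", "condition",
                         "conditions") if c in df.columns]
    rest = [c for c in df.columns if c not in front]
    return df[front + rest]
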