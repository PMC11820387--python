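"""Rank tests against independent enumeration oracles, plus the battery."""

import itertools
import json

import numpy as np
import pytest
import scipy.stats as sps

import dyadsync as ds
from dyadsync.preprocess import perfect_quality
from dyadsync.stats import (effect_size_r, mann_whitney_u, median_split,
                            overall_split, rank_correlation, run_battery,
                            report_to_frame, wilcoxon_signed_rank)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive, no rankdata reuse)
# ---------------------------------------------------------------------------

def oracle_mw_exact_p(x, y):
    """Exact two-sided MW p by pair-counting U over every group labeling."""
    def u_min(a, b):
        u = sum(1.0 if ai > bj else 0.5 if ai == bj else 0.0
                for ai in a for bj in b)
        return min(u, len(a) * len(b) - u)

    pooled = list(x) + list(y)
    obs = u_min(x, y)
    n1 = len(x)
    count = total = 0
    for subset in itertools.combinations(range(len(pooled)), n1):
        a = [pooled[i] for i in subset]
        b = [pooled[i] for i in range(len(pooled)) if i not in subset]
        total += 1
        if u_min(a, b) <= obs + 1e-9:
            count += 1
    return count / total


def oracle_wilcoxon_exact_p(x, y):
    """Exact two-sided Wilcoxon p by sign enumeration with naive ranks."""
    d = [xi - yi for xi, yi in zip(x, y) if xi != yi]
    mags = sorted(abs(v) for v in d)
    ranks = [np.mean([i + 1 for i, m in enumerate(mags) if m == abs(v)])
             for v in d]
    w_sum = sum(ranks)
    w_obs = min(sum(r for r, v in zip(ranks, d) if v > 0),
                sum(r for r, v in zip(ranks, d) if v < 0))
    count = total = 0
    for signs in itertools.product((1, -1), repeat=len(d)):
        wp = sum(r for r, s in zip(ranks, signs) if s > 0)
        total += 1
        if min(wp, w_sum - wp) <= w_obs + 1e-9:
            count += 1
    return count / total


# ---------------------------------------------------------------------------


class TestMedianSplit:
    def test_even_split_on_distinct_values(self):
        g = median_split([0, 1, 2, 3], [10, 80, 20, 90], "ActiveHard")
        assert g.group("HIGH") == [1, 3]
        assert g.group("LOW") == [0, 2]
        assert g.median_closeness == pytest.approx(50.0)

    def test_ties_at_median_fall_low(self):
        g = median_split([0, 1, 2], [30, 30, 90], "")
        assert g.group("HIGH") == [2]
        assert g.group("LOW") == [0, 1]

    def test_too_few_viewers_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            median_split([0], [50])

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split([0, 1, 2], [40, 40, 40])


class TestMannWhitney:
    def test_disjoint_samples_exact_p(self):
        # x entirely below y: U_min = 0, exact p = 2 / C(6,3) = 0.1
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.exact
        assert res.p == pytest.approx(0.1)
        assert res.z < 0  # x ranks lower

    def test_exact_matches_oracle_on_random_draws(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            n1 = rng.integers(3, 6)
            n2 = rng.integers(3, 13 - n1)
            x = rng.normal(size=n1)
            y = rng.normal(0.5, 1.0, size=n2)
            res = mann_whitney_u(x, y)
            assert res.exact
            assert res.p == pytest.approx(oracle_mw_exact_p(x, y))

    def test_approx_matches_scipy_on_larger_samples(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            x = rng.normal(size=15)
            y = rng.normal(0.4, 1.2, size=18)
            res = mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(x, y, method="asymptotic")
            assert not res.exact
            assert res.p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_approx_close_to_exact_in_overlap_regime(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(0.3, 1.0, size=6)
            exact = mann_whitney_u(x, y, exact=True).p
            approx = mann_whitney_u(x, y, exact=False).p
            assert abs(exact - approx) <= 0.05

    def test_symmetric_in_sample_order(self):
        x, y = [3.1, 4.0, 2.2, 5.5], [4.4, 6.1, 3.3, 7.0, 5.0]
        a, b = mann_whitney_u(x, y), mann_whitney_u(y, x)
        assert a.statistic == b.statistic
        assert a.p == pytest.approx(b.p)
        assert a.z == pytest.approx(-b.z)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            mann_whitney_u([], [1.0, 2.0])


class TestWilcoxon:
    def test_uniform_shift_exact_p(self):
        # five nonzero same-sign differences: W = 0, p = 2 / 2^5
        res = wilcoxon_signed_rank([5, 8, 11, 3, 9], [1, 2, 4, 1, 5])
        assert res.statistic == 0.0
        assert res.exact
        assert res.p == pytest.approx(0.0625)

    def test_exact_matches_oracle_on_random_draws(self):
        rng = np.random.default_rng(41)
        for _ in range(15):
            n = rng.integers(4, 11)
            x = rng.normal(size=n)
            y = x + rng.normal(0.4, 0.8, size=n)
            res = wilcoxon_signed_rank(x, y)
            assert res.exact
            assert res.p == pytest.approx(oracle_wilcoxon_exact_p(x, y))

    def test_approx_matches_scipy_on_larger_samples(self):
        rng = np.random.default_rng(43)
        for _ in range(10):
            x = rng.normal(size=25)
            y = x + rng.normal(0.3, 1.0, size=25)
            res = wilcoxon_signed_rank(x, y)
            ref = sps.wilcoxon(x, y, correction=True, method="approx")
            assert not res.exact
            assert res.p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_antisymmetric_z_under_swap(self):
        x = [10.0, 14.0, 9.0, 20.0, 13.0, 8.0]
        y = [12.0, 11.0, 15.0, 16.0, 19.0, 7.0]
        a, b = wilcoxon_signed_rank(x, y), wilcoxon_signed_rank(y, x)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_zero_differences_dropped_but_n_reported_as_supplied(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 10], [1, 2, 3, 5, 4])
        assert res.n == 5  # pairs supplied, per reporting convention

    def test_identical_samples_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            wilcoxon_signed_rank([1.0, 2.0], [1.0])


class TestEffectSize:
    def test_definition(self):
        assert effect_size_r(2.982, 12) == pytest.approx(2.982 / np.sqrt(12))
        assert effect_size_r(-1.5, 9) == pytest.approx(-0.5)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            effect_size_r(1.0, 0)

    def test_battery_cells_obey_z_over_sqrt_n(self):
        # every rank-test cell in a battery report satisfies r = Z / sqrt(N)
        sim = ds.SimConfig(n_pairs=8, seed=61)
        cohort = ds.simulate_cohort(sim, ds.RatingEffectConfig(seed=61),
                                    signal_level="ibi")
        report = run_battery(cohort.ratings, _paired_from(cohort))
        checked = 0
        for section in ("stress_within", "concern_between", "vmhrv_between",
                        "vmhrv_within"):
            for cell in report["sections"][section]:
                if cell["p"] is None:
                    continue
                assert cell["effect_r"] == pytest.approx(
                    cell["z"] / np.sqrt(cell["n"]), abs=1e-6)
                checked += 1
        assert checked >= 5


class TestRankCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(1.0, 11.0)
        res = rank_correlation(x, 2 * x + 1, method="pearson")
        assert res.statistic == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_monotone_nonlinear_relation(self):
        x = np.arange(-5.0, 6.0)
        res = rank_correlation(x, x ** 3, method="spearman")
        assert res.statistic == pytest.approx(1.0)
        pear = rank_correlation(x, x ** 3, method="pearson")
        assert pear.statistic < 1.0

    def test_exact_permutation_small_n(self):
        # oracle: naive enumeration of all pairings via scipy's pearsonr
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=6), rng.normal(size=6)
        res = rank_correlation(x, y, method="pearson")
        assert res.exact
        r_obs = abs(sps.pearsonr(x, y).statistic)
        hits = total = 0
        for perm in itertools.permutations(range(6)):
            total += 1
            if abs(sps.pearsonr(x, y[list(perm)]).statistic) >= r_obs - 1e-9:
                hits += 1
        assert res.p == pytest.approx(hits / total)

    def test_approx_p_matches_scipy_t_approximation(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        res = rank_correlation(x, y, method="spearman")
        ref = sps.spearmanr(x, y)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_errors(self):
        with pytest.raises(ValueError, match="n >= 3"):
            rank_correlation([1, 2], [3, 4])
        with pytest.raises(ValueError, match="zero-variance"):
            rank_correlation([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------


def _paired_from(cohort):
    q = perfect_quality(300.0)
    paired = {}
    for key, sess in cohort.sessions.items():
        paired[key] = ds.pair_windows(
            ds.windowed_pnn50(sess.viewer_ibi, q),
            ds.windowed_pnn50(sess.player_ibi, q))
    return paired


@pytest.fixture(scope="module")
def cohort():
    sim = ds.SimConfig(n_pairs=8, seed=71)
    return ds.simulate_cohort(sim, ds.RatingEffectConfig(seed=71),
                              signal_level="ibi")


@pytest.fixture(scope="module")
def report(cohort):
    return run_battery(cohort.ratings, _paired_from(cohort))


class TestBattery:
    def test_section_structure(self, report):
        secs = report["sections"]
        assert set(secs) == {"stress_within", "concern_between",
                             "empathy_correlations", "vmhrv_between",
                             "vmhrv_within", "synchrony"}
        assert len(secs["stress_within"]) == 12   # 2 measures x 2 groups x 3
        assert len(secs["concern_between"]) == 3
        assert len(secs["vmhrv_between"]) == 3
        assert len(secs["vmhrv_within"]) == 12    # 2 groups x C(4,2)
        assert len(secs["synchrony"]) == 3

    def test_alpha_levels_applied(self, report):
        for cell in report["sections"]["concern_between"]:
            if cell["alpha"] is not None:
                assert cell["alpha"] == 0.017
        for cell in report["sections"]["vmhrv_within"]:
            if cell["alpha"] is not None:
                assert cell["alpha"] == 0.008

    def test_byte_deterministic(self, cohort, report):
        again = run_battery(cohort.ratings, _paired_from(cohort))
        assert json.dumps(report, sort_keys=True) == \
            json.dumps(again, sort_keys=True)

    def test_json_serializable_and_flattenable(self, report):
        json.dumps(report)
        df = report_to_frame(report)
        assert len(df) == sum(len(c) for c in report["sections"].values())
        assert "p" in df.columns

    def test_ratings_only_battery_omits_physiology_sections(self, cohort):
        rep = run_battery(cohort.ratings, None)
        assert "vmhrv_between" not in rep["sections"]
        assert "stress_within" in rep["sections"]

    def test_overall_split_stable_across_conditions(self, cohort):
        g = overall_split(cohort.ratings)
        assert set(g.labels.values()) <= {"HIGH", "LOW"}
        assert len(g.labels) == cohort.ratings["pair_id"].nunique()
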