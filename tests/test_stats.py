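"""Statistical battery: contingency tests, FDR, CMH, t-tests, correlations,
ANOVA, and the logistic odds-ratio models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

import nftburden as nb
from nftburden.errors import DesignError, DomainError, SeparationError


# ---------------------------------------------------------------------------
# Chi-square tests
# ---------------------------------------------------------------------------

class TestChiSquare:
    def test_proportional_rows_give_zero_statistic(self):
        res = nb.chi_square_2x2([[10, 20], [30, 60]], correction="none")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(DomainError):
            nb.chi_square_2x2([[0, 0], [5, 5]])

    def test_identical_column_distributions(self):
        res = nb.chi_square_rxc([[5, 5], [7, 7], [3, 3]])
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 2

    def test_rxc_matches_formula_oracle(self, rng):
        table = rng.integers(5, 60, (3, 3)).astype(float)
        res = nb.chi_square_rxc(table)
        row = table.sum(1, keepdims=True)
        col = table.sum(0, keepdims=True)
        expect = row @ col / table.sum()
        stat = ((table - expect) ** 2 / expect).sum()
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.df == 4


# ---------------------------------------------------------------------------
# Benjamini–Hochberg FDR
# ---------------------------------------------------------------------------

def bh_oracle(p):
    """Step-up definition: sort, scale by m/rank, reverse cumulative min,
    unsort, cap at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert nb.bh_fdr([0.031])[0] == pytest.approx(0.031)

    def test_hand_worked_step_up(self):
        assert nb.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_definition_oracle(self, rng):
        p = rng.random(200)
        assert nb.bh_fdr(p) == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            nb.bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=40))
    def test_adjusted_at_least_raw_capped_and_order_preserving(self, ps):
        adj = nb.bh_fdr(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        # weak order preservation: smaller raw p never gets a larger adjustment
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


# ---------------------------------------------------------------------------
# Cochran–Mantel–Haenszel
# ---------------------------------------------------------------------------

class TestCMH:
    def test_single_stratum_equals_simple_or(self):
        t = np.array([[12, 8], [5, 15]], float)
        or_pooled, _ = nb.cmh_pooled_or([t])
        assert or_pooled == pytest.approx((12 * 15) / (8 * 5))

    def test_two_identical_strata_closed_form(self):
        t = [[10, 20], [20, 10]]
        or_pooled, _ = nb.cmh_pooled_or([t, t])
        assert or_pooled == pytest.approx(0.25)

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_copies_of_one_stratum_are_invariant(self, k):
        t = np.array([[30, 10], [12, 25]], float)
        single, _ = nb.cmh_pooled_or([t])
        pooled, _ = nb.cmh_pooled_or([t] * k)
        assert pooled == pytest.approx(single)

    def test_degenerate_strata_rejected(self):
        with pytest.raises(DomainError):
            nb.cmh_pooled_or([np.zeros((2, 2))])

    def test_adjusts_for_a_common_cause(self, rng):
        # binary stratum drives both exposure and outcome; conditional OR = 1
        n = 4000
        s = rng.random(n) < 0.5
        e = (rng.random(n) < np.where(s, 0.7, 0.2)).astype(float)
        y = (rng.random(n) < np.where(s, 0.7, 0.2)).astype(float)
        crude = nb.cmh_pooled_or([pd.crosstab(e, y).to_numpy()[::-1, ::-1]])[0]
        strata = []
        for lev in (False, True):
            m = s == lev
            strata.append(pd.crosstab(e[m], y[m]).to_numpy()[::-1, ::-1])
        pooled, _ = nb.cmh_pooled_or(strata)
        assert abs(np.log(pooled)) < abs(np.log(crude))
        assert pooled == pytest.approx(1.0, abs=0.35)

    def test_age_stratified_tables_median_split(self):
        e = np.array([1, 1, 0, 0, 1, 0])
        y = np.array([1, 0, 1, 0, 1, 0])
        age = np.array([60, 70, 80, 90, 95, 99])
        tables = nb.age_stratified_tables(e, y, age)
        assert len(tables) == 2
        assert sum(t.sum() for t in tables) == 6


# ---------------------------------------------------------------------------
# t-tests, correlations, ANOVA
# ---------------------------------------------------------------------------

def welch_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    from scipy.stats import t as tdist

    return t, 2 * tdist.sf(abs(t), df)


class TestGroupTTest:
    def test_identical_groups(self):
        t, p = nb.group_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_welch_formula(self):
        a = [23.1, 25.2, 21.8, 24.0, 26.7, 22.5]
        b = [19.4, 20.1, 22.3, 18.8, 21.0]
        t, p = nb.group_t_test(a, b)
        te, pe = welch_oracle(a, b)
        assert t == pytest.approx(te, abs=1e-10)
        assert p == pytest.approx(pe, abs=1e-10)

    def test_one_sd_shift_detected(self, rng):
        a = rng.normal(0, 1, 100)
        b = rng.normal(1, 1, 100)
        _, p = nb.group_t_test(a, b)
        assert p < 0.001

    def test_degenerate_unequal_means_rejected(self):
        with pytest.raises(DomainError):
            nb.group_t_test([1.0, 1.0], [2.0, 2.0])


class TestCorrelations:
    def test_monotone_nonlinear(self):
        x = np.arange(1.0, 20.0)
        y = np.exp(x / 3)
        rho, _ = nb.spearman_corr(x, y)
        r, _ = nb.pearson_corr(x, y)
        assert rho == pytest.approx(1.0)
        assert r < 1.0

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert nb.spearman_corr(x, -x)[0] == pytest.approx(-1.0)
        assert nb.pearson_corr(x, -x)[0] == pytest.approx(-1.0)

    def test_bivariate_normal_recovery(self, rng):
        cov = [[1, 0.3], [0.3, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=700)
        r, p = nb.pearson_corr(xy[:, 0], xy[:, 1])
        assert abs(r - 0.3) < 0.08
        assert p < 0.01

    def test_constant_vector_is_undefined(self):
        rho, p = nb.spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho)


def anova_oracle(values, f1, f2):
    """Hand-computed Type-I sums of squares on a balanced two-way design."""
    df = pd.DataFrame({"v": values, "a": f1, "b": f2})
    grand = df.v.mean()
    n_cell = df.groupby(["a", "b"]).size().iloc[0]
    ss_a = sum(len(g) * (g.v.mean() - grand) ** 2 for _, g in df.groupby("a"))
    ss_b = sum(len(g) * (g.v.mean() - grand) ** 2 for _, g in df.groupby("b"))
    cell_means = df.groupby(["a", "b"]).v.mean()
    ss_cells = n_cell * sum(
        (cm - grand) ** 2 for cm in cell_means
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(
        ((g.v - g.v.mean()) ** 2).sum() for _, g in df.groupby(["a", "b"])
    )
    return ss_a, ss_b, ss_ab, ss_err


class TestTwoWayAnova:
    def test_matches_hand_computed_sums_of_squares(self, rng):
        regions_f = np.repeat(["hip", "ent"], 20)
        status_f = np.tile(np.repeat(["NCI", "CI"], 10), 2)
        values = rng.normal(0, 1, 40) + (status_f == "CI") * 0.8
        tab = nb.two_way_anova(values, regions_f, status_f)
        ss_a, ss_b, ss_ab, ss_err = anova_oracle(values, regions_f, status_f)
        assert tab.loc["region", "sum_sq"] == pytest.approx(ss_a, abs=1e-9)
        assert tab.loc["status", "sum_sq"] == pytest.approx(ss_b, abs=1e-9)
        assert tab.loc["region:status", "sum_sq"] == pytest.approx(ss_ab, abs=1e-9)
        assert tab.loc["residual", "sum_sq"] == pytest.approx(ss_err, abs=1e-9)

    def test_pure_status_effect_leaves_region_flat(self, rng):
        status_f = np.tile(np.repeat(["NCI", "CI"], 50), 2)
        regions_f = np.repeat(["hip", "ent"], 100)
        values = (status_f == "CI") * 2.0 + rng.normal(0, 1e-6, 200)
        tab = nb.two_way_anova(values, regions_f, status_f)
        assert tab.loc["status", "F"] > 1e6
        assert tab.loc["region", "F"] < 10

    def test_empty_cell_rejected(self):
        with pytest.raises(DesignError):
            nb.two_way_anova([1.0, 2.0, 3.0], ["a", "a", "b"], ["x", "y", "x"])


# ---------------------------------------------------------------------------
# Logistic odds ratios
# ---------------------------------------------------------------------------

class TestLogisticOR:
    def test_affine_rescaling_invariance_when_standardized(self, rng):
        n = 300
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-0.5 * x))).astype(float)
        a = nb.fit_logistic_or(y, x, standardize=True)
        b = nb.fit_logistic_or(y, 3.7 * x - 12.0, standardize=True)
        assert a.odds_ratio == pytest.approx(b.odds_ratio, abs=1e-9)
        assert a.p_raw == pytest.approx(b.p_raw, abs=1e-9)

    def test_separation_detected(self):
        y = np.array([0.0] * 20 + [1.0] * 20)
        with pytest.raises(SeparationError):
            nb.fit_logistic_or(y, y)

    def test_constant_predictor_rejected(self):
        y = np.array([0.0, 1.0] * 10)
        with pytest.raises(DomainError):
            nb.fit_logistic_or(y, np.ones(20))

    def test_null_coverage(self):
        # predictor independent of outcome: the 95% CI should cover OR = 1
        # in at least 93 of 100 seeded replicates
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = (rng.random(1000) < 0.5).astype(float)
            x = rng.normal(0, 1, 1000)
            res = nb.fit_logistic_or(y, x)
            hits += res.ci95_low <= 1.0 <= res.ci95_high
        assert hits >= 93

    def test_battery_assigns_fdr_within_family(self, rng):
        n = 200
        y = (rng.random(n) < 0.5).astype(float)
        measures = {f"m{i}": rng.normal(0, 1, n) for i in range(5)}
        results = nb.or_battery(y, measures)
        raws = [r.p_raw for r in results]
        assert [r.p_fdr for r in results] == pytest.approx(bh_oracle(raws))
        for r in results:
            assert r.p_fdr >= r.p_raw - 1e-15
            assert r.ci95_low <= r.odds_ratio <= r.ci95_high


class TestORCurve:
    def test_single_radius_reduces_to_plain_fit(self, rng):
        n = 60
        sweeps = []
        ccs = rng.uniform(0, 1, n)
        counts = rng.integers(10, 200, n)
        for i in range(n):
            sweeps.append(nb.ClusteringSweep(
                subject_id=f"s{i}", r_values_px=[800.0],
                mean_cc=[ccs[i]], n_nfts=int(counts[i]),
            ))
        y = (rng.random(n) < 0.5).astype(float)
        curve = nb.or_curve_over_r(sweeps, y, include_n_nfts=True)
        direct = nb.fit_logistic_or(
            y, ccs, covariates=pd.DataFrame({"n_nfts": counts.astype(float)}),
        )
        assert curve.odds_ratio[0] == pytest.approx(direct.odds_ratio, rel=1e-9)
        assert curve.p_raw[0] == pytest.approx(direct.p_raw, rel=1e-9)
        assert curve.p_fdr[0] == pytest.approx(direct.p_raw, rel=1e-9)

    def test_band_contains_point_estimate(self, small_bundle):
        sweeps = [
            nb.clustering_sweep(
                np.array([[n.centroid_x, n.centroid_y] for n in s.nfts]),
                r_start_px=400, r_stop_px=1200, r_step_px=400,
                subject_id=s.subject_id,
            )
            for s in small_bundle.slides
        ]
        y = np.array([r.cognitive_status == nb.CI for r in small_bundle.records],
                     float)
        curve = nb.or_curve_over_r(sweeps, y)
        ok = np.isfinite(curve.odds_ratio)
        assert ok.any()
        assert np.all(curve.ci95_low[ok] <= curve.odds_ratio[ok])
        assert np.all(curve.odds_ratio[ok] <= curve.ci95_high[ok])
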