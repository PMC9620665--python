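"""Clinicopathologic statistical battery.

Everything downstream of the burden metrics lives here: contingency tests
(Pearson chi-square with optional Yates continuity correction, and the
Cochran–Mantel–Haenszel stratified pooled odds ratio used for age
adjustment of categorical associations), Welch t-tests, rank and product
correlations, two-way ANOVA, Benjamini–Hochberg FDR control, and the
logistic odds-ratio models that relate each burden measure to cognitive
status.

Continuous predictors are z-scored before logistic fits by default, so
reported odds ratios are per standard deviation of the measure — burden
measures live on wildly different native scales (counts/mm² vs 0–1
fractions) and per-SD ORs are the only comparable scale.  Confidence
intervals and p-values are Wald-based.

Model fitting is delegated to statsmodels; this module owns the study
design (covariate sets, FDR families, stratification rules) and the
result containers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import DesignError, DomainError, SeparationError
from .spatial import ClusteringSweep

Z_95 = sps.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class ORResult:
    """Logistic odds ratio for one burden measure (per SD if standardized)."""

    measure_name: str
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    p_raw: float
    p_fdr: Optional[float] = None
    adjusted_for_age: bool = False
    covariates: list[str] = field(default_factory=list)
    n: int = 0


@dataclass
class ContingencyResult:
    statistic: float
    df: int
    p_value: float
    correction: str  # "none" or "yates"
    table_dims: tuple[int, int]


@dataclass
class ORCurve:
    """Per-radius odds ratios for the clustering metric (Fig-6-style)."""

    r_values_px: np.ndarray
    odds_ratio: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    n_per_r: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_px": self.r_values_px,
                "odds_ratio": self.odds_ratio,
                "ci95_low": self.ci95_low,
                "ci95_high": self.ci95_high,
                "p_raw": self.p_raw,
                "p_fdr": self.p_fdr,
                "n": self.n_per_r,
            }
        )


# ---------------------------------------------------------------------------
# Logistic odds-ratio models
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise DomainError("cannot standardize a constant predictor")
    return (x - x.mean()) / sd


def fit_logistic_or(
    outcome,
    predictor,
    covariates: Optional[pd.DataFrame] = None,
    standardize: bool = True,
    measure_name: str = "",
    adjusted_for_age: bool = False,
) -> ORResult:
    """Maximum-likelihood logistic fit of a binary outcome on one predictor.

    With ``standardize`` (the default) the predictor and all continuous
    covariates are z-scored, so the returned odds ratio is per SD.  The CI
    is the Wald 95% interval ``exp(beta ± 1.96 se)`` and the p-value the
    two-sided Wald test on the predictor coefficient.

    Raises :class:`SeparationError` on (quasi-)complete separation and
    :class:`DomainError` for constant predictors or single-class outcomes.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise DomainError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise DomainError("outcome has a single class")
    if np.ptp(x) == 0:
        raise DomainError(f"predictor {measure_name or 'x'} is constant")

    cols = {"predictor": _zscore(x) if standardize else x}
    cov_names: list[str] = []
    if covariates is not None:
        for name in covariates.columns:
            v = np.asarray(covariates[name], dtype=float)
            if standardize and np.ptp(v) > 0 and len(np.unique(v)) > 2:
                v = _zscore(v)
            cols[name] = v
            cov_names.append(str(name))
    X = sm.add_constant(pd.DataFrame(cols), has_constant="add")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(
                f"separation while fitting {measure_name or 'predictor'}: {exc}"
            ) from None
    beta = res.params["predictor"]
    se = res.bse["predictor"]
    if not res.mle_retvals.get("converged", True) or abs(beta) > 50 or not np.isfinite(se):
        raise SeparationError(
            f"logistic fit for {measure_name or 'predictor'} did not converge "
            "(quasi-complete separation?)"
        )
    return ORResult(
        measure_name=measure_name,
        odds_ratio=float(np.exp(beta)),
        ci95_low=float(np.exp(beta - Z_95 * se)),
        ci95_high=float(np.exp(beta + Z_95 * se)),
        p_raw=float(res.pvalues["predictor"]),
        adjusted_for_age=adjusted_for_age,
        covariates=cov_names,
        n=int(len(y)),
    )


def or_curve_over_r(
    sweeps: Sequence[ClusteringSweep],
    outcome,
    age: Optional[Sequence[float]] = None,
    include_n_nfts: bool = True,
    standardize: bool = True,
) -> ORCurve:
    """Odds ratio of impairment on mean clustering coefficient at each radius.

    Every fit includes the subject's total NFT count as a nuisance covariate
    (unless ``include_n_nfts`` is off) and, optionally, age.  Subjects whose
    sweep is undefined at a radius (fewer than 3 NFTs) are dropped from that
    radius's fit.  Raw p-values are FDR-corrected across the radius grid.
    """
    if not sweeps:
        raise DomainError("no sweeps supplied")
    rs = sweeps[0].r_values_px
    for sw in sweeps[1:]:
        if not np.array_equal(sw.r_values_px, rs):
            raise DomainError("sweeps must share one radius grid")
    y_all = np.asarray(outcome, dtype=float)
    if len(y_all) != len(sweeps):
        raise DomainError("outcome length must match number of sweeps")
    age_all = None if age is None else np.asarray(age, dtype=float)
    cc = np.vstack([sw.mean_cc for sw in sweeps])  # subjects x radii
    n_nfts = np.array([sw.n_nfts for sw in sweeps], dtype=float)

    m = len(rs)
    out = {k: np.full(m, np.nan) for k in
           ("odds_ratio", "ci95_low", "ci95_high", "p_raw")}
    n_per_r = np.zeros(m, dtype=int)
    for k in range(m):
        col = cc[:, k]
        mask = np.isfinite(col)
        y = y_all[mask]
        if mask.sum() < 4 or len(np.unique(y)) < 2 or np.ptp(col[mask]) == 0:
            continue
        cov = {}
        if include_n_nfts:
            cov["n_nfts"] = n_nfts[mask]
        if age_all is not None:
            cov["age"] = age_all[mask]
        try:
            res = fit_logistic_or(
                y, col[mask],
                covariates=pd.DataFrame(cov) if cov else None,
                standardize=standardize,
                measure_name=f"mean_cc@r={rs[k]:g}",
            )
        except (SeparationError, DomainError):
            continue
        out["odds_ratio"][k] = res.odds_ratio
        out["ci95_low"][k] = res.ci95_low
        out["ci95_high"][k] = res.ci95_high
        out["p_raw"][k] = res.p_raw
        n_per_r[k] = res.n

    p_fdr = np.full(m, np.nan)
    ok = np.isfinite(out["p_raw"])
    if ok.any():
        p_fdr[ok] = bh_fdr(out["p_raw"][ok])
    return ORCurve(
        r_values_px=np.asarray(rs, dtype=float),
        odds_ratio=out["odds_ratio"],
        ci95_low=out["ci95_low"],
        ci95_high=out["ci95_high"],
        p_raw=out["p_raw"],
        p_fdr=p_fdr,
        n_per_r=n_per_r,
    )


# ---------------------------------------------------------------------------
# Contingency tests
# ---------------------------------------------------------------------------

def _check_table(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise DomainError("contingency table must hold nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DomainError("contingency table has a zero margin")
    return t


def chi_square_2x2(table, correction: str = "yates") -> ContingencyResult:
    """Pearson chi-square on a 2×2 table, Yates-corrected by default."""
    t = _check_table(table)
    if t.shape != (2, 2):
        raise DomainError(f"expected a 2x2 table, got {t.shape}")
    if correction not in ("yates", "none"):
        raise DomainError("correction must be 'yates' or 'none'")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=(correction == "yates"))
    return ContingencyResult(statistic=float(stat), df=int(dof), p_value=float(p),
                             correction=correction, table_dims=(2, 2))


def chi_square_rxc(table) -> ContingencyResult:
    """Pearson chi-square on an r×c table, no continuity correction."""
    t = _check_table(table)
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return ContingencyResult(statistic=float(stat), df=int(dof), p_value=float(p),
                             correction="none", table_dims=t.shape)


def cmh_pooled_or(strata: Sequence) -> tuple[float, float]:
    """Mantel–Haenszel pooled odds ratio and CMH chi-square p over 2×2 strata.

    The pooled OR is ``sum(a_i d_i / n_i) / sum(b_i c_i / n_i)``; the test
    is the CMH chi-square with continuity correction (the statsmodels
    default), matching the classical Mantel–Haenszel procedure.
    """
    tables = [np.asarray(t, dtype=float) for t in strata]
    if not tables:
        raise DomainError("need at least one stratum")
    for t in tables:
        if t.shape != (2, 2) or np.any(t < 0):
            raise DomainError("each stratum must be a nonnegative 2x2 table")
        if t.sum() <= 0:
            raise DomainError("stratum with zero total")
    num = sum(t[0, 0] * t[1, 1] / t.sum() for t in tables)
    den = sum(t[0, 1] * t[1, 0] / t.sum() for t in tables)
    if num == 0 and den == 0:
        raise DomainError("all strata degenerate: no discordant pairs")
    st = StratifiedTable(np.dstack(tables))
    test = st.test_null_odds(correction=True)
    return float(num / den) if den > 0 else float("inf"), float(test.pvalue)


def age_stratified_tables(
    exposure, outcome, age, cut: Optional[float] = None
) -> list[np.ndarray]:
    """Split a 2×2 exposure/outcome cross-tab into two age strata.

    The default cut point is the cohort's median age ("two-level
    stratification"); rows are exposure +/-, columns outcome +/-.
    """
    e = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    a = np.asarray(age, dtype=float)
    if cut is None:
        cut = float(np.median(a))
    tables = []
    for in_stratum in (a < cut, a >= cut):
        t = np.array(
            [
                [np.sum((e == 1) & (y == 1) & in_stratum), np.sum((e == 1) & (y == 0) & in_stratum)],
                [np.sum((e == 0) & (y == 1) & in_stratum), np.sum((e == 0) & (y == 0) & in_stratum)],
            ],
            dtype=float,
        )
        tables.append(t)
    return tables


# ---------------------------------------------------------------------------
# Multiple-testing correction
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DomainError("p_values must be a 1-D vector")
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Group tests, correlations, ANOVA
# ---------------------------------------------------------------------------

def group_t_test(values_a, values_b, equal_var: bool = False) -> tuple[float, float]:
    """Two-sample t-test (Welch by default); returns (t, two-sided p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DomainError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise DomainError("both groups degenerate (zero variance, unequal means)")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties); (rho, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise DomainError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation; (r, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise DomainError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def two_way_anova(values, factor_region, factor_status) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction (Type-I sums of squares).

    Intended for balanced region × cognitive-status designs, where Type-I
    decomposition is unambiguous.  Returns a frame indexed by effect
    (region, status, region:status, residual) with sum_sq, df, F, p columns.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "region": np.asarray(factor_region, dtype=object),
            "status": np.asarray(factor_status, dtype=object),
        }
    )
    cells = df.groupby(["region", "status"], observed=True).size()
    n_regions = df["region"].nunique()
    n_status = df["status"].nunique()
    if n_regions < 2 or n_status < 2:
        raise DesignError("each factor needs at least 2 levels")
    if len(cells) < n_regions * n_status:
        raise DesignError("empty cell in the region x status design")
    fit = smf.ols("value ~ C(region) * C(status)", data=df).fit()
    tab = anova_lm(fit, typ=1)
    tab = tab.rename(
        index={
            "C(region)": "region",
            "C(status)": "status",
            "C(region):C(status)": "region:status",
            "Residual": "residual",
        }
    )
    return tab.rename(columns={"PR(>F)": "p"})


# ---------------------------------------------------------------------------
# The Table-2-shaped burden battery
# ---------------------------------------------------------------------------

def or_battery(
    outcome,
    measures: dict[str, np.ndarray],
    age: Optional[Sequence[float]] = None,
    nuisance: Optional[dict[str, pd.DataFrame]] = None,
    standardize: bool = True,
) -> list[ORResult]:
    """Fit the odds-of-impairment model for every burden measure.

    One logistic fit per entry of ``measures`` (name -> per-subject values);
    ``nuisance`` optionally maps a measure name to extra covariates that are
    always included for that measure (the clustering metric carries total
    NFT count).  When ``age`` is given every fit is age-adjusted.  Raw
    p-values are FDR-corrected across the battery (one family per
    adjustment condition).  Subjects with a missing value on a measure are
    dropped from that measure's fit (listwise deletion), with a log entry.
    """
    nuisance = nuisance or {}
    y_all = np.asarray(outcome, dtype=float)
    age_all = None if age is None else np.asarray(age, dtype=float)
    results = []
    for name, vals in measures.items():
        v = np.asarray(vals, dtype=float)
        mask = np.isfinite(v) & np.isfinite(y_all)
        extra = nuisance.get(name)
        cov = {}
        if extra is not None:
            for c in extra.columns:
                cov[c] = np.asarray(extra[c], dtype=float)
        if age_all is not None:
            cov["age"] = age_all
        if cov:
            for c in cov.values():
                mask &= np.isfinite(c)
        dropped = int((~mask).sum())
        if dropped:
            import logging
            logging.getLogger("nftburden").warning(
                "measure %s: %d subject(s) excluded (missing data)", name, dropped
            )
        cov_df = (
            pd.DataFrame({c: arr[mask] for c, arr in cov.items()}) if cov else None
        )
        results.append(
            fit_logistic_or(
                y_all[mask], v[mask], covariates=cov_df,
                standardize=standardize, measure_name=name,
                adjusted_for_age=age_all is not None,
            )
        )
    adj = bh_fdr([r.p_raw for r in results])
    for r, q in zip(results, adj):
        r.p_fdr = float(q)
    return results


def battery_to_frame(results: Sequence[ORResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "measure": r.measure_name,
                "odds_ratio": r.odds_ratio,
                "ci95_low": r.ci95_low,
                "ci95_high": r.ci95_high,
                "p_raw": r.p_raw,
                "p_fdr": r.p_fdr,
                "adjusted_for_age": r.adjusted_for_age,
                "n": r.n,
            }
            for r in results
        ]
    )
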