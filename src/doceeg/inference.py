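"""Clinical/statistical layer: routed two-sample tests, exact tests, FDR,
and confounder-adjusted outcome models.

Routing follows standard biostatistics practice for two-group cohorts:
Shapiro-Wilk normality in both groups gates Student's (pooled-variance) t
versus Mann-Whitney U; 2x2 categoricals use Fisher's exact test. Effect
sizes accompany every test (Cohen's d, rank-biserial r, Cramer's V).
Families of EEG comparisons are adjusted by Benjamini-Hochberg FDR.

Outcome models: multiple logistic regression for the binary 3-month
improvement flag and multiple linear regression for respiratory recovery
time, both adjusting for age, etiology (TBI vs CVD) and baseline CRS-R;
EEG metrics can be added as extra covariates and compared against the
reduced model with a likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import InvalidInputError, InvalidParameterError
from .synthetic import STATE_LADDER

DEFAULT_COVARIATES = ("group", "age", "etiology", "crsr_baseline")


@dataclass
class StatResult:
    """One two-group comparison: test, statistic, p, effect size."""

    test: str
    statistic: float
    p_raw: float
    effect_size: float
    effect_name: str
    p_fdr: float | None = None
    label: str = ""
    summaries: dict = dc_field(default_factory=dict)


@dataclass
class ModelFit:
    """A fitted outcome model with Wald inference per coefficient.

    ``params`` rows: coef, se, ci_low, ci_high and (for logistic) the
    exponentiated columns or/or_low/or_high.
    """

    outcome: str
    kind: str  # "logistic" | "linear"
    params: pd.DataFrame
    loglike: float
    n: int
    converged: bool = True
    separation: bool = False
    covariates: tuple[str, ...] = ()

    def coef(self, name: str) -> float:
        return float(self.params.loc[name, "coef"])


# ---------------------------------------------------------------------------
# two-sample machinery

def shapiro_route(group_a: np.ndarray, group_b: np.ndarray,
                  alpha: float = 0.05) -> str:
    """'t_test' iff Shapiro-Wilk p >= alpha in both groups, else 'mann_whitney'."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InvalidParameterError("Shapiro-Wilk needs at least 3 values per group")
    pa = stats.shapiro(a).pvalue
    pb = stats.shapiro(b).pvalue
    return "t_test" if (pa >= alpha and pb >= alpha) else "mann_whitney"


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def two_sample_t(group_a, group_b) -> StatResult:
    """Pooled-variance Student t (orientation A - B) with Cohen's d."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("need at least 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return StatResult("t_test", 0.0, 1.0, 0.0, "cohens_d")
        raise InvalidInputError(
            "degenerate input: zero variance in both groups with unequal means"
        )
    res = stats.ttest_ind(a, b, equal_var=True)
    return StatResult(
        test="t_test", statistic=float(res.statistic),
        p_raw=float(res.pvalue), effect_size=_cohens_d(a, b),
        effect_name="cohens_d",
        summaries={"mean_a": a.mean(), "sd_a": a.std(ddof=1), "n_a": a.size,
                   "mean_b": b.mean(), "sd_b": b.std(ddof=1), "n_b": b.size},
    )


def two_sample_t_from_stats(mean_a: float, sd_a: float, n_a: int,
                            mean_b: float, sd_b: float, n_b: int) -> StatResult:
    """Pooled t from summary statistics (equivalent to the raw-data path)."""
    res = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                     equal_var=True)
    sp2 = ((n_a - 1) * sd_a ** 2 + (n_b - 1) * sd_b ** 2) / (n_a + n_b - 2)
    d = 0.0 if sp2 == 0 else (mean_a - mean_b) / np.sqrt(sp2)
    return StatResult(
        test="t_test", statistic=float(res.statistic), p_raw=float(res.pvalue),
        effect_size=float(d), effect_name="cohens_d",
        summaries={"mean_a": mean_a, "sd_a": sd_a, "n_a": n_a,
                   "mean_b": mean_b, "sd_b": sd_b, "n_b": n_b},
    )


def mann_whitney(group_a, group_b) -> StatResult:
    """Mann-Whitney U with rank-biserial effect size r = 1 - 2U/(nA nB).

    Exact enumeration when nA + nB <= 12 and there are no ties; otherwise
    the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise InvalidParameterError("need at least 1 value per group")
    method = "exact" if (a.size + b.size) <= 12 else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
    u = float(res.statistic)  # U for group A
    r = 1.0 - 2.0 * u / (a.size * b.size)
    return StatResult(
        test="mann_whitney", statistic=u, p_raw=float(res.pvalue),
        effect_size=float(r), effect_name="rank_biserial_r",
        summaries={"median_a": float(np.median(a)),
                   "median_b": float(np.median(b)),
                   "n_a": a.size, "n_b": b.size},
    )


def routed_two_sample(group_a, group_b) -> StatResult:
    """Shapiro-gated choice between Student t and Mann-Whitney U."""
    route = shapiro_route(group_a, group_b)
    return two_sample_t(group_a, group_b) if route == "t_test" \
        else mann_whitney(group_a, group_b)


def fisher_exact(table) -> StatResult:
    """Two-sided Fisher exact test on a 2x2 table with Cramer's V.

    The two-sided p sums hypergeometric probabilities of all tables with
    fixed margins whose probability does not exceed the observed one.
    Cramer's V is computed from the uncorrected chi-square.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = np.asarray(table, dtype=float)
        if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.rint(t)):
            raise InvalidParameterError("table must be 2x2 nonnegative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise InvalidInputError("Fisher exact undefined with an all-zero margin")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    n = t.sum()
    chi2 = stats.chi2_contingency(t, correction=False).statistic \
        if np.all(t.sum(axis=0) > 0) else 0.0
    v = float(np.sqrt(chi2 / n))
    return StatResult(test="fisher_exact", statistic=float(odds),
                      p_raw=float(p), effect_size=v, effect_name="cramers_v",
                      summaries={"table": t.tolist()})


def benjamini_hochberg(p_values, family: str = "") -> np.ndarray:
    """Step-up FDR adjustment; order-preserving with monotonicity enforced."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidParameterError(f"p-values out of [0, 1] in family {family!r}")
    return multipletests(p, method="fdr_bh")[1]


def adjust_family(results: list[StatResult], family: str = "") -> list[StatResult]:
    """Attach FDR-adjusted p-values to a family of StatResults (in place)."""
    adj = benjamini_hochberg([r.p_raw for r in results], family)
    for r, q in zip(results, adj):
        r.p_fdr = float(q)
    return results


# ---------------------------------------------------------------------------
# outcome models

def mark_improved(cohort: pd.DataFrame) -> pd.Series:
    """Binary improvement: upward move on the UWS < MCS- < MCS+ < EMCS ladder."""
    base = cohort["baseline_state"].map(STATE_LADDER.index)
    final = cohort["state_3mo"].map(STATE_LADDER.index)
    if base.isna().any() or final.isna().any():
        raise InvalidInputError("unknown consciousness state label in cohort")
    return final > base


def _design(cohort: pd.DataFrame, covariates, extra_covariates) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        if cov == "group":
            cols["group_esketamine"] = (cohort["group"] == "esketamine").astype(float)
        elif cov == "etiology":
            cols["etiology_tbi"] = (cohort["etiology"] == "TBI").astype(float)
        else:
            cols[cov] = cohort[cov].astype(float)
    for cov in (extra_covariates or ()):
        cols[cov] = cohort[cov].astype(float)
    x = pd.DataFrame(cols, index=cohort.index)
    return sm.add_constant(x, has_constant="add")


def _wald_table(params, ses, exponentiate: bool) -> pd.DataFrame:
    z = stats.norm.ppf(0.975)
    out = pd.DataFrame({
        "coef": params, "se": ses,
        "ci_low": params - z * ses, "ci_high": params + z * ses,
    })
    if exponentiate:
        out["or"] = np.exp(out["coef"])
        out["or_low"] = np.exp(out["ci_low"])
        out["or_high"] = np.exp(out["ci_high"])
    return out


def fit_logistic(cohort: pd.DataFrame, outcome: str = "improved",
                 covariates=DEFAULT_COVARIATES,
                 extra_covariates=None) -> ModelFit:
    """Multiple logistic regression with Wald 95% CIs and adjusted ORs.

    Separation (including a single-class outcome) is flagged explicitly:
    the fit is returned with ``separation=True`` and NaN estimates rather
    than silently unstable numbers.
    """
    y = cohort[outcome].astype(float)
    x = _design(cohort, covariates, extra_covariates)
    names = tuple(c for c in x.columns if c != "const")
    if len(cohort) <= x.shape[1]:
        raise InvalidParameterError(
            f"n={len(cohort)} too small for {x.shape[1]} parameters"
        )

    def _flagged() -> ModelFit:
        nan = pd.DataFrame(np.nan, index=x.columns,
                           columns=["coef", "se", "ci_low", "ci_high",
                                    "or", "or_low", "or_high"])
        return ModelFit(outcome=outcome, kind="logistic", params=nan,
                        loglike=np.nan, n=len(cohort), converged=False,
                        separation=True, covariates=names)

    if y.nunique() < 2:
        return _flagged()
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, x).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return _flagged()
    ses = np.asarray(res.bse)
    if not res.mle_retvals.get("converged", False) or np.any(ses > 50) \
            or not np.all(np.isfinite(ses)):
        return _flagged()
    table = _wald_table(np.asarray(res.params), ses, exponentiate=True)
    table.index = x.columns
    return ModelFit(outcome=outcome, kind="logistic", params=table,
                    loglike=float(res.llf), n=len(cohort),
                    converged=True, covariates=names)


def fit_linear(cohort: pd.DataFrame, outcome: str = "recovery_time",
               covariates=DEFAULT_COVARIATES,
               extra_covariates=None) -> ModelFit:
    """Multiple linear regression (OLS) with coefficient SEs and 95% CIs."""
    y = cohort[outcome].astype(float)
    x = _design(cohort, covariates, extra_covariates)
    names = tuple(c for c in x.columns if c != "const")
    if len(cohort) <= x.shape[1]:
        raise InvalidParameterError(
            f"n={len(cohort)} too small for {x.shape[1]} parameters"
        )
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        kept = np.empty((len(x), 0))
        for c in x.columns:
            cand = np.column_stack([kept, x[c].to_numpy()])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                bad.append(c)
        raise InvalidInputError(f"design matrix rank-deficient; collinear: {bad}")
    res = sm.OLS(y, x).fit()
    table = _wald_table(np.asarray(res.params), np.asarray(res.bse),
                        exponentiate=False)
    table.index = x.columns
    return ModelFit(outcome=outcome, kind="linear", params=table,
                    loglike=float(res.llf), n=len(cohort), covariates=names)


def likelihood_ratio(full: ModelFit, reduced: ModelFit) -> StatResult:
    """LRT between nested fits: chi2 = 2 (ll_full - ll_reduced)."""
    if full.n != reduced.n:
        raise InvalidInputError("models fit on different numbers of rows")
    if not set(reduced.covariates) <= set(full.covariates):
        raise InvalidInputError("models are not nested")
    df = len(full.covariates) - len(reduced.covariates)
    if df < 1:
        raise InvalidInputError("full model adds no parameters")
    chi2 = 2.0 * (full.loglike - reduced.loglike)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df))
    return StatResult(test="likelihood_ratio", statistic=float(chi2),
                      p_raw=p, effect_size=float(df), effect_name="df")


# ---------------------------------------------------------------------------
# Table-1 style cohort summary

def _pct(k: int, n: int) -> str:
    return f"{k} ({0 if n == 0 else 100.0 * k / n:.2f}%)"


def _fmt_mean_sd(x: np.ndarray) -> str:
    return f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"


def _fmt_median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}, {q3:.2f})"


def _categorical_test(cohort: pd.DataFrame, col: str) -> StatResult:
    tab = pd.crosstab(cohort[col], cohort["group"])
    counts = tab.to_numpy()
    if counts.shape == (2, 2):
        return fisher_exact(counts)
    # r x 2 table (>2 levels): deterministic chi-square; SciPy's r x c
    # Fisher test is Monte-Carlo based and would break report determinism
    res = stats.chi2_contingency(counts, correction=False)
    n = counts.sum()
    v = float(np.sqrt(res.statistic / (n * (min(counts.shape) - 1))))
    return StatResult(test="chi2", statistic=float(res.statistic),
                      p_raw=float(res.pvalue),
                      effect_size=v, effect_name="cramers_v",
                      summaries={"table": counts.tolist()})


def table_one(cohort: pd.DataFrame) -> pd.DataFrame:
    """Group-wise baseline/outcome summary with routed tests.

    Continuous variables route through Shapiro-Wilk to pooled t (mean +/- SD)
    or Mann-Whitney (median (IQR)); categoricals use exact tests with n (%).
    The test orientation is propofol - esketamine, matching the convention
    of reporting the esketamine column first.
    """
    if cohort.empty:
        raise InvalidInputError("empty cohort")
    esk = cohort[cohort["group"] == "esketamine"]
    pro = cohort[cohort["group"] == "propofol"]
    rows = []

    continuous = [("age", "Age (years)"),
                  ("duration_months", "Disease duration (months)"),
                  ("crsr_baseline", "CRS-R score"),
                  ("surgical_time", "Surgical time (min)"),
                  ("recovery_time", "Time for respiratory recovery (min)")]
    for col, label in continuous:
        a = esk[col].to_numpy(dtype=float)
        b = pro[col].to_numpy(dtype=float)
        route = shapiro_route(a, b)
        if route == "t_test":
            res = two_sample_t(b, a)  # propofol - esketamine orientation
            summ_a, summ_b = _fmt_mean_sd(a), _fmt_mean_sd(b)
        else:
            res = mann_whitney(b, a)
            summ_a, summ_b = _fmt_median_iqr(a), _fmt_median_iqr(b)
        rows.append({"variable": label, "esketamine": summ_a,
                     "propofol": summ_b, "test": res.test,
                     "statistic": res.statistic, "p": res.p_raw,
                     "effect_size": res.effect_size,
                     "effect_name": res.effect_name})

    categorical = [("sex", "Sex = M"), ("etiology", "Etiology = TBI"),
                   ("baseline_state", "Level of consciousness"),
                   ("norepinephrine", "Norepinephrine = yes")]
    for col, label in categorical:
        res = _categorical_test(cohort, col)
        if cohort[col].nunique() == 2:
            top = sorted(cohort[col].unique())[-1]
            ka, kb = int((esk[col] == top).sum()), int((pro[col] == top).sum())
            summ_a, summ_b = _pct(ka, len(esk)), _pct(kb, len(pro))
        else:
            summ_a = "; ".join(_pct(int((esk[col] == lv).sum()), len(esk))
                               + f" {lv}" for lv in sorted(cohort[col].unique()))
            summ_b = "; ".join(_pct(int((pro[col] == lv).sum()), len(pro))
                               + f" {lv}" for lv in sorted(cohort[col].unique()))
        rows.append({"variable": label, "esketamine": summ_a,
                     "propofol": summ_b, "test": res.test,
                     "statistic": res.statistic, "p": res.p_raw,
                     "effect_size": res.effect_size,
                     "effect_name": res.effect_name})
    return pd.DataFrame(rows)


def ordinal_state_contrast(cohort: pd.DataFrame, column: str = "state_3mo") -> StatResult:
    """Two-sample t on the 0-3 coded consciousness ladder.

    A deliberately simple contrast of ordinal state scores between groups
    (coding UWS=0 .. EMCS=3); see the methods note for caveats about
    treating an ordinal scale this way.
    """
    coded = cohort[column].map(STATE_LADDER.index).astype(float)
    a = coded[cohort["group"] == "esketamine"].to_numpy()
    b = coded[cohort["group"] == "propofol"].to_numpy()
    return two_sample_t(b, a)  # propofol - esketamine orientation
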