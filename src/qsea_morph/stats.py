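"""Two-group tests, logistic adjustment and bootstrap ROC.

Continuous contrasts are gated on normality: Shapiro–Wilk on each sample
at alpha 0.05, Welch t-test if both pass, Mann–Whitney U otherwise (a
mixed pair goes nonparametric).  Categorical contrasts use Fisher's exact
test for 2×2 tables and chi-squared otherwise.  Associations are adjusted
by maximum-likelihood logistic regression with Wald odds-ratio CIs, and
discrimination is summarized as AUC with a seeded percentile-bootstrap CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

#: confounder sets used when confirming univariate associations; applied to
#: whichever of the named columns the input table provides
ADJUSTMENT_PRESETS: dict[str, tuple[str, ...]] = {
    "euploidy": ("maternal_age", "morphology_tier"),
    "live_birth": ("morphology_tier",),
}

_NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    summaries: dict = field(default_factory=dict)
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def compare_groups(
    x,
    y,
    continuous: bool = True,
    normality_alpha: float = _NORMALITY_ALPHA,
) -> TestResult:
    """Two-group comparison with the normality gate (continuous) or an
    exact/chi-squared test (categorical).

    For categorical data pass the contingency table as ``x`` (2-D array);
    ``y`` is ignored.
    """
    if not continuous:
        table = np.asarray(x, dtype=float)
        if table.ndim != 2 or table.size == 0:
            raise ValueError("categorical comparison needs a 2-D contingency table")
        if table.shape == (2, 2):
            stat, p = sps.fisher_exact(table)
            return TestResult("fisher_exact", float(stat), float(p), {"table": table.tolist()})
        chi2 = sps.chi2_contingency(table)
        return TestResult(
            "chi_squared", float(chi2.statistic), float(chi2.pvalue), {"table": table.tolist()}
        )

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    if len(x) < 3 or len(y) < 3:
        raise ValueError("continuous comparison needs n >= 3 per group")
    summaries = {
        "mean_x": float(x.mean()),
        "sd_x": float(x.std(ddof=1)),
        "n_x": int(len(x)),
        "mean_y": float(y.mean()),
        "sd_y": float(y.std(ddof=1)),
        "n_y": int(len(y)),
    }
    if x.std() == 0 and y.std() == 0:
        flag = ("zero_variance",)
        return TestResult("degenerate", 0.0, 1.0, summaries, flag)

    def is_normal(s: np.ndarray) -> bool:
        if s.std() == 0:
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sps.shapiro(s).pvalue >= normality_alpha

    if is_normal(x) and is_normal(y):
        res = sps.ttest_ind(x, y, equal_var=False)
        return TestResult("welch_t", float(res.statistic), float(res.pvalue), summaries)
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult("mann_whitney_u", float(res.statistic), float(res.pvalue), summaries)


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald odds-ratio CIs."""

    odds_ratios: pd.DataFrame  # index: covariate; columns: OR, ci_low, ci_high, p
    params: pd.Series  # coefficients incl. intercept, log-odds scale
    converged: bool
    n: int
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            bad = (
                (self.odds_ratios["ci_low"] <= 0)
                | (self.odds_ratios["ci_low"] > self.odds_ratios["OR"])
                | (self.odds_ratios["OR"] > self.odds_ratios["ci_high"])
            )
            if bad.any():
                raise ValueError("invalid odds-ratio confidence bounds")


def fit_logistic(outcome, covariates: pd.DataFrame) -> LogisticFit:
    """Fit P(outcome=1 | covariates) by maximum likelihood (IRLS/Newton).

    Odds ratios are exp(coefficients) with Wald 95% CIs.  Complete
    separation or non-convergence is flagged rather than raised, except
    for degenerate inputs (single-class outcome, constant covariate).
    """
    y = np.asarray(outcome, dtype=float)
    X = pd.DataFrame(covariates).astype(float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes (0 and 1)")
    if len(y) != len(X):
        raise ValueError("outcome and covariates differ in length")
    const_cols = [c for c in X.columns if X[c].nunique() <= 1]
    if const_cols:
        raise ValueError(f"constant covariate(s) besides the intercept: {const_cols}")
    Xc = sm.add_constant(X, has_constant="add")
    converged, message = True, ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=False, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            if not converged:
                message = "did not converge"
        except Exception as exc:  # perfect separation, singular Hessian
            return LogisticFit(
                odds_ratios=pd.DataFrame(columns=["OR", "ci_low", "ci_high", "p"]),
                params=pd.Series(dtype=float),
                converged=False,
                n=len(y),
                message=f"separation or singular fit: {exc}",
            )
    # huge coefficients with exploding SEs also indicate separation
    if converged and (np.abs(res.params.drop("const")) > 15).any():
        converged, message = False, "coefficients diverged (separation?)"
    ci = res.conf_int(alpha=0.05)
    ors = pd.DataFrame(
        {
            "OR": np.exp(res.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "p": res.pvalues,
        }
    ).drop(index="const")
    return LogisticFit(
        odds_ratios=ors if converged else ors.iloc[0:0],
        params=res.params,
        converged=converged,
        n=len(y),
        message=message,
    )


def composite_score(fit: LogisticFit, covariates: pd.DataFrame) -> np.ndarray:
    """Linear predictor (log-odds) of a fitted model on new covariates;
    the natural score input to :func:`roc_auc` for adjusted AUCs."""
    X = pd.DataFrame(covariates).astype(float)
    expected = [c for c in fit.params.index if c != "const"]
    if list(X.columns) != expected:
        raise ValueError(f"covariate mismatch: expected {expected}, got {list(X.columns)}")
    Xc = sm.add_constant(X, has_constant="add")
    return Xc.to_numpy() @ fit.params.reindex(Xc.columns).to_numpy()


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    n_boot: int
    seed: int | None

    def __post_init__(self) -> None:
        for v in (self.auc, self.ci_low, self.ci_high):
            if not 0.0 <= v <= 1.0:
                raise ValueError("AUC and CI must lie in [0, 1]")


def roc_auc(scores, labels, n_boot: int = 2000, seed: int | None = 0) -> RocResult:
    """Rank-statistic AUC (tie-corrected) with a seeded percentile
    bootstrap over subjects for the 95% CI."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    auc = float(roc_auc_score(y, s))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    n = len(y)
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():  # resample lost a class; redraw
            continue
        boots[i] = roc_auc_score(yb, s[idx])
        i += 1
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RocResult(
        auc=auc,
        ci_low=float(lo),
        ci_high=float(hi),
        n_pos=int(y.sum()),
        n_neg=int((1 - y).sum()),
        n_boot=n_boot,
        seed=seed,
    )
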