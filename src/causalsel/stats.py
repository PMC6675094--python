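"""Statistical pipeline for rating experiments.

Implements the analyses applied to the rating data: main-effect slopes of
the two priors with subject-level random effects, extrapolation tests for
outsized jumps at the certain (p = 1) conditions, conditional-effect tests
with BIC Bayes factors, slope-by-certainty interaction tests, trial-order
robustness checks, and item-level model comparison (Pearson correlations
between each predictor's 100-condition profile and the empirical condition
means, with Williams's test for dependent correlations).

All analyses operate on the 0-1 scaled rating, with predictors coded as
grid indices (one unit = a 0.1 probability step), so fitted slopes are in
the same units as the generator's.  Raw p-values are reported throughout;
no multiplicity correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .scm import ATOL
from .predictors import PredictionGrid
from .simulate import _with_scaled

__all__ = [
    "EffectEstimate",
    "CertaintyJumpResult",
    "ConditionalEffectResult",
    "InteractionResult",
    "OrderEffectReport",
    "ItemCorrelation",
    "WilliamsResult",
    "ComparisonReport",
    "fit_main_effects",
    "certainty_jump_test",
    "conditional_effect_test",
    "interaction_test",
    "order_effect_checks",
    "item_correlation",
    "williams_compare",
    "bayes_factor_null",
    "compare_models",
]

_VARIABLES = ("focal", "alternate")


def _check_variable(variable: str) -> str:
    if variable not in _VARIABLES:
        raise ValueError(f"variable must be one of {_VARIABLES}, got {variable!r}")
    return variable


def _indices(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    g_f = np.rint(10.0 * table["p_focal"].to_numpy()).astype(float)
    g_a = np.rint(10.0 * table["p_alternate"].to_numpy()).astype(float)
    return g_f, g_a


# ---------------------------------------------------------------------------
# Main effects


@dataclass(frozen=True)
class EffectEstimate:
    """Fixed-effect slopes of the two priors (scaled rating per 0.1 step)."""

    slope_focal: float
    slope_alternate: float
    se_focal: float
    se_alternate: float
    t_focal: float
    t_alternate: float
    p_focal: float
    p_alternate: float
    n_subjects: int
    estimator: str
    zero_variance: bool = False

    def ci(self, variable: str, level: float = 0.95) -> tuple[float, float]:
        """Normal-approximation confidence interval for a slope."""
        _check_variable(variable)
        slope = getattr(self, f"slope_{variable}")
        se = getattr(self, f"se_{variable}")
        z = sps.norm.ppf(0.5 + level / 2.0)
        return (slope - z * se, slope + z * se)


def _certainty_design(g_f, g_a):
    """Fixed-effect design absorbing the certainty nonlinearities.

    Columns: 1, g_f, g_a, I(f=10), I(a=10), g_f*I(a=10), g_a*I(f=10).
    The jump dummies absorb the additive offsets and the interactions the
    suppression of each slope, so the main g coefficients estimate the
    linear-regime slopes.
    """
    d_f = (g_f == 10).astype(float)
    d_a = (g_a == 10).astype(float)
    X = np.column_stack(
        [np.ones_like(g_f), g_f, g_a, d_f, d_a, g_f * d_a, g_a * d_f]
    )
    names = ["const", "g_focal", "g_alternate", "cert_focal", "cert_alternate",
             "g_focal:cert_alternate", "g_alternate:cert_focal"]
    keep = [i for i in range(X.shape[1]) if np.ptp(X[:, i]) > 0 or i == 0]
    return X[:, keep], [names[i] for i in keep]


def fit_main_effects(
    table: pd.DataFrame,
    estimator: Literal["mixedlm", "ols_cluster", "censored_ml", "two_stage"] = "mixedlm",
    design: Literal["certainty", "linear"] = "certainty",
) -> EffectEstimate:
    """Estimate the fixed-effect slopes of both priors.

    ``mixedlm`` fits a linear mixed model (REML) with subject-level random
    intercepts and slopes for both priors.  ``ols_cluster`` pools all
    trials in one OLS with subject-clustered (sandwich) standard errors —
    nearly as precise here and orders of magnitude faster, so it is the
    workhorse for replicate simulations.  ``censored_ml`` additionally
    models the clamp-and-round measurement of the 1-9 scale (interval-
    censored likelihood with known thresholds), undoing the slope
    attenuation the scale ends induce in the linear fits; it is the
    estimator of choice for parameter recovery.  ``two_stage`` runs a per-subject
    OLS and averages the coefficients across subjects (the random design
    makes the unweighted average unbiased; its standard error is the
    between-subject SD over sqrt(n)); with only five trials per subject it
    is unbiased but noisy.

    The default ``certainty`` design keeps the certain (p = 1) conditions
    from contaminating the slopes: the pooled fits add certainty dummies
    and slope-by-certainty interactions, while the two-stage fit restricts
    to the p < 1 linear regime.  ``linear`` fits the plain two-slope model
    on all trials.
    """
    table = _with_scaled(table)
    subjects = table["subject"].to_numpy()
    if len(np.unique(subjects)) < 2:
        raise ValueError("main-effects fit requires at least 2 subjects")
    if len(table.drop_duplicates(["p_focal", "p_alternate"])) < 2:
        raise ValueError("main-effects fit requires at least 2 distinct settings")

    y = table["rating_scaled"].to_numpy(dtype=float)
    g_f, g_a = _indices(table)
    n_subjects = int(len(np.unique(subjects)))
    if np.ptp(y) == 0:
        return EffectEstimate(
            0.0, 0.0, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            n_subjects, estimator, zero_variance=True,
        )
    for name, g in (("p_focal", g_f), ("p_alternate", g_a)):
        if np.ptp(g) == 0:
            raise ValueError(f"degenerate design: predictor {name} is constant")

    if estimator == "mixedlm":
        return _fit_mixedlm(y, g_f, g_a, subjects, design, n_subjects)
    if estimator == "ols_cluster":
        return _fit_ols_cluster(y, g_f, g_a, subjects, design, n_subjects)
    if estimator == "censored_ml":
        return _fit_censored_ml(y, g_f, g_a, subjects, design, n_subjects)
    if estimator == "two_stage":
        return _fit_two_stage(y, g_f, g_a, subjects, design, n_subjects)
    raise ValueError(f"unknown estimator {estimator!r}")


def _fit_mixedlm(y, g_f, g_a, subjects, design, n_subjects) -> EffectEstimate:
    if design == "certainty":
        X, names = _certainty_design(g_f, g_a)
    elif design == "linear":
        X = np.column_stack([np.ones_like(g_f), g_f, g_a])
        names = ["const", "g_focal", "g_alternate"]
    else:
        raise ValueError(f"unknown design {design!r}")
    exog_re = np.column_stack([np.ones_like(g_f), g_f, g_a])
    model = sm.MixedLM(y, X, groups=subjects, exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
    i_f, i_a = names.index("g_focal"), names.index("g_alternate")
    return EffectEstimate(
        slope_focal=float(result.fe_params[i_f]),
        slope_alternate=float(result.fe_params[i_a]),
        se_focal=float(result.bse_fe[i_f]),
        se_alternate=float(result.bse_fe[i_a]),
        t_focal=float(result.tvalues[i_f]),
        t_alternate=float(result.tvalues[i_a]),
        p_focal=float(result.pvalues[i_f]),
        p_alternate=float(result.pvalues[i_a]),
        n_subjects=n_subjects,
        estimator=f"mixedlm/{design}",
    )


def _fit_ols_cluster(y, g_f, g_a, subjects, design, n_subjects) -> EffectEstimate:
    if design == "certainty":
        X, names = _certainty_design(g_f, g_a)
    elif design == "linear":
        X = np.column_stack([np.ones_like(g_f), g_f, g_a])
        names = ["const", "g_focal", "g_alternate"]
    else:
        raise ValueError(f"unknown design {design!r}")
    fit = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": subjects})
    i_f, i_a = names.index("g_focal"), names.index("g_alternate")
    return EffectEstimate(
        slope_focal=float(fit.params[i_f]),
        slope_alternate=float(fit.params[i_a]),
        se_focal=float(fit.bse[i_f]),
        se_alternate=float(fit.bse[i_a]),
        t_focal=float(fit.tvalues[i_f]),
        t_alternate=float(fit.tvalues[i_a]),
        p_focal=float(fit.pvalues[i_f]),
        p_alternate=float(fit.pvalues[i_a]),
        n_subjects=n_subjects,
        estimator=f"ols_cluster/{design}",
    )


def _fit_censored_ml(y, g_f, g_a, subjects, design, n_subjects) -> EffectEstimate:
    """Interval-censored marginal ML for the clamp-and-round rating scale.

    A raw rating r arises from a latent value clamped to [0, 1] and mapped
    by round(1 + 8v): r corresponds to the latent interval
    [(r - 1.5)/8, (r - 0.5)/8), open-ended at r = 1 and r = 9.  The latent
    mean follows the requested fixed-effect design and the latent variance
    the generator's structure, c0 + cf*g_f^2 + ca*g_a^2 (residual plus
    random intercept and two random slopes).  Maximizing the independence
    working likelihood is consistent for the slopes despite within-subject
    correlation; standard errors come from a subject-clustered sandwich.
    """
    if design == "certainty":
        X, names = _certainty_design(g_f, g_a)
    elif design == "linear":
        X = np.column_stack([np.ones_like(g_f), g_f, g_a])
        names = ["const", "g_focal", "g_alternate"]
    else:
        raise ValueError(f"unknown design {design!r}")
    from scipy.optimize import minimize

    raw = np.rint(1.0 + 8.0 * y)  # y is the scaled rating: invertible
    lower = np.where(raw <= 1, -np.inf, (raw - 1.5) / 8.0)
    upper = np.where(raw >= 9, np.inf, (raw - 0.5) / 8.0)
    gf2, ga2 = g_f**2, g_a**2
    k = X.shape[1]

    def unpack(theta):
        beta = theta[:k]
        c = np.exp(theta[k:])  # c0, cf, ca > 0
        sigma = np.sqrt(c[0] + c[1] * gf2 + c[2] * ga2)
        return beta, c, sigma

    def loglik_terms(theta):
        beta, _, sigma = unpack(theta)
        mu = X @ beta
        zu = (upper - mu) / sigma
        zl = (lower - mu) / sigma
        prob = sps.norm.cdf(zu) - sps.norm.cdf(zl)
        return np.log(np.clip(prob, 1e-300, None)), mu, sigma, zl, zu, prob

    def negll(theta):
        return -loglik_terms(theta)[0].sum()

    def scores(theta):
        """Per-observation score vector (n x (k + 3))."""
        ll, mu, sigma, zl, zu, prob = loglik_terms(theta)
        prob = np.clip(prob, 1e-300, None)
        pdf_u = np.where(np.isfinite(zu), sps.norm.pdf(zu), 0.0)
        pdf_l = np.where(np.isfinite(zl), sps.norm.pdf(zl), 0.0)
        dmu = (pdf_l - pdf_u) / (sigma * prob)
        zpdf_u = np.where(np.isfinite(zu), pdf_u * np.nan_to_num(zu), 0.0)
        zpdf_l = np.where(np.isfinite(zl), pdf_l * np.nan_to_num(zl), 0.0)
        dsigma = (zpdf_l - zpdf_u) / (sigma * prob)
        c = np.exp(theta[k:])
        bases = np.column_stack([np.ones_like(gf2), gf2, ga2])
        # d sigma / d log c_j = c_j * base_j / (2 sigma)
        dlogc = dsigma[:, None] * (c[None, :] * bases) / (2.0 * sigma[:, None])
        return np.column_stack([dmu[:, None] * X, dlogc])

    ols = sm.OLS(y, X).fit()
    theta0 = np.concatenate([ols.params, np.log([max(ols.mse_resid, 1e-4), 1e-4, 1e-4])])
    opt = minimize(
        negll,
        theta0,
        jac=lambda th: -scores(th).sum(axis=0),
        method="L-BFGS-B",
        options={"maxiter": 500},
    )
    theta = opt.x

    # Clustered sandwich: H^-1 (sum_g s_g s_g') H^-1, H from numeric
    # differentiation of the analytic score.
    p = len(theta)
    H = np.zeros((p, p))
    eps = 1e-6
    for j in range(p):
        step = np.zeros(p)
        step[j] = eps
        H[:, j] = (scores(theta + step).sum(axis=0) - scores(theta - step).sum(axis=0)) / (2 * eps)
    H = -(H + H.T) / 2.0  # observed information
    S = scores(theta)
    meat = np.zeros((p, p))
    for _, idx in pd.Series(np.arange(len(y))).groupby(subjects):
        s_g = S[idx.to_numpy()].sum(axis=0)
        meat += np.outer(s_g, s_g)
    Hinv = np.linalg.pinv(H)
    cov = Hinv @ meat @ Hinv
    bse = np.sqrt(np.diag(cov))

    i_f, i_a = names.index("g_focal"), names.index("g_alternate")
    t_f = theta[i_f] / bse[i_f]
    t_a = theta[i_a] / bse[i_a]
    return EffectEstimate(
        slope_focal=float(theta[i_f]),
        slope_alternate=float(theta[i_a]),
        se_focal=float(bse[i_f]),
        se_alternate=float(bse[i_a]),
        t_focal=float(t_f),
        t_alternate=float(t_a),
        p_focal=float(2.0 * sps.norm.sf(abs(t_f))),
        p_alternate=float(2.0 * sps.norm.sf(abs(t_a))),
        n_subjects=n_subjects,
        estimator=f"censored_ml/{design}",
    )


def _fit_two_stage(y, g_f, g_a, subjects, design, n_subjects) -> EffectEstimate:
    if design == "certainty":
        keep = (g_f < 10) & (g_a < 10)
    elif design == "linear":
        keep = np.ones_like(g_f, dtype=bool)
    else:
        raise ValueError(f"unknown design {design!r}")
    y, g_f, g_a, subjects = y[keep], g_f[keep], g_a[keep], subjects[keep]

    coefs = []
    for _, idx in pd.Series(np.arange(len(y))).groupby(subjects):
        ii = idx.to_numpy()
        if len(ii) < 3:
            continue
        X = np.column_stack([np.ones(len(ii)), g_f[ii], g_a[ii]])
        if np.linalg.matrix_rank(X) < 3:
            continue
        beta, *_ = np.linalg.lstsq(X, y[ii], rcond=None)
        coefs.append(beta)
    if len(coefs) < 2:
        raise ValueError("too few subjects with an identifiable within-subject design")
    coefs = np.asarray(coefs)
    k = len(coefs)
    mean = coefs.mean(axis=0)
    se = coefs.std(axis=0, ddof=1) / np.sqrt(k)
    t = mean / se
    p = 2.0 * sps.t.sf(np.abs(t), df=k - 1)
    return EffectEstimate(
        slope_focal=float(mean[1]),
        slope_alternate=float(mean[2]),
        se_focal=float(se[1]),
        se_alternate=float(se[2]),
        t_focal=float(t[1]),
        t_alternate=float(t[2]),
        p_focal=float(p[1]),
        p_alternate=float(p[2]),
        n_subjects=k,
        estimator=f"two_stage/{design}",
    )


# ---------------------------------------------------------------------------
# Certainty-jump extrapolation test


@dataclass(frozen=True)
class CertaintyJumpResult:
    """Is the certain (p = 1) condition off the linear extrapolation?

    A simple regression of ratings on the tested prior is fit on the
    p < 1 trials and extrapolated to p = 1; the interval is a 95%
    prediction interval for the *mean of the m observed certain trials*
    (se^2 = se_pred_mean^2 + sigma^2/m), so with no true jump the flag
    fires at the nominal 5% rate.
    """

    variable: str
    predicted_mean: float
    interval: tuple[float, float]
    observed_mean: float
    outside_flag: bool
    n_certain: int
    slope: float

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not lo < hi:
            raise ValueError("degenerate prediction interval")


def certainty_jump_test(table: pd.DataFrame, variable: str) -> CertaintyJumpResult:
    """Test whether ratings at p = 1 fall outside the extrapolation interval."""
    _check_variable(variable)
    table = _with_scaled(table)
    p = table[f"p_{variable}"].to_numpy(dtype=float)
    g = np.rint(10.0 * p)
    y = table["rating_scaled"].to_numpy(dtype=float)

    certain = g == 10
    m = int(certain.sum())
    if m == 0:
        raise ValueError(f"no p_{variable} = 1 trials to test")
    if (~certain).sum() < 3 or np.ptp(g[~certain]) == 0:
        raise ValueError("too few non-certain trials to fit the extrapolation")

    X = sm.add_constant(g[~certain])
    fit = sm.OLS(y[~certain], X).fit()
    x0 = np.array([1.0, 10.0])
    predicted = float(x0 @ fit.params)
    se_mean = float(np.sqrt(x0 @ fit.cov_params() @ x0))
    sigma2 = float(fit.mse_resid)
    se_total = np.sqrt(se_mean**2 + sigma2 / m)
    tcrit = sps.t.ppf(0.975, df=fit.df_resid)
    interval = (predicted - tcrit * se_total, predicted + tcrit * se_total)
    observed = float(y[certain].mean())
    return CertaintyJumpResult(
        variable=variable,
        predicted_mean=predicted,
        interval=interval,
        observed_mean=observed,
        outside_flag=not (interval[0] <= observed <= interval[1]),
        n_certain=m,
        slope=float(fit.params[1]),
    )


# ---------------------------------------------------------------------------
# Conditional effects, Bayes factors, interactions


def bayes_factor_null(null_fit, alt_fit) -> float:
    """BF in favor of the null from two nested fits, by BIC approximation.

    BF_null = exp((BIC_alt - BIC_null) / 2); values above 1 favor the
    null.  Requires the fits to share the data and the null to be the
    smaller model.  A unit-information-prior reconstruction — the printed
    Bayes factors' method is not reproduced exactly.
    """
    if int(null_fit.nobs) != int(alt_fit.nobs):
        raise ValueError("nested fits must share the same observations")
    if null_fit.df_model > alt_fit.df_model:
        raise ValueError("the null model must be nested in the alternative")
    return float(np.exp((alt_fit.bic - null_fit.bic) / 2.0))


@dataclass(frozen=True)
class ConditionalEffectResult:
    """Slope of one prior restricted to the other prior's certain trials."""

    tested: str
    conditioning: str
    slope: float
    se: float
    t: float
    p: float
    bf_null: float
    n_trials: int


def conditional_effect_test(
    table: pd.DataFrame, tested: str, conditioning: str
) -> ConditionalEffectResult:
    """Does the tested prior still matter when the other prior is certain?

    Restricts to trials with the conditioning prior equal to 1 and the
    tested prior below 1, regresses scaled ratings on the tested grid
    index, and quantifies support for a zero slope with a BIC Bayes
    factor.
    """
    _check_variable(tested)
    _check_variable(conditioning)
    if tested == conditioning:
        raise ValueError("tested and conditioning variables must differ")
    table = _with_scaled(table)
    p_t = table[f"p_{tested}"].to_numpy(dtype=float)
    p_c = table[f"p_{conditioning}"].to_numpy(dtype=float)
    keep = (p_c >= 1.0 - ATOL) & (p_t < 1.0 - ATOL)
    if not keep.any():
        raise ValueError("empty restriction: no qualifying trials")
    g = np.rint(10.0 * p_t[keep])
    y = table["rating_scaled"].to_numpy(dtype=float)[keep]
    if len(np.unique(g)) < 2:
        raise ValueError("degenerate design: single tested-variable value in subset")

    alt = sm.OLS(y, sm.add_constant(g)).fit()
    null = sm.OLS(y, np.ones((len(y), 1))).fit()
    return ConditionalEffectResult(
        tested=tested,
        conditioning=conditioning,
        slope=float(alt.params[1]),
        se=float(alt.bse[1]),
        t=float(alt.tvalues[1]),
        p=float(alt.pvalues[1]),
        bf_null=bayes_factor_null(null, alt),
        n_trials=int(keep.sum()),
    )


@dataclass(frozen=True)
class InteractionResult:
    """Slope difference between moderator-certain and other trials.

    ``estimate`` is slope(certain stratum) − slope(non-certain stratum).
    """

    tested: str
    moderator: str
    estimate: float
    se: float
    t: float
    p: float
    n_certain: int
    n_other: int


def interaction_test(
    table: pd.DataFrame, tested: str, moderator_certain: str
) -> InteractionResult:
    """Does the tested prior's slope change when the moderator is certain?

    Fits rating ~ g_tested * I(moderator = 1) on trials with the tested
    prior below 1 and reports the interaction coefficient.
    """
    _check_variable(tested)
    _check_variable(moderator_certain)
    if tested == moderator_certain:
        raise ValueError("tested and moderator variables must differ")
    table = _with_scaled(table)
    p_t = table[f"p_{tested}"].to_numpy(dtype=float)
    p_m = table[f"p_{moderator_certain}"].to_numpy(dtype=float)
    keep = p_t < 1.0 - ATOL
    g = np.rint(10.0 * p_t[keep])
    cert = (p_m[keep] >= 1.0 - ATOL).astype(float)
    y = table["rating_scaled"].to_numpy(dtype=float)[keep]
    if cert.min() == cert.max():
        raise ValueError("both moderator strata (certain and not) must be present")

    X = np.column_stack([np.ones_like(g), g, cert, g * cert])
    fit = sm.OLS(y, X).fit()
    return InteractionResult(
        tested=tested,
        moderator=moderator_certain,
        estimate=float(fit.params[3]),
        se=float(fit.bse[3]),
        t=float(fit.tvalues[3]),
        p=float(fit.pvalues[3]),
        n_certain=int(cert.sum()),
        n_other=int((1 - cert).sum()),
    )


# ---------------------------------------------------------------------------
# Trial-order robustness


@dataclass(frozen=True)
class OrderEffectReport:
    """Three re-analyses probing repeated-measures order effects."""

    controlled: EffectEstimate  # slopes with trial index as covariate
    first_trial: EffectEstimate  # slopes on first-trial data only
    interaction_focal: tuple[float, float, float] | None  # (b, se, p)
    interaction_alternate: tuple[float, float, float] | None


def order_effect_checks(table: pd.DataFrame) -> OrderEffectReport:
    """Check that the prior-probability slopes are not order artifacts."""
    table = _with_scaled(table)
    if "trial" not in table.columns:
        raise ValueError("ratings table has no trial index")
    y = table["rating_scaled"].to_numpy(dtype=float)
    g_f, g_a = _indices(table)
    trial = table["trial"].to_numpy(dtype=float)

    def _ols_effects(X, names, yv, n_subj) -> EffectEstimate:
        fit = sm.OLS(yv, X).fit()
        i_f, i_a = names.index("g_focal"), names.index("g_alternate")
        return EffectEstimate(
            slope_focal=float(fit.params[i_f]),
            slope_alternate=float(fit.params[i_a]),
            se_focal=float(fit.bse[i_f]),
            se_alternate=float(fit.bse[i_a]),
            t_focal=float(fit.tvalues[i_f]),
            t_alternate=float(fit.tvalues[i_a]),
            p_focal=float(fit.pvalues[i_f]),
            p_alternate=float(fit.pvalues[i_a]),
            n_subjects=n_subj,
            estimator="ols/order",
        )

    n_subj = int(table["subject"].nunique())
    X = np.column_stack([np.ones_like(y), g_f, g_a, trial])
    controlled = _ols_effects(X, ["const", "g_focal", "g_alternate", "trial"], y, n_subj)

    first = trial == trial.min()
    Xf = np.column_stack([np.ones(first.sum()), g_f[first], g_a[first]])
    first_trial = _ols_effects(
        Xf, ["const", "g_focal", "g_alternate"], y[first], int(first.sum())
    )

    if np.ptp(trial) == 0:
        warnings.warn(
            "single trial per subject: skipping slope-by-order interactions",
            stacklevel=2,
        )
        return OrderEffectReport(controlled, first_trial, None, None)

    Xi = np.column_stack(
        [np.ones_like(y), g_f, g_a, trial, g_f * trial, g_a * trial]
    )
    fit = sm.OLS(y, Xi).fit()
    return OrderEffectReport(
        controlled=controlled,
        first_trial=first_trial,
        interaction_focal=(float(fit.params[4]), float(fit.bse[4]), float(fit.pvalues[4])),
        interaction_alternate=(float(fit.params[5]), float(fit.bse[5]), float(fit.pvalues[5])),
    )


# ---------------------------------------------------------------------------
# Item-level model comparison


@dataclass(frozen=True)
class ItemCorrelation:
    """Pearson r between a predictor profile and empirical condition means."""

    model: str
    r: float | None
    ci_95: tuple[float, float] | None
    n: int
    not_applicable: bool = False
    note: str = ""


def item_correlation(
    predictions: np.ndarray, means: np.ndarray, model: str = ""
) -> ItemCorrelation:
    """Correlate a model's per-condition predictions with condition means.

    Constant prediction profiles leave the correlation undefined; they are
    reported as not-applicable rather than as a number.  The CI is the
    Fisher-z interval.
    """
    predictions = np.asarray(predictions, dtype=float)
    means = np.asarray(means, dtype=float)
    if predictions.shape != means.shape or predictions.ndim != 1:
        raise ValueError("predictions and means must be aligned 1-d arrays")
    n = len(predictions)
    if n < 3:
        raise ValueError("at least 3 shared settings required")
    if np.ptp(predictions) <= ATOL:
        return ItemCorrelation(
            model=model, r=None, ci_95=None, n=n, not_applicable=True,
            note="constant prediction profile: correlation undefined",
        )
    r, _ = sps.pearsonr(predictions, means)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = sps.norm.ppf(0.975) / np.sqrt(n - 3)
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return ItemCorrelation(model=model, r=float(r), ci_95=ci, n=n)


@dataclass(frozen=True)
class WilliamsResult:
    t: float
    df: int
    p: float


def williams_compare(r_a: float, r_b: float, r_ab: float, n: int) -> WilliamsResult:
    """Williams's test for two dependent correlations sharing a variable.

    ``r_a`` and ``r_b`` correlate two predictors with the same empirical
    variable; ``r_ab`` is the correlation between the predictors.  Uses
    the Steiger formulation of Williams's t with df = n − 3, two-tailed.
    """
    for name, r in (("r_a", r_a), ("r_b", r_b), ("r_ab", r_ab)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly in (-1, 1), got {r}")
    if n < 4:
        raise ValueError("Williams's test requires n >= 4")
    det = 1.0 - r_a**2 - r_b**2 - r_ab**2 + 2.0 * r_a * r_b * r_ab
    if det <= 0.0:
        raise ValueError("degenerate correlation matrix (non-positive determinant)")
    rbar = (r_a + r_b) / 2.0
    denom = 2.0 * det * (n - 1) / (n - 3) + rbar**2 * (1.0 - r_ab) ** 3
    t = (r_a - r_b) * np.sqrt((n - 1) * (1.0 + r_ab) / denom)
    df = n - 3
    p = 2.0 * sps.t.sf(abs(t), df=df)
    return WilliamsResult(t=float(t), df=int(df), p=float(p))


@dataclass(frozen=True)
class ComparisonReport:
    """Item-level fit of each model plus pairwise dependent-correlation tests."""

    correlations: tuple[ItemCorrelation, ...]
    pairwise: tuple[tuple[str, str, WilliamsResult], ...]
    n_conditions: int

    def best_model(self) -> str:
        defined = [c for c in self.correlations if not c.not_applicable]
        if not defined:
            raise ValueError("no model has a defined correlation")
        return max(defined, key=lambda c: c.r).model


def compare_models(
    grids: dict[str, PredictionGrid], means: pd.DataFrame
) -> ComparisonReport:
    """Compare predictor profiles against empirical condition means.

    ``means`` is the frame from :func:`causalsel.simulate.condition_means`
    (indexed by (p_focal, p_alternate)); each model's grid is aligned to
    the settings present there.  Models with constant profiles are
    reported not-applicable and excluded from the pairwise tests.
    """
    if not grids:
        raise ValueError("no prediction grids supplied")
    aligned: dict[str, np.ndarray] = {}
    mean_vec = None
    for name, grid in grids.items():
        frame = grid.to_frame().set_index(["p_focal", "p_alternate"])
        frame.index = pd.MultiIndex.from_tuples(
            [(round(f, 1), round(a, 1)) for f, a in frame.index]
        )
        means_idx = pd.MultiIndex.from_tuples(
            [(round(f, 1), round(a, 1)) for f, a in means.index]
        )
        shared = means_idx.intersection(frame.index)
        if len(shared) < 3:
            raise ValueError("fewer than 3 settings shared between grid and means")
        aligned[name] = frame.loc[shared, "prediction"].to_numpy()
        mean_vec = means.set_axis(means_idx).loc[shared, "mean"].to_numpy()
    n = len(mean_vec)

    correlations = tuple(
        item_correlation(aligned[name], mean_vec, model=name) for name in grids
    )
    defined = {c.model: c.r for c in correlations if not c.not_applicable}
    pairwise = []
    names = list(defined)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            r_ab, _ = sps.pearsonr(aligned[a], aligned[b])
            if not -1.0 + 1e-12 < r_ab < 1.0 - 1e-12:
                continue  # identical profiles: no meaningful contrast
            pairwise.append((a, b, williams_compare(defined[a], defined[b], float(r_ab), n)))
    return ComparisonReport(
        correlations=correlations, pairwise=tuple(pairwise), n_conditions=n
    )
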