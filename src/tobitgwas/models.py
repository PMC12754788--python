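"""The four regression engines used for below-LOD phenotype GWAS.

* linear — OLS on the INT-transformed outcome (statsmodels).
* Tobit — censored-normal maximum likelihood on the INT-transformed outcome,
  with the censored block contributing through the normal CDF at the
  transformed-scale threshold. The likelihood, analytic gradient and
  observed-information standard errors are implemented here.
* Cox — proportional-hazards partial likelihood on the flipped pseudo-time
  (lifelines, Efron tie handling), with the Grambsch-Therneau Schoenfeld
  residual test of the PH assumption.
* logistic — IRLS logistic regression on the above-LOD indicator
  (statsmodels).

All genotype-term p-values are two-sided Wald tests, matching GWAS
convention. Design matrices are column stacks [intercept, genotype,
covariates...]; the Cox engine drops the intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import proportional_hazard_test
from scipy.optimize import minimize
from scipy.special import log_ndtr
from scipy.stats import norm

from .transforms import CoxOutcome, TransformedOutcome

__all__ = [
    "FitResult",
    "build_design",
    "fit_linear",
    "fit_tobit",
    "fit_cox",
    "schoenfeld_ph_test",
    "fit_logistic",
    "MIN_MINOR_ALLELE_COUNT",
    "MIN_MINORITY_CLASS",
]

# genome-wide loops skip near-monomorphic variants instead of raising
MIN_MINOR_ALLELE_COUNT = 3
# logistic fits with a tiny minority class are refused as unstable
MIN_MINORITY_CLASS = 10

_GENO_COL = 1  # column index of the genotype term in an intercept design

_P_FLOOR = 1e-300


@dataclass
class FitResult:
    """Genotype-term estimate from one engine on one variant.

    ``beta`` is the coefficient on the engine's own scale: transformed-scale
    slope (linear/Tobit), log hazard per effect allele (Cox), or log odds of
    being above the LOD per effect allele (logistic).
    """

    model: str
    beta: float
    se: float
    p_value: float
    converged: bool
    n_used: int
    sigma: float | None = None
    diagnostics: dict = field(default_factory=dict)


def build_design(
    genotype: np.ndarray,
    covariates: np.ndarray | None = None,
    intercept: bool = True,
) -> np.ndarray:
    """Stack [intercept, genotype, covariates] and validate rank."""
    g = np.asarray(genotype, dtype=float)
    if g.ndim != 1:
        raise ValueError("genotype must be a 1-D dosage vector")
    if np.ptp(g) == 0:
        raise ValueError("genotype column is constant (monomorphic)")
    cols = [g]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != g.shape[0]:
            raise ValueError("covariates and genotype have different n")
        cols.append(cov)
    if intercept:
        cols.insert(0, np.ones_like(g))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    return X


def _wald_p(beta: float, se: float) -> float:
    if not np.isfinite(se) or se <= 0:
        return np.nan
    return float(max(2.0 * norm.sf(abs(beta) / se), _P_FLOOR))


def fit_linear(
    outcome: TransformedOutcome | np.ndarray, design: np.ndarray
) -> FitResult:
    """Ordinary least squares; two-sided t test on the genotype term."""
    y = outcome.values if isinstance(outcome, TransformedOutcome) else np.asarray(outcome, float)
    n, k = design.shape
    if n <= k:
        raise ValueError("need more observations than design columns")
    res = sm.OLS(y, design).fit()
    return FitResult(
        model="linear",
        beta=float(res.params[_GENO_COL]),
        se=float(res.bse[_GENO_COL]),
        p_value=float(max(res.pvalues[_GENO_COL], _P_FLOOR)),
        converged=True,
        n_used=n,
        sigma=float(np.sqrt(res.scale)),
    )


# ---------------------------------------------------------------------------
# Tobit (left-censored normal) maximum likelihood


def _tobit_nll_grad(theta, X, y, cens, c):
    """Mean negative log-likelihood and gradient, theta = (beta..., log sigma).

    l_i = -log(sigma) + log phi((y_i - x_i b)/sigma)      (uncensored)
    l_i = log Phi((c - x_i b)/sigma)                      (censored)
    """
    k = X.shape[1]
    beta, s = theta[:k], theta[k]
    sigma = np.exp(s)
    xb = X @ beta
    n = y.shape[0]

    r = (y[~cens] - xb[~cens]) / sigma
    u = (c - xb[cens]) / sigma
    # inverse Mills ratio, stable in the lower tail
    lam = np.exp(-0.5 * u * u - 0.5 * np.log(2 * np.pi) - log_ndtr(u))

    nll = -(
        np.sum(-s - 0.5 * np.log(2 * np.pi) - 0.5 * r * r) + np.sum(log_ndtr(u))
    ) / n

    g_beta = -(X[~cens].T @ r - X[cens].T @ lam) / (sigma * n)
    g_s = -(np.sum(r * r) - r.shape[0] - np.sum(u * lam)) / n
    return nll, np.append(g_beta, g_s)


def _numeric_hessian(fun_grad, theta, *args) -> np.ndarray:
    """Central-difference Hessian from the analytic gradient."""
    p = theta.shape[0]
    H = np.empty((p, p))
    for i in range(p):
        h = 1e-5 * (1.0 + abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        _, gp = fun_grad(tp, *args)
        _, gm = fun_grad(tm, *args)
        H[i] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def fit_tobit(
    outcome: TransformedOutcome, design: np.ndarray, max_iter: int = 200
) -> FitResult:
    """Censored-normal MLE with analytic gradient.

    Quasi-Newton (BFGS) on (beta, log sigma) warm-started from OLS on the
    substituted outcome; Nelder-Mead polish on line-search failure. Standard
    errors come from the inverse observed information (numerical Hessian of
    the analytic gradient).
    """
    if outcome.censor_threshold is None:
        raise ValueError("outcome has no censor_threshold; use prepare_tobit_outcome")
    y = np.asarray(outcome.values, dtype=float)
    c = float(outcome.censor_threshold)
    cens = y <= c + 1e-12
    if cens.all():
        raise ValueError("all observations censored: Tobit likelihood degenerate")
    n, k = design.shape
    if n <= k:
        raise ValueError("need more observations than design columns")

    ols = sm.OLS(y, design).fit()
    theta0 = np.append(ols.params, np.log(max(np.sqrt(ols.scale), 1e-3)))

    res = minimize(
        _tobit_nll_grad,
        theta0,
        args=(design, y, cens, c),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-6, "maxiter": max_iter},
    )
    if not res.success:
        # line-search/precision failures: polish with a derivative-free pass
        nm = minimize(
            lambda t: _tobit_nll_grad(t, design, y, cens, c)[0],
            res.x,
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-10, "fatol": 1e-12},
        )
        if nm.fun <= res.fun:
            res = nm
    _, grad = _tobit_nll_grad(res.x, design, y, cens, c)
    grad_norm = float(np.linalg.norm(grad))
    converged = grad_norm < 1e-6 or (res.success and grad_norm < 1e-4)

    H = _numeric_hessian(_tobit_nll_grad, res.x, design, y, cens, c) * n
    try:
        cov = np.linalg.inv(H)
        se = float(np.sqrt(max(cov[_GENO_COL, _GENO_COL], 0.0)))
    except np.linalg.LinAlgError:
        se, converged = np.nan, False

    beta = float(res.x[_GENO_COL])
    return FitResult(
        model="tobit",
        beta=beta,
        se=se,
        p_value=_wald_p(beta, se),
        converged=bool(converged),
        n_used=n,
        sigma=float(np.exp(res.x[k])),
        diagnostics={"grad_norm": grad_norm, "n_censored": int(cens.sum())},
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards on flipped pseudo-time


def _cox_frame(outcome: CoxOutcome, design: np.ndarray):
    import pandas as pd

    # drop the intercept column: the Cox baseline hazard absorbs it
    covars = design[:, 1:] if np.ptp(design[:, 0]) == 0 else design
    cols = {f"x{j}": covars[:, j] for j in range(covars.shape[1])}
    df = pd.DataFrame(
        {"pseudo_time": outcome.pseudo_time, "event": outcome.event.astype(int), **cols}
    )
    return df, "x0"


def fit_cox(outcome: CoxOutcome, design: np.ndarray) -> FitResult:
    """Cox partial likelihood (Efron ties) on the flipped outcome.

    ``beta`` is the change in log hazard per effect allele on the pseudo-time
    scale; a non-event-free fit is required.
    """
    if not outcome.event.any():
        raise ValueError("no events (all observations censored)")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    df, geno_col = _cox_frame(outcome, design)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="pseudo_time", event_col="event")
        beta = float(cph.params_[geno_col])
        se = float(cph.standard_errors_[geno_col])
        converged = np.isfinite(beta) and np.isfinite(se)
    except ConvergenceError as exc:
        return FitResult(
            model="cox", beta=np.nan, se=np.nan, p_value=np.nan,
            converged=False, n_used=outcome.n,
            diagnostics={"error": str(exc)},
        )
    return FitResult(
        model="cox",
        beta=beta,
        se=se,
        p_value=_wald_p(beta, se),
        converged=converged,
        n_used=outcome.n,
        diagnostics={"_fitter": cph, "_frame": df, "geno_col": geno_col},
    )


def schoenfeld_ph_test(
    fit: FitResult,
    outcome: CoxOutcome | None = None,
    design: np.ndarray | None = None,
    time_transform: str = "km",
) -> float:
    """Grambsch-Therneau test of the proportional-hazards assumption.

    Score test for correlation between scaled Schoenfeld residuals and the
    (Kaplan-Meier-transformed, by default) pseudo-time; returns the
    genotype-term p-value, to be read against 0.05 and 5e-8.
    """
    if fit.model != "cox" or not fit.converged:
        raise ValueError("requires a converged Cox fit")
    cph = fit.diagnostics.get("_fitter")
    df = fit.diagnostics.get("_frame")
    if cph is None or df is None:
        if outcome is None or design is None:
            raise ValueError("fit carries no fitter; pass outcome and design")
        refit = fit_cox(outcome, design)
        cph, df = refit.diagnostics["_fitter"], refit.diagnostics["_frame"]
    if int(df["event"].sum()) < 2:
        raise ValueError("Schoenfeld test undefined with fewer than 2 events")
    res = proportional_hazard_test(cph, df, time_transform=time_transform)
    p = res.summary.loc[fit.diagnostics.get("geno_col", "x0"), "p"]
    return float(np.asarray(p).ravel()[0])


# ---------------------------------------------------------------------------
# Logistic regression on the censoring indicator


def fit_logistic(event: np.ndarray, design: np.ndarray) -> FitResult:
    """Logistic MLE (IRLS); beta = log odds of being above the LOD per allele.

    A minority class below ``MIN_MINORITY_CLASS`` yields a refused
    (non-converged) result with a diagnostic instead of unstable estimates.
    """
    y = np.asarray(event).astype(float)
    if y.min() == y.max():
        raise ValueError("single-class outcome: logistic model undefined")
    n_minority = int(min(y.sum(), (1 - y).sum()))
    if n_minority < MIN_MINORITY_CLASS:
        return FitResult(
            model="logistic", beta=np.nan, se=np.nan, p_value=np.nan,
            converged=False, n_used=y.shape[0],
            diagnostics={"reason": f"minority class has {n_minority} < "
                                   f"{MIN_MINORITY_CLASS} observations"},
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=100)
        beta = float(res.params[_GENO_COL])
        se = float(res.bse[_GENO_COL])
        ok = bool(res.mle_retvals.get("converged", False)) and np.isfinite(se)
    except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
        return FitResult(
            model="logistic", beta=np.nan, se=np.nan, p_value=np.nan,
            converged=False, n_used=y.shape[0], diagnostics={"error": str(exc)},
        )
    return FitResult(
        model="logistic",
        beta=beta,
        se=se,
        p_value=_wald_p(beta, se),
        converged=ok,
        n_used=y.shape[0],
    )
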