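"""Maximum-likelihood estimation of EU models and information criteria.

The logistic parametrisation leaves the coefficient space unconstrained, so
the likelihood is maximised directly with a quasi-Newton method (BFGS with the
analytic gradient), followed by a short Newton polish using a finite-difference
Hessian to drive the gradient norm to the convergence tolerance.  The observed
information at the optimum doubles as an identifiability diagnostic: single
embryo transfer data only identify the product of the uterine and embryo
success paths, which shows up as a near-singular Hessian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .model import Dataset, LikelihoodEvaluator, ModelSpec, ParameterVector

__all__ = ["FitResult", "FitWarning", "fit_eu", "information_criteria"]

GRADIENT_TOL = 1e-8
MAX_ITER = 500
HESSIAN_CONDITION_WARN = 1e8


class FitWarning(UserWarning):
    """Non-fatal fitting diagnostics (identifiability, sparse data)."""


@dataclass(frozen=True)
class FitResult:
    """MLE output for one (dataset, spec) pair.

    ``aic = -2 logL + 2 p`` and ``bic = -2 logL + p ln(n_cycles)``; the BIC
    sample size is the number of cycles because the outcome is observed at the
    cycle level.  ``hessian_condition`` is the condition number of the observed
    information (large values flag weak identifiability).  ``se_theta`` are
    diagnostic standard errors from the inverse observed information; all
    hypothesis tests in this package are likelihood-ratio based.
    """

    spec: ModelSpec
    theta_hat: ParameterVector
    logL: float
    aic: float
    bic: float
    n_cycles: int
    converged: bool
    gradient_norm: float
    hessian_condition: float
    n_iter: int
    tolerance: float = GRADIENT_TOL
    se_theta: tuple[float, ...] | None = None


def information_criteria(logL: float, p: int, n_cycles: int) -> tuple[float, float]:
    """AIC and BIC for a fitted model with ``p`` parameters on ``n_cycles`` cycles."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    aic = -2.0 * logL + 2.0 * p
    bic = -2.0 * logL + p * np.log(n_cycles)
    return float(aic), float(bic)


def _starting_values(ev: LikelihoodEvaluator) -> np.ndarray:
    """Crude moment-matched intercepts, zero slopes.

    The uterine intercept assumes roughly half of receptive uteri produce a
    pregnancy, so the receptivity rate is taken as twice the success rate; the
    embryo intercept matches the per-embryo implantation rate among successful
    cycles.  Cheap, deterministic, and robust in the regimes of interest.
    """
    k = ev.k
    n_t = ev.n_transferred
    success = k > 0
    success_rate = float(np.mean(success))
    u0 = np.clip(2.0 * success_rate, 0.02, 0.98)
    if success.any():
        e0 = np.clip(k[success].sum() / n_t[success].sum(), 0.02, 0.98)
    else:
        e0 = 0.02
    theta0 = np.zeros(ev.p)
    theta0[0] = np.log(u0 / (1.0 - u0))
    theta0[ev.X_u.shape[1]] = np.log(e0 / (1.0 - e0))
    return theta0


def _fd_hessian(grad, theta: np.ndarray, h_scale: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of the analytic gradient, symmetrised."""
    p = len(theta)
    H = np.empty((p, p))
    for i in range(p):
        h = h_scale * max(1.0, abs(theta[i]))
        tp = theta.copy()
        tm = theta.copy()
        tp[i] += h
        tm[i] -= h
        H[i] = (grad(tp) - grad(tm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit_eu(
    data: Dataset,
    spec: ModelSpec,
    *,
    start: np.ndarray | None = None,
    gtol: float = GRADIENT_TOL,
    maxiter: int = MAX_ITER,
    diagnostics: bool = True,
) -> FitResult:
    """Fit an EU model by direct maximisation of the likelihood.

    Deterministic given the data and spec.  Non-convergence is reported via
    ``converged=False`` rather than an exception; callers must check.  A
    near-singular observed information (condition number above 1e8, e.g. on
    single-embryo-transfer-only data) triggers a :class:`FitWarning` — such
    data are statistically, not programmatically, degenerate.
    """
    ev = LikelihoodEvaluator(data, spec)
    n_cycles = data.n_cycles
    if n_cycles < ev.p:
        warnings.warn(
            f"only {n_cycles} cycles for {ev.p} free parameters", FitWarning,
            stacklevel=2,
        )

    def neg(theta):
        f, g = ev.value_and_grad(theta)
        return -f, -g

    def grad_only(theta):
        return -ev.value_and_grad(theta)[1]

    theta0 = _starting_values(ev) if start is None else np.asarray(start, float)
    res = minimize(
        neg, theta0, jac=True, method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    theta = res.x
    n_iter = int(res.nit)

    # Newton polish: BFGS can stall with a gradient norm above gtol; damped
    # Newton steps with a finite-difference Hessian finish the job.  Near the
    # optimum the Hessian is essentially constant, so it is computed once and
    # refreshed only if a step fails to shrink the gradient.
    g = grad_only(theta)
    H_polish = None
    fresh = False
    for _ in range(30):
        gn = np.linalg.norm(g)
        if gn <= gtol:
            break
        if H_polish is None:
            H_polish = _fd_hessian(grad_only, theta)
            fresh = True
        try:
            step = np.linalg.solve(H_polish, g)
        except np.linalg.LinAlgError:
            break
        improved = False
        for damp in (1.0, 0.5, 0.1):
            cand = theta - damp * step
            gc = grad_only(cand)
            if np.linalg.norm(gc) < gn:
                theta, g = cand, gc
                improved = True
                break
        n_iter += 1
        if improved:
            fresh = False
        elif fresh:
            break  # even a freshly computed Hessian makes no progress
        else:
            H_polish = None  # refresh and retry

    grad_norm = float(np.linalg.norm(g))
    converged = grad_norm <= gtol

    # observed-information diagnostics (condition number, standard errors);
    # skippable in bulk simulation loops where only theta_hat and logL matter
    cond = float("nan")
    se: tuple[float, ...] | None = None
    if diagnostics:
        H = _fd_hessian(grad_only, theta)
        try:
            cond = float(np.linalg.cond(H))
        except np.linalg.LinAlgError:  # pragma: no cover
            cond = float("inf")
        if not np.isfinite(cond) or cond > HESSIAN_CONDITION_WARN:
            warnings.warn(
                f"observed information is near-singular (condition {cond:.3g}); "
                "the model may be weakly identified on these data",
                FitWarning,
                stacklevel=2,
            )
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            se = tuple(np.sqrt(np.where(d > 0, d, np.nan)))
        except np.linalg.LinAlgError:
            se = None

    logL = float(ev.value(theta))
    aic, bic = information_criteria(logL, spec.p, n_cycles)
    return FitResult(
        spec=spec,
        theta_hat=ParameterVector.from_flat(theta, spec),
        logL=logL,
        aic=aic,
        bic=bic,
        n_cycles=n_cycles,
        converged=converged,
        gradient_norm=grad_norm,
        hessian_condition=cond,
        n_iter=n_iter,
        tolerance=gtol,
        se_theta=se,
    )
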