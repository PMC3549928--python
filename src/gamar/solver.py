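"""Maximum partial likelihood estimation by a modified Newton method.

The update is ``theta <- theta + Gamma*^{-1}(theta) score(theta)`` where
``Gamma*^{-1}`` is the inverse of the observed information after flooring
its eigenvalues at ``delta`` (default 0.01), which keeps the step matrix
positive definite far from the optimum.  A step-halving guard enforces
monotone ascent of the log partial likelihood.  The plain GAM is the
``p = 0`` special case, for which the iteration reduces to Newton scoring
for a Poisson log-linear model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .model_core import (
    Dataset,
    DesignInfo,
    ModelSpec,
    ParameterVector,
    PredictorOverflowError,
    SmoothTerm,
    build_design,
    dispersion,
    information,
    linear_predictor,
    log_partial_likelihood,
    pearson_residuals,
    score,
)

__all__ = [
    "NewtonSettings",
    "FitResult",
    "modified_inverse",
    "fit_gamar",
    "wald_ci",
    "overdispersion_adjusted_ci",
    "aic_grid_search",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NewtonSettings:
    """Tuning knobs of the modified Newton iteration."""

    delta: float = 0.01          # eigenvalue floor for the step matrix
    tol_score: float = 1e-6      # stop when max |score| falls below this
    tol_rel_loglik: float = 1e-9  # ... or the relative log-PL change does
    max_iter: int = 100
    step_halving_max: int = 20

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class FitResult:
    """A fitted GAMAR model and everything Wald inference needs."""

    theta_hat: ParameterVector
    cov: np.ndarray
    se: np.ndarray
    loglik: float
    aic: float
    phi_hat: float
    mu_hat: np.ndarray
    eta_hat: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_iter: int
    stop_reason: str
    spec: Optional[ModelSpec]
    design: DesignInfo
    loglik_trace: Optional[np.ndarray] = None  # accepted log-PL per iteration

    @property
    def n_params(self) -> int:
        return len(self.theta_hat.full)

    def params_frame(self):
        """Tidy per-coefficient table: estimate, se, z, two-sided p."""
        import pandas as pd

        est = self.theta_hat.full
        names = list(self.design.column_names) + [
            f"AR{j + 1}" for j in range(len(self.theta_hat.c))
        ]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, est / self.se, np.inf * np.sign(est))
        p = 2.0 * (1.0 - stats.norm.cdf(np.abs(z)))
        return pd.DataFrame(
            {"term": names, "estimate": est, "se": self.se, "z": z, "p": p}
        )


def modified_inverse(gamma: np.ndarray, delta: float = 0.01) -> np.ndarray:
    """Eigenvalue-floored inverse ``P diag(max(lambda_i, delta)^-1) P^T``.

    Equals the ordinary inverse whenever every eigenvalue already exceeds
    ``delta``; otherwise returns the nearest positive-definite surrogate in
    the eigenbasis.
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim != 2 or gamma.shape[0] != gamma.shape[1]:
        raise ValueError("information matrix must be square")
    asym = np.max(np.abs(gamma - gamma.T))
    scale = max(1.0, np.max(np.abs(gamma)))
    if asym > 1e-8 * scale:
        raise ValueError(f"matrix not symmetric (max asymmetry {asym:.3g})")
    lam, P = np.linalg.eigh((gamma + gamma.T) / 2.0)
    lam_star = np.maximum(lam, delta)
    inv = (P / lam_star) @ P.T
    return (inv + inv.T) / 2.0


def _safe_loglik(theta, design, y, ystar) -> float:
    try:
        return log_partial_likelihood(theta, design, y, ystar)
    except PredictorOverflowError:
        return -math.inf


def fit_gamar(
    spec: ModelSpec,
    data: Dataset,
    settings: NewtonSettings = NewtonSettings(),
    init: Optional[ParameterVector] = None,
    design: Optional[DesignInfo] = None,
) -> FitResult:
    """Fit a Poisson GAMAR by maximum partial likelihood.

    With no ``init``, the spline/linear coefficients start from a ``p = 0``
    fit (itself started at ``beta0 = ln mean(y*)``) and the AR coefficients
    at zero.  Non-convergence is flagged on the result, not raised.
    """
    if design is None:
        design = build_design(spec, data)
    X = design.X
    y = data.y[design.offset :]
    ystar = data.ystar(spec.tau)[design.offset :]
    m, p = X.shape[1], spec.ar_order
    if X.shape[0] - p <= m + p:
        raise ValueError("series too short for the requested model")
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            "design matrix is numerically singular; most collinear columns: "
            f"{design.column_names[i + 1]!r} and {design.column_names[j + 1]!r}"
        )

    if init is None:
        beta0 = np.zeros(m)
        beta0[0] = math.log(float(np.mean(ystar)))
        if p > 0:
            base = fit_gamar(
                replace_ar(spec, 0), data, settings, ParameterVector(beta0), design
            )
            beta0 = base.theta_hat.beta
        theta = ParameterVector(beta0, np.zeros(p))
    else:
        theta = ParameterVector(np.array(init.beta), np.array(init.c))

    ll = _safe_loglik(theta, design, y, ystar)
    trace = [ll]
    converged = False
    reason = "max_iter"
    it = 0
    for it in range(1, settings.max_iter + 1):
        g = score(theta, design, y, ystar)
        if np.max(np.abs(g)) < settings.tol_score:
            converged, reason = True, "score"
            break
        gamma = information(theta, design, y, ystar)
        step = modified_inverse(gamma, settings.delta) @ g
        new_theta, new_ll = theta, ll
        ok = False
        for _ in range(settings.step_halving_max + 1):
            cand = ParameterVector.from_full(theta.full + step, m)
            cll = _safe_loglik(cand, design, y, ystar)
            if cll >= ll - 1e-12 * max(1.0, abs(ll)):
                new_theta, new_ll, ok = cand, cll, True
                break
            step = step / 2.0
        if not ok:
            reason = "step_halving_failed"
            break
        rel = abs(new_ll - ll) / max(1.0, abs(ll))
        theta, ll = new_theta, new_ll
        trace.append(ll)
        if rel < settings.tol_rel_loglik:
            converged = np.max(np.abs(score(theta, design, y, ystar))) < 1e-3
            reason = "loglik"
            break

    gamma = information(theta, design, y, ystar)
    cov = modified_inverse(gamma, settings.delta)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    eta = linear_predictor(theta, design, ystar)
    mu = np.exp(eta)
    z = pearson_residuals(mu, y[p:])
    phi = dispersion(z, m + p)
    ll = log_partial_likelihood(theta, design, y, ystar)
    return FitResult(
        theta_hat=theta,
        cov=cov,
        se=se,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * (m + p),
        phi_hat=phi,
        mu_hat=mu,
        eta_hat=eta,
        residuals=z,
        converged=converged,
        n_iter=it,
        stop_reason=reason,
        spec=spec,
        design=design,
        loglik_trace=np.asarray(trace),
    )


def replace_ar(spec: ModelSpec, p: int) -> ModelSpec:
    """Copy of ``spec`` with a different AR order."""
    return ModelSpec(terms=list(spec.terms), ar_order=p, tau=spec.tau, link=spec.link)


def wald_ci(fit: FitResult, level: float = 0.95) -> np.ndarray:
    """Per-parameter normal intervals ``theta_hat +- z * se``; rows are
    ``(lower, upper)``."""
    zq = stats.norm.ppf((1.0 + level) / 2.0)
    est = fit.theta_hat.full
    return np.column_stack([est - zq * fit.se, est + zq * fit.se])


def overdispersion_adjusted_ci(fit: FitResult, level: float = 0.95) -> np.ndarray:
    """Wald intervals with standard errors inflated by ``sqrt(phi_hat)``;
    the point estimates themselves are unchanged."""
    zq = stats.norm.ppf((1.0 + level) / 2.0)
    se = fit.se * math.sqrt(max(fit.phi_hat, 0.0))
    est = fit.theta_hat.full
    return np.column_stack([est - zq * se, est + zq * se])


def aic_grid_search(
    data: Dataset,
    base_spec: ModelSpec,
    df_grid: dict,
    lag_grid: Optional[dict] = None,
    settings: NewtonSettings = NewtonSettings(),
    max_sweeps: int = 10,
) -> ModelSpec:
    """Coordinate-descent AIC minimisation over smooth-term df and lag.

    ``df_grid``/``lag_grid`` map a smooth term's covariate name to the
    candidate values.  Each sweep optimises one coordinate at a time,
    holding the others fixed, and sweeps repeat until no single change
    lowers the AIC.  Ties prefer the smaller df/lag; grid points whose fit
    fails are skipped with a warning.
    """
    lag_grid = lag_grid or {}
    spec = base_spec

    def try_aic(s: ModelSpec) -> float:
        try:
            fit = fit_gamar(s, data, settings)
        except (ValueError, PredictorOverflowError) as exc:
            logger.warning("grid point failed: %s", exc)
            return math.inf
        if not fit.converged:
            logger.warning("grid point did not converge")
            return math.inf
        return fit.aic

    def set_term(s: ModelSpec, name: str, df=None, lag=None) -> ModelSpec:
        terms = []
        for t in s.terms:
            if isinstance(t, SmoothTerm) and t.covariate == name:
                terms.append(
                    SmoothTerm(
                        t.covariate,
                        df if df is not None else t.df,
                        lag if lag is not None else t.lag,
                    )
                )
            else:
                terms.append(t)
        return ModelSpec(terms, s.ar_order, s.tau, s.link)

    best = try_aic(spec)
    coords = [("df", name, vals) for name, vals in df_grid.items()]
    coords += [("lag", name, vals) for name, vals in lag_grid.items()]
    for _ in range(max_sweeps):
        improved = False
        for kind, name, vals in coords:
            for v in sorted(vals):
                cand = set_term(spec, name, **{kind: int(v)})
                a = try_aic(cand)
                if a < best - 1e-9:
                    spec, best, improved = cand, a, True
        if not improved:
            break
    if not math.isfinite(best):
        raise ValueError("no grid point produced a converged fit")
    return spec
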