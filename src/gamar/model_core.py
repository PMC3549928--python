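"""Poisson GAMAR model: data container, design matrix, partial likelihood.

The model for daily counts ``y_t`` with covariate row ``X_t`` is

    y_t | past  ~  Poisson(mu_t)
    ln mu_t = eta_t = sum_i beta_i X_ti
              + sum_{j=1..p} c_j ( ln y*_{t-j} - sum_i beta_i X_{t-j,i} )

where ``y*_t = max(y_t, tau)`` with a positive threshold ``tau`` so the log
is always defined, and the AR terms feed back past discrepancies between
the observed (log) count and the covariate part of the predictor.  The
design matrix columns are an intercept, natural-spline basis blocks,
plain linear columns and factor indicator columns; splines make the
predictor linear in all of ``theta = (beta, c)``.

Estimation is by maximum partial likelihood conditional on the first ``p``
observations: the product of Poisson conditionals runs over
``t = p+1 .. n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .splines import BasisMatrix, SplineSpec, build_spline_spec, evaluate_basis

__all__ = [
    "Dataset",
    "SmoothTerm",
    "LinearTerm",
    "FactorTerm",
    "ModelSpec",
    "DesignInfo",
    "ParameterVector",
    "clip_counts",
    "build_design",
    "linear_predictor",
    "log_partial_likelihood",
    "score",
    "information",
    "pearson_residuals",
    "dispersion",
]

#: predictor ceiling; exp(50) counts would be astronomically outside the
#: Poisson regime this model targets and signals a diverging recursion
ETA_MAX = 50.0


class PredictorOverflowError(FloatingPointError):
    """Linear predictor exploded; reports the first offending time index."""


def clip_counts(y: Sequence[float], tau: float) -> np.ndarray:
    """``y* = max(y, tau)`` elementwise; makes ``ln y*`` well defined."""
    if tau <= 0:
        raise ValueError(f"threshold tau must be positive, got {tau}")
    y = np.asarray(y, dtype=float)
    return np.maximum(y, tau)


@dataclass
class Dataset:
    """Contiguous daily count series plus covariates.

    ``frame`` must contain the count column and every covariate; the index
    is an integer day counter, 1-based and gap-free (AR lags assume
    contiguity).
    """

    frame: pd.DataFrame
    count_col: str = "y"

    def __post_init__(self) -> None:
        t = np.asarray(self.frame.index)
        if len(t) > 1 and not np.all(np.diff(t) == 1):
            gaps = np.asarray(self.frame.index)[:-1][np.diff(t) != 1]
            raise ValueError(f"day index has gaps after positions {gaps[:5].tolist()}")
        y = self.y
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise ValueError("counts must be nonnegative integers")

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.frame[self.count_col], dtype=float)

    def ystar(self, tau: float) -> np.ndarray:
        return clip_counts(self.y, tau)

    def covariate(self, name: str) -> np.ndarray:
        return np.asarray(self.frame[name])

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class SmoothTerm:
    """Natural-spline smooth of a (possibly lagged) covariate."""

    covariate: str
    df: int
    lag: int = 0
    knots: Optional[SplineSpec] = None

    def label(self) -> str:
        if self.lag:
            return f"ns({self.covariate}_l{self.lag},{self.df})"
        return f"ns({self.covariate},{self.df})"


@dataclass(frozen=True)
class LinearTerm:
    covariate: str
    lag: int = 0

    def label(self) -> str:
        return f"lin({self.covariate}{f'_l{self.lag}' if self.lag else ''})"


@dataclass(frozen=True)
class FactorTerm:
    """Dummy coding of a categorical covariate (reference level omitted)."""

    covariate: str
    reference: Optional[str] = None

    def label(self) -> str:
        return f"factor({self.covariate})"


Term = Union[SmoothTerm, LinearTerm, FactorTerm]


@dataclass
class ModelSpec:
    """Full model definition: terms, AR order and count threshold."""

    terms: list
    ar_order: int = 0
    tau: float = 0.5
    link: str = "log"

    def __post_init__(self) -> None:
        if self.ar_order < 0:
            raise ValueError("ar_order must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.link != "log":
            raise ValueError("only the log link is supported")
        cats = [t.covariate for t in self.terms if isinstance(t, FactorTerm)]
        if len(cats) != len(set(cats)):
            raise ValueError("at most one factor term per categorical covariate")


@dataclass
class DesignInfo:
    """Expanded ``n_eff x m`` design matrix with term metadata.

    ``offset`` rows were dropped from the head of the series because a
    lagged covariate was unavailable there; ``X`` and the responses align
    with ``dataset.frame.iloc[offset:]``.
    """

    X: np.ndarray
    column_names: list
    column_map: dict
    spline_specs: dict
    offset: int

    @property
    def m(self) -> int:
        return self.X.shape[1]


def build_design(spec: ModelSpec, data: Dataset) -> DesignInfo:
    """Assemble intercept + spline blocks + linear + indicator columns.

    Lagged terms shift the covariate back in time; rows whose lagged value
    would fall before the start of the series are dropped, so the design
    starts at ``offset = max(lag)``.
    """
    n = len(data)
    max_lag = max([0] + [t.lag for t in spec.terms if not isinstance(t, FactorTerm)])
    rows = slice(max_lag, n)

    cols = [np.ones(n - max_lag)]
    names = ["(intercept)"]
    column_map: dict = {"(intercept)": [0]}
    spline_specs: dict = {}
    j = 1
    for term in spec.terms:
        if isinstance(term, SmoothTerm):
            x_full = np.asarray(data.covariate(term.covariate), dtype=float)
            x = x_full[max_lag - term.lag : n - term.lag]
            sspec = term.knots or build_spline_spec(x, term.df, name=term.covariate)
            basis: BasisMatrix = evaluate_basis(sspec, x)
            cols.append(basis.values)
            lbl = term.label()
            names += [f"{lbl}.{k + 1}" for k in range(term.df)]
            column_map[lbl] = list(range(j, j + term.df))
            spline_specs[lbl] = sspec
            j += term.df
        elif isinstance(term, LinearTerm):
            x_full = np.asarray(data.covariate(term.covariate), dtype=float)
            cols.append(x_full[max_lag - term.lag : n - term.lag, None])
            column_map[term.label()] = [j]
            names.append(term.label())
            j += 1
        elif isinstance(term, FactorTerm):
            v = pd.Series(data.covariate(term.covariate)[rows])
            levels = list(pd.unique(v))
            ref = term.reference if term.reference is not None else levels[0]
            others = [lv for lv in levels if lv != ref]
            ind = np.column_stack([(v == lv).to_numpy(float) for lv in others])
            cols.append(ind)
            lbl = term.label()
            names += [f"{lbl}[{lv}]" for lv in others]
            column_map[lbl] = list(range(j, j + len(others)))
            j += len(others)
        else:
            raise TypeError(f"unknown term type {type(term).__name__}")

    X = np.column_stack(cols)
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite entries")
    return DesignInfo(
        X=X,
        column_names=names,
        column_map=column_map,
        spline_specs=spline_specs,
        offset=max_lag,
    )


@dataclass
class ParameterVector:
    """``theta = (beta_1..beta_m, c_1..c_p)``."""

    beta: np.ndarray
    c: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float)) if len(
            np.atleast_1d(self.c)
        ) else np.empty(0)
        if not (np.all(np.isfinite(self.beta)) and np.all(np.isfinite(self.c))):
            raise ValueError("parameters must be finite")

    @property
    def full(self) -> np.ndarray:
        return np.concatenate([self.beta, self.c])

    @classmethod
    def from_full(cls, theta: np.ndarray, m: int) -> "ParameterVector":
        theta = np.asarray(theta, dtype=float)
        return cls(beta=theta[:m], c=theta[m:])


def _ar_parts(theta: ParameterVector, X: np.ndarray, log_ystar: np.ndarray):
    """Shared pieces of eta and its derivatives on the window t = p+1..n.

    Returns ``(eta, Xt, R)`` where ``Xt[t, i] = X_ti - sum_r c_r X_{t-r,i}``
    is d(eta)/d(beta) and ``R[t, j] = ln y*_{t-j} - X_{t-j} beta`` is
    d(eta)/d(c_j), both stacked over the estimation window.
    """
    p = len(theta.c)
    n = X.shape[0]
    if n - p < 1:
        raise ValueError("series shorter than AR order")
    xb = X @ theta.beta
    resid = log_ystar - xb  # ln y*_t - X_t beta, full length
    eta = xb[p:].copy()
    Xt = X[p:].copy()
    R = np.empty((n - p, p))
    for j in range(1, p + 1):
        eta += theta.c[j - 1] * resid[p - j : n - j]
        Xt -= theta.c[j - 1] * X[p - j : n - j]
        R[:, j - 1] = resid[p - j : n - j]
    return eta, Xt, R


def linear_predictor(
    theta: ParameterVector,
    design: DesignInfo,
    ystar: np.ndarray,
    p: Optional[int] = None,
) -> np.ndarray:
    """``eta_t`` on the estimation window ``t = p+1 .. n``.

    ``ystar`` aligns with ``design.X`` (both start at ``design.offset``).
    Raises :class:`PredictorOverflowError` when ``exp(eta)`` would not be
    representable, naming the first bad window position.
    """
    if p is not None and p != len(theta.c):
        raise ValueError(f"p={p} inconsistent with len(c)={len(theta.c)}")
    eta, _, _ = _ar_parts(theta, design.X, np.log(np.asarray(ystar, dtype=float)))
    if np.any(eta > ETA_MAX) or not np.all(np.isfinite(eta)):
        bad = int(np.argmax((eta > ETA_MAX) | ~np.isfinite(eta)))
        raise PredictorOverflowError(
            f"linear predictor overflow at window position {bad} "
            f"(eta={eta[bad]:.3g})"
        )
    return eta


def log_partial_likelihood(
    theta: ParameterVector, design: DesignInfo, y: np.ndarray, ystar: np.ndarray
) -> float:
    """Sum of Poisson log-densities ``y_t ln mu_t - mu_t - ln y_t!`` over
    the estimation window (conditional on the first ``p`` points)."""
    p = len(theta.c)
    eta = linear_predictor(theta, design, ystar)
    mu = np.exp(eta)
    yw = np.asarray(y, dtype=float)[p:]
    return float(np.sum(yw * eta - mu - gammaln(yw + 1.0)))


def score(
    theta: ParameterVector, design: DesignInfo, y: np.ndarray, ystar: np.ndarray
) -> np.ndarray:
    """Analytic gradient of the log partial likelihood.

    ``d lnPL / d theta_i = sum_t (y_t - mu_t) d eta_t / d theta_i`` with
    ``d eta/d beta_i = X_ti - sum_r c_r X_{t-r,i}`` and
    ``d eta/d c_j = ln y*_{t-j} - X_{t-j} beta``.
    """
    p = len(theta.c)
    eta, Xt, R = _ar_parts(theta, design.X, np.log(np.asarray(ystar, dtype=float)))
    w = np.asarray(y, dtype=float)[p:] - np.exp(eta)
    return np.concatenate([Xt.T @ w, R.T @ w])


def information(
    theta: ParameterVector, design: DesignInfo, y: np.ndarray, ystar: np.ndarray
) -> np.ndarray:
    """Observed information ``Gamma = -d2 lnPL / d theta d theta^T``.

    Block form ``[[A, B], [B^T, C]]`` with

        A_ij = sum_t mu_t (deta/dbeta_i)(deta/dbeta_j)
        B_ij = sum_t mu_t (deta/dbeta_i)(deta/dc_j) + (y_t - mu_t) X_{t-j,i}
        C_ij = sum_t mu_t (deta/dc_i)(deta/dc_j)

    The cross block keeps the ``(y - mu)`` term coming from the bilinear
    part of eta, so this is the observed (not expected) information.
    """
    p = len(theta.c)
    X = design.X
    n = X.shape[0]
    eta, Xt, R = _ar_parts(theta, X, np.log(np.asarray(ystar, dtype=float)))
    mu = np.exp(eta)
    w = np.asarray(y, dtype=float)[p:] - mu
    A = (Xt * mu[:, None]).T @ Xt
    C = (R * mu[:, None]).T @ R
    B = (Xt * mu[:, None]).T @ R
    for j in range(1, p + 1):
        B[:, j - 1] += X[p - j : n - j].T @ w
    gamma = np.vstack([np.hstack([A, B]), np.hstack([B.T, C])])
    return (gamma + gamma.T) / 2.0  # exact symmetry despite matmul rounding


def pearson_residuals(mu_hat: np.ndarray, y: np.ndarray) -> np.ndarray:
    """``z_t = (y_t - mu_t) / sqrt(mu_t)``; white noise under a good fit."""
    mu_hat = np.asarray(mu_hat, dtype=float)
    if np.any(mu_hat <= 0):
        raise ValueError("fitted means must be strictly positive")
    return (np.asarray(y, dtype=float) - mu_hat) / np.sqrt(mu_hat)


def dispersion(z: np.ndarray, n_params: int) -> float:
    """Pearson dispersion ``phi = sum z^2 / (n_eff - n_params)``; values
    well above 1 flag overdispersion (or unmodelled autocorrelation)."""
    z = np.asarray(z, dtype=float)
    if len(z) <= n_params:
        raise ValueError("residual window no longer than parameter count")
    return float(np.sum(z**2) / (len(z) - n_params))
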