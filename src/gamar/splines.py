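"""Natural cubic spline bases for smooth covariate terms.

A natural cubic spline on an interval [a, b] with interior knots
``xi_1 < ... < xi_{df-1}`` is piecewise cubic, has continuous value, first
and second derivative at every interior knot, and is linear beyond the
boundary knots.  The spline space including the constant function has
dimension ``df + 1``; this module produces a basis of ``df`` columns that,
together with an explicit intercept column, spans that space.  The model
layer always carries its own intercept, so the basis here deliberately
excludes it.

Construction: the cubic B-spline basis on the augmented knot sequence is
restricted to the natural-spline subspace by projecting onto the null
space of the two second-derivative-at-boundary constraints (QR based,
mirroring the convention of the widely used ``ns()`` design).  Beyond the
boundary knots each basis function is continued by its tangent line at the
boundary, which is exact for a natural spline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineSpec", "BasisMatrix", "build_spline_spec", "evaluate_basis"]


class DegenerateBasisError(ValueError):
    """Raised when the requested basis cannot be built from the data."""


@dataclass(frozen=True)
class SplineSpec:
    """Knot layout of a natural cubic spline term.

    Parameters
    ----------
    covariate_name
        Name of the covariate the basis is built for.
    df
        Number of basis columns (regression degrees of freedom excluding
        the intercept).
    boundary_knots
        Pair ``(a, b)`` delimiting the cubic region.
    interior_knots
        ``df - 1`` strictly increasing knots inside ``(a, b)``.
    """

    covariate_name: str
    df: int
    boundary_knots: tuple[float, float]
    interior_knots: tuple[float, ...]

    def __post_init__(self) -> None:
        a, b = self.boundary_knots
        ik = np.asarray(self.interior_knots, dtype=float)
        if self.df < 1:
            raise ValueError(f"df must be >= 1, got {self.df}")
        if len(ik) != self.df - 1:
            raise ValueError(
                f"need df-1={self.df - 1} interior knots, got {len(ik)}"
            )
        if not a < b:
            raise ValueError(f"boundary knots must satisfy a < b, got ({a}, {b})")
        if len(ik) and (np.any(np.diff(ik) <= 0) or ik[0] <= a or ik[-1] >= b):
            raise DegenerateBasisError(
                "interior knots must be strictly increasing and strictly "
                f"inside ({a}, {b}); got {ik.tolist()}"
            )

    def to_dict(self) -> dict:
        return {
            "covariate": self.covariate_name,
            "df": self.df,
            "boundary_knots": [float(k) for k in self.boundary_knots],
            "interior_knots": [float(k) for k in self.interior_knots],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(
            covariate_name=d["covariate"],
            df=int(d["df"]),
            boundary_knots=tuple(float(k) for k in d["boundary_knots"]),
            interior_knots=tuple(float(k) for k in d["interior_knots"]),
        )


@dataclass(frozen=True)
class BasisMatrix:
    """Evaluated basis: an ``n x df`` matrix plus the spec that built it."""

    values: np.ndarray
    spec: SplineSpec


def build_spline_spec(
    x: Sequence[float],
    df: int,
    name: str = "x",
    placement: str = "quantile",
) -> SplineSpec:
    """Choose knots for a natural spline with ``df`` basis columns.

    Boundary knots sit at ``min(x)`` and ``max(x)``.  With
    ``placement="quantile"`` (default) the ``df - 1`` interior knots sit at
    the ``j/df`` quantiles of ``x``; ``placement="uniform"`` spaces them
    evenly over the range instead.  The two coincide for uniform grids.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate contains non-finite values")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if np.unique(x).size < df + 1:
        raise DegenerateBasisError(
            f"need at least df+1={df + 1} distinct covariate values, "
            f"got {np.unique(x).size}"
        )
    a, b = float(np.min(x)), float(np.max(x))
    if df == 1:
        interior = np.empty(0)
    elif placement == "quantile":
        interior = np.quantile(x, np.arange(1, df) / df)
    elif placement == "uniform":
        interior = a + (b - a) * np.arange(1, df) / df
    else:
        raise ValueError(f"unknown knot placement {placement!r}")
    if len(interior) and (
        np.any(np.diff(interior) <= 0) or interior[0] <= a or interior[-1] >= b
    ):
        raise DegenerateBasisError(
            "tied quantiles produced coincident knots; reduce df or "
            "deduplicate the covariate"
        )
    return SplineSpec(
        covariate_name=name,
        df=int(df),
        boundary_knots=(a, b),
        interior_knots=tuple(float(k) for k in interior),
    )


def _natural_transform(spec: SplineSpec) -> tuple[np.ndarray, np.ndarray]:
    """Augmented knot vector and the (df+2) x df null-space map.

    The full cubic B-spline basis on the knots has ``df + 3`` functions.
    The first is dropped (its role is absorbed by the model intercept) and
    the remaining ``df + 2`` are mapped onto the null space of the two
    second-derivative constraints at the boundary knots, leaving ``df``
    natural-spline basis functions.
    """
    a, b = spec.boundary_knots
    knots = np.concatenate(
        ([a] * 4, spec.interior_knots, [b] * 4)
    )
    # second derivatives of each B-spline at the two boundary knots,
    # built column by column from scalar BSpline objects
    nb = len(knots) - 4
    d2 = np.empty((2, nb))
    for j in range(nb):
        coef = np.zeros(nb)
        coef[j] = 1.0
        d2[:, j] = BSpline(knots, coef, 3)(np.array([a, b]), nu=2)
    const = d2[:, 1:]  # drop first B-spline
    q, _ = np.linalg.qr(const.T, mode="complete")
    return knots, q[:, 2:]


def evaluate_basis(spec: SplineSpec, x: Sequence[float]) -> BasisMatrix:
    """Evaluate the ``df`` natural-spline basis functions at ``x``.

    Points outside the boundary knots are handled by linear continuation of
    each basis function from the nearer boundary (value plus first
    derivative there), the defining tail behaviour of a natural spline.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("evaluation points contain non-finite values")
    a, b = spec.boundary_knots
    knots, nullmap = _natural_transform(spec)
    nb = knots.size - 4

    xc = np.clip(x, a, b)
    design = BSpline.design_matrix(xc, knots, 3).toarray()

    outside = (x < a) | (x > b)
    if np.any(outside):
        d1 = np.empty((2, nb))
        for j in range(nb):
            coef = np.zeros(nb)
            coef[j] = 1.0
            d1[:, j] = BSpline(knots, coef, 3)(np.array([a, b]), nu=1)
        lo = x < a
        hi = x > b
        design[lo] += np.outer(x[lo] - a, d1[0])
        design[hi] += np.outer(x[hi] - b, d1[1])

    values = design[:, 1:] @ nullmap
    return BasisMatrix(values=np.ascontiguousarray(values), spec=spec)
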