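"""Residual correlogram diagnostics for AR-order selection.

Pearson residuals of a well-specified model should be white noise.  The
sample ACF tails off and the PACF cuts off after lag ``p`` when an AR(p)
structure is left in the residuals, so lags whose PACF exceeds the
white-noise band ``+- z / sqrt(n)`` point at AR terms worth modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CorrelogramResult", "acf", "pacf", "whiteness_report"]


def acf(z: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelations ``rho(1..max_lag)``, biased-denominator
    convention (divide by the lag-0 sum of squares)."""
    z = np.asarray(z, dtype=float)
    n = len(z)
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the series length")
    zc = z - z.mean()
    denom = float(zc @ zc)
    if denom == 0.0:
        raise ValueError("constant series has undefined autocorrelation")
    return np.array([float(zc[: n - k] @ zc[k:]) / denom for k in range(1, max_lag + 1)])


def pacf(z: np.ndarray, max_lag: int) -> np.ndarray:
    """Partial autocorrelations via the Durbin-Levinson recursion on the
    biased sample ACF.  ``pacf[0] == acf[0]`` by construction."""
    rho = acf(z, max_lag)
    phi = np.zeros((max_lag + 1, max_lag + 1))
    out = np.empty(max_lag)
    phi[1, 1] = rho[0]
    out[0] = rho[0]
    for k in range(2, max_lag + 1):
        num = rho[k - 1] - np.sum(phi[k - 1, 1:k] * rho[k - 2 :: -1][: k - 1])
        den = 1.0 - np.sum(phi[k - 1, 1:k] * rho[: k - 1])
        phi[k, k] = num / den
        phi[k, 1:k] = phi[k - 1, 1:k] - phi[k, k] * phi[k - 1, k - 1 : 0 : -1]
        out[k - 1] = phi[k, k]
    return out


@dataclass
class CorrelogramResult:
    """ACF/PACF over lags 1..L with the white-noise confidence band."""

    lags: np.ndarray
    acf: np.ndarray
    pacf: np.ndarray
    bound: float
    level: float
    flagged_acf: np.ndarray
    flagged_pacf: np.ndarray
    suggested_order: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "lag": self.lags,
                "acf": self.acf,
                "pacf": self.pacf,
                "acf_flagged": self.flagged_acf,
                "pacf_flagged": self.flagged_pacf,
            }
        )


def whiteness_report(
    z: np.ndarray, max_lag: int = 20, level: float = 0.95
) -> CorrelogramResult:
    """Flag lags whose |PACF| exceeds the white-noise band and suggest an
    AR order (the largest flagged PACF lag; 0 when none are flagged)."""
    z = np.asarray(z, dtype=float)
    a = acf(z, max_lag)
    pa = pacf(z, max_lag)
    bound = float(stats.norm.ppf((1.0 + level) / 2.0) / np.sqrt(len(z)))
    fa = np.abs(a) > bound
    fp = np.abs(pa) > bound
    order = int(np.max(np.nonzero(fp)[0]) + 1) if np.any(fp) else 0
    return CorrelogramResult(
        lags=np.arange(1, max_lag + 1),
        acf=a,
        pacf=pa,
        bound=bound,
        level=level,
        flagged_acf=fa,
        flagged_pacf=fp,
        suggested_order=order,
    )
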