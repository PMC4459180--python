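"""Global carrying-coefficient regression (MLRA).

The multiple linear regression decomposes the total POC export flux of each
station into mineral-associated portions plus a non-associated residual::

    f_poc = a·f_pic + b·f_bsi + c·f_lith + d + ε

``a``, ``b``, ``c`` are the *carrying coefficients* (mg POC per mg mineral
exported) and the intercept ``d`` is the portion of POC export not
statistically associated with any mineral phase (mg m⁻² d⁻¹).  Coefficients
are unconstrained: negative values are reported as-is.

Model comparison uses the small-sample corrected AIC in the Gaussian form
common in the geographically-weighted-regression literature, so the global
fit and the local (GWR) fit are scored on one scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .data_io import StationTable

logger = logging.getLogger(__name__)

#: Number of regression parameters (three carrying coefficients + intercept).
N_PARAMS = 4


class SingularityError(ValueError):
    """Design matrix is rank deficient."""


class DataError(ValueError):
    """Too few complete stations to fit the model."""


@dataclass
class GlobalFit:
    """Global MLRA carrying coefficients with fit statistics.

    ``a``, ``b``, ``c`` in mg C per mg mineral (PIC, BSi, lithogenic);
    ``d`` in mg m⁻² d⁻¹.  ``aicc`` uses :func:`aicc_gaussian` with
    ``k_eff = p + 1`` (regression parameters plus the error variance).
    """

    a: float
    b: float
    c: float
    d: float
    r2: float
    aicc: float
    rss: float
    n: int
    p: int
    residuals: np.ndarray
    fitted: np.ndarray

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficient vector ordered as the design matrix [pic, bsi, lith, 1]."""
        return np.array([self.a, self.b, self.c, self.d])

    def predict(self, table: StationTable) -> np.ndarray:
        return table.design_matrix() @ self.coefficients


def aicc_gaussian(rss: float, n: int, k_eff: float) -> float:
    """Small-sample corrected AIC for a Gaussian model.

    AICc = 2n·ln σ̂ + n·ln 2π + n·(n + k_eff)/(n − 2 − k_eff), σ̂ = √(rss/n).

    ``k_eff`` is the effective number of parameters; in the local-regression
    setting it plays the role of the hat-matrix trace tr(S), which makes the
    criterion comparable between a global fit and a GWR fit.
    """
    if rss <= 0:
        raise ValueError("rss must be > 0")
    if n <= k_eff + 2:
        raise ValueError(f"degenerate degrees of freedom: n={n} <= k_eff+2={k_eff + 2}")
    sigma_hat = math.sqrt(rss / n)
    return 2.0 * n * math.log(sigma_hat) + n * math.log(2.0 * math.pi) + n * (n + k_eff) / (
        n - 2.0 - k_eff
    )


def fit_mlra(table: StationTable) -> GlobalFit:
    """Fit the global POC-vs-mineral-flux regression by ordinary least squares.

    Requires at least 5 complete stations and a full-rank design
    [f_pic, f_bsi, f_lith, 1].  Coefficients are unconstrained.

    Raises
    ------
    DataError
        Fewer than 5 complete stations.
    SingularityError
        Collinear mineral-flux columns.
    """
    X = table.design_matrix()
    y = table.column("f_poc")
    complete = np.isfinite(X).all(axis=1) & np.isfinite(y)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("excluding %d station(s) with incomplete fluxes from the MLRA", n_dropped)
        X, y = X[complete], y[complete]
    n = X.shape[0]
    if n < 5:
        raise DataError(f"need >= 5 complete stations, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < N_PARAMS:
        # name the offending columns: those whose removal restores full rank
        names = ["f_pic", "f_bsi", "f_lith", "intercept"]
        collinear = [
            names[j]
            for j in range(N_PARAMS)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise SingularityError(f"rank-deficient design; collinear column(s): {collinear}")

    res = sm.OLS(y, X).fit()
    residuals = np.asarray(res.resid)
    rss = float(residuals @ residuals)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    if rss <= 0:
        aicc = float("-inf")
    elif n <= N_PARAMS + 3:
        logger.warning("too few stations (n=%d) for a finite AICc; reporting NaN", n)
        aicc = float("nan")
    else:
        aicc = aicc_gaussian(rss, n, N_PARAMS + 1)
    return GlobalFit(
        a=float(res.params[0]),
        b=float(res.params[1]),
        c=float(res.params[2]),
        d=float(res.params[3]),
        r2=r2,
        aicc=aicc,
        rss=rss,
        n=n,
        p=N_PARAMS,
        residuals=residuals,
        fitted=np.asarray(res.fittedvalues),
    )
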