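"""Empirical exponential model of qL, the fraction of open PSII reaction centers.

qL declines nonlinearly as photosynthetically active radiation (PAR) rises,
because closed reaction centers accumulate under high light.  The model is

    qL(PAR) = a * exp(b * PAR),      a > 0,  b <= 0,

fitted to (qL, PAR) pairs by nonlinear least squares on the original scale,
initialized from a log-linear fit.  The fitted (a, b) feed the SIF-to-ETR
conversion in :mod:`siftraits.retrieval`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QLPair:
    """One (PAR, qL) observation. PAR in W m-2; qL a fraction in (0, 1]."""

    par: float
    ql: float

    def __post_init__(self) -> None:
        if not self.par >= 0:
            raise ValueError(f"PAR must be >= 0, got {self.par}")
        if not 0 < self.ql <= 1:
            raise ValueError(f"qL must lie in (0, 1], got {self.ql}")


@dataclass(frozen=True)
class QLModel:
    """Fitted qL(PAR) = a*exp(b*PAR) with fit diagnostics.

    ``r2`` is None for models built from config keys rather than a fit.
    ``b`` must be non-positive: qL cannot increase with light.
    """

    a: float
    b: float
    r2: float | None = None
    n: int = 0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"amplitude a must be > 0, got {self.a}")
        if self.b > 0:
            raise ValueError(
                f"rate coefficient b must be <= 0 (qL non-increasing in PAR), got {self.b}"
            )
        if self.r2 is not None and not 0 <= self.r2 <= 1:
            raise ValueError(f"r2 must lie in [0, 1], got {self.r2}")


def _as_arrays(pairs: Iterable[QLPair | Sequence[float]]) -> tuple[np.ndarray, np.ndarray]:
    par, ql = [], []
    for p in pairs:
        if isinstance(p, QLPair):
            par.append(p.par)
            ql.append(p.ql)
        else:
            pr, q = p
            par.append(float(pr))
            ql.append(float(q))
    return np.asarray(par, dtype=float), np.asarray(ql, dtype=float)


def loglinear_init(par: np.ndarray, ql: np.ndarray) -> tuple[float, float]:
    """Log-linear starting point: OLS of ln(qL) on PAR.

    Log-transforming reweights the residuals, so this is only used to seed
    the nonlinear optimizer, never as the final estimate.
    """
    coef = np.polyfit(par, np.log(ql), 1)
    b0 = float(coef[0])
    a0 = float(math.exp(coef[1]))
    return a0, b0


def fit_ql_par(pairs: Iterable[QLPair | Sequence[float]], maxfev: int = 10000) -> QLModel:
    """Fit qL = a*exp(b*PAR) by least squares on the original scale.

    Parameters
    ----------
    pairs
        (PAR, qL) observations, as :class:`QLPair` or 2-sequences.
        At least 3 pairs with at least 2 distinct PAR values.
    maxfev
        Iteration cap for the nonlinear optimizer.

    Returns
    -------
    QLModel
        Fitted (a, b) with R^2 = 1 - SSres/SStot computed on the original
        (not log) scale.

    Raises
    ------
    ValueError
        Fewer than 3 pairs, a degenerate PAR column, or a fitted b > 0.
    RuntimeError
        Optimizer non-convergence within ``maxfev`` evaluations.
    """
    par, ql = _as_arrays(pairs)
    if par.size < 3:
        raise ValueError(f"need at least 3 (qL, PAR) pairs, got {par.size}")
    if np.unique(par).size < 2:
        raise ValueError("PAR column is degenerate: need at least 2 distinct values")
    if np.any(ql <= 0) or np.any(ql > 1):
        raise ValueError("qL values must lie in (0, 1]")
    if np.any(par < 0):
        raise ValueError("PAR values must be >= 0")

    a0, b0 = loglinear_init(par, ql)
    popt, _ = curve_fit(
        lambda x, a, b: a * np.exp(b * x), par, ql, p0=(a0, min(b0, 0.0)), maxfev=maxfev
    )
    a, b = float(popt[0]), float(popt[1])
    resid = ql - a * np.exp(b * par)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((ql - ql.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if r2 < 0:
        logger.warning("exponential fit worse than the mean (R^2 clipped to 0)")
        r2 = 0.0
    return QLModel(a=a, b=b, r2=r2, n=int(par.size))


def predict_ql(model: QLModel, par):
    """Evaluate qL(PAR) = a*exp(b*PAR), clamped into (0, 1].

    Accepts a scalar or array of PAR values (W m-2, non-negative).  Values
    above 1 (possible when a > 1) are clamped to 1 and the event is logged;
    the raw exponential is strictly positive so no lower clamp is needed.
    """
    par_arr = np.asarray(par, dtype=float)
    if np.any(par_arr < 0):
        raise ValueError("PAR must be >= 0")
    raw = model.a * np.exp(model.b * par_arr)
    n_clamped = int(np.count_nonzero(raw > 1.0))
    if n_clamped:
        logger.warning("clamped %d qL prediction(s) above 1 to 1.0", n_clamped)
    out = np.minimum(raw, 1.0)
    if np.isscalar(par) or par_arr.ndim == 0:
        return float(out)
    return out
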