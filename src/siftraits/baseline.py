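"""Empirical linear SIF-to-Vcmax baseline.

The comparison model: ordinary least squares of observed Vcmax on SIF,
pooled across the series, with an intercept.  Negative predictions are
floored at zero because Vcmax is non-negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinearModel:
    """OLS fit of Vcmax on SIF: slope in (umol m-2 s-1)/(mW m-2 nm-1 sr-1)."""

    slope: float
    intercept: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"linear model needs n >= 2 samples, got {self.n}")


def fit_linear(sif, vcmax_obs) -> LinearModel:
    """Fit the pooled OLS baseline vcmax_obs ~ slope*sif + intercept.

    Requires equal-length inputs of length >= 2 with at least 2 distinct
    SIF values.
    """
    x = np.asarray(sif, dtype=float)
    y = np.asarray(vcmax_obs, dtype=float)
    if x.shape != y.shape:
        raise ValueError("sif and vcmax_obs must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if np.unique(x).size < 2:
        raise ValueError("degenerate input: SIF values are all identical")
    res = stats.linregress(x, y)
    return LinearModel(slope=float(res.slope), intercept=float(res.intercept), n=int(x.size))


def predict_linear(model: LinearModel, sif):
    """Predict Vcmax = slope*SIF + intercept, floored at 0.

    Negative raw predictions (possible with a negative intercept at low
    SIF) are floored at zero and logged.
    """
    x = np.asarray(sif, dtype=float)
    raw = model.slope * x + model.intercept
    n_floored = int(np.count_nonzero(raw < 0))
    if n_floored:
        logger.warning("floored %d negative Vcmax prediction(s) at 0", n_floored)
    out = np.maximum(raw, 0.0)
    if np.isscalar(sif):
        return float(out)
    return out
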