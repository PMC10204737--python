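"""Accuracy indices for trait retrievals: R^2, MAE, RMSE, OLS slope.

R^2 is the squared Pearson correlation between observed and predicted
values, reported together with the slope/intercept of the OLS regression
of predictions on observations (the scatter-plot convention).  Note that a
high R^2 alone does not imply agreement: a perfectly anticorrelated
prediction also has R^2 = 1 but slope -1.

"Accuracy improvement" between two methods is defined on MAE:
100*(MAE_baseline - MAE_model)/MAE_baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class EvalMetrics:
    r2: float
    mae: float
    rmse: float
    slope: float
    intercept: float
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.r2 <= 1 + 1e-12:
            raise ValueError(f"r2 must lie in [0, 1], got {self.r2}")
        if self.mae < 0 or self.rmse < 0:
            raise ValueError("mae and rmse must be >= 0")


def evaluate(obs, pred) -> EvalMetrics:
    """Compare predictions against observations.

    Parameters
    ----------
    obs, pred
        Equal-length numeric sequences, length >= 2; ``obs`` must have
        nonzero variance.

    Returns
    -------
    EvalMetrics
        r2 (squared Pearson correlation), mae, rmse, and slope/intercept
        of the OLS fit of ``pred`` on ``obs``.
    """
    x = np.asarray(obs, dtype=float)
    y = np.asarray(pred, dtype=float)
    if x.shape != y.shape:
        raise ValueError("obs and pred must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if np.var(x) == 0:
        raise ValueError("obs has zero variance")

    err = y - x
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if np.var(y) == 0:
        # constant prediction: correlation undefined; no linear association
        r2, slope, intercept = 0.0, 0.0, float(y[0])
    else:
        r = stats.pearsonr(x, y).statistic
        r2 = float(min(r * r, 1.0))
        ols = stats.linregress(x, y)
        slope, intercept = float(ols.slope), float(ols.intercept)
    return EvalMetrics(r2=r2, mae=mae, rmse=rmse, slope=slope, intercept=intercept, n=int(x.size))


def improvement_percent(mae_baseline: float, mae_model: float) -> float:
    """Relative MAE reduction of a model over a baseline, in percent.

    100*(mae_baseline - mae_model)/mae_baseline; positive when the model
    beats the baseline, negative when it is worse.
    """
    if not mae_baseline > 0:
        raise ValueError(f"mae_baseline must be > 0, got {mae_baseline}")
    if mae_model < 0:
        raise ValueError(f"mae_model must be >= 0, got {mae_model}")
    return 100.0 * (mae_baseline - mae_model) / mae_baseline
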