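"""Forward simulator: synthetic canopy seasons with known trait truth.

Generates a growing season of (SIF, PAR, NIRv, FPAR) observations from a
prescribed true Vcmax trajectory by inverting the retrieval chain, so the
noise-free simulation is the exact algebraic inverse of
:func:`siftraits.retrieval.retrieve_series`:

* Vcmax*(d): a smooth log-normal-shaped seasonal curve peaking early and
  declining toward harvest.
* ETR* = 4*Vcmax**mc/m; gs* = (dr/4)*m*ETR*/(Ca-Ci).
* qL* = a*exp(b*PAR(d)), with PAR following a smooth seasonal arc.
* Noise-free SIF = ETR**(1-Phi)*eps / (qL**Phi*(1+kDF)), eps = NIRv/FPAR.
* Observed SIF/NIRv/FPAR = truth times mean-one lognormal noise with a
  given coefficient of variation, deterministic under the seed.

NIRv and FPAR follow a double-logistic green-up/senescence trajectory.
The simulator emulates the site-season structure of a rice paddy campaign;
it makes no claim about instrument error, canopy radiative transfer, or
diurnal cycles (one value per day).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .io_timeseries import TraitSeries
from .ql_model import QLPair, QLModel
from .retrieval import PhotoParams, m_factor, mc_factor, mechanistic_gain, gs_from_etr

CurveFn = Callable[[np.ndarray], np.ndarray]


def _double_logistic(t: np.ndarray, lo: float, hi: float,
                     t_up: float = 0.15, k_up: float = 25.0,
                     t_down: float = 0.90, k_down: float = 18.0) -> np.ndarray:
    """Green-up/senescence trajectory on normalized season time t in [0, 1]."""
    g = 1.0 / (1.0 + np.exp(-k_up * (t - t_up)))
    g *= 1.0 / (1.0 + np.exp(k_down * (t - t_down)))
    return lo + (hi - lo) * g


def default_fpar_curve(t: np.ndarray) -> np.ndarray:
    return _double_logistic(t, 0.15, 0.95)


def default_nirv_curve(t: np.ndarray) -> np.ndarray:
    return _double_logistic(t, 0.05, 0.55)


@dataclass
class SimConfig:
    """Conditions of one synthetic season.

    ``vcmax_shape`` is (mode, sigma) of the log-normal-shaped seasonal
    curve on normalized time t in (0, 1]: Vcmax(t) =
    vcmax_peak * exp(-ln(t/mode)^2 / (2*sigma^2)), peaking at t = mode.
    PAR (W m-2) follows par_amplitude*(0.65 + 0.35*sin(pi*t)), a smooth
    arc between 65% and 100% of the amplitude.  Noise CVs are the
    coefficients of variation of the mean-one lognormal observation noise
    on SIF and on the reflectance indices (NIRv, FPAR) respectively.
    """

    n_days: int = 120
    year: int = 2017
    doy_start: int = 150
    vcmax_peak: float = 130.0
    vcmax_shape: tuple[float, float] = (0.25, 0.8)
    par_amplitude: float = 500.0
    ql_a: float = 0.9
    ql_b: float = -0.001
    nirv_curve: CurveFn = field(default=default_nirv_curve)
    fpar_curve: CurveFn = field(default=default_fpar_curve)
    noise_cv_sif: float = 0.05
    noise_cv_index: float = 0.0
    seed: int = 42
    photo: PhotoParams = field(default_factory=PhotoParams)

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.vcmax_peak <= 0 or self.par_amplitude <= 0:
            raise ValueError("vcmax_peak and par_amplitude must be > 0")
        if self.noise_cv_sif < 0 or self.noise_cv_index < 0:
            raise ValueError("noise CVs must be >= 0")
        mode, sigma = self.vcmax_shape
        if mode <= 0 or sigma <= 0:
            raise ValueError("vcmax_shape (mode, sigma) must be positive")
        if self.ql_a <= 0 or self.ql_b > 0:
            raise ValueError("qL truth requires a > 0 and b <= 0")


@dataclass
class SyntheticTruth:
    """Noise-free per-day truth, internally consistent with the chain."""

    frame: pd.DataFrame  # year, doy, par, nirv, fpar, epsilon, ql, etr, vcmax, gs, sif

    def __len__(self) -> int:
        return len(self.frame)


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(0.0, sigma, n) - sigma**2 / 2.0)


def simulate_season(cfg: SimConfig) -> tuple[TraitSeries, SyntheticTruth]:
    """Generate one synthetic season and its generating truth.

    Deterministic given (cfg, cfg.seed); two calls yield identical output.
    With zero noise CVs, running the retrieval on the returned TraitSeries
    reproduces the truth to machine precision.
    """
    p = cfg.photo
    d = np.arange(cfg.n_days)
    t = (d + 1) / cfg.n_days  # normalized season time in (0, 1]
    # seasons longer than a calendar year roll into subsequent years
    doy_raw = cfg.doy_start + d - 1
    year = cfg.year + doy_raw // 365
    doy = doy_raw % 365 + 1

    mode, sigma = cfg.vcmax_shape
    vcmax = cfg.vcmax_peak * np.exp(-np.log(t / mode) ** 2 / (2.0 * sigma**2))
    par = cfg.par_amplitude * (0.65 + 0.35 * np.sin(np.pi * t))
    nirv = np.asarray(cfg.nirv_curve(t), dtype=float)
    fpar = np.asarray(cfg.fpar_curve(t), dtype=float)
    if np.any(fpar <= 0) or np.any(fpar > 1) or np.any(nirv <= 0):
        raise ValueError("nirv/fpar curves must stay within physical ranges")
    eps = nirv / fpar

    m, mc = m_factor(p), mc_factor(p)
    etr = 4.0 * vcmax * mc / m
    gs = gs_from_etr(etr, p)
    ql = cfg.ql_a * np.exp(cfg.ql_b * par)
    sif_true = etr * eps / (ql * mechanistic_gain(p) * p.sif_scale)

    rng = np.random.default_rng(cfg.seed)
    sif_obs = sif_true * _lognormal_factors(rng, cfg.noise_cv_sif, cfg.n_days)
    nirv_obs = nirv * _lognormal_factors(rng, cfg.noise_cv_index, cfg.n_days)
    fpar_obs = np.minimum(fpar * _lognormal_factors(rng, cfg.noise_cv_index, cfg.n_days), 1.0)

    obs = pd.DataFrame(
        {
            "year": year.astype(int),
            "doy": doy.astype(int),
            "sif": sif_obs,
            "par": par,
            "nirv": nirv_obs,
            "fpar": fpar_obs,
            "vcmax_obs": vcmax,
            "gs_obs": gs,
        }
    )
    truth = pd.DataFrame(
        {
            "year": year.astype(int),
            "doy": doy.astype(int),
            "par": par,
            "nirv": nirv,
            "fpar": fpar,
            "epsilon": eps,
            "ql": ql,
            "etr": etr,
            "vcmax": vcmax,
            "gs": gs,
            "sif": sif_true,
        }
    )
    label = f"synthetic-{cfg.year}-seed{cfg.seed}"
    return TraitSeries(frame=obs, label=label), SyntheticTruth(frame=truth)


def generate_ql_pairs(
    a: float,
    b: float,
    n: int = 40,
    par_max: float = 2000.0,
    noise_sd: float = 0.0,
    seed: int = 42,
) -> list[QLPair]:
    """Synthetic (qL, PAR) pairs on an even PAR grid [0, par_max].

    qL = a*exp(b*PAR) + Gaussian(0, noise_sd), clamped into (0, 1];
    deterministic given the seed.  Stands in for model-simulated pairs
    when fitting :func:`siftraits.ql_model.fit_ql_par`.
    """
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if par_max <= 0:
        raise ValueError("par_max must be > 0")
    if a <= 0 or b > 0:
        raise ValueError("truth requires a > 0 and b <= 0")
    par = np.linspace(0.0, par_max, n)
    ql = a * np.exp(b * par)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ql = ql + rng.normal(0.0, noise_sd, n)
    ql = np.clip(ql, 1e-6, 1.0)
    return [QLPair(par=float(pr), ql=float(q)) for pr, q in zip(par, ql)]
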