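"""Mechanistic SIF -> ETR -> Vcmax / gs retrieval chain for a C3 canopy.

The chain has three stages:

1. **SIF to ETR.**  In the "lake" model of PSII energy partitioning, the
   electron transport rate is proportional to SIF through the fraction of
   open reaction centers qL, the maximum PSII photochemical yield
   Phi_PSIImax, the thermal-dissipation/fluorescence rate-constant ratio
   kDF = kD/kF, and the canopy escape probability eps ~ NIRv/FPAR::

       ETR = qL(PAR) * Phi * (1 + kDF) / ((1 - Phi) * eps) * SIF

   With the rice defaults Phi = 0.83 and kDF = 19 the mechanistic gain
   Phi*(1+kDF)/(1-Phi) is 97.647059.

2. **ETR to Vcmax.**  Evolutionary optimality assumes Rubisco-limited and
   electron-transport-limited assimilation are coordinated, Ac = Aj.  With
   Ac = Vcmax*mc and Aj = (ETR/4)*m, where m = (Ci-G)/(Ci+2G) and
   mc = (Ci-G)/(Ci+Km) (G the CO2 compensation point), this gives
   Vcmax = ETR*m/(4*mc).

3. **ETR to gs.**  Net assimilation A = (ETR/4)*m (electron-use
   efficiency), combined with Fick's law A = gs*(Ca-Ci)/1.6, gives
   gs = 0.4*m*ETR/(Ca-Ci).

CO2 quantities are treated as mole fractions (umol mol-1); only differences
and ratios enter, so any internally consistent unit works.  SIF enters in
mW m-2 nm-1 sr-1 with the radiometric conversion absorbed into the
proportionality; ``PhotoParams.sif_scale`` exposes an optional user
calibration factor (default 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .ql_model import QLModel, predict_ql

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhotoParams:
    """Physiological and biochemical constants of the retrieval chain.

    Attributes
    ----------
    phi_psii_max
        Maximum PSII photochemical quantum yield (dark-adapted Fv/Fm
        analog), in (0, 1).  Default 0.83, typical for unstressed C3 leaves.
    k_df
        Ratio kD/kF of the thermal-dissipation to fluorescence rate
        constants, > 0.  Default 19.
    ci, ca
        Intercellular / ambient CO2 mole fraction, umol mol-1.  Defaults
        280 and 400 (the standard Ci/Ca ~ 0.7 C3 operating point).
    gamma_star
        CO2 compensation point without mitochondrial respiration,
        umol mol-1.  Default 42.75 (25 C).
    km
        Effective Michaelis-Menten constant of Rubisco for CO2 in the
        presence of O2, umol mol-1.  Default 711 (25 C).
    diffusivity_ratio
        Water-to-CO2 diffusivity ratio in Fick's law.  Default 1.6.
    sif_scale
        Optional unit-calibration factor multiplying SIF before the chain.
        Default 1.0 (use the radiance values literally).
    """

    phi_psii_max: float = 0.83
    k_df: float = 19.0
    ci: float = 280.0
    ca: float = 400.0
    gamma_star: float = 42.75
    km: float = 711.0
    diffusivity_ratio: float = 1.6
    sif_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.phi_psii_max < 1:
            raise ValueError(f"phi_psii_max must lie in (0, 1), got {self.phi_psii_max}")
        if not self.k_df > 0:
            raise ValueError(f"k_df must be > 0, got {self.k_df}")
        if not self.ca > self.ci > self.gamma_star > 0:
            raise ValueError(
                f"require ca > ci > gamma_star > 0, got ca={self.ca}, "
                f"ci={self.ci}, gamma_star={self.gamma_star}"
            )
        if not self.km > 0:
            raise ValueError(f"km must be > 0, got {self.km}")
        if not self.diffusivity_ratio > 0:
            raise ValueError(f"diffusivity_ratio must be > 0, got {self.diffusivity_ratio}")
        if not self.sif_scale > 0:
            raise ValueError(f"sif_scale must be > 0, got {self.sif_scale}")

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


@dataclass
class RetrievalSeries:
    """Per-timestamp derived quantities plus the inputs that produced them.

    ``frame`` columns: year, doy, epsilon, ql, etr, vcmax, gs (gs is NaN
    for ETR/Vcmax-only runs), preserving the source series ordering.
    """

    frame: pd.DataFrame
    params_used: PhotoParams
    ql_model_used: QLModel
    n_skipped: int = 0
    label: str = ""

    def __len__(self) -> int:
        return len(self.frame)


def mechanistic_gain(p: PhotoParams) -> float:
    """The scaling constant Phi*(1+kDF)/(1-Phi): 97.647059 at defaults."""
    return p.phi_psii_max * (1.0 + p.k_df) / (1.0 - p.phi_psii_max)


def escape_ratio(nirv, fpar):
    """Canopy escape probability eps ~ NIRv / FPAR.

    The fraction of emitted fluorescence photons escaping the canopy toward
    the sensor.  Accepts scalars or arrays; requires fpar in (0, 1] and
    nirv >= 0.
    """
    nirv_arr = np.asarray(nirv, dtype=float)
    fpar_arr = np.asarray(fpar, dtype=float)
    if np.any(fpar_arr <= 0) or np.any(fpar_arr > 1):
        raise ValueError("fpar must lie in (0, 1]")
    if np.any(nirv_arr < 0):
        raise ValueError("nirv must be >= 0")
    out = nirv_arr / fpar_arr
    if np.isscalar(nirv) and np.isscalar(fpar):
        return float(out)
    return out


def etr_from_sif(sif, par, ql_model: QLModel, p: PhotoParams, epsilon):
    """Electron transport rate from SIF, PAR and the escape probability.

    ETR = qL(PAR) * Phi*(1+kDF)/(1-Phi) * SIF / eps, umol m-2 s-1.
    ``epsilon`` must be strictly positive (use :func:`escape_ratio`).
    """
    sif_arr = np.asarray(sif, dtype=float)
    eps_arr = np.asarray(epsilon, dtype=float)
    if np.any(sif_arr < 0):
        raise ValueError("sif must be >= 0")
    if np.any(eps_arr <= 0):
        raise ValueError("epsilon must be > 0 (degenerate NIRv/FPAR record)")
    ql = predict_ql(ql_model, par)
    out = np.asarray(ql) * mechanistic_gain(p) * (p.sif_scale * sif_arr) / eps_arr
    if np.isscalar(sif):
        return float(out)
    return out


def m_factor(p: PhotoParams) -> float:
    """Electron-transport CO2 factor m = (Ci - G)/(Ci + 2G), in (0, 1)."""
    return (p.ci - p.gamma_star) / (p.ci + 2.0 * p.gamma_star)


def mc_factor(p: PhotoParams) -> float:
    """Rubisco CO2 factor mc = (Ci - G)/(Ci + Km), in (0, 1)."""
    return (p.ci - p.gamma_star) / (p.ci + p.km)


def vcmax_from_etr(etr, p: PhotoParams):
    """Maximum carboxylation rate via Ac = Aj coordination.

    Solving Vcmax*mc = (ETR/4)*m gives Vcmax = ETR * m / (4 * mc),
    umol m-2 s-1.  Linear in ETR at fixed parameters.
    """
    etr_arr = np.asarray(etr, dtype=float)
    if np.any(etr_arr < 0):
        raise ValueError("etr must be >= 0")
    out = etr_arr * m_factor(p) / (4.0 * mc_factor(p))
    if np.isscalar(etr):
        return float(out)
    return out


def gs_from_etr(etr, p: PhotoParams):
    """Stomatal conductance via electron-use efficiency and Fick's law.

    gs = (diffusivity_ratio/4) * m * ETR / (Ca - Ci), mol m-2 s-1 when
    (Ca - Ci) is in umol mol-1 and ETR in umol m-2 s-1.  With the default
    ratio 1.6 this is 0.4*m*ETR/(Ca-Ci).
    """
    etr_arr = np.asarray(etr, dtype=float)
    if np.any(etr_arr < 0):
        raise ValueError("etr must be >= 0")
    if not p.ca > p.ci:
        raise ValueError("require ca > ci")
    out = (p.diffusivity_ratio / 4.0) * m_factor(p) * etr_arr / (p.ca - p.ci)
    if np.isscalar(etr):
        return float(out)
    return out


def retrieve_series(
    series,
    ql_model: QLModel,
    p: PhotoParams,
    compute_gs: bool = True,
) -> RetrievalSeries:
    """Run the full chain over a :class:`~siftraits.io_timeseries.TraitSeries`.

    Per record: eps = NIRv/FPAR, qL = qL(PAR), ETR from SIF, Vcmax from
    ETR, and (unless ``compute_gs`` is False) gs from ETR.  Records with a
    degenerate escape probability (eps <= 0) or negative SIF are skipped
    and logged; output length + skip count equals input length.

    Raises
    ------
    ValueError
        If every record is skipped.
    """
    df = series.frame
    valid = (df["fpar"] > 0) & (df["fpar"] <= 1) & (df["nirv"] > 0) & (df["sif"] >= 0)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.warning(
            "skipped %d record(s) with degenerate NIRv/FPAR or negative SIF", n_skipped
        )
    sub = df.loc[valid]
    if sub.empty:
        raise ValueError("all records skipped: no valid NIRv/FPAR/SIF values")

    eps = escape_ratio(sub["nirv"].to_numpy(), sub["fpar"].to_numpy())
    par = sub["par"].to_numpy()
    ql = predict_ql(ql_model, par)
    etr = np.asarray(ql) * mechanistic_gain(p) * (p.sif_scale * sub["sif"].to_numpy()) / eps
    vcmax = vcmax_from_etr(etr, p)
    gs = gs_from_etr(etr, p) if compute_gs else np.full(len(sub), np.nan)

    out = pd.DataFrame(
        {
            "year": sub["year"].to_numpy(),
            "doy": sub["doy"].to_numpy(),
            "epsilon": eps,
            "ql": ql,
            "etr": etr,
            "vcmax": vcmax,
            "gs": gs,
        }
    )
    if "hour" in sub.columns:
        out["hour"] = sub["hour"].to_numpy()
    return RetrievalSeries(
        frame=out.reset_index(drop=True),
        params_used=p,
        ql_model_used=ql_model,
        n_skipped=n_skipped,
        label=getattr(series, "label", ""),
    )
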