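"""CSV time-series and flat-YAML config I/O.

Input series are plain comma-separated files with a header row, '.' decimal
and UTF-8 encoding, one row per (year, day-of-year) timestamp.  Missing or
invalid rows are dropped and logged rather than imputed.  Configuration is
a flat YAML key-value mapping covering the photosynthetic constants
(phi_psii_max, k_df, ci, ca, gamma_star, km, diffusivity_ratio) and the
fitted qL-model coefficients (ql_a, ql_b).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .retrieval import PhotoParams, RetrievalSeries

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("year", "doy", "sif", "par", "nirv", "fpar")
OPTIONAL_COLUMNS = ("vcmax_obs", "gs_obs", "hour")

RETRIEVAL_COLUMNS = ("year", "doy", "epsilon", "ql", "etr", "vcmax", "gs")

#: Config keys that map onto PhotoParams fields.
PHOTO_KEYS = (
    "phi_psii_max",
    "k_df",
    "ci",
    "ca",
    "gamma_star",
    "km",
    "diffusivity_ratio",
    "sif_scale",
)


@dataclass(frozen=True)
class TraitRecord:
    """One observed timestamp of the canopy series.

    SIF in mW m-2 nm-1 sr-1, PAR in W m-2, NIRv unitless, FPAR in (0, 1];
    observed traits, when present, in umol m-2 s-1 (Vcmax) and
    mol m-2 s-1 (gs).
    """

    year: int
    doy: int
    sif: float
    par: float
    nirv: float
    fpar: float
    vcmax_obs: float | None = None
    gs_obs: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.doy <= 366:
            raise ValueError(f"doy must lie in [1, 366], got {self.doy}")
        if self.sif < 0 or self.par < 0 or self.nirv < 0:
            raise ValueError("sif, par and nirv must be >= 0")
        if not 0 < self.fpar <= 1:
            raise ValueError(f"fpar must lie in (0, 1], got {self.fpar}")


@dataclass
class TraitSeries:
    """An ordered, validated canopy time series backed by a DataFrame."""

    frame: pd.DataFrame
    label: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.frame.empty:
            raise ValueError("TraitSeries must be non-empty")
        keys = self.frame[["year", "doy"]]
        if keys.duplicated().any():
            raise ValueError("(year, doy) pairs must be unique within a series")
        k = keys.to_numpy()
        order = np.lexsort((k[:, 1], k[:, 0]))
        if not np.array_equal(order, np.arange(len(k))):
            raise ValueError("records must be sorted ascending by (year, doy)")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> Iterator[TraitRecord]:
        for row in self.frame.itertuples(index=False):
            yield TraitRecord(
                year=int(row.year),
                doy=int(row.doy),
                sif=float(row.sif),
                par=float(row.par),
                nirv=float(row.nirv),
                fpar=float(row.fpar),
                vcmax_obs=float(row.vcmax_obs)
                if "vcmax_obs" in self.frame.columns and np.isfinite(row.vcmax_obs)
                else None,
                gs_obs=float(row.gs_obs)
                if "gs_obs" in self.frame.columns and np.isfinite(row.gs_obs)
                else None,
            )


def read_timeseries(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    label: str = "",
) -> TraitSeries:
    """Read and validate a canopy time-series CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Optional mapping from canonical names (``year``, ``doy``, ``sif``,
        ``par``, ``nirv``, ``fpar``, and optionally ``vcmax_obs``,
        ``gs_obs``, ``hour``) to the column names in the file.  Canonical
        names are used directly when omitted.

    Rows whose required fields are missing, non-numeric, or outside the
    physical ranges (sif/par/nirv >= 0, 0 < fpar <= 1) are dropped and the
    count logged.

    Raises
    ------
    FileNotFoundError
        Missing file.
    ValueError
        A mapped column absent from the file, or zero valid rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    raw = pd.read_csv(path)

    column_map = dict(column_map or {})
    rename = {}
    for canonical in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source in raw.columns:
            rename[source] = canonical
        elif canonical in REQUIRED_COLUMNS:
            raise ValueError(f"required column '{source}' (for '{canonical}') not found in {path}")
    df = raw.rename(columns=rename)
    keep = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df = df[keep].apply(pd.to_numeric, errors="coerce")

    valid = df[list(REQUIRED_COLUMNS)].notna().all(axis=1)
    valid &= (df["sif"] >= 0) & (df["par"] >= 0) & (df["nirv"] >= 0)
    valid &= (df["fpar"] > 0) & (df["fpar"] <= 1)
    valid &= (df["doy"] >= 1) & (df["doy"] <= 366)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("dropped %d invalid row(s) while reading %s", n_dropped, path)
    df = df.loc[valid].copy()
    if df.empty:
        raise ValueError(f"zero valid rows after filtering in {path}")
    df["year"] = df["year"].astype(int)
    df["doy"] = df["doy"].astype(int)
    df = df.sort_values(["year", "doy"]).reset_index(drop=True)
    return TraitSeries(frame=df, label=label or path.stem, n_dropped=n_dropped)


def write_retrieval(path: str | Path, series: RetrievalSeries) -> None:
    """Write a retrieval series as CSV (year,doy,epsilon,ql,etr,vcmax,gs).

    Values are printed at 10 significant digits so the file round-trips
    through :func:`read_retrieval` within 1e-9 relative.  An empty series
    yields a header-only file; NaN entries (e.g. gs from an ETR-only run)
    are written as empty cells.
    """
    df = series.frame
    cols = [c for c in RETRIEVAL_COLUMNS if c in df.columns] or list(RETRIEVAL_COLUMNS)
    if df.empty:
        pd.DataFrame(columns=list(RETRIEVAL_COLUMNS)).to_csv(path, index=False)
        return
    df[cols].to_csv(path, index=False, float_format="%.10g")


def read_retrieval(path: str | Path) -> pd.DataFrame:
    """Read back a retrieval CSV written by :func:`write_retrieval`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return pd.read_csv(path)


def load_config(path: str | Path | None) -> tuple[PhotoParams, dict]:
    """Load a flat YAML config into PhotoParams plus remaining run options.

    Keys in :data:`PHOTO_KEYS` populate :class:`PhotoParams`, falling back
    to its documented defaults; all other keys (e.g. ``ql_a``, ``ql_b``)
    are returned in the options dict.  ``path=None`` yields full defaults.

    Raises
    ------
    ValueError
        Unparsable file, non-mapping content, non-numeric values, or a
        parameter outside its admissible range (via PhotoParams).
    """
    if path is None:
        return PhotoParams(), {}
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config file: {path}")
    try:
        data = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ValueError(f"unparsable config {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")

    photo_kwargs = {}
    options = {}
    for key, value in data.items():
        if key in PHOTO_KEYS:
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ValueError(f"config key '{key}' must be numeric, got {value!r}")
            photo_kwargs[key] = float(value)
        else:
            options[key] = value
    return PhotoParams(**photo_kwargs), options


def dump_config(path: str | Path, params: PhotoParams, extra: Mapping | None = None) -> None:
    """Write PhotoParams (plus extra keys such as ql_a/ql_b) as flat YAML."""
    data = {k: getattr(params, k) for k in PHOTO_KEYS}
    if extra:
        data.update(extra)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
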