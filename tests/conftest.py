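import numpy as np
import pandas as pd
import pytest

from siftraits import PhotoParams, QLModel, SimConfig, simulate_season


@pytest.fixture
def params43() -> PhotoParams:
    """Defaults with the round compensation point used in worked examples."""
    return PhotoParams(ci=280.0, ca=400.0, gamma_star=43.0, km=711.0)


@pytest.fixture
def ql_default() -> QLModel:
    return QLModel(a=0.9, b=-0.001)


@pytest.fixture
def noisefree_season():
    cfg = SimConfig(noise_cv_sif=0.0, noise_cv_index=0.0)
    series, truth = simulate_season(cfg)
    return cfg, series, truth


@pytest.fixture
def season_csv(tmp_path):
    """Write a small valid observation CSV and return its path."""

    def _write(rows=None, name="season.csv", columns=None):
        if rows is None:
            rows = [
                (2017, 180, 1.2, 400.0, 0.30, 0.90),
                (2017, 181, 1.5, 450.0, 0.32, 0.92),
                (2017, 182, 1.1, 380.0, 0.28, 0.88),
            ]
        cols = columns or ["year", "doy", "sif", "par", "nirv", "fpar"]
        path = tmp_path / name
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        return path

    return _write
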