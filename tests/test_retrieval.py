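"""The mechanistic SIF -> ETR -> Vcmax / gs chain and its invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from siftraits import (
    PhotoParams,
    QLModel,
    escape_ratio,
    etr_from_sif,
    gs_from_etr,
    m_factor,
    mc_factor,
    retrieve_series,
    vcmax_from_etr,
)
from siftraits.io_timeseries import TraitSeries
from siftraits.retrieval import mechanistic_gain

# PAR at which qL(a=0.9, b=-0.001) is exactly 0.3
PAR_QL03 = math.log(0.3 / 0.9) / -0.001


class TestEscapeRatio:
    @pytest.mark.parametrize(
        "nirv, fpar, expected",
        [(0.3, 0.9, 1 / 3), (0.0, 0.5, 0.0), (0.5, 0.5, 1.0)],
    )
    def test_values(self, nirv, fpar, expected):
        assert escape_ratio(nirv, fpar) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_fpar_rejected(self):
        with pytest.raises(ValueError):
            escape_ratio(0.3, 0.0)


class TestEtrFromSif:
    def test_default_gain_constant(self, params43):
        assert mechanistic_gain(params43) == pytest.approx(97.647059, abs=1e-6)

    def test_hand_chain_value(self, params43, ql_default):
        etr = etr_from_sif(1.0, PAR_QL03, ql_default, params43, 1 / 3)
        assert etr == pytest.approx(87.882353, abs=1e-5)

    def test_zero_sif_gives_zero_etr(self, params43, ql_default):
        assert etr_from_sif(0.0, 500.0, ql_default, params43, 0.4) == 0.0

    def test_linearity_in_sif(self, params43, ql_default):
        one = etr_from_sif(1.3, 700.0, ql_default, params43, 0.5)
        two = etr_from_sif(2.6, 700.0, ql_default, params43, 0.5)
        assert two == pytest.approx(2 * one, rel=1e-14)

    def test_degenerate_epsilon_rejected(self, params43, ql_default):
        with pytest.raises(ValueError, match="epsilon"):
            etr_from_sif(1.0, 500.0, ql_default, params43, 0.0)


class TestCO2Factors:
    def test_m_hand_value(self, params43):
        assert m_factor(params43) == pytest.approx(237 / 366, abs=1e-9)
        assert m_factor(params43) == pytest.approx(0.647541, abs=1e-6)

    def test_mc_hand_value(self, params43):
        assert mc_factor(params43) == pytest.approx(237 / 991, abs=1e-9)
        assert mc_factor(params43) == pytest.approx(0.239152, abs=1e-6)

    def test_limits(self):
        near_gamma = PhotoParams(ci=43.001, gamma_star=43.0)
        assert m_factor(near_gamma) == pytest.approx(0.0, abs=1e-4)
        assert mc_factor(near_gamma) == pytest.approx(0.0, abs=1e-4)
        big_ci = PhotoParams(ci=4e6, ca=5e6)
        assert m_factor(big_ci) == pytest.approx(1.0, abs=1e-4)

    def test_m_equals_mc_when_km_is_twice_gamma(self):
        p = PhotoParams(ci=280, gamma_star=43.0, km=86.0)
        assert m_factor(p) == pytest.approx(mc_factor(p), rel=1e-14)

    def test_factors_strictly_inside_unit_interval(self, params43):
        assert 0 < mc_factor(params43) < m_factor(params43) < 1


class TestVcmaxAndGs:
    def test_vcmax_hand_value(self, params43):
        assert vcmax_from_etr(87.882353, params43) == pytest.approx(59.489, abs=1e-3)

    def test_gs_hand_value(self, params43):
        exact = 0.4 * (237 / 366) * 87.882353 / 120
        assert gs_from_etr(87.882353, params43) == pytest.approx(exact, rel=1e-12)
        # quoted 0.189693 was derived from m rounded to 6 digits
        assert gs_from_etr(87.882353, params43) == pytest.approx(0.189693, abs=5e-6)

    def test_zero_etr(self, params43):
        assert vcmax_from_etr(0.0, params43) == 0.0
        assert gs_from_etr(0.0, params43) == 0.0

    def test_vcmax_linear_in_etr(self, params43):
        assert vcmax_from_etr(10.0, params43) * 7 == pytest.approx(
            vcmax_from_etr(70.0, params43), rel=1e-14
        )

    def test_vcmax_exceeds_quarter_etr_when_km_large(self, params43):
        # m/mc > 1 whenever Km > 2*Gamma, so Vcmax > ETR/4
        assert vcmax_from_etr(100.0, params43) > 25.0

    def test_implied_assimilation_consistency(self, params43):
        """gs*(Ca-Ci)/1.6 must equal (ETR/4)*m: Fick's law and EUE agree."""
        etr = 87.882353
        gs = gs_from_etr(etr, params43)
        a_fick = gs * (params43.ca - params43.ci) / params43.diffusivity_ratio
        a_eue = etr / 4 * m_factor(params43)
        assert a_fick == pytest.approx(a_eue, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(scale=hst.floats(0.1, 10), sif=hst.floats(0.01, 5))
    def test_chain_homogeneous_degree_one_in_sif(self, scale, sif):
        p = PhotoParams()
        ql = QLModel(a=0.9, b=-0.001)
        etr1 = etr_from_sif(sif, 500.0, ql, p, 0.5)
        etr2 = etr_from_sif(scale * sif, 500.0, ql, p, 0.5)
        assert etr2 == pytest.approx(scale * etr1, rel=1e-9)
        assert vcmax_from_etr(etr2, p) == pytest.approx(
            scale * vcmax_from_etr(etr1, p), rel=1e-9
        )
        assert gs_from_etr(etr2, p) == pytest.approx(scale * gs_from_etr(etr1, p), rel=1e-9)


class TestElasticities:
    def _log_etr(self, p):
        ql = QLModel(a=0.9, b=-0.001)
        return math.log(etr_from_sif(1.0, 500.0, ql, p, 0.4))

    def test_finite_difference_matches_analytic(self, params43):
        import dataclasses

        delta = 1e-6
        for name, analytic in [
            ("phi_psii_max", 1 / (1 - params43.phi_psii_max)),
            ("k_df", params43.k_df / (1 + params43.k_df)),
        ]:
            up = dataclasses.replace(params43, **{name: getattr(params43, name) * (1 + delta)})
            dn = dataclasses.replace(params43, **{name: getattr(params43, name) * (1 - delta)})
            fd = (self._log_etr(up) - self._log_etr(dn)) / (
                math.log(1 + delta) - math.log(1 - delta)
            )
            assert fd == pytest.approx(analytic, abs=1e-4)


class TestRetrieveSeries:
    def _series(self, rows):
        cols = ["year", "doy", "sif", "par", "nirv", "fpar"]
        return TraitSeries(frame=pd.DataFrame(rows, columns=cols))

    def test_single_record_composition(self, params43, ql_default):
        series = self._series([(2017, 200, 1.0, PAR_QL03, 0.3, 0.9)])
        out = retrieve_series(series, ql_default, params43)
        row = out.frame.iloc[0]
        assert row["epsilon"] == pytest.approx(1 / 3, abs=1e-9)
        assert row["ql"] == pytest.approx(0.3, abs=1e-12)
        assert row["etr"] == pytest.approx(87.882353, abs=1e-5)
        assert row["vcmax"] == pytest.approx(59.489, abs=1e-3)
        assert row["gs"] == pytest.approx(0.189693, abs=5e-6)

    def test_noise_free_season_recovers_truth(self, noisefree_season):
        cfg, series, truth = noisefree_season
        ql = QLModel(a=cfg.ql_a, b=cfg.ql_b)
        out = retrieve_series(series, ql, cfg.photo)
        for col in ("ql", "etr", "vcmax", "gs"):
            np.testing.assert_allclose(
                out.frame[col].to_numpy(), truth.frame[col].to_numpy(), rtol=1e-10
            )

    def test_degenerate_records_skipped_and_counted(self, params43, ql_default, caplog):
        rows = [(2017, 190 + i, 1.0, 500.0, 0.3, 0.9) for i in range(10)]
        rows[4] = (2017, 194, 1.0, 500.0, 0.0, 0.9)  # nirv=0 -> epsilon=0
        series = self._series(rows)
        with caplog.at_level("WARNING"):
            out = retrieve_series(series, ql_default, params43)
        assert len(out) == 9
        assert out.n_skipped == 1
        assert len(out) + out.n_skipped == len(series)

    def test_all_skipped_is_an_error(self, params43, ql_default):
        series = self._series([(2017, 200, 1.0, 500.0, 0.0, 0.9)])
        with pytest.raises(ValueError, match="all records skipped"):
            retrieve_series(series, ql_default, params43)

    def test_gs_stage_can_be_disabled(self, params43, ql_default):
        series = self._series([(2017, 200, 1.0, 500.0, 0.3, 0.9)])
        out = retrieve_series(series, ql_default, params43, compute_gs=False)
        assert np.isnan(out.frame["gs"]).all()
        assert np.isfinite(out.frame["vcmax"]).all()


class TestPhotoParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"phi_psii_max": 1.2},
            {"phi_psii_max": 0.0},
            {"k_df": -1.0},
            {"ci": 500.0},  # violates ca > ci
            {"gamma_star": 300.0},  # violates ci > gamma_star
            {"km": 0.0},
            {"diffusivity_ratio": 0.0},
        ],
    )
    def test_invariants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhotoParams(**kwargs)
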