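"""Spectral containers, CSV round trips, and peak measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from albind.simulate import GeneratorConfig, simulate_titration
from albind.spectra import (
    EmissionSpectrum,
    IndeterminatePeakError,
    SpectraError,
    TitrationSeries,
    inner_filter_correct,
    measure_shift,
    peak_position,
    read_titration,
    write_titration,
)


def _band(center, sigma=25.0):
    wl = np.arange(300.0, 500.5, 1.0)
    return EmissionSpectrum(wl, 1000 * np.exp(-0.5 * ((wl - center) / sigma) ** 2))


def _series_from_matrix(wl, cols, concs, T=298.0):
    spectra = tuple(EmissionSpectrum(wl, c) for c in cols)
    return TitrationSeries("HSA", 2e-6, np.asarray(concs), spectra, T)


class TestContainers:
    def test_non_monotone_grid_rejected(self):
        with pytest.raises(SpectraError):
            EmissionSpectrum([300, 302, 301], [1.0, 2.0, 3.0])

    def test_negative_intensity_rejected(self):
        with pytest.raises(SpectraError):
            EmissionSpectrum([300, 301, 302], [1.0, -2.0, 3.0])

    def test_spectra_concentration_count_mismatch(self):
        wl = np.arange(300.0, 310.0)
        with pytest.raises(SpectraError, match="concentration"):
            _series_from_matrix(wl, [np.ones_like(wl)] * 3, [0.0, 2e-6])

    def test_decreasing_concentrations_rejected(self):
        wl = np.arange(300.0, 310.0)
        with pytest.raises(SpectraError):
            _series_from_matrix(wl, [np.ones_like(wl)] * 2, [2e-6, 1e-6])


class TestTitrationIO:
    def test_minimal_two_column_round_trip(self, tmp_path):
        wl = np.arange(300.0, 320.0)
        series = _series_from_matrix(
            wl, [np.full_like(wl, 5.0), np.full_like(wl, 3.0)], [0.0, 2e-6]
        )
        path = write_titration(series, tmp_path / "t.csv")
        back = read_titration(path)
        assert len(back.spectra) == 2
        assert back.temperature_K == 298.0

    def test_generator_round_trip_bit_identical(self, tmp_path, epx_hsa_config):
        series = simulate_titration(epx_hsa_config, 298.0)
        path = write_titration(series, tmp_path / "t.csv")
        back = read_titration(path)
        assert np.array_equal(back.wavelength_nm, series.wavelength_nm)
        assert np.array_equal(back.quencher_conc_M, series.quencher_conc_M)
        for a, b in zip(back.spectra, series.spectra):
            assert np.array_equal(a.intensity, b.intensity)
        assert back.truth["K_A"] == series.truth["K_A"]

    def test_column_count_mismatch_errors(self, tmp_path):
        wl = np.arange(300.0, 310.0)
        series = _series_from_matrix(
            wl, [np.ones_like(wl) * k for k in (3, 2, 1)], [0.0, 2e-6, 5e-6]
        )
        path = write_titration(series, tmp_path / "t.csv")
        bad_meta = {"quencher_conc_M": [0.0, 2e-6], "temperature_K": 298.0}
        with pytest.raises(SpectraError, match="columns"):
            read_titration(path, metadata=bad_meta)


class TestPeakPosition:
    @settings(max_examples=50, derandomize=True)
    @given(center=st.floats(min_value=310.0, max_value=490.0))
    def test_gaussian_center_recovered_within_0p1_nm(self, center):
        wl = np.arange(300.0, 500.5, 1.0)
        spec = EmissionSpectrum(wl, 1000 * np.exp(-0.5 * ((wl - center) / 25.0) ** 2))
        est = peak_position(spec)
        assert not est.at_edge
        assert abs(est.peak_nm - center) < 0.1

    def test_monotone_ramp_returns_edge(self):
        wl = np.arange(300.0, 310.0)
        est = peak_position(EmissionSpectrum(wl, np.arange(10.0)))
        assert est.at_edge and est.peak_nm == wl[-1]

    def test_flat_spectrum_indeterminate(self):
        wl = np.arange(300.0, 310.0)
        with pytest.raises(IndeterminatePeakError):
            peak_position(EmissionSpectrum(wl, np.ones_like(wl)))

    def test_empty_window_errors(self, gaussian_band):
        with pytest.raises(SpectraError):
            peak_position(gaussian_band(), window=(600.0, 700.0))


class TestMeasureShift:
    @pytest.mark.parametrize(
        "ref, obs, shift, direction",
        [(207.0, 215.0, 8.0, "red"), (343.0, 340.0, -3.0, "blue"), (340.0, 340.0, 0.0, "none")],
    )
    def test_classification(self, ref, obs, shift, direction):
        ps = measure_shift(ref, obs)
        assert ps.shift_nm == pytest.approx(shift)
        assert ps.direction == direction

    def test_sub_threshold_shift_is_none(self, gaussian_band):
        ps = measure_shift(gaussian_band(340.0), gaussian_band(341.0))
        assert ps.direction == "none"

    @settings(max_examples=30, derandomize=True)
    @given(
        a=st.floats(min_value=310.0, max_value=480.0),
        b=st.floats(min_value=310.0, max_value=480.0),
    )
    def test_antisymmetry(self, a, b):
        fwd = measure_shift(_band(a), _band(b))
        rev = measure_shift(_band(b), _band(a))
        assert fwd.shift_nm == pytest.approx(-rev.shift_nm, abs=1e-9)


class TestInnerFilter:
    def test_identity_and_direct_value(self):
        assert inner_filter_correct(100.0, 0.0, 0.0) == 100.0
        # 100 * 10**((0.1 + 0.1)/2) = 100 * 10**0.1
        assert inner_filter_correct(100.0, 0.1, 0.1) == pytest.approx(
            100 * 10**0.1
        )
        assert round(inner_filter_correct(100.0, 0.1, 0.1), 2) == 125.89

    def test_negative_absorbance_rejected(self):
        with pytest.raises(SpectraError):
            inner_filter_correct(100.0, -0.1, 0.0)
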