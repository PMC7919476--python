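"""Synchronous scans, EEM peak picking, UV/Vis shifts and CD helix content."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from albind.simulate import (
    GeneratorConfig,
    simulate_cd,
    simulate_eem,
    simulate_synchronous,
    simulate_uvvis,
)
from albind.spectra import SpectraError
from albind.structure import (
    CDSpectrum,
    alpha_helix_percent,
    cd_analysis,
    compare_eem_peaks,
    find_eem_peaks,
    mre,
    mre_at,
    synchronous_analysis,
    uvvis_analysis,
)


def _cd(ellipticity, c=3e-6, n=585, l=0.1):
    wl = np.arange(190.0, 270.0, 1.0)
    return CDSpectrum(wl, np.full_like(wl, ellipticity), c, n, l)


class TestMRE:
    def test_zero_ellipticity_gives_zero(self):
        assert np.all(mre(_cd(0.0)) == 0.0)

    def test_direct_evaluation(self):
        # -10 mdeg / (10 * 3e-6 * 585 * 0.1) = -5698.0 deg cm^2/dmol
        assert mre(_cd(-10.0))[0] == pytest.approx(-5698.0, abs=0.05)

    @settings(max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_linearity_and_inverse_proportionality(self, scale):
        base = mre(_cd(-10.0))[0]
        assert mre(_cd(-10.0 * scale))[0] == pytest.approx(base * scale, rel=1e-12)
        assert mre(_cd(-10.0, c=3e-6 * scale))[0] == pytest.approx(base / scale, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(SpectraError):
            _cd(-10.0, c=0.0)


class TestAlphaHelix:
    @pytest.mark.parametrize(
        "mre208, expected", [(-4000.0, 0.0), (-33000.0, 100.0), (-18592.8, 50.32)]
    )
    def test_anchor_values(self, mre208, expected):
        assert alpha_helix_percent(mre208).alpha_helix_pct == pytest.approx(expected, abs=1e-6)

    def test_out_of_range_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            res = alpha_helix_percent(-40000.0)
        assert res.alpha_helix_pct == 100.0
        assert res.alpha_helix_pct_raw > 100.0

    @settings(max_examples=40, derandomize=True)
    @given(pct=st.floats(min_value=0.0, max_value=100.0))
    def test_inverse_identity(self, pct):
        mre208 = -(pct / 100.0 * 29000.0 + 4000.0)
        assert alpha_helix_percent(mre208).alpha_helix_pct == pytest.approx(pct, abs=1e-10)

    @pytest.mark.parametrize("alpha", [0.0, 50.32, 57.20, 100.0])
    def test_cd_generator_round_trip(self, alpha):
        cfg = GeneratorConfig(seed=1)
        cd = simulate_cd(alpha, cfg)
        assert cd_analysis(cd).alpha_helix_pct == pytest.approx(alpha, abs=1e-6)

    def test_mre_at_requires_in_span_wavelength(self):
        with pytest.raises(SpectraError):
            mre_at(_cd(-10.0), 500.0)


class TestSynchronous:
    def test_trp_channel_blue_shift_detected(self):
        cfg = GeneratorConfig(seed=5)
        sync = simulate_synchronous(cfg, 60.0, final_quench_fraction=0.4, shift_nm=-3.0)
        res = synchronous_analysis(sync)
        assert res.residue == "Trp"
        assert res.shift.direction == "blue"
        assert res.shift.shift_nm == pytest.approx(-3.0, abs=0.3)
        # emission-convention positions are the scanned axis plus the offset
        assert np.allclose(res.peak_em_nm, res.peak_ex_nm + 60.0)

    def test_constant_series_has_zero_quenching_and_no_shift(self):
        cfg = GeneratorConfig(seed=5)
        sync = simulate_synchronous(cfg, 15.0, final_quench_fraction=0.0)
        res = synchronous_analysis(sync)
        assert res.residue == "Tyr"
        assert np.allclose(res.quench_fraction, 0.0, atol=1e-12)
        assert res.shift.direction == "none"

    def test_final_quench_fraction_matches_truth(self):
        cfg = GeneratorConfig(seed=5)
        sync = simulate_synchronous(cfg, 60.0, final_quench_fraction=0.40)
        res = synchronous_analysis(sync)
        assert res.quench_fraction[-1] == pytest.approx(0.40, abs=0.01)


class TestEEM:
    def test_single_peak_recovered_with_ridges_present(self):
        eem = simulate_eem(peaks=((280.0, 340.0, 800.0),), ridges=True)
        found = find_eem_peaks(eem)
        assert found.peak1 is not None
        assert found.peak1.ex_nm == pytest.approx(280.0, abs=1.0)
        assert found.peak1.em_nm == pytest.approx(340.0, abs=1.0)
        assert found.rayleigh_1 is not None and found.rayleigh_2 is not None

    def test_zero_matrix_yields_no_features(self):
        eem = simulate_eem(peaks=((280.0, 340.0, 0.0),), ridges=False)
        found = find_eem_peaks(eem)
        assert found.peak1 is None and found.peak2 is None
        assert found.rayleigh_1 is None and found.rayleigh_2 is None

    def test_ridges_only_yield_no_fluorescence_peaks(self):
        eem = simulate_eem(peaks=(), ridges=True)
        found = find_eem_peaks(eem)
        assert found.peak1 is None and found.peak2 is None

    def test_peaks_never_reported_inside_ridge_bands(self):
        eem = simulate_eem(ridges=True, noise_pct=1.0, seed=11)
        found = find_eem_peaks(eem)
        for p in (found.peak1, found.peak2):
            if p is not None:
                assert abs(p.em_nm - p.ex_nm) > 5.0
                assert abs(p.em_nm - 2 * p.ex_nm) > 5.0

    def test_peak_locations_within_1nm_at_1pct_noise(self):
        for seed in range(5):
            found = find_eem_peaks(simulate_eem(noise_pct=1.0, seed=seed))
            assert found.peak1.ex_nm == pytest.approx(280.0, abs=1.0)
            assert found.peak1.em_nm == pytest.approx(340.0, abs=1.0)
            assert found.peak2.ex_nm == pytest.approx(230.0, abs=1.0)
            assert found.peak2.em_nm == pytest.approx(330.0, abs=1.0)

    def test_imposed_intensity_drop_recovered(self):
        free = simulate_eem()
        bound = simulate_eem(
            peaks=((280.0, 340.0, 800.0 * 0.65), (230.0, 330.0, 400.0 * 0.65))
        )
        cmp = compare_eem_peaks(free, bound)
        assert cmp["peak1_drop"] == pytest.approx(0.35, abs=0.02)
        assert cmp["peak2_drop"] == pytest.approx(0.35, abs=0.02)

    def test_out_of_grid_peak_rejected(self):
        with pytest.raises(ValueError):
            simulate_eem(peaks=((100.0, 340.0, 1.0),))


class TestUVVis:
    def test_red_shift_of_backbone_band_detected(self):
        cfg = GeneratorConfig(seed=9)
        spectra, q = simulate_uvvis(cfg, peak1_shift_nm=8.0)
        res = uvvis_analysis(spectra, q)
        assert res.peak1_shift.direction == "red"
        assert res.peak1_shift.shift_nm == pytest.approx(8.0, abs=0.5)
        assert res.peak2_shift.direction == "none"

    def test_stationary_bands_report_no_shift(self):
        cfg = GeneratorConfig(seed=9)
        spectra, q = simulate_uvvis(cfg)
        res = uvvis_analysis(spectra, q)
        assert res.peak1_shift.direction == "none"
        assert res.peak1_nm[0] == pytest.approx(207.0, abs=0.5)
        assert res.peak2_nm[0] == pytest.approx(280.0, abs=0.5)

    def test_single_spectrum_reports_peaks_without_shifts(self):
        cfg = GeneratorConfig(seed=9)
        spectra, _ = simulate_uvvis(cfg)
        res = uvvis_analysis(spectra[:1], [0.0])
        assert res.peak1_shift is None and res.peak2_shift is None
        assert res.peak1_nm[0] == pytest.approx(207.0, abs=0.5)
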