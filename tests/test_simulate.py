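"""Generator contracts: determinism, ground-truth embedding, exact inversion."""

import numpy as np
import pytest

from albind.binding import HillModel
from albind.quenching import SternVolmerModel, classify_mechanism, quench_ratios
from albind.reference import REFERENCE_COMPLEXES
from albind.simulate import (
    GeneratorConfig,
    K_A_from_thermo,
    generate_study,
    simulate_eem,
    simulate_titration,
)
from albind.spectra import read_titration
from albind.thermo import R_GAS


class TestDeterminism:
    def test_same_seed_bit_identical_titration(self):
        cfg = GeneratorConfig(seed=13, K_A_by_T={298.0: 5e4}, noise_pct=1.0)
        a = simulate_titration(cfg, 298.0)
        b = simulate_titration(cfg, 298.0)
        for sa, sb in zip(a.spectra, b.spectra):
            assert np.array_equal(sa.intensity, sb.intensity)

    def test_different_seeds_differ(self):
        a = simulate_titration(
            GeneratorConfig(seed=13, K_A_by_T={298.0: 5e4}, noise_pct=1.0), 298.0
        )
        b = simulate_titration(
            GeneratorConfig(seed=14, K_A_by_T={298.0: 5e4}, noise_pct=1.0), 298.0
        )
        assert not np.array_equal(a.spectra[1].intensity, b.spectra[1].intensity)

    def test_eem_seeded(self):
        assert np.array_equal(
            simulate_eem(noise_pct=1.0, seed=4).intensity,
            simulate_eem(noise_pct=1.0, seed=4).intensity,
        )


class TestGroundTruth:
    def test_truth_embedded_in_written_files(self, tmp_path, epx_hsa_config):
        series = simulate_titration(epx_hsa_config, 303.0)
        from albind.spectra import write_titration

        back = read_titration(write_titration(series, tmp_path / "t.csv"))
        assert back.truth["K_A"] == pytest.approx(2.04e4)
        assert back.truth["n"] == pytest.approx(0.95)

    def test_thermo_link_is_exact(self):
        dH, dS = -84.85, -174.18
        cfg = GeneratorConfig(seed=0, delta_H_kJ=dH, delta_S_J=dS)
        for T in cfg.temperatures_K:
            expected = np.exp(-dH * 1000.0 / (R_GAS * T) + dS / R_GAS)
            assert cfg.K_A(T) == pytest.approx(expected, rel=1e-14)


class TestExactInversion:
    def test_hill_fit_inverts_noise_free_titration(self, epx_hsa_config):
        series = simulate_titration(epx_hsa_config, 298.0)
        res = HillModel(series).fit()
        assert res.K_A == pytest.approx(series.truth["K_A"], rel=1e-8)
        assert res.n == pytest.approx(series.truth["n"], rel=1e-8)

    def test_zero_quencher_only_leaves_unit_ratios(self, epx_hsa_config):
        series = simulate_titration(epx_hsa_config, 298.0)
        free = series.free_spectrum
        band = epx_hsa_config.band_amplitude * np.exp(
            -0.5 * ((free.wavelength_nm - 340.0) / 25.0) ** 2
        )
        assert np.allclose(free.intensity, band, rtol=1e-12)

    def test_enhancement_mode_raises_lowest_points(self):
        ref = REFERENCE_COMPLEXES["PTC/HSA"]
        cfg = GeneratorConfig(
            protein="HSA",
            K_A_by_T=ref["K_A"],
            n_by_T=ref["n"],
            mode="enhancement_then_quench",
        )
        series = simulate_titration(cfg, 298.0)
        q, r = quench_ratios(series)
        # at K_A = 5.75e5 quenching dominates the +5% rise except at the
        # lowest concentration, which must show net enhancement handling
        res = HillModel(series).fit()
        assert 1 in res.points_dropped or r[1] > 1.0

    def test_static_mode_classified_static_across_temperatures(self, epx_hsa_config):
        svs = [
            SternVolmerModel(simulate_titration(epx_hsa_config, T)).fit()
            for T in epx_hsa_config.temperatures_K
        ]
        assert classify_mechanism(svs).mechanism == "static"


class TestStudyGeneration:
    def test_study_directory_is_complete(self, tmp_path):
        cfg_path = generate_study(tmp_path / "s", "PTC/BSA", seed=2)
        names = {p.name for p in (tmp_path / "s").iterdir()}
        expected = {
            "study.yaml",
            "titration_298K.csv",
            "titration_303K.csv",
            "titration_310K.csv",
            "displacement_KPF.csv",
            "displacement_IBF.csv",
            "sync_dl15.csv",
            "sync_dl60.csv",
            "eem_free.csv",
            "eem_bound.csv",
            "uvvis.csv",
            "cd_free.csv",
            "cd_bound.csv",
        }
        assert expected <= names

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(mode="fancy")

    def test_missing_truth_rejected(self):
        cfg = GeneratorConfig()
        with pytest.raises(ValueError, match="K_A_by_T"):
            cfg.K_A(298.0)
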