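import numpy as np
import pytest

from albind.reference import REFERENCE_COMPLEXES
from albind.simulate import GeneratorConfig
from albind.spectra import EmissionSpectrum, TitrationSeries


@pytest.fixture
def epx_hsa_config():
    """Noise-free generator config carrying the EPX/HSA reference truth."""
    ref = REFERENCE_COMPLEXES["EPX/HSA"]
    return GeneratorConfig(
        seed=7, protein="HSA", K_A_by_T=ref["K_A"], n_by_T=ref["n"]
    )


@pytest.fixture
def gaussian_band():
    """Factory for a Gaussian emission band on a 1 nm grid."""

    def make(center=340.0, sigma=25.0, amplitude=1000.0, lo=300.0, hi=500.0):
        wl = np.arange(lo, hi + 0.5, 1.0)
        return EmissionSpectrum(wl, amplitude * np.exp(-0.5 * ((wl - center) / sigma) ** 2))

    return make


@pytest.fixture
def static_series(gaussian_band):
    """Factory for an exact static-quenching titration F = F0/(1 + K Q^n)."""

    def make(K=5000.0, n=1.0, concs=None, temperature_K=298.0):
        if concs is None:
            concs = np.concatenate([[0.0], (2.0 + 3.0 * np.arange(11)) * 1e-6])
        free = gaussian_band()
        spectra = tuple(
            EmissionSpectrum(free.wavelength_nm, free.intensity / (1.0 + K * q**n))
            for q in concs
        )
        return TitrationSeries(
            protein_id="HSA",
            protein_conc_M=2e-6,
            quencher_conc_M=np.asarray(concs),
            spectra=spectra,
            temperature_K=temperature_K,
        )

    return make
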