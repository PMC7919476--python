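"""Seeded synthetic-data generator for every pipeline input.

Emulates a fluorescence titration study of a serum albumin (fixed at
2e-6 mol/L) with a small-molecule quencher titrated from 2e-6 to
32e-6 mol/L, recorded at 298/303/310 K, plus the companion synchronous,
excitation-emission, UV/Vis and CD measurements.  Every generator embeds
its ground truth in the output (the ``truth`` metadata block), and at zero
noise each generator is the exact algebraic inverse of its paired analysis
operation:

* emission titrations follow F = F0 / (1 + K_A [Q]^n) with K_A(T) given
  directly or through the van't Hoff relation from (dH, dS);
* CD spectra are rendered so the mean residue ellipticity at 208 nm maps
  back to the requested helix percentage;
* EEMs are sums of 2-D Gaussian fluorescence peaks and Rayleigh ridge
  terms along em = ex and em = 2*ex.

Noise is multiplicative Gaussian on intensities (a percentage sigma); the
wavelength grids are fixed.  All randomness flows from the config seed, so
identical configs produce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .displacement import DisplacementCurve, MARKER_SITES
from .spectra import (
    EEM,
    AbsorptionSpectrum,
    EmissionSpectrum,
    SynchronousSeries,
    TitrationSeries,
)
from .structure import CDSpectrum, N_RESIDUES
from .thermo import R_GAS

__all__ = [
    "GeneratorConfig",
    "K_A_from_thermo",
    "simulate_titration",
    "simulate_synchronous",
    "simulate_displacement",
    "simulate_cd",
    "simulate_eem",
    "simulate_uvvis",
]

#: emission-band centres (nm) of the free proteins at 295 nm excitation
BAND_CENTER_NM = {"HSA": 340.0, "BSA": 343.0}

#: 11-point titration design, 2e-6 to 32e-6 mol/L in 3e-6 steps
DEFAULT_QUENCHER_CONCS_M = tuple((2.0 + 3.0 * i) * 1e-6 for i in range(11))


def K_A_from_thermo(delta_H_kJ: float, delta_S_J: float, T_K: float) -> float:
    """Association constant implied by (dH, dS) through the van't Hoff relation."""
    return float(np.exp(-delta_H_kJ * 1000.0 / (R_GAS * T_K) + delta_S_J / R_GAS))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generators.

    The defaults reproduce the reference experimental design: a 2e-6 mol/L
    albumin titrated with 11 quencher concentrations from 2e-6 to
    32e-6 mol/L at 298, 303 and 310 K, emission collected 300-500 nm at
    295 nm excitation.  Binding ground truth is given either as per-
    temperature association constants (``K_A_by_T``) or as thermodynamic
    parameters (``delta_H_kJ``, ``delta_S_J``) from which K_A(T) follows
    exactly.
    """

    seed: int = 0
    protein: str = "HSA"
    protein_conc_M: float = 2e-6
    quencher_concs_M: tuple[float, ...] = DEFAULT_QUENCHER_CONCS_M
    temperatures_K: tuple[float, ...] = (298.0, 303.0, 310.0)
    # binding ground truth
    K_A_by_T: dict[float, float] | None = None
    n_by_T: dict[float, float] | None = None
    n_sites: float = 1.0
    delta_H_kJ: float | None = None
    delta_S_J: float | None = None
    # spectral band
    excitation_nm: float = 295.0
    band_center_nm: float | None = None  # default: protein lookup
    band_sigma_nm: float = 25.0
    band_amplitude: float = 1000.0
    emission_grid_nm: tuple[float, float, float] = (300.0, 500.0, 1.0)
    # distortions
    noise_pct: float = 0.0
    shift_nm: float = 0.0  # progressive peak shift at full titration (signed)
    mode: str = "static"  # static | dynamic | enhancement_then_quench
    enhancement_pct: float = 5.0  # rise at the two lowest [Q] in enhancement mode

    def __post_init__(self):
        if self.noise_pct < 0:
            raise ValueError("noise_pct must be non-negative")
        q = np.asarray(self.quencher_concs_M, dtype=float)
        if np.any(q <= 0) or not np.all(np.diff(q) > 0):
            raise ValueError("quencher_concs_M must be positive and increasing")
        if self.mode not in ("static", "dynamic", "enhancement_then_quench"):
            raise ValueError(f"unknown titration mode {self.mode!r}")
        if self.protein not in N_RESIDUES and self.band_center_nm is None:
            raise ValueError(
                f"unknown protein {self.protein!r}: supply band_center_nm"
            )

    @property
    def center_nm(self) -> float:
        return (
            self.band_center_nm
            if self.band_center_nm is not None
            else BAND_CENTER_NM[self.protein]
        )

    def K_A(self, T_K: float) -> float:
        """Ground-truth association constant at a temperature."""
        if self.K_A_by_T is not None:
            return float(self.K_A_by_T[T_K])
        if self.delta_H_kJ is not None and self.delta_S_J is not None:
            return K_A_from_thermo(self.delta_H_kJ, self.delta_S_J, T_K)
        raise ValueError("config gives neither K_A_by_T nor (delta_H_kJ, delta_S_J)")

    def n(self, T_K: float) -> float:
        if self.n_by_T is not None:
            return float(self.n_by_T[T_K])
        return float(self.n_sites)

    def rng(self, *stream: int) -> np.random.Generator:
        """Independent generator for a named stream, derived from the seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=tuple(stream))
        )


def _gaussian(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _apply_noise(y: np.ndarray, noise_pct: float, rng: np.random.Generator) -> np.ndarray:
    if noise_pct == 0:
        return y
    noisy = y * (1.0 + (noise_pct / 100.0) * rng.standard_normal(y.shape))
    return np.clip(noisy, 0.0, None)


def simulate_titration(
    config: GeneratorConfig, temperature_K: float | None = None
) -> TitrationSeries:
    """Generate one emission titration series at one temperature.

    The free-protein spectrum ([Q] = 0) is a Gaussian band; each titrated
    spectrum is the band divided by (1 + K_A [Q]^n), optionally shifted
    progressively along the titration and perturbed by multiplicative
    noise.  ``enhancement_then_quench`` raises the two lowest-concentration
    spectra by ``enhancement_pct`` to mimic a structural-opening rise before
    regular quenching sets in.
    """
    if temperature_K is None:
        temperature_K = config.temperatures_K[0]
    t_index = (
        config.temperatures_K.index(temperature_K)
        if temperature_K in config.temperatures_K
        else int(round(temperature_K))
    )
    K = config.K_A(temperature_K)
    n = config.n(temperature_K)
    lo, hi, step = config.emission_grid_nm
    wl = np.arange(lo, hi + step / 2, step)
    q_nonzero = np.asarray(config.quencher_concs_M, dtype=float)
    Q = np.concatenate([[0.0], q_nonzero])
    qmax = q_nonzero[-1]
    rng = config.rng(1, t_index)
    spectra = []
    for i, qi in enumerate(Q):
        center = config.center_nm + config.shift_nm * (qi / qmax)
        band = config.band_amplitude * _gaussian(wl, center, config.band_sigma_nm)
        F = band / (1.0 + K * qi**n) if qi > 0 else band
        if config.mode == "enhancement_then_quench" and 0 < i <= 2:
            F = F * (1.0 + config.enhancement_pct / 100.0)
        F = _apply_noise(F, config.noise_pct, rng)
        spectra.append(EmissionSpectrum(wl, F, excitation_nm=config.excitation_nm))
    truth = {
        "K_A": K,
        "n": n,
        "mode": config.mode,
        "temperature_K": float(temperature_K),
        "band_center_nm": float(config.center_nm),
        "shift_nm": float(config.shift_nm),
        "noise_pct": float(config.noise_pct),
    }
    if config.delta_H_kJ is not None:
        truth["delta_H_kJ"] = float(config.delta_H_kJ)
        truth["delta_S_J"] = float(config.delta_S_J)
    return TitrationSeries(
        protein_id=config.protein,
        protein_conc_M=config.protein_conc_M,
        quencher_conc_M=Q,
        spectra=tuple(spectra),
        temperature_K=float(temperature_K),
        truth=truth,
    )


#: default synchronous-scan band centres on the scanned (excitation) axis
_SYNC_CENTER_EX = {15.0: 288.0, 60.0: 280.0}


def simulate_synchronous(
    config: GeneratorConfig,
    delta_lambda_nm: float,
    final_quench_fraction: float = 0.4,
    shift_nm: float = 0.0,
    temperature_K: float = 298.0,
) -> SynchronousSeries:
    """Generate a synchronous-scan titration at a fixed offset.

    The apparent quenching constant is calibrated so the fraction
    1 - F/F0 at the highest quencher concentration equals
    ``final_quench_fraction``; the band centre moves linearly with
    concentration up to ``shift_nm`` at full titration.
    """
    if not (0 <= final_quench_fraction < 1):
        raise ValueError("final_quench_fraction must be in [0, 1)")
    q_nonzero = np.asarray(config.quencher_concs_M, dtype=float)
    qmax = q_nonzero[-1]
    K = (
        final_quench_fraction / ((1.0 - final_quench_fraction) * qmax)
        if final_quench_fraction > 0
        else 0.0
    )
    center = _SYNC_CENTER_EX.get(float(delta_lambda_nm), config.center_nm - delta_lambda_nm)
    wl = np.arange(center - 50.0, center + 50.0 + 0.5, 1.0)
    Q = np.concatenate([[0.0], q_nonzero])
    rng = config.rng(2, int(delta_lambda_nm))
    spectra = []
    for qi in Q:
        c = center + shift_nm * (qi / qmax)
        F = config.band_amplitude * _gaussian(wl, c, 15.0) / (1.0 + K * qi)
        F = _apply_noise(F, config.noise_pct, rng)
        spectra.append(EmissionSpectrum(wl, F))
    series = TitrationSeries(
        protein_id=config.protein,
        protein_conc_M=config.protein_conc_M,
        quencher_conc_M=Q,
        spectra=tuple(spectra),
        temperature_K=float(temperature_K),
        truth={
            "final_quench_fraction": float(final_quench_fraction),
            "shift_nm": float(shift_nm),
            "delta_lambda_nm": float(delta_lambda_nm),
        },
    )
    return SynchronousSeries(delta_lambda_nm=float(delta_lambda_nm), series=series)


def simulate_displacement(
    config: GeneratorConfig,
    displaced: bool,
    probe_id: str = "KPF",
    final_ratio: float | None = None,
) -> DisplacementCurve:
    """Generate a marker-displacement curve for one probe.

    ``displaced=True`` produces ratios decaying hyperbolically to
    ``final_ratio`` (default 0.55) at the highest probe concentration;
    ``displaced=False`` keeps the ratios within 1 +/- 0.05 (a mild drift
    plus the configured noise).
    """
    c = np.asarray(config.quencher_concs_M, dtype=float)
    rng = config.rng(3, 1 if displaced else 0, sum(map(ord, probe_id)))
    if displaced:
        target = 0.55 if final_ratio is None else final_ratio
        if not (0 < target < 1):
            raise ValueError("final_ratio must be in (0, 1) when displaced")
        Kp = (1.0 / target - 1.0) / c[-1]
        ratio = 1.0 / (1.0 + Kp * c)
    else:
        target = 0.97 if final_ratio is None else final_ratio
        ratio = 1.0 - (1.0 - target) * (c / c[-1])
    ratio = np.clip(_apply_noise(ratio, config.noise_pct, rng), 1e-6, None)
    return DisplacementCurve(
        probe_id=probe_id,
        probe_conc_M=c,
        ratio=ratio,
        site_marked=MARKER_SITES.get(probe_id, "SudlowI"),
    )


def simulate_cd(
    alpha_pct: float,
    config: GeneratorConfig,
    protein_conc_M: float = 3e-6,
    path_length_cm: float = 0.1,
) -> CDSpectrum:
    """Generate a far-UV CD spectrum with a known helix percentage.

    The spectrum is two negative Gaussian bands at 208 and 222 nm whose
    amplitudes are solved so the mean residue ellipticity at 208 nm equals
    -(alpha_pct/100 * 29000 + 4000) deg cm^2/dmol (the inverse of the helix
    formula) and the 222 nm band is 95% of it; MRE is then converted to
    observed millidegrees with the given c, n and l.
    """
    if not (0 <= alpha_pct <= 100):
        raise ValueError("alpha_pct must be in [0, 100]")
    n_res = N_RESIDUES.get(config.protein, 585)
    mre208 = -(alpha_pct / 100.0 * 29000.0 + 4000.0)
    mre222 = 0.95 * mre208
    wl = np.arange(190.0, 270.0 + 0.25, 0.5)
    g1 = _gaussian(wl, 208.0, 7.0)
    g2 = _gaussian(wl, 222.0, 8.0)
    # solve band amplitudes so the summed spectrum hits both anchors exactly
    M = np.array(
        [
            [_gaussian(np.array([208.0]), 208.0, 7.0)[0], _gaussian(np.array([208.0]), 222.0, 8.0)[0]],
            [_gaussian(np.array([222.0]), 208.0, 7.0)[0], _gaussian(np.array([222.0]), 222.0, 8.0)[0]],
        ]
    )
    a1, a2 = np.linalg.solve(M, np.array([mre208, mre222]))
    mre_spec = a1 * g1 + a2 * g2
    mdeg = mre_spec * 10.0 * protein_conc_M * n_res * path_length_cm
    rng = config.rng(4)
    if config.noise_pct > 0:
        mdeg = mdeg * (1.0 + (config.noise_pct / 100.0) * rng.standard_normal(mdeg.shape))
    return CDSpectrum(
        wavelength_nm=wl,
        ellipticity_mdeg=mdeg,
        protein_conc_M=protein_conc_M,
        n_residues=n_res,
        path_length_cm=path_length_cm,
    )


def simulate_eem(
    peaks=((280.0, 340.0, 800.0), (230.0, 330.0, 400.0)),
    ridges: bool = True,
    noise_pct: float = 0.0,
    seed: int = 0,
    ex_grid=(220.0, 340.0, 5.0),
    em_grid=(250.0, 500.0, 1.0),
    sigma_ex: float = 12.0,
    sigma_em: float = 18.0,
    ridge_amplitudes=(1000.0, 500.0),
    ridge_sigma_nm: float = 3.0,
) -> EEM:
    """Generate an excitation-emission matrix with known features.

    ``peaks`` is a sequence of (ex_nm, em_nm, amplitude) fluorescence peaks
    rendered as 2-D Gaussians; Rayleigh ridges of first and second order are
    added along em = ex and em = 2*ex when ``ridges`` is true.
    """
    ex = np.arange(ex_grid[0], ex_grid[1] + ex_grid[2] / 2, ex_grid[2])
    em = np.arange(em_grid[0], em_grid[1] + em_grid[2] / 2, em_grid[2])
    if not peaks and not ridges:
        raise ValueError("need at least one peak or the Rayleigh ridges")
    EX = ex[:, None]
    EM = em[None, :]
    z = np.zeros((ex.size, em.size))
    for px, pm, amp in peaks:
        if not (ex[0] <= px <= ex[-1] and em[0] <= pm <= em[-1]):
            raise ValueError(f"peak ({px}, {pm}) outside the EEM grids")
        z += amp * np.exp(
            -0.5 * (((EX - px) / sigma_ex) ** 2 + ((EM - pm) / sigma_em) ** 2)
        )
    if ridges:
        z += ridge_amplitudes[0] * np.exp(-0.5 * ((EM - EX) / ridge_sigma_nm) ** 2)
        z += ridge_amplitudes[1] * np.exp(-0.5 * ((EM - 2 * EX) / ridge_sigma_nm) ** 2)
    if noise_pct > 0:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(5,)))
        z = np.clip(z * (1.0 + noise_pct / 100.0 * rng.standard_normal(z.shape)), 0.0, None)
    return EEM(excitation_nm=ex, emission_nm=em, intensity=z)


def simulate_uvvis(
    config: GeneratorConfig,
    peak1_shift_nm: float = 0.0,
    peak2_shift_nm: float = 0.0,
    hypochromism: float = 0.3,
) -> tuple[list[AbsorptionSpectrum], np.ndarray]:
    """Generate a UV/Vis absorption titration (spectra, concentrations).

    The free protein shows the strong backbone band at 207 nm and the
    aromatic band at 280 nm; along the titration the band intensities fall
    by ``hypochromism`` (fraction at full titration) and the band centres
    drift linearly by the requested shifts.  Returns the spectra (first one
    at zero ligand) and the matching concentration vector.
    """
    wl = np.arange(200.0, 350.0 + 0.5, 1.0)
    q_nonzero = np.asarray(config.quencher_concs_M, dtype=float)
    Q = np.concatenate([[0.0], q_nonzero])
    qmax = q_nonzero[-1]
    rng = config.rng(6)
    spectra = []
    for qi in Q:
        f = qi / qmax
        scale = 1.0 - hypochromism * f
        a = 0.9 * scale * _gaussian(wl, 207.0 + peak1_shift_nm * f, 8.0)
        a = a + 0.06 * scale * _gaussian(wl, 280.0 + peak2_shift_nm * f, 12.0)
        if config.noise_pct > 0:
            a = np.clip(
                a * (1.0 + config.noise_pct / 100.0 * rng.standard_normal(a.shape)),
                0.0,
                None,
            )
        spectra.append(AbsorptionSpectrum(wl, a))
    return spectra, Q


# ---------------------------------------------------------------------------
# whole-study generation
# ---------------------------------------------------------------------------

#: free-protein helix percentages used for the synthetic CD stage
FREE_HELIX_PCT = {"HSA": 50.32, "BSA": 57.20}


def generate_study(
    out_dir,
    complex_label: str = "EPX/HSA",
    seed: int = 0,
    noise_pct: float = 0.0,
) -> "Path":
    """Write a complete synthetic study directory for one complex.

    Uses the reference binding parameters of the named conazole/albumin
    complex (association constants and Hill coefficients per temperature,
    displacement behaviour of the two Sudlow markers, characteristic UV/Vis
    and synchronous shifts, free-protein helix content) to generate every
    input file the pipeline reads, plus a ``study.yaml`` config pointing at
    them.  Returns the config path.
    """
    import yaml

    from .displacement import write_displacement_csv
    from .reference import REFERENCE_COMPLEXES
    from .spectra import write_eem_csv, write_titration, _meta_path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = REFERENCE_COMPLEXES[complex_label]
    ligand = complex_label.split("/")[0]
    config = GeneratorConfig(
        seed=seed,
        protein=ref["protein"],
        K_A_by_T=ref["K_A"],
        n_by_T=ref["n"],
        noise_pct=noise_pct,
    )
    # emission titrations, one per temperature
    titration_paths = {}
    for T in config.temperatures_K:
        series = simulate_titration(config, T)
        p = out_dir / f"titration_{int(T)}K.csv"
        write_titration(series, p)
        titration_paths[float(T)] = p.name
    # site-marker displacement curves
    displacement_paths = []
    for probe in ("KPF", "IBF"):
        curve = simulate_displacement(
            config, displaced=probe in ref["displaced_markers"], probe_id=probe
        )
        p = out_dir / f"displacement_{probe}.csv"
        write_displacement_csv(curve, p)
        displacement_paths.append(p.name)
    # synchronous scans: Trp channel carries the complex's characteristic
    # shift; Tyr channel quenches mildly and stays put
    sync_paths = []
    trp_shift = -3.0 if complex_label == "PTC/BSA" else 0.0
    for dl, qf, shift in ((15.0, 0.10, 0.0), (60.0, 0.40, trp_shift)):
        sync = simulate_synchronous(config, dl, final_quench_fraction=qf, shift_nm=shift)
        p = out_dir / f"sync_dl{int(dl)}.csv"
        write_titration(sync.series, p)
        mp = _meta_path(p)
        meta = yaml.safe_load(mp.read_text(encoding="utf-8"))
        meta["delta_lambda_nm"] = float(dl)
        mp.write_text(yaml.safe_dump(meta, sort_keys=False), encoding="utf-8")
        sync_paths.append(p.name)
    # EEM pair: complex shows a 35% drop of both fluorescence peaks
    eem_free = simulate_eem(noise_pct=noise_pct, seed=seed)
    eem_bound = simulate_eem(
        peaks=((280.0, 340.0, 800.0 * 0.65), (230.0, 330.0, 400.0 * 0.65)),
        noise_pct=noise_pct,
        seed=seed + 1,
    )
    write_eem_csv(eem_free, out_dir / "eem_free.csv")
    write_eem_csv(eem_bound, out_dir / "eem_bound.csv")
    # UV/Vis titration: backbone band red-shifts 8 nm for EPX, 2 nm for PTC
    uv_shift = 8.0 if ligand == "EPX" else 2.0
    spectra, Q = simulate_uvvis(config, peak1_shift_nm=uv_shift)
    uv_path = out_dir / "uvvis.csv"
    with open(uv_path, "w", encoding="utf-8") as fh:
        fh.write("wavelength_nm," + ",".join(f"Q_{c:.17g}" for c in Q) + "\n")
        mat = np.column_stack([spectra[0].wavelength_nm] + [s.absorbance for s in spectra])
        for row in mat:
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")
    with open(_meta_path(uv_path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"quencher_conc_M": [float(c) for c in Q], "truth": {"peak1_shift_nm": uv_shift}},
            fh,
            sort_keys=False,
        )
    # CD pair: complex loses a few points of helix
    alpha_free = FREE_HELIX_PCT[ref["protein"]]
    cd_paths = {}
    for name, alpha in (("free", alpha_free), ("bound", alpha_free - 3.5)):
        cd = simulate_cd(alpha, config)
        p = out_dir / f"cd_{name}.csv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("wavelength_nm,ellipticity_mdeg\n")
            for w, e in zip(cd.wavelength_nm, cd.ellipticity_mdeg):
                fh.write(f"{w:.17g},{e:.17g}\n")
        with open(_meta_path(p), "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "protein_conc_M": cd.protein_conc_M,
                    "n_residues": cd.n_residues,
                    "path_length_cm": cd.path_length_cm,
                    "truth": {"alpha_helix_pct": float(alpha)},
                },
                fh,
                sort_keys=False,
            )
        cd_paths[name] = p.name
    study = {
        "complex_label": complex_label,
        "titration_paths": titration_paths,
        "displacement_paths": displacement_paths,
        "synchronous_paths": sync_paths,
        "eem_free_path": "eem_free.csv",
        "eem_bound_path": "eem_bound.csv",
        "uvvis_path": uv_path.name,
        "cd_free_path": cd_paths["free"],
        "cd_bound_path": cd_paths["bound"],
        "seed": seed,
    }
    cfg_path = out_dir / "study.yaml"
    cfg_path.write_text(yaml.safe_dump(study, sort_keys=False), encoding="utf-8")
    return cfg_path
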