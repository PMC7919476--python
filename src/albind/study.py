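"""Whole-study orchestration: from spectra to one structured report.

:class:`BindingStudy` is the top-level model object.  It is built from the
spectral inputs of one ligand/albumin complex (titrations at one or more
temperatures, optionally displacement, synchronous, EEM, UV/Vis and CD
data); ``fit()`` runs the stages in dependency order — quenching ->
binding -> thermodynamics, with site mapping and structural analyses
independent — and returns a :class:`BindingStudyResults` carrying every
per-stage result, a machine-readable warning list, a ``summary()`` text
table of binding and thermodynamic parameters, and JSON serialisation.

:func:`run_study` is the file-level driver: it loads a YAML study config
naming the input files, assembles the model and fits it.  Missing optional
inputs yield absent report sections, not failures.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .binding import BindingResult, HillModel
from .displacement import (
    DEFAULT_DISPLACEMENT_THRESHOLD,
    DisplacementCurve,
    SiteCall,
    infer_site,
    read_displacement_csv,
)
from .quenching import DEFAULT_TAU0_S, MechanismCall, SternVolmerModel, SVResult, classify_mechanism
from .spectra import (
    DEFAULT_SHIFT_THRESHOLD_NM,
    EEM,
    AbsorptionSpectrum,
    SpectraError,
    SynchronousSeries,
    TitrationSeries,
    read_eem_csv,
    read_titration,
)
from .structure import (
    CDSpectrum,
    SecondaryStructure,
    SynchronousResult,
    UVVisResult,
    cd_analysis,
    compare_eem_peaks,
    synchronous_analysis,
    uvvis_analysis,
)
from .thermo import ThermoResult, VantHoffModel

__all__ = [
    "StudyConfig",
    "BindingStudy",
    "BindingStudyResults",
    "run_study",
    "render_table1",
]

REPORT_SCHEMA_VERSION = 1


@dataclass
class StudyConfig:
    """File-level description of one complex's study inputs."""

    complex_label: str
    titration_paths: dict[float, str]  # temperature (K) -> CSV path
    displacement_paths: tuple[str, ...] = ()
    synchronous_paths: tuple[str, ...] = ()
    eem_free_path: str | None = None
    eem_bound_path: str | None = None
    uvvis_path: str | None = None
    cd_free_path: str | None = None
    cd_bound_path: str | None = None
    tau0_s: float = DEFAULT_TAU0_S
    shift_threshold_nm: float = DEFAULT_SHIFT_THRESHOLD_NM
    displacement_threshold: float = DEFAULT_DISPLACEMENT_THRESHOLD
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def resolve(p):
            return str((base / p).resolve()) if p else None

        titr = {float(t): resolve(p) for t, p in raw["titration_paths"].items()}
        cfg = cls(
            complex_label=raw.get("complex_label", "unknown"),
            titration_paths=titr,
            displacement_paths=tuple(resolve(p) for p in raw.get("displacement_paths", [])),
            synchronous_paths=tuple(resolve(p) for p in raw.get("synchronous_paths", [])),
            eem_free_path=resolve(raw.get("eem_free_path")),
            eem_bound_path=resolve(raw.get("eem_bound_path")),
            uvvis_path=resolve(raw.get("uvvis_path")),
            cd_free_path=resolve(raw.get("cd_free_path")),
            cd_bound_path=resolve(raw.get("cd_bound_path")),
            tau0_s=float(raw.get("tau0_s", DEFAULT_TAU0_S)),
            shift_threshold_nm=float(raw.get("shift_threshold_nm", DEFAULT_SHIFT_THRESHOLD_NM)),
            displacement_threshold=float(
                raw.get("displacement_threshold", DEFAULT_DISPLACEMENT_THRESHOLD)
            ),
            seed=int(raw.get("seed", 0)),
        )
        for t, p in cfg.titration_paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"titration file for {t} K not found: {p}")
        return cfg


@dataclass(frozen=True)
class BindingStudyResults:
    """Fitted results of a whole binding study.

    Sections are None when the corresponding inputs were absent.  The
    ``warnings`` list records every default filtering action (excluded
    enhancement points, clipped percentages, ...) machine-readably.
    """

    complex_label: str
    sv_by_T: dict[float, SVResult]
    mechanism: MechanismCall | None
    binding_by_T: dict[float, BindingResult]
    thermo: ThermoResult | None
    site_call: SiteCall | None
    displacement_curves: tuple[DisplacementCurve, ...]
    synchronous: tuple[SynchronousResult, ...]
    eem_comparison: dict | None
    uvvis: UVVisResult | None
    cd_free: SecondaryStructure | None
    cd_bound: SecondaryStructure | None
    warnings: tuple[str, ...]
    config_echo: dict

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Binding and thermodynamic parameter table plus key calls."""
        lines = [render_table1(self)]
        if self.mechanism:
            lines.append(f"Quenching mechanism: {self.mechanism.mechanism}")
        if self.thermo:
            lines.append(f"Dominant forces: {self.thermo.force_class.label}"
                         f" ({self.thermo.force_class.rule_applied})")
        if self.site_call:
            lines.append(
                f"Binding site: {self.site_call.site}"
                f" (displaced by: {', '.join(self.site_call.displaced_by) or 'none'})"
            )
        if self.cd_free:
            lines.append(f"Free-protein alpha-helix: {self.cd_free.alpha_helix_pct:.2f}%")
        if self.cd_bound:
            lines.append(f"Complex alpha-helix: {self.cd_bound.alpha_helix_pct:.2f}%")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if hasattr(obj, "__dataclass_fields__"):
                d = {k: conv(getattr(obj, k)) for k in obj.__dataclass_fields__}
                # derived quantities worth reporting
                if isinstance(obj, SVResult):
                    d["K_q"] = conv(obj.K_q)
                return d
            return obj

        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "package_version": _pkg_version,
            "complex": self.complex_label,
            "stern_volmer": {str(t): conv(r) for t, r in self.sv_by_T.items()},
            "mechanism": conv(self.mechanism),
            "binding": {str(t): conv(r) for t, r in self.binding_by_T.items()},
            "thermodynamics": conv(self.thermo),
            "site": conv(self.site_call),
            "displacement_curves": conv(self.displacement_curves),
            "synchronous": conv(self.synchronous),
            "eem": conv(self.eem_comparison),
            "uvvis": conv(self.uvvis),
            "cd": {"free": conv(self.cd_free), "bound": conv(self.cd_bound)},
            "warnings": list(self.warnings),
            "config": conv(self.config_echo),
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=False)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def render_table1(results) -> str:
    """Render the binding/thermodynamic parameter table.

    Accepts a :class:`BindingStudyResults` or its JSON report dict (the
    canonical form; the table is always derived, never recomputed).
    Columns: complex, T (K), K_A (L/mol, scientific notation), n, dG, dH
    (kJ/mol, 2 decimals) and dS (J/(mol K), 2 decimals).
    """
    if isinstance(results, BindingStudyResults):
        label = results.complex_label
        binding = {
            T: {"K_A": b.K_A, "n": b.n} for T, b in results.binding_by_T.items()
        }
        thermo = None
        if results.thermo is not None:
            thermo = {
                "delta_H": results.thermo.delta_H,
                "delta_S": results.thermo.delta_S,
                "delta_G_by_T": {
                    str(T): g for T, g in results.thermo.delta_G_by_T.items()
                },
            }
    else:
        label = results.get("complex", "")
        binding = {float(T): b for T, b in results.get("binding", {}).items()}
        thermo = results.get("thermodynamics")
    header = (
        f"{'Complex':<10}{'T (K)':>7}{'K_A (L/mol)':>14}{'n':>7}"
        f"{'dG (kJ/mol)':>13}{'dH (kJ/mol)':>13}{'dS (J/mol.K)':>14}"
    )
    lines = [header]
    for i, (T, b) in enumerate(sorted(binding.items())):
        dg = dh = ds = ""
        if thermo:
            dG_map = {float(k): v for k, v in thermo["delta_G_by_T"].items()}
            if float(T) in dG_map:
                dg = f"{dG_map[float(T)]:.2f}"
            if i == 0:
                dh = f"{thermo['delta_H']:.2f}"
                ds = f"{thermo['delta_S']:.2f}"
        lines.append(
            f"{label if i == 0 else '':<10}{T:>7.0f}{b['K_A']:>14.2e}"
            f"{b['n']:>7.2f}{dg:>13}{dh:>13}{ds:>14}"
        )
    return "\n".join(lines)


class BindingStudy:
    """Model object for one ligand/albumin complex.

    Parameters
    ----------
    titrations : mapping T (K) -> TitrationSeries
        Emission titrations; at least one temperature is mandatory.
    displacement_curves : sequence of DisplacementCurve, optional
    synchronous : sequence of SynchronousSeries, optional
    eem_free, eem_bound : EEM, optional
        Matrices of the free protein and the complex for peak comparison.
    uvvis : (spectra, concentrations), optional
    cd_free, cd_bound : CDSpectrum, optional
    tau0_s, shift_threshold_nm, displacement_threshold : float
        Analysis knobs, echoed into the report.
    """

    def __init__(
        self,
        titrations: Mapping[float, TitrationSeries],
        displacement_curves: Sequence[DisplacementCurve] = (),
        synchronous: Sequence[SynchronousSeries] = (),
        eem_free: EEM | None = None,
        eem_bound: EEM | None = None,
        uvvis: tuple[Sequence[AbsorptionSpectrum], np.ndarray] | None = None,
        cd_free: CDSpectrum | None = None,
        cd_bound: CDSpectrum | None = None,
        complex_label: str = "complex",
        tau0_s: float = DEFAULT_TAU0_S,
        shift_threshold_nm: float = DEFAULT_SHIFT_THRESHOLD_NM,
        displacement_threshold: float = DEFAULT_DISPLACEMENT_THRESHOLD,
    ):
        if not titrations:
            raise ValueError("at least one titration series is mandatory")
        for T, series in titrations.items():
            if series.temperature_K != T:
                raise SpectraError(
                    f"titration declared at {T} K but its metadata says "
                    f"{series.temperature_K} K"
                )
        self.titrations = dict(sorted(titrations.items()))
        self.displacement_curves = tuple(displacement_curves)
        self.synchronous = tuple(synchronous)
        self.eem_free, self.eem_bound = eem_free, eem_bound
        self.uvvis = uvvis
        self.cd_free, self.cd_bound = cd_free, cd_bound
        self.complex_label = complex_label
        self.tau0_s = tau0_s
        self.shift_threshold_nm = shift_threshold_nm
        self.displacement_threshold = displacement_threshold

    def fit(self) -> BindingStudyResults:
        warnings: list[str] = []
        # quenching stage
        sv_by_T: dict[float, SVResult] = {}
        for T, series in self.titrations.items():
            res = SternVolmerModel(series, tau0_s=self.tau0_s).fit()
            if res.excluded_points:
                warnings.append(
                    f"stern_volmer[{T}K]: excluded enhancement points "
                    f"{list(res.excluded_points)} (F0/F < 1)"
                )
            sv_by_T[T] = res
        mechanism = classify_mechanism(list(sv_by_T.values())) if len(sv_by_T) >= 2 else None
        # binding stage
        binding_by_T: dict[float, BindingResult] = {}
        for T, series in self.titrations.items():
            b = HillModel(series).fit()
            if b.points_dropped:
                warnings.append(
                    f"hill[{T}K]: dropped points {list(b.points_dropped)} "
                    "([Q]=0 or F>=F0)"
                )
            binding_by_T[T] = b
        # thermodynamics
        thermo = None
        if len(binding_by_T) >= 2:
            thermo = VantHoffModel(
                [(T, b.K_A) for T, b in binding_by_T.items()]
            ).fit()
        # site mapping
        site_call = None
        if self.displacement_curves:
            site_call = infer_site(
                self.displacement_curves, threshold=self.displacement_threshold
            )
        # structural stages
        sync_results = tuple(
            synchronous_analysis(s, threshold_nm=self.shift_threshold_nm)
            for s in self.synchronous
        )
        eem_comparison = None
        if self.eem_free is not None and self.eem_bound is not None:
            eem_comparison = compare_eem_peaks(self.eem_free, self.eem_bound)
        elif self.eem_free is not None or self.eem_bound is not None:
            warnings.append("eem: only one matrix supplied; peak comparison skipped")
        uvvis_result = None
        if self.uvvis is not None:
            spectra, concs = self.uvvis
            uvvis_result = uvvis_analysis(
                spectra, concs, threshold_nm=self.shift_threshold_nm
            )
        cd_free_res = cd_analysis(self.cd_free) if self.cd_free is not None else None
        cd_bound_res = cd_analysis(self.cd_bound) if self.cd_bound is not None else None
        for name, res in (("free", cd_free_res), ("bound", cd_bound_res)):
            if res is not None and res.alpha_helix_pct != res.alpha_helix_pct_raw:
                warnings.append(
                    f"cd[{name}]: raw helix {res.alpha_helix_pct_raw:.2f}% clipped"
                )
        return BindingStudyResults(
            complex_label=self.complex_label,
            sv_by_T=sv_by_T,
            mechanism=mechanism,
            binding_by_T=binding_by_T,
            thermo=thermo,
            site_call=site_call,
            displacement_curves=self.displacement_curves,
            synchronous=sync_results,
            eem_comparison=eem_comparison,
            uvvis=uvvis_result,
            cd_free=cd_free_res,
            cd_bound=cd_bound_res,
            warnings=tuple(warnings),
            config_echo={
                "tau0_s": self.tau0_s,
                "shift_threshold_nm": self.shift_threshold_nm,
                "displacement_threshold": self.displacement_threshold,
                "temperatures_K": list(self.titrations),
            },
        )


# ---------------------------------------------------------------------------
# file-level driver
# ---------------------------------------------------------------------------

def _read_synchronous(path) -> SynchronousSeries:
    meta_path = Path(str(path) + ".meta.yaml")
    with open(meta_path, encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    series = read_titration(path, metadata=meta)
    return SynchronousSeries(delta_lambda_nm=float(meta["delta_lambda_nm"]), series=series)


def _read_uvvis(path) -> tuple[list[AbsorptionSpectrum], np.ndarray]:
    meta_path = Path(str(path) + ".meta.yaml")
    with open(meta_path, encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    data = np.loadtxt(path, delimiter=",", skiprows=1, dtype=float)
    wl, cols = data[:, 0], data[:, 1:]
    q = np.asarray(meta["quencher_conc_M"], dtype=float)
    if cols.shape[1] != q.size:
        raise SpectraError(
            f"{path}: {cols.shape[1]} absorbance columns but {q.size} concentrations"
        )
    return [AbsorptionSpectrum(wl, cols[:, j]) for j in range(cols.shape[1])], q


def _read_cd(path) -> CDSpectrum:
    meta_path = Path(str(path) + ".meta.yaml")
    with open(meta_path, encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    data = np.loadtxt(path, delimiter=",", skiprows=1, dtype=float)
    return CDSpectrum(
        wavelength_nm=data[:, 0],
        ellipticity_mdeg=data[:, 1],
        protein_conc_M=float(meta["protein_conc_M"]),
        n_residues=int(meta["n_residues"]),
        path_length_cm=float(meta["path_length_cm"]),
    )


def run_study(config: StudyConfig | str | Path) -> BindingStudyResults:
    """Load every input named by the config, fit the study, return results.

    Titration files whose sidecar temperature disagrees with the
    temperature the config assigns them raise an error naming both.
    Missing optional inputs simply leave their report sections absent.
    """
    if not isinstance(config, StudyConfig):
        config = StudyConfig.from_yaml(config)
    titrations: dict[float, TitrationSeries] = {}
    for T, path in sorted(config.titration_paths.items()):
        series = read_titration(path)
        if series.temperature_K != T:
            raise SpectraError(
                f"temperature mismatch: config assigns {path} to {T} K but its "
                f"metadata sidecar says {series.temperature_K} K"
            )
        titrations[T] = series
    curves = tuple(read_displacement_csv(p) for p in config.displacement_paths)
    sync = tuple(_read_synchronous(p) for p in config.synchronous_paths)
    eem_free = read_eem_csv(config.eem_free_path) if config.eem_free_path else None
    eem_bound = read_eem_csv(config.eem_bound_path) if config.eem_bound_path else None
    uvvis = _read_uvvis(config.uvvis_path) if config.uvvis_path else None
    cd_free = _read_cd(config.cd_free_path) if config.cd_free_path else None
    cd_bound = _read_cd(config.cd_bound_path) if config.cd_bound_path else None
    model = BindingStudy(
        titrations,
        displacement_curves=curves,
        synchronous=sync,
        eem_free=eem_free,
        eem_bound=eem_bound,
        uvvis=uvvis,
        cd_free=cd_free,
        cd_bound=cd_bound,
        complex_label=config.complex_label,
        tau0_s=config.tau0_s,
        shift_threshold_nm=config.shift_threshold_nm,
        displacement_threshold=config.displacement_threshold,
    )
    return model.fit()
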