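"""Site-marker competitive displacement analysis.

Serum albumin has two principal drug pockets: Sudlow site I (subdomain IIA,
marked by warfarin/ketoprofen) and Sudlow site II (subdomain IIIA, marked by
ibuprofen).  Titrating a site marker into a preformed ligand/albumin complex
and tracking the probe-displacement ratio

    F2 / F1   (complex fluorescence with / without the probe)

reveals whether the ligand shares the marker's pocket: a marker that drives
the ratio well below 1 competes for the ligand's site.  A marker whose
curve stays near 1 leaves the ligand untouched.  If neither marker
displaces, the ligand most plausibly binds at the protein surface or some
other non-Sudlow site.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "DEFAULT_DISPLACEMENT_THRESHOLD",
    "MARKER_SITES",
    "DisplacementCurve",
    "SiteCall",
    "displacement_ratio",
    "infer_site",
    "curve_from_titration",
    "read_displacement_csv",
    "write_displacement_csv",
]

#: A marker is said to displace the ligand when the F2/F1 ratio at the
#: marker's highest concentration falls below this value.
DEFAULT_DISPLACEMENT_THRESHOLD = 0.8

#: Conventional site assignment of the standard markers.
MARKER_SITES = {"KPF": "SudlowI", "WAR": "SudlowI", "IBF": "SudlowII"}


def displacement_ratio(F2, F1):
    """Probe-displacement ratio F2/F1.

    ``F1`` is the complex fluorescence without the probe (must be positive);
    ``F2`` with the probe (non-negative).
    """
    F1 = np.asarray(F1, dtype=float)
    F2 = np.asarray(F2, dtype=float)
    if np.any(F1 <= 0):
        raise ValueError("F1 (fluorescence without probe) must be positive")
    if np.any(F2 < 0):
        raise ValueError("F2 must be non-negative")
    out = F2 / F1
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DisplacementCurve:
    """F2/F1 ratios of one ligand/albumin complex versus probe concentration."""

    probe_id: str
    probe_conc_M: np.ndarray
    ratio: np.ndarray
    site_marked: str  # SudlowI | SudlowII

    def __post_init__(self):
        c = np.asarray(self.probe_conc_M, dtype=float)
        r = np.asarray(self.ratio, dtype=float)
        if c.ndim != 1 or r.shape != c.shape:
            raise ValueError("probe_conc_M and ratio must be equal-length 1-D arrays")
        if not np.all(np.diff(c) > 0):
            raise ValueError("probe_conc_M must be strictly increasing")
        if np.any(r <= 0):
            raise ValueError("ratios must be positive")
        if self.site_marked not in ("SudlowI", "SudlowII"):
            raise ValueError(f"unknown site label {self.site_marked!r}")
        object.__setattr__(self, "probe_conc_M", c)
        object.__setattr__(self, "ratio", r)

    @property
    def final_ratio(self) -> float:
        """Ratio at the highest probe concentration."""
        return float(self.ratio[-1])

    def displaces(self, threshold: float = DEFAULT_DISPLACEMENT_THRESHOLD) -> bool:
        return self.final_ratio < threshold


@dataclass(frozen=True)
class SiteCall:
    """Binding-site inference from the marker displacement pattern."""

    site: str  # SudlowI | SudlowII | surface_or_other | ambiguous
    displaced_by: tuple[str, ...]
    threshold_used: float


def infer_site(
    curves: Sequence[DisplacementCurve],
    threshold: float = DEFAULT_DISPLACEMENT_THRESHOLD,
) -> SiteCall:
    """Infer the ligand's binding site from marker displacement curves.

    Only the site-I marker displaces -> SudlowI; only the site-II marker ->
    SudlowII; both -> ambiguous; neither -> surface_or_other.  The call is
    invariant to uniform rescaling of the fluorescence intensities (it
    depends only on the F2/F1 ratios) and monotone in the threshold.
    """
    if not curves:
        raise ValueError("at least one displacement curve is required")
    for c in curves:
        if c.probe_conc_M.size < 2:
            raise ValueError(f"curve {c.probe_id}: >= 2 probe concentrations required")
    displacing_sites = {c.site_marked for c in curves if c.displaces(threshold)}
    displaced_by = tuple(c.probe_id for c in curves if c.displaces(threshold))
    if displacing_sites == {"SudlowI"}:
        site = "SudlowI"
    elif displacing_sites == {"SudlowII"}:
        site = "SudlowII"
    elif not displacing_sites:
        site = "surface_or_other"
    else:
        site = "ambiguous"
    return SiteCall(site=site, displaced_by=displaced_by, threshold_used=threshold)


def curve_from_titration(series, probe_id: str, site_marked: str | None = None) -> DisplacementCurve:
    """Build a displacement curve from a probe-into-complex titration.

    ``series`` is a :class:`~albind.spectra.TitrationSeries` whose
    "quencher" axis is the site-marker concentration and whose [probe] = 0
    spectrum is the preformed ligand/albumin complex (the F1 source).
    Intensities are read at the F1 peak wavelength.
    """
    from .spectra import peak_position  # local import avoids a cycle

    free_peak = peak_position(series.free_spectrum)
    F1 = free_peak.peak_intensity
    c = series.quencher_conc_M[1:]
    F2 = np.array([s.intensity_at(free_peak.peak_nm) for s in series.spectra[1:]])
    return DisplacementCurve(
        probe_id=probe_id,
        probe_conc_M=c,
        ratio=displacement_ratio(F2, F1),
        site_marked=site_marked or MARKER_SITES.get(probe_id, "SudlowI"),
    )


def write_displacement_csv(curve: DisplacementCurve, path) -> Path:
    """Write a curve as CSV (probe_conc_M, ratio) plus a YAML sidecar."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_conc_M,ratio\n")
        for c, r in zip(curve.probe_conc_M, curve.ratio):
            fh.write(f"{c:.17g},{r:.17g}\n")
    meta = {"probe_id": curve.probe_id, "site_marked": curve.site_marked}
    with open(path.with_suffix(path.suffix + ".meta.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_displacement_csv(path) -> DisplacementCurve:
    """Read a curve written by :func:`write_displacement_csv`."""
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1, dtype=float)
    with open(path.with_suffix(path.suffix + ".meta.yaml"), encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    return DisplacementCurve(
        probe_id=meta["probe_id"],
        probe_conc_M=data[:, 0],
        ratio=data[:, 1],
        site_marked=meta["site_marked"],
    )
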