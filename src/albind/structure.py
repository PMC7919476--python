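"""Structural spectroscopy: synchronous scans, 3D fluorescence, UV/Vis and CD.

Four techniques that characterise how ligand binding perturbs the protein:

* synchronous fluorescence at a fixed excitation-emission offset (15 nm for
  tyrosine, 60 nm for tryptophan) reports per-residue quenching and
  micro-environment polarity shifts;
* the excitation-emission matrix (EEM) carries two fluorescence peaks — the
  Trp/Tyr band excited near 280 nm and the polypeptide-backbone band excited
  near 230 nm — plus first- and second-order Rayleigh scattering ridges
  along lambda_em = lambda_ex and lambda_em = 2*lambda_ex;
* UV/Vis absorption shows the backbone n->pi* band near 207 nm and the
  aromatic pi->pi* band near 280 nm, whose shifts track conformational
  change;
* circular dichroism is converted to mean residue ellipticity

      MRE = theta_obs(mdeg) / (10 * c * n * l)

  (c molar protein concentration, n residue count, l path length in cm) and
  the alpha-helix content estimated from the 208 nm band:

      helix% = (-MRE_208 - 4000) / (33000 - 4000) * 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectra import (
    DEFAULT_SHIFT_THRESHOLD_NM,
    EEM,
    AbsorptionSpectrum,
    IndeterminatePeakError,
    PeakShift,
    SpectraError,
    SynchronousSeries,
    measure_shift,
    peak_position,
)

__all__ = [
    "CDSpectrum",
    "SecondaryStructure",
    "EEMPeaks",
    "SynchronousResult",
    "UVVisResult",
    "mre",
    "alpha_helix_percent",
    "synchronous_analysis",
    "find_eem_peaks",
    "compare_eem_peaks",
    "uvvis_analysis",
]

#: residue counts of the two albumins
N_RESIDUES = {"HSA": 585, "BSA": 583}

#: MRE_208 values (deg cm^2/dmol) anchoring 0% and 100% helix
_HELIX_MRE_0, _HELIX_MRE_100 = -4000.0, -33000.0

#: half-width (nm) of the Rayleigh ridge exclusion bands in an EEM
DEFAULT_RAYLEIGH_TOL_NM = 5.0

#: excitation windows assigning EEM fluorescence peaks: Trp/Tyr band vs
#: polypeptide-backbone band
PEAK1_EX_BAND = (260.0, 300.0)
PEAK2_EX_BAND = (220.0, 250.0)


@dataclass(frozen=True)
class CDSpectrum:
    """Far-UV circular dichroism spectrum with its MRE conversion parameters."""

    wavelength_nm: np.ndarray
    ellipticity_mdeg: np.ndarray
    protein_conc_M: float
    n_residues: int
    path_length_cm: float

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        el = np.asarray(self.ellipticity_mdeg, dtype=float)
        if wl.ndim != 1 or not np.all(np.diff(wl) > 0):
            raise SpectraError("wavelength_nm must be strictly increasing")
        if el.shape != wl.shape:
            raise SpectraError("ellipticity and wavelength must have equal length")
        if self.protein_conc_M <= 0 or self.n_residues <= 0 or self.path_length_cm <= 0:
            raise SpectraError("c, n and l must all be positive")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "ellipticity_mdeg", el)


def mre(cd: CDSpectrum) -> np.ndarray:
    """Mean residue ellipticity spectrum, deg cm^2/dmol.

    MRE(lambda) = ellipticity(mdeg) / (10 * c * n * l); linear in the
    observed ellipticity and inversely proportional to each of c, n and l.
    """
    denom = 10.0 * cd.protein_conc_M * cd.n_residues * cd.path_length_cm
    return cd.ellipticity_mdeg / denom


@dataclass(frozen=True)
class SecondaryStructure:
    """Alpha-helix content estimated from the 208 nm MRE band."""

    alpha_helix_pct: float  # clipped to [0, 100]
    alpha_helix_pct_raw: float  # unclipped formula value
    mre_208: float  # deg cm^2/dmol


def alpha_helix_percent(mre_208: float) -> SecondaryStructure:
    """Alpha-helix percentage from MRE at 208 nm.

    helix% = (-MRE_208 - 4000) / (33000 - 4000) * 100; values outside
    [0, 100] are retained raw and clipped with a warning.
    """
    if not np.isfinite(mre_208):
        raise ValueError("MRE at 208 nm must be finite")
    raw = (-mre_208 - (-_HELIX_MRE_0)) / ((-_HELIX_MRE_100) - (-_HELIX_MRE_0)) * 100.0
    clipped = float(np.clip(raw, 0.0, 100.0))
    if clipped != raw:
        warnings.warn(
            f"alpha-helix estimate {raw:.2f}% outside [0, 100]; clipped",
            stacklevel=2,
        )
    return SecondaryStructure(
        alpha_helix_pct=clipped, alpha_helix_pct_raw=float(raw), mre_208=float(mre_208)
    )


def mre_at(cd: CDSpectrum, wavelength_nm: float = 208.0) -> float:
    """MRE at a single wavelength (linear interpolation on the grid)."""
    wl = cd.wavelength_nm
    if not (wl[0] <= wavelength_nm <= wl[-1]):
        raise SpectraError(f"{wavelength_nm} nm outside CD grid span")
    return float(np.interp(wavelength_nm, wl, mre(cd)))


def cd_analysis(cd: CDSpectrum) -> SecondaryStructure:
    """Full CD stage: MRE conversion then helix quantification at 208 nm."""
    return alpha_helix_percent(mre_at(cd, 208.0))


# ---------------------------------------------------------------------------
# synchronous fluorescence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynchronousResult:
    """Per-concentration peak table and shift call for one synchronous scan."""

    residue: str  # Tyr | Trp | unattributed
    delta_lambda_nm: float
    quencher_conc_M: np.ndarray
    peak_ex_nm: np.ndarray  # scanned-axis (excitation) peak positions
    peak_em_nm: np.ndarray  # same peaks in the emission convention (ex + dl)
    peak_intensity: np.ndarray
    quench_fraction: np.ndarray  # 1 - F/F0 at the free-protein peak
    shift: PeakShift  # highest concentration vs free protein


def synchronous_analysis(
    sync: SynchronousSeries,
    threshold_nm: float = DEFAULT_SHIFT_THRESHOLD_NM,
) -> SynchronousResult:
    """Quenching and peak-shift analysis of a synchronous titration.

    The quench fraction at each concentration is 1 - F/F0 read at the
    free-protein peak position (scanned excitation axis); the shift compares
    the highest-concentration spectrum with the free protein.  Peak
    positions are reported in both conventions (scanned excitation
    wavelength and excitation + delta-lambda).
    """
    series = sync.series
    free = series.free_spectrum
    free_peak = peak_position(free)
    F0 = free_peak.peak_intensity
    n = series.quencher_conc_M.size
    ex = np.empty(n)
    inten = np.empty(n)
    qf = np.empty(n)
    for i, spec in enumerate(series.spectra):
        p = peak_position(spec)
        ex[i], inten[i] = p.peak_nm, p.peak_intensity
        qf[i] = 1.0 - spec.intensity_at(free_peak.peak_nm) / F0
    shift = measure_shift(free, series.spectra[-1], threshold_nm=threshold_nm)
    return SynchronousResult(
        residue=sync.residue,
        delta_lambda_nm=sync.delta_lambda_nm,
        quencher_conc_M=series.quencher_conc_M,
        peak_ex_nm=ex,
        peak_em_nm=ex + sync.delta_lambda_nm,
        peak_intensity=inten,
        quench_fraction=qf,
        shift=shift,
    )


# ---------------------------------------------------------------------------
# excitation-emission matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EEMPeak:
    ex_nm: float
    em_nm: float
    intensity: float


@dataclass(frozen=True)
class RayleighRidge:
    order: int  # 1: em = ex; 2: em = 2*ex
    max_intensity: float
    mean_intensity: float


@dataclass(frozen=True)
class EEMPeaks:
    """Located features of an excitation-emission matrix."""

    peak1: EEMPeak | None  # Trp/Tyr fluorescence, excitation ~ 280 nm
    peak2: EEMPeak | None  # polypeptide backbone, excitation ~ 230 nm
    rayleigh_1: RayleighRidge | None
    rayleigh_2: RayleighRidge | None


def _ridge_mask(eem: EEM, tol_nm: float) -> np.ndarray:
    """Boolean mask of cells within ``tol_nm`` of either Rayleigh ridge."""
    ex = eem.excitation_nm[:, None]
    em = eem.emission_nm[None, :]
    return (np.abs(em - ex) <= tol_nm) | (np.abs(em - 2 * ex) <= tol_nm)


def _ridge_summary(eem: EEM, order: int, tol_nm: float) -> RayleighRidge | None:
    ex = eem.excitation_nm[:, None]
    em = eem.emission_nm[None, :]
    mask = np.abs(em - order * ex) <= tol_nm
    if not mask.any():
        return None
    vals = eem.intensity[mask]
    if vals.max() <= 0:
        return None
    return RayleighRidge(order, float(vals.max()), float(vals.mean()))


def _refine_2d(eem: EEM, i: int, j: int, half_window_nm: float = 8.0) -> EEMPeak:
    """Quadratic refinement of a local maximum along each grid axis.

    The parabola is fitted over all samples within ``half_window_nm`` of
    the discrete maximum (at least its two neighbours), which keeps the
    vertex estimate stable against per-sample noise on the nearly flat
    band top of a finely sampled axis.
    """

    def refine(grid, vals, k):
        if k == 0 or k == len(grid) - 1:
            return float(grid[k]), float(vals[k])
        hw = max(half_window_nm, grid[k + 1] - grid[k])
        sel = np.abs(grid - grid[k]) <= hw
        if sel.sum() < 3:
            sel = np.zeros_like(grid, dtype=bool)
            sel[k - 1 : k + 2] = True
        c = np.polyfit(grid[sel] - grid[k], vals[sel], 2)
        if c[0] >= 0:
            return float(grid[k]), float(vals[k])
        lo = float(grid[sel][0] - grid[k])
        hi = float(grid[sel][-1] - grid[k])
        x = float(np.clip(-c[1] / (2 * c[0]), lo, hi))
        return float(grid[k] + x), float(np.polyval(c, x))

    ex, iex = refine(eem.excitation_nm, eem.intensity[:, j], i)
    em, iem = refine(eem.emission_nm, eem.intensity[i, :], j)
    return EEMPeak(ex_nm=ex, em_nm=em, intensity=float(max(iex, iem)))


def find_eem_peaks(
    eem: EEM,
    ridge_tol_nm: float = DEFAULT_RAYLEIGH_TOL_NM,
    peak1_ex_band: tuple[float, float] = PEAK1_EX_BAND,
    peak2_ex_band: tuple[float, float] = PEAK2_EX_BAND,
) -> EEMPeaks:
    """Locate the fluorescence peaks and Rayleigh ridges of an EEM.

    Rayleigh ridges are identified geometrically (|em - order*ex| within the
    tolerance); fluorescence peaks are searched off-ridge, one per
    excitation band (Trp/Tyr ~260-300 nm; backbone ~220-250 nm), and refined
    by per-axis parabolic interpolation.  A fluorescence peak is never
    reported inside a ridge band.  An all-zero matrix yields no features.
    """
    off_ridge = ~_ridge_mask(eem, ridge_tol_nm)
    # a fluorescence peak must be a genuine 2-D local maximum: the largest
    # off-ridge cell alone could be a Rayleigh tail at the mask boundary
    z = eem.intensity
    padded = np.pad(z, 1, constant_values=-np.inf)
    local_max = np.ones_like(z, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            local_max &= z >= padded[1 + di : 1 + di + z.shape[0], 1 + dj : 1 + dj + z.shape[1]]

    def band_peak(band):
        sel = (eem.excitation_nm >= band[0]) & (eem.excitation_nm <= band[1])
        if not sel.any():
            return None
        masked = np.where(off_ridge & local_max, z, -np.inf)
        masked[~sel, :] = -np.inf
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if not np.isfinite(masked[i, j]) or masked[i, j] <= 0:
            return None
        return _refine_2d(eem, int(i), int(j))

    return EEMPeaks(
        peak1=band_peak(peak1_ex_band),
        peak2=band_peak(peak2_ex_band),
        rayleigh_1=_ridge_summary(eem, 1, ridge_tol_nm),
        rayleigh_2=_ridge_summary(eem, 2, ridge_tol_nm),
    )


def compare_eem_peaks(free: EEM, bound: EEM, **kwargs) -> dict:
    """Fractional intensity change of each fluorescence peak, free vs complex.

    Returns a dict with the located peaks in both matrices and the drop
    fraction (1 - I_bound/I_free) for peak 1 and peak 2 where both exist.
    """
    pf = find_eem_peaks(free, **kwargs)
    pb = find_eem_peaks(bound, **kwargs)
    out = {"free": pf, "bound": pb, "peak1_drop": None, "peak2_drop": None}
    if pf.peak1 and pb.peak1:
        out["peak1_drop"] = 1.0 - pb.peak1.intensity / pf.peak1.intensity
    if pf.peak2 and pb.peak2:
        out["peak2_drop"] = 1.0 - pb.peak2.intensity / pf.peak2.intensity
    return out


# ---------------------------------------------------------------------------
# UV/Vis absorption titrations
# ---------------------------------------------------------------------------

#: search windows for the two absorption bands
UV_PEAK1_WINDOW = (200.0, 240.0)  # backbone n->pi*, ~207 nm
UV_PEAK2_WINDOW = (260.0, 300.0)  # aromatic pi->pi*, ~280 nm


@dataclass(frozen=True)
class UVVisResult:
    """Per-concentration peak table and shift calls for a UV/Vis titration."""

    quencher_conc_M: np.ndarray
    peak1_nm: np.ndarray
    peak1_absorbance: np.ndarray
    peak2_nm: np.ndarray
    peak2_absorbance: np.ndarray
    peak1_shift: PeakShift | None  # highest concentration vs free protein
    peak2_shift: PeakShift | None


def uvvis_analysis(
    spectra,
    quencher_conc_M,
    threshold_nm: float = DEFAULT_SHIFT_THRESHOLD_NM,
    peak1_window: tuple[float, float] = UV_PEAK1_WINDOW,
    peak2_window: tuple[float, float] = UV_PEAK2_WINDOW,
) -> UVVisResult:
    """Track both absorption bands along a titration and measure their shifts.

    ``spectra`` is a sequence of :class:`~albind.spectra.AbsorptionSpectrum`
    ordered by the (increasing) ligand concentrations.  Shifts compare the
    highest-concentration spectrum with the first (free protein when its
    concentration is 0); with a single spectrum the peaks are reported and
    the shifts are None.
    """
    q = np.asarray(quencher_conc_M, dtype=float)
    spectra = list(spectra)
    if len(spectra) != q.size:
        raise SpectraError("one absorption spectrum per concentration required")
    n = q.size
    p1_nm, p1_a = np.empty(n), np.empty(n)
    p2_nm, p2_a = np.empty(n), np.empty(n)
    for i, s in enumerate(spectra):
        e1 = peak_position(s, window=peak1_window)
        e2 = peak_position(s, window=peak2_window)
        p1_nm[i], p1_a[i] = e1.peak_nm, e1.peak_intensity
        p2_nm[i], p2_a[i] = e2.peak_nm, e2.peak_intensity
    if n > 1:
        s1 = measure_shift(p1_nm[0], p1_nm[-1], threshold_nm=threshold_nm)
        s2 = measure_shift(p2_nm[0], p2_nm[-1], threshold_nm=threshold_nm)
    else:
        s1 = s2 = None
    return UVVisResult(q, p1_nm, p1_a, p2_nm, p2_a, s1, s2)
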