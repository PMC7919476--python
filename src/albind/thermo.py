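"""Van't Hoff thermodynamics of ligand-albumin binding.

The temperature dependence of the association constant follows

    ln K_A = -dH / (R T) + dS / R

so an OLS line of ln K_A on 1/T yields the binding enthalpy dH (kJ/mol,
from the slope) and entropy dS (J/(mol K), from the intercept).  The Gibbs
energy is obtained two ways:

    dG = dH - T dS          (primary pathway; reproduces tabulated values)
    dG = -R T ln K_A        (reported alongside as a consistency check)

The signs of (dH, dS) indicate the dominant interaction force: both
negative points to hydrogen bonding and van der Waals contacts; dH < 0 with
dS > 0 points to hydrophobic interactions.  Conventional extensions of this
sign table (dH > 0 and dS > 0 -> hydrophobic; dH ~ 0 and dS > 0 ->
electrostatic) are applied only when explicitly enabled and are labelled as
extensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "R_GAS",
    "ThermoResult",
    "ForceClass",
    "VantHoffModel",
    "vant_hoff_fit",
    "gibbs_from_HS",
    "gibbs_from_K",
    "classify_forces",
]

#: Universal gas constant, J/(mol*K).
R_GAS = 8.314

#: half-width (kJ/mol) of the "dH approximately zero" band used by the
#: extended force-classification rules.
DEFAULT_DH_ZERO_BAND_KJ = 5.0


def gibbs_from_HS(delta_H_kJ: float, delta_S_J: float, T_K: float) -> float:
    """Gibbs energy dG = dH - T*dS, in kJ/mol.

    ``delta_H_kJ`` in kJ/mol, ``delta_S_J`` in J/(mol*K), T in K.
    """
    if T_K <= 0:
        raise ValueError("temperature must be positive (K)")
    return float(delta_H_kJ - T_K * delta_S_J / 1000.0)


def gibbs_from_K(K_A: float, T_K: float) -> float:
    """Gibbs energy dG = -R*T*ln(K_A), in kJ/mol."""
    if K_A <= 0:
        raise ValueError("K_A must be positive")
    if T_K <= 0:
        raise ValueError("temperature must be positive (K)")
    return float(-R_GAS * T_K * np.log(K_A) / 1000.0)


@dataclass(frozen=True)
class ForceClass:
    """Dominant-interaction-force call from the (dH, dS) sign pattern."""

    label: str  # hbond_vdw | hydrophobic | electrostatic | ... | indeterminate
    rule_applied: str
    is_extension: bool = False


def classify_forces(
    delta_H_kJ: float,
    delta_S_J: float,
    extended: bool = False,
    dh_zero_band_kJ: float = DEFAULT_DH_ZERO_BAND_KJ,
) -> ForceClass:
    """Classify the dominant binding force from the signs of dH and dS.

    The two primary rules: dH < 0 and dS < 0 -> hydrogen bonds + van der
    Waals; dH < 0 and dS > 0 -> hydrophobic.  With ``extended=True`` the
    conventional additional rules are applied (and labelled extensions):
    |dH| < band and dS > 0 -> electrostatic; dH > 0 and dS > 0 ->
    hydrophobic.  Anything else is indeterminate.
    """
    if not (np.isfinite(delta_H_kJ) and np.isfinite(delta_S_J)):
        raise ValueError("dH and dS must be finite")
    if extended and abs(delta_H_kJ) < dh_zero_band_kJ and delta_S_J > 0:
        return ForceClass(
            "electrostatic",
            f"dH ~ 0 (|dH| < {dh_zero_band_kJ} kJ/mol) and dS > 0 (extension)",
            is_extension=True,
        )
    if delta_H_kJ < 0 and delta_S_J < 0:
        return ForceClass("hbond_vdw", "dH < 0 and dS < 0")
    if delta_H_kJ < 0 and delta_S_J > 0:
        return ForceClass("hydrophobic", "dH < 0 and dS > 0")
    if extended and delta_H_kJ > 0 and delta_S_J > 0:
        return ForceClass(
            "hydrophobic", "dH > 0 and dS > 0 (extension)", is_extension=True
        )
    return ForceClass("indeterminate", "sign pattern outside applied rules")


@dataclass(frozen=True)
class ThermoResult:
    """Van't Hoff fit with Gibbs energies and the force classification.

    ``delta_G_by_T`` holds dH - T*dS per temperature (the primary pathway);
    ``delta_G_from_K_by_T`` holds -RT ln K_A for the fitted input points, so
    the two pathways can be compared directly.
    """

    delta_H: float  # kJ/mol
    delta_S: float  # J/(mol*K)
    r_squared: float
    delta_G_by_T: dict[float, float]  # T (K) -> dG (kJ/mol) via dH - T dS
    delta_G_from_K_by_T: dict[float, float]  # T (K) -> -RT ln K_A
    force_class: ForceClass
    gas_constant: float = R_GAS

    @property
    def consistency_delta_by_T(self) -> dict[float, float]:
        """Per-temperature (dH - T dS) minus (-RT ln K_A), kJ/mol."""
        return {
            T: self.delta_G_by_T[T] - self.delta_G_from_K_by_T[T]
            for T in self.delta_G_by_T
            if T in self.delta_G_from_K_by_T
        }


class VantHoffModel:
    """Van't Hoff regression over (temperature, association constant) pairs.

    Parameters
    ----------
    pairs : sequence of (T_K, K_A) or mapping T_K -> K_A
        Association constants at >= 2 distinct temperatures, K_A > 0.
    extended_forces : bool
        Enable the extended force-classification rules.
    """

    def __init__(self, pairs, extended_forces: bool = False):
        if isinstance(pairs, Mapping):
            pairs = list(pairs.items())
        arr = np.asarray(sorted(pairs), dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("van't Hoff fit needs >= 2 (T, K_A) pairs")
        T, K = arr[:, 0], arr[:, 1]
        if np.unique(T).size != T.size:
            raise ValueError("duplicate temperatures in van't Hoff input")
        if np.any(K <= 0):
            raise ValueError("K_A values must be positive")
        self.T_K, self.K_A = T, K
        self.extended_forces = extended_forces

    def fit(self) -> ThermoResult:
        """OLS of ln K_A on 1/T; dH = -slope*R, dS = intercept*R."""
        x = 1.0 / self.T_K
        y = np.log(self.K_A)
        res = stats.linregress(x, y)
        dH = -float(res.slope) * R_GAS / 1000.0  # kJ/mol
        dS = float(res.intercept) * R_GAS  # J/(mol*K)
        dG = {float(T): gibbs_from_HS(dH, dS, T) for T in self.T_K}
        dGk = {float(T): gibbs_from_K(K, T) for T, K in zip(self.T_K, self.K_A)}
        return ThermoResult(
            delta_H=dH,
            delta_S=dS,
            r_squared=float(res.rvalue**2) if self.T_K.size > 2 else 1.0,
            delta_G_by_T=dG,
            delta_G_from_K_by_T=dGk,
            force_class=classify_forces(dH, dS, extended=self.extended_forces),
        )


def vant_hoff_fit(pairs) -> tuple[float, float, float]:
    """Functional wrapper returning (dH kJ/mol, dS J/(mol*K), r_squared)."""
    res = VantHoffModel(pairs).fit()
    return res.delta_H, res.delta_S, res.r_squared
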