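"""Reference binding parameters for the four conazole/albumin complexes.

Published association constants (K_A, L/mol), Hill coefficients (n) and
thermodynamic parameters (dH kJ/mol, dS J/(mol K), dG kJ/mol) for
epoxiconazole (EPX) and prothioconazole (PTC) binding to human and bovine
serum albumin at 298/303/310 K, together with the qualitative site-marker
displacement outcome for each complex.  These values parameterise the
synthetic study conditions and serve as cross-check anchors.
"""

from __future__ import annotations

__all__ = ["REFERENCE_COMPLEXES", "TEMPERATURES_K"]

TEMPERATURES_K = (298.0, 303.0, 310.0)

REFERENCE_COMPLEXES: dict[str, dict] = {
    "EPX/HSA": {
        "protein": "HSA",
        "K_A": {298.0: 6.22e4, 303.0: 2.04e4, 310.0: 8.14e3},
        "n": {298.0: 0.98, 303.0: 0.95, 310.0: 0.91},
        "delta_H_kJ": -105.74,
        "delta_S_J": -265.88,
        "delta_G_kJ": {298.0: -26.51, 303.0: -25.18, 310.0: -23.32},
        "site": "SudlowI",  # only the site-I marker (ketoprofen) displaces
        "displaced_markers": ("KPF",),
    },
    "EPX/BSA": {
        "protein": "BSA",
        "K_A": {298.0: 3.80e4, 303.0: 1.04e4, 310.0: 7.90e3},
        "n": {298.0: 0.90, 303.0: 0.96, 310.0: 0.95},
        "delta_H_kJ": -81.54,
        "delta_S_J": -199.35,
        "delta_G_kJ": {298.0: -22.14, 303.0: -21.13, 310.0: -19.73},
        "site": "SudlowI",
        "displaced_markers": ("KPF",),
    },
    "PTC/HSA": {
        "protein": "HSA",
        "K_A": {298.0: 5.75e5, 303.0: 3.80e5, 310.0: 2.08e5},
        "n": {298.0: 1.11, 303.0: 1.07, 310.0: 0.98},
        "delta_H_kJ": -64.39,
        "delta_S_J": -105.50,
        "delta_G_kJ": {298.0: -32.95, 303.0: -32.42, 310.0: -31.68},
        "site": "SudlowI",
        "displaced_markers": ("KPF",),
    },
    "PTC/BSA": {
        "protein": "BSA",
        "K_A": {298.0: 6.45e5, 303.0: 2.89e5, 310.0: 1.66e5},
        "n": {298.0: 1.06, 303.0: 0.99, 310.0: 0.95},
        "delta_H_kJ": -84.85,
        "delta_S_J": -174.18,
        "delta_G_kJ": {298.0: -32.94, 303.0: -32.07, 310.0: -30.85},
        # neither Sudlow marker displaces: surface binding near Trp134
        "site": "surface_or_other",
        "displaced_markers": (),
    },
}
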