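# Methods

## Scope and model

`albind` analyses the binding of small hydrophobic ligands (here: the
conazole fungicides epoxiconazole, EPX, and prothioconazole, PTC) to serum
albumins (HSA, BSA) from standard solution-spectroscopy measurements. The
core chain is:

1. **Stern–Volmer quenching.** The intrinsic Trp/Tyr fluorescence of the
   protein obeys F₀/F = 1 + K_SV[Q] = 1 + K_q τ₀ [Q]. K_SV is the slope of
   an unweighted OLS line of F₀/F on [Q]; K_q = K_SV/τ₀. The temperature
   trend of K_SV classifies the mechanism: strictly decreasing with T ⇒
   static (ground-state complex), strictly increasing ⇒ dynamic
   (collisional), anything else ⇒ indeterminate. We deliberately fit the
   purely linear form — a single quenching population is assumed; no
   static+dynamic quadratic variant is offered.
2. **Hill double-logarithm binding.** For static quenching,
   log₁₀[(F₀−F)/F] = log₁₀K_A + n·log₁₀[Q]. OLS gives n (slope, apparent
   binding-site number) and K_A = 10^intercept (L/mol). Points with
   [Q] = 0 or F ≥ F₀ (fluorescence enhancement) have no defined transform
   and are dropped, with the exclusion recorded in the results and report
   warnings. Concentrations are total added ligand; no free-ligand
   correction is applied.
3. **Van't Hoff thermodynamics.** ln K_A = −ΔH/(RT) + ΔS/R with
   R = 8.314 J/(mol·K). ΔG is computed primarily as ΔH − TΔS and always
   alongside as −RT ln K_A, with the per-temperature difference exposed as
   a consistency diagnostic — with only three temperatures the two routes
   can disagree noticeably when the K_A(T) values are not exactly van't
   Hoff-consistent, and the package reports rather than reconciles that.
   Force classification by sign pattern: ΔH<0 ∧ ΔS<0 ⇒ hydrogen bonds +
   van der Waals; ΔH<0 ∧ ΔS>0 ⇒ hydrophobic. Conventional extensions
   (ΔH>0 ∧ ΔS>0 ⇒ hydrophobic; |ΔH| < 5 kJ/mol ∧ ΔS>0 ⇒ electrostatic)
   are opt-in and labelled as extensions; the ΔH≈0 band is configurable.
4. **Site-marker displacement.** F₂/F₁ (complex fluorescence with/without
   probe) versus probe concentration for the Sudlow site I marker
   ketoprofen and site II marker ibuprofen. A marker "displaces" iff the
   ratio at its highest concentration falls below a threshold (default
   0.8). Only-site-I ⇒ Sudlow I; only-site-II ⇒ Sudlow II; both ⇒
   ambiguous; neither ⇒ surface or other site. The call is invariant to
   uniform intensity rescaling and monotone in the threshold. No
   quantitative competitive-binding (Kd partitioning) model is attempted.
5. **Structural spectroscopy.** Synchronous scans (Δλ = 15 nm → Tyr,
   60 nm → Trp) give per-residue quenching fractions and micro-environment
   shifts; EEMs are decomposed into two Rayleigh ridges (λem ≈ λex and
   λem ≈ 2λex, ±5 nm tolerance) and two fluorescence peaks (Trp/Tyr band,
   excitation 260–300 nm; backbone band, 220–250 nm); UV/Vis tracks the
   ~207 nm backbone and ~280 nm aromatic absorption bands; CD is converted
   to mean residue ellipticity MRE = θ_obs/(10·c·n·l) (c molar, n residue
   count — 585 HSA / 583 BSA, l in cm) and α-helix % =
   (−MRE₂₀₈ − 4000)/29000 × 100, clipped to [0, 100] with the raw value
   retained. The 222 nm band is characterised but not used for a second
   helix estimate, and no CD deconvolution (CONTIN/SELCON-style or
   β-strand estimation) is provided.

## Peak measurement and intensity read-out

Peak positions are located as the discrete maximum refined by a parabola
through it and its two neighbours (local three points on non-uniform
grids), reported at 0.1 nm resolution; at a window or grid edge the
discrete maximum is returned with an edge flag, and a flat window raises an
indeterminate-peak error. Shifts are signed (observed − reference);
|shift| below a 2 nm threshold (configurable) is classified "none", since
sub-instrument-resolution changes of 0–1 nm are conventionally read as
"almost unchanged" while 3 nm is a genuine shift.

Quench ratios read F for *every* spectrum — including the free-protein F₀
— with the same estimator: a local quadratic least-squares fit over a ±5 nm
window evaluated at the free-protein peak wavelength ("fixed" policy,
default; robust to small progressive peak shifts along a titration). Using
one shared, data-linear estimator matters: taking F₀ from the argmax of a
noisy spectrum selects the largest noise excursion on the nearly flat band
top and biases F₀ upward by ~2σ, which propagates into a large downward
bias in K_A and n. A "per_spectrum" policy (each spectrum's own maximum)
is selectable. Stored intensities are never smoothed.

EEM peak refinement analogously fits a quadratic over a ±8 nm window per
axis (falling back to the three-point parabola where the axis is sampled
more coarsely than the window); candidate fluorescence peaks must be true
2-D local maxima off the ridge bands, which prevents ridge tails at the
mask boundary from being reported as peaks.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| τ₀ | 1 × 10⁻⁸ | s | conventional average biopolymer fluorescence lifetime; only scales K_q, always echoed in reports |
| shift threshold | 2 | nm | below: "none"; 3 nm shifts must classify |
| displacement threshold | 0.8 | — | ratio at highest probe concentration; the qualitative reports ("decreasing" vs "little impact") give no number, so this is a documented knob and the full curves are always reported |
| Rayleigh tolerance | ±5 | nm | ridge half-width for masking and summary |
| ΔH ≈ 0 band | 5 | kJ/mol | extended electrostatic rule only |
| R | 8.314 | J/(mol·K) | CODATA value |
| helix anchors | −4000 / −33000 | deg·cm²/dmol | MRE₂₀₈ at 0% and 100% α-helix |

## Synthetic data generator

The generator emulates the study design the analyses expect: protein fixed
at 2 × 10⁻⁶ mol/L, quencher titrated over eleven points from 2 × 10⁻⁶ to
32 × 10⁻⁶ mol/L (3 × 10⁻⁶ steps), temperatures 298/303/310 K, excitation
295 nm, emission collected 300–500 nm on a 1 nm grid. The emission band is
a single Gaussian (centre 340 nm HSA / 343 nm BSA, σ = 25 nm) — adequate
for testing the analysis algebra, not a photophysical model. Titrations
are built by exact inversion of the Hill relation, F = F₀/(1 + K_A[Q]ⁿ),
with K_A(T) either given per temperature or derived exactly from (ΔH, ΔS)
through the van't Hoff relation; an `enhancement_then_quench` mode raises
the two lowest-concentration spectra by +5% to mimic the
structural-opening intensity rise seen for PTC/HSA (no published magnitude
exists; 5% is a fixed choice). Noise is multiplicative Gaussian per
intensity sample (σ as a percentage); there is no wavelength jitter,
baseline drift, inner-filter forward model or detector noise spectrum —
so passing tests demonstrate correctness of the analysis chain under the
stated noise model, not robustness to every instrument artefact. All
randomness derives from a single seed via named `SeedSequence` streams;
identical configs are bit-identical. CD spectra are two negative Gaussian
bands (208/222 nm) whose amplitudes are solved linearly so MRE₂₀₈ maps
back exactly to the requested helix percentage; EEMs are 2-D Gaussian
peaks plus Gaussian-profile Rayleigh ridges; UV/Vis titrations impose a
configurable hypochromism and linear band drift. Ground truth is embedded
in every written file's metadata sidecar so tests never hard-code expected
values.

`generate_study` assembles a complete per-complex study directory using
the reference parameter set in `albind.reference` (published K_A/n per
temperature, (ΔH, ΔS), marker-displacement pattern and free-protein helix
content for the four EPX/PTC × HSA/BSA complexes) plus characteristic
structural scenarios: an 8 nm (EPX) or 2 nm (PTC) red drift of the 207 nm
absorption band, a −3 nm Trp-channel synchronous shift for PTC/BSA, a 35%
drop of both EEM fluorescence peaks, and a 3.5-point helix loss on
binding.

## Numerical choices and degenerate inputs

- All regressions are unweighted OLS (`scipy.stats.linregress`); fits are
  exact (r² = 1, parameters to ~1e-10 relative) on noise-free affine
  input. Constant-ratio input short-circuits to slope 0 rather than
  producing an undefined correlation.
- Logarithms in the Hill analysis are base 10; K_A is reported in L/mol
  even when n ≠ 1, matching the field's reporting convention over
  dimensional strictness.
- Stern–Volmer and Hill fits require ≥ 3 usable points; van't Hoff ≥ 2
  distinct temperatures; duplicate temperatures and non-positive K_A are
  rejected.
- Enhancement points (F₀/F < 1 at [Q] > 0) are excluded from the SV fit
  and the Hill transform by default (the transform is undefined there);
  exclusions are recorded per-result and surfaced as report warnings.
  The filter is F ≥ F₀ exactly (ε = 0).
- Titration CSV round trips are bit-identical on the numeric payload
  (17-significant-digit formatting).
- Synchronous-series maxima are stored on the scanned excitation axis and
  reported in both conventions (λex and λex + Δλ), since figures in the
  literature use either.
- Helix percentages outside [0, 100] are clipped with a warning; the raw
  value is kept.

## Problem sizes

Default test and acceptance runs use the study design above (12 spectra ×
201 wavelengths per titration, three temperatures), 200 seeded replicates
for the stochastic recovery checks, and EEM grids of 25 × 251 cells —
small enough that the entire suite runs in a few seconds while matching
the design the analyses are meant for.

## Known limitations

- The mechanism call is a strict-monotonicity rule over as few as three
  K_SV values; it does not propagate fit uncertainty into the call.
- The van't Hoff fit with three temperatures has essentially no leverage
  to detect curvature (heat-capacity effects are out of scope), and
  (ΔH, ΔS) from it are strongly anti-correlated.
- At the weakest binding (K_A ≈ 8 × 10³ L/mol at 310 K) the lowest
  titration point quenches only ~1.6%, so 1% intensity noise makes the
  log-transformed point very noisy; replicate-mean K_A estimates are
  heavy-tailed there.
- The displacement analysis is a threshold rule on ratio trends, not a
  competitive-binding model; "surface_or_other" means "neither Sudlow
  marker competes", not a positive identification of a surface site.
- β-strand content cannot be derived from the single-wavelength helix
  formula and is not estimated.
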