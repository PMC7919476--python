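# albind

Spectroscopic analysis of small-molecule binding to serum albumins.

Serum albumins (human HSA, bovine BSA) are the main transport proteins of
blood plasma; how strongly and where a pesticide, drug or other small
molecule binds to them governs its distribution, free concentration and
toxicity. The standard desk workflow for characterising such an
interaction — fluorescence-quenching titrations, UV/Vis, synchronous and
three-dimensional fluorescence, circular dichroism, and site-marker
competition — produces a handful of spectra per condition and a chain of
small linear analyses that are usually redone by hand for every study.
`albind` implements that chain as tested, reusable model objects, for
spectroscopists and computational toxicologists who want the numbers (and
their diagnostics) reproducibly from raw CSV spectra. It ships with a
seeded synthetic-data generator so the entire pipeline is testable without
instrument data; the built-in reference conditions emulate titrations of
the conazole fungicides epoxiconazole (EPX) and prothioconazole (PTC)
against HSA and BSA.

## The analysis chain

Fluorescence quenching of the protein's Trp/Tyr emission by a titrated
ligand Q follows the Stern–Volmer relation

    F₀/F = 1 + K_SV [Q] = 1 + K_q τ₀ [Q]

whose temperature trend identifies the mechanism (K_SV falling with T ⇒
static quenching, i.e. ground-state complex formation). For static
quenching, the double-logarithm Hill plot

    log₁₀[(F₀ − F)/F] = log₁₀ K_A + n log₁₀[Q]

yields the association constant K_A (L/mol) and binding-site number n, and
the van't Hoff relation over temperatures

    ln K_A = −ΔH/(R T) + ΔS/R,   ΔG = ΔH − TΔS = −RT ln K_A

gives the binding enthalpy, entropy and Gibbs energy; the (ΔH, ΔS) sign
pattern classifies the dominant interaction force (both negative ⇒
hydrogen bonds + van der Waals). Site-marker competition (ketoprofen for
Sudlow site I, ibuprofen for site II) maps the binding pocket through the
probe-displacement ratio F₂/F₁, and synchronous scans (Δλ = 15/60 nm),
excitation–emission matrices, UV/Vis band shifts and circular dichroism
(mean residue ellipticity → α-helix %) characterise the structural
response. See `docs/methods.md` for the full model description, defaults
and limitations.

## Worked example

Generate a synthetic PTC/BSA study (every input file, with ground truth in
the metadata sidecars) and analyse it:

```python
from albind.simulate import generate_study
from albind.study import run_study

cfg = generate_study("demo", "PTC/BSA", seed=42)
res = run_study(cfg)
print(res.summary())
```

prints

```
Complex     T (K)   K_A (L/mol)      n  dG (kJ/mol)  dH (kJ/mol)  dS (J/mol.K)
PTC/BSA       298      6.45e+05   1.06       -32.93       -85.47       -176.30
              303      2.89e+05   0.99       -32.05
              310      1.66e+05   0.95       -30.82
Quenching mechanism: static
Dominant forces: hbond_vdw (dH < 0 and dS < 0)
Binding site: surface_or_other (displaced by: none)
Free-protein alpha-helix: 57.20%
Complex alpha-helix: 53.70%
```

Reading the output: the Hill fits recover the per-temperature association
constants and site numbers the generator imposed (K_A falling from
6.45 × 10⁵ to 1.66 × 10⁵ L/mol between 298 and 310 K, n ≈ 1); that
decrease also classifies the quenching as static. The van't Hoff line
through those three constants gives ΔH = −85.47 kJ/mol and
ΔS = −176.30 J/(mol·K) — both negative, hence a hydrogen-bond/van der
Waals dominated, spontaneous (ΔG < 0) interaction. Neither Sudlow-site
marker displaces the ligand, so the site call is "surface or other", and
the CD stage reports the imposed helix loss on binding (57.20% → 53.70%).

The same pipeline runs from the shell:

```sh
albind simulate --out demo --complex PTC/BSA --seed 42
albind analyze demo/study.yaml --out report.json
albind report report.json
```

`report.json` is the canonical machine-readable result (all fits,
diagnostics, curves and warnings); the text table is derived from it.

Lower-level model objects are available individually
(`SternVolmerModel`, `HillModel`, `VantHoffModel`, `BindingStudy` — each
with a `fit()` returning a results object), as are the pure functions
(`gibbs_from_K`, `classify_forces`, `alpha_helix_percent`, ...).

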