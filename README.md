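# actinmech

Quantitative analysis of actin filament mechanics, inter-subunit
geometry, fibre-diffraction profiles and in vitro motility — the
measurement pipeline used to characterise disease-linked actin variants
such as the myopathy mutation H40Y in skeletal-muscle α-actin (*ACTA1*),
which sits in the DNase-I-binding loop (D-loop, residues 38–52) and
alters how subunits pack along the filament.

The package is aimed at people who have, or simulate, any of:

* **coordinate ensembles** of filaments (MD snapshots, polymer-model
  conformations) and want persistence length, helical rise/twist and
  crossover length with honest uncertainties;
* **1D X-ray diffraction profiles** of muscle reflections (e.g. the
  troponin meridional order TN3, d = 12.9 nm) and want sub-pixel peak
  positions, spacing changes, widths, asymmetry and intensity fold
  changes;
* **filament sliding speeds** from motility assays and want to know
  whether the speed distribution is mono- or biphasic and how two
  conditions compare.

Every stage has a seeded synthetic-data generator, so the entire
pipeline is testable without any experimental recordings.

## Models and statistics

**Persistence length.** A filament trace with nodes spaced `b` (Å) is
treated as a discrete worm-like chain: unit tangents decorrelate as
`⟨t_i · t_{i+k}⟩ = exp(−k b / L_p)`. `PersistenceLengthModel.fit()`
fits `ln⟨cos θ_k⟩` vs `k` over the initial decay and reports
`L_p = −b / slope` in μm, with an uncertainty from per-frame estimates
blocked at the Flyvbjerg–Petersen block-averaging plateau.

**Helical symmetry.** Per frame, the filament axis is recovered from
second differences of the subunit centres of geometry (exactly normal
to the axis for an ideal helix), giving the rise `h` (Å/subunit) and
signed twist `φ` (deg/subunit, negative = left-handed genetic helix).
The crossover length of the two long-pitch strands is
`L_c = 180·h / (180 − |φ|)`.

**Contacts and coarse-grained geometry.** Residue-pair distances
between subunits `i` and `i+2` (longitudinal, along-strand) or `i+1`
(lateral), contact counts under a cutoff, and the coarse-grained
subunit description R1–R4 (centres of geometry of the rigid sub-groups
SG1: 5–33, 80–147, 334–349; SG2: 34–39, 52–59; SG3: 148–179, 273–333;
SG4: 180–219, 252–262) with bonds, angles and the R2–R1–R3–R4 torsion.

**Sub-pixel peak analysis.** After linear-flank background subtraction,
`A·exp(−(x−μ)²/2σ²) + c` is fitted over ±3 or ±4 pixels around the
observed peak; with `d ∝ 1/R` (small-angle), spacing changes between
conditions are `(R_rest/R_act − 1)·100 %`. Fitting at both windows is a
diagnostic for composite (two-population) reflections.

**Speed mixtures and the decision procedure.** Speeds are fitted with
1- and 2-component Gaussian mixtures (closed form / EM, best of seeded
restarts), compared by `BIC = −2 logL + (3k−1) ln n`; samples are split
at 3.50 μm/s. Two groups are compared with Student's unpaired t-test,
unless a Kolmogorov–Smirnov normality test rejects (p < 0.05) for
either group, in which case the Mann–Whitney rank-sum test is used.

## Worked example

```sh
actinmech run --config examples/demo.yaml --out demo_out
```

runs every stage on synthetic data (a 150-frame worm-like-chain
ensemble generated at L_p = 12.21 μm, a 13-subunit helix at
27.5 Å / −166.15° with 0.5 Å thermal noise, four TN3-style profiles and
two speed samples) and prints:

```
actinmech pipeline summary
==============================
persistence length: 12.05 +/- 5.30 um (k* = 230, 150 frames)
helix: rise 27.494 +/- 0.067 A, twist -166.146 +/- 0.099 deg, crossover 357.24 +/- 2.75 A
geometry: 9 contact rows, 6 CG rows, D-loop contact count 35.38 (cutoff 8.0 A)
xray shift wt_w3: +0.196 %
xray shift wt_w4: +0.189 %
xray shift mut_w3: +0.122 %
xray shift mut_w4: +0.136 %
xray fold change wt_activation: 1.384
motility wt: mean 2.63 +/- 0.04 um/s (n=150), below/above 3.5 um/s: 0.96/0.04, BIC-selected k=1
motility mut: mean 3.44 +/- 0.09 um/s (n=150), below/above 3.5 um/s: 0.56/0.44, BIC-selected k=2
stats wt_vs_mut: mann-whitney p = 6.89e-09
```

Reading it: the persistence-length estimator recovers the generator's
12.21 μm within its uncertainty; the helix stage recovers the set
rise/twist and a crossover of ≈357 Å; the "wt" reflection, generated
with a 0.18 % spacing increase on activation, is measured at ≈0.19 % by
both fit windows, while the two-population "mut" composite (a narrow
shifting component over a broad static one) yields smaller,
window-dependent shifts; the unimodal speed sample is called
monophasic (k=1) and the 58/42 mixture biphasic (k=2), with the
normality gate routing the group comparison to Mann–Whitney.
`demo_out/` additionally contains the contact-distance and
coarse-grained geometry tables as CSV, all simulated inputs, and
`report.json` with config hash, derived seeds and library versions.

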