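# Methods

## Scope and model

`mrmquant` covers the computational side of a label-free MRM workflow for
quantifying specific secreted proteins in bacterial culture supernatants:
transition design from protein sequence, chromatogram simulation (standing
in for the instrument), peak integration, calibration, and strain
comparison. The wet-lab steps it brackets (culturing, TCA precipitation,
SDS-PAGE, in-gel digestion, the LC gradient itself) appear only as
bookkeeping: chain annotations, total-protein concentrations, retention
times carried as metadata.

### Mass arithmetic

All masses are monoisotopic and come from one `ResidueMassTable`
(residue masses from pyteomics' standard table; H₂O = 18.010565 Da,
proton = 1.007276 Da). For a peptide of length n:

* neutral mass `M = Σ residues + H₂O`
* precursor `m/z = (M + z·m_H⁺)/z`, z fixed at 2 for the assay
* `b_i` (1+) = sum of the i N-terminal residues + proton
* `y_i` (1+) = sum of the i C-terminal residues + H₂O + proton

giving the identity `b_i + y_{n−i} = M + 2·m_H⁺`, which the tests enforce
at 1e-9 Da for random peptides. Isoleucine and leucine are mass-identical
but kept distinct as strings, so proteotypicity checks (exact string
matching against a background digest) do not collapse I/L variants; that
collapsing could be added but is deliberately not the default.

### Digestion and candidate filtering

Trypsin cleaves C-terminal of K/R; the default rule suppresses cleavage
before proline (Keil), matching mainstream transition-design software, with
a "strict" switch because sources differ on the proline exception. Missed
cleavages default to 0. Candidate peptides are kept when 8–25 residues long
(shorter peptides are rarely selective, longer ones extract poorly from
gels), free of Cys/Met (oxidation/alkylation risk during processing), and —
when a background proteome is supplied — found in exactly one background
protein.

### Product ions and instrument parameters

The automatic pick ("y-prefer") takes the n = 3 highest-m/z y ions with
index ≥ 3, skipping anything within ±3 Th of the precursor (no selectivity
there). Experimentally refined assays rarely match any simple rule, so an
"explicit" policy accepts a user-supplied ion list; the bundled published
assay (6 peptides × 3 y ions) is reproduced that way. One transition per
peptide is flagged quantifier; the rest are confirmatory.

CE and DP are modelled as linear functions of precursor m/z for 2+
precursors and fitted by ordinary least squares to the published six-pair
table; the fit recovers the familiar vendor defaults
(CE ≈ 0.036·mz + 8.82, DP ≈ 0.0729·mz + 31.13) with residuals ≤ 0.15 V,
which is strong evidence that the published values were generated from m/z
alone. The fitted coefficients ship as the package default and are
refittable from any (m/z, CE/DP) pairs.

## Synthetic data generator

Each trace is a uniform time grid (default 0.005 min step over a 15 min
run, the order of a 20 ms MRM duty cycle) with

```
intensity(t) = A·exp(−(t−rt)²/2σ²) + baseline + N(0, noise_sd),  clipped at 0
A·σ·√(2π) = response_factor · concentration
```

`rt` is drawn once per trace from N(nominal RT, rt_jitter_sd). Defaults:
σ = 0.05 min, baseline 20 counts, noise 4 counts, RT jitter 0.01 min,
response 1e5 area units per µg mL⁻¹. Optional ingredients: a hard area
plateau above `saturation_level` (emulating the upper-linearity loss seen
for the GseBp transition at 1.65 µg mL⁻¹), a contaminant Gaussian at a
configurable RT offset, and two response-level noise terms:

* `response_cv` — per-trace multiplicative area variability (default 5 %;
  injection/ionisation variability). Additive point noise alone perturbs a
  trapezoidal area by far less than 1 %, so without a response-level term
  simulated replicate areas would be unrealistically tight.
* `area_noise_sd` — additive area noise floor (default 0), used to emulate
  a chemical-background-limited low end when exercising the LLOQ rules.

The calibration default levels are the published serial dilution
0.0033–3.3 µg mL⁻¹ (decade steps plus midpoints, 7 levels × 3 replicates).

The bundled strain panel has 10 samples: wild-type *B. pumilus* 3-19
(both proteases), the protease-free negative control *B. subtilis* AT1
(both controls grown without inducer), and four recombinant *B. subtilis*
strains (MRB044/046 for AprBp, MRB047/049 for GseBp) with and without
bacitracin induction. Ground truth is anchored on the *reported
supernatant concentrations*, with the true vial concentration back-derived
as `sn·C/total`; anchoring on the reported vial values instead would break
the published fold-changes for the one internally inconsistent row (MRB046
uninduced), because the published ratios are ratios of supernatant values.

Because the real precursor sequences were not republished, the bundled
FASTA contains *synthetic stand-ins*: precursors with the annotated chain
layout (AprBp 381 aa, signal 1–29, propeptide 30–107, mature 108–381;
GseBp 303 aa, signal 1–26, propeptide 27–88, mature 89–303) whose mature
chains release the six published peptides on digestion, padded with filler
tryptic peptides — including deliberately filter-failing ones (Cys/Met,
too short/long, shared between proteins) so the design filters are
exercised. The published GseBp annotation has propeptide and mature chain
sharing residue 89; the records accept a one-residue shared boundary and
the fixture uses the non-overlapping variant 27–88/89–303.

What passing on this generator does *not* show: robustness to peak tailing
and asymmetry, ion suppression/matrix effects, RT drift between runs,
isotope interference, or in-gel digestion losses. The generator emulates
the well-behaved, symmetric-peak case that assay development selects for.

## Peak integration and detection

Traces are smoothed with a Savitzky–Golay filter (window 7, order 2);
baseline is the median intensity outside the RT window; noise is
1.4826·MAD of the off-window residuals. The apex is the smoothed maximum
inside the window (flagged when on the window edge), boundaries are found
walking outward until the smoothed trace returns to
`baseline + max(0.5·noise, 1e-6·height)` — the second term makes a
noiseless Gaussian terminate at ~5σ, keeping the integral within 0.5 % of
the closed form — and the area is the trapezoidal integral of the *raw*
signal above baseline between the boundaries, floored at 0.

A peptide is *detected* in a sample when every transition reaches
S/N ≥ 3 and all apexes agree within 0.1 min. The S/N threshold is a
package convention (the underlying study does not state one); both values
are config parameters. Quantification uses only the quantifier
transition's area; confirmatory transitions contribute to detection only.

## Calibration and quantification

* **Fit**: ordinary least squares, optionally 1/x-weighted. The pipeline
  default is 1/x: over a 3-decade serial dilution an unweighted fit lets
  the top standards set an intercept error of the order of the lowest
  standards' entire signal, biasing low-end back-calculation by tens of
  percent. (Unweighted remains available and is the right choice for
  narrow ranges.)
* **Linear range**: drop the highest level while r² < 0.99 (error if fewer
  than 3 levels would remain; a flat, fully saturated series is trimmed
  until that error fires).
* **LLOQ**: lowest level whose back-calculated mean is within ±20 % of
  nominal with replicate CV ≤ 20 % — standard bioanalytical acceptance
  values; the curve is flagged if no level qualifies.
* **Back-calculation**: `conc = (area − intercept)/slope`, floored at 0
  with a `below_lloq` flag; `above_linear_range` flags extrapolation but
  does not suppress the value.
* **Vial → supernatant**: `sn = vial · total_sn / C`. The constant C — the
  total-protein concentration of the measurement vial — is not stated in
  the source study; it is derived as the median of the per-row implied
  constants `vial·total/sn` over the published panel, giving C = 50/3 ≈
  16.67 µg mL⁻¹, consistent with 8 of the 10 nonzero rows to ±0.01 µg mL⁻¹
  (a plain least-squares fit is dominated by the three largest rows and
  fits fewer). Two published rows (MRB046 uninduced, *B. pumilus* GseBp)
  do not satisfy any single constant; they are carried as published, not
  corrected. C is a config field and always overridable.
* **Fold-changes**: induced/uninduced per strain, and per-target ratios
  against a reference strain (defaults MRB046 for AprBp, MRB047 for
  GseBp, which reproduces the published 50× and 12× comparisons). Ratios
  with a zero denominator render as "not computable".

## Problem sizes and seeds

The test suite and demo run the full pipeline at the study's own scale:
10 samples × 9–18 transitions (~150 traces of 3001 points) plus
7 × 3 calibration traces per target — a few seconds end to end. All
randomness flows through numpy `SeedSequence` spawning, so every artifact
is bit-reproducible for a given seed; CSV artifacts carry a provenance
header (config hash, seed, stage).

## Known limitations

* Single-Gaussian peaks only; no deconvolution of overlapping peaks and no
  cross-sample RT alignment.
* Proteotypicity is exact string matching against a supplied background
  digest, not a spectral-library or genome-wide search.
* No modified peptides, no semi-tryptic products, no isotope patterns, no
  mzML/vendor raw I/O (traces move as CSV).
* Uncertainty is tracked only as replicate CV; no error propagation onto
  reported concentrations or fold-changes.
* The ≤1-residue chain-overlap tolerance and the vial-total constant both
  encode annotation/reporting ambiguities of the source data; both are
  overridable rather than resolved.
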