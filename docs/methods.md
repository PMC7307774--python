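# Methods

This note documents the models, conventions and design choices behind
`ftirco`: what each stage computes, which knobs matter, what the synthetic
data do and do not emulate, and where the implementation had to make a call
that the underlying methodology leaves open.

## Data model and conventions

Spectra are absorbance vectors on a shared wavenumber axis (cm⁻¹). The axis
is stored strictly ascending; instrument exports in descending order are
flipped on load. The default transmission (HTS) grid spans 500–4000 cm⁻¹
with a 1.928 cm⁻¹ digital spacing (1816 points). The default ATR grid spans
600–4000 cm⁻¹ at the same spacing — the nominal ATR spectral resolution is
coarser (4 cm⁻¹), but the digitization of a shared spectrometer is retained
so that single-wavenumber reads land within 1 cm⁻¹ of the nominal marker
bands.

Single-wavenumber absorbance reads (the 937, 1034, 1637 and 1799 cm⁻¹
markers) use the **nearest grid point**, with ties broken toward the higher
wavenumber. Interpolation was deliberately avoided: nearest-point reads are
reproducible, order-independent, and on a ≤2 cm⁻¹ grid the difference is far
below the band widths involved (≥20 cm⁻¹ FWHM).

Region definitions (lipid, polyphosphate, chitin/chitosan) are closed
intervals; a point on the boundary belongs to the region. Technical /
biological replicate averaging is a plain arithmetic mean per group, with
groups ordered by first appearance so outputs are deterministic.

## Synthetic data generator

The generator exists so that every downstream stage can be validated against
known truth. It emulates:

* **Design structure** — the full 9 × 2 × 6 × 3 factorial with 3 technical
  replicates and the two no-growth exclusions (both *Mortierella* strains at
  Pi8), giving the bookkeeping 324 / 312 / 936. Media exist for all 324
  biological samples (spent medium is measurable even without growth), in 3
  technical replicates → 972 ATR spectra.
* **Biomass spectra** — linear mixing of five pure-component band systems
  (lipid, chitin/chitosan, polyphosphate, protein, carbohydrate), each a sum
  of Gaussian bands at the standard mid-IR assignment positions. Narrow
  bands default to 20 cm⁻¹ FWHM, broad (polyphosphate, water, amide-region)
  bands to 40–120 cm⁻¹; this narrow-vs-broad contrast is what makes the two
  derivative window sizes meaningful. Each measured spectrum is
  `b·Σ c_k s_k(ν) + a0 + a1·x + a2·x²+ ε(ν)`: a log-normal multiplicative
  path length `b` (log-sd 0.15, reflecting the large sample-thickness
  variance of dried-droplet HTS measurements), a quadratic baseline in the
  scaled axis `x ∈ [−1,1]` (coefficients uniform in ±0.05/±0.02/±0.02), and
  i.i.d. Gaussian noise (sd 0.003). These distortions are exactly the family
  that quadratic-extended EMSC removes — by construction, so that parameter
  recovery is a meaningful test of the correction.
* **Concentration effects** — per-strain baseline levels plus additive
  N-source effects and log2(Pi)-linear slopes, with an extra slope on
  ammonium sulphate (where inorganic phosphate is the only phosphorus
  source). Defaults encode the screening's qualitative biology:
  polyphosphate storage rises with Pi (strongest on AS), chitin/chitosan
  rises under phosphorus starvation on AS, lipids drop at low Pi on AS.
  Biological-replicate scatter is Gaussian (sd 0.02) on the concentration
  scale; concentrations are clamped at zero. No attempt is made to calibrate
  absolute g/L values — the synthetic effect sizes are stand-ins chosen to
  be comfortably above the noise floor yet far from saturation.
* **Media spectra** — water + glucose + phosphate (+ an organic-acid
  carbonyl band for grown AS cultures, scaled up under Pi limitation) + a
  random offset + noise. The glucose signal is proportional to the fraction
  of the (uniform) starting glucose remaining; the phosphate signal to the
  fraction remaining times the Pi-level multiple of the starting recipe.
  Pure water and a pure phosphate solution are appended as reference rows.

It does **not** emulate: instrument line-shape/apodization physics, Mie or
resonant-Mie scattering, atmospheric CO₂/water-vapour lines, detector
nonlinearity, band-position shifts with composition, or correlated
(pink/drift) noise. Passing tests therefore demonstrate the pipeline's
algebraic and statistical correctness under the stated noise model, not
robustness to every artefact of real measurements.

Determinism: one global seed; the per-sample streams are derived from
`(seed, stream_id, counter)` tuples where the counter is the biological or
technical sample index, so identical seeds give bit-identical outputs and
subsets of a design reproduce the same spectra they would have inside the
full design.

## Preprocessing

**Savitzky–Golay second derivative.** Degree-2 local polynomial, window 11
or 61 points, second derivative with respect to wavenumber (the index-space
derivative divided by the spacing squared, so units are absorbance·cm²).
The axis must be uniform to a relative tolerance of 1e-3. Boundary channels
are produced by one-sided polynomial fits over the first/last window
(scipy's `mode="interp"`), keeping output and input lengths equal; since
region extraction happens afterwards and all analysis regions sit well
inside the axis, boundary behaviour never touches the analyses. A degree-2
fit reproduces the second derivative of any quadratic exactly — one of the
acceptance contracts.

**EMSC.** Ordinary least squares of each spectrum onto
{reference, 1, x, x²}, correction `(s − a − d·x − e·x²)/b`. The reference
defaults to the mean spectrum of the set being corrected (a designated
external reference is accepted); the axis is mapped to [−1,1] before
building polynomial terms, for conditioning. Degenerate cases are refused
explicitly: a reference that lies (numerically) in the polynomial span makes
`b` unidentifiable (conditioning error), and a fitted |b| ≤ 1e-12 names the
offending sample. EMSC correction is idempotent and exactly inverts any
multiplicative + quadratic-baseline distortion of the reference — both are
tested at 1e-8.

**Branch order.** Branch 1 applies derivative → EMSC → technical averaging,
in that sequence; averaging after correction is the stated processing order
of the original workflow and is kept even though averaging first would be
cheaper. Branch 2 averages technical then biological replicates before a
single EMSC pass. Applying branch 1 to already-differentiated data is legal
(second derivatives of derivatives are occasionally useful) but is flagged
in the provenance record rather than silently accepted. Whether the original
workflow used the set mean or a dedicated reference spectrum for EMSC is not
documented; the set mean is the default here and the choice is recorded in
every provenance log.

Every `SpectraSet` carries a provenance list (stage name + parameters) that
the pipeline serializes next to its outputs.

## PCA

Column-mean-centered SVD without variance scaling (standard for spectra,
where the channel scale is physically meaningful). Explained-variance
fractions are σ²ᵢ over the sum of **all** squared singular values up to the
matrix rank, so reported fractions are comparable across different numbers
of retained components. Sign indeterminacy is resolved by flipping each
loading so its largest-magnitude element is positive; scores flip
accordingly. Region PCAs run per nitrogen-source split on the concatenated
channels of the region's intervals, with the derivative window bound to the
region (11 for lipid and chitin/chitosan, 61 for polyphosphate, following
the narrow-vs-broad band rationale; the binding lives in configuration, not
code).

## ANOVA variance decomposition

For one strain at a time, with technical replicates already averaged and
biological replicates retained: the data matrix is written as grand mean +
N-source effect + Pi effect + interaction effect + residual, where each
effect row is the corresponding level mean minus the grand mean (the
interaction additionally subtracts both main effects). The decomposition
reconstructs X exactly for any input, balanced or not. Factor contributions
are sums of squared entries of the effect matrices normalized over the three
factors of interest (so they total 100%); the residual sum of squares —
biological scatter and anything not of design interest — is reported
separately and never normalized in.

Missing cells (the *Mortierella* Pi8 no-growth combinations) follow a
cell-means-with-available-data convention: all means are taken over observed
rows only, and a factor observed at a single level contributes a zero effect
matrix plus a warning rather than an error. With missing cells the per-factor
sums of squares are no longer orthogonal; the shares remain well-defined
because the normalization is over the three factor SS themselves, and
exactness of the reconstruction is unaffected.

Percentages are reported at full precision in machine-readable output and
rounded to 0.1 in printed summaries.

## Media estimation

The three-step ATR preprocessing (baseline at 1799 cm⁻¹, water-peak
normalization at 1637 cm⁻¹, subtraction of the identically-treated water
reference) makes the estimates exactly invariant to additive offsets and
positive multiplicative scalings of the raw spectrum. P_FTIR is the
preprocessed absorbance at 937 cm⁻¹. G_FTIR subtracts the phosphate
contribution at 1034 cm⁻¹ estimated from a pure phosphate-solution
reference; for any scaled copy of that reference the formula cancels to
exactly zero, which is tested as an identity. Negative estimates (possible
under noise near zero concentration) are reported as-is with a warning, not
clamped, so downstream averaging remains unbiased. Estimates stay in
corrected-absorbance units; converting to g/L requires an external
calibration, for which the report functions accept externally supplied
two-point calibrations but ship none.

Sample exclusions (the four technical-error media samples of one biological
replicate in the original screening) are handled by id list: excluded
samples appear in the per-sample table with a reason and are omitted from
the condition-level summary means.

## Problem sizes and runtime

All study-shaped computations run on the full design (936 biomass spectra ×
1816 channels, 972 media spectra), which takes seconds; the
replicated attribution study (30 simulation seeds) runs a single-strain
design (108 spectra) per seed through the complete branch-1 + decomposition
path. The whole test suite completes in well under a minute on one CPU.

## Known limitations

* The synthetic effect sizes and noise levels are plausible but not
  calibrated to any measured chemistry; conclusions about detection limits
  on real data cannot be drawn from them.
* The variance decomposition quantifies design-factor shares only; it does
  not test significance (no permutation testing or score-space ellipses, as
  in full ASCA/ANOVA-PCA workflows).
* The reproduction of the published explained variances requires the
  original deposited raw spectra, which cannot be redistributed here; the
  corresponding acceptance test reports failure until a local export is
  provided (`data/deposited_biomass_hts.csv` + `.meta.tsv`).
* JCAMP-DX support is a minimal XY-pair subset, not a general reader;
  Bruker OPUS binaries are out of scope.
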