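# Methods

This note documents the models behind `iptlpipe`: what the synthetic-data
generator emulates, how the quantification pipeline is specified, the
tunable parameters and their defaults, and the numerical choices made
where the design was genuinely open.

## Study design emulated by the generator

The generator reproduces the design of a nutrient-limitation proteomics
experiment on a PR-bearing marine *Vibrio*: two defined media differing
only in substrate ratio (C-limited: 2.78 mM maltose + 2 mM NH₄Cl, molar
C/N 16.68:1; N-limited: 8.33 mM maltose + 1 mM NH₄Cl, 99.96:1), each under
continuous light and continuous dark, in biological triplicate. Proteomic
samples are taken at nine timepoints (7.5–15 h every 1.5 h, then 27.5,
51.5, 75.5 h), designated 3/4/2 to exponential/transition/stationary
phase; growth measurements continue on a ~24 h cadence to 171.5 h. Each
proteomic sample yields a membrane fraction (chymotrypsin + trypsin
digest) and a cytosolic fraction (trypsin only), labeled with *inverse*
channel orientation relative to a pooled internal standard: membrane
samples carry the d4-dimethyl N terminus and light C-terminal oxygens,
cytosolic samples the converse.

### Ground-truth components

- **Growth** is logistic, `OD(t) = OD_max / (1 + ((OD_max−OD₀)/OD₀)
  e^(−μt))` with OD₀ = 0.005 (1.25 mL of an OD 0.4 preculture into
  100 mL). C-limited: μ_max = 0.14 h⁻¹, OD_max = 0.72, with exponential OD
  decline (rate 0.015 h⁻¹) after a 70 h onset while CFU decline only
  slowly (0.005 h⁻¹) — the "dwarfing with maintained cultivability"
  phenotype. N-limited: μ_max = 0.15 h⁻¹, OD_max = 0.83, OD maintained but
  CFU collapsing steeply from the entry into stationary phase and zero
  from 99 h on. Viability declines sigmoidally to condition- and
  light-specific terminal values (C: 0.82–0.88; N: 0.05 light / 0.20
  dark).
- **Protein expression truths** are per-(protein, condition, light,
  timepoint) log2 ratios against the pooled standard. Most proteins sit at
  0, so every sample's true median is 0 and median-zero normalization is
  truth-preserving; a few are light-responsive, a few respond to the
  limiting nutrient (both signs, ramping into stationary phase, default
  effect 2.0 log2 units), and the PR-like protein follows a trajectory
  that plateaus at the transition, higher under C limitation.
- **PR absolute abundance.** The C-limited copies/cell trajectory rises
  through exponential phase and plateaus at a maximum of 5,606
  copies/cell; the N-limited trajectory has the same shape, scaled so that
  the true ratio of stationary-phase (last two timepoints) mean PR
  amounts is exactly 4.4. Amounts follow from copies/cell × cells in the
  4.5 mL harvest, with cell density = 10⁹ cells mL⁻¹ per OD unit.
- **Transcripts.** Per-gene relative-quantity shapes over the nine
  timepoints: PR and rpoS peak during the transition to stationary phase
  (PR 2.3-fold higher in the dark under C limitation from the transition
  on), blh has a transition peak and a larger one late in stationary
  phase, recA is constant (the reference). Ct = −log_E(quantity) with
  primer efficiency E = 2.

### Spectra

Each selected peptide (≤ 3 per protein, unique in the proteome, 5–25
residues) yields `2 + Poisson(1)` spectra containing all singly charged
b/y fragments of *both* channels; sample-channel intensities are the base
intensity × 2^(true log2) and every fragment carries multiplicative
lognormal noise (sd 0.1 in log2 units). A configurable fraction (default
10%) of pure-noise spectra (20–50 uniform peaks) is appended as decoy
fodder. Retention time, isotope envelopes and charge states > 2 are not
modeled — fragment-pair ratio extraction, which is what the pipeline
quantifies, does not depend on them.

Label masses are built from monoisotopic atomic masses: light dimethyl
+2×CH₂ = 28.031300 Da, d4 dimethyl +4(D−H) above that = 32.056407 Da,
double ¹⁸O exchange +2(¹⁸O−¹⁶O) = 4.008490 Da. Lysine side-chain
dimethylation is not modeled (labeling is N-terminal), and ¹⁸O exchange is
treated as complete double exchange.

## Pipeline specification

- **Matching.** Score = number of theoretical fragment m/z (either
  channel) with an observed peak within the tolerance (default 0.01 Da —
  narrower than the channel gaps by two orders of magnitude, wide enough
  for centroid jitter). Candidates are all unique digestion products plus
  full-sequence-reversal decoys; ties break lexicographically by peptide,
  then target before decoy, making matching order-independent.
- **q-values.** At threshold s, FDR̂(s) = (#decoys ≥ s)/(#targets ≥ s)
  (0 if no targets); q(s) is the minimum FDR̂ over thresholds ≤ s, which
  enforces monotonicity. Targets are retained at q < 0.001. Computed per
  fraction, since each fraction is a separate search space.
- **Spectrum ratios.** Median of fragment-pair log2 ratios (robust to a
  single interfered fragment); a summed-intensity mode is available
  (`method="sum"`). The sample channel is resolved per fraction from the
  label orientation.
- **Aggregation.** Peptides with < 2 spectra per (protein, sample) are
  discarded; protein log2 = mean of surviving spectrum ratios, SE =
  sd/√n. Proteins with nothing surviving are absent, not zero.
- **Tables.** Normalization is per LC-MS sample (fraction × condition ×
  light × replicate × timepoint) and precedes fraction assignment.
  Consolidation uses the n−1 sample standard deviation for σ_x. Fraction
  ties go to cytosolic (documented tie-break). Phase designation for
  non-nine-point courses splits proportionally (largest remainder of
  3:4:2, each phase ≥ 1 point).
- **Differential expression.** Contrasts use replicate-level (not
  consolidated) values so residual variance is estimable, pooling
  replicates and timepoints within a phase as exchangeable. The variance
  prior (s₀², d₀) is estimated by the method of moments on log variances
  (trigamma inversion by Newton iteration); the implementation agrees
  with R limma's `lmFit`+`eBayes` to ~10⁻⁸ on a fixed two-group fixture.
  With literally identical variances (zero dispersion) the prior is set
  to the common value with d₀ = ∞, so moderation is a fixed point there.
  Significance is BH-adjusted p < 0.05.
- **PR absolute quantification.** Trapezoidal integration stands in for
  manual peak integration where XICs are provided; the generator emits
  areas directly. Amount = mean two-peptide area ratio × 0.375 pmol
  (0.75 μL × 0.5 pmol/μL). The OD → cells/mL calibration is ordinary
  least squares on paired observations log-spaced across OD 0.01–0.9, so
  early-exponential samples are interpolated — extrapolating below the
  calibrated range lets intercept error produce near-zero predicted cell
  counts and unstable copies/cell (the pipeline raises if predicted cells
  ≤ 0). Injection-fraction bookkeeping cancels in the native/standard
  ratio and is not carried explicitly.
- **Physiology.** μ_max uses a 3-point sliding window (configurable);
  windows with nonpositive OD are skipped. Peak detection requires a
  local maximum of replicate means and a two-sided Welch test against the
  t = 9 h reference at p < 0.05.

## Noise defaults and why

| parameter | default | rationale |
|---|---|---|
| fragment intensity sd | 0.1 (log2) | ~7% CV, typical for well-measured CID fragment intensities |
| MS1 area ratio sd | 0.15 (ln) | ~15% CV of manual MS1 integration across runs |
| OD sd | 0.01 (multiplicative) | spectrophotometer replicate error ~1% |
| CFU sd | 0.10 (ln) | spot-plating counting error |
| Ct sd | 0.15 cycles | typical qPCR technical variation |
| calibration cell-count sd | 0.03 (ln) | averaged flow-cytometry/CFU counts |

Intensity scale and spectra-per-peptide counts are free parameters of the
generator (no instrument is being reproduced); they are surfaced in the
`Scenario` dataclass.

## What passing tests do and do not show

The generator's spectra are idealized: complete fragment series, no
chromatographic effects, no co-isolation interference, no missing
channels, uniform noise. Round-trip exactness at zero noise therefore
validates the *bookkeeping* (label arithmetic, orientation handling,
normalization, consolidation, unit conversions), and the noisy-recovery
tests validate statistical behavior (FDR control on null spectra, type-I
control and power of the moderated tests, unbiasedness of the ratio
estimators) — they do not demonstrate performance on real LC-MS data,
where matching difficulty and interference dominate. The minimal
fragment-counting matcher is sufficient for the toy proteome; it is not a
replacement for a full database-search engine on genome-scale searches.

## Problem sizes

The default (`caim519`) scenario carries the full 2 × 2 × 3 × 9 sample
design for growth, PR-area and qPCR simulation; scenario recovery runs it
over ten seeds. Spectrum-level tests run on the `tiny` scenario (8
proteins, 2 replicates, 3 timepoints, both fractions), which exercises
every code path of the MS pipeline at a few thousand spectra.
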