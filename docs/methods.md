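# Methods

## Scope and model

fetoquant implements a desk-scale version of a spiked-standard absolute
quantification workflow for plasma proteomics, plus the statistical battery
used to assess candidate markers of diabetic fetopathy. The pipeline is
pure computation on validated tables: peptide-level intensities in,
calibrated concentrations, group statistics and ROC panels out. Everything
upstream of identified peptide intensities (spectra, database search, FDR
control) is out of scope by design; the documented TSV is the boundary.

### Intensity response and calibration

The response model is a power law: a protein at final concentration
C (fmol/µL) yields normalized total intensity
`I = 10^b · C^a · ε` with `ε` lognormal, `E[ε] = 1`. The calibration stage
fits `log10 I = a·log10 C + b` by OLS. Defaults follow the published
protocol: a 6 × 8 ladder from 50,000 down to 0.5 fmol (×10 steps, total
mass rescaled to 10.6 µg), working dilution at amount/10 fmol/µL, 1:10
spike (final 0.005–500 fmol/µL), six replicates, 2 µL injection.

Gate interpretation choices (the protocol text is terse):

- "standard deviation of intensities not exceeding 20 %" is read as
  **relative** SD (CV). An absolute SD gate across five decades of
  intensity would be meaningless.
- the regression is performed in log10–log10 space. A linear fit in raw
  space over five orders of magnitude is dominated by the top tier, and
  the published before/after-selection correlation values are only
  coherent for a log-space fit.
- the prohibited margin is the half-open on-column band [0.5, 42) fmol
  with on-column = concentration × injection volume (2 µL default, the
  injection volume the protocol implies); the upper boundary is retained
  so the quoted measured range starting at 42 fmol stays usable.
- point selection is exactly: ≥ 2 detected replicates, CV gates, margin
  gate. No manual exclusion step exists.

Inversion is exact (`C = 10^((log10 I − b)/a)`); predictions outside the
span of selected nominal concentrations are flagged `extrapolated`, and
those whose implied on-column amount falls inside the margin are flagged
`unreliable_margin`. Flags are advisory: flagged concentrations are still
computed, because the immunoglobulin markers legitimately sit above the
ladder's top point and the control-group CNDP1 sits near the margin, and
dropping them would bias group means.

### Quantification and normalization

"Normalized" is defined as the per-sample total-intensity fraction over
proteotypic (single-protein) peptides. This is the minimal normalization
that makes standards and unknowns commensurable, and the same function is
applied to both. NSAF is implemented separately and used only for ranking;
the two abundance measures are never mixed. Missing means absent: no
imputation; an undetected marker contributes to detection frequency, not to
concentration statistics. Mass-unit conversion uses
`ng/mL = fmol/µL × MW(Da) × 10⁻³`. Molecular masses use the circulating
species: UniProt monomer average masses for CRP/CEACAM1/CNDP1, assembled
antibody masses for immunoglobulins (IgG ≈ 146 kDa, IgA ≈ 160 kDa, IgM
pentamer ≈ 970 kDa), since the printed mg/mL levels refer to whole
antibody; no PTM or glycosylation mass is modelled.

### Statistics

Kruskal–Wallis (midrank ties, χ² approximation, df = groups − 1) for the
five-group comparison; two-sided Mann–Whitney for pairwise contrasts,
exact when the smaller sample has ≤ 8 untied observations; Spearman and
Kendall tau-b for bias checks; plain group-mean ratios for fold changes.
Fisher's exact test is reserved for 2 × 2 count tables — applying it to
continuous concentrations requires an undocumented dichotomization, so
continuous contrasts use the rank tests and a dichotomize-at-median helper
is provided for fidelity experiments. No multiplicity correction is applied
across the handful of reported markers; Bonferroni is applied where it
belongs, in the generic term-overrepresentation test (one-sided
hypergeometric tail per term). Benjamini–Hochberg is available as an
option.

### ROC panel

The integrative score is a ridge-stabilized logistic regression on
z-scored marker concentrations (penalty 10⁻⁶ — only enough to keep
complete separation finite; monotone-equivalent to LDA under binormality).
Marker directions are learned, never hard-coded. AUC is pair-counting via
midranks (ties half), which equals trapezoidal ROC integration; CIs are
stratified percentile bootstrap (2,000 resamples by default, seeded);
the operating point maximizes Youden's J over score midpoints with ties
resolved to the lowest threshold. The positive class defaults to the two
fetopathy groups (G02 ∪ G04) against all others; whether the
uncomplicated-pregnancy group belongs in the negative set is a
configuration switch, included by default. Leave-one-marker-out refits
report each marker's AUC contribution. No cross-validation is performed:
the quantity of interest is the apparent AUC, as in the source analysis.

## The synthetic generator

The generator emulates exactly the statistical structure the analysis
assumes, with published values as defaults:

- **Standards**: 48 proteins, geometric ladder 50,000 … 0.5 fmol, masses
  rescaled so Σ(amount × MW) = 10.6 µg; six replicates with multiplicative
  lognormal noise (default technical CV 10 %, the top-point gate value).
- **Cohort**: groups of 43/37/34/29/36 subjects; marker concentrations are
  zero-truncated normals at the published means ± SD (the publication
  reports no distributional form; truncation only prevents negative
  concentrations and is negligible at the published mean/SD ratios). The
  published SDs are treated as total between-subject dispersion, since no
  technical/biological variance decomposition was reported.
- **Forward model**: each subject-marker concentration is pushed through
  the generating response line to an intensity fraction, perturbed by
  per-subject lognormal noise (default biological CV 10 %), split over
  3 synthetic proteotypic peptides, and padded with a single background
  protein so each sample's total intensity is exact — making noiseless
  quantification the exact inverse of the forward model (tested to 1e-9
  relative). Spectral counts are proportional to intensity.
- **Dropout**: detection is logistic in log on-column amount. The default
  midpoint is 0.002 fmol, i.e. detection is effectively complete across
  the ladder. A midpoint high enough to degrade the prohibited band would
  also erase the lowest calibration tier and with it the published
  0.005–500 fmol/µL validity range, so degraded-detection behaviour is
  exercised in tests at explicit stronger settings rather than by default.
- **Gain**: the response intercept defaults to 10⁻⁶ (log10 b = −6) so
  that the mg/mL-scale immunoglobulins occupy ~12 % of total signal,
  leaving a plasma-realistic background share; a higher gain would
  overflow the per-sample intensity budget.
- **Determinism**: one seed per run; per-stage substreams are derived
  through fixed `SeedSequence` spawn keys, so tables are byte-identical
  under identical configuration.

### What passing tests do and do not show

The generator draws independent, truncated-normal markers with
multiplicative noise and near-complete detection. Real plasma data have
correlated markers, heavy tails, batch effects, shared peptides, incomplete
and abundance-dependent detection, and interference between co-eluting
species. Parameter-recovery results therefore validate the *computational
chain* (normalization, calibration, inversion, unit conversion, group
bookkeeping), not the clinical performance of the markers. In particular
the panel AUC on simulated cohorts saturates near 1.0 because the published
group means are many within-group SDs apart; the published real-data AUC of
0.893 reflects overlap that the printed summary statistics do not encode,
and is treated as a floor the simulation must exceed, never a value to
match.

## Numerical choices and problem sizes

- CVs use sample SD (ddof = 1) over the mean; a zero-mean point with
  nonzero SD is an error, not a silent skip.
- Lognormal noise uses `σ² = ln(1 + cv²)` with mean-one parameterization,
  so recovery is unbiased in expectation.
- JSON outputs have sorted keys, repr-precision floats, a schema_version
  field, and NaN → null with a warning; reruns are byte-identical.
- Default problem sizes keep the full test suite around a minute on one
  core: 2,000 null simulations for the type-I-error check, 500
  replications × 300 resamples for bootstrap coverage, exhaustive
  enumeration oracles only at N ≤ 12, and the end-to-end recovery runs at
  the published cohort sizes (179 subjects).

## Known limitations

- One calibration curve serves all proteins; per-protein response factors
  (real instruments have them) are out of scope, so absolute accuracy on
  real data depends on the spiked standard spanning the analytes'
  ionization behaviour.
- The stated group-specific protein counts are reproduced as set algebra
  on generated detection patterns; the generator does not model the
  underlying biology of presence/absence.
- `frequency = 1.0` is a harsh filter at these group sizes; the package
  exposes the threshold but defaults to the published rule.
- Exact Mann–Whitney p-values are enumerated only for untied small
  samples; ties fall back to the tie-corrected normal approximation.
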