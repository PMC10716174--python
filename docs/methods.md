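# Methods

## Data model

The unit of observation is a channel-resolved precursor: one (modified
peptide sequence, charge) species measured in one SILAC channel (L/M/H)
of one run, with an MS1-style and an MS2-style quantity and three
confidence scores (precursor FDR q-value, channel q-value, translated
q-value). Tables arrive in the column dialect of DIA-NN channel
matrices (`Protein.Group`, `Channel.Q.Value`, …) or a snake_case
"simple" dialect for MaxQuant-style exports; both are normalized to one
canonical pandas frame. Channel labels are mapped to {L, M, H} at read
time through a configurable mapping.

### Filtering

Contaminant protein groups are removed first (a multi-accession group
is removed if *any* member matches an accession list or prefix rule —
a conservative choice), then rows are kept only when all three q-values
are strictly below their thresholds (default 0.01 each; a value exactly
at the threshold is removed, mirroring the "< 0.01" convention).
q-values absent from simple-dialect tables pass with a prominent
warning. Filtering is idempotent, and contaminant and q-value filters
commute; both properties are under test. The precursor-FDR filter is
applied per row as read; whether upstream tools apply it per run or
globally is not observable from the table itself.

## MaxLFQ across SILAC channels

For one protein, let columns be (run, channel) pairs and `I_kj` the
chosen quantity of precursor k in column j. For every column pair
sharing at least `min_shared_peptides` precursors (default 1, to keep
single-channel identifications), the pairwise estimate is the median of
per-precursor log2 ratios; ties with an even count use the mean of the
central values (numpy median). The per-column log2 abundances `x`
minimize Σ (x_b − x_a − r_ab)² via the graph Laplacian normal
equations (pseudo-inverse solve). The solution is defined per connected
component up to a constant, fixed by requiring Σ_j 2^{x_j} to equal the
component's total observed intensity; singleton components are
quantified by their summed intensity. Zero intensities are treated as
absent. On any matrix the result matches an independently coded
brute-force least-squares oracle to 1e-9 relative (500 random matrices
under test).

Two modes exist: **joint** (default) runs one solve over all
(run, channel) columns of a protein, keeping the channels on a common
scale; **per_channel** solves each channel separately across runs,
which is the natural reading of "LFQ applied to the individual
channels". On the benchmark designs the two agree to well within the
reported tolerances; the benchmark drivers and the acceptance script
use per_channel. No cross-run normalization is applied by default.

Precursor counts attached to protein quantifications count distinct
(modified sequence, charge) species, ignoring channel and run.

### Ratios and benchmark metrics

log2 ratios for an ordered channel pair are formed per sample only
where both channels are quantified; no imputation anywhere. CVs are
computed on linear-scale ratios (100·SD/mean), matching the 5–15%
magnitudes conventional in proteomics benchmarks; a log-scale variant
is not provided because nothing downstream consumes it. Accuracy is the
per-protein median-over-samples log2 ratio minus the theoretical mixing
log2 ratio. Missing rates are computed over protein-level ratio cells
of proteins quantified in ≥ 1 sample (precursor-level missingness would
be an alternative reading; the protein-level one is what the ratio
matrices support directly). PCA operates on complete-case proteins,
column-centered, by SVD; fold enrichment is the ratio of medians of
labeled/unlabeled precursor intensity ratio distributions.

## Moderated differential expression

Design: one-sample. Within each replicate run the log2 ratio of the
treatment channel over the control channel is the observation; the null
is mean 0. Per protein: `log2FC` = mean, `s2` = sample variance,
`df = n − 1`; proteins with fewer than two ratios are reported without
test statistics.

The variance prior depends on the precursor count: a lowess fit
(span 0.75, configurable; counts log-transformed) of log s2 on
log count estimates E[log s2 | count]. Under the scaled-F sampling
model s2/s2_prior ~ F(df, d0), so the fitted trend equals
log s2_prior + E[log F(df, d0)], and the known log-F mean is subtracted
to de-bias the prior. The lowess is run *without* robustifying
iterations: log χ² residuals are left-skewed, and robust reweighting
of that tail biases the conditional mean (hence the prior) upward by up
to +0.25 in log space, which measurably de-calibrates the null test.
d0 comes from the method of moments: the residual variance of
log s2 about the trend estimates trigamma(df/2) + trigamma(d0/2), and
the trigamma term is inverted by Newton iteration; non-positive excess
gives d0 = ∞. In the exactly degenerate case (zero residual scatter)
the observed common variance is taken as the prior with d0 = ∞, with no
log-F correction — the only self-consistent convention when the data
show no sampling scatter at all. s2 is floored at 1e-12 before logging.

Moderation squeezes `s2_post = (d0·s2_prior + df·s2)/(d0 + df)`
(s2_post = s2_prior when d0 = ∞); `t = log2FC/sqrt(s2_post/n)` is
referred to a t distribution with `df + d0` degrees of freedom (d0 = ∞
capped at 1e6, numerically normal). d0 = 0 reproduces the ordinary
one-sample t-test exactly. BH adjustment (statsmodels step-up) is
applied separately per time point; significance requires adjusted
p < 0.05 and |log2 FC| > 0.585, and only unique (single-accession)
protein groups are eligible. Under null simulation the raw p < 0.05
fraction is nominal (binomial 99% interval at 5000 proteins), and the
moderated ranking dominates the unmoderated t-test at matched
empirical FDR — both under test.

## Temporal classification

Selection: a protein is a candidate if at some time point
|log2 FC| > 1 with adjusted p < 0.05, *and* its replicate CV is below
20%. The CV gate defaults to the maximum over time points of the
within-time-point replicate CV (linear scale): a pooled CV across all
time points' replicates would be dominated by the protein's own
regulation (a step to |log2 FC| = 1.5 alone forces a pooled CV ≈ 60%)
and would exclude every genuinely regulated late protein, defeating the
selection's purpose; the pooled variant remains available as
`cv_mode="pooled"`. Classification takes the earliest time point at
which the relaxed rule (|log2 FC| > 0.585, adjusted p < 0.05) holds and
maps it through the class map (default 2 h → early, 4–9 h →
intermediate, 24 h → late). Any selected protein necessarily passes the
relaxed rule at its selection time point, so every selected protein
receives a class. Untested time points count as non-significant; a time
point entirely missing from the input is an error.

## Over-representation analysis

One-sided hypergeometric tail P(X ≥ k), evaluated by log-gamma
binomials and logsumexp; exact against rational enumeration for all
N ≤ 50 under test. Gene sets are restricted to the background before
counting; matching is case-insensitive on the first gene symbol of a
group; query members outside the background are dropped with a warning;
sets with fewer than 3 background members are skipped (configurable —
an artifact convention, common in ORA practice). BH across tested sets,
significance at q < 0.05.

## Synthetic data generator

What it emulates: per-protein baseline abundances (log-normal, log2
mean 20, SD 2 — placeholder magnitudes typical of Orbitrap intensity
scales, not fitted values), per-peptide ionization factors (log-normal,
log2 SD 1.5) shared across channels and runs, channel intensities in
exact mixing proportions before noise, multiplicative log-normal noise
(σ in log2 units, default 0.25) drawn independently for the MS1-style
and MS2-style quantity, row-wise missingness (default 5%), a fraction
of rows with failing channel/translated q-values (default 2%,
two-point pass/fail — the pipeline only thresholds them), and sticky
unlabeled background added to the L channel for a random protein subset
with intensity drawn independently of the protein's own abundance.
Peptide counts per protein are negative-binomial (mean 5, dispersion 2)
floored at 1. Regulation classes are step functions: the treatment
channel is multiplied by 2^effect from the class's onset time point
onward. One seed governs all draws; ground-truth and report streams are
split from a single SeedSequence so identical (design, seed) give
byte-identical outputs.

What it does not model: spectra (no m/z, retention time or fragments),
label-incorporation kinetics during the pulse, search-engine scoring,
intensity-dependent missingness, interference/ratio compression, or
shared peptides between protein groups. Passing tests therefore
demonstrate correctness of the *quantification and inference* pipeline
under a faithful statistical abstraction of channel-resolved reports,
not robustness to every artifact of real acquisitions.

## Sizes and defaults used by the shipped runs

Benchmark drivers: 1000 proteins × 3 runs per mixture; the
benchmark-recovery script: 5000 proteins × 3 runs, σ = 0.25 — the
scale at which the recovery tolerances (median log2 H/M within ±0.05,
channel shares within ±2 points) are comfortably resolved. Time-course
driver: 800 proteins × 5 time points × 3 replicates, σ = 0.15, planted
effect |log2 FC| = 1.5 with 5%/5%/5% up classes and 3% repressed.
Classifier recovery in the acceptance suite uses 500 proteins at the
same noise level. The d0 parameter-recovery simulation uses 2000
proteins with df = 4, where the moment estimator's sampling error is a
small fraction of the 25% tolerance (at df = 2 the estimator's
sampling SD alone is ~25% of d0, which would make the check
uninformative).

## Known limitations

- The joint-vs-per-channel MaxLFQ question has no single canonical
  answer for channel-resolved data; both are provided and agree on the
  shipped benchmarks, but they can differ on sparse real data.
- The de-biasing of the variance-prior trend assumes a common df across
  proteins when computing the log-F mean (the per-protein trigamma
  terms are averaged for the scatter); with strongly varying replicate
  counts the prior location can be slightly off.
- BH is applied per time point; no across-time-point multiplicity
  control is attempted.
- Ratios are not re-centered before testing (no normalization flag is
  enabled by default); systematic mixing errors would appear as a
  global fold-change offset.
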