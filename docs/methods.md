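# Methods

## Signal model

A germline CNV changes the expected read depth of every bin it covers by a
fixed factor: 0.5 for a heterozygous deletion, 1.5 for a heterozygous
duplication, intermediate values for mosaic events. At the coverage this
package targets — off-target reads of a capture assay, binned so each bin
collects on the order of 100 reads — individual bins are noisy (Poisson
relative sd ≈ 10% at 100 reads), so events are detected by aggregating
evidence over runs of bins rather than from any single bin.

## Normalization

Counts are normalized in two sequential divisions: by each sample's mean
count over active bins (library size), then by each bin's across-sample
mean of the resulting values (locus-specific capture efficiency and
mappability). The result, the relative dosage d, has bin-wise mean exactly
1 and is invariant to uniform rescaling of any sample's counts. *Active*
bins are those with mean raw count ≥ 1 across the cohort (boundary
inclusive); empty or unmappable regions carry no dosage and never
contribute call evidence. Partial terminal bins are retained and flagged;
their lower expected read count flows into the error model automatically.

Residual structure shared across samples — batch, chemistry and handling
effects — is low-rank, so the largest `n_discard` singular components
(default 5) of log d are subtracted and the residual exponentiated.
Natural log is used (any base works; natural log keeps the algebra clean),
with dosage floored at 0.01 beforehand so zero-count cells stay finite
while still registering as strong deletions. `n_discard = 0` disables
denoising; the pipeline caps `n_discard` at min(samples, active bins) − 1
with a warning so small cohorts remain callable. The residual is used
as-is, without re-normalization.

Denoising trades a little signal for a lot of bias removal: each discarded
component absorbs its projection of any true event, shrinking event
amplitude toward 1 (we observe ~0.1 shrinkage on 1.5-dosage duplications
when 40 events are planted across 100 samples). Detection therefore runs on
the denoised matrix, but the reported `mean_dosage` of each call is
quantified from the pre-SVD normalized dosage, which is unbiased. The
flip side: in a cohort with *no* shared structure (clean high-depth
simulations), the discarded components have nothing real to capture and
will latch onto the strongest CNVs themselves — cohorts analysed together
should share real batch structure, or denoising should be reduced.

## Error model

The dosage sd of sample s in bin b is modelled multiplicatively:

    σ[s,b] = max( sd_bin[b] · sd_sample[s] / mean_sd , 1/√N[s,b] )

sd_bin (across-sample sd of the bin) captures how intrinsically variable
the locus is — tandem-repeat-like regions can vary far more than counting
noise; sd_sample (across-bin sd of the sample) captures how noisy the
sample is; dividing by the cohort mean of sd_sample puts an average-noise
sample at σ ≈ sd_bin. The Poisson floor 1/√N, with N the cell's expected
raw read count (sample mean count × bin relative depth, from
pre-normalization counts — counting noise is a property of raw counts),
is a theoretical minimum: the model never reports an error below it.
Standard deviations are computed on the linear dosage scale (ddof = 1)
because the emission comparisons against 0.5/1.0/1.5 are linear-scale. At
least 3 samples are required; cohorts of ≥ 50 are where detection power
saturates (see the cohort-size property test). A `model="poisson"` option
replaces the estimate with the floor alone; it exists for ablation and
demonstrably inflates false positives at hypervariable loci.

No post-hoc calibration rescaling is applied to σ; the test suite checks
empirically (simulation, 60 × 800 cells) that σ tracks the realized dosage
sd within 25% for ≥ 95% of cells when the noise is purely Poisson.

## HMM segmentation and scoring

Emission weights are one-sided normal tails: P(d ≤ 0.5), P(d ≥ 1.5) and
P(d ≤ 1) or P(d ≥ 1), evaluated as Φ(z) of the standardized distance.
They are deliberately unnormalized — Viterbi is invariant to per-bin
constants. Tails are computed and consumed in log space (`log_ndtr`):
at small σ both tails underflow double precision, and the default
non-mosaic gating — deletion evidence exceeds normal evidence exactly when
d < 0.75, duplication when d > 1.25 — depends on their ordering, not their
clamped values. Exposed probabilities are clamped to [1e-300, 1 − 1e-16].

The 3-state chain (DEL, NORM, DUP) uses initial distribution
(t, 1 − 2t, t) and a symmetric transition matrix with stay probability
1 − 2t. The default t = 10⁻⁵ sits at the geometric midpoint of the range
worth sweeping (10⁻¹⁰ to 0.1): entering and leaving a CNV state costs
about 2·ln(1/t) ≈ 23 nats, which a genuine heterozygous event at ~100
reads/bin repays with ~14 nats per bin — two bins suffice, single-bin
flickers are suppressed. Viterbi runs per chromosome per sample (calls
cannot span chromosomes), vectorized across samples, with ties broken
toward NORM then DEL (conservative). Maximal DEL/DUP runs over active bins
become calls; inactive bins interior to a run are spanned but not counted
as support. Call quality is (10/ln 10) · Σ (ln p_state − ln p_norm) over
the run's active bins, floored at 0 — a phred-like, additive,
threshold-sweepable score. The default quality filter is 0 (report
everything); the benchmarking protocol sweeps all cutoffs anyway.

Mosaic mode replaces the CNV tails with P(d ≤ 1)/P(d ≥ 1) wholesale, so
intermediate dosages (e.g. 0.8) accumulate evidence; it finds mosaic
events at the cost of many more noise calls, which is why it is off by
default.

Sex chromosomes receive no special treatment: X in a mixed-sex cohort is
normalized against the cohort mean, so male samples sit near dosage
0.5·(cohort mean) there and may produce spurious X calls. Analyse sexes
separately or ignore X calls in mixed cohorts.

## Simulator

`simulate_cohort` draws counts ~ Poisson(λ) with
λ = mean_reads_per_bin · scale[s] · exp(Σ u_k[s]·v_k[b]) · dosage[s,b] ·
h[s,b] · width_frac[b]. Defaults emulate the off-target panel regime: 100
reads per 200 kb bin (the ~0.065× off-target depth of a small panel),
lognormal library-size scatter (sd 0.1), rank-3 multiplicative shared bias
(sample loadings N(0,1), bin loadings N(0, 0.05) — per-cell log-bias sd
≈ 0.09, comparable to the Poisson noise), and 2% hypervariable bins with
lognormal noise of sd 0.5 (≈ 5× the Poisson relative error), standing in
for tandem-repeat regions. Planted events need not be bin-aligned; a
partially covered bin gets dosage 1 + (event − 1) · covered fraction.
Everything is reproducible from a single integer seed.

What the simulator does *not* emulate: GC-content waves, mappability
structure correlated along the genome, capture-target spikes inside bins,
reference artifacts, and relatedness between samples. Passing tests
therefore demonstrate the statistical machinery — normalization, denoising,
error calibration, segmentation, benchmarking — under the regime the
method assumes, not performance on any particular real capture chemistry.

## Benchmarking

A truth event is detected if any call of the same sample (and, by default,
the same type — a DUP call should not validate a DEL truth) overlaps it by
≥ 1 bp under half-open semantics; a call is true under the same rule. One
call spanning two truths detects both but counts once in precision, so TP
(true calls) and detected-truth counts are kept separate. Precision with
zero calls is reported as missing, never 1, to avoid inflating frontiers.
Boundary error averages |Δstart| and |Δend| over all matched pairs (both
endpoints pooled). The sweep runs the caller over a parameter grid, tries
every quality cutoff, and reports the best precision at each attainable
recall plus the max-recall-at-precision-≥50% summary; size stratification
uses <1 Mb / 1–5 Mb / >5 Mb bands.

## Problem sizes

Simulation-based tests use cohorts of 30–100 samples over 0.16–0.62 Gb
genomes (800–3100 bins of 200 kb) — large enough that the error model and
SVD operate in their intended regime, small enough that the full suite
runs in seconds. The acceptance benchmark uses 100 samples × 3100 bins
with 40 planted events of 1.2–5 Mb.

## Known limitations

- Copy-number states are fixed at {1, 2, 3}; homozygous deletions and
  high-level amplifications are called as DEL/DUP without a distinct state.
- Boundary resolution is the bin size; no split-read refinement (the
  off-target regime has no read-level breakpoint information).
- Read counting is per-read (leftmost aligned base, MAPQ ≥ 20, duplicates
  excluded by default), not fragment-level, and no GC correction is
  applied — the SVD absorbs smooth shared biases instead.
- Very small cohorts (< ~15 samples) lack the rank budget and sd
  estimates the model needs; detection power is materially lower.
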