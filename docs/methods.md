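# Methods

## Pipeline contracts

### Shared-read attribution

Attribution is two-pass and conservative. Pass 1 tallies uniquely mapped
reads per gene. Pass 2 splits each shared read over its tied candidates
proportionally to the pass-1 unique counts; when every candidate has zero
unique count the read is split uniformly across them. Uniform splitting
is the only unbiased choice that still conserves read totals, which is
the invariant everything downstream (downsizing targets, richness)
relies on.

### Downsizing

Rarefaction draws exactly `target` reads without replacement per sample
(multivariate hypergeometric), so the expected downsized proportion of a
gene equals its raw proportion. Because shared-read attribution produces
fractional counts and subsampling needs integers, fractional parts are
resolved by stochastic rounding (floor plus a seeded Bernoulli draw on the
fraction): unbiased in expectation, unlike flooring or half-even rounding.
Samples whose rounded total falls below the target are excluded and
reported rather than kept at lower depth — detection-based metrics (gene
and MSP richness) are only comparable at a single common depth.
Downsizing is performed once per sample, not averaged over repeated
rarefactions. The configured default target is 14 million mapped reads,
the conventional depth for catalog-based gut profiling; tests and
examples use small targets with the same code path.

### FPKM frequencies

`frequency = count / (length_bp/1000) / (mapped/10⁶)`. The per-million
constant is configurable: every downstream statistic is rank- or
ratio-based, so the constant affects only reporting scale.

### MSP quantification

Abundance is the arithmetic mean of the 100 marker-gene frequencies with
zeros included — not the mean over detected markers — and is set to
exactly 0 when fewer than 10 of the 100 markers are detected. The 10%
rule is read strictly: a sample with exactly 10 detected markers keeps
its mean. Marker selection itself (the most co-varying genes of a
cluster) is a catalog-construction concern; markers arrive as input
flags. Whether study pipelines renormalize MSP abundances per sample is
convention-dependent, so both scales are exposed
(`msp_abundance(..., renormalize=True)`); the raw marker-mean scale is
the default. Taxon roll-ups sum member MSPs; taxa with no member in the
matrix are absent rather than fabricated as zero rows, and MSPs without
an entry at the requested rank pool under `unclassified`.

### Functional carriage

Modules are flat item sets. KEGG-module alternative-path logic is not
modeled: gut metabolic modules are themselves curated KO sets, and the
carriage definition used here specifies only a coverage fraction.
Completeness is |items covered by the restricted gene set| / |items|;
"carries" means strictly above 0.90. For single-item CAZy modules this
reduces exactly to "at least one annotated gene", which the tests assert.
Core genes are input flags (the generator marks a configurable core
fraction per MSP); "detected MSP" means post-detection-rule abundance
strictly positive.

## Statistical layer

### Interaction test

The bread × visit interaction is tested with the rank-based ANOVA-type
statistic (ATS) for a fully within-subject 2×2 layout: all 4n
observations are mid-ranked jointly, subject rank vectors estimate the
4×4 covariance, and the interaction contrast (1, −1, −1, 1) yields a
statistic referred to F(f̂, ∞) with box-type degrees of freedom (f̂ = 1
for a one-row contrast). The exact sub-design conventions of rank-based
longitudinal packages differ; this construction is arbitrated against a
within-subject permutation oracle (all 2ⁿ bread-label swaps) in the
tests, agreeing within 0.05 at n = 8, and its null rejection rate at
α = 0.05 sits inside the 99% binomial band over 200 simulations at
n = 40. All-tied features raise a degenerate-data error rather than
returning p = 1, and are excluded from the BH family so that undefined
p-values cannot shrink it.

### Wilcoxon signed-rank

Exact two-sided p-values for up to 25 nonzero pairs are computed by
dynamic programming over doubled mid-ranks — identical to enumerating all
2ⁿ sign assignments, and valid under ties, which the usual exact-mode
implementations refuse. Above 25 pairs a tie-corrected normal
approximation with continuity correction is used; at the boundary the two
agree to ~0.01. Zero differences are dropped (classic convention) with a
`pratt` option that ranks them but excludes them from the statistic.

### Effect sizes and correction

Cliff's delta compares the post distribution against the pre distribution
of the same arm over all n × n cross pairs (the cited effect-size
convention; pairing is not used). Magnitude grades are strict:
negligible < 0.147 ≤ small < 0.33 ≤ medium < 0.474 ≤ large.
Benjamini–Hochberg correction delegates to statsmodels and is verified
against an independent step-up reference; screens flag q ≤ 0.1, and
correlation tables carry the secondary raw p ≤ 0.05 annotation.

### Clinical contrasts

The estimated group difference is the paired-difference contract:
per subject, EGD averages Δ_MF − Δ_CTL, with a t-interval on those
paired differences. This deliberately replaces a repeated-measures mixed
model with Toeplitz/autoregressive covariance (period and sequence fixed
effects, log transforms): exact replication of mixed-model contrasts is
not claimed, but the estimand coincides under a balanced complete design
and the paired form is transparent and assumption-light. HOMA-IR is
glucose(mM) × insulin(mIU/l) / 22.5; Friedewald LDL is TC − HDL − TG/2.2
in mmol/L, flagged (not refused) above the 4.5 mM triglyceride validity
bound. iAUC defaults to the net incremental convention
(tAUC − baseline × span, negative excursions allowed) with a
truncate-negative option, since published tables rarely state which is
used; tAUC is trapezoidal on the observed grid with no interpolation.

## Synthetic-data generator

The generator emulates the data *shapes* and *design* of a fiber
crossover trial: a catalog with ≥100-gene MSPs and exactly 100 markers
each plus a configurable unassigned fraction; balanced randomized
sequence allocation over 4 profiled visits (pre/post × two periods);
log-normal latent compositions (per-MSP mean spread σ_msp = 1.5,
between-subject σ_subject = 0.8, per-visit σ_visit = 0.4 on the log
scale — heavy-tailed compositions with realistic subject stability; the
source trial publishes no variance components, so these are generator
parameters, not estimates); alignment records with length-weighted gene
sampling and within-MSP shared reads; and a clinical table with baselines
near the published cohort means, unimodal postprandial curves anchored at
the fasting value, and optional linear couplings to planted features.

Planted effects are multiplicative shifts on a target MSP at the post
visits of one arm, applied before renormalization. The multiplier is
calibrated numerically: under the log-normal model the post-minus-pre
log difference is N(L, 2σ_v²) within subject and N(L, 2σ_s² + 2σ_v²)
across subjects, so the expected Cliff's delta is an n-weighted mixture
of two normal orderings, inverted for L by bisection. Monte-Carlo checks
show realized deltas within ±0.15 of target at n = 40; the small residual
attenuation comes from simplex renormalization.

What the generator does **not** emulate: sequence content (no FASTQ, no
mapping error or identity thresholds), strain-level variation, real
KEGG/CAZy database structure, annotation-pipeline score filters (the
e-value/bit-score step is upstream of the emulated inputs), correlated
MSP co-occurrence networks, or compositional zero-inflation beyond what
sampling depth induces. Passing tests therefore demonstrate correctness
of the quantification and inference contracts under a plausible
generative model — not performance on real sequencing artefacts.

## Problem sizes used in validation

Unit tests run on hand-built catalogs (1–3 MSPs). The end-to-end
simulations use a 200-MSP × 20,000-gene catalog, 40 subjects × 4 visits,
10,000 reads per sample downsized to 8,000 — small enough to run a
hundred null replicates and fifty power replicates as ordinary tests,
large enough that every pipeline stage (shared-read attribution,
stochastic rounding, detection rules, tie-heavy rank tests) is exercised
with realistic sparsity. Under the global null the observed FDR of the
screen stays ≤ 0.15 at q ≤ 0.1; a single planted feature with
Cliff's-delta target 0.7 among 200 nulls is recovered in ≥80% of
replicates.

## Known limitations

- Modules are KO sets; true KEGG boolean definitions with alternative
  paths would need a definition parser and are out of scope.
- The EGD contrast ignores period and carry-over effects by construction;
  the generator plants none, but real crossover data may contain them.
- `functional_profile` loops over sample × MSP pairs; it is sized for
  hundreds of MSPs and modules, not for catalog-scale annotation sweeps.
- Exact Wilcoxon switches to the normal approximation above 25 nonzero
  pairs; for n = 26–40 the approximation error is ~0.01 in p.
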