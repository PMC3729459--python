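# Methods

This note documents the statistical machinery, the synthetic study design,
the numerical choices, and what the test suite does and does not establish.

## Pooled model

Each probe pair *g* is modelled across the pooled samples as

    y_gi = β0_g + β_s2,g·[study_i = 2] + β_s3,g·[study_i = 3]
           + β_PE,g·PE_i + β_GA,g·GA_i + ε_gi,        ε_gi ~ N(0, σ_g²)

with PE a 0/1 indicator and GA in weeks. The study factor absorbs
between-study mean differences per feature (tissue sampling, platform,
cohort composition); no study-by-covariate interactions are modelled, so
the PE and GA coefficients are effects shared across studies. A PE×GA
interaction model is fitted as a separate run; main effects are always
reported from the no-interaction model. Designs degrade gracefully: a
single-study fit drops the study dummies, a control-only study drops PE
(and the interaction with it). Collinear designs are rejected with the
offending columns named rather than silently pseudo-inverted.

Fitting is per-feature OLS with a shared design (QR factorization, one
solve for all features). Residual variances are moderated with the
standard empirical-Bayes hierarchical model: s_g² ~ s₀²·F(d_g, d₀)
marginally, posterior variance s̃_g² = (d₀s₀² + d_g s_g²)/(d₀ + d_g), and
moderated t = β̂/(s̃_g·u_j) on d₀ + d_g degrees of freedom. The prior
(d₀, s₀²) is estimated by moment matching on log s_g²: the excess of the
sample variance of log s_g² over trigamma(d_g/2) identifies d₀ through a
Newton inversion of the trigamma function (tolerance 1e-8, 50 iterations);
non-positive excess flags d₀ = ∞, in which case every variance is shrunk
to the geometric mean of the observed variances (so identical variances
shrink to themselves). Features with s_g = 0 (interpolating fits) are
handled by the posterior blend itself when d₀ > 0; in the d₀ = 0 bypass
(ordinary t) they receive s₀² to avoid infinite statistics. The
implementation is cross-checked in the test suite against R limma
(`lmFit`/`eBayes`) to <1e-4 relative agreement and against a direct
numerical maximum-likelihood fit of the scaled-F model.

## Multiplicity and reporting conventions

The Bonferroni family is the number of probe pairs tested, m (not the
number of transcripts or genes): the threshold α/m is reported exactly and
to 3 significant figures (α = 0.05, m = 33,088 gives 1.51e-06; note that a
rounding to 1.52e-06 also circulates for this family — we report the exact
quotient). Benjamini–Hochberg step-up q-values are computed with support
for a family larger than the tested vector, so subset reanalyses stay
calibrated against the full family. Coefficients are additionally reported
as signed fold changes, FC = 2^β for β ≥ 0 and −2^(−β) otherwise, so
|FC| ≥ 1 and the sign gives direction. On inverse-normal-transformed data
this is a reporting convention — the transformed scale is not literally
log2 abundance — chosen because it makes per-week GA effects legible
(≈ ±1.06/week at the simulated effect sizes).

## π₀: proportion of non-differentially-expressed features

π₀ is estimated as f̂(1) of the maximum-likelihood convex decreasing
density fitted to the p-value distribution. Any convex decreasing density
on [0,1] is a mixture of the uniform and the triangular densities
f_θ(x) = 2(θ−x)₊/θ², θ ∈ (0,1]; only the uniform is positive at 1, so
π₀ equals the fitted uniform weight. The mixture is fitted by EM over a
θ-grid of 100 points on p-values binned into 512 histogram cells (the
mixture densities are smooth, so binning loses nothing of note while
making each EM sweep cheap); 30,000 iterations or a 1e-12 relative
log-likelihood change, whichever first. The estimator is cross-checked
against an SLSQP fit of the same mixture and against limma's `convest`.
Like all estimators in this family it is conservative (biased up) when
many true effects are small: under the default effect sizes the bias is
about 0.07–0.09, which the recovery tests measure by averaging over five
seeded replicates.

## Normalization

Within each study: quantile normalization (each sample column receives the
across-sample mean of order statistics at its ranks; idempotent, rank-
preserving), then the two-pass INT. Pass 1 transforms each sample across
features; pass 2 each feature across the study's samples, mapping rank r
of n to Φ⁻¹((r−c)/(n−2c+1)). The offset c defaults to 0 (r/(n+1)), and is
configurable (Blom's 3/8 is one choice in the literature; nothing
downstream is sensitive to it because the fitted models see the same
monotone grid either way). Ties: the standalone transform gives tied
inputs average ranks (hence equal z-values, deterministically). Inside
`double_int`, pass 1 places every column on the same quantile grid, so a
feature holding the same rank in two samples yields tied pass-1 values
even for continuous data; pass 2 breaks those ties by sample order (stable
ordinal ranks). This keeps the output a function of within-column ranks
only — hence invariant to any per-sample monotone distortion and to prior
quantile normalization — and guarantees that every feature row is an
exact permutation of the canonical quantile vector, which is what makes
the studies poolable. Pooling maps each pair to its probeset's values in
the 25-mer studies and its probe's values in the 50-mer study; pairs
missing a feature anywhere are dropped and counted, and a couple assigned
to several transcripts contributes one pooled row.

## Probe mapping

Probes are matched directly against transcript sequences (not via a
genome assembly): every placement of the probe or its reverse complement
with Hamming distance ≤ 1 (configurable) is found by pigeonhole seeding —
a probe with ≤ k mismatches contains at least one of k+1 disjoint exact
12-mers, so candidates come from a k-mer index and are verified exactly;
short probes fall back to a full scan. Each (transcript, offset) placement
counts once (the lower-mismatch strand wins ties, sense preferred).
Promiscuity is judged on total placements across the catalog, counting
multiple placements on one transcript — the desk-scale analog of genomic
locations — with probes at ≥ 100 placements discarded before the probeset
majority rule, whose denominator remains the original probeset size
(discarded probes count as non-matching). The ≤ 1-mismatch criterion is
applied uniformly, including inside the majority rule. Pairs are the full
per-transcript cross product; the identity m = Σ_t |probesets(t)|·|probes(t)|
is asserted property-style in the tests.

## Synthetic study design

The generator reproduces the pooled design the analysis targets:

| study | PE | NP | GA (PE) | GA (NP) | platform |
|---|---|---|---|---|---|
| 1 | 0 | 36 | — | 27 in weeks 14–24, 9 in 37–40 | 25-mer probesets |
| 2 | 12 | 11 | 24.1–37.6 | 24.7–36.6 | 25-mer probesets |
| 3 | 37 | 58 | 25.0–39.0 | 37.0–42.0 | 50-mer probes |

154 samples, 49 PE / 105 NP. GA is drawn uniformly within each configured
interval (only means and ranges of the design are known, so no further
distributional structure is imposed); the intervals deliberately preserve
the PE-delivers-earlier confounding that motivates modelling both
covariates. Expression is simulated on a latent log2-like scale as
μ_g + shift_{g,s} + β_PE·PE + β_GA·GA + ε with per-feature study shifts
(SD 0.5, study 1 as reference), spike-and-slab effects (DE with
probability 0.30 for PE and 0.49 for GA — the DE fractions the pooled
analysis is designed to estimate — and N(0, sd) effects when DE, with
β_PE sd 0.5 and β_GA sd 0.05/week), and residual variances from the
scaled inverse-χ² prior with d₀ = 4, s₀² = 0.25, matching the moderation
model's assumption (the real per-feature variance distribution is unknown;
this choice makes the prior-recovery experiments well-posed). Default
catalog: 2,000 transcripts of 250 nt with ~1.24 transcripts per gene,
mirroring the transcript/gene ratio of the real pair table at reduced
scale. All randomness derives from one integer seed through
`numpy.random.SeedSequence` spawn keys; runs are bit-reproducible.

What the generator does *not* emulate: probe-level intensity physics
(RMA/bead summarization is upstream of this pipeline), correlated
features, study-by-effect interactions, RNA degradation or spatial
artifacts. Passing tests therefore demonstrate calibration and recovery
under an idealized independent-feature model, not robustness to those
real-data pathologies.

## Experiment design in the tests and acceptance script

* **Null calibration** (no true effects, full INT pipeline, 5,000
  features): KS uniformity of the moderated p-values and family-wise error
  over 200 replicate simulations — FWER comes out well under α because
  Bonferroni is conservative and the INT lightens tails.
* **Parameter recovery** runs on the latent (pre-INT) scale: the INT fixes
  every feature's marginal, so the generative prior and effect sizes are
  only identifiable before it. The π₀ error is averaged over five seeded
  replicates for the reason given above.
* **GA model agreement** uses the control-only study design: noise-free
  linear effects make the continuous and dichotomized (≤24 vs ≥37 weeks,
  the boundaries of that design's two GA clusters; samples between are
  excluded) coefficients exactly proportional, so their correlation is 1;
  at the default noise level the correlation stays above 0.9. The
  comparison correlates OLS coefficients — moderation rescales
  t-statistics, not coefficients, and the noise-free case has no variance
  dispersion to moderate.
* **Concordance** ranks by nominal p with ties broken by feature id;
  dichotomized "log2FC" is the group contrast without per-week rescaling
  (Pearson correlation is scale-invariant, so the choice is immaterial).
* Problem sizes (2,000–5,000 features; 200 null replicates) were chosen so
  the whole suite and the acceptance script each complete in about a
  minute on one CPU while keeping Monte Carlo error well inside every
  tolerance used.

## Known limitations

* Matching is ungapped and splice-unaware by design; the promiscuity count
  is catalog-relative, so it underestimates genomic repeat counts for
  small catalogs unless repeats are simulated explicitly.
* The π₀ estimator's conservative bias grows as true effects shrink; under
  weak-signal regimes it approaches 1 regardless of the true value.
* The BH q-values are reported for completeness; the headline significance
  calls are Bonferroni, as in the pooled design this package follows.
* `ProbePairTable` rows sharing an Illumina probe duplicate that probe's
  values across pooled rows by construction; results are per *pair*, and
  transcript/gene-level counts deduplicate through the pair table.
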