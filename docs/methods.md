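# Methods

`surfmon` analyses multi-method surveys of surf-zone fish communities in
which the same set of beach sites is sampled contemporaneously by beach
seine hauls, baited remote underwater video (BRUV), and eDNA
metabarcoding of filtered seawater. This note records the models, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic-data generator does and does not emulate.

## Metabarcoding preparation

The raw eDNA observation is an ASV-by-replicate read table whose columns
are keyed by (site, bottle, PCR replicate, marker): three 0.5 L bottles
per site, each amplified in PCR triplicate, is the default design.

**Replicate-consistency filter.** An ASV's reads at a site are zeroed
unless it has nonzero reads in at least `min_replicates` (default 2) of
that site's technical replicates. "Technical replicates in a site" pools
all PCR reactions across bottles (default 9); a `scope="bottle"` option
evaluates the rule within bottles instead. The rule is per-site: an ASV
may survive at one site and be removed at another. Single-replicate
records are the signature of index hopping and carry-over contamination,
which is why the filter targets them; field blanks and PCR controls are
never subtracted, as blank-based correction tends to delete the very
abundant ASVs whose reads hop between samples.

**Occupancy screen (optional, off by default).** Each ASV's per-site
detection history over PCR replicates can additionally be fitted with the
occupancy model below; sites where the posterior probability of
occurrence falls under a threshold (0.8) are zeroed. It is off by default
because the mandatory two-replicate rule already removes single-replicate
contaminants exactly, and the screen costs one MCMC fit per ASV. If the
sampler does not converge for an ASV the ASV is kept unchanged — the
conservative direction for a decontamination step.

**Taxonomic aggregation.** ASVs with identical assigned taxonomic paths
are summed (per-replicate totals are conserved exactly). Paths that stop
above species rank — e.g. surfperches whose barcode cannot separate
congeners — become a single coarser taxon and stay that way downstream.

**eDNA index.** For taxon *t* and replicate *r* with read proportion
`prop(t, r) = reads(t, r) / total(r)`, the index is
`prop(t, r) / max_r' prop(t, r')`, the maximum taken over all replicates
of all samples. It is a within-taxon relative-abundance signal in [0, 1]
that cancels species-specific amplification efficiency; it carries no
information between taxa. Degenerate cases are defined, not errored:
all-zero taxa and zero-total replicates index to 0.

**Detection histories.** Presence/absence per replicate unit with a read
threshold of 1 post-decontamination (no read floor is imposed beyond
decontamination). For eDNA the default unit is the bottle (a bottle
detects a taxon if any of its PCR replicates does; K = 3), configurable
to PCR-level (K = 9). Seine (K = 4) and BRUV (K = 3) replicates detect a
species when its count or MaxN reaches the threshold. Sites with a
missing deployment simply emit no history for that method.

## Occupancy model with false positives

For one species and one method, each site contributes (N, K): N
detections out of K replicate surveys. With occupancy probability ψ,
per-replicate true-positive rate p11 and false-positive rate p10:

    z_i ~ Bernoulli(ψ),   N_i | z_i ~ Binomial(K_i, z_i ? p11 : p10)

The latent z is marginalized analytically, giving the per-site mixture
likelihood ψ·Bin(N; K, p11) + (1−ψ)·Bin(N; K, p10); the posterior is
identical to sampling z, and mixing is better. Identical (N, K) cells are
collapsed with multiplicities, so the likelihood cost is independent of
the number of sites.

Derived quantities, computed per posterior draw and then summarized:

- probability of occurrence at a site:
  ψ·p11^N(1−p11)^{K−N} / [ψ·p11^N(1−p11)^{K−N} + (1−ψ)·p10^N(1−p10)^{K−N}],
  evaluated in log space (log-space and direct evaluations agree to
  1e-12 away from the boundary; p10 = 0 with N ≥ 1 gives exactly 1,
  p11 = p10 returns ψ).
- sensitivity p11/(p11+p10) and specificity (1−p10)/((1−p10)+(1−p11)),
  each the proportion of true positives (negatives) among positive
  (negative) calls at the per-replicate level; both are 0.5 when
  p11 = p10 and undefined (NaN, with a warning) at the degenerate corners.

**Priors and constraint.** Beta(1,1) on ψ and p11, Beta(1,10) on p10,
with the hard ordering constraint p10 < p11. The mixture is invariant
under (ψ, p11, p10) → (1−ψ, p10, p11); the constraint plus the
small-p10 prior pins the labelling to "false positives are the rarer
event", which is the scientific reading of a detection method worth
using.

**Sampling.** Affine-invariant ensemble MCMC (emcee), 32 walkers × 2000
steps with 1000 discarded as warmup, using differential-evolution moves
(DEMove 0.8 / snooker 0.2): the ψ–p10 ridge of weakly-identified
histories mixes poorly under the default stretch move (split-chain R-hat
≈ 1.2) but well under DE moves (≈ 1.02). Convergence is reported per
parameter as split-chain R-hat (threshold 1.05) and effective sample
size; non-convergence is flagged, never silently accepted. Fits are
exactly reproducible for a fixed seed; per-species seeds are spawned
deterministically from one run seed. Species never detected by a method
are skipped (their parameters are unidentified and the posterior would
only return the prior).

**Method comparison.** Species-level sensitivity, specificity and mean
per-site probability of occurrence are compared across methods with
unweighted means, one-way ANOVA (species as observations — the
site-level alternative is available by aggregating differently) and
Tukey HSD pairwise tests.

## Community comparison

**Jaccard-binary dissimilarity** on presence/absence rows (site × method
units): d = 1 − |shared| / |union|; a pair of all-empty rows is defined
as distance 0 and flagged.

**PERMANOVA.** Sequential (Type I) distance-based partition of the model
`detection ~ method + site`, method entered first, via the
Gower-centered inner-product matrix G: SS(term) = tr(H_term G) with
projection (hat) matrices of the sequentially growing dummy design.
Hat matrices are built from an SVD basis because dummy designs are rank
deficient and QR is not rank-revealing. Pseudo-F per term uses the
residual mean square. p-values come from free permutation of rows
(999 by default); when n! ≤ 10,000 the full enumeration replaces
sampling and the p-value is exact. Sites missing any method are dropped
listwise before the test (the analysis is of a balanced crossing);
coverage and richness below use all available units per method. The
implementation reproduces R vegan `adonis2(..., by="terms")` to 1e-8 on
a frozen fixture, and its type-I error at α = 0.05 is 0.03–0.07 under an
exchangeable null. With a real site effect present, free permutation of
the sequential method term is known to be mildly anti-conservative;
the calibration statement is for the exchangeable null.

**Homogeneity of dispersions.** Principal-coordinate embedding of G
(eigenvectors scaled by √|λ|); squared distances to group centroids
subtract the contribution of negative-eigenvalue axes (the standard
correction for semi-metric dissimilarities) and are clipped at zero;
one-way ANOVA on the distances. Group centroids (not spatial medians)
are used, matching `betadisper(..., type="centroid")`, which the
implementation reproduces to 1e-8. Groups with one member are excluded;
numerically identical dispersions short-circuit to F = 0, p = 1.

**Coverage and rarefaction (incidence-based, Hill q = 0).** With T
sampling units, U total incidences, Q1 uniques and Q2 duplicates:

    Ĉ = 1 − (Q1/U) · (T−1)Q1 / ((T−1)Q1 + 2Q2)

Chao2 asymptotic richness S_obs + ((T−1)/T)·Q1²/(2Q2) (bias-corrected
Q1(Q1−1)/(2(Q2+1)) when Q2 = 0). Interpolated richness uses the
combinatorial expectation S(t) = S_obs − Σ_i C(T−Y_i, t)/C(T, t)
(evaluated through log-gamma); extrapolated richness approaches the
Chao2 asymptote geometrically and extrapolated coverage approaches 1.
Estimates are invariant to unit order and to all-zero species columns.

## Abundance concordance

Per-site means: seine catch per haul and BRUV MaxN per deployment are
summed over a site's replicates and divided by the number of replicate
surveys (absent records are zeros); the eDNA value is the mean index
over the site's PCR replicates. Species enter a regression only if both
methods have a nonzero site mean at ≥ 3 sites. Regressions are
unweighted OLS on untransformed means with a two-sided slope t-test.
Because the eDNA index is compositional and within-taxon only, these
regressions are a diagnostic of concordance, not a calibration; both
directions are emitted (R² is direction-invariant, slopes are labelled).
A constant response defines R² = 0; a zero-variance predictor reports a
missing slope.

## Synthetic-data generator

The generator emulates the study conditions so that every stage can be
scored against known truth: 18 beach sites; 4 seine hauls, 3 BRUV
deployments, 3 bottles × 3 PCR replicates per site; a 40-species pool.
One biological occupancy state z per species × site (shared across
methods — the methods observe the same community) with
ψ ~ Beta(0.7, 1.8), a right-skewed draw giving the many-rare/few-common
structure typical of fish assemblages; detection rates per species ×
method, p11 ~ U(0.55, 0.95), p10 ~ U(0.01, 0.10), with p10 < p11
enforced as a configuration guard. Latent local abundance λ is
log-normal (mean 20, σ = 1) and shared across methods so cross-method
abundance signal exists by construction; amplification efficiencies are
log-normal (σ = 0.7).

Counts: seine and BRUV replicates draw Poisson(c·λ·z) with method
catchabilities defaulting to 1 (neutral; lower them to emulate gear
bias). Reads: per PCR replicate, species membership in the amplicon pool
is an explicit Bernoulli(p11) thinning (Bernoulli(p10) for absent
species, emulating trace contamination); each detected species receives
one guaranteed read plus a multinomial share of the remaining depth
(default 50,000) with weights ∝ efficiency × λ. The guaranteed read
makes the generated detection pattern exactly recoverable from the read
table at threshold 1 — the price is a ≤ n_species/depth distortion of
the multinomial composition, negligible at default depth. Species reads
are split over 1 + Poisson(0.7) ASVs with fixed Dirichlet proportions;
~10% of species carry family-level paths (barcode sharing). Contaminant
ASVs come from a disjoint taxon pool and land in exactly one PCR
replicate each (per-replicate injection probability = contamination
rate), which makes filter efficacy measurable as exact precision/recall.

Not emulated: sequence-level artifacts (chimeras, index hopping beyond
single-replicate contaminants), eDNA transport between sites,
degradation kinetics, tide/temperature covariates, and observer error in
MaxN scoring. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative assumptions, not
robustness to every field reality.

## Problem sizes used in the shipped checks

The end-to-end acceptance script runs the campaign at the default
18-site/40-species scale; parameter recovery uses 40 species × 200 sites
× K = 3 at (ψ, p11, p10) = (0.5, 0.8, 0.05); permutation calibration
uses 500 null datasets of 12 rows × 199 permutations (the test suite
uses 1,000). These sizes give stable Monte-Carlo summaries on a single
CPU in a few minutes.

## Known limitations

- The occupancy model is single-season, covariate-free, and fitted
  independently per species × method; no hierarchical sharing.
- The ANOVA on species-level metrics treats fitted posterior summaries
  as data, ignoring their posterior uncertainty.
- Free permutation (not restricted within sites) is used for both terms
  of the sequential PERMANOVA.
- The supplementary-workbook adapter targets one canonical layout
  (sheet per method, site × species); other layouts must be reshaped
  first.
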