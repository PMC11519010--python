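# Methods

`gepatlas` implements the computational core of a longitudinal single-cell
therapeutic atlas analysis: discovery of gene expression programmes (GEPs)
by consensus non-negative matrix factorisation, detection of hubs of
covarying programmes with a permutation test on a signed correlation
network, a composite 0–10 inflammation score, remission and longitudinal
abundance-pattern classification, and projection of fixed GEP spectra onto
bulk or spatial expression. Everything is exercised end to end on synthetic
atlases with planted ground truth. This note records the models, the
parameters that matter, and the design decisions taken where the procedure
was genuinely open.

## The synthetic atlas generator

The generator produces the study conditions under which the pipeline is
validated. Per sample *s* and GEP *g*, a latent log-activity is drawn from
a one-factor Gaussian model,

    m_sg = sqrt(rho) * u_{s,hub(g)} + sqrt(1 - rho) * eps_sg,

with `u` a standard-normal factor shared by all GEPs assigned to the same
hub and `rho = within_hub_usage_correlation`. Sample-level mean usage is
`exp(sigma * m_sg)` with `sigma = sample_heterogeneity_sd` (default 0.6, a
moderately skewed lognormal across samples; 0 makes cells exchangeable
across samples). Inflamed samples add `inflammation_effect_size` to the
latent activity of designated GEPs — on the usage scale a shift of 1.0 is
roughly a `exp(0.6) ≈ 1.8`-fold increase. Per cell, GEP usages are Gamma
draws (shape 4) around the sample-level mean, so within-sample usage
distributions are overdispersed and right-skewed like real usage
distributions.

Counts are Dirichlet-multinomial: a cell's library size is Poisson around
`mean_library_size`, gene probabilities are `usage · spectra` perturbed by
a Dirichlet with concentration `noise_dispersion` (default 1000; per-gene
marginals are then negative-binomial-like with variance roughly twice the
Poisson variance at a 2,000-count library), and the library is allocated
multinomially. Drawing counts conditional on the library size keeps the
per-cell total exactly equal to the drawn library size — a conservation
property the tests rely on — while still producing overdispersion; letting
`noise_dispersion → ∞` recovers the plain multinomial (Poisson-limit)
model. Spectra are block-structured: each GEP has a disjoint block of
high-weight genes over a flat floor, with five `MT-` genes given extra
baseline so every cell has a nonzero mitochondrial fraction.

Defaults (20 patients × 2 samples, 40 cells per sample per compartment,
two compartments × six GEPs in three hubs, 400 genes, rho = 0.7, half of
samples inflamed) were chosen once as a desk-scale cohort that preserves
the statistical structure of a large atlas: enough samples for the
correlation test, enough cells per sample for stable quantiles, and
realistic usage skew. What the generator does **not** emulate: batch
effects, doublets, ambient RNA, cell-type misassignment, and spatial
structure. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted structure under idealised
sampling, not robustness to those artefacts.

Clinical metadata (disease, site, age, sex, indices, remission labels) are
drawn from simple conditional distributions and carried as covariates;
remission labels are assigned per patient by configuration rather than
simulated from biology — the remission classifiers are tested on explicit
clinical-index fixtures instead.

## Preprocessing

Cells expressing fewer than 500 genes or with a mitochondrial count
fraction above 60% are removed; genes detected in fewer than three cells
are removed. The thresholds are *removal* conditions, so exactly 500
detected genes or exactly 60% mitochondrial counts is retained. Filters
run cells-first, then genes, with detected-gene counts recomputed; both
are idempotent. On synthetic data with a few hundred genes the
detected-gene threshold must be scaled down by the caller (the examples
use 50/400 genes). Normalisation is transcripts-per-10,000 followed by
natural-log `log1p`; pseudobulk is the integer per-sample sum of counts.
An optional gene-exclusion list is deliberately absent: no gene families
are removed before factorisation, since the evidence for doing so concerns
graph-based clustering, not NMF.

## Consensus NMF

Frobenius NMF (scikit-learn coordinate descent, seeded random
initialisations) is run `n_restarts ≥ 10` times; all spectra are
L2-normalised and pooled. A component whose Euclidean distance to its
nearest neighbour *from another restart* exceeds a threshold is dropped as
an outlier; the default threshold is the 95th percentile of
nearest-neighbour distances, a reproducible stand-in for choosing the
cutoff from the distance histogram by eye (same-restart neighbours are
excluded so a rogue restart cannot shield its own components). Survivors
are clustered by seeded k-means into k groups; the consensus spectrum is
the per-cluster median, renormalised to unit L2; usages are refit per cell
by active-set NNLS against the fixed consensus spectra, which is the exact
minimiser rather than an iterative approximation.

k is chosen from the silhouette of the pooled-spectra clustering and the
relative Frobenius reconstruction error read jointly: silhouettes within
0.01 of the maximum count as a stability tie (near-stable solutions
routinely differ only by silhouette noise), and within the tie the
smallest k is kept unless a larger one lowers the error by more than 5% —
as it does up to the true rank, after which the error curve flattens.
Whether a solution is biologically meaningful cannot be automated; the
per-k diagnostics are returned for review. Gene scores are
joint ordinary least squares of z-scored expression on all usage columns —
one multiple regression per gene — so a gene loading on two correlated
programmes is attributed jointly rather than twice.

Numerical choices: inner solver tolerance 1e-6 with 500 iterations by
default (tightenable per call; exact-factorisation tests use 1e-12/5000);
k-means uses 10 initialisations from the given seed; rank-deficient usage
matrices are rejected with the collinear GEP pairs named.

## Hub discovery

Per sample and GEP, activity is the set of empirical usage quantiles
(0.25, 0.5, 0.75, 0.95, 0.99; linear interpolation) over the sample's
cells of the GEP's own compartment; entries from fewer than 10 cells are
flagged, and samples with no cells of a compartment yield missing values.
For each GEP pair, Pearson correlations across samples are computed per
quantile and the test statistic is the mean over quantiles of the Fisher
transform, with correlations clipped to |r| ≤ 1 − 1e−7 so degenerate
perfect correlations stay finite; zero-variance quantiles are excluded
from the mean.

The null distribution permutes cells' sample labels within each
compartment stratum (preserving per-compartment sample sizes exactly) and
recomputes the statistic; 10,000 permutations by default. The two-sided
p-value is `2 × min(#above, #below) / n_perm`, ties counted in both
tails, floored at `2 / n_perm` so no p-value is zero. All pairs form one
BH family at FDR 10%. The reported effect size is the adjusted
correlation: mean true r minus mean permuted r, on the correlation scale
(the z scale is used only for testing and edge weights).

**Calibration caveat.** The permutation null is *within-stratum
exchangeability of sample labels*, which is stronger than pairwise
independence. When samples differ strongly in marginal per-GEP activity
(skewed lognormal heterogeneity, as the generator defaults produce),
pairwise-independent GEPs can still show inflated false-positive rates
(~18% at nominal 5% in our simulations) because the permuted summaries
have lighter tails than the heterogeneous true summaries. Under the
exchangeable null the test is calibrated (4.8% at nominal 5% across 210
pairs). The adjusted-r effect size and FDR thresholding mitigate, but
edge lists on strongly heterogeneous cohorts should be read as rankings
rather than exact error-controlled calls.

Significant associations form a signed weighted graph (weight = mean
Fisher z, negatives preserved). Communities are found by a signed Leiden
search: positive- and negative-edge layers optimised jointly with layer
weights (+1, −1) under the RB-configuration quality at each of 40
log-spaced resolutions in [0.001, 0.2]. Pairs co-clustered in at least a
tau = 0.2 fraction of the sweep are linked, and connected components of
that consensus graph are the initial hubs; this consensus reading of tau
makes the resolution sweep consequential and is an interpretation, not a
claim about the original signed-modularity reference. Hubs with more than
three nodes are then iteratively re-partitioned, a split being accepted
only if it strictly improves total signed modularity (positive-part
modularity minus negative-part modularity, weighted by each part's total
edge strength). The procedure is deterministic given its seed and
invariant to node relabelling (nodes are processed in sorted order).

GEP–inflammation association fits, per GEP, a linear mixed model of the
per-sample mean of the five quantile activities on inflammation status
with age, sex, site, disease duration and treatment as fixed effects and
a random intercept per patient, falling back to OLS with the same fixed
effects when the mixed fit fails (singular random-effect variance is
common at 2 samples per patient). P-values are BH-adjusted across GEPs at
5%. A hub is inflammatory iff strictly more than half of its members are
significantly enriched with positive sign — a hub of four needs three.

## Scoring and classification

The inflammation score is a single-sample rank-based enrichment of a gene
signature in pseudobulk profiles: genes are ranked within each sample,
walked from the top rank down, and the signature CDF (steps weighted
`rank^0.25`) is integrated against the background CDF. Because it depends
on expression only through within-sample ranks, the score is invariant
under any monotone per-sample transform. Scores are min–max scaled to
[0, 10] across the scored cohort — so they are comparable only within one
cohort, a documented caveat — and the cutoff is the maximum scaled score
among the designated healthy (reference) samples. The exponent 0.25 is
the conventional default of this enrichment family and is exposed as a
parameter. Scaling is cohort-wide by default; restricting to a disease
subset is the caller's choice of input cohort.

Remission is two-of-three at follow-up: CD — HBI < 5, no macroscopic
ulcers, Nancy ≤ 1; UC — SSCAI ≤ 2, UCEIS ≤ 1, Nancy ≤ 1. Escalation to
another biologic forces nonremission regardless of indices. Missing
indices raise rather than guess; negative indices are rejected. The rules
are monotone: worsening any index never converts nonremission to
remission.

Longitudinal abundance outcomes are mapped onto six patterns by a total
decision table over (baseline remission-vs-nonremission difference,
post-treatment change in remission, post-treatment change in
nonremission), evaluated in the order 3, 1, 4, 5, 6, 2 — baseline-
difference rules first, then concordant, then discordant changes — with
an `unclassified` fallback. The precedence resolves the genuine overlap
between patterns 1 and 2 when both groups decrease (such states read as
pattern 2, the nonremission decrease being the distinguishing call). The
upstream differential-abundance test models per-sample state proportions
with a linear mixed model (patient random intercept; OLS fallback) and BH
across states; it is deliberately simple plumbing whose outputs feed the
pattern table, not a full compositional analysis.

## Projection

External samples are projected onto fixed spectra by per-sample NNLS over
the intersected gene set (in the spectra's gene order): `w_s = argmin_{w≥0}
‖x_s − wH‖₂`. H is held strictly fixed rather than warm-started, because a
free factorisation would change what each programme means. The fit is
scale-equivariant; matrices are used on whatever normalised scale they
arrive on, recorded in the result. Negative entries are clamped to zero
with a logged count; all-zero samples project to zero usage with a
warning; fewer shared genes than programmes is an error. Group summaries
are Kruskal–Wallis per GEP (BH within the family) with pairwise Wilcoxon
rank-sum follow-up only for significant GEPs (BH within the pairwise
family); projected usages are compared raw, with renormalisation left to
the caller.

## Problem sizes used in the test-suite and acceptance script

Simulated cohorts are desk-scale by design: 40 samples, 3,200–4,000 cells,
240–400 genes for the hub pipeline; 2,000 cells × 500 genes for the
consensus-NMF k sweep (10 restarts, k = 2…7); 1,000 permutations for hub
recovery and null calibration and 2,000 for the exhaustive-oracle
comparison. These sizes keep every property measurable (the planted-hub
ARI, null false-positive rate, silhouette-selected k, spectra cosines)
while the whole suite runs in minutes.

## Known limitations

- The permutation test's anticonservativeness under strong per-sample
  marginal heterogeneity (above) is a property of the statistic, not of
  this implementation.
- Mixed-model power at 2 samples per patient is limited; the OLS fallback
  triggers routinely on small cohorts, and enrichment calls near the FDR
  boundary vary between seeds at the default effect size.
- The signed-modularity variant and the consensus reading of tau are one
  defensible instantiation of a procedure the source methods describe only
  loosely; alternatives (per-resolution modularity averaging, different
  null-strength decompositions) would give similar but not identical
  partitions.
- Biological meaningfulness of a chosen k is not automated; `select_k`
  reports diagnostics for human judgement.
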