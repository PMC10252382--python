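# Methods

## Replication gradient and the PTR

A bacterial population that is actively replicating its single circular
chromosome carries, at any instant, a mixture of partially duplicated
genomes. Regions near the replication origin are present in more copies
than regions near the terminus, so sequencing coverage decays from oriC
toward the terminus. Writing d(x) ∈ [0, 1] for the relative distance of
position x from the origin along its replichore (0 at oriC, 1 at the
terminus, folded over both replichores), the steady-state expectation is

    c(x) ∝ PTR^(−d(x)),

where the peak-to-trough ratio PTR = c(ori)/c(ter). PTR = 1 means no
gradient — a non-replicating population; values meaningfully above 1
indicate active replication.

### Coverage profiling

The complete genome is split into 20 equal virtual contigs (sizes differ by
at most 1 bp; the remainder goes to the leading contigs). Alignments are
kept when all three of: mapping length ≥ 50 bp, MAPQ ≥ 5, mismatch ratio
(edit distance / aligned length) ≤ 0.03 — all comparisons inclusive.
Secondary, supplementary and unmapped records are excluded before
filtering so each read counts once. Records lacking the edit-distance tag
are treated as mismatch-free with a loud warning: quality-based rejection
without evidence would silently bias coverage, so the permissive choice is
surfaced rather than hidden.

Coverage within each contig is summarised in sliding windows. No canonical
window geometry exists for virtual contigs, so the defaults are scale-free:
window = contig length / 5 (integer division), step = window / 2,
both configurable. A contig with any zero-coverage window is masked for
that sample; retained values are log2 of the mean window coverage. Contigs
masked in any sample are dropped globally, because the PCA step needs a
complete matrix.

### Distance inference

The samples × contigs matrix is centered per sample (removing sequencing
depth) and the contigs are ordered by their scores on the first principal
component, min–max rescaled to [0, 1]. Orientation is fixed so the median
per-sample OLS slope of coverage on distance is negative (origin = high
coverage). When PC1 carries less than 50% of the variance the ordering is
treated as noise and the estimate is flagged degenerate; every downstream
sample is then flagged non-replicating. Below that fraction the leading
axis of a pure-noise matrix is not separable from a genuine gradient.
Note the degeneracy test gains resolution with samples: with only 3
samples the leading-eigenvalue share of a pure-noise matrix fluctuates
around 0.5, so 5 or more samples are recommended when non-replication is a
plausible outcome.

### Mixed model and PTR construction

On the complete matrix the model is

    y_sc = β0 + b_s · x_c + u_s + v_c + ε_sc,

with fixed per-sample slopes b_s on inferred distance x_c and crossed
random intercepts for sample (u_s) and contig (v_c), fitted by REML
(Powell first, then L-BFGS; restricted likelihoods here are flat enough
that gradient-based optimizers often stop without declaring convergence).
Per-sample slopes — rather than one global slope — are required to report
one PTR per sample. Rows are centered per sample before fitting so that a
library-size shift is removed exactly rather than through the shrinkage of
u_s; this makes PTR estimates invariant to per-sample coverage offsets by
construction. Singular fits (noiseless data has zero residual variance)
and non-convergent fits fall back to per-sample OLS of coverage on
distance, recorded in the diagnostics. The fallback deliberately omits
contig fixed effects: together with per-sample slopes they leave the model
rank-deficient (any multiple of x_c can move between the contig effects
and a shared slope component).

With x spanning [0, 1] and replication giving b_s < 0, the model's
origin/terminus coverage ratio is exactly 2^(−b_s), which is taken as the
PTR; the 95% interval maps b_s ± 1.96·SE through the same transform.
Samples with PTR ≤ 1 or a degenerate distance estimate are flagged
non-replicating.

**Known bias.** Contig midpoints never sit exactly on the origin or the
terminus, so the true distances of the extreme contigs are ≈ 0.05 and
≈ 0.95 at 20 contigs. Min–max rescaling stretches this span to [0, 1],
attenuating slopes by ≈ 0.9 and biasing PTR toward 1 as PTR^0.9 (≈ 7% low
at PTR 2, ≈ 10% at PTR 3). This is a property of rescaled inferred
distances, not of the estimator: supplying true distances recovers
noiseless PTRs to machine precision. Read-level recovery at 50,000 reads
per sample lands within 15% of truth, dominated by this attenuation plus
counting noise.

## Synthetic data

The generators define the conditions under which the pipeline is tested.

* **Reads.** Start positions are drawn by closed-form inverse-CDF from the
  truncated exponential c ∝ PTR^(−d) per replichore (exact; no rejection
  sampling). Optional coverage noise multiplies per-bin densities by
  2^N(0, σ²) over 100 bins per replichore. A configurable fraction of
  records is emitted to fail exactly one alignment filter each — aligned
  length 30 via soft-clipping, MAPQ 2, or edit-distance ratio 0.05 — and
  is listed in the truth file. MAPQ is 40 for clean records. Reads that
  would run past the linear end of the circular reference are redrawn,
  since one SAM record cannot wrap; the resulting deficit affects only the
  final read-length of the coordinate system and is negligible at the
  genome sizes used. Same seed ⇒ byte-identical SAM.
* **Coverage matrices.** y_sc = a_s − log2(PTR_s)·d_c + N(0, σ²) with
  a_s ~ N(5, 0.5), bypassing read sampling for fast exact tests.
* **Metabolome and community.** 3 regions × 3 bioreplicates × 2 treatment
  phases, n samples per cell. log2 intensity = baseline N(10, 1) +
  per-metabolite region effect N(0, σ_region²) + bioreplicate effect
  N(0, (σ_region/2)²) + treatment effect (±effect size, affected subset
  only, treated samples only) + w·(latent factor · loading) +
  N(0, σ_noise²). Two latent factors are shared with the community table:
  community rows are a softmax of taxon loadings on the same factors plus
  independent logit noise (σ_noise/2), so rows sum to 1 and the Mantel
  congruence is tuned by the weight w. Loadings are orthonormalized so
  that in the noiseless w = 1 limit the CLR-Euclidean community geometry
  equals the metabolite geometry exactly (softmax followed by CLR
  recovers centered logits). Defaults mirror the study design this
  package addresses: 654 metabolites, 24% treatment-affected at ±1 log2,
  and a small AC-restricted subset (5%) mimicking amino acids produced
  only in the ascending colon. The detection floor is 1/100 of the median
  baseline; linear intensities below it are reported missing, exercising
  the imputation path. What the generator does **not** emulate: sequencing
  error profiles, compositional count noise (community rows are exact
  proportions), metabolite–metabolite correlation beyond two latent
  factors, and temporal autocorrelation across sampling days — so passing
  tests certify the estimators' statistical behaviour, not robustness to
  every artefact of real MS or sequencing data.

## Metabolite statistics

Missing values (below-detection) are imputed with half the per-metabolite
minimum observed intensity — the standard left-censoring rule for
untargeted MS — then log2-transformed; metabolites missing in > 80% of
samples are dropped with a report. Each metabolite is tested with the
additive linear model `y ~ treatment + bioreplicate + region` (treatment
coded LGG = 1, so the coefficient is the log2 treated-vs-control
difference; the coefficient t test equals the nested-model F test for one
binary factor). Sampling day is not a default covariate but can be
included. All metabolites share one design matrix, so the fits are one
vectorised least-squares solve — this is what makes the 1,000-metabolite ×
200-replicate calibration cheap. BH correction is applied across
metabolites at α = 0.05; zero-variance metabolites report coefficient 0
and p = 1 with a flag. Sub-pathway summaries apply the same test to the
mean log2 profile of member metabolites, BH across sub-pathways;
unannotated metabolites form an explicit "unannotated" group. Pairwise
region comparisons use one-way ANOVA with Tukey's HSD on the studentized
range distribution (family-wise α = 0.05).

## Congruence

CLR applies to the compositional community table only (zeros replaced by
half the smallest nonzero value in the matrix, natural log, row-centered)
— metabolite intensities are not compositional and are never
CLR-transformed. Community dissimilarity is Bray–Curtis; metabolite
distance is Euclidean on the preprocessed, unit-variance-scaled table (no
canonical choice exists; Euclidean on standardized log intensities is the
least structured one). PCoA is classical scaling with negative eigenvalues
dropped and variance explained reported over the positive spectrum. The
Mantel test is one-sided (greater — congruence is a directional
hypothesis) with r the Pearson correlation of upper triangles, the null
built by simultaneously permuting rows and columns of the second matrix
with one seeded generator, and the add-one estimate
p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm), whose floor at 9,999
permutations is 1/10,000. The identity permutation is not counted among
the draws.

## Treatment classification

Random Forest (500 trees by default, standard feature subsampling) on
preprocessed metabolite profiles, repeated over 200 stratified 70/30
train/test splits. Stratification is by treatment and, when metadata is
present, region — the split method of record is unspecified in this
design, and stratification prevents empty-class test sets at small n.
Splits and forests are keyed on sorted sample ids with per-iteration seeds
derived from one master seed, so reports are reproducible and invariant to
input row order. Errors are reported per class, overall, and per sample
(misclassification counts), so the most confusable samples can be read
off with their metadata.

## Problem sizes and numerical choices

Tests and the acceptance script run everything at desk scale: 100 kb
genomes, 50,000 reads per sample, 1,000-metabolite calibrations with 200
replicates, 9,999 Mantel permutations, 200 Random Forest iterations at
200 trees. These sizes give Monte-Carlo standard errors comfortably inside
every asserted tolerance while keeping a full run in minutes. Degenerate
inputs are errors, not warnings: genomes shorter than the contig count,
all-zero compositional rows, single-observation ANOVA groups, matrices
with fewer than 3 samples or 4 surviving contigs, and Mantel inputs with
mismatched labels all raise with the offending item named. Ties in PC1
scores are broken by contig index; PTR confidence intervals use the normal
quantile on the slope scale.

## Limitations

* PTR estimates inherit the min–max rescaling attenuation described above;
  comparisons across samples (same contig set) are unaffected.
* The estimator assumes one genome, co-linear virtual contigs and a single
  contig cluster; draft genomes with real contigs and multi-species
  screening are out of scope, as is de novo oriC detection.
* With fewer than ~5 samples the degeneracy flag for non-replicating
  populations is unreliable (see above).
* Reproducing the source study's headline numbers requires its unreleased
  metabolite tables and deposited sequencing data; all quantitative claims
  here are about recovery of known synthetic truth.
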