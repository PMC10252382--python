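# ptrmetab

Tools for asking two questions about a probiotic strain introduced into a
multi-vessel simulated human colon (ascending / transverse / descending
reactors, three faecal bioreplicates):

1. **Is the strain actively replicating?** From shotgun metagenomic reads
   aligned to the strain's complete circular genome, `ptrmetab` estimates the
   **peak-to-trough ratio (PTR)** — the ratio of sequencing coverage at the
   replication origin to coverage at the terminus. A replicating population
   carries partially duplicated chromosomes, so coverage decays from oriC to
   the terminus and PTR > 1; a dormant population has PTR = 1.
2. **Did the treatment move the metabolome, and in step with the
   community?** Per-metabolite linear models with Benjamini–Hochberg
   correction test treatment effects while controlling for bioreplicate and
   colon region; a permutation Mantel test quantifies microbiome–metabolome
   congruence; and a repeated-split Random Forest measures how well metabolite
   profiles separate treated from control samples.

A synthetic-data module generates every input the pipeline consumes — SAM
alignments from a replicating circular chromosome with known PTR, metabolite
tables with region/bioreplicate/treatment structure, and a compositional
community table with tunable congruence — with the ground truth serialized
alongside, so every stage can be scored against known answers.

## The model

The genome (length *L*, origin *o*) is split into 20 equal **virtual
contigs**. Alignments are kept when mapping length ≥ 50 bp, MAPQ ≥ 5 and
mismatch ratio ≤ 0.03 (all inclusive). Per contig, coverage is averaged over
sliding windows; a contig with any zero-coverage window is masked for that
sample, and retained values are log2-transformed.

Writing d(x) ∈ [0, 1] for the relative distance of position *x* from oriC
along its replichore, steady-state replication gives coverage
c(x) ∝ PTR^−d(x), i.e. log2 coverage falls linearly in d. Relative contig
distances are inferred by PCA across samples (contigs as observations,
per-sample centering; PC1 scores min–max rescaled to [0, 1]), then a linear
mixed-effects model

    y_sc = β0 + b_s · x_c + u_s + v_c + ε_sc,   u_s ~ N(0, σ_s²), v_c ~ N(0, σ_c²)

is fitted by REML with per-sample fixed slopes b_s and crossed random
intercepts for sample and contig. Each sample's PTR is **2^(−b_s)**, the
model's origin/terminus coverage ratio. Samples are flagged non-replicating
when PTR ≤ 1 or when PC1 explains < 50% of coverage variance (no coherent
gradient to order contigs).

The metabolome side: half-minimum imputation of sub-detection values, log2,
then per metabolite `y ~ treatment + bioreplicate + region` with BH across
metabolites (and the same test on sub-pathway mean profiles); one-way ANOVA
with Tukey's HSD for pairwise region contrasts; CLR / Bray–Curtis /
PCA / PCoA ordinations; a one-sided permutation Mantel test with the add-one
estimate p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm); and a stratified
70/30-split Random Forest repeated 200 times.

## Worked example

```python
import tempfile
from ptrmetab import (GenomeModel, ReplicationScenario,
                      simulate_alignments, estimate_ptr)

genome = GenomeModel(length=100_000, ori_position=0)
scenario = ReplicationScenario(ptr_per_sample=[2.0, 2.0, 3.0],
                               reads_per_sample=50_000, seed=1)
with tempfile.TemporaryDirectory() as tmp:
    sam_paths, truth = simulate_alignments(genome, scenario, tmp)
    results, diagnostics = estimate_ptr(sam_paths, f"{tmp}/reference.fasta")
print(results[["slope", "ptr", "flag_nonreplicating"]].round(3))
```

prints

```
           slope    ptr  flag_nonreplicating
sample_id
S01       -0.826  1.772                False
S02       -0.900  1.866                False
S03       -1.459  2.748                False
```

Two samples simulated at PTR 2 are estimated at ≈ 1.77–1.87 and the PTR 3
sample at ≈ 2.75: every sample is correctly called as replicating, in the
right order, within the ~10% attenuation expected from min–max rescaling of
PCA-inferred distances (contig midpoints never sit exactly on the origin or
terminus, so the inferred [0, 1] axis slightly stretches the true one; see
`docs/methods.md`). The `diagnostics` table holds per-sample regression
lines of log2 coverage on inferred distance with a 99% confidence band.

The same stages are available from the shell:

```bash
ptrmetab simulate reads --ptr 2 --ptr 2 --ptr 3 --seed 1 --out-dir sim/
ptrmetab ptr --sam 'sim/*.sam' --genome sim/reference.fasta --out ptr.tsv
ptrmetab simulate metabolome --seed 1 --out-dir met/
ptrmetab metab-stats --table met/metabolites.tsv --annotations met/annotations.tsv --out res.tsv
ptrmetab congruence --metabolites met/metabolites.tsv --community met/community.tsv --out-dir cong/
ptrmetab classify --table met/metabolites.tsv --seed 1 --out rf.tsv
```

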