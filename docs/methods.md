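# Methods

`hebkit` analyzes homoeolog expression bias (HEB) — unequal expression of the
A, B and D copies of a gene triad in an allohexaploid — in biparental F5
populations, and maps its genetic basis. This note documents the models, the
synthetic population the package tests itself against, the numerical choices,
and the limits of what the tests show.

## HEB quantification

A triad-sample is summarized by its **ternary point**
(f_A, f_B, f_D) = (t_A, t_B, t_C)/(t_A+t_B+t_D) of the three homoeolog TPMs,
and by the **coefficient of variation** CV = SD(t_A, t_B, t_D)/mean. Both are
invariant to the triad's overall expression level; CV measures only how
unequal the three copies are. With the sample-SD convention (ddof = 1,
default) CV ranges over [0, √3]; population SD (ddof = 0, range [0, √2]) is a
parameter, and the choice is recorded in output metadata. The categorical
7-archetype scheme (balanced; A/B/D-dominant at the simplex corners;
A/B/D-suppressed at the edge midpoints) is retained for comparison via
nearest-centroid assignment; exact ties (a measure-zero set) resolve to the
first archetype in enum order, and the centroids are configurable.

Two filters precede inference, with the canonical thresholds: a triad is
**expressed** for a line when the mean over replicates of its TPM total
exceeds 0.5 and at least one homoeolog is nonzero, and must be expressed in
every line; a triad is **replicate-stable** when the spread of its replicate
ternary points stays within 0.01. The spread statistic defaults to the mean
pairwise Euclidean distance, with max-pairwise and distance-to-centroid
selectable, and a triad is removed when any line exceeds the threshold. The
0.01 threshold is deliberately stringent — at ordinary counting noise it
removes most triads — so pipelines exploring synthetic data may need to relax
`rep_dist_max` explicitly; the default is kept because it is the canonical
setting.

## Line-effect inference

Heritability of HEB is tested per triad with the mixed model

    CV ~ F5 line (fixed) + (1 | replicate)

The package fits this by **profiled maximum likelihood**: with a single
random intercept the likelihood depends only on the variance ratio
λ = σ²_rep/σ²_res once the fixed effects and residual variance are profiled
out by GLS, so the fit is a bounded 1-D optimization with the boundary λ = 0
(no replicate variance — the typical null triad) an ordinary point. The
fitter reproduces lme4's ML log-likelihoods to ~1e-6 on a reference fit
(frozen in the test suite). General-purpose mixed-model optimizers are
fragile exactly at this boundary, which is why the fitter is bespoke.

The **default p-value, however, is not the LRT**. Null simulation at the
study design (50 lines × 3 replicates) shows the asymptotic χ²₄₉ reference
for the likelihood-ratio statistic is severely anticonservative in the far
tail (P(p < 1e-4) ≈ 7e-3 under the null — ~50-fold inflation), an expected
failure with 49 numerator degrees of freedom on 150 observations. For this
balanced single-random-intercept design the mixed-model ANOVA F-test for the
line term is numerically the two-way ANOVA F with replicate as a block and is
exact under normality, so it is the default (`method="f"`); the LRT remains
available (`method="lrt"`). Significance is Benjamini–Hochberg FDR across all
tested triads at q < 1e-4. Zero-variance responses return p = 1 flagged
`degenerate`; fit failures fall back to the OLS blocked F-test, flagged.

## Bias distance and inheritance patterns

A line's HEB is compared to each parent by the Euclidean distance between
ternary points (maximum √2). The line's point is the ternary transform of its
replicate-mean TPMs by default (`mean_tpm`); averaging per-replicate ternary
points first (`mean_ternary`) is selectable, and parents are processed
identically. Pattern rules, with strict inequalities as printed in the
protocol this package implements:

* `DFO_a`: d(parent1) > 0.2 and d(parent2) < 0.1 — follows parent 2;
* `DFO_b`: mirror image — follows parent 1;
* `DFB`: > 0.2 from both; `Con`: < 0.2 from both; anything else
  uncategorized (e.g. 0.1 ≤ d ≤ 0.2 against one parent only).

The rules are mutually exclusive; divergence rules are evaluated before the
conserved rule so overlaps cannot arise even if thresholds are reconfigured
carelessly. A triad supports a pattern when ≥ `min_lines` lines (default 15
of 50) show it; triads supporting both DFO patterns are summarized by their
line split, which under a single segregating locus at F5 should be ~1:1
(0.46875 : 0.46875 of homozygote classes).

## Genotype association

RNA-seq-derived SNP calls are polarized to {P1, P2, HET, MISSING} against the
parents, filtered (missingness < 10%, depth ≥ 10 in ≥ 5 samples, parents
homozygous-different), and consolidated per gene: a line whose non-missing
SNP calls inside the gene conflict becomes MISSING for that gene — the line,
not the gene, is disqualified, and the > 80% call-rate gate then decides
testability. Lines with > 15% heterozygous gene calls are excluded (the F5
expectation is 6.25%; the cutoff sits ~2.4× above it). Expression is
TMM-normalized CPM (trimmed mean of M-values: 30%/5% two-sided trims on M/A,
reference = sample with most typical upper-quartile fraction, unweighted
trimmed mean), averaged per line, and each testable homoeolog is scored by
one-way ANOVA on genotype class with HET as its own class, BH FDR at
q < 0.05. Summaries count, among triads whose parents diverge in HEB
(parental distance > 0.2), how many homoeologs per triad are associated, and
whether the associated homoeolog carries the largest across-line SD
(Wilcoxon rank-sum on log SD).

## eQTL scan

SNPs pass a stricter gauntlet: depth < 3 masked to missing, then > 50%
missing, > 3% heterozygous, MAF < 5% (non-missing calls, HET contributing
one allele each) or non-informative parents removed. The surviving set is
the conjunction of the rules, so filter order affects only the log
attribution. Expression (log2 CPM + 1) is residualized by OLS on batch, tray
column and replicate — deliberately *not* on line: conditional residuals of
a model with line as a random effect would strip the genetic signal the scan
exists to find, so marginal (fixed-covariate) residuals are the default. A
design in which those covariates are confounded with line is rejected with a
diagnostic. Per-line residual means are regressed on additive genotype dose
(P1 = 0, HET = 1, P2 = 2) for every SNP-gene pair; BH FDR over all tested
pairs at q < 1e-3. Classes are purely positional: different chromosome →
`trans_d`; same chromosome and ≤ 1 Mb from the nearest gene-body boundary
(0 inside the gene, the exact 1 Mb boundary inclusive) → `cis`; else
`trans_s`.

## Synthetic populations

The generator (`simulate_population`) emulates the study design the analysis
assumes; its defaults are the canonical conditions:

| parameter | default | meaning |
| --- | --- | --- |
| `n_triads` | 1000 | expressed triads (3000 genes) |
| `n_lines` / `n_replicates` | 50 / 3 | F5 lines; replicates = batches |
| `selfing_generations` | 4 | F1 → F5 single-seed descent |
| `prop_cis_triads` | 0.20 | triads with a single-homoeolog cis effect |
| `cis_effect_size` | 2.0 | fold-change tied to the parent-2 allele |
| `baseline_log_tpm` | (3.0, 1.0) | log-normal per-homoeolog mean |
| `dispersion` | 0.01 | NB dispersion; biological CV ≈ 0.1, the canonical value for genetically identical replicates |
| `batch_effects` | (1.0, 1.1, 0.9) | per-batch library factors |
| `batch_gene_sigma` | 0.05 | gene-specific log-normal batch wobble |
| `depth_per_tpm` | 0.05 | genotype read depth per unit TPM (~10× at median expression) |
| `min_call_depth` | 3 | below this a call is MISSING |

Each gene has one recombination-free locus; loci are independent across
genes (no linkage map), with an optional `chromosome_blocks` mode that shares
one genotype per line and chromosome to create long-range within-chromosome
structure. Heterozygote expression is the geometric mean of the homozygote
means, consistent with multiplicative effects. Counts are gamma-Poisson
(negative binomial) around expected TPM × length shares of a 2-million-read
library; TPM is then recomputed from counts, so all compositional coupling
between triads is present. Genotype observation is RNA-seq-like: per-SNP
depth is Poisson with mean proportional to the line's expression of the
gene, calls below depth 3 are missing, and heterozygotes are read through
binomial allele sampling, so low-depth hets are miscalled homozygous at rate
2·(1/2)^depth. This reproduces two real phenomena: lowly expressed
homoeologs lose genotype information, and apparent heterozygosity is
deflated at shallow depth.

What the generator does **not** model: read-level alignment artifacts and
homoeolog cross-mapping, allele-specific expression within heterozygotes,
linkage disequilibrium between neighboring genes (unless block mode),
trans-acting variants, GC/length biases, and epigenetic effects. Passing
recovery tests therefore demonstrates the statistical machinery is correct
and calibrated under the assumed data-generating process, not that the
biological conclusions of any real dataset are reproduced.

## Benchmarks and problem sizes

`hebkit.benchmark` scores the full chain against the generator's truth:
line-effect power and null rate, causal-homoeolog identification,
one-homoeolog dominance among divergent triads, DFO segregation balance, and
cis-eQTL precision/recall (with a separate all-null population for the
false-discovery check, 300 triads). The packaged benchmark sizes — 1000
triads for recovery, 2000 lines for the selfing-law check, 10,000 random
SNP-gene pairs for the classification oracle — run the whole suite in well
under a minute on one core. Causal-homoeolog identification is reported both
unconditionally and conditional on the causal homoeolog passing the call-rate
gate: under RNA-seq genotype observation a noticeable fraction of causal
homoeologs simply have no usable genotype calls, which is a property of the
observation process, not of the test.

## Known limitations

* The replicate-variability filter's 0.01 threshold is taken as given; its
  exact statistic is underdetermined, hence the three selectable variants.
* TMM omits edgeR's precision weighting of M-values (unweighted trimmed
  mean); factors agree with the direct formula to 1e-6 on toy data but can
  differ slightly from weighted implementations on extreme libraries.
* TPM uses annotated gene length, not effective transcript length.
* The eQTL scan is a dense all-pairs OLS; it is sized for populations of
  10²–10⁴ SNPs, not genome-scale panels.
* `read_vcf` drops records it cannot polarize (multiallelic, or a parent
  heterozygous/missing) rather than imputing them.
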