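# Methods

`scxa` implements the single-cell and pseudobulk statistics used to
characterise X-chromosome regulation (meiotic sex chromosome inactivation,
dosage compensation) and the transcriptomic consequences of an X-linked
meiotic driver in testis scRNA-seq from standard (ST) and sex-ratio drive
(SR) males, together with a synthetic-data generator that reproduces the
statistical structure these analyses assume.

## Quality control

Cells are removed when they detect fewer than 200 features (count >= 1) or
exceed 20% mitochondrial expression; genes are kept when expressed
(count > 1) in at least three cells. Two definitions of "expressed"
coexist deliberately: detection (>= 1) for the feature tally, strict
(> 1) for every biology-facing metric. The two cell criteria are joined by
"any" (a cell failing either rule is removed), the standard practice;
`filter_logic="all"` switches to the conjunctive reading. Boundary cells
(exactly 200 features, exactly 20% mito) are retained, as the removal
inequalities are strict.

## Per-cell X:A metrics and the inactivation classifier

For each cell, the expressed-gene ratio is the number of expressed
(count > 1) X-linked genes over expressed autosomal genes; the CPM ratio is
summary(CPM of expressed X genes) / summary(CPM of expressed autosomal
genes), computed within the cell with mitochondrial genes excluded from
numerator and denominator (mitochondrial load is a QC artifact, not
chromosomal dosage). The summary is the median by default — robust to the
heavy right tail of expression — with the mean available
(`summary="mean"`). A cell is classified X-inactivated when its CPM ratio
is at most 0.33 (inclusive); under silencing the X falls well below this,
while mere absence of dosage compensation (half dosage) sits near 0.5.
Germline and somatic inactivated fractions are compared with a Pearson
chi-square without continuity correction; Fisher's exact test is offered
when expected counts are small. A zero table margin yields statistic 0 and
p = 1 with a warning.

Detection bias matters at low dosage: when the X is nearly silent, the few
X genes that clear count > 1 are the extreme-rate tail, which inflates the
median-over-expressed ratio in shallow cells. Classification accuracy
claims therefore condition on well-measured cells (hundreds of expressed
genes), which requires deep libraries in simulation.

## Pseudobulk and TMM

Counts are summed within (sample, cell type) units so the biological
replicate is the male. Units are normalised by trimmed mean of M-values:
log2 ratios against a reference unit (the one whose upper-quartile
count/library-size is closest to the mean upper-quartile) are trimmed 30%
on M and 5% on A, combined with inverse-variance weights, and the
resulting factors rescaled to geometric mean 1. The implementation is
validated against factors computed independently with edgeR's
`calcNormFactors` on frozen fixtures (agreement to 8 decimals). Plain
total-count scaling is available (`normalize("total")`).

## Dosage compensation

Per cell type, genes enter the statistic when (i) expressed (count > 1) in
at least 5% of that cell type's cells and (ii) log2(CPM) > 2 in strictly
more than half of the ST samples or strictly more than half of the SR
samples. For each unit, each filtered X-linked gene contributes
log2(CPM / median CPM of filtered autosomal genes of the same unit); the
statistic is internal to the unit, so it is invariant to rescaling the
unit's counts. 0 means even X/autosome expression (complete compensation);
-1 means the X at half the autosomal level. Per cell type and genotype,
each gene's values are averaged across that genotype's samples; the
per-gene averages are tested against 0 with a two-sided Wilcoxon
signed-rank (the replicate is the gene, matching per-gene box plots;
per-sample medians are an alternative unit, switchable), and genotypes are
compared with a two-sided rank-sum over the same per-gene values. Genes
with zero CPM after filtering are excluded with a warning rather than
pseudocounted (the CPM filter makes this rare). Results can be stratified
by gene class (testis-specific vs broadly expressed), recomputing all
statistics within class.

The signed-rank test uses a tie-aware exact permutation distribution
(dynamic programming over doubled ranks) for n <= 25 after zero removal
and the normal approximation with tie correction beyond.

## Differential expression: NB conditional exact test

One engine serves expression (SR vs ST per cell type) and DNA coverage.
Counts are mapped to a common library size (geometric mean) with
quantile-to-quantile negative-binomial pseudo-counts: each observation's
tail probability is preserved while its mean moves from `mu * N_i` to
`mu * N_common`, averaging the normal and gamma approximations; the
per-gene common abundance `mu` is the one-group NB maximum-likelihood fit.
Dispersions (`var = mu + phi mu^2`) are estimated on the equalized counts
by conditional maximum likelihood: given a group's total, the conditional
likelihood is free of the group mean, so a common phi maximizes the summed
conditional log-likelihood over a dispersion grid (refined in two passes),
and tagwise phi maximizes each gene's conditional likelihood plus a prior
weight (default: the equivalent of 10 genes) times the average
likelihood — weighted-likelihood shrinkage toward the common value.
Underdispersed genes floor at phi = 0.

Conditional on a gene's total s across units and equal library sizes, the
group-1 total is distributed BetaBinomial(s, n1/phi, n2/phi) under the
null (binomial with probability n1/(n1+n2) in the Poisson limit phi -> 0).
The two-sided p doubles the smaller tail, capped at 1. Totals above 4000
use the moment-matched normal tail with continuity correction; below that
the exact pmf is evaluated. The phi = 0 path is verified against binomial
enumeration for every split of every total <= 30 (|dp| < 1e-9). The log2
fold change comes from prior-offset (0.5 counts per unit) group-mean
pseudo-counts. Significance is |log2FC| > 1 and Benjamini-Hochberg
FDR < 0.05, with FDR computed within cell type; a cell type needs at least
two pseudobulk units per genotype.

## Chromosomal enrichment and the pseudo-replicate null

Per-gene significance flags are modelled with a binomial GLM,
`significant ~ chromosome_class * cell_type` (X indicator coded
explicitly, so its coefficient is the X log-odds against autosomes).
Nested models are compared by likelihood-ratio chi-square in a fixed
order — interaction first, then the chromosome main effect — with degrees
of freedom equal to the parameter difference. Separation is detected
(fitted probabilities at 0/1 or extreme coefficients) and reported.

The resampling null calibrates the percent of genes called DE when no true
genotype difference exists: per repeat, 4 + 4 pseudo-samples of 100 cells
are drawn with replacement from the ST pool (ST vs ST) or from the ST and
SR pools (ST vs SR), aggregated to pseudobulk, filtered with the same two
gene filters evaluated within the repeat, and run through the same DE
engine and thresholds. The sampling unit is the cell, ignoring sample
identity, with an option to stratify by sample. The percent of eligible
genes significant is recorded per chromosome class and the ST-vs-ST and
ST-vs-SR percent distributions are compared by two-sided rank-sum. A fixed
seed makes the whole object bit-identical.

## Cell-type abundance GLMM

Contrasts (germline vs cyst; early vs late cyst; pre- vs post-meiotic
germline) reduce cells to a binary outcome; secondary spermatocytes are
meiotically active and excluded from the pre/post contrast by default
(configurable). The model is a random-intercept logistic regression,
outcome ~ genotype + (1|sample), fitted on the per-sample collapsed
binomial by Laplace-approximated maximum likelihood (Newton inner modes;
Nelder-Mead plus BFGS outer optimisation over intercept, treatment
log-odds, and log sigma_u). A 15-node adaptive Gauss-Hermite fit
(`method="agq"`) serves as a cross-check, agreeing with Laplace to
< 1e-3 in the treatment effect at these group sizes. The ML fit
(`reml=False`) reproduces `lme4::glmer` to four decimals on a frozen
dataset.

With eight samples the ML estimate of sigma_u is biased low and plain z
Wald intervals undercover (~86%, identically so for lme4). Estimation
therefore defaults to a restricted-likelihood (REML) adjustment — the
objective is penalised by half the log-determinant of the fixed-effects
information, computed from group-level Gaussian weights
1/(sigma^2 + 1/(n p (1-p))) at the conditional modes — and the reported
interval uses a t quantile with n_samples - 2 degrees of freedom. On the
reference design (8 samples x 800 cells, beta = 0.7, sigma_u = 0.5) this
restores ~92% empirical coverage of the nominal 95% interval. The Wald z
p-value is reported unchanged. A sigma_u estimate under 1e-3 triggers a
fall-back to ordinary logistic regression, reported as such.

## Ploidy calling

A site is homozygous when one allele has >= 2 reads and the other 0,
heterozygous when both have >= 2 reads; a 2/1 split satisfies neither rule
and stays ungenotyped. Cells genotyped at fewer than 10 sites are
unclassified; otherwise a cell is haploid iff its homozygous fraction
reaches the cutoff. The default cutoff of 1.0 means any heterozygous
genotyped site implies diploid; on real data a tolerance such as 0.95 is
advisable, since a single erroneous heterozygous call would otherwise tip
a haploid cell to diploid. Classification is monotone in the cutoff and
symmetric under ref/alt exchange.

## Coverage (CNV proxy) and the expression link

Per-gene DNA read counts for ST and SR individuals are tested with the
same NB exact test; normalization defaults to total counts, since
genome-wide coverage is less composition-biased than expression (TMM
optional). The expression-coverage association is a Spearman rank
correlation with average-rank ties, aligned by gene; p is by full
permutation enumeration for n <= 8 and the t-approximation beyond. Signed
fold changes are correlated by default; `absolute=True` correlates
magnitudes. Joint candidates are genes with p < 0.05 in both analyses,
reported with both effect sizes.

## Synthetic data generator

The generator emulates: eight males (4 ST, 4 SR); three chromosomes
(chr1, chr2, chrX — the X gene-rich, as in taxa where the X is a large
fused element) plus ~15 mitochondrial genes; three somatic cell types and
five ordered germline stages with declining transcriptomes; stage- and
genotype-specific X dosage; drive-biased genes; overdispersed counts; and
haploid/diploid allele-count profiles.

Counts are NB (`var = mu + phi mu^2`, default phi = 0.15, a typical
biological squared CV) drawn as gamma-Poisson. The expected count of gene
j in cell c of type t, genotype g is `L_c * w_j / sum_k w_k` with
`w_j = lambda_j * on_{t,j} * d_{t,g}[chrX] * 2^beta_j[SR, DE gene]`:
per-gene rates lambda are log-normal (meanlog 0, sdlog 1); `on_{t,j}` is a
per-stage Bernoulli inclusion (genes "off" contribute rate 0), with
probabilities declining across germline stages; the realized library size
L_c is log-normal (default median ~30k counts) scaled by a stage activity
factor, so defaults span roughly 4000 expressed genes in
GSC/spermatogonia down to ~500 in late spermatids. Mitochondrial genes
receive the cell's Beta(2, 38) (~5%) share. Default X dosage is 0.5 in
GSC/spermatogonia and primary spermatocytes and 1.0 elsewhere (lack of
early-germline compensation with somatic and late-stage compensation).
Doublets (summed cell pairs, truth-labelled) default to rate 0. One global
seed feeds named sub-streams per operation, so each stage is independently
reproducible and identical configs are byte-identical.

Allele-count sites: depth is Poisson per cell and site; haploid cells draw
all reads from one allele (errors land on the other at `error_rate`);
diploid cells are heterozygous at `het_rate` with binomial read splits.
Coverage tables: per-individual, per-gene NB counts with log-normal gene
means and individual size factors; CNV genes are scaled by their ratio in
SR individuals.

What the generator does not model: ambient RNA, UMI collapsing and read-level
noise, batch effects beyond library size, correlated gene programs,
cell-cycle structure, or continuous differentiation (stages are discrete).
Passing recovery tests therefore shows the estimators are correct under
the stated sampling model, not that real-data artifacts are handled.

## Numerical choices and problem sizes

Dispersion grids span 1e-4 to 5 (80 log-spaced points) with a two-pass
re-equalization; edge maxima report phi = 0. Tail probabilities in the
quantile mapping are clipped at 1e-300, with mean-scaling fallback for
non-finite quantiles. GLM fits iterate to tolerance 1e-8; GLMM inner
Newton to 1e-10. Library-equalized group totals are rounded to integers
before the conditional test.

Test-suite simulations use a few hundred to a few thousand genes and tens
to hundreds of cells per sample — sizes at which every recovery target has
comfortable Monte-Carlo margins; calibration checks use 20-200 replicates
(FDR: 20 null datasets; resampling null: 100 repeats plus 20
meta-replicates of 30; GLMM coverage: 200 fits). The synthetic defaults
(8 samples x 8 cell types x 150 cells) run the full pipeline in a few
minutes on one CPU.
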