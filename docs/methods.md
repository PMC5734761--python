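# Methods

`fampoly` re-implements, as a tested pipeline over synthetic data, the
computational chain of a family-based genome-wide association study of
chronic rhinosinusitis with nasal polyps (CRSwNP): cohort quality
control, two family-aware association scans, LD-interval gene-set
enrichment, differential-expression overlap, and a directed eQTL
enrichment with a matched-gene empirical null.  This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic data do and do not establish.

## Synthetic cohort model

Genotypes are biallelic autosomal SNPs.  Markers come in LD blocks with
one allele frequency per block, drawn uniformly from `maf_range`
(default (0.05, 0.5)).  Haplotypes follow a first-order copying process:
within a block each allele copies the previous marker's allele with
probability `within_block_r` (default 0.85 in the study drivers), else
it is a fresh Bernoulli draw at the block frequency.  The process is
stationary, so marginal frequencies equal the block frequency and
adjacent-marker r^2 is tunable through the copy probability.  This is
deliberately not a coalescent: it produces the two features downstream
stages depend on — tunable pairwise r^2 and block boundaries — at
negligible cost.  Marker spacing is jittered uniformly on (0.2, 1.8)
times the nominal 50 kb so that SNP-density matching in the enrichment
null is non-degenerate (a strictly regular grid makes integer SNP
counts in a shifted window almost unmatchable).

Families are nuclear: two founder parents drawn at Hardy–Weinberg from
the haplotype process, and `n_children` children receiving one allele
per parent per marker by a fair coin.  Transmission is per-marker, so
children's haplotypes are not contiguous parental haplotypes; the
within-family tests only require fair per-marker transmission, and the
LD used by pruning and interval building is dominated by the founders.

Affection is sampled per individual from a multiplicative relative-risk
model: penetrance = `baseline_prevalence` × Π RR^x over the risk loci,
capped at 1, with x the additive, dominant or recessive coding of the
risk-allele dosage.  Family ascertainment (on by default) redraws a
whole family until at least one child is affected, emulating
recruitment through affected index patients; it is what gives a
family arm of realistic informativeness at a baseline prevalence of
0.15–0.3.  Unrelated cases and controls are rejection-sampled
singletons.  Sex is simulated but carries no genetics (all markers are
autosomal).

Missing genotypes are a dedicated sentinel (−1), never a 0 dosage, so
allele counts are unbiased under missingness.

### Planted QC artifacts

`inject_qc_artifacts` writes every corruption it makes into a log keyed
by sample ID, so the tests can assert exact recovery: per-sample
missingness; heterozygosity inflation (hom→het flips) or deflation;
Mendelian errors constructed to be parent-inconsistent at the chosen
child calls (a call with two heterozygous parents cannot be made
inconsistent and is skipped); and admixture, which redraws a sample's
genotypes at frequencies shifted ±`admix_shift` along a fixed
per-marker direction, so admixed samples form a single displaced
cluster.  Masking interactions are deliberate: missingness is applied
last and can hide planted Mendel errors, which is why the recovery test
for 120 planted errors asserts ≥100 recovered, not equality.  A planted
admixed sample whose redrawn genotypes break its pedigree will be
caught by the Mendelian filter before PCA — in the study drivers the
admixed samples are therefore unrelated singletons.

## Quality control

Filter order is pinned: sample filters first (missingness > 2%,
heterozygosity more than 3 SD from the cohort mean, > 100 Mendelian
errors), then marker filters (missingness > 2%, > 3 Mendelian errors,
monomorphic), then LD pruning and ancestry PCA.  All threshold
comparisons are strict inequalities; a marker at exactly 2.0%
missingness survives.  The heterozygosity filter is a single pass (mean
and SD computed once); zero variance retains everybody with a warning.

Mendelian errors use trio rules when both parents are genotyped at a
marker and duo rules (child must carry an allele the genotyped parent
can transmit) when one is.  Each erroneous child call increments the
child, each genotyped parent of that child, and the marker once.  This
shared attribution means a child with planted errors usually takes its
parents over the per-sample threshold too — accepted, and close to how
PLINK behaves.  The counter is verified against exhaustive enumeration
of all 27 trio genotype combinations.

LD pruning is greedy and windowed (defaults 50 markers / step 5,
configurable): within a window, the lower-MAF member of any pair with
r^2 ≥ 0.2 is dropped (tie: the later position) until no pair violates;
windows slide per chromosome and passes repeat to a fixpoint, so on
output no same-chromosome pair within `window − step` retained markers
violates the bound.  r^2 is the squared Pearson correlation of
mean-imputed dosages, checked against a direct correlation oracle at
1e-12.

Ancestry outliers: the genomic relationship matrix of the pooled
(study + reference) standardized dosages ((g − 2f)/√(2f(1−f)), pooled
frequency f, monomorphic markers dropped) is eigendecomposed; sample
scores are the top three eigenvectors scaled by √eigenvalue.  E is the
Euclidean distance of each study sample to the mean score of the
designated reference subgroup, and a sample is removed iff
E > 5 × SD(E) over study samples (single pass, SD computed before any
removal).  Two practical points the implementation enforces: reference
alleles are re-oriented to the study's allele-1 labels before pooling
(text PLINK files do not pin which allele is allele 1), and the
reference panel should contain a divergent subpopulation on the same
axis as the suspected admixture — with a single-population reference
the top eigenvectors are family structure and the E > 5·SD rule flags
only its noise tail (about 1% of samples in the study drivers), which
is the rule behaving as stated, not a bug.

## Association scans

**Stratified CMH (DFAM-style).**  Per marker, three kinds of strata:

* Trio transmissions: for each affected child with both parents
  genotyped at the marker, the number of allele-1 transmissions from
  heterozygous parents is O = child dosage − transmissions forced by
  homozygous parents, with E = h/2 and V = h/4 for h heterozygous
  parents.  Duos are skipped (a het parent with a het child is
  unresolvable without the second parent).
* Sibships (families without two genotyped parents, at least one
  affected and one unaffected genotyped sib): the affected sibs' 2·n_aff
  allele slots are a hypergeometric draw from the cluster's pooled
  allele counts; O is the affected sibs' allele-1 count.
* Unrelated singletons: one allelic case/control 2×2 with
  hypergeometric E and V.

The statistic is T = (ΣO − ΣE)² / ΣV against χ²(1); a marker with zero
total variance reports p = 1 and is flagged uninformative.  The
stratum construction is this package's pinned definition — numerical
identity with PLINK's DFAM is not claimed.  E and V of every stratum
are verified against exhaustive enumeration (all transmission patterns;
all allele-slot draws) on small fixtures, and the scan's null rejection
rate at α = 0.05 sits in [0.04, 0.06] over 2000 independent null
markers.

**EMMAX-style mixed model.**  The binary phenotype is treated as
quantitative.  Variance components of y = μ + g + e,
Var = σg²K + σe²I, are fit once by REML on the eigenbasis of the
standardized-dosage GRM: a grid over log δ ∈ [−10, 10] (δ = σe²/σg²)
followed by bounded scalar minimization.  Eigenvalues are floored at
zero after an absolute-minimum jitter of 1e-8 for numerically non-PSD
K.  Each marker is then tested by weighted least squares on the rotated
data under additive (0,1,2), dominant (0,1,1) and recessive (0,0,1)
codings of the allele-1 dosage, missing values mean-imputed per coding;
the Wald p uses a t reference with n − 2 df, which makes the
identity-kinship case agree with OLS to 1e-9.  The reported p is the
minimum over testable codings, with the winning model label — exactly
the convention of the original analysis, unadjusted for trying three
models and therefore anti-conservative; the output metadata says so.
A constant coding (e.g. recessive with no minor-allele homozygotes) is
skipped.

## LD intervals and gene-set enrichment

The top-k markers by p (k = 1000 in the original; 200 in the scaled
drivers) are merged into intervals by transitive closure of pairwise
r² > 0.25 on the same chromosome ("chain" linkage — order-independent,
and the common reading of "pairwise" interval construction).  An
interval spans [min bp, max bp] of its members, 1-based inclusive;
singletons are 1-bp intervals.  Interval-to-gene overlap converts the
inclusive interval [start, end] to the half-open [start, end + 1) on
the BED axis, so a gene starting exactly at `end` overlaps.

Enrichment per gene set: the observed statistic is the number of
intervals overlapping ≥ 1 member gene.  Each null replicate places one
random region per interval, matched in length (exactly) and SNP density
(±10%, relative); placement anchors a region on a uniformly chosen
array marker with a uniform offset, mirroring the observed intervals
(which always contain markers) and making 1-bp templates feasible.  If
200 attempts fail, the density tolerance relaxes stepwise ×1.5 with a
warning.  The empirical p is (1 + #{replicates ≥ observed}) / (R + 1)
— never zero.  Ranking for the target-gene list takes each run's top-20
sets by ascending empirical p (ties: larger observed overlap, then
name) and unions the member genes that overlap any interval of that
run.  The second-stage multiple-testing bootstrap of the INRICH tool is
not reproduced; raw empirical p is used for ranking, as in the original
analysis.

Because the statistic is a small integer count, tied replicates push
the empirical p upward; the KS uniformity check is therefore run in a
regime with ~100 intervals and per-region hit probability near 0.5,
where the tie mass is a few percent.  With few intervals the p is
conservative (mass displaced toward 1), which is the correct direction
for a "≥ observed" permutation p.

## Differential expression and overlap

Per probe, Welch's two-sample t on log2 intensities and
log2FC = mean(case) − mean(control); zero variance in both groups gives
p = 1 at equal means and a flagged p → 0 otherwise.  BH adjustment is
the step-up rule adj_i = min_{j≥i} (m p_(j) / j) capped at 1, verified
against a brute-force implementation and against statsmodels.  The
DE gene set is all genes with ≥ 1 probe at adjusted p < 0.05; the
overlap table reports each target gene through its minimum-adjusted-p
probe with FC = 2^log2FC.  The moderated (empirical-Bayes) t of the
GEO2R/limma route is a noted possible extension, not implemented;
Welch is assumption-light and the planted-signal operating point
(|log2FC| ≥ 1, σ = 0.3, n = 20 vs 17) is insensitive to the choice.

## Directed eQTL enrichment

Catalogue filters: the multi-tissue dialect keeps, per (SNP, gene), the
tissue record (LCL vs skin) with the smaller p, then drops records with
p > 0.05 or |β| < 0.01 (both boundaries inclusive-keep); the blood
dialect keeps FDR < 0.5 with no effect-size limit.  Each surviving SNP
is binned by effect direction (up iff β > 0 for the effect allele;
β = 0 excluded with a warning) × frequency bin ("+" iff the effect
allele's frequency in all affected exceeds that in all unaffected by
more than 1e-12; equality is "similar", hence "−", following the
published table footnotes).  Frequencies count relatives, as in the
original PLINK frequency run; relatedness is deliberately ignored here
because the matched-gene empirical null, not the Fisher p, carries the
inference.

The two-sided Fisher exact test uses the minimum-likelihood rule: the
sum of hypergeometric probabilities (fixed margins) of all tables at
most (1 + 1e-7) times as probable as the observed one; degenerate
margins give p = 1 exactly.  This convention reproduces the eight
published contingency-table p-values at printed precision and matches
both scipy and a factorial brute-force enumerator to 1e-12 on every
table with total ≤ 40.

Empirical null per target gene with n filtered SNPs: order the
catalogue's genes by filtered SNP count, remove the target and every
differentially-expressed gene (targets are DE by construction, so the
removal applies to the null pool only), take genes with exactly n
SNPs, then n+1, n+2, … until 500 are collected (within the final,
partially used level the genes are chosen at random); a null gene with
more than n SNPs has n subsampled without replacement, once per
target.  Each null gene is binned and Fisher-tested identically; the
empirical p is (1 + #{null p ≤ target p}) / (N + 1), reported with the
achieved N, so the uncorrected r/N variant is recoverable.  If the
catalogue cannot supply 500 matched genes the procedure uses what
exists and warns — an empirical p of 1 over a pool of 0 means "no
matched null available", not "null accepted".

Discreteness: the Fisher p of a small 2×2 has an atom at 1 (whenever
the observed table is the modal table), and a rank-based empirical p
inherits that atom.  Measured on exchangeable catalogues the atom is
~0.43 at 8–30 SNPs/gene, ~0.12 at 80–200, ~0.07 at 200–400; the KS
calibration check therefore runs at 200–400 SNPs per gene, where the
statistic is nearly continuous and the empirical p is uniform (KS
p ≈ 0.27).  At realistic catalogue sizes the empirical p is valid but
conservative near 1 — the right direction for a screening statistic.

## Problem sizes

The synthetic study analysed by the numbered drivers uses 300
ascertained nuclear families (2 children), 100 + 100 unrelated
cases/controls, 2000 markers in 10-marker LD blocks, three planted risk
loci (RR 1.8–2.2 across the three inheritance models), 400 annotated
genes, 2 × 31 gene sets, a 37-sample expression series with 40 planted
DE genes, and 350-gene eQTL catalogues; enrichment uses 2000
permutations and the empirical null 500 matched genes.  These sizes
keep every stage's statistical behaviour in its intended regime while
each driver finishes in seconds to a couple of minutes.

## Limitations

* The haplotype model has no recombination map, mutation or
  demography; per-marker child transmission breaks child-haplotype
  contiguity.
* Single-pass heterozygosity and ancestry filters (no iteration after
  removals); whether the original iterated is unstated.
* DFAM stratification and the Golden Helix EMMAX build are
  re-specified, not byte-replicated; only their statistical behaviour
  (type-I error, oracle identities, power) is claimed.
* Gene names are matched exactly; no synonym resolution or GO ancestry
  propagation.
* The published GWAS-scale numbers (top-SNP p-values, the 138-gene
  target list, the 36-gene overlap) depend on the unavailable cohort
  and external resources and are reproduced structurally, not
  numerically; the reproducible surface is the eight contingency-table
  Fisher p-values plus the calibration and recovery properties above.
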