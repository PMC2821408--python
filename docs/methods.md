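# Methods

## Design and scope

The package analyses a pooled-sample expression design: one normalized log2
intensity column per condition (`control`, `ivf_m16`, `ivf_g1g2`), no
replicates.  Everything downstream of normalization is in scope; CEL parsing,
RMA/MAS5 and motif scanning are not — the expression matrix, the annotation
table and the promoter × TFBS count matrix are inputs.

## Fold-change model

For comparison (numerator, denominator) the per-transcript statistic is the
log2 ratio R = x_num − x_den.  Classes are assigned with *strict*
inequalities: induced at fold f iff R > log2 f, repressed iff R < −log2 f,
for f = 2 and f = 4.  Strictness matters only on a measure-zero boundary but
is fixed so that counts are reproducible; a transcript exactly at two-fold is
*unchanged*.  Percentages are rounded half-up to one decimal, matching how
count tables are conventionally printed.  Condition similarity uses the
Pearson correlation over all transcripts and average-linkage agglomeration on
d = 1 − r; the linkage method is a documented default (the upstream tooling
this emulates does not state one), and leaves are pre-sorted lexicographically
so ties break deterministically and the tree is invariant to column order.

Gene-level values (for selecting the most induced / most repressed genes,
default 17 each) are the mean log2 ratio over a gene's transcripts, with
eligibility |mean| ≥ 1 (at least two-fold on average) and lexicographic
tie-breaks.

A sex-balance control checks designated Y-linked marker transcripts: a marker
whose largest pairwise |log2 difference| across conditions exceeds 1.0 log2
unit flags a possible male/female imbalance between pools.

## Category enrichment

A category (chromosome, imprinted set) is tested with the Pearson chi-square
on the 2×3 table (in set / complement) × (induced / repressed / unchanged),
df = 2, no continuity correction, expected counts from the margins.  A zero
row or column margin leaves the test undefined; the package refuses to
collapse categories silently and raises instead.  A `low_expected` flag marks
tables with any expected cell < 5, where the chi-square reference
distribution is unreliable — calibration analyses should exclude those tests.
The chromosome scan applies p < α/m with m defaulting to the number of
chromosomes actually scanned; a direct threshold override reproduces
published-style cutoffs such as 0.0025 = 0.05/20.  All categorical units are
the transcript records passed in; transcript→gene aggregation is the caller's
choice via the annotation table.

Imprinted genes are split by expressed allele (maternal / paternal / unknown);
unknown-allele genes are reported separately and excluded from parental
proportions.  Positional structure on a chromosome is tested with the
Spearman rank correlation between |position − anchor| and the induced
indicator; negative rho means induction concentrates near the anchor (e.g.
the X-inactivation center).  Constant distances or a constant indicator leave
rho undefined and raise.

## Term enrichment

Per-term over-representation of a query list uses the exact upper-tail
hypergeometric probability (via the survival function of the hypergeometric
distribution, evaluated in log space internally), one-sided because only
over-representation is asked of a keyword analysis.  Benjamini–Hochberg
step-up adjustment runs across all terms actually tested (k ≥ 1 after
intersecting memberships with the universe).  The universe is caller-supplied
(whole array vs annotated genes is a study decision, not a package one).

Term grouping is a deterministic greedy agglomeration in ascending-p order: a
term joins the first cluster whose gene-set Jaccard similarity is ≥ 0.5
(default), else founds a new cluster.  This replaces the fuzzy kappa
heuristic of interactive annotation tools with something reproducible; the
exact cluster count of any particular web tool version is not a target.  The
cluster enrichment score is mean(−log10 p) over member terms — equivalently
−log10 of the geometric mean p.  Because the score grows with query-list
size, significance uses a simulated null: draw uniform random gene lists of
the same size, run the identical enrich→cluster→score pipeline, record each
list's maximal cluster score, and take the 95th percentile (quantile
configurable) as the minimal interesting score.  Published thresholds of this
kind (e.g. 1.75 and 2.70 for induced and repressed lists) are data-dependent
outputs, not constants, and are therefore recomputed, never hard-coded.

## Promoter-content PCA

The promoter × motif count matrix is augmented with the per-promoter log2
induction ratio as an *active* variable (a supplementary mode that correlates
the ratio with axes post hoc is available for sensitivity analysis).  All
variables are standardized and the correlation matrix eigendecomposed;
eigenvalues sum to the number of retained variables, zero-variance variables
are dropped with a warning, and each axis sign is fixed so the ratio loads
positively (dominant-component-positive on ratio-free axes).

Axis relevance to expression change is measured by the variable–axis
*correlation*, i.e. eigenvector loading × √eigenvalue — the "loading" a
correlation-matrix PCA reports.  Two degeneracies make the raw eigenvector
entry the wrong ranking statistic: (i) with more variables than promoters the
correlation matrix has a null space whose eigenvectors are arbitrary, and
(ii) a correlated (ratio, motif) pair contributes a difference eigenvector
with eigenvalue 1 − r that has a large ratio entry but almost no variance.
The √eigenvalue scaling suppresses both automatically.  The default selects
the k = 2 top ratio axes, mirroring the two-axis projection this analysis is
known for.

Per-motif contrasts between induced and repressed promoters use the
pooled-variance two-sample Student t (df = n1 + n2 − 2), two-sided, with
Bonferroni correction across the motifs testable (pooled variance > 0);
motifs constant in both groups are reported untestable rather than p = 1.
The count~ratio relationship of a single motif family is the Pearson
correlation with the p value from the t transform on n − 2 df.  Promoter
sequence composition (optional FASTA input) reports GC fraction
(G+C)/(A+C+G+T) and CpG observed/expected = count(CG)·L/(count(C)·count(G))
with L the unambiguous-base count; N bases are excluded from denominators.

## Synthetic data generator

The generator encodes the study conditions and is the test bed for every
stage.  Defaults (units are log2 intensities unless stated):

| parameter | default | meaning |
|---|---|---|
| `n_transcripts` | 20,000 | array features (genes plus ~10% duplicate probes) |
| `baseline_mean`, `baseline_sd` | 8.0, 2.0 | control intensity distribution, typical of normalized arrays |
| `p_changed` | 0.08 | per-condition perturbation probability (≈ the 6–8% changed fraction of this design) |
| `shared_change_fraction` | 0.7 | share of perturbations common to both in vitro groups (shared fertilization/culture stress); yields the two-branch dendrogram with the control isolated |
| `down_fraction_global` | 2/3 | repressed share of changed autosomal non-imprinted transcripts |
| `up_fraction_x`, `up_fraction_imprinted` | 2/3 | induced share of changed X-linked / imprinted transcripts (the inverted skew) |
| `effect_log2_mean/sd`, `min_effect_log2` | 1.5, 0.5, 1.05 | perturbation magnitude \|Normal\| floored above 1 so every true perturbation crosses the strict two-fold threshold in the noiseless limit, making ground-truth recovery exact |
| `noise_sd` | 0.25 | residual log2 noise per in vitro column |
| `n_imprinted` | 89 | imprinted genes (autosomal), 27/89 paternal, 24/89 unknown allele, rest maternal |
| `n_y_markers` | 3 | Y-linked marker transcripts, never perturbed (sex-balanced pools); the rest of Y behaves like any autosome so the null chromosome scan stays exchangeable |
| `n_promoters`, `n_motifs` | 60, 152 | promoter table shape (27 induced / 33 repressed, \|log2 ratio\| uniform in [1, 3]) |
| `motif_base_rate` | 2.0 | Poisson mean motif count per promoter |
| `focal_motifs` | {V$FKHD: 0.5} | count(m, p) ~ Poisson(rate·exp(β_m·ratio_p)); β = 0 elsewhere |

Chromosome assignment follows approximate mouse gene-content weights (X ≈
5.5%).  Each generator draws from an independent stream derived from the
master seed, so identical seeds give byte-identical output files.

What the generator does **not** emulate: probe-level intensity structure,
batch/spatial artifacts, biological replicates (one column per condition, as
analyzed), inter-motif correlation (all non-focal motif families are
independent Poisson noise), and the real genome's gene-density and imprinting
cluster geography.  Passing tests therefore demonstrate correctness of the
statistics and recoverability of the *planted* structure — not performance on
real arrays, where motif count matrices in particular are strongly
correlated.

The i.i.d. motif null has one measurable consequence worth stating.  A single
(ratio, focal-motif) correlation block has eigenvalue at most 1 + r ≤ 2,
while the random-matrix eigenvalue bulk of 153 independent variables over 60
promoters extends to about (1 + √(153/60))² ≈ 6.8; the signal axis therefore
sits inside the noise bulk and hybridizes with noise axes.  At β = 0.5 the
focal motif is the smallest Bonferroni-adjusted contrast p in ~100% of seeds,
but lands in the top-5 loadings of the leading ratio axis in only ~2/3 of
seeds (the rate rises to 100% once the variable count drops safely below the
promoter count).  Real promoter tables, whose leading axes are large
correlated composition blocks, do not share this limitation.

## Problem sizes and numerical choices

Stochastic suites run at sizes chosen to give stable rates in minutes:
chromosome-scan null calibration uses 500 datasets of 6,000 transcripts at
p_changed = 0.15 (keeping expected cells ≥ 5 on all major chromosomes, with
low-expected tests excluded); X-recovery uses 100 seeds at the 20,000-
transcript defaults; promoter recovery uses 100 (tests) / 50 (acceptance
script) seeds of the 60 × 152 design.  Hypergeometric results are validated
against exhaustive subset enumeration up to universe size 12; PCA
eigenstructure against an independent SVD to 1e-8.  Eigenvalues within 1e-9
of zero are clipped to zero; axes with eigenvalue ≤ 1e-9 are treated as null
space.  BH adjustment and the chi-square statistic come from statsmodels and
scipy respectively; both are cross-checked in the tests against hand-rolled
formulas.
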