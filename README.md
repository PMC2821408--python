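# placentome

Analysis toolkit for studies of how in vitro fertilization and embryo culture
perturb the placental transcriptome, built for the single-array-per-condition
design common to pooled-sample mouse experiments: an in vivo control and one
or more in vitro culture groups (M16 medium, sequential G1/G2 medium), each
hybridized once on a whole-transcriptome expression array.

With no replicates there is no variance-based test statistic; the analysis
rests on per-transcript fold changes and on categorical and multivariate
structure:

- **Fold-change classification** — per transcript,
  log2 R = x_ivf − x_control; classes *induced* / *repressed* / *unchanged*
  at the strict two-fold (|R| > 1 on the log2 scale) and four-fold (|R| > 2)
  thresholds, with count tables, condition Pearson correlations and an
  average-linkage dendrogram on the correlation distance 1 − r.
- **Category enrichment** — for a gene category (a chromosome, the imprinted
  genes, maternally/paternally expressed subsets), the 2×3 contingency table
  of membership × two-fold class is tested with a Pearson chi-square (df = 2),
  Bonferroni-controlled across the chromosome scan; plus a Spearman test of
  whether induced genes cluster near an anchor locus such as the
  X-inactivation center.
- **Term enrichment** — keyword/pathway over-representation by the upper-tail
  hypergeometric p = Σᵢ₌ₖ C(K,i)C(N−K,n−i)/C(N,n), Benjamini–Hochberg
  adjusted; greedy Jaccard grouping of terms; per-group enrichment score
  mean(−log10 p); and a simulation-calibrated minimal score (the 95th
  percentile of maximal scores of random gene lists of the same size).
- **Promoter-content PCA (PCPCA)** — PCA of the correlation matrix of a
  promoter × TFBS-count table with the log2 induction ratio included as an
  active variable; axes are ranked by their correlation with the ratio
  (loading × √eigenvalue), promoters are projected on the ratio axes, and
  per-motif induced-vs-repressed contrasts use the pooled-variance Student t
  with Bonferroni correction.
- **Synthetic data** — a seeded generator that emulates the study conditions
  (a minority of transcripts perturbed, 2/3 repressed genome-wide, X-linked
  and imprinted genes skewed 2/3 toward induction, paternally expressed genes
  mostly induced, balanced Y markers, one TFBS family whose counts rise with
  the induction ratio), so every stage is testable without array data.

## Worked example

```python
import placentome as pt

cfg = pt.SimulationConfig(seed=42)
matrix, annotations, truth = pt.simulate_dataset(cfg)
records = pt.classify_fold_change(
    pt.compute_log2_ratios(matrix, pt.ComparisonSpec("ivf_g1g2", "control"))
)
summary = pt.summarize_counts(records, total=matrix.n_transcripts)
print(f"changed at 2x: {summary.changed2} ({summary.percent(summary.changed2)}%), "
      f"{summary.down2} down / {summary.up2} up")

scan = pt.per_chromosome_scan(records, annotations, significance_threshold=0.0025)
x = next(r for r in scan if r.label == "X")
print(f"X chromosome: {100*x.in_proportion_induced:.1f}% induced vs "
      f"{100*x.out_proportion_induced:.1f}% genome-wide, chi2 p = {x.p:.2e}, "
      f"significant: {x.significant}")

promoters = pt.simulate_promoters(cfg, pt.default_promoter_ratios(cfg))
induced = [p for p, g in zip(promoters.promoter_ids, promoters.groups) if g == "induced"]
repressed = [p for p, g in zip(promoters.promoter_ids, promoters.groups) if g == "repressed"]
contrast = pt.tfbs_contrast(promoters, induced, repressed)
top = contrast.as_frame().iloc[0]
r, p = pt.tfbs_ratio_correlation(promoters, str(top["motif_id"]))
print(f"most differential TFBS: {top['motif_id']} "
      f"(Bonferroni p = {top['p_bonferroni']:.2e}); count~ratio r = {r:.2f}")
```

prints

```
changed at 2x: 1350 (6.8%), 887 down / 463 up
X chromosome: 4.9% induced vs 2.2% genome-wide, chi2 p = 3.38e-11, significant: True
most differential TFBS: V$FKHD (Bonferroni p = 6.33e-12); count~ratio r = 0.82
```

Reading: ~7% of transcripts cross the two-fold threshold after in vitro
culture and about two thirds of them are repressed, yet the X chromosome runs
the other way (twice the genome-wide induced fraction, far below the
Bonferroni-corrected 0.0025 cutoff), and the promoters of the most induced
genes are enriched for one forkhead-family binding site whose per-promoter
count tracks the induction ratio.

## Command line

```
placentome simulate --seed 1 --out-dir data/
placentome all --seed 1 --data-dir data/ --out-dir results/
```

writes the synthetic dataset (expression, annotation, term and TFBS tables
plus ground truth) and then a full JSON report with per-stage tables
(fold-change counts, dendrogram as Newick, chromosome scan, term clusters,
PCPCA loadings and scatter).  Exit codes: 0 ok, 1 usage, 2 I/O,
3 computation.

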