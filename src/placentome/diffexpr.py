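"""Fold-change computation and classification, count summaries, sample
correlation and hierarchical clustering, extreme-gene selection, and
Y-marker balance checks.

The study design has one pooled array per condition, so differential
expression is a per-transcript log2 ratio (a column difference on the log2
scale) classified against strict two-fold and four-fold thresholds; there is
no replicate-based test statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .io_model import ComparisonSpec, ExpressionMatrix, GeneAnnotation


class FoldClass(str, Enum):
    UP = "up"
    DOWN = "down"
    UNCHANGED = "unchanged"


@dataclass(frozen=True, slots=True)
class FoldChangeRecord:
    """Per-transcript log2 ratio and its two-fold / four-fold class."""

    transcript_id: str
    comparison: ComparisonSpec
    log2_ratio: float
    class2: FoldClass | None = None
    class4: FoldClass | None = None


@dataclass(frozen=True)
class CountSummary:
    """Counts of transcripts beyond the two-fold and four-fold thresholds for
    one comparison, with percentages of the array total (1 decimal,
    half-up)."""

    comparison: str
    total: int
    up2: int
    down2: int
    up4: int
    down4: int

    @property
    def changed2(self) -> int:
        return self.up2 + self.down2

    @property
    def changed4(self) -> int:
        return self.up4 + self.down4

    @property
    def unchanged2(self) -> int:
        return self.total - self.changed2

    def percent(self, count: int) -> float:
        return percent_of(count, self.total)

    def as_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "total": self.total,
            "up2": self.up2,
            "down2": self.down2,
            "up4": self.up4,
            "down4": self.down4,
            "changed2": self.changed2,
            "changed4": self.changed4,
            "pct_up2": self.percent(self.up2),
            "pct_down2": self.percent(self.down2),
            "pct_up4": self.percent(self.up4),
            "pct_down4": self.percent(self.down4),
            "pct_changed2": self.percent(self.changed2),
        }


def percent_of(count: int, total: int) -> float:
    """Percentage of ``total``, rounded half-up to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    return float(
        (Decimal(count) * 100 / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def compute_log2_ratios(
    matrix: ExpressionMatrix, comparison: ComparisonSpec
) -> list[FoldChangeRecord]:
    """Log2 ratio per transcript: numerator column minus denominator column
    (inputs are already log2 intensities)."""
    comparison.validate_against(matrix)
    ratios = matrix.column(comparison.numerator) - matrix.column(comparison.denominator)
    return [
        FoldChangeRecord(tid, comparison, float(r))
        for tid, r in zip(matrix.transcript_ids, ratios)
    ]


def classify_fold_change(
    records: Sequence[FoldChangeRecord], thresholds: tuple[float, float] = (2.0, 4.0)
) -> list[FoldChangeRecord]:
    """Attach two-fold / four-fold classes.

    A transcript is up at fold f iff log2_ratio > log2(f) (strict, matching
    the "> two-fold" convention) and down iff log2_ratio < -log2(f).
    """
    f2, f4 = thresholds
    if not (f2 > 1 and f4 > 1):
        raise ValueError("fold thresholds must exceed 1")
    t2, t4 = math.log2(f2), math.log2(f4)
    out = []
    for rec in records:
        if not math.isfinite(rec.log2_ratio):
            raise ValueError(f"non-finite log2 ratio for {rec.transcript_id!r}")
        out.append(
            replace(rec, class2=_classify(rec.log2_ratio, t2), class4=_classify(rec.log2_ratio, t4))
        )
    return out


def _classify(ratio: float, threshold: float) -> FoldClass:
    if ratio > threshold:
        return FoldClass.UP
    if ratio < -threshold:
        return FoldClass.DOWN
    return FoldClass.UNCHANGED


def summarize_counts(records: Sequence[FoldChangeRecord], total: int) -> CountSummary:
    """Table-style count summary for one comparison."""
    if total < len(records):
        raise ValueError(f"total {total} < number of records {len(records)}")
    if not records:
        raise ValueError("no records to summarize")
    comparisons = {r.comparison.label for r in records}
    if len(comparisons) != 1:
        raise ValueError("records mix multiple comparisons")
    counts = {"up2": 0, "down2": 0, "up4": 0, "down4": 0}
    for rec in records:
        if rec.class2 is None or rec.class4 is None:
            raise ValueError(f"record {rec.transcript_id!r} is not classified")
        if rec.class2 is FoldClass.UP:
            counts["up2"] += 1
        elif rec.class2 is FoldClass.DOWN:
            counts["down2"] += 1
        if rec.class4 is FoldClass.UP:
            counts["up4"] += 1
        elif rec.class4 is FoldClass.DOWN:
            counts["down4"] += 1
    return CountSummary(comparison=comparisons.pop(), total=total, **counts)


@dataclass(frozen=True)
class SampleCorrelation:
    """Pearson correlation between condition columns across all transcripts."""

    condition_labels: tuple[str, ...]
    matrix: np.ndarray

    def r(self, a: str, b: str) -> float:
        i = self.condition_labels.index(a)
        j = self.condition_labels.index(b)
        return float(self.matrix[i, j])

    def pairs(self) -> dict[str, float]:
        out = {}
        for i, a in enumerate(self.condition_labels):
            for j in range(i + 1, len(self.condition_labels)):
                out[f"{a}~{self.condition_labels[j]}"] = float(self.matrix[i, j])
        return out


def sample_correlation(matrix: ExpressionMatrix) -> SampleCorrelation:
    if matrix.n_transcripts < 2:
        raise ValueError("need >=2 transcripts for correlation")
    stds = matrix.values.std(axis=0)
    for label, s in zip(matrix.condition_labels, stds):
        if s == 0:
            raise ValueError(f"condition {label!r} has zero variance")
    corr = np.corrcoef(matrix.values, rowvar=False)
    return SampleCorrelation(tuple(matrix.condition_labels), corr)


@dataclass(frozen=True)
class LinkageTree:
    """Average-linkage dendrogram of condition columns under correlation
    distance d = 1 - Pearson r.  ``merges`` is a scipy linkage matrix over
    ``labels`` (leaves in lexicographic order, giving a deterministic
    tie-break)."""

    labels: tuple[str, ...]
    merges: np.ndarray

    def __post_init__(self) -> None:
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")
        if self.merges.shape[0] != len(self.labels) - 1:
            raise ValueError("need n-1 merges for n leaves")

    def to_newick(self) -> str:
        root = to_tree(self.merges)

        def render(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6f}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6f}"

        return render(root, root.dist).rsplit(":", 1)[0] + ";"


def hierarchical_cluster(matrix: ExpressionMatrix) -> LinkageTree:
    """Cluster condition columns by average linkage on 1 - Pearson r."""
    if len(matrix.condition_labels) < 2:
        raise ValueError("need >=2 conditions to cluster")
    corr = sample_correlation(matrix)  # also validates variance
    order = sorted(range(len(matrix.condition_labels)), key=lambda i: matrix.condition_labels[i])
    labels = tuple(matrix.condition_labels[i] for i in order)
    dist = 1.0 - corr.matrix[np.ix_(order, order)]
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(np.clip(dist, 0.0, None), checks=False)
    merges = linkage(condensed, method="average")
    merges[:, 2] = np.maximum(merges[:, 2], 0.0)
    return LinkageTree(labels, merges)


@dataclass(frozen=True, slots=True)
class GeneScore:
    gene_symbol: str
    mean_log2_ratio: float
    n_transcripts: int


def select_extreme_genes(
    records: Sequence[FoldChangeRecord],
    annotations: Iterable[GeneAnnotation],
    n_each: int = 17,
) -> tuple[list[GeneScore], list[GeneScore]]:
    """The most induced and most repressed genes at gene level.

    A gene's value is the mean log2 ratio over its transcripts; genes with
    |mean| >= 1 (at least two-fold on average) are eligible.  Returns the top
    ``n_each`` induced and repressed genes, ties broken lexicographically by
    symbol; fewer are returned with a warning when not enough are eligible.
    """
    if n_each < 1:
        raise ValueError("n_each must be >= 1")
    gene_of = {a.transcript_id: a.gene_symbol for a in annotations}
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for rec in records:
        try:
            gene = gene_of[rec.transcript_id]
        except KeyError:
            raise ValueError(
                f"transcript {rec.transcript_id!r} has no gene annotation"
            ) from None
        sums[gene] = sums.get(gene, 0.0) + rec.log2_ratio
        counts[gene] = counts.get(gene, 0) + 1
    scores = [
        GeneScore(g, sums[g] / counts[g], counts[g]) for g in sums
    ]
    induced = sorted(
        (s for s in scores if s.mean_log2_ratio >= 1.0),
        key=lambda s: (-s.mean_log2_ratio, s.gene_symbol),
    )
    repressed = sorted(
        (s for s in scores if s.mean_log2_ratio <= -1.0),
        key=lambda s: (s.mean_log2_ratio, s.gene_symbol),
    )
    if len(induced) < n_each or len(repressed) < n_each:
        warnings.warn(
            f"only {len(induced)} induced / {len(repressed)} repressed genes "
            f"eligible (requested {n_each} each)",
            stacklevel=2,
        )
    return induced[:n_each], repressed[:n_each]


@dataclass(frozen=True, slots=True)
class MarkerBalance:
    marker_id: str
    max_abs_log2_diff: float
    flagged: bool


def marker_balance_check(
    matrix: ExpressionMatrix,
    marker_ids: Sequence[str],
    threshold: float = 1.0,
) -> list[MarkerBalance]:
    """Check that sex-marker transcripts (e.g. Y-specific markers) are level
    across conditions; a marker is flagged when its largest pairwise |log2
    difference| exceeds ``threshold`` (default one log2 unit), indicating a
    possible male/female imbalance between pools."""
    index = {tid: i for i, tid in enumerate(matrix.transcript_ids)}
    out = []
    for marker in marker_ids:
        if marker not in index:
            raise KeyError(f"marker transcript {marker!r} not in expression matrix")
        row = matrix.values[index[marker]]
        diff = float(row.max() - row.min())
        out.append(MarkerBalance(marker, diff, diff > threshold))
    return out
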