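"""Three-category enrichment of a gene set against the rest of the genome.

For a category of transcripts (a chromosome, the imprinted genes, ...) the
two-fold classes (induced / repressed / unchanged) are cross-tabulated against
category membership and tested with a 2x3 Pearson chi-square (df = 2, no
continuity correction).  Includes a per-chromosome scan with Bonferroni-style
multiple-testing control, an imprinted-gene parental-allele breakdown, and a
positional profile testing whether induced genes cluster near an anchor locus
(the X-inactivation center on the X chromosome).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import chi2_contingency, spearmanr

from .diffexpr import FoldChangeRecord, FoldClass
from .io_model import CHROMOSOMES, GeneAnnotation, ImprintStatus, annotation_index


@dataclass(frozen=True)
class CategoryTable:
    """2x3 contingency table: (in set, complement) x (induced, repressed,
    unchanged) at the two-fold threshold."""

    label: str
    in_counts: tuple[int, int, int]
    out_counts: tuple[int, int, int]

    def as_array(self) -> np.ndarray:
        return np.array([self.in_counts, self.out_counts], dtype=float)

    @property
    def grand_total(self) -> int:
        return sum(self.in_counts) + sum(self.out_counts)

    @property
    def in_total(self) -> int:
        return sum(self.in_counts)

    @property
    def out_total(self) -> int:
        return sum(self.out_counts)


@dataclass(frozen=True)
class CategoryTestResult:
    label: str
    chi2: float
    df: int
    p: float
    in_proportion_induced: float
    in_proportion_repressed: float
    out_proportion_induced: float
    out_proportion_repressed: float
    significant: bool | None
    low_expected: bool

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "in_proportion_induced": self.in_proportion_induced,
            "in_proportion_repressed": self.in_proportion_repressed,
            "out_proportion_induced": self.out_proportion_induced,
            "out_proportion_repressed": self.out_proportion_repressed,
            "significant": self.significant,
            "low_expected": self.low_expected,
        }


def _require_classified(records: Sequence[FoldChangeRecord]) -> None:
    for rec in records:
        if rec.class2 is None:
            raise ValueError(f"record {rec.transcript_id!r} is not classified")


def build_category_table(
    records: Sequence[FoldChangeRecord],
    membership: Iterable[str],
    label: str = "",
) -> CategoryTable:
    """Cross-tabulate two-fold class against membership in a transcript set."""
    members = set(membership)
    if not members:
        raise ValueError("category membership is empty")
    _require_classified(records)
    ids = {r.transcript_id for r in records}
    missing = members - ids
    if missing:
        raise ValueError(
            f"category member(s) absent from records: {sorted(missing)[:5]}"
        )
    counts = {True: [0, 0, 0], False: [0, 0, 0]}
    slot = {FoldClass.UP: 0, FoldClass.DOWN: 1, FoldClass.UNCHANGED: 2}
    for rec in records:
        counts[rec.transcript_id in members][slot[rec.class2]] += 1
    return CategoryTable(label, tuple(counts[True]), tuple(counts[False]))


def chi2_test(
    table: CategoryTable, significance_threshold: float | None = None
) -> CategoryTestResult:
    """Pearson chi-square on the 2x3 table with expected counts from the
    margins; df = 2, no continuity correction.

    A zero row or column margin makes the test undefined; no collapsing of
    categories is performed — the caller must decide how to handle it.  A
    ``low_expected`` flag is raised when any expected cell is below 5 (the
    usual validity rule for the chi-square approximation).
    """
    obs = table.as_array()
    if obs.min() < 0:
        raise ValueError("negative count in contingency table")
    if np.any(obs.sum(axis=1) == 0) or np.any(obs.sum(axis=0) == 0):
        raise ValueError(
            f"category {table.label!r}: zero row or column margin — the 2x3 "
            "chi-square is undefined; categories are not collapsed, drop or "
            "merge them explicitly"
        )
    chi2, p, df, expected = chi2_contingency(obs, correction=False)
    in_total, out_total = table.in_total, table.out_total
    result = CategoryTestResult(
        label=table.label,
        chi2=float(chi2),
        df=int(df),
        p=float(p),
        in_proportion_induced=table.in_counts[0] / in_total,
        in_proportion_repressed=table.in_counts[1] / in_total,
        out_proportion_induced=table.out_counts[0] / out_total,
        out_proportion_repressed=table.out_counts[1] / out_total,
        significant=(p < significance_threshold)
        if significance_threshold is not None
        else None,
        low_expected=bool((expected < 5).any()),
    )
    return result


def per_chromosome_scan(
    records: Sequence[FoldChangeRecord],
    annotations: Iterable[GeneAnnotation],
    alpha: float = 0.05,
    m_tests: int | None = None,
    significance_threshold: float | None = None,
) -> list[CategoryTestResult]:
    """Chi-square of every chromosome against the rest of the genome.

    Each result carries the uncorrected p; ``significant`` applies
    ``p < alpha / m`` with m defaulting to the number of chromosomes actually
    scanned.  ``significance_threshold`` overrides the corrected cutoff
    directly (e.g. 0.0025 = 0.05/20).  Chromosomes with no annotated
    transcript are skipped with a warning.
    """
    ann = annotation_index(annotations)
    by_chrom: dict[str, set[str]] = {c: set() for c in CHROMOSOMES}
    for rec in records:
        try:
            by_chrom[ann[rec.transcript_id].chromosome].add(rec.transcript_id)
        except KeyError:
            raise ValueError(
                f"record {rec.transcript_id!r} has no chromosome annotation"
            ) from None
    scanned = [c for c in CHROMOSOMES if by_chrom[c]]
    skipped = [c for c in CHROMOSOMES if not by_chrom[c]]
    if skipped:
        warnings.warn(
            f"chromosome(s) without annotated transcripts skipped: {skipped}",
            stacklevel=2,
        )
    m = m_tests if m_tests is not None else len(scanned)
    threshold = significance_threshold if significance_threshold is not None else alpha / m
    results = []
    for chrom in scanned:
        table = build_category_table(records, by_chrom[chrom], label=chrom)
        results.append(chi2_test(table, significance_threshold=threshold))
    return results


@dataclass(frozen=True)
class ParentalBreakdown:
    """Induced/repressed/unchanged counts among imprinted genes split by the
    expressed parental allele; unknown-allele genes are reported separately
    and excluded from the maternal/paternal proportions."""

    maternal: tuple[int, int, int]
    paternal: tuple[int, int, int]
    unknown_allele: tuple[int, int, int]

    @property
    def n_maternal(self) -> int:
        return sum(self.maternal)

    @property
    def n_paternal(self) -> int:
        return sum(self.paternal)

    @property
    def n_unknown(self) -> int:
        return sum(self.unknown_allele)

    @property
    def n_imprinted(self) -> int:
        return self.n_maternal + self.n_paternal + self.n_unknown


def parental_breakdown(
    records: Sequence[FoldChangeRecord],
    annotations: Iterable[GeneAnnotation],
) -> ParentalBreakdown:
    _require_classified(records)
    ann = annotation_index(annotations)
    slot = {FoldClass.UP: 0, FoldClass.DOWN: 1, FoldClass.UNCHANGED: 2}
    tallies = {
        ImprintStatus.MATERNAL: [0, 0, 0],
        ImprintStatus.PATERNAL: [0, 0, 0],
        ImprintStatus.UNKNOWN_ALLELE: [0, 0, 0],
    }
    for rec in records:
        a = ann.get(rec.transcript_id)
        if a is None or not a.imprint_status.is_imprinted:
            continue
        tallies[a.imprint_status][slot[rec.class2]] += 1
    return ParentalBreakdown(
        maternal=tuple(tallies[ImprintStatus.MATERNAL]),
        paternal=tuple(tallies[ImprintStatus.PATERNAL]),
        unknown_allele=tuple(tallies[ImprintStatus.UNKNOWN_ALLELE]),
    )


@dataclass(frozen=True)
class PositionalProfile:
    """Per-gene (position, log2 ratio) series along a chromosome plus the
    Spearman rank correlation between distance-to-anchor and the induced
    indicator."""

    chromosome: str
    anchor_bp: int
    series: tuple[tuple[str, int, float, str], ...]  # id, position, ratio, class2
    rho: float
    p: float


def positional_profile(
    records: Sequence[FoldChangeRecord],
    annotations: Iterable[GeneAnnotation],
    chromosome: str = "X",
    anchor_bp: int = 0,
) -> PositionalProfile:
    """Test whether induced genes cluster near an anchor locus.

    Spearman rho between |position - anchor_bp| and indicator(class2 = up)
    over the chromosome's transcripts, sorted by position.  A negative rho
    means induction concentrates near the anchor.  Degenerate inputs (fewer
    than 3 genes, constant distances or a constant indicator) leave rho
    undefined and raise.
    """
    _require_classified(records)
    ann = annotation_index(annotations)
    rows = []
    for rec in records:
        a = ann.get(rec.transcript_id)
        if a is not None and a.chromosome == chromosome:
            rows.append(
                (rec.transcript_id, a.position_bp, rec.log2_ratio, rec.class2.value)
            )
    if len(rows) < 3:
        raise ValueError(
            f"need >=3 genes on chromosome {chromosome!r}, found {len(rows)}"
        )
    rows.sort(key=lambda r: (r[1], r[0]))
    dist = np.array([abs(r[1] - anchor_bp) for r in rows], dtype=float)
    induced = np.array([1.0 if r[3] == FoldClass.UP.value else 0.0 for r in rows])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-input warning handled below
        rho, p = spearmanr(dist, induced)
    if not (np.isfinite(rho) and np.isfinite(p)):
        raise ValueError(
            "Spearman correlation undefined (constant distances or constant "
            "induced indicator)"
        )
    return PositionalProfile(chromosome, anchor_bp, tuple(rows), float(rho), float(p))
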