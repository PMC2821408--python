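"""Shared domain types, validation, and tabular readers/writers.

Every stage of the pipeline exchanges data through a small set of validated
containers: a log2 expression matrix (transcripts x conditions), per-transcript
gene annotations (symbol, chromosome, position, imprinting status, term
memberships), a comparison specification (which condition is contrasted against
which reference), and a catalog of annotation terms (keyword / pathway gene
sets).

The canonical on-disk dialect is tab-separated UTF-8 text with ``#``-prefixed
comment lines ignored; term catalogs use the GMT convention
(``term_id<TAB>name<TAB>gene...``).  JSON writers stamp a ``schema_version``
field so downstream consumers can detect format drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1.0"

#: Allowed chromosome vocabulary (mouse): 19 autosomes, the sex chromosomes
#: and the mitochondrial genome.
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 20)) + ("X", "Y", "MT")

#: Condition labels required for the full three-way pipeline: in vivo control
#: and the two in vitro embryo-culture groups (M16 medium, sequential G1/G2).
CONTROL_CONDITION = "control"
IN_VITRO_CONDITIONS: tuple[str, str] = ("ivf_m16", "ivf_g1g2")
REQUIRED_CONDITIONS: tuple[str, ...] = (CONTROL_CONDITION,) + IN_VITRO_CONDITIONS


class ImprintStatus(str, Enum):
    """Genomic imprinting status of a gene (which parental allele is expressed)."""

    NOT_IMPRINTED = "not_imprinted"
    MATERNAL = "imprinted_maternal"
    PATERNAL = "imprinted_paternal"
    UNKNOWN_ALLELE = "imprinted_unknown_allele"

    @property
    def is_imprinted(self) -> bool:
        return self is not ImprintStatus.NOT_IMPRINTED


@dataclass(frozen=True, slots=True)
class GeneAnnotation:
    """Annotation of one transcript (array feature).

    ``position_bp`` is the 1-based gene midpoint; only relative distances are
    ever used downstream, so a single convention suffices.  Several transcripts
    may share one ``gene_symbol`` (probe redundancy on the array); gene-level
    quantities are obtained downstream by averaging log2 ratios over a gene's
    transcripts.
    """

    transcript_id: str
    gene_symbol: str
    chromosome: str
    position_bp: int
    imprint_status: ImprintStatus = ImprintStatus.NOT_IMPRINTED
    term_ids: frozenset[str] = field(default_factory=frozenset)

    def validate(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise ValueError(
                f"transcript {self.transcript_id!r}: unknown chromosome "
                f"{self.chromosome!r} (allowed: {', '.join(CHROMOSOMES)})"
            )
        if self.position_bp < 0:
            raise ValueError(
                f"transcript {self.transcript_id!r}: negative position_bp "
                f"{self.position_bp}"
            )


@dataclass
class ExpressionMatrix:
    """Normalized log2 intensity matrix, transcripts x conditions."""

    transcript_ids: list[str]
    condition_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        if self.values.shape != (len(self.transcript_ids), len(self.condition_labels)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.transcript_ids)} transcripts x "
                f"{len(self.condition_labels)} conditions"
            )
        dup = _first_duplicate(self.transcript_ids)
        if dup is not None:
            raise ValueError(f"duplicate transcript id {dup!r}")
        dup = _first_duplicate(self.condition_labels)
        if dup is not None:
            raise ValueError(f"duplicate condition label {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = map(int, np.argwhere(~np.isfinite(self.values))[0])
            raise ValueError(
                f"non-finite expression value for transcript "
                f"{self.transcript_ids[i]!r}, condition {self.condition_labels[j]!r}"
            )
        self._col_index = {c: j for j, c in enumerate(self.condition_labels)}

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_ids)

    def column(self, condition: str) -> np.ndarray:
        try:
            return self.values[:, self._col_index[condition]]
        except KeyError:
            raise KeyError(
                f"condition {condition!r} not in matrix "
                f"(have: {', '.join(self.condition_labels)})"
            ) from None

    def require_conditions(self, labels: Iterable[str] = REQUIRED_CONDITIONS) -> None:
        missing = [c for c in labels if c not in self._col_index]
        if missing:
            raise ValueError(
                f"expression matrix is missing required condition(s): "
                f"{', '.join(missing)}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.transcript_ids, columns=self.condition_labels
        )


@dataclass(frozen=True, slots=True)
class ComparisonSpec:
    """One pairwise contrast: ``numerator`` (in vitro group) over ``denominator``
    (reference).  On the log2 scale the ratio is a column difference."""

    numerator: str
    denominator: str

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError("comparison numerator and denominator must differ")

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        matrix.require_conditions((self.numerator, self.denominator))

    @property
    def label(self) -> str:
        return f"{self.numerator}_vs_{self.denominator}"


@dataclass(frozen=True, slots=True)
class Term:
    """One annotation term (keyword or pathway): a named gene set."""

    term_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"term {self.term_id!r} has no members")


@dataclass
class TermCatalog:
    """Collection of annotation terms keyed by term id."""

    terms: dict[str, Term]

    def __post_init__(self) -> None:
        for key, term in self.terms.items():
            if key != term.term_id:
                raise ValueError(f"catalog key {key!r} != term id {term.term_id!r}")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[Term]:
        return iter(self.terms.values())

    def __getitem__(self, term_id: str) -> Term:
        return self.terms[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = (
    "transcript_id",
    "gene_symbol",
    "chromosome",
    "position_bp",
    "imprint_status",
    "term_ids",
)


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return None


def read_expression_tsv(
    path: str | Path, required_conditions: Iterable[str] | None = None
) -> ExpressionMatrix:
    """Read a transcripts x conditions TSV (first column = transcript_id).

    Row and column order are preserved.  Duplicated transcript ids and
    non-numeric cells are hard errors naming the offending record.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected transcript_id plus >=1 condition column")
    ids = df.iloc[:, 0].tolist()
    dup = _first_duplicate(ids)
    if dup is not None:
        raise ValueError(f"{path}: duplicate transcript id {dup!r}")
    labels = list(df.columns[1:])
    values = np.empty((len(ids), len(labels)), dtype=float)
    for j, col in enumerate(labels):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[i]!r} in row "
                f"{ids[i]!r}, column {col!r}"
            )
        values[:, j] = converted.to_numpy()
    matrix = ExpressionMatrix(ids, labels, values)
    if required_conditions is not None:
        matrix.require_conditions(required_conditions)
    return matrix


def write_expression_tsv(
    matrix: ExpressionMatrix, path: str | Path, float_format: str = "%.6f"
) -> None:
    frame = matrix.to_frame()
    frame.index.name = "transcript_id"
    frame.to_csv(path, sep="\t", float_format=float_format)


def read_annotation_tsv(path: str | Path) -> list[GeneAnnotation]:
    """Read per-transcript annotations; chromosome and imprint vocabulary are
    enforced with errors naming the offending transcript."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation column(s): {', '.join(missing)}")
    dup = _first_duplicate(df["transcript_id"].tolist())
    if dup is not None:
        raise ValueError(f"{path}: duplicate transcript id {dup!r}")
    annotations: list[GeneAnnotation] = []
    valid_status = {s.value for s in ImprintStatus}
    for row in df.itertuples(index=False):
        status = row.imprint_status
        if status not in valid_status:
            raise ValueError(
                f"{path}: transcript {row.transcript_id!r}: imprint_status "
                f"{status!r} not in {sorted(valid_status)}"
            )
        try:
            position = int(row.position_bp)
        except ValueError:
            raise ValueError(
                f"{path}: transcript {row.transcript_id!r}: non-integer "
                f"position_bp {row.position_bp!r}"
            ) from None
        terms = frozenset(t for t in str(row.term_ids).split(";") if t)
        ann = GeneAnnotation(
            transcript_id=row.transcript_id,
            gene_symbol=row.gene_symbol,
            chromosome=row.chromosome,
            position_bp=position,
            imprint_status=ImprintStatus(status),
            term_ids=terms,
        )
        ann.validate()
        annotations.append(ann)
    return annotations


def write_annotation_tsv(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    rows = [
        {
            "transcript_id": a.transcript_id,
            "gene_symbol": a.gene_symbol,
            "chromosome": a.chromosome,
            "position_bp": a.position_bp,
            "imprint_status": a.imprint_status.value,
            "term_ids": ";".join(sorted(a.term_ids)),
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def annotation_index(annotations: Iterable[GeneAnnotation]) -> dict[str, GeneAnnotation]:
    """transcript_id -> annotation lookup (duplicates are a hard error)."""
    index: dict[str, GeneAnnotation] = {}
    for a in annotations:
        if a.transcript_id in index:
            raise ValueError(f"duplicate transcript id {a.transcript_id!r}")
        index[a.transcript_id] = a
    return index


def read_gmt(path: str | Path) -> TermCatalog:
    """Read a GMT term file: ``term_id<TAB>name<TAB>gene1<TAB>gene2...``."""
    terms: dict[str, Term] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs term_id, name and >=1 gene"
            )
        term_id, name = parts[0], parts[1]
        if term_id in terms:
            raise ValueError(f"{path}:{lineno}: duplicate term id {term_id!r}")
        members = frozenset(g for g in parts[2:] if g)
        terms[term_id] = Term(term_id, name, members)
    return TermCatalog(terms)


def write_gmt(catalog: TermCatalog, path: str | Path) -> None:
    lines = [
        "\t".join([term.term_id, term.name, *sorted(term.members)])
        for term in sorted(catalog, key=lambda t: t.term_id)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(payload: Mapping, path: str | Path) -> None:
    """Serialize a result bundle as JSON, stamped with the schema version."""
    out = {"schema_version": SCHEMA_VERSION}
    out.update(payload)
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, Enum):
        return obj.value
    raise TypeError(f"cannot serialize {type(obj)!r}")
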