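"""Promoter-Content Principal Component Analysis (PCPCA).

A promoter x TFBS-count matrix is augmented with each promoter's log2
induction ratio as an additional *active* variable; PCA is performed on the
correlation matrix of all variables (motif counts + ratio).  Axes whose
ratio-variable loading is large link promoter motif composition to expression
change; promoters projected on those axes separate induced from repressed
genes when such a link exists.  Per-motif induced-vs-repressed contrasts use
the pooled-variance two-sample Student t with Bonferroni correction, and a
single motif family can be tested for a linear count~ratio relationship with
the Pearson correlation.

Promoter sequence composition statistics (GC fraction, CpG observed/expected)
are computed from an optional FASTA; motif scanning itself is out of scope —
the count matrix is an input.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

#: Name of the induction-ratio variable inside the PCA variable set.
RATIO_VARIABLE = "log2_induction_ratio"

_META_COLUMNS = ("promoter_id", "gene_symbol", RATIO_VARIABLE, "group")
_GROUPS = ("induced", "repressed", "unlabeled")


@dataclass
class PromoterTFBSMatrix:
    """Promoter records with a log2 induction ratio and integer motif counts."""

    promoter_ids: list[str]
    gene_symbols: list[str]
    log2_ratios: np.ndarray
    groups: list[str]
    motif_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.log2_ratios = np.asarray(self.log2_ratios, dtype=float)
        self.counts = np.asarray(self.counts)
        n, m = len(self.promoter_ids), len(self.motif_ids)
        if len(set(self.promoter_ids)) != n:
            raise ValueError("duplicate promoter ids")
        if self.counts.shape != (n, m):
            raise ValueError(
                f"count matrix shape {self.counts.shape} != ({n} promoters, {m} motifs)"
            )
        if len(self.gene_symbols) != n or len(self.groups) != n or self.log2_ratios.shape != (n,):
            raise ValueError("promoter metadata lengths disagree")
        if n and not np.all(np.isfinite(self.log2_ratios)):
            raise ValueError("log2 induction ratios must be finite")
        if self.counts.size:
            if not np.issubdtype(self.counts.dtype, np.integer):
                if not np.allclose(self.counts, np.round(self.counts)):
                    raise ValueError("motif counts must be integers")
                self.counts = self.counts.astype(int)
            if self.counts.min() < 0:
                raise ValueError("motif counts must be non-negative")
        else:
            self.counts = self.counts.astype(int).reshape(n, m)
        bad = set(self.groups) - set(_GROUPS)
        if bad:
            raise ValueError(f"unknown promoter group(s): {sorted(bad)}")

    @property
    def n_promoters(self) -> int:
        return len(self.promoter_ids)

    @property
    def n_motifs(self) -> int:
        return len(self.motif_ids)

    def motif_index(self, motif_id: str) -> int:
        try:
            return self.motif_ids.index(motif_id)
        except ValueError:
            raise KeyError(f"motif {motif_id!r} not in matrix") from None

    def promoter_index(self, promoter_id: str) -> int:
        try:
            return self.promoter_ids.index(promoter_id)
        except ValueError:
            raise KeyError(f"promoter {promoter_id!r} not in matrix") from None


def derive_group(ratio: float) -> str:
    return "induced" if ratio > 0 else ("repressed" if ratio < 0 else "unlabeled")


def read_tfbs_matrix(path: str | Path) -> PromoterTFBSMatrix:
    """Read a promoter x motif count TSV.

    Two orientations are accepted, detected from the first header cell:
    ``promoter_id`` — one row per promoter with metadata columns then motif
    columns; ``motif_id`` — transposed (one row per motif, one column per
    promoter, with ``gene_symbol``/``log2_induction_ratio``/``group`` given as
    special rows), the layout of published supplementary promoter tables.
    When ``group`` is absent it is derived from the sign of the ratio.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    sentinel = df.columns[0]
    if sentinel == "motif_id":
        df = _transpose_tfbs(df)
    elif sentinel != "promoter_id":
        raise ValueError(
            f"{path}: first column must be 'promoter_id' (canonical) or "
            f"'motif_id' (transposed), got {sentinel!r}"
        )
    if RATIO_VARIABLE not in df.columns:
        raise ValueError(f"{path}: missing {RATIO_VARIABLE!r} column")
    if "gene_symbol" not in df.columns:
        raise ValueError(f"{path}: missing 'gene_symbol' column")
    motif_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if not motif_cols:
        raise ValueError(f"{path}: no motif count columns found")
    try:
        ratios = df[RATIO_VARIABLE].astype(float).to_numpy()
    except ValueError:
        raise ValueError(f"{path}: non-numeric induction ratio") from None
    counts = np.empty((len(df), len(motif_cols)))
    for j, col in enumerate(motif_cols):
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            i = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric count {df[col].iloc[i]!r} for motif "
                f"{col!r}, promoter {df['promoter_id'].iloc[i]!r}"
            )
        counts[:, j] = converted.to_numpy()
    if not np.allclose(counts, np.round(counts)):
        raise ValueError(f"{path}: motif counts must be integers")
    if counts.size and counts.min() < 0:
        raise ValueError(f"{path}: negative motif count")
    if "group" in df.columns:
        groups = [g if g else derive_group(r) for g, r in zip(df["group"], ratios)]
    else:
        groups = [derive_group(r) for r in ratios]
    return PromoterTFBSMatrix(
        promoter_ids=df["promoter_id"].tolist(),
        gene_symbols=df["gene_symbol"].tolist(),
        log2_ratios=ratios,
        groups=groups,
        motif_ids=motif_cols,
        counts=counts.astype(int),
    )


def _transpose_tfbs(df: pd.DataFrame) -> pd.DataFrame:
    wide = df.set_index("motif_id").T
    wide.index.name = "promoter_id"
    wide = wide.reset_index()
    wide.columns.name = None
    return wide


def write_tfbs_matrix(
    matrix: PromoterTFBSMatrix, path: str | Path, transposed: bool = False
) -> None:
    frame = pd.DataFrame(matrix.counts, columns=matrix.motif_ids)
    frame.insert(0, "group", matrix.groups)
    frame.insert(0, RATIO_VARIABLE, matrix.log2_ratios)
    frame.insert(0, "gene_symbol", matrix.gene_symbols)
    frame.insert(0, "promoter_id", matrix.promoter_ids)
    if transposed:
        t = frame.set_index("promoter_id").T
        t.index.name = "motif_id"
        t.to_csv(path, sep="\t")
    else:
        frame.to_csv(path, sep="\t", index=False)


@dataclass
class PCPCAResult:
    """Eigenstructure of the promoter-content correlation matrix.

    ``loadings`` is variables x axes (orthonormal eigenvectors, descending
    eigenvalue order); ``scores`` is observations x axes (projections of the
    standardized observations).  When the ratio is an active variable its
    loadings row ranks the axes; in supplementary mode ``ratio_correlations``
    holds the post-hoc Pearson correlation of the ratio with each axis score.
    """

    eigenvalues: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    variable_names: list[str]
    dropped_variables: list[str]
    promoter_ids: list[str]
    groups: list[str]
    ratio_variable: str | None = RATIO_VARIABLE
    ratio_correlations: np.ndarray | None = None

    @property
    def n_axes(self) -> int:
        return self.loadings.shape[1]

    def variable_axis_correlations(self) -> np.ndarray:
        """Correlation of each (standardized) variable with each axis score:
        eigenvector loading scaled by sqrt(eigenvalue).  This is the
        "loading" a correlation-matrix PCA reports and the quantity that says
        how strongly an axis is correlated with a variable."""
        return self.loadings * np.sqrt(np.clip(self.eigenvalues, 0.0, None))

    def ratio_loadings(self) -> np.ndarray:
        """Correlation of the induction ratio with each axis (active mode:
        sqrt(eigenvalue)-scaled loading; supplementary mode: post-hoc Pearson
        correlation with the axis scores)."""
        if self.ratio_variable is not None:
            idx = self.variable_names.index(self.ratio_variable)
            return self.variable_axis_correlations()[idx, :]
        if self.ratio_correlations is not None:
            return self.ratio_correlations
        raise ValueError("no ratio information in this PCPCA result")

    def ratio_axis_ranking(self) -> np.ndarray:
        """Axes ordered by |correlation with the induction ratio|.  The
        sqrt(eigenvalue) scaling automatically ranks null-space axes
        (eigenvalue ~0, which arise whenever there are more variables than
        promoters) last: they carry no variance and their eigenvector
        entries are arbitrary."""
        return np.argsort(-np.abs(self.ratio_loadings()), kind="stable")


def run_pcpca(
    matrix: PromoterTFBSMatrix, ratio_as_variable: bool = True
) -> PCPCAResult:
    """PCA of the correlation matrix of motif counts (+ the induction ratio).

    Every variable is standardized to zero mean and unit variance across
    promoters; the eigendecomposition of the variable correlation matrix
    yields eigenvalues (summing to the number of retained variables), loadings
    and observation scores.  Zero-variance variables are dropped with a
    warning.  Axis signs are fixed so the ratio variable loads positively
    (falling back to a positive dominant component on ratio-free axes).
    """
    if matrix.n_promoters < 3:
        raise ValueError("need at least 3 promoters for PCA")
    X = matrix.counts.astype(float)
    names = list(matrix.motif_ids)
    if ratio_as_variable:
        X = np.column_stack([X, matrix.log2_ratios])
        names = names + [RATIO_VARIABLE]
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance variable(s): {dropped[:5]}",
            stacklevel=2,
        )
    if ratio_as_variable and RATIO_VARIABLE in dropped:
        raise ValueError("induction ratio has zero variance across promoters")
    kept_names = [n for n, k in zip(names, keep) if k]
    if len(kept_names) < 2:
        raise ValueError("need >=2 variables with non-zero variance")
    Xk = X[:, keep]
    corr = np.corrcoef(Xk, rowvar=False)
    eigenvalues, vectors = np.linalg.eigh(corr)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    vectors = vectors[:, order]
    eigenvalues[(eigenvalues < 0) & (eigenvalues > -1e-9)] = 0.0

    ratio_idx = kept_names.index(RATIO_VARIABLE) if ratio_as_variable else None
    for j in range(vectors.shape[1]):
        if ratio_idx is not None and abs(vectors[ratio_idx, j]) > 1e-12:
            flip = vectors[ratio_idx, j] < 0
        else:
            dominant = int(np.argmax(np.abs(vectors[:, j])))
            flip = vectors[dominant, j] < 0
        if flip:
            vectors[:, j] = -vectors[:, j]

    Z = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0, ddof=1)
    scores = Z @ vectors

    result = PCPCAResult(
        eigenvalues=eigenvalues,
        loadings=vectors,
        scores=scores,
        variable_names=kept_names,
        dropped_variables=dropped,
        promoter_ids=list(matrix.promoter_ids),
        groups=list(matrix.groups),
        ratio_variable=RATIO_VARIABLE if ratio_as_variable else None,
    )
    if not ratio_as_variable:
        ratio = matrix.log2_ratios
        if ratio.std(ddof=1) == 0:
            warnings.warn(
                "induction ratio is constant; supplementary ratio correlations "
                "are unavailable",
                stacklevel=2,
            )
        else:
            result.ratio_correlations = np.array(
                [
                    _pearson(ratio, scores[:, j]) if scores[:, j].std(ddof=1) > 0 else 0.0
                    for j in range(scores.shape[1])
                ]
            )
    return result


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def select_ratio_axes(result: PCPCAResult, k: int = 2) -> list[int]:
    """The k axes most associated with the induction ratio (0-based indices,
    descending |ratio loading|)."""
    if k < 1 or k > result.n_axes:
        raise ValueError(f"k must be in [1, {result.n_axes}], got {k}")
    return [int(i) for i in result.ratio_axis_ranking()[:k]]


def project_promoters(result: PCPCAResult, axes: Sequence[int]) -> pd.DataFrame:
    """Per-promoter coordinates on a pair of axes with the group label
    (the scatter behind an induced-vs-repressed promoter plot)."""
    if len(axes) != 2:
        raise ValueError("axes must be a pair")
    i, j = axes
    if not (0 <= i < result.n_axes and 0 <= j < result.n_axes):
        raise ValueError(f"axis index out of range (0..{result.n_axes - 1})")
    return pd.DataFrame(
        {
            "promoter_id": result.promoter_ids,
            f"axis_{i + 1}": result.scores[:, i],
            f"axis_{j + 1}": result.scores[:, j],
            "group": result.groups,
        }
    )


@dataclass
class TFBSContrastResult:
    """Per-motif induced-vs-repressed contrast (pooled-variance Student t,
    two-sided, Bonferroni over the motifs actually testable)."""

    motif_ids: list[str]
    mean_induced: np.ndarray
    mean_repressed: np.ndarray
    t: np.ndarray
    p_raw: np.ndarray
    p_bonferroni: np.ndarray
    testable: np.ndarray
    df: int
    n_tested: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motif_id": self.motif_ids,
                "mean_induced": self.mean_induced,
                "mean_repressed": self.mean_repressed,
                "t": self.t,
                "p_raw": self.p_raw,
                "p_bonferroni": self.p_bonferroni,
                "testable": self.testable,
            }
        ).sort_values(["p_bonferroni", "p_raw", "motif_id"], kind="stable")

    def motif_result(self, motif_id: str) -> dict:
        i = self.motif_ids.index(motif_id)
        return {
            "motif_id": motif_id,
            "mean_induced": float(self.mean_induced[i]),
            "mean_repressed": float(self.mean_repressed[i]),
            "t": float(self.t[i]),
            "p_raw": float(self.p_raw[i]),
            "p_bonferroni": float(self.p_bonferroni[i]),
            "testable": bool(self.testable[i]),
        }


def tfbs_contrast(
    matrix: PromoterTFBSMatrix,
    induced_ids: Sequence[str],
    repressed_ids: Sequence[str],
) -> TFBSContrastResult:
    """Student t contrast of motif counts between induced and repressed
    promoters.  Pooled variance, df = n1 + n2 - 2; motifs with zero variance
    in both groups are reported as untestable; Bonferroni multiplies raw p by
    the number of testable motifs."""
    rows_a = [matrix.promoter_index(p) for p in induced_ids]
    rows_b = [matrix.promoter_index(p) for p in repressed_ids]
    n1, n2 = len(rows_a), len(rows_b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 promoters")
    A = matrix.counts[rows_a].astype(float)
    B = matrix.counts[rows_b].astype(float)
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    var_a = A.var(axis=0, ddof=1)
    var_b = B.var(axis=0, ddof=1)
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * var_a + (n2 - 1) * var_b) / df
    testable = pooled > 0
    se = np.sqrt(pooled * (1 / n1 + 1 / n2))
    t = np.zeros(matrix.n_motifs)
    p = np.ones(matrix.n_motifs)
    np.divide(mean_a - mean_b, se, out=t, where=testable)
    p[testable] = 2 * stats.t.sf(np.abs(t[testable]), df)
    n_tested = int(testable.sum())
    p_bonf = np.minimum(p * max(n_tested, 1), 1.0)
    p_bonf[~testable] = np.nan
    t_out = np.where(testable, t, np.nan)
    p_out = np.where(testable, p, np.nan)
    return TFBSContrastResult(
        motif_ids=list(matrix.motif_ids),
        mean_induced=mean_a,
        mean_repressed=mean_b,
        t=t_out,
        p_raw=p_out,
        p_bonferroni=p_bonf,
        testable=testable,
        df=df,
        n_tested=n_tested,
    )


def tfbs_ratio_correlation(
    matrix: PromoterTFBSMatrix, motif_id: str
) -> tuple[float, float]:
    """Pearson correlation between a motif family's promoter counts and the
    log2 induction ratio, with the p value from the t transform (n - 2 df)."""
    j = matrix.motif_index(motif_id)
    counts = matrix.counts[:, j].astype(float)
    if counts.std(ddof=1) == 0:
        raise ValueError(f"motif {motif_id!r} has zero count variance")
    if matrix.log2_ratios.std(ddof=1) == 0:
        raise ValueError("induction ratio has zero variance")
    r, p = stats.pearsonr(counts, matrix.log2_ratios)
    return float(r), float(p)


_VALID_BASES = set("ACGTN")


def promoter_composition(
    source: str | Path | Iterable,
) -> pd.DataFrame:
    """Per-promoter GC fraction and CpG observed/expected from FASTA.

    GC = (G+C)/(A+C+G+T); CpG o/e = count(CG) * L / (count(C) * count(G)) with
    L the number of unambiguous (ACGT) bases; N bases are excluded from the
    denominators.  CpG o/e is NaN when a sequence has no C or no G.
    """
    if isinstance(source, (str, Path)):
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(source), "fasta")]
    else:
        records = [
            (rec.id, str(rec.seq)) if hasattr(rec, "seq") else (rec[0], str(rec[1]))
            for rec in source
        ]
    rows = []
    for name, seq in records:
        s = seq.upper()
        if not s:
            raise ValueError(f"promoter {name!r}: empty sequence")
        invalid = set(s) - _VALID_BASES
        if invalid:
            raise ValueError(
                f"promoter {name!r}: invalid base(s) {sorted(invalid)}"
            )
        a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
        length = a + c + g + t
        if length == 0:
            raise ValueError(f"promoter {name!r}: no unambiguous bases")
        cg = s.count("CG")
        oe = cg * length / (c * g) if c > 0 and g > 0 else math.nan
        rows.append(
            {"promoter_id": name, "gc_fraction": (g + c) / length, "cpg_obs_exp": oe}
        )
    return pd.DataFrame(rows, columns=["promoter_id", "gc_fraction", "cpg_obs_exp"])
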