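"""Seeded generators of expression matrices, annotations, term catalogs and
promoter TFBS count matrices with the statistical structure of an
IVF/embryo-culture placental transcriptome study.

The default configuration encodes the study conditions this package analyses:
one pooled array per condition (in vivo control plus two in vitro culture
groups), a minority of transcripts perturbed per in vitro condition, roughly
two thirds of perturbed transcripts repressed genome-wide while X-linked and
imprinted transcripts are skewed the opposite way (two thirds induced),
paternally expressed imprinted genes mostly induced, Y-linked marker
transcripts left untouched (sex-balanced pools), and one focal TFBS family
whose per-promoter motif counts increase with the log2 induction ratio.

Every generator is a pure function of its :class:`SimulationConfig` seed; the
same seed yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_model import (
    CHROMOSOMES,
    CONTROL_CONDITION,
    IN_VITRO_CONDITIONS,
    ExpressionMatrix,
    GeneAnnotation,
    ImprintStatus,
    Term,
    TermCatalog,
)
from .pcpca import PromoterTFBSMatrix

# Per-chromosome sampling weights, roughly proportional to mouse gene content
# (autosomes 1..19 in decreasing size, X ~5-6% of genes, few Y and MT genes).
DEFAULT_CHROMOSOME_WEIGHTS: dict[str, float] = {
    "1": 0.072, "2": 0.070, "3": 0.052, "4": 0.060, "5": 0.058,
    "6": 0.054, "7": 0.056, "8": 0.049, "9": 0.049, "10": 0.047,
    "11": 0.052, "12": 0.042, "13": 0.043, "14": 0.041, "15": 0.039,
    "16": 0.035, "17": 0.037, "18": 0.032, "19": 0.026,
    "X": 0.055, "Y": 0.003, "MT": 0.001,
}

#: Classes used for ground-truth and classification interchange.
INDUCED, REPRESSED, UNCHANGED = "induced", "repressed", "unchanged"

# Sub-stream identifiers so each generator draws from an independent,
# reproducible stream derived from the master seed.
_STREAM_DATASET = 0
_STREAM_PROMOTERS = 1
_STREAM_TERMS = 2
_STREAM_RATIOS = 3


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults are the study conditions: 2/3 of changed transcripts repressed
    genome-wide (``down_fraction_global``), 2/3 of changed X-linked and
    imprinted transcripts induced (``up_fraction_x``/``up_fraction_imprinted``),
    89 imprinted genes of which 27/89 paternally expressed and 24/89 of unknown
    allele, 60 promoters x 152 motif families with one focal family linked to
    the induction ratio.
    """

    n_transcripts: int = 20_000
    chromosome_weights: dict[str, float] | None = None
    n_imprinted: int = 89
    paternal_fraction: float = 27 / 89
    unknown_allele_fraction: float = 24 / 89
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    p_changed: float = 0.08
    shared_change_fraction: float = 0.7
    down_fraction_global: float = 2 / 3
    up_fraction_x: float = 2 / 3
    up_fraction_imprinted: float = 2 / 3
    effect_log2_mean: float = 1.5
    effect_log2_sd: float = 0.5
    min_effect_log2: float = 1.05
    noise_sd: float = 0.25
    duplicate_probe_fraction: float = 0.10
    n_y_markers: int = 3
    n_promoters: int = 60
    n_motifs: int = 152
    motif_base_rate: float = 2.0
    focal_motifs: dict[str, float] = field(default_factory=lambda: {"V$FKHD": 0.5})
    n_terms: int = 150
    term_size_range: tuple[int, int] = (10, 40)
    n_enriched_terms: int = 3
    enriched_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        for name in (
            "paternal_fraction", "unknown_allele_fraction", "p_changed",
            "shared_change_fraction",
            "down_fraction_global", "up_fraction_x", "up_fraction_imprinted",
            "duplicate_probe_fraction", "enriched_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.paternal_fraction + self.unknown_allele_fraction > 1.0:
            raise ValueError("paternal + unknown-allele fractions exceed 1")
        for name in ("baseline_sd", "effect_log2_sd", "motif_base_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_imprinted > self.n_transcripts:
            raise ValueError("n_imprinted exceeds n_transcripts")
        if self.n_imprinted < 0 or self.n_y_markers < 0:
            raise ValueError("counts must be non-negative")
        for beta in self.focal_motifs.values():
            if not math.isfinite(beta):
                raise ValueError("focal motif link coefficients must be finite")
        if len(self.focal_motifs) > self.n_motifs:
            raise ValueError("more focal motifs than n_motifs")
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi):
            raise ValueError("term_size_range must satisfy 1 <= lo <= hi")
        if self.chromosome_weights is not None:
            unknown = set(self.chromosome_weights) - set(CHROMOSOMES)
            if unknown:
                raise ValueError(f"unknown chromosome(s) in weights: {sorted(unknown)}")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class GroundTruth:
    """True perturbation classes per transcript and per in vitro condition,
    plus the marker transcripts and the motif link coefficients."""

    transcript_ids: list[str]
    gene_symbols: list[str]
    classes: dict[str, np.ndarray]
    marker_ids: tuple[str, ...]
    motif_betas: dict[str, float]

    def class_counts(self, condition: str) -> dict[str, int]:
        arr = self.classes[condition]
        return {c: int(np.sum(arr == c)) for c in (INDUCED, REPRESSED, UNCHANGED)}

    def induced_genes(self, condition: str) -> set[str]:
        arr = self.classes[condition]
        return {g for g, c in zip(self.gene_symbols, arr) if c == INDUCED}


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, list[GeneAnnotation], GroundTruth]:
    """Generate a control + two in vitro condition expression matrix.

    The control column is Normal(baseline_mean, baseline_sd) per transcript.
    Each in vitro column is control + delta + Normal(0, noise_sd), where delta
    is zero with probability 1 - p_changed and otherwise a signed magnitude
    |Normal(effect_log2_mean, effect_log2_sd)| floored at ``min_effect_log2``
    so a perturbed transcript always crosses the strict two-fold threshold in
    the noiseless limit.  The sign is positive with probability
    ``up_fraction_x`` on the X, ``up_fraction_imprinted`` for imprinted genes,
    and ``1 - down_fraction_global`` elsewhere.  A fraction
    ``shared_change_fraction`` of perturbations is common to both in vitro
    conditions (shared fertilization / culture stress), which makes the two
    in vitro columns more inter-correlated than either is with the control;
    the marginal per-condition perturbation rate stays exactly ``p_changed``.
    Dedicated Y-linked marker transcripts are never perturbed.
    """
    rng = config._rng(_STREAM_DATASET)
    n = config.n_transcripts
    n_markers = min(config.n_y_markers, max(n - 1, 0))
    n_regular = n - n_markers
    n_dup = int(round(config.duplicate_probe_fraction * n_regular))
    n_genes = max(n_regular - n_dup, 1)
    n_dup = n_regular - n_genes
    if config.n_imprinted > n_genes:
        raise ValueError("n_imprinted exceeds the number of simulated genes")

    weights = dict(config.chromosome_weights or DEFAULT_CHROMOSOME_WEIGHTS)
    labels = [c for c in CHROMOSOMES if weights.get(c, 0.0) > 0]
    probs = np.array([weights[c] for c in labels], dtype=float)
    probs /= probs.sum()

    gene_chrom = rng.choice(np.array(labels, dtype=object), size=n_genes, p=probs)
    gene_pos = rng.integers(1, 171_000_000, size=n_genes)
    # note: np.full would coerce the str-subclass enum to a plain string
    gene_status = np.empty(n_genes, dtype=object)
    gene_status[:] = ImprintStatus.NOT_IMPRINTED
    autosomal = np.flatnonzero(~np.isin(gene_chrom, ("X", "Y", "MT")))
    if config.n_imprinted > len(autosomal):
        raise ValueError("not enough autosomal genes to place imprinted genes")
    if config.n_imprinted:
        imp = rng.choice(autosomal, size=config.n_imprinted, replace=False)
        n_pat = int(round(config.paternal_fraction * config.n_imprinted))
        n_unk = int(round(config.unknown_allele_fraction * config.n_imprinted))
        n_unk = min(n_unk, config.n_imprinted - n_pat)
        gene_status[imp[:n_pat]] = ImprintStatus.PATERNAL
        gene_status[imp[n_pat:n_pat + n_unk]] = ImprintStatus.UNKNOWN_ALLELE
        gene_status[imp[n_pat + n_unk:]] = ImprintStatus.MATERNAL

    gene_of = np.concatenate(
        [np.arange(n_genes), rng.integers(0, n_genes, size=n_dup)]
    )
    gene_of = gene_of[rng.permutation(n_regular)]

    transcript_ids = [f"TX{i:06d}" for i in range(n_regular)]
    chrom = gene_chrom[gene_of]
    pos = gene_pos[gene_of]
    status = gene_status[gene_of]
    symbols = np.array([f"G{g:05d}" for g in gene_of], dtype=object)

    # Y-linked marker transcripts: equal means across conditions by design.
    marker_ids = tuple(f"YMARK{j:02d}" for j in range(n_markers))
    if n_markers:
        transcript_ids += list(marker_ids)
        chrom = np.concatenate([chrom, np.full(n_markers, "Y", dtype=object)])
        pos = np.concatenate([pos, rng.integers(1, 91_000_000, size=n_markers)])
        marker_status = np.empty(n_markers, dtype=object)
        marker_status[:] = ImprintStatus.NOT_IMPRINTED
        status = np.concatenate([status, marker_status])
        symbols = np.concatenate(
            [symbols, np.array([f"Uty_like_{j}" for j in range(n_markers)], dtype=object)]
        )

    marker_mask = np.zeros(n, dtype=bool)
    marker_mask[n_regular:] = True
    is_x = chrom == "X"
    is_imprinted = np.array([s.is_imprinted for s in status])

    control = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    columns = [control]
    classes: dict[str, np.ndarray] = {}
    p_up = np.where(
        is_imprinted,
        config.up_fraction_imprinted,
        np.where(is_x, config.up_fraction_x, 1.0 - config.down_fraction_global),
    )
    def _signed_magnitude(mask: np.ndarray) -> np.ndarray:
        up = rng.random(n) < p_up
        magnitude = np.maximum(
            np.abs(rng.normal(config.effect_log2_mean, config.effect_log2_sd, size=n)),
            config.min_effect_log2,
        )
        return np.where(mask, np.where(up, magnitude, -magnitude), 0.0)

    # Perturbations common to both in vitro groups (shared fertilization /
    # culture stress) plus condition-specific ones; the conditional own-change
    # probability keeps the marginal per-condition rate at exactly p_changed.
    p_common = config.p_changed * config.shared_change_fraction
    changed_common = (rng.random(n) < p_common) & ~marker_mask
    delta_common = _signed_magnitude(changed_common)
    p_own = (
        config.p_changed * (1.0 - config.shared_change_fraction) / (1.0 - p_common)
        if p_common < 1.0
        else 0.0
    )
    for condition in IN_VITRO_CONDITIONS:
        changed_own = (rng.random(n) < p_own) & ~marker_mask & ~changed_common
        delta = delta_common + _signed_magnitude(changed_own)
        noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
        columns.append(control + delta + noise)
        classes[condition] = np.where(
            delta > 0, INDUCED, np.where(delta < 0, REPRESSED, UNCHANGED)
        )

    matrix = ExpressionMatrix(
        transcript_ids,
        [CONTROL_CONDITION, *IN_VITRO_CONDITIONS],
        np.column_stack(columns),
    )
    annotations = [
        GeneAnnotation(
            transcript_id=tid,
            gene_symbol=str(sym),
            chromosome=str(ch),
            position_bp=int(p),
            imprint_status=st,
        )
        for tid, sym, ch, p, st in zip(transcript_ids, symbols, chrom, pos, status)
    ]
    truth = GroundTruth(
        transcript_ids=list(transcript_ids),
        gene_symbols=[str(s) for s in symbols],
        classes=classes,
        marker_ids=marker_ids,
        motif_betas=dict(config.focal_motifs),
    )
    return matrix, annotations, truth


def motif_names(config: SimulationConfig) -> list[str]:
    """Motif family identifiers: the focal families first, generic fillers after."""
    names = list(config.focal_motifs)
    i = 0
    while len(names) < config.n_motifs:
        candidate = f"V$M{i:03d}"
        if candidate not in config.focal_motifs:
            names.append(candidate)
        i += 1
    return names


def default_promoter_ratios(config: SimulationConfig) -> np.ndarray:
    """Log2 induction ratios for a promoter set mirroring the extreme-gene
    design: 27/60 induced and 33/60 repressed promoters with |log2 ratio|
    drawn uniformly in [1, 3]."""
    rng = config._rng(_STREAM_RATIOS)
    n = config.n_promoters
    n_induced = int(round(n * 27 / 60))
    magnitude = rng.uniform(1.0, 3.0, size=n)
    sign = np.where(np.arange(n) < n_induced, 1.0, -1.0)
    return sign * magnitude


def simulate_promoters(
    config: SimulationConfig, log2_ratios: np.ndarray
) -> PromoterTFBSMatrix:
    """Generate a promoter x motif count matrix with Poisson counts.

    count(motif m, promoter p) ~ Poisson(motif_base_rate * exp(beta_m * ratio_p))
    with beta_m = 0 for every non-focal motif family.
    """
    ratios = np.asarray(log2_ratios, dtype=float)
    if ratios.ndim != 1:
        raise ValueError("log2_ratios must be one-dimensional")
    if ratios.size and not np.all(np.isfinite(ratios)):
        raise ValueError("log2 induction ratios must be finite")
    rng = config._rng(_STREAM_PROMOTERS)
    names = motif_names(config)
    betas = np.array([config.focal_motifs.get(m, 0.0) for m in names])
    lam = config.motif_base_rate * np.exp(np.outer(ratios, betas))
    counts = rng.poisson(lam) if ratios.size else np.zeros((0, len(names)), dtype=int)
    groups = [
        "induced" if r > 0 else ("repressed" if r < 0 else "unlabeled")
        for r in ratios
    ]
    return PromoterTFBSMatrix(
        promoter_ids=[f"PR{i:03d}" for i in range(ratios.size)],
        gene_symbols=[f"PG{i:03d}" for i in range(ratios.size)],
        log2_ratios=ratios,
        groups=groups,
        motif_ids=names,
        counts=np.asarray(counts, dtype=int),
    )


def simulate_term_catalog(
    config: SimulationConfig,
    truth: GroundTruth,
    condition: str = "ivf_g1g2",
) -> tuple[TermCatalog, tuple[str, ...]]:
    """Generate an annotation-term catalog over the simulated gene universe.

    The first ``n_enriched_terms`` terms draw at least ``enriched_fraction`` of
    their members from truly induced genes; all remaining members, and every
    other term, are drawn uniformly from the universe.  Returns the catalog
    together with the planted (enriched) term ids.
    """
    rng = config._rng(_STREAM_TERMS)
    universe = sorted(set(truth.gene_symbols))
    induced = sorted(truth.induced_genes(condition))
    rest = sorted(set(universe) - set(induced))
    lo, hi = config.term_size_range
    if hi > len(universe):
        raise ValueError("term_size_range upper bound exceeds gene universe")
    terms: dict[str, Term] = {}
    enriched_ids: list[str] = []
    for t in range(config.n_terms):
        term_id = f"T{t:03d}"
        size = int(rng.integers(lo, hi + 1))
        if t < config.n_enriched_terms and induced:
            k_induced = min(math.ceil(config.enriched_fraction * size), len(induced))
            members = set(rng.choice(induced, size=k_induced, replace=False))
            pool = [g for g in rest if g not in members]
            k_rest = min(size - k_induced, len(pool))
            if k_rest:
                members |= set(rng.choice(pool, size=k_rest, replace=False))
            enriched_ids.append(term_id)
        else:
            members = set(rng.choice(universe, size=size, replace=False))
        terms[term_id] = Term(term_id, f"synthetic term {t}", frozenset(members))
    return TermCatalog(terms), tuple(enriched_ids)
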