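"""The four-stage candidate-neoantigen filter cascade.

Stage order: binder selection feeds (a) expression, then (b) MS evidence;
(c) similarity against the curated neoantigen database and (d) the strict
affinity/abundance screen act as two parallel terminal screens on the MS
survivors. Every stage returns a subset of its input, so stage counts are
non-increasing along the cascade.

(a) keeps candidates whose source transcript/gene is expressed (TPM strictly
above a cutoff, default 0 — the intent is removing peptides from unexpressed
genes). (b) keeps candidates supported by an MS-identified peptide whose
shared residues cover at least one mutant position. (c) matches candidates
whose best similarity against the curated database falls in a configurable
band (default 20..100) and reports the matching ratio. (d) keeps class I
candidates with IC50 <= 34 nM and abundance >= 33 TPM (both inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .alignment import LocalAlignment, similarity_score
from .models import STANDARD_AA, ExpressionTable, MSEvidence, NeoDBEntry
from .sequences import MutantProtein
from .windows import CandidatePeptide

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    tpm_min_exclusive: float = 0.0
    strict_ic50_max_nM: float = 34.0
    strict_tpm_min: float = 33.0
    sim_threshold_low: float = 20.0
    sim_threshold_high: float = 100.0
    ms_min_overlap: int = 7
    drop_wildtype: bool = False
    expression_enabled: bool = True
    ms_enabled: bool = True
    neodb_enabled: bool = True
    strict_enabled: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.sim_threshold_low <= self.sim_threshold_high <= 100):
            raise ValueError("similarity thresholds must satisfy 0 <= low <= high <= 100")
        if self.strict_ic50_max_nM <= 0 or self.strict_tpm_min < 0 or self.ms_min_overlap < 1:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class AnnotatedCandidate:
    """A candidate carrying the per-allele binding record and the annotations
    the cascade attaches (TPM, supporting MS peptides, best db similarity)."""

    peptide: CandidatePeptide
    allele: str
    ic50_nM: float
    rank_pct: float
    category: str
    tpm: float | None = None
    ms_support: tuple[str, ...] = ()
    best_similarity: float | None = None
    best_db_peptide: str | None = None


@dataclass(frozen=True)
class SimilarityHit:
    query: str
    subject: NeoDBEntry
    aln_score: int
    similarity: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]

    def __post_init__(self) -> None:
        if not (0 <= self.similarity <= 100):
            raise ValueError(f"similarity {self.similarity} outside [0, 100]")


@dataclass
class StageResult:
    name: str
    n_in: int
    n_out: int
    removed_reasons: dict[str, int] = field(default_factory=dict)


def matching_ratio(matched: int, compared: int) -> float | None:
    """100 * matched / compared, rounded to 2 decimals; None when nothing was
    compared (undefined, never reported as 0)."""
    if compared == 0:
        return None
    if not (0 <= matched <= compared):
        raise ValueError(f"matched {matched} outside 0..{compared}")
    return round(100.0 * matched / compared, 2)


# ---------------------------------------------------------------------------
# (a) expression


def filter_expression(candidates: Sequence[AnnotatedCandidate],
                      expression: ExpressionTable,
                      cfg: FilterConfig,
                      transcript_of: Mapping[str, str] | None = None,
                      gene_of: Mapping[str, str] | None = None,
                      stage: StageResult | None = None,
                      ) -> list[AnnotatedCandidate]:
    """Keep candidates whose source variant is expressed (TPM > cutoff).

    The variant's transcript id is looked up first, then its gene symbol.
    Variants absent from the table are treated as unexpressed and counted
    under their own reason.
    """
    transcript_of = transcript_of or {}
    gene_of = gene_of or {}
    kept: list[AnnotatedCandidate] = []
    reasons: dict[str, int] = {}
    for c in candidates:
        vid = c.peptide.source_variant
        tpm = None
        for key in (transcript_of.get(vid), gene_of.get(vid) or c.peptide.gene, vid):
            if key and key in expression:
                tpm = expression.get(key)
                break
        if tpm is None:
            reasons["no expression data"] = reasons.get("no expression data", 0) + 1
            continue
        if tpm > cfg.tpm_min_exclusive:
            kept.append(replace(c, tpm=tpm))
        else:
            reasons["unexpressed"] = reasons.get("unexpressed", 0) + 1
    if stage is not None:
        stage.name, stage.n_in, stage.n_out = "expression", len(candidates), len(kept)
        stage.removed_reasons = reasons
    return kept


# ---------------------------------------------------------------------------
# (b) MS evidence


def _supports(candidate: CandidatePeptide, ms_pep: str, min_overlap: int,
              mutant_seq: str | None) -> bool:
    """Does one MS-identified peptide support the candidate?

    Substring containment in either direction qualifies if the shared residues
    cover a mutant position; otherwise the two must overlap by >= min_overlap
    residues when located on the same mutant protein, again covering a mutant
    position.
    """
    cand = candidate.sequence
    if cand in ms_pep:
        return True  # shared region is the whole candidate, mut_positions non-empty
    idx = cand.find(ms_pep)
    if idx >= 0:
        shared = set(range(idx + 1, idx + len(ms_pep) + 1))
        return bool(shared & candidate.mut_positions)
    if mutant_seq is None or min_overlap < 1:
        return False
    # co-location: place both on the mutant protein and intersect intervals
    c_lo = candidate.start
    c_hi = candidate.start + candidate.k - 1
    mut_abs = {candidate.start + p - 1 for p in candidate.mut_positions}
    start = 0
    while True:
        pos = mutant_seq.find(ms_pep, start)
        if pos < 0:
            return False
        p_lo, p_hi = pos + 1, pos + len(ms_pep)
        lo, hi = max(c_lo, p_lo), min(c_hi, p_hi)
        if hi - lo + 1 >= min_overlap and any(lo <= a <= hi for a in mut_abs):
            return True
        start = pos + 1


def filter_ms(candidates: Sequence[AnnotatedCandidate], ms: MSEvidence,
              cfg: FilterConfig,
              mutants: Mapping[str, MutantProtein] | None = None,
              stage: StageResult | None = None) -> list[AnnotatedCandidate]:
    """Keep candidates with protein-level (MS) support covering a mutant site."""
    mutants = mutants or {}
    kept: list[AnnotatedCandidate] = []
    n_unsupported = 0
    for c in candidates:
        mseq = mutants.get(c.peptide.source_variant)
        support = tuple(sorted(
            p for p in ms.peptides
            if _supports(c.peptide, p, cfg.ms_min_overlap,
                         mseq.sequence if mseq else None)
        ))
        if support:
            kept.append(replace(c, ms_support=support))
        else:
            n_unsupported += 1
    if stage is not None:
        stage.name, stage.n_in, stage.n_out = "ms", len(candidates), len(kept)
        stage.removed_reasons = {"no MS support": n_unsupported}
    return kept


# ---------------------------------------------------------------------------
# (c) curated-database similarity


def similarity_search(query: str, db: Sequence[NeoDBEntry]) -> list[SimilarityHit]:
    """Best local alignment of the query against every database peptide,
    sorted by similarity descending (score as tie-break)."""
    if not db:
        raise ValueError("similarity search against an empty database")
    if set(query) - STANDARD_AA:
        raise ValueError(f"query {query!r} contains non-standard residues")
    hits = []
    for entry in db:
        sim, aln = similarity_score(query, entry.peptide)
        hits.append(SimilarityHit(
            query=query, subject=entry, aln_score=aln.score, similarity=sim,
            query_span=aln.query_span, subject_span=aln.subject_span,
        ))
    hits.sort(key=lambda h: (-h.similarity, -h.aln_score, h.subject.peptide))
    return hits


def filter_neodb(candidates: Sequence[AnnotatedCandidate], db: Sequence[NeoDBEntry],
                 cfg: FilterConfig, stage: StageResult | None = None,
                 ) -> tuple[list[AnnotatedCandidate], float | None]:
    """Candidates whose best similarity falls within the configured band, plus
    the matching ratio (percentage, 2 decimals; None for an empty input)."""
    matched: list[AnnotatedCandidate] = []
    cache: dict[str, tuple[float, str]] = {}
    for c in candidates:
        seq = c.peptide.sequence
        if seq not in cache:
            hits = similarity_search(seq, db)
            cache[seq] = (hits[0].similarity, hits[0].subject.peptide)
        best, best_pep = cache[seq]
        annotated = replace(c, best_similarity=best, best_db_peptide=best_pep)
        if cfg.sim_threshold_low <= best <= cfg.sim_threshold_high:
            matched.append(annotated)
    ratio = matching_ratio(len(matched), len(candidates))
    if stage is not None:
        stage.name, stage.n_in, stage.n_out = "neodb", len(candidates), len(matched)
        stage.removed_reasons = {"below similarity band": len(candidates) - len(matched)}
    return matched, ratio


# ---------------------------------------------------------------------------
# (d) strict affinity/abundance screen (class I only)


def filter_strict(candidates: Sequence[AnnotatedCandidate], cfg: FilterConfig,
                  stage: StageResult | None = None) -> list[AnnotatedCandidate]:
    """Keep class I candidates with IC50 <= max and TPM >= min, both inclusive.
    Class II candidates are skipped with a warning, not an error."""
    kept: list[AnnotatedCandidate] = []
    reasons: dict[str, int] = {}
    for c in candidates:
        if c.peptide.mhc_class != "I":
            logger.warning("strict filter skipping class II candidate %s",
                           c.peptide.sequence)
            reasons["class II skipped"] = reasons.get("class II skipped", 0) + 1
            continue
        if c.tpm is None:
            reasons["no TPM attached"] = reasons.get("no TPM attached", 0) + 1
            continue
        if c.ic50_nM <= cfg.strict_ic50_max_nM and c.tpm >= cfg.strict_tpm_min:
            kept.append(c)
        else:
            reasons["failed thresholds"] = reasons.get("failed thresholds", 0) + 1
    if stage is not None:
        stage.name, stage.n_in, stage.n_out = "strict", len(candidates), len(kept)
        stage.removed_reasons = reasons
    return kept
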