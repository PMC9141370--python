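"""Mutation-anchored k-mer window extraction.

For a mutant protein of length L with novel region [a, b] (1-based), the
windows of length k that contain at least one novel residue are exactly the
substrings starting at s in [max(1, a-k+1), min(b, L-k+1)] — the window is
taken "k-1 in front of the mutation site" and slid with stride 1 until the
site would fall out. Class I uses k in 8..11, class II k in 15..30.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .models import STANDARD_AA
from .sequences import MutantProtein, ReferenceProteome

logger = logging.getLogger(__name__)

CLASS_I_RANGE = (8, 11)
CLASS_II_RANGE = (15, 30)


@dataclass(frozen=True)
class CandidatePeptide:
    sequence: str
    k: int
    start: int  # 1-based start in the mutant protein
    mut_positions: frozenset[int]  # window-relative 1-based novel positions
    source_variant: str
    mhc_class: str  # "I" | "II"
    var_class: str = ""
    gene: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != self.k:
            raise ValueError("sequence length disagrees with k")
        lo, hi = CLASS_I_RANGE if self.mhc_class == "I" else CLASS_II_RANGE
        if not (lo <= self.k <= hi):
            raise ValueError(f"k={self.k} outside class {self.mhc_class} range {lo}-{hi}")
        if not self.mut_positions:
            raise ValueError("window contains no mutant position")


@dataclass
class ExtractionStats:
    n_windows: int = 0
    n_dropped_nonstandard: int = 0
    n_deduplicated: int = 0
    too_short: list[str] = field(default_factory=list)


def extract_windows(mutant: MutantProtein, k_min: int, k_max: int, mhc_class: str,
                    stats: ExtractionStats | None = None) -> list[CandidatePeptide]:
    """All k-mers (k_min <= k <= k_max, stride 1) intersecting the novel region.

    Windows containing non-standard residues (X, U, ...) are dropped and
    counted; duplicates on (sequence, k) within this variant are collapsed
    keeping first-start provenance. A protein shorter than k_min yields an
    empty list (logged), not an error.
    """
    if k_min > k_max:
        raise ValueError(f"k_min {k_min} > k_max {k_max}")
    stats = stats if stats is not None else ExtractionStats()
    seq, (a, b) = mutant.sequence, mutant.mut_region
    L = len(seq)
    if L < k_min:
        stats.too_short.append(mutant.source_variant)
        logger.info("%s: length %d below k_min %d", mutant.source_variant, L, k_min)
        return []
    out: list[CandidatePeptide] = []
    seen: set[tuple[str, int]] = set()
    for k in range(k_min, min(k_max, L) + 1):
        for s in range(max(1, a - k + 1), min(b, L - k + 1) + 1):
            window = seq[s - 1: s - 1 + k]
            if set(window) - STANDARD_AA:
                stats.n_dropped_nonstandard += 1
                continue
            key = (window, k)
            if key in seen:
                stats.n_deduplicated += 1
                continue
            seen.add(key)
            muts = frozenset(
                p - s + 1 for p in range(max(s, a), min(s + k - 1, b) + 1)
            )
            out.append(CandidatePeptide(
                sequence=window, k=k, start=s, mut_positions=muts,
                source_variant=mutant.source_variant, mhc_class=mhc_class,
                var_class=mutant.var_class.value, gene=mutant.gene,
            ))
            stats.n_windows += 1
    return out


def extract_all(mutants: Iterable[MutantProtein], mhc_class: str,
                stats: ExtractionStats | None = None) -> list[CandidatePeptide]:
    lo, hi = CLASS_I_RANGE if mhc_class == "I" else CLASS_II_RANGE
    out: list[CandidatePeptide] = []
    for m in mutants:
        out.extend(extract_windows(m, lo, hi, mhc_class, stats))
    return out


def drop_wildtype_windows(candidates: list[CandidatePeptide],
                          proteome: ReferenceProteome,
                          enabled: bool = True) -> list[CandidatePeptide]:
    """Optionally remove windows that occur verbatim in the reference proteome
    (possible for deletion/fusion junction windows whose novelty is positional)."""
    if not enabled:
        return list(candidates)
    kept = [c for c in candidates if not proteome.contains_subsequence(c.sequence)]
    removed = len(candidates) - len(kept)
    if removed:
        logger.info("dropped %d wild-type-identical windows", removed)
    return kept


def write_fasta(candidates: Iterable[CandidatePeptide], path: str | Path) -> None:
    """One record per candidate, '>variant_id|k|start' headers."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f">{c.source_variant}|{c.k}|{c.start}\n{c.sequence}\n")


_TSV_COLS = ["sequence", "k", "start", "mut_positions", "source_variant",
             "mhc_class", "var_class", "gene"]


def write_tsv(candidates: Iterable[CandidatePeptide], path: str | Path) -> None:
    rows = [{
        "sequence": c.sequence, "k": c.k, "start": c.start,
        "mut_positions": ",".join(map(str, sorted(c.mut_positions))),
        "source_variant": c.source_variant, "mhc_class": c.mhc_class,
        "var_class": c.var_class, "gene": c.gene,
    } for c in candidates]
    pd.DataFrame(rows, columns=_TSV_COLS).to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> list[CandidatePeptide]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [CandidatePeptide(
        sequence=r["sequence"], k=int(r["k"]), start=int(r["start"]),
        mut_positions=frozenset(int(x) for x in r["mut_positions"].split(",") if x),
        source_variant=r["source_variant"], mhc_class=r["mhc_class"],
        var_class=r["var_class"], gene=r["gene"],
    ) for _, r in df.iterrows()]
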