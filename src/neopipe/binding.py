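"""Peptide–HLA binding tables: %Rank-based binder classes, table parsing and a
deterministic mock predictor for offline runs.

Binder selection uses %Rank only; predicted IC50 values are carried through
untouched so the strict affinity/abundance screen can use them later.
Thresholds (percentile rank, lower = stronger):

* class I:  strong %Rank <= 0.5, weak 0.5 < %Rank <= 2
* class II: strong %Rank <= 2,   weak 2 < %Rank <= 10
"""

from __future__ import annotations

import hashlib
import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .windows import CandidatePeptide

logger = logging.getLogger(__name__)

STRONG_MAX = {"I": 0.5, "II": 2.0}
WEAK_MAX = {"I": 2.0, "II": 10.0}


def classify_binder(mhc_class: str, rank_pct: float) -> str:
    """Map a percentile rank to 'strong' | 'weak' | 'non' (boundaries inclusive)."""
    if rank_pct <= 0:
        raise ValueError(f"%Rank must be positive, got {rank_pct}")
    if mhc_class not in STRONG_MAX:
        raise ValueError(f"unknown MHC class {mhc_class!r}")
    if rank_pct <= STRONG_MAX[mhc_class]:
        return "strong"
    if rank_pct <= WEAK_MAX[mhc_class]:
        return "weak"
    return "non"


@dataclass(frozen=True)
class BindingRecord:
    peptide: str
    allele: str
    ic50_nM: float
    rank_pct: float
    mhc_class: str
    category: str = ""
    flagged_unknown: bool = False  # peptide not among submitted candidates

    def __post_init__(self) -> None:
        if self.ic50_nM <= 0 or self.rank_pct <= 0:
            raise ValueError("IC50 and %Rank must be positive")
        expected = classify_binder(self.mhc_class, self.rank_pct)
        if self.category and self.category != expected:
            raise ValueError(
                f"category {self.category!r} inconsistent with %Rank {self.rank_pct}"
            )
        if not self.category:
            object.__setattr__(self, "category", expected)


_ALLELE_I = re.compile(r"^HLA-([A-C])[*_:-]?(\d{2})[:_]?(\d{2})$")
_ALLELE_II = re.compile(r"^(D[PQR][AB]\d?)[*_-]?(\d{2})[:_]?(\d{2})$")


def normalize_allele(name: str) -> str:
    """Canonicalize mixed HLA notations.

    'HLA-A*03:01' / 'HLA-A03:01' / 'HLA-A_03_01' -> 'HLA-A*03:01';
    'DRB4_0103' -> 'DRB4*01:03'. Names that do not match the known shapes are
    returned verbatim (NetMHCIIpan heterodimer names pass through).
    """
    name = name.strip()
    m = _ALLELE_I.match(name)
    if m:
        return f"HLA-{m.group(1)}*{m.group(2)}:{m.group(3)}"
    compact = name.replace("*", "").replace(":", "").replace("-", "_")
    m2 = re.match(r"^(D[PQR][AB]\d?)_?(\d{2})(\d{2})$", compact)
    if m2:
        return f"{m2.group(1)}*{m2.group(2)}:{m2.group(3)}"
    return name


def parse_binding_table(path: str | Path, dialect: str = "generic_long",
                        known_peptides: set[str] | None = None) -> list[BindingRecord]:
    """Read a binding-affinity table.

    ``generic_long``: TSV with header peptide, allele, mhc_class, ic50_nM,
    rank_pct. ``netmhcpan_xls``: the predictor's tab-separated multi-allele
    layout (two header rows; per-allele nM/Rank column blocks). Categories are
    assigned on ingest; peptides absent from ``known_peptides`` are retained
    but flagged.
    """
    if dialect == "generic_long":
        return _parse_generic_long(path, known_peptides)
    if dialect == "netmhcpan_xls":
        return _parse_netmhcpan_xls(path, known_peptides)
    raise ValueError(f"unknown binding dialect {dialect!r}")


def _parse_generic_long(path: str | Path,
                        known: set[str] | None) -> list[BindingRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["peptide", "allele", "mhc_class", "ic50_nM", "rank_pct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    records, rejected = [], 0
    for _, row in df.iterrows():
        try:
            records.append(BindingRecord(
                peptide=row["peptide"].strip().upper(),
                allele=normalize_allele(row["allele"]),
                ic50_nM=float(row["ic50_nM"]), rank_pct=float(row["rank_pct"]),
                mhc_class=row["mhc_class"].strip(),
                flagged_unknown=(known is not None
                                 and row["peptide"].strip().upper() not in known),
            ))
        except (ValueError, AttributeError):
            rejected += 1
    if rejected:
        logger.warning("%s: rejected %d unparseable rows", path, rejected)
    return records


def _parse_netmhcpan_xls(path: str | Path,
                         known: set[str] | None) -> list[BindingRecord]:
    """The '-xls' export: first line names the alleles above their column
    blocks, second line holds per-block headers including nM and Rank."""
    with open(path) as fh:
        allele_line = fh.readline().rstrip("\n").split("\t")
        header = fh.readline().rstrip("\n").split("\t")
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    alleles = [(i, normalize_allele(tok)) for i, tok in enumerate(allele_line) if tok.strip()]
    if not alleles:
        raise ValueError(f"{path}: no alleles in the first header line")
    if "Rank" not in header:
        raise ValueError(f"{path}: missing Rank column")
    try:
        pep_col = header.index("Peptide")
    except ValueError:
        raise ValueError(f"{path}: missing Peptide column") from None
    records = []
    for row in rows:
        peptide = row[pep_col].strip().upper()
        mhc_class = "I" if len(peptide) <= 14 else "II"
        for start, allele in alleles:
            block = {header[j]: row[j] for j in range(start, len(header))
                     if header[j] in ("nM", "Rank")}
            # the block's nM/Rank are the first such columns at/after the
            # allele anchor; rebuild them positionally to survive repeats
            nm_idx = _block_col(header, start, "nM")
            rk_idx = _block_col(header, start, "Rank")
            if nm_idx is None or rk_idx is None:
                raise ValueError(f"{path}: allele block for {allele} lacks nM/Rank")
            del block
            records.append(BindingRecord(
                peptide=peptide, allele=allele,
                ic50_nM=float(row[nm_idx]), rank_pct=float(row[rk_idx]),
                mhc_class=mhc_class,
                flagged_unknown=(known is not None and peptide not in known),
            ))
    return records


def _block_col(header: list[str], start: int, name: str) -> int | None:
    for j in range(start, len(header)):
        if header[j] == name:
            return j
    return None


def write_binding_table(records: Iterable[BindingRecord], path: str | Path) -> None:
    """generic_long serialization; round-trips losslessly with the parser."""
    pd.DataFrame([{
        "peptide": r.peptide, "allele": r.allele, "mhc_class": r.mhc_class,
        "ic50_nM": repr(r.ic50_nM), "rank_pct": repr(r.rank_pct),
    } for r in records],
        columns=["peptide", "allele", "mhc_class", "ic50_nM", "rank_pct"],
    ).to_csv(path, sep="\t", index=False)


_IC50_LOG_MIN = math.log(1.0)
_IC50_LOG_MAX = math.log(50000.0)


def _hash_unit(seed: int, peptide: str, allele: str, salt: str) -> float:
    """Uniform in (0, 1], a pure function of (seed, peptide, allele, salt)."""
    digest = hashlib.sha256(f"{seed}:{peptide}:{allele}:{salt}".encode()).digest()
    v = int.from_bytes(digest[:8], "big")
    return (v + 1) / 2**64


def mock_predict(candidates: Sequence[CandidatePeptide | str], alleles: Sequence[str],
                 seed: int, mhc_class: str | None = None) -> list[BindingRecord]:
    """Deterministic stand-in for an external binding predictor.

    %Rank is uniform on (0, 100] and IC50 log-uniform on [1, 50000] nM, both
    derived from a seeded hash of (peptide, allele) so identical inputs give
    byte-identical tables regardless of call order.
    """
    records = []
    for c in candidates:
        peptide = c if isinstance(c, str) else c.sequence
        cls = mhc_class or (c.mhc_class if not isinstance(c, str) else "I")
        for allele in alleles:
            canon = normalize_allele(allele)
            rank = 100.0 * _hash_unit(seed, peptide, canon, "rank")
            ic50 = math.exp(_IC50_LOG_MIN + (_IC50_LOG_MAX - _IC50_LOG_MIN)
                            * _hash_unit(seed, peptide, canon, "ic50"))
            records.append(BindingRecord(peptide=peptide, allele=canon,
                                         ic50_nM=ic50, rank_pct=rank, mhc_class=cls))
    return records


def select_binders(candidates: Sequence[CandidatePeptide],
                   records: Sequence[BindingRecord],
                   ) -> list[tuple[CandidatePeptide, BindingRecord]]:
    """Keep (candidate, record) pairs whose %Rank category is strong or weak."""
    by_peptide: dict[str, list[BindingRecord]] = {}
    for r in records:
        by_peptide.setdefault(r.peptide, []).append(r)
    out = []
    for c in candidates:
        for r in by_peptide.get(c.sequence, []):
            if r.mhc_class == c.mhc_class and r.category in ("strong", "weak"):
                out.append((c, r))
    return out
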