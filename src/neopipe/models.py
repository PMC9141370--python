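"""Typed records for annotated variants, fusions, expression, MS evidence and the
curated neoantigen reference database.

Coordinate convention: everything that crosses an I/O boundary (HGVS-style protein
changes, cDNA changes, TSV columns) is 1-based inclusive; internal slicing converts
to 0-based half-open only inside the sequence-editing code, never here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class VariantClass(str, Enum):
    MISSENSE = "missense"
    INFRAME_INS = "inframe_ins"
    INFRAME_DEL = "inframe_del"
    FRAMESHIFT = "frameshift"
    FUSION = "fusion"


class FrameStatus(str, Enum):
    IN_FRAME = "in_frame"
    FRAMESHIFT_3PRIME = "frameshift_3prime"


class VariantParseError(ValueError):
    """A row that cannot be turned into a valid VariantRecord."""


@dataclass(frozen=True)
class GenomicLocus:
    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:  # traceability column in result files
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class VariantRecord:
    """One protein-altering somatic event.

    ``protein_pos`` is the 1-based position of the first affected residue;
    ``ref_aa``/``alt_aa`` are protein-level (may be empty for pure ins/del).
    Frameshifts carry the nucleotide edit in ``cdna_change`` because their
    protein consequence must be recomputed by translation.
    """

    variant_id: str
    gene: str
    transcript_id: str
    protein_id: str
    var_class: VariantClass
    protein_pos: int | None = None
    ref_aa: str = ""
    alt_aa: str = ""
    cdna_change: str = ""
    genomic_locus: GenomicLocus | None = None

    def __post_init__(self) -> None:
        c = self.var_class
        if c is not VariantClass.FUSION:
            if self.protein_pos is None or self.protein_pos < 1:
                raise VariantParseError(
                    f"{self.variant_id}: protein_pos must be >= 1 for {c.value}"
                )
        if c is VariantClass.MISSENSE:
            if len(self.ref_aa) != 1 or len(self.alt_aa) != 1 or self.ref_aa == self.alt_aa:
                raise VariantParseError(
                    f"{self.variant_id}: missense needs single, differing ref/alt residues"
                )
        elif c is VariantClass.INFRAME_INS:
            if not self.alt_aa:
                raise VariantParseError(f"{self.variant_id}: insertion with empty alt_aa")
        elif c is VariantClass.INFRAME_DEL:
            if not self.ref_aa:
                raise VariantParseError(f"{self.variant_id}: deletion with empty ref_aa")
        elif c is VariantClass.FRAMESHIFT:
            if not self.cdna_change:
                raise VariantParseError(f"{self.variant_id}: frameshift without cdna_change")
            edit = parse_cdna_change(self.cdna_change)
            if len(edit.bases) % 3 == 0:
                raise VariantParseError(
                    f"{self.variant_id}: frameshift indel length divisible by 3"
                )


@dataclass(frozen=True)
class CdnaEdit:
    """A nucleotide insertion or deletion inside a CDS, 1-based.

    For insertions ``pos`` is the base AFTER which ``bases`` are inserted
    (HGVS c.6_7insC -> pos=6, bases='C'). For deletions ``pos`` is the first
    deleted base.
    """

    kind: str  # "ins" | "del"
    pos: int
    bases: str


_CDNA_INS = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")
_CDNA_DEL = re.compile(r"^c\.(\d+)(?:_(\d+))?del([ACGT]*)$")


def parse_cdna_change(text: str) -> CdnaEdit:
    """Parse the supported HGVS cDNA indel grammar (c.#_#insSEQ / c.#[_#]del[SEQ])."""
    m = _CDNA_INS.match(text)
    if m:
        start, end, bases = int(m.group(1)), int(m.group(2)), m.group(3)
        if end != start + 1:
            raise VariantParseError(f"non-adjacent insertion coordinates in {text!r}")
        return CdnaEdit("ins", start, bases)
    m = _CDNA_DEL.match(text)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        bases = m.group(3)
        n = end - start + 1
        if n < 1:
            raise VariantParseError(f"bad deletion span in {text!r}")
        if bases and len(bases) != n:
            raise VariantParseError(f"deletion span/bases length mismatch in {text!r}")
        return CdnaEdit("del", start, bases or "N" * n)
    raise VariantParseError(f"unsupported cDNA change {text!r}")


@dataclass(frozen=True)
class FusionRecord:
    """A gene-fusion coding-effect product: the already-translated junction protein.

    ``junction_index`` is the 1-based index of the last residue encoded entirely
    by the 5' partner.
    """

    fusion_id: str
    gene5: str
    gene3: str
    junction_protein_seq: str
    junction_index: int
    frame_status: FrameStatus

    def __post_init__(self) -> None:
        if not (1 <= self.junction_index < len(self.junction_protein_seq)):
            raise VariantParseError(
                f"{self.fusion_id}: junction_index {self.junction_index} out of range "
                f"for a {len(self.junction_protein_seq)}-mer junction sequence"
            )


class ExpressionTable:
    """transcript/gene -> TPM lookup; duplicate ids keep the maximum TPM."""

    def __init__(self, values: Mapping[str, float] | None = None):
        self._tpm: dict[str, float] = {}
        if values:
            for k, v in values.items():
                self.add(k, v)

    def add(self, ident: str, tpm: float) -> None:
        if tpm < 0:
            raise ValueError(f"negative TPM {tpm} for {ident}: corrupt input")
        prev = self._tpm.get(ident)
        if prev is not None:
            if prev != tpm:
                logger.info("duplicate expression id %s: keeping max(%g, %g)", ident, prev, tpm)
            self._tpm[ident] = max(prev, tpm)
        else:
            self._tpm[ident] = tpm

    def get(self, ident: str) -> float | None:
        return self._tpm.get(ident)

    def __len__(self) -> int:
        return len(self._tpm)

    def __contains__(self, ident: str) -> bool:
        return ident in self._tpm

    def items(self):
        return self._tpm.items()


@dataclass(frozen=True)
class MSEvidence:
    """Peptides identified by the MS database search (MaxQuant-style)."""

    peptides: frozenset[str]

    MIN_LEN = 7  # mirrors the search-engine minimum peptide length

    def __post_init__(self) -> None:
        for p in self.peptides:
            if len(p) < self.MIN_LEN:
                raise ValueError(f"MS peptide {p!r} shorter than {self.MIN_LEN} residues")
            if set(p) - STANDARD_AA:
                raise ValueError(f"MS peptide {p!r} contains non-standard residues")


class NeoTier(str, Enum):
    HIGH = "high"      # experimentally verified immunogenic
    MEDIUM = "medium"  # verified by MS + WGS/WES


@dataclass(frozen=True)
class NeoDBEntry:
    peptide: str
    tier: NeoTier

    def __post_init__(self) -> None:
        if not self.peptide or set(self.peptide) - STANDARD_AA:
            raise ValueError(f"invalid neoantigen peptide {self.peptide!r}")


# ---------------------------------------------------------------------------
# protein-change grammar (HGVS-like, the subset ANNOVAR emits)

_P_MISSENSE = re.compile(r"^p\.([ACDEFGHIKLMNPQRSTVWY])(\d+)([ACDEFGHIKLMNPQRSTVWY])$")
_P_DEL = re.compile(r"^p\.([ACDEFGHIKLMNPQRSTVWY])(\d+)(?:_([ACDEFGHIKLMNPQRSTVWY])(\d+))?del$")
_P_INS = re.compile(r"^p\.([ACDEFGHIKLMNPQRSTVWY])(\d+)_([ACDEFGHIKLMNPQRSTVWY])(\d+)ins([ACDEFGHIKLMNPQRSTVWY]+)$")
_P_INS_ANCHOR = re.compile(r"^p\.([ACDEFGHIKLMNPQRSTVWY])(\d+)ins([ACDEFGHIKLMNPQRSTVWY]+)$")


def parse_protein_change(text: str) -> tuple[VariantClass, int, str, str]:
    """Parse 'p.Y5F' / 'p.A4_Y5del' / 'p.K3_T4insQQ' -> (class, pos, ref_aa, alt_aa).

    For deletions ``pos`` is the first deleted residue and ``ref_aa`` the deleted
    block (filled with the flanking letters; interior residues unknown from the
    string are not reconstructed -- the span length carries the information, and
    the editor re-checks against the reference sequence). For insertions ``pos``
    is the residue AFTER which the new block goes.
    """
    m = _P_MISSENSE.match(text)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if ref == alt:
            raise VariantParseError(f"synonymous change {text!r}")
        return VariantClass.MISSENSE, pos, ref, alt
    m = _P_DEL.match(text)
    if m:
        start = int(m.group(2))
        if m.group(3) is None:
            return VariantClass.INFRAME_DEL, start, m.group(1), ""
        end = int(m.group(4))
        if end < start:
            raise VariantParseError(f"reversed deletion span {text!r}")
        if end == start:
            ref = m.group(1)
        else:
            # interior letters unknown from the HGVS string; pad with '?' so the
            # span length is right, the editor validates flanks against the ref
            ref = m.group(1) + "?" * (end - start - 1) + m.group(3)
        return VariantClass.INFRAME_DEL, start, ref, ""
    m = _P_INS.match(text)
    if m:
        left, right = int(m.group(2)), int(m.group(4))
        if right != left + 1:
            raise VariantParseError(f"non-adjacent insertion anchors {text!r}")
        return VariantClass.INFRAME_INS, left, m.group(1), m.group(5)
    m = _P_INS_ANCHOR.match(text)  # single-anchor form, our own serialization
    if m:
        return VariantClass.INFRAME_INS, int(m.group(2)), m.group(1), m.group(3)
    raise VariantParseError(f"unsupported protein change {text!r}")


def format_protein_change(rec: VariantRecord) -> str:
    """Inverse of :func:`parse_protein_change` for the classes it covers."""
    c, p = rec.var_class, rec.protein_pos
    if c is VariantClass.MISSENSE:
        return f"p.{rec.ref_aa}{p}{rec.alt_aa}"
    if c is VariantClass.INFRAME_DEL:
        if len(rec.ref_aa) == 1:
            return f"p.{rec.ref_aa}{p}del"
        end = p + len(rec.ref_aa) - 1
        return f"p.{rec.ref_aa[0]}{p}_{rec.ref_aa[-1]}{end}del"
    if c is VariantClass.INFRAME_INS:
        # single-anchor form: the residue after which the block is inserted
        return f"p.{rec.ref_aa or 'X'}{p}ins{rec.alt_aa}"
    raise ValueError(f"no protein-change string for class {c.value}")


# ---------------------------------------------------------------------------
# parsers

_ANNOVAR_CLASS = {
    "nonsynonymous SNV": VariantClass.MISSENSE,
    "nonframeshift insertion": VariantClass.INFRAME_INS,
    "nonframeshift deletion": VariantClass.INFRAME_DEL,
    "frameshift insertion": VariantClass.FRAMESHIFT,
    "frameshift deletion": VariantClass.FRAMESHIFT,
}
_SKIPPED_ANNOVAR = {"synonymous SNV", "unknown", "intronic", "UTR5", "UTR3"}


@dataclass
class ParseResult:
    records: list[VariantRecord]
    rejects: list[tuple[dict, str]] = field(default_factory=list)
    skipped: int = 0


def _read_tsv(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {', '.join(missing)}")
    return df


def parse_variant_table(path: str | Path, dialect: str = "simple") -> ParseResult:
    """Read an annotated variant table into VariantRecords.

    ``dialect='annovar'`` expects columns Gene, Transcript, ExonicFunc, AAChange
    (plus optional CdnaChange, Chrom/Pos/Ref/Alt); ``dialect='simple'`` is the
    package's own TSV (see :func:`write_variant_table`). Non-protein-altering
    rows are skipped and counted; malformed rows go to ``rejects`` with a reason.
    """
    if dialect == "simple":
        return _parse_simple(path)
    if dialect == "annovar":
        return _parse_annovar(path)
    raise ValueError(f"unknown variant dialect {dialect!r}")


def _locus_from_row(row: Mapping[str, str]) -> GenomicLocus | None:
    if row.get("Chrom") or row.get("chrom"):
        try:
            return GenomicLocus(
                chrom=row.get("Chrom") or row.get("chrom", ""),
                pos=int(row.get("Pos") or row.get("pos") or 0),
                ref=row.get("Ref") or row.get("ref", ""),
                alt=row.get("Alt") or row.get("alt", ""),
            )
        except (TypeError, ValueError):
            return None
    return None


def _parse_annovar(path: str | Path) -> ParseResult:
    df = _read_tsv(path, ["Gene", "Transcript", "ExonicFunc", "AAChange"])
    out = ParseResult(records=[])
    for i, row in df.iterrows():
        func = row["ExonicFunc"].strip()
        if func in _SKIPPED_ANNOVAR or not func:
            out.skipped += 1
            continue
        cls = _ANNOVAR_CLASS.get(func)
        if cls is None:
            out.rejects.append((dict(row), f"unknown variant class token {func!r}"))
            continue
        vid = row.get("VariantId", "") or f"{row['Gene']}:{row['AAChange']}"
        try:
            if cls is VariantClass.FRAMESHIFT:
                cdna = row.get("CdnaChange", "")
                rec = VariantRecord(
                    variant_id=vid, gene=row["Gene"], transcript_id=row["Transcript"],
                    protein_id=row.get("Protein", row["Transcript"]),
                    var_class=cls, protein_pos=_fs_pos(row["AAChange"]),
                    cdna_change=cdna, genomic_locus=_locus_from_row(row),
                )
            else:
                pcls, pos, ref, alt = parse_protein_change(row["AAChange"].strip())
                if pcls is not cls:
                    raise VariantParseError(
                        f"class {cls.value} disagrees with change {row['AAChange']!r}"
                    )
                rec = VariantRecord(
                    variant_id=vid, gene=row["Gene"], transcript_id=row["Transcript"],
                    protein_id=row.get("Protein", row["Transcript"]),
                    var_class=cls, protein_pos=pos, ref_aa=ref, alt_aa=alt,
                    cdna_change=row.get("CdnaChange", ""),
                    genomic_locus=_locus_from_row(row),
                )
        except VariantParseError as e:
            out.rejects.append((dict(row), str(e)))
            continue
        out.records.append(rec)
    if out.skipped:
        logger.info("%s: skipped %d non-protein-altering rows", path, out.skipped)
    return out


_P_FS = re.compile(r"^p\.[ACDEFGHIKLMNPQRSTVWYX](\d+)")  # X: residue unknown


def _fs_pos(aachange: str) -> int:
    """First affected residue from a frameshift AAChange like 'p.K3fs' (fallback 1)."""
    m = _P_FS.match(aachange.strip())
    return int(m.group(1)) if m else 1


_SIMPLE_COLS = ["variant_id", "gene", "transcript_id", "protein_id",
                "var_class", "protein_change", "cdna_change"]


def _parse_simple(path: str | Path) -> ParseResult:
    df = _read_tsv(path, _SIMPLE_COLS)
    out = ParseResult(records=[])
    for _, row in df.iterrows():
        try:
            cls = VariantClass(row["var_class"])
        except ValueError:
            out.rejects.append((dict(row), f"unknown var_class {row['var_class']!r}"))
            continue
        try:
            if cls is VariantClass.FRAMESHIFT:
                rec = VariantRecord(
                    variant_id=row["variant_id"], gene=row["gene"],
                    transcript_id=row["transcript_id"], protein_id=row["protein_id"],
                    var_class=cls, protein_pos=_fs_pos(row["protein_change"]) or 1,
                    cdna_change=row["cdna_change"], genomic_locus=_locus_from_row(row),
                )
            else:
                pcls, pos, ref, alt = parse_protein_change(row["protein_change"].strip())
                if pcls is not cls:
                    raise VariantParseError(
                        f"class {cls.value} disagrees with {row['protein_change']!r}"
                    )
                rec = VariantRecord(
                    variant_id=row["variant_id"], gene=row["gene"],
                    transcript_id=row["transcript_id"], protein_id=row["protein_id"],
                    var_class=cls, protein_pos=pos, ref_aa=ref, alt_aa=alt,
                    cdna_change=row["cdna_change"], genomic_locus=_locus_from_row(row),
                )
        except VariantParseError as e:
            out.rejects.append((dict(row), str(e)))
            continue
        out.records.append(rec)
    return out


def write_variant_table(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Serialize records to the 'simple' TSV dialect (round-trips with the parser)."""
    rows = []
    for r in records:
        if r.var_class is VariantClass.FRAMESHIFT:
            change = f"p.{'X'}{r.protein_pos}fs" if r.protein_pos else "p.X1fs"
        elif r.var_class is VariantClass.FUSION:
            raise ValueError("fusions are serialized via write_fusion_table")
        else:
            change = format_protein_change(r)
        row = {
            "variant_id": r.variant_id, "gene": r.gene,
            "transcript_id": r.transcript_id, "protein_id": r.protein_id,
            "var_class": r.var_class.value, "protein_change": change,
            "cdna_change": r.cdna_change,
        }
        if r.genomic_locus:
            row.update(chrom=r.genomic_locus.chrom, pos=r.genomic_locus.pos,
                       ref=r.genomic_locus.ref, alt=r.genomic_locus.alt)
        rows.append(row)
    pd.DataFrame(rows, columns=_SIMPLE_COLS + ["chrom", "pos", "ref", "alt"]).to_csv(
        path, sep="\t", index=False)


_FUSION_COLS = ["fusion_id", "gene5", "gene3", "junction_protein_seq",
                "junction_index", "frame_status"]


def parse_fusion_table(path: str | Path) -> list[FusionRecord]:
    """STAR-Fusion-style coding-effect records: the junction protein is given."""
    df = _read_tsv(path, _FUSION_COLS)
    return [
        FusionRecord(
            fusion_id=row["fusion_id"], gene5=row["gene5"], gene3=row["gene3"],
            junction_protein_seq=row["junction_protein_seq"].upper(),
            junction_index=int(row["junction_index"]),
            frame_status=FrameStatus(row["frame_status"]),
        )
        for _, row in df.iterrows()
    ]


def write_fusion_table(records: Iterable[FusionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"fusion_id": r.fusion_id, "gene5": r.gene5, "gene3": r.gene3,
          "junction_protein_seq": r.junction_protein_seq,
          "junction_index": r.junction_index,
          "frame_status": r.frame_status.value} for r in records],
        columns=_FUSION_COLS,
    ).to_csv(path, sep="\t", index=False)


def parse_expression(path: str | Path) -> ExpressionTable:
    """Kallisto abundance.tsv-compatible: columns target_id, tpm."""
    df = _read_tsv(path, ["target_id", "tpm"])
    table = ExpressionTable()
    for _, row in df.iterrows():
        table.add(row["target_id"], float(row["tpm"]))
    return table


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    pd.DataFrame(sorted(table.items()), columns=["target_id", "tpm"]).to_csv(
        path, sep="\t", index=False)


def parse_ms_evidence(path: str | Path) -> MSEvidence:
    """MaxQuant peptides.txt-compatible: one 'Sequence' column is required."""
    df = _read_tsv(path, ["Sequence"])
    peps = {p.strip().upper() for p in df["Sequence"] if p.strip()}
    return MSEvidence(peptides=frozenset(peps))


def load_neodb(path: str | Path) -> list[NeoDBEntry]:
    """Curated neoantigen peptides with confidence tier.

    Accepts FASTA with ``>id tier=high|medium`` headers or a two-column TSV
    ``peptide<TAB>tier``. Entries with non-amino-acid characters are rejected
    with a warning; duplicates on (peptide, tier) are collapsed.
    """
    path = Path(path)
    entries: list[NeoDBEntry] = []
    text = path.read_text()
    if text.lstrip().startswith(">"):
        for rec in SeqIO.parse(str(path), "fasta"):
            m = re.search(r"tier=(high|medium)", rec.description)
            tier = NeoTier(m.group(1)) if m else NeoTier.HIGH
            pep = str(rec.seq).upper()
            try:
                entries.append(NeoDBEntry(peptide=pep, tier=tier))
            except ValueError as e:
                logger.warning("neodb entry %s rejected: %s", rec.id, e)
    else:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.lower().startswith("peptide\t"):
                continue
            parts = line.split("\t")
            pep, tier = parts[0].upper(), NeoTier(parts[1]) if len(parts) > 1 else NeoTier.HIGH
            try:
                entries.append(NeoDBEntry(peptide=pep, tier=tier))
            except ValueError as e:
                logger.warning("neodb entry %r rejected: %s", pep, e)
    seen: set[tuple[str, NeoTier]] = set()
    unique = []
    for e in entries:
        key = (e.peptide, e.tier)
        if key not in seen:
            seen.add(key)
            unique.append(e)
    return unique
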