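"""Mutant protein construction and custom search-database assembly.

Each editing operation returns a :class:`MutantProtein` whose ``mut_region``
marks, in 1-based MUTANT coordinates, the residues considered novel:

* missense / in-frame insertion: the substituted or inserted residues;
* in-frame deletion: the two residues flanking the junction (the novelty is
  the new adjacency, not any residue identity);
* frameshift: first residue that differs from the reference translation
  through the end of the product;
* fusion: the two residues spanning the junction, or junction through the end
  when the 3' partner is read out of frame.

Downstream peptide windows must intersect this region to qualify as
mutation-containing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    CdnaEdit,
    FrameStatus,
    FusionRecord,
    VariantClass,
    VariantRecord,
    parse_cdna_change,
)

logger = logging.getLogger(__name__)

_CODON_TABLE_ID = 1  # standard nuclear code


class RefMismatch(ValueError):
    """Annotated reference residue(s) disagree with the reference sequence."""

    def __init__(self, pos: int, expected: str, observed: str):
        self.pos, self.expected, self.observed = pos, expected, observed
        super().__init__(
            f"reference mismatch at {pos}: expected {expected!r}, found {observed!r}"
        )


class InvalidVariant(ValueError):
    """A variant that cannot be applied to its sequence."""


class ReferenceProteome:
    """protein_id -> sequence, plus gene -> protein_ids lookup from FASTA headers.

    Headers of the form ``>PROT_ID GN=GENE ...`` (or plain ``>PROT_ID``) are
    accepted. Non-standard residues (X, U) are tolerated and flagged; peptide
    windows overlapping them are discarded later.
    """

    def __init__(self) -> None:
        self.sequences: dict[str, str] = {}
        self.by_gene: dict[str, set[str]] = {}
        self._concat: str | None = None

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceProteome":
        self = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            if "X" in seq or "U" in seq:
                logger.info("protein %s contains non-standard residues", rec.id)
            self.add(rec.id, seq, gene=_gene_from_desc(rec.description))
        return self

    def add(self, protein_id: str, seq: str, gene: str | None = None) -> None:
        self.sequences[protein_id] = seq.upper()
        if gene:
            self.by_gene.setdefault(gene, set()).add(protein_id)
        self._concat = None

    def get(self, protein_id: str) -> str | None:
        return self.sequences.get(protein_id)

    def contains_subsequence(self, peptide: str) -> bool:
        if self._concat is None:
            # '#' separators stop matches from straddling protein boundaries
            self._concat = "#".join(self.sequences.values())
        return peptide in self._concat

    def __len__(self) -> int:
        return len(self.sequences)


def _gene_from_desc(desc: str) -> str | None:
    for token in desc.split():
        if token.startswith("GN="):
            return token[3:]
    return None


class TranscriptCDS:
    """transcript_id -> coding nucleotide sequence (ATG..stop)."""

    def __init__(self) -> None:
        self.sequences: dict[str, str] = {}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "TranscriptCDS":
        self = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            self.add(rec.id, str(rec.seq).upper())
        return self

    def add(self, transcript_id: str, cds: str) -> None:
        cds = cds.upper()
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS {transcript_id} length {len(cds)} not divisible by 3")
        if not cds.startswith("ATG"):
            logger.warning("CDS %s does not start with ATG", transcript_id)
        self.sequences[transcript_id] = cds

    def get(self, transcript_id: str) -> str | None:
        return self.sequences.get(transcript_id)

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class MutantProtein:
    source_variant: str
    sequence: str
    mut_region: tuple[int, int]  # 1-based inclusive, mutant coordinates
    var_class: VariantClass
    gene: str = ""
    stop_found: bool | None = None  # frameshift only

    def __post_init__(self) -> None:
        a, b = self.mut_region
        if not (1 <= a <= b <= len(self.sequence)):
            raise InvalidVariant(
                f"{self.source_variant}: mut_region {self.mut_region} outside "
                f"1..{len(self.sequence)}"
            )


def apply_missense(ref_seq: str, pos: int, ref_aa: str, alt_aa: str,
                   variant_id: str = "", gene: str = "") -> MutantProtein:
    """Single-residue substitution at 1-based ``pos``; mut_region = [pos, pos]."""
    if not (1 <= pos <= len(ref_seq)):
        raise InvalidVariant(f"{variant_id}: position {pos} outside sequence")
    observed = ref_seq[pos - 1]
    if observed != ref_aa:
        raise RefMismatch(pos, ref_aa, observed)
    mutant = ref_seq[: pos - 1] + alt_aa + ref_seq[pos:]
    return MutantProtein(variant_id, mutant, (pos, pos), VariantClass.MISSENSE, gene)


def apply_inframe_indel(ref_seq: str, variant: VariantRecord) -> MutantProtein:
    """Protein-level in-frame insertion or deletion.

    Insertion: ``alt_aa`` goes after residue ``protein_pos``; mut_region spans
    the inserted block. Deletion: ``ref_aa`` (length n; '?' wildcards stand for
    interior residues not recoverable from an HGVS span) is removed starting at
    ``protein_pos``; mut_region is the junction pair [p-1, p] in mutant
    coordinates, clamped at the termini.
    """
    pos = variant.protein_pos
    assert pos is not None
    if variant.var_class is VariantClass.INFRAME_INS:
        if not (1 <= pos <= len(ref_seq)):
            raise InvalidVariant(f"{variant.variant_id}: anchor {pos} outside sequence")
        ins = variant.alt_aa
        mutant = ref_seq[:pos] + ins + ref_seq[pos:]
        return MutantProtein(variant.variant_id, mutant, (pos + 1, pos + len(ins)),
                             VariantClass.INFRAME_INS, variant.gene)
    if variant.var_class is VariantClass.INFRAME_DEL:
        n = len(variant.ref_aa)
        if not (1 <= pos and pos + n - 1 <= len(ref_seq)):
            raise InvalidVariant(f"{variant.variant_id}: deletion span outside sequence")
        if n >= len(ref_seq):
            raise InvalidVariant(f"{variant.variant_id}: deletion removes entire sequence")
        observed = ref_seq[pos - 1: pos - 1 + n]
        for e, o in zip(variant.ref_aa, observed):
            if e not in ("?", o):
                raise RefMismatch(pos, variant.ref_aa, observed)
        mutant = ref_seq[: pos - 1] + ref_seq[pos - 1 + n:]
        a = max(1, min(pos - 1, len(mutant)))
        b = max(1, min(pos, len(mutant)))
        return MutantProtein(variant.variant_id, mutant, (a, b),
                             VariantClass.INFRAME_DEL, variant.gene)
    raise InvalidVariant(f"{variant.variant_id}: not an in-frame indel")


def _translate_to_stop(cds: str) -> tuple[str, bool]:
    """Codon-by-codon translation halting at the first stop; trailing partial
    codons are ignored. Returns (protein, stop_found)."""
    protein = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = str(Seq(cds[i:i + 3]).translate(table=_CODON_TABLE_ID))
        if aa == "*":
            return "".join(protein), True
        protein.append(aa)
    return "".join(protein), False


def apply_cdna_edit(cds: str, edit: CdnaEdit) -> str:
    if edit.kind == "ins":
        if not (0 <= edit.pos <= len(cds)):
            raise InvalidVariant(f"insertion offset {edit.pos} beyond CDS of {len(cds)} nt")
        return cds[: edit.pos] + edit.bases + cds[edit.pos:]
    if edit.kind == "del":
        end = edit.pos + len(edit.bases) - 1
        if not (1 <= edit.pos and end <= len(cds)):
            raise InvalidVariant(f"deletion span {edit.pos}..{end} beyond CDS of {len(cds)} nt")
        return cds[: edit.pos - 1] + cds[end:]
    raise InvalidVariant(f"unknown edit kind {edit.kind!r}")


def translate_frameshift(cds: str, cdna_change: str | CdnaEdit,
                         variant_id: str = "", gene: str = "") -> MutantProtein:
    """Apply a frame-disrupting nucleotide edit and retranslate from the start.

    The product runs to the first stop codon (``stop_found=True``) or to the
    last complete codon if translation never hits a stop (``stop_found=False``;
    such products are kept and flagged rather than dropped). ``mut_region``
    spans from the first residue differing from the reference translation to
    the end of the mutant product.
    """
    edit = parse_cdna_change(cdna_change) if isinstance(cdna_change, str) else cdna_change
    if len(edit.bases) % 3 == 0:
        raise InvalidVariant(f"{variant_id}: edit of length {len(edit.bases)} is in-frame")
    if edit.pos > len(cds):
        raise InvalidVariant(f"{variant_id}: edit offset {edit.pos} beyond CDS")
    ref_protein, _ = _translate_to_stop(cds)
    mutant_cds = apply_cdna_edit(cds, edit)
    mut_protein, stop_found = _translate_to_stop(mutant_cds)
    if not mut_protein:
        raise InvalidVariant(f"{variant_id}: frameshift product is empty")
    first_diff = None
    for i, aa in enumerate(mut_protein):
        if i >= len(ref_protein) or ref_protein[i] != aa:
            first_diff = i + 1
            break
    if first_diff is None:
        # product is a prefix of the reference (early stop in the shifted
        # frame); mark the truncation point itself
        first_diff = len(mut_protein)
    return MutantProtein(variant_id, mut_protein, (first_diff, len(mut_protein)),
                         VariantClass.FRAMESHIFT, gene, stop_found=stop_found)


def fusion_to_mutant(fusion: FusionRecord) -> MutantProtein:
    """Wrap a fusion junction product; novelty is the junction (or the whole
    out-of-frame 3' tail)."""
    seq = fusion.junction_protein_seq
    j = fusion.junction_index
    if not (1 <= j < len(seq)):
        raise InvalidVariant(f"{fusion.fusion_id}: junction index out of range")
    if fusion.frame_status is FrameStatus.IN_FRAME:
        region = (j, j + 1)
    else:
        region = (j, len(seq))
    return MutantProtein(fusion.fusion_id, seq, region, VariantClass.FUSION,
                         gene=f"{fusion.gene5}--{fusion.gene3}")


def build_mutants(variants: Iterable[VariantRecord], fusions: Iterable[FusionRecord],
                  proteome: ReferenceProteome, cds: TranscriptCDS,
                  ) -> tuple[list[MutantProtein], list[tuple[str, str]]]:
    """Apply every variant to its reference; unbuildable ones are returned as
    (variant_id, reason) instead of raising, so one bad annotation cannot stop
    a run."""
    mutants: list[MutantProtein] = []
    failures: list[tuple[str, str]] = []
    for v in variants:
        try:
            if v.var_class is VariantClass.FRAMESHIFT:
                seq = cds.get(v.transcript_id)
                if seq is None:
                    raise InvalidVariant(f"no CDS for transcript {v.transcript_id}")
                mutants.append(translate_frameshift(seq, v.cdna_change, v.variant_id, v.gene))
                continue
            ref = proteome.get(v.protein_id)
            if ref is None:
                raise InvalidVariant(f"no reference protein {v.protein_id}")
            if v.var_class is VariantClass.MISSENSE:
                assert v.protein_pos is not None
                mutants.append(apply_missense(ref, v.protein_pos, v.ref_aa, v.alt_aa,
                                              v.variant_id, v.gene))
            else:
                mutants.append(apply_inframe_indel(ref, v))
        except (RefMismatch, InvalidVariant, ValueError) as e:
            failures.append((v.variant_id, str(e)))
    for f in fusions:
        try:
            mutants.append(fusion_to_mutant(f))
        except (InvalidVariant, ValueError) as e:
            failures.append((f.fusion_id, str(e)))
    if failures:
        logger.warning("%d variant(s) could not be applied", len(failures))
    return mutants, failures


def build_custom_db(proteome: ReferenceProteome,
                    contaminants: Mapping[str, str],
                    mutants: Iterable[MutantProtein],
                    out_path: str | Path) -> dict:
    """Assemble the proteogenomic search database FASTA.

    Normal entries are written verbatim, contaminants with a ``CON__`` prefix,
    mutants with structured ``>MUT|variant_id|gene|class|region=a-b`` headers.
    Mutant entries with identical sequences are merged (first provenance kept).
    Wild-type entries coexist with their mutant counterparts so the search
    engine retains wild-type context. Returns the manifest (also written next
    to the FASTA as ``<out>.manifest.tsv``).
    """
    out_path = Path(out_path)
    records: list[SeqRecord] = []
    for pid, seq in proteome.sequences.items():
        records.append(SeqRecord(Seq(seq), id=pid, description=""))
    for cid, seq in contaminants.items():
        name = cid if cid.startswith("CON__") else f"CON__{cid}"
        records.append(SeqRecord(Seq(seq.upper()), id=name, description=""))
    seen: dict[str, str] = {}
    merged: list[tuple[str, str]] = []
    n_mut = 0
    for m in mutants:
        if m.sequence in seen:
            merged.append((m.source_variant, seen[m.sequence]))
            continue
        seen[m.sequence] = m.source_variant
        a, b = m.mut_region
        header = f"MUT|{m.source_variant}|{m.gene}|{m.var_class.value}|region={a}-{b}"
        records.append(SeqRecord(Seq(m.sequence), id=header, description=""))
        n_mut += 1
    if n_mut == 0:
        logger.warning("custom DB contains no mutant entries")
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)
    manifest = {
        "normal": len(proteome.sequences),
        "contaminant": len(contaminants),
        "mutant": n_mut,
        "merged_duplicates": merged,
    }
    mpath = out_path.with_suffix(out_path.suffix + ".manifest.tsv")
    with open(mpath, "w") as fh:
        fh.write("category\tcount\n")
        for k in ("normal", "contaminant", "mutant"):
            fh.write(f"{k}\t{manifest[k]}\n")
        for dup, kept in merged:
            fh.write(f"merged\t{dup}->{kept}\n")
    return manifest
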