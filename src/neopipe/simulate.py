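"""Synthetic input generator: a complete, internally consistent toy data set
covering every pipeline input format.

The generator emulates the annotated-output level the pipeline consumes — an
annotated variant table over a small proteome with matching coding sequences,
fusion coding-effect records, a transcript-expression table, an MS-identified
peptide list and a curated neoantigen database. What makes it an oracle:

* expression is assigned per transcript, so the set of expressed variants is
  known before any filter runs;
* the MS peptide list is built by excising, from each "detected" mutant
  protein, a fragment that spans the whole novel region with generous flanks,
  so every mutation-anchored window of a detected variant has MS support and
  none of an undetected one does. This is exact at the variant level because
  each point variant occupies its own protein, while fusion partners and
  wild-type decoy fragments are drawn from variant-free proteins (a deletion's
  junction windows are wild-type-identical content, so a fragment from a
  second variant on the same protein would support them coincidentally);
* the curated database contains exact copies of a known subset of generated
  class I windows (similarity 100 by identity) alongside random peptides.

A ground-truth JSON records these sets. Defaults keep a full run in seconds:
50 proteins of ~300 residues, 5 variants per class, 5 fusions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from . import sequences as seqmod
from .models import (
    FrameStatus,
    FusionRecord,
    VariantClass,
    VariantRecord,
    write_expression,
    write_fusion_table,
    write_variant_table,
)
from .models import ExpressionTable
from .sequences import MutantProtein, ReferenceProteome, TranscriptCDS
from .windows import CLASS_I_RANGE, extract_windows

AA20 = "ACDEFGHIKLMNPQRSTVWY"

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    _CODONS_FOR.setdefault(aa, []).append(codon)
_STOPS = sorted(_TABLE.stop_codons)

# study-condition allele panels: five class I and two class II alleles, as
# typed for the leukemia cell line the tool was demonstrated on
DEFAULT_ALLELES_I = ["HLA-A*03:01", "HLA-B*07:02", "HLA-B*35:03",
                     "HLA-C*07:02", "HLA-C*04:01"]
DEFAULT_ALLELES_II = ["DRB4*01:03", "DRB4*01:01"]


@dataclass
class FixtureSpec:
    seed: int
    n_proteins: int = 50
    protein_length: tuple[int, int] = (280, 320)
    n_variants_per_class: int = 5  # missense / inframe_ins / inframe_del / frameshift
    n_fusions: int = 5
    alleles_i: list[str] = field(default_factory=lambda: list(DEFAULT_ALLELES_I))
    alleles_ii: list[str] = field(default_factory=lambda: list(DEFAULT_ALLELES_II))
    expressed_fraction: float = 0.7
    ms_detected_fraction: float = 0.5
    neodb_size: int = 40
    n_planted: int = 10

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for frac in (self.expressed_fraction, self.ms_detected_fraction):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        if min(self.n_proteins, self.n_variants_per_class, self.n_fusions,
               self.neodb_size, self.n_planted) < 0:
            raise ValueError("counts must be non-negative")


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [_CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in protein]
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    body = "".join(AA20[i] for i in rng.integers(0, 20, size=length - 1))
    return "M" + body


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write the full input set plus ground_truth.json; returns the ground truth.

    Identical spec + seed produce byte-identical files: every stochastic choice
    flows from one numpy Generator in a fixed order.
    """
    rng = np.random.default_rng(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- proteome + CDS -----------------------------------------------------
    proteome = ReferenceProteome()
    cds = TranscriptCDS()
    ids = []
    for i in range(spec.n_proteins):
        pid, tid, gene = f"P{i:04d}", f"T{i:04d}", f"GENE{i:04d}"
        lo, hi = spec.protein_length
        protein = _random_protein(int(rng.integers(lo, hi + 1)), rng)
        proteome.add(pid, protein, gene=gene)
        cds.add(tid, _back_translate(protein, rng))
        ids.append((pid, tid, gene))
    with open(out / "proteome.fasta", "w") as fh:
        for pid, _, gene in ids:
            fh.write(f">{pid} GN={gene}\n{proteome.get(pid)}\n")
    with open(out / "cds.fasta", "w") as fh:
        for _, tid, _ in ids:
            fh.write(f">{tid}\n{cds.get(tid)}\n")

    # --- variants -----------------------------------------------------------
    # each point variant gets its own protein; fusion partners and wild-type
    # decoys come from the variant-free remainder (keeps MS support exact)
    n_variant_proteins = 4 * spec.n_variants_per_class
    if n_variant_proteins > spec.n_proteins:
        raise ValueError(
            f"need {n_variant_proteins} proteins for variants, have {spec.n_proteins}")
    perm = [ids[int(i)] for i in rng.permutation(len(ids))]
    variant_slots = iter(perm[:n_variant_proteins])
    other_pool = perm[n_variant_proteins:]
    if spec.n_fusions > 0 and len(other_pool) < 2:
        raise ValueError("need at least 2 variant-free proteins for fusions")

    variants: list[VariantRecord] = []
    counter = 0

    def pick_variant_protein() -> tuple[str, str, str, str]:
        pid, tid, gene = next(variant_slots)
        return pid, tid, gene, proteome.get(pid)  # type: ignore[return-value]

    def pick_other_protein() -> tuple[str, str, str, str]:
        pid, tid, gene = other_pool[rng.integers(len(other_pool))]
        return pid, tid, gene, proteome.get(pid)  # type: ignore[return-value]

    for _ in range(spec.n_variants_per_class):  # missense
        pid, tid, gene, seq = pick_variant_protein()
        pos = int(rng.integers(2, len(seq)))
        ref = seq[pos - 1]
        alt = AA20[rng.integers(20)]
        while alt == ref:
            alt = AA20[rng.integers(20)]
        counter += 1
        variants.append(VariantRecord(
            variant_id=f"V{counter:04d}", gene=gene, transcript_id=tid,
            protein_id=pid, var_class=VariantClass.MISSENSE,
            protein_pos=pos, ref_aa=ref, alt_aa=alt))

    for _ in range(spec.n_variants_per_class):  # in-frame insertion
        pid, tid, gene, seq = pick_variant_protein()
        pos = int(rng.integers(2, len(seq) - 1))
        ins = "".join(AA20[i] for i in rng.integers(0, 20, size=int(rng.integers(1, 4))))
        counter += 1
        variants.append(VariantRecord(
            variant_id=f"V{counter:04d}", gene=gene, transcript_id=tid,
            protein_id=pid, var_class=VariantClass.INFRAME_INS,
            protein_pos=pos, ref_aa=seq[pos - 1], alt_aa=ins))

    for _ in range(spec.n_variants_per_class):  # in-frame deletion
        pid, tid, gene, seq = pick_variant_protein()
        n_del = int(rng.integers(1, 4))
        pos = int(rng.integers(2, len(seq) - n_del))
        counter += 1
        variants.append(VariantRecord(
            variant_id=f"V{counter:04d}", gene=gene, transcript_id=tid,
            protein_id=pid, var_class=VariantClass.INFRAME_DEL,
            protein_pos=pos, ref_aa=seq[pos - 1: pos - 1 + n_del]))

    for _ in range(spec.n_variants_per_class):  # frameshift
        pid, tid, gene, seq = pick_variant_protein()
        cds_seq = cds.get(tid)
        assert cds_seq is not None
        p = int(rng.integers(6, 3 * (len(seq) - 20)))
        if rng.random() < 0.5:
            n = int(rng.integers(1, 3))
            bases = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
            change = f"c.{p}_{p + 1}ins{bases}"
            first_codon = p // 3 + 1
        else:
            n = int(rng.integers(1, 3))
            delled = cds_seq[p - 1: p - 1 + n]
            change = (f"c.{p}del{delled}" if n == 1
                      else f"c.{p}_{p + n - 1}del{delled}")
            first_codon = (p - 1) // 3 + 1
        first_codon = min(first_codon, len(seq))
        counter += 1
        variants.append(VariantRecord(
            variant_id=f"V{counter:04d}", gene=gene, transcript_id=tid,
            protein_id=pid, var_class=VariantClass.FRAMESHIFT,
            protein_pos=first_codon, cdna_change=change))

    write_variant_table(variants, out / "variants.tsv")

    fusions: list[FusionRecord] = []
    for i in range(spec.n_fusions):
        (pid5, _, gene5, seq5), (pid3, _, gene3, seq3) = \
            pick_other_protein(), pick_other_protein()
        while pid3 == pid5:
            pid3, _, gene3, seq3 = pick_other_protein()
        ja = int(rng.integers(20, len(seq5) - 20))
        if rng.random() < 0.5:
            jb = int(rng.integers(20, len(seq3) - 20))
            junction = seq5[:ja] + seq3[jb:]
            status = FrameStatus.IN_FRAME
        else:
            tail = "".join(AA20[k] for k in rng.integers(0, 20, size=int(rng.integers(20, 41))))
            junction = seq5[:ja] + tail
            status = FrameStatus.FRAMESHIFT_3PRIME
        fusions.append(FusionRecord(
            fusion_id=f"FUS{i + 1:03d}", gene5=gene5, gene3=gene3,
            junction_protein_seq=junction, junction_index=ja, frame_status=status))
    write_fusion_table(fusions, out / "fusions.tsv")

    # --- expression ---------------------------------------------------------
    expression = ExpressionTable()
    expressed_transcripts: set[str] = set()
    for _, tid, gene in ids:
        if rng.random() < spec.expressed_fraction:
            tpm = float(10 ** rng.uniform(0, 3))  # log-uniform on [1, 1000]
            expressed_transcripts.add(tid)
        else:
            tpm = 0.0
        # transcript- and gene-level rows (fusions are screened by gene)
        expression.add(tid, tpm)
        expression.add(gene, tpm)
    write_expression(expression, out / "expression.tsv")

    expressed_variants = sorted(
        v.variant_id for v in variants if v.transcript_id in expressed_transcripts
    )
    # fusions are expression-screened via their 5' gene; map gene -> transcript
    gene_tid = {gene: tid for _, tid, gene in ids}
    expressed_fusions = sorted(
        f.fusion_id for f in fusions if gene_tid[f.gene5] in expressed_transcripts
    )

    # --- mutant proteins (needed to cut MS fragments and plant db windows) --
    mutants, failures = seqmod.build_mutants(variants, fusions, proteome, cds)
    if failures:
        raise RuntimeError(f"fixture generated unbuildable variants: {failures}")
    by_id: dict[str, MutantProtein] = {m.source_variant: m for m in mutants}

    # --- MS evidence --------------------------------------------------------
    all_ids = sorted(by_id)
    n_det = int(round(spec.ms_detected_fraction * len(all_ids)))
    detected = sorted(rng.choice(all_ids, size=n_det, replace=False).tolist())
    ms_rows: list[str] = []
    for vid in detected:
        m = by_id[vid]
        a, b = m.mut_region
        frag = m.sequence[max(0, a - 36): min(len(m.sequence), b + 35)]
        if len(frag) >= 7:
            ms_rows.append(frag)
    # wild-type decoys: real reference fragments that must never rescue a
    # candidate (no mutant-site coverage)
    for _ in range(5 if other_pool else 0):
        pid, _, _, seq = pick_other_protein()
        s = int(rng.integers(0, len(seq) - 12))
        ms_rows.append(seq[s: s + 12])
    with open(out / "ms_peptides.tsv", "w") as fh:
        fh.write("Sequence\n")
        for p in sorted(set(ms_rows)):
            fh.write(p + "\n")

    # --- curated neoantigen database ---------------------------------------
    window_pool: list[str] = []
    for vid in sorted(by_id):
        m = by_id[vid]
        for c in extract_windows(m, *CLASS_I_RANGE, "I"):
            window_pool.append(c.sequence)
    window_pool = sorted(set(window_pool))
    n_planted = min(spec.n_planted, len(window_pool))
    planted = sorted(
        rng.choice(window_pool, size=n_planted, replace=False).tolist()
    ) if n_planted else []
    entries: list[tuple[str, str]] = [
        (p, "high" if rng.random() < 0.76 else "medium") for p in planted
    ]
    while len(entries) < spec.neodb_size:
        length = int(rng.integers(9, 16))
        pep = "".join(AA20[i] for i in rng.integers(0, 20, size=length))
        entries.append((pep, "high" if rng.random() < 0.76 else "medium"))
    with open(out / "neodb.fasta", "w") as fh:
        for i, (pep, tier) in enumerate(entries):
            fh.write(f">NEO{i + 1:04d} tier={tier}\n{pep}\n")

    # --- contaminants -------------------------------------------------------
    with open(out / "contaminants.fasta", "w") as fh:
        for i in range(3):
            pep = _random_protein(int(rng.integers(100, 200)), rng)
            fh.write(f">CON{i + 1:03d}\n{pep}\n")

    ground_truth = {
        "seed": spec.seed,
        "expressed_variants": expressed_variants + expressed_fusions,
        "ms_detected_variants": detected,
        "neodb_planted_peptides": planted,
        "n_variants": len(variants),
        "n_fusions": len(fusions),
    }
    (out / "ground_truth.json").write_text(json.dumps(ground_truth, indent=2) + "\n")
    spec_dict = asdict(spec)
    spec_dict["protein_length"] = list(spec.protein_length)
    (out / "fixture_spec.json").write_text(json.dumps(spec_dict, indent=2) + "\n")
    return ground_truth


@dataclass
class FixtureCheck:
    ok: bool
    issues: list[str]


REQUIRED_FILES = ["proteome.fasta", "cds.fasta", "variants.tsv", "fusions.tsv",
                  "expression.tsv", "ms_peptides.tsv", "neodb.fasta",
                  "contaminants.fasta", "ground_truth.json", "fixture_spec.json"]


def check_fixture(out_dir: str | Path) -> FixtureCheck:
    """Validate internal consistency of a generated fixture.

    Checks: all files present; every CDS translates exactly to its protein
    (plus one stop codon); every annotated reference residue matches the
    proteome; every variant can be applied.
    """
    out = Path(out_dir)
    issues: list[str] = []
    for name in REQUIRED_FILES:
        if not (out / name).exists():
            issues.append(f"missing input file {name}")
    if issues:
        return FixtureCheck(False, issues)

    from .models import parse_fusion_table, parse_variant_table

    proteome = ReferenceProteome.from_fasta(out / "proteome.fasta")
    cds = TranscriptCDS.from_fasta(out / "cds.fasta")
    for i, (tid, cseq) in enumerate(sorted(cds.sequences.items())):
        pid = f"P{tid[1:]}"
        protein = proteome.get(pid)
        if protein is None:
            issues.append(f"{tid}: no matching protein {pid}")
            continue
        translated, stop = seqmod._translate_to_stop(cseq)
        if translated != protein or not stop:
            issues.append(f"{tid}: CDS does not translate to {pid}")
    parsed = parse_variant_table(out / "variants.tsv", dialect="simple")
    if parsed.rejects:
        issues.extend(f"variant row rejected: {reason}" for _, reason in parsed.rejects)
    for v in parsed.records:
        if v.var_class in (VariantClass.MISSENSE, VariantClass.INFRAME_DEL):
            seq = proteome.get(v.protein_id) or ""
            assert v.protein_pos is not None
            span = seq[v.protein_pos - 1: v.protein_pos - 1 + len(v.ref_aa)]
            for e, o in zip(v.ref_aa, span):
                if e not in ("?", o):
                    issues.append(f"{v.variant_id}: reference residue mismatch "
                                  f"({v.ref_aa!r} vs {span!r})")
                    break
    fusions = parse_fusion_table(out / "fusions.tsv")
    _, failures = seqmod.build_mutants(parsed.records, fusions, proteome, cds)
    issues.extend(f"{vid}: cannot build mutant ({reason})" for vid, reason in failures)
    return FixtureCheck(not issues, issues)
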