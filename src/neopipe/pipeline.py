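"""End-to-end orchestration: inputs -> mutant proteins -> windows -> binder
selection -> filter cascade -> report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import binding as bindmod
from . import filters as filtmod
from . import report as repmod
from . import windows as winmod
from .filters import AnnotatedCandidate, FilterConfig, StageResult
from .models import (
    ExpressionTable,
    MSEvidence,
    NeoDBEntry,
    load_neodb,
    parse_expression,
    parse_fusion_table,
    parse_ms_evidence,
    parse_variant_table,
)
from .sequences import MutantProtein, ReferenceProteome, TranscriptCDS, build_mutants
from .simulate import DEFAULT_ALLELES_I, DEFAULT_ALLELES_II

logger = logging.getLogger(__name__)


@dataclass
class PipelineInputs:
    proteome: ReferenceProteome
    cds: TranscriptCDS
    variants: list
    fusions: list
    expression: ExpressionTable
    ms: MSEvidence
    neodb: list[NeoDBEntry]

    @classmethod
    def from_dir(cls, input_dir: str | Path) -> "PipelineInputs":
        d = Path(input_dir)
        parsed = parse_variant_table(d / "variants.tsv", dialect="simple")
        if parsed.rejects:
            logger.warning("%d variant rows rejected", len(parsed.rejects))
        return cls(
            proteome=ReferenceProteome.from_fasta(d / "proteome.fasta"),
            cds=TranscriptCDS.from_fasta(d / "cds.fasta"),
            variants=parsed.records,
            fusions=parse_fusion_table(d / "fusions.tsv"),
            expression=parse_expression(d / "expression.tsv"),
            ms=parse_ms_evidence(d / "ms_peptides.tsv"),
            neodb=load_neodb(d / "neodb.fasta"),
        )


@dataclass
class PipelineResult:
    mutants: list[MutantProtein]
    build_failures: list[tuple[str, str]]
    candidates_i: list
    candidates_ii: list
    binders: list[AnnotatedCandidate]
    expressed: list[AnnotatedCandidate]
    ms_supported: list[AnnotatedCandidate]
    db_matched: list[AnnotatedCandidate]
    strict_survivors: list[AnnotatedCandidate]
    matching_ratios: dict[str, float | None]
    stages: list[StageResult] = field(default_factory=list)
    report: repmod.FilterReport | None = None


def run_pipeline(inputs: PipelineInputs, cfg: FilterConfig | None = None,
                 seed: int = 0,
                 alleles_i: list[str] | None = None,
                 alleles_ii: list[str] | None = None,
                 binding_records: list[bindmod.BindingRecord] | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the whole pipeline.

    Binding predictions come from ``binding_records`` when supplied (parsed
    from an external predictor's output), otherwise from the deterministic
    mock predictor under ``seed``.
    """
    cfg = cfg or FilterConfig()
    alleles_i = alleles_i or list(DEFAULT_ALLELES_I)
    alleles_ii = alleles_ii or list(DEFAULT_ALLELES_II)

    mutants, failures = build_mutants(inputs.variants, inputs.fusions,
                                      inputs.proteome, inputs.cds)

    cand_i = winmod.extract_all(mutants, "I")
    cand_ii = winmod.extract_all(mutants, "II")
    if cfg.drop_wildtype:
        cand_i = winmod.drop_wildtype_windows(cand_i, inputs.proteome)
        cand_ii = winmod.drop_wildtype_windows(cand_ii, inputs.proteome)

    if binding_records is None:
        binding_records = (
            bindmod.mock_predict(cand_i, alleles_i, seed, mhc_class="I")
            + bindmod.mock_predict(cand_ii, alleles_ii, seed, mhc_class="II")
        )
    pairs = bindmod.select_binders(cand_i + cand_ii, binding_records)
    binders = [AnnotatedCandidate(peptide=c, allele=r.allele, ic50_nM=r.ic50_nM,
                                  rank_pct=r.rank_pct, category=r.category)
               for c, r in pairs]

    transcript_of = {v.variant_id: v.transcript_id for v in inputs.variants}
    gene_of = {v.variant_id: v.gene for v in inputs.variants}
    # fusions are screened on their 5' partner's expression
    gene_of.update({f.fusion_id: f.gene5 for f in inputs.fusions})

    st_expr, st_ms, st_db, st_strict = (StageResult("", 0, 0) for _ in range(4))
    expressed = filtmod.filter_expression(binders, inputs.expression, cfg,
                                          transcript_of, gene_of, stage=st_expr) \
        if cfg.expression_enabled else list(binders)
    mutants_by_id = {m.source_variant: m for m in mutants}
    ms_supported = filtmod.filter_ms(expressed, inputs.ms, cfg,
                                     mutants_by_id, stage=st_ms) \
        if cfg.ms_enabled else list(expressed)

    ratios: dict[str, float | None] = {}
    ms_i = [c for c in ms_supported if c.peptide.mhc_class == "I"]
    if cfg.neodb_enabled and inputs.neodb:
        db_matched, ratio = filtmod.filter_neodb(ms_i, inputs.neodb, cfg, stage=st_db)
        ratios["ms_survivors_vs_db"] = ratio
    else:
        db_matched, st_db = [], StageResult("neodb", len(ms_i), len(ms_i))
    strict_survivors = filtmod.filter_strict(ms_i, cfg, stage=st_strict) \
        if cfg.strict_enabled else list(ms_i)
    if cfg.neodb_enabled and inputs.neodb and strict_survivors:
        strict_matched, strict_ratio = filtmod.filter_neodb(
            strict_survivors, inputs.neodb, cfg)
        ratios["strict_survivors_vs_db"] = strict_ratio

    stages = [s for s in (st_expr, st_ms, st_db, st_strict) if s.name]
    known = {v.variant_id: v.var_class.value for v in inputs.variants}
    known.update({f.fusion_id: "fusion" for f in inputs.fusions})
    report = repmod.aggregate(
        {"binders": binders, "expression": expressed, "ms": ms_supported,
         "neodb": db_matched, "strict": strict_survivors},
        known_variants=known, matching_ratios=ratios, stages=stages)

    result = PipelineResult(
        mutants=mutants, build_failures=failures,
        candidates_i=cand_i, candidates_ii=cand_ii, binders=binders,
        expressed=expressed, ms_supported=ms_supported, db_matched=db_matched,
        strict_survivors=strict_survivors, matching_ratios=ratios,
        stages=stages, report=report)

    if out_dir is not None:
        variants_by_id = {v.variant_id: v for v in inputs.variants}
        repmod.write_results(ms_supported, out_dir, variants=variants_by_id,
                             report=report)
    return result
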