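"""Aggregated counts, matching ratios and per-mutation-type result files.

Internal consistency is enforced at aggregation time: per-mutation-class
counts must sum to each stage total, and strong + weak binder counts must
equal the selected-binder total for each MHC class.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .filters import AnnotatedCandidate, StageResult, matching_ratio
from .models import VariantClass, VariantRecord

logger = logging.getLogger(__name__)

MUTATION_CLASSES = [c.value for c in VariantClass]


@dataclass
class FilterReport:
    # (stage, mutation class, mhc class) -> count
    counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    per_allele: dict[str, int] = field(default_factory=dict)
    matching_ratios: dict[str, float | None] = field(default_factory=dict)
    strong_weak: dict[tuple[str, str], int] = field(default_factory=dict)
    stages: list[StageResult] = field(default_factory=list)

    def stage_total(self, stage: str, mhc_class: str) -> int:
        return sum(v for (s, _, m), v in self.counts.items()
                   if s == stage and m == mhc_class)


def percent_increase(old_count: int, new_count: int) -> float | None:
    """100 * (new - old) / old to 1 decimal; None (NA) when old is zero."""
    if old_count == 0:
        return None
    return round(100.0 * (new_count - old_count) / old_count, 1)


def aggregate(stage_candidates: Mapping[str, Sequence[AnnotatedCandidate]],
              known_variants: Mapping[str, str] | None = None,
              matching_ratios: Mapping[str, float | None] | None = None,
              stages: Sequence[StageResult] = (),
              ) -> FilterReport:
    """Build the report from per-stage candidate lists.

    ``known_variants`` (variant_id -> mutation class) lets aggregation reject
    candidates referencing unknown variants; ``matching_ratios`` carries the
    named database-comparison ratios computed by the cascade.
    """
    report = FilterReport(stages=list(stages))
    for stage, cands in stage_candidates.items():
        for c in cands:
            vid = c.peptide.source_variant
            if known_variants is not None and vid not in known_variants:
                raise ValueError(f"candidate references unknown variant {vid!r}")
            key = (stage, c.peptide.var_class, c.peptide.mhc_class)
            report.counts[key] = report.counts.get(key, 0) + 1
    binders = stage_candidates.get("binders", [])
    uniq_per_allele: dict[str, set[str]] = {}
    for c in binders:
        # cross-variant duplicate peptides collapse inside each allele count
        uniq_per_allele.setdefault(c.allele, set()).add(c.peptide.sequence)
        k = (c.peptide.mhc_class, c.category)
        report.strong_weak[k] = report.strong_weak.get(k, 0) + 1
    report.per_allele = {a: len(s) for a, s in sorted(uniq_per_allele.items())}
    report.matching_ratios = dict(matching_ratios or {})
    _check_sums(report)
    return report


def _check_sums(report: FilterReport) -> None:
    for mhc in ("I", "II"):
        total = report.stage_total("binders", mhc)
        sw = (report.strong_weak.get((mhc, "strong"), 0)
              + report.strong_weak.get((mhc, "weak"), 0))
        if total != sw:
            raise ValueError(
                f"class {mhc}: strong+weak {sw} != selected binder total {total}"
            )


def class_totals(per_class_counts: Sequence[int]) -> int:
    """Sum of per-mutation-class candidate counts (exact integer arithmetic)."""
    return int(sum(per_class_counts))


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


_RESULT_COLS = ["peptide", "k", "allele", "ic50_nM", "rank_pct", "category",
                "tpm", "genomic_locus", "ms_support", "best_similarity",
                "mhc_class", "source_variant"]


def write_results(candidates: Sequence[AnnotatedCandidate], out_dir: str | Path,
                  variants: Mapping[str, VariantRecord] | None = None,
                  report: FilterReport | None = None) -> list[Path]:
    """One TSV per mutation class plus a summary; rewrites are atomic
    (write-then-rename) so a crashed run never leaves a half file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    variants = variants or {}
    written: list[Path] = []
    by_class: dict[str, list[AnnotatedCandidate]] = {c: [] for c in MUTATION_CLASSES}
    for c in candidates:
        by_class.setdefault(c.peptide.var_class, []).append(c)
    for cls, cands in by_class.items():
        rows = []
        for c in cands:
            v = variants.get(c.peptide.source_variant)
            rows.append({
                "peptide": c.peptide.sequence, "k": c.peptide.k,
                "allele": c.allele, "ic50_nM": round(c.ic50_nM, 3),
                "rank_pct": round(c.rank_pct, 4), "category": c.category,
                "tpm": "" if c.tpm is None else round(c.tpm, 3),
                "genomic_locus": str(v.genomic_locus) if v and v.genomic_locus else "",
                "ms_support": ";".join(c.ms_support),
                "best_similarity": ("" if c.best_similarity is None
                                    else round(c.best_similarity, 2)),
                "mhc_class": c.peptide.mhc_class,
                "source_variant": c.peptide.source_variant,
            })
        df = pd.DataFrame(rows, columns=_RESULT_COLS)
        path = out_dir / f"neoantigens.{cls}.tsv"
        _atomic_write(path, df.to_csv(sep="\t", index=False))
        written.append(path)
    if report is not None:
        written.append(write_report(report, out_dir))
    return written


def write_report(report: FilterReport, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["section\tkey\tvalue"]
    for (stage, cls, mhc), n in sorted(report.counts.items()):
        lines.append(f"counts\t{stage}|{cls}|{mhc}\t{n}")
    for allele, n in report.per_allele.items():
        lines.append(f"per_allele\t{allele}\t{n}")
    for name, r in report.matching_ratios.items():
        lines.append(f"matching_ratio\t{name}\t{'NA' if r is None else r}")
    for (mhc, cat), n in sorted(report.strong_weak.items()):
        lines.append(f"strong_weak\t{mhc}|{cat}\t{n}")
    for s in report.stages:
        lines.append(f"stage\t{s.name}\t{s.n_in}->{s.n_out}")
    path = out_dir / "summary.tsv"
    _atomic_write(path, "\n".join(lines) + "\n")
    json_path = out_dir / "summary.json"
    payload = {
        "counts": {f"{s}|{c}|{m}": n for (s, c, m), n in sorted(report.counts.items())},
        "per_allele": report.per_allele,
        "matching_ratios": report.matching_ratios,
        "strong_weak": {f"{m}|{c}": n for (m, c), n in sorted(report.strong_weak.items())},
        "stages": [{"name": s.name, "in": s.n_in, "out": s.n_out,
                    "removed": s.removed_reasons} for s in report.stages],
    }
    _atomic_write(json_path, json.dumps(payload, indent=2) + "\n")
    return path


def read_report(out_dir: str | Path) -> FilterReport:
    """Rebuild a FilterReport from summary.tsv (round-trips with write_report
    for the count sections)."""
    report = FilterReport()
    df = pd.read_csv(Path(out_dir) / "summary.tsv", sep="\t", dtype=str,
                     keep_default_na=False)
    for _, row in df.iterrows():
        section, key, value = row["section"], row["key"], row["value"]
        if section == "counts":
            stage, cls, mhc = key.split("|")
            report.counts[(stage, cls, mhc)] = int(value)
        elif section == "per_allele":
            report.per_allele[key] = int(value)
        elif section == "matching_ratio":
            report.matching_ratios[key] = None if value == "NA" else float(value)
        elif section == "strong_weak":
            mhc, cat = key.split("|")
            report.strong_weak[(mhc, cat)] = int(value)
        elif section == "stage":
            n_in, n_out = value.split("->")
            report.stages.append(StageResult(key, int(n_in), int(n_out)))
    return report


__all__ = [
    "FilterReport", "aggregate", "percent_increase", "matching_ratio",
    "class_totals", "write_results", "write_report", "read_report",
    "MUTATION_CLASSES",
]
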