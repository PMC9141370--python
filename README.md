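# neopipe

Candidate neoantigen construction and filtering from annotated somatic
variants.

Tumor-specific mutations — missense substitutions, in-frame insertions and
deletions, frameshifts and gene fusions — can create peptides absent from the
normal proteome. When such a peptide is presented by an HLA molecule it
becomes a candidate neoantigen. `neopipe` implements the downstream half of
that discovery process: starting from an annotated variant table, a reference
proteome and matching coding sequences, it

1. builds the mutant protein for every variant (including frameshift
   re-translation of the edited CDS and fusion junction products) and records
   the novel residue interval of each,
2. assembles a customized proteogenomic search database (normal + contaminant
   + mutant entries, duplicates merged),
3. extracts every mutation-anchored k-mer window (8–11-mers for HLA class I,
   15–30-mers for class II, stride 1; each window must contain a mutated
   residue),
4. classifies predicted binding by percentile rank (class I: strong ≤ 0.5,
   weak ≤ 2; class II: strong ≤ 2, weak ≤ 10) with parsers for external
   predictor output plus a deterministic mock predictor for offline work,
5. applies a four-stage filter cascade — transcript expression (TPM > 0),
   mass-spectrometry support covering a mutant position, similarity to a
   curated neoantigen database (Smith–Waterman/BLOSUM62, positive-pair
   similarity within 20–100), and a strict affinity/abundance screen
   (IC50 ≤ 34 nM and TPM ≥ 33, class I) — and
6. reports per-stage, per-mutation-class and per-allele counts with matching
   ratios, written as one TSV per mutation type plus a summary.

A synthetic-data generator (`neopipe.simulate`) produces complete,
internally consistent toy inputs whose expected filter outcomes are known by
construction, so the entire pipeline runs and is tested offline.

## Worked example

Generate a toy data set and run the full pipeline with the seeded mock
predictor:

```bash
$ neopipe simulate --seed 42 --out-dir demo/inputs --check
fixture written to demo/inputs (20 variants, 5 fusions)
fixture check passed

$ neopipe run --input-dir demo/inputs --out-dir demo/results --seed 42
expression: 1669 -> 1115
ms: 1115 -> 526
neodb: 40 -> 40
strict: 40 -> 11
ms_survivors_vs_db: 100.00%
strict_survivors_vs_db: 100.00%

$ ls demo/results
neoantigens.frameshift.tsv  neoantigens.fusion.tsv  neoantigens.inframe_del.tsv
neoantigens.inframe_ins.tsv neoantigens.missense.tsv summary.json summary.tsv
```

1,669 window/allele pairs are selected as strong or weak binders; 1,115
survive the expression screen, 526 have MS support, all 40 class I MS
survivors match the toy curated database (the generator plants exact window
copies, so 100% matching is expected on toy data), and 11 pass the strict
screen. The same steps are available programmatically:

```python
from neopipe.pipeline import PipelineInputs, run_pipeline
from neopipe.simulate import FixtureSpec, generate_fixture

generate_fixture(FixtureSpec(seed=42), "demo/inputs")
result = run_pipeline(PipelineInputs.from_dir("demo/inputs"), seed=42)
print(len(result.binders), len(result.strict_survivors))
```

Other subcommands operate on individual stages: `build-db` (search database
FASTA), `peptides` (window extraction), `classify` (binding-table parsing and
%Rank classification), `filter` (cascade on existing tables), `report`
(summary of a finished run). `--config` accepts a YAML file overriding any
filter threshold, length range or allele panel.

## Layout

- `src/neopipe/` — `models` (variant/fusion/expression/MS/database records
  and parsers), `sequences` (mutant-protein construction), `windows`
  (k-mer extraction), `binding` (classification, predictors, parsers),
  `alignment` (Smith–Waterman similarity), `filters` (the cascade),
  `report` (aggregation and output), `simulate` (toy-data generator),
  `pipeline` (orchestration), `cli`.
- `tests/` — unit, property-based and oracle-equivalence tests;
  `tests/test_acceptance.py` holds the acceptance suite.
- `docs/methods.md` — model description, parameter tables and numerical
  conventions.
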