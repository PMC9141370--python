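# Methods

## Scope and model

`neopipe` consumes annotation-level inputs — a variant table with protein
and cDNA change strings, a reference proteome, matching coding sequences,
fusion coding-effect records, a transcript/gene expression table, a list of
MS-identified peptides and a curated neoantigen database — and produces
filtered candidate neoantigen tables. Read alignment, variant calling,
annotation and spectral search are out of scope: the package starts where
those tools' outputs end.

All residue and base coordinates are 1-based and inclusive at every
interface, matching HGVS conventions; conversion to Python indexing happens
only inside function bodies.

## Mutant proteins

Each variant yields one mutant protein plus the interval of novel residues
(`mut_region`, 1-based inclusive) used to anchor peptide windows:

- **Missense** — single-residue substitution; region is that position. The
  annotated reference residue is checked against the proteome; a mismatch is
  a per-variant error (`RefMismatch`), not a crash.
- **In-frame insertion** — region covers exactly the inserted residues.
- **In-frame deletion** — no new residue exists, so the region is the novel
  junction pair `[p−1, p]`, clamped into the sequence at either terminus.
  Deleting the whole protein is invalid.
- **Frameshift** — the cDNA edit (`c.<pos>ins/del<bases>`) is applied to the
  CDS and the result re-translated codon-by-codon to the first stop. The
  region runs from the first residue that differs from the reference
  translation to the new C-terminus. Edits whose length is a multiple of 3
  are rejected here (they are in-frame by definition).
- **Fusion** — the junction protein is taken from the fusion record; for
  in-frame fusions the region is the junction residue pair, for fusions
  that shift the 3' partner's frame it is the junction to the end.

The customized search database concatenates normal proteome entries,
contaminant entries (prefixed `CON__`) and mutant entries with
self-describing headers (`MUT|id|gene|class|region=a-b`); mutants with
identical sequences are merged and recorded in a manifest.

## Peptide windows

For a mutant of length `L` with region `[a, b]`, the k-mer windows
containing at least one novel residue start at
`s ∈ [max(1, a−k+1), min(b, L−k+1)]` (stride 1). Class I uses k = 8–11,
class II k = 15–30. Windows containing non-standard residues are dropped and
counted; duplicate (sequence, k) pairs within a variant collapse to the
first start. Proteins shorter than k_min yield an empty list, not an error.

## Binding classification

Binding is classified purely from the predictor's percentile rank:

| MHC class | strong | weak |
|---|---|---|
| I | rank ≤ 0.5 | 0.5 < rank ≤ 2 |
| II | rank ≤ 2 | 2 < rank ≤ 10 |

Boundaries are inclusive. IC50 values are carried through untouched and only
used by the strict filter. Parsers cover a generic long table and the
multi-allele NetMHCpan-style spreadsheet layout; a missing rank column is
fatal. The deterministic mock predictor hashes
`(seed, peptide, allele, salt)` with SHA-256 to draw rank uniformly from
(0, 100] and IC50 log-uniformly from [1, 50000] nM — reproducible,
call-order independent, and obviously not a real predictor.

## Filter cascade

Defaults (all overridable via `FilterConfig` / `--config`):

| parameter | default | unit |
|---|---|---|
| `tpm_min_exclusive` | 0 | TPM |
| `ms_min_overlap` | 7 | residues |
| `sim_threshold_low/high` | 20 / 100 | similarity % |
| `strict_ic50_max_nM` | 34 | nM |
| `strict_tpm_min` | 33 | TPM |

1. **Expression** — keep candidates whose transcript (fallback: gene) has
   TPM strictly above the cutoff. Fusions are screened via their 5' partner
   gene. Variants absent from the table are removed under a separate reason.
2. **MS evidence** — keep candidates supported by an identified peptide:
   substring containment in either direction, or an overlap of at least
   `ms_min_overlap` residues when both are located on the same mutant
   protein; the shared residues must cover at least one mutant position, so
   pure wild-type fragments never rescue a candidate.
3. **Database similarity** — best local alignment of each candidate against
   every curated peptide; candidates whose similarity falls inside the band
   are "matched", and the matching ratio (100·matched/compared, 2 decimals;
   NA when nothing was compared) is reported.
4. **Strict screen** — class I only: IC50 ≤ 34 nM and TPM ≥ 33, both
   inclusive. Class II candidates are skipped with a warning.

Stages 3 and 4 act in parallel on the class I MS survivors.

## Similarity score

Smith–Waterman local alignment (Gotoh affine-gap formulation) under
BLOSUM62 with a gap of length L costing 11 + L (equivalently: −12 to open a
1-residue gap, −1 per extension). The similarity of query q against subject
s is `100 × (aligned pairs with positive BLOSUM62 score) / len(q)` for the
optimal alignment — identity gives 100, disjoint alphabets give 0, and
conservative substitutions (positive-scoring pairs) do not reduce the score.
The in-package dynamic programming implementation is verified against
Biopython's `PairwiseAligner` as an independent oracle; co-optimal
alignments can differ in their positive-pair count, so tests assert
membership in the oracle's set of optimal values.

## Reporting

Counts are keyed by (stage, mutation class, MHC class); per-allele counts
collapse duplicate peptides within an allele. Two identities are enforced at
aggregation time: per-mutation-class counts sum to each stage total, and
strong + weak binder counts equal the selected-binder total per MHC class.
Ratios are rounded to 2 decimals, percent changes to 1 decimal, both
matching the precision such numbers are conventionally reported at. Output
files are rewritten atomically (write-then-rename). `read_report`
reconstructs the report from `summary.tsv` losslessly.

## Toy-data generator as oracle

`generate_fixture` writes a complete input set plus a ground-truth JSON.
Design choices that make expected outcomes exact:

- expression is assigned per transcript (and mirrored at gene level, which
  the fusion screen needs) before any filter runs;
- every point variant occupies its own protein, fusion partners and
  wild-type decoy fragments come from variant-free proteins, and each
  "detected" variant contributes one MS fragment spanning its whole novel
  region with ≥35-residue flanks — so a candidate has MS support if and
  only if its variant is detected (a deletion's junction windows are
  wild-type-identical content and would otherwise be supported
  coincidentally by fragments of other variants on the same protein);
- the curated database contains exact copies of a known subset of class I
  windows (similarity 100 by identity) plus random peptides.

On toy data essentially all MS survivors match the database at
similarity ≥ 20: with a 20-to-40-entry random database, short queries
almost always achieve one positive-scoring aligned pair per 8–11 residues
(12.5% similarity is a single pair for a 8-mer, two pairs reach 25%). The
100% matching ratios in the demo are therefore a property of the similarity
definition at toy scale, not a bug; the band bounds are study conditions
and are not tuned.

## Limitations

- The mock predictor models no binding biology; absolute binder counts on
  fixtures are meaningless and only determinism and arithmetic are tested.
- Published cohort-scale counts (hundreds of thousands of peptides) require
  the original sequencing/MS inputs and a real predictor; the test suite
  verifies their internal arithmetic and all scale-free behavior instead.
- The expression screen interprets "remove unexpressed genes" as TPM
  strictly greater than the cutoff (default 0); a literal negative-TPM
  reading would be unsatisfiable.
- Two published class II totals differ by 4 (289,142 vs 289,138); the
  per-class sum supports 289,142, which is what the sum identity asserts.
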