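"""The four-stage filter cascade: expression, MS evidence, curated-database
similarity and the strict affinity/abundance screen."""

import random
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neopipe.filters import (
    AnnotatedCandidate,
    FilterConfig,
    StageResult,
    filter_expression,
    filter_ms,
    filter_neodb,
    filter_strict,
    matching_ratio,
    similarity_search,
)
from neopipe.models import ExpressionTable, MSEvidence, NeoDBEntry, NeoTier, VariantClass
from neopipe.sequences import MutantProtein
from neopipe.windows import CandidatePeptide

AA = "ACDEFGHIKLMNPQRSTVWY"


def _cand(seq="KTAFIAKL", start=2, muts=(4,), vid="v1", mhc="I",
          ic50=10.0, rank=0.4, tpm=None):
    pep = CandidatePeptide(seq, len(seq), start, frozenset(muts), vid, mhc,
                          var_class="missense")
    return AnnotatedCandidate(peptide=pep, allele="HLA-A*03:01", ic50_nM=ic50,
                              rank_pct=rank, category="strong", tpm=tpm)


class TestExpressionFilter:
    def test_expressed_kept_zero_removed(self):
        table = ExpressionTable({"T1": 5.2, "T2": 0.0})
        cands = [_cand(vid="v1"), _cand(vid="v2")]
        stage = StageResult("", 0, 0)
        kept = filter_expression(cands, table, FilterConfig(),
                                 transcript_of={"v1": "T1", "v2": "T2"},
                                 stage=stage)
        assert [c.peptide.source_variant for c in kept] == ["v1"]
        assert kept[0].tpm == 5.2
        assert stage.removed_reasons == {"unexpressed": 1}

    def test_absent_variant_counted_separately(self):
        stage = StageResult("", 0, 0)
        kept = filter_expression([_cand(vid="vX")], ExpressionTable({"T1": 5.0}),
                                 FilterConfig(), stage=stage)
        assert kept == []
        assert stage.removed_reasons == {"no expression data": 1}

    def test_negative_cutoff_removes_nothing_by_value(self):
        table = ExpressionTable({"T1": 0.0})
        kept = filter_expression([_cand(vid="v1")], table,
                                 FilterConfig(tpm_min_exclusive=-1),
                                 transcript_of={"v1": "T1"})
        assert len(kept) == 1

    def test_gene_fallback_lookup(self):
        table = ExpressionTable({"GENE9": 3.0})
        kept = filter_expression([_cand(vid="v1")], table, FilterConfig(),
                                 gene_of={"v1": "GENE9"})
        assert len(kept) == 1 and kept[0].tpm == 3.0


class TestMSFilter:
    def test_candidate_contained_in_identified_peptide_kept(self):
        # identified peptide contains the candidate; shared residues include
        # the mutant position by containment
        cand = _cand("KTAFIAKL", start=2, muts=(4,))
        ms = MSEvidence(frozenset({"MKTAFIAKLW"}))
        kept = filter_ms([cand], ms, FilterConfig())
        assert len(kept) == 1 and kept[0].ms_support

    def test_no_supporting_peptide_removed(self):
        kept = filter_ms([_cand("KTAFIAKL")], MSEvidence(frozenset({"WWWWWWW"})),
                         FilterConfig())
        assert kept == []

    def test_wildtype_only_overlap_removed(self):
        # identified peptide is a substring of the candidate but covers no
        # mutant position (mutation at window position 8)
        cand = _cand("KTAYIAKLW", muts=(9,))
        ms = MSEvidence(frozenset({"KTAYIAK"}))  # positions 1-7 only
        assert filter_ms([cand], ms, FilterConfig()) == []

    def test_identified_substring_covering_mutation_kept(self):
        cand = _cand("KTAYIAKLW", muts=(4,))
        ms = MSEvidence(frozenset({"TAYIAKL"}))  # positions 2-8 cover 4
        assert len(filter_ms([cand], ms, FilterConfig())) == 1

    def test_colocated_overlap_requires_mutant_protein(self):
        # candidate 2..9 on the mutant protein; MS peptide 5..12 overlaps by 5
        mutant = MutantProtein("v1", "MKTAFIAKLWCDEF", (5, 5), VariantClass.MISSENSE)
        cand = _cand("KTAFIAKL", start=2, muts=(4,))
        ms = MSEvidence(frozenset({"FIAKLWCD"}))  # 5..12: overlap 5..9 covers site 5
        cfg = FilterConfig(ms_min_overlap=5)
        kept = filter_ms([cand], ms, cfg, mutants={"v1": mutant})
        assert len(kept) == 1
        # without the mutant protein the co-location clause cannot fire
        assert filter_ms([cand], ms, cfg) == []

    def test_overlap_below_minimum_removed(self):
        mutant = MutantProtein("v1", "MKTAFIAKLWCDEFGH", (5, 5), VariantClass.MISSENSE)
        cand = _cand("KTAFIAKL", start=2, muts=(4,))
        ms = MSEvidence(frozenset({"FIAKLWCD"}))
        kept = filter_ms([cand], ms, FilterConfig(ms_min_overlap=7),
                         mutants={"v1": mutant})
        assert kept == []


class TestSimilaritySearch:
    def _db(self, peptides):
        return [NeoDBEntry(p, NeoTier.HIGH) for p in peptides]

    def test_identity_hit_scores_100_and_sorts_first(self):
        db = self._db(["SIINFEKL", "WWWWWWWWW"])
        hits = similarity_search("SIINFEKL", db)
        assert hits[0].similarity == 100.0
        assert hits[0].subject.peptide == "SIINFEKL"

    def test_no_positive_pairs_scores_0(self):
        hits = similarity_search("AAAAAAAAA", self._db(["WWWWWWWWW"]))
        assert hits[0].similarity == 0.0

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            similarity_search("SIINFEKL", [])

    def test_nonstandard_query_rejected(self):
        with pytest.raises(ValueError):
            similarity_search("SIINFEXL", self._db(["SIINFEKL"]))


class TestMatchingRatio:
    @pytest.mark.parametrize("matched,compared,expected", [
        (122, 636, 19.18),
        (4, 19, 21.05),
        (0, 10, 0.0),
    ])
    def test_printed_pairs(self, matched, compared, expected):
        assert matching_ratio(matched, compared) == expected

    def test_empty_comparison_is_na_not_zero(self):
        assert matching_ratio(0, 0) is None

    @settings(max_examples=300, deadline=None)
    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    def test_matches_exact_rational_arithmetic(self, a, b):
        m, n = min(a, b), max(a, b)
        if n == 0:
            assert matching_ratio(m, n) is None
            return
        exact = Fraction(100 * m, n)
        assert matching_ratio(m, n) == pytest.approx(float(exact), abs=0.005000001)
        assert matching_ratio(m, n) == round(float(exact), 2)


class TestNeoDBFilter:
    def test_planted_identity_matches_band(self):
        db = [NeoDBEntry("SIINFEKL", NeoTier.HIGH),
              NeoDBEntry("WWWWWWWWW", NeoTier.MEDIUM)]
        cands = [_cand("SIINFEKL", muts=(4,)), _cand("AAAAAAAA", muts=(4,), vid="v2")]
        matched, ratio = filter_neodb(cands, db, FilterConfig())
        assert [c.peptide.sequence for c in matched] == ["SIINFEKL"]
        assert matched[0].best_similarity == 100.0
        assert ratio == 50.0

    def test_empty_candidates_na_ratio(self):
        matched, ratio = filter_neodb([], [NeoDBEntry("SIINFEKL", NeoTier.HIGH)],
                                      FilterConfig())
        assert matched == [] and ratio is None

    def test_band_bounds_are_inclusive(self):
        db = [NeoDBEntry("SIINFEKL", NeoTier.HIGH)]
        cfg = FilterConfig(sim_threshold_low=100, sim_threshold_high=100)
        matched, _ = filter_neodb([_cand("SIINFEKL", muts=(4,))], db, cfg)
        assert len(matched) == 1


class TestStrictFilter:
    @pytest.mark.parametrize("ic50,tpm,kept", [
        (34.0, 33.0, True),      # both exactly at the inclusive boundaries
        (34.0001, 33.0, False),
        (34.0, 32.9999, False),
        (34.1, 100.0, False),
        (10.0, 32.9, False),
        (1.0, 1000.0, True),
    ])
    def test_boundaries(self, ic50, tpm, kept):
        out = filter_strict([_cand(ic50=ic50, tpm=tpm)], FilterConfig())
        assert bool(out) is kept

    def test_class_ii_skipped_with_warning_not_error(self):
        c = _cand("K" * 15 + "L", muts=(4,), mhc="II", ic50=1.0, tpm=100.0)
        stage = StageResult("", 0, 0)
        out = filter_strict([c], FilterConfig(), stage=stage)
        assert out == []
        assert stage.removed_reasons == {"class II skipped": 1}

    def test_infinite_thresholds_are_identity(self):
        cands = [_cand(ic50=x, tpm=t) for x, t in ((5, 5), (5000, 0.1), (34, 33))]
        cfg = FilterConfig(strict_ic50_max_nM=float("inf"), strict_tpm_min=0)
        assert filter_strict(cands, cfg) == cands


class TestCascadeMonotonicity:
    def test_each_stage_output_subset_of_input(self):
        rng = random.Random(10)
        cands = []
        for i in range(30):
            seq = "".join(rng.choices(AA, k=9))
            cands.append(_cand(seq, muts=(5,), vid=f"v{i % 6}",
                               ic50=rng.uniform(1, 100), rank=rng.uniform(0.1, 2)))
        table = ExpressionTable({f"v{i}": rng.uniform(0, 100) for i in range(6)})
        cfg = FilterConfig()
        e = filter_expression(cands, table, cfg)
        assert {c.peptide for c in e} <= {c.peptide for c in cands}
        ms = MSEvidence(frozenset({c.peptide.sequence for c in e[:7]} | {"WWWWWWW"}))
        m = filter_ms(e, ms, cfg)
        assert {c.peptide for c in m} <= {c.peptide for c in e}
        db = [NeoDBEntry("".join(rng.choices(AA, k=9)), NeoTier.HIGH) for _ in range(5)]
        matched, _ = filter_neodb(m, db, cfg)
        assert {c.peptide for c in matched} <= {c.peptide for c in m}
        s = filter_strict(m, cfg)
        assert {c.peptide for c in s} <= {c.peptide for c in m}
        assert len(cands) >= len(e) >= len(m) >= len(s)


class TestConfigValidation:
    def test_bad_similarity_band_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(sim_threshold_low=50, sim_threshold_high=20)

    def test_nonpositive_thresholds_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(strict_ic50_max_nM=0)
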