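"""Variant/fusion/expression/MS/neodb record types and their parsers."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neopipe.models import (
    ExpressionTable,
    FusionRecord,
    FrameStatus,
    MSEvidence,
    NeoDBEntry,
    NeoTier,
    VariantClass,
    VariantParseError,
    VariantRecord,
    load_neodb,
    parse_cdna_change,
    parse_expression,
    parse_ms_evidence,
    parse_protein_change,
    parse_variant_table,
    write_variant_table,
)


class TestProteinChangeGrammar:
    @pytest.mark.parametrize("text,expected", [
        ("p.Y5F", (VariantClass.MISSENSE, 5, "Y", "F")),
        ("p.A4_Y5del", (VariantClass.INFRAME_DEL, 4, "AY", "")),
        ("p.M1del", (VariantClass.INFRAME_DEL, 1, "M", "")),
        ("p.K3_T4insQQ", (VariantClass.INFRAME_INS, 3, "K", "QQ")),
        ("p.K3insQQ", (VariantClass.INFRAME_INS, 3, "K", "QQ")),
    ])
    def test_accepted_forms(self, text, expected):
        assert parse_protein_change(text) == expected

    @pytest.mark.parametrize("text", [
        "p.Y5Y", "Y5F", "p.5YF", "p.K3_T5insQQ", "p.B2C", "", "p.A4_Y3del",
    ])
    def test_rejected_forms(self, text):
        with pytest.raises(VariantParseError):
            parse_protein_change(text)

    def test_multiresidue_deletion_pads_interior_with_wildcards(self):
        cls, pos, ref, alt = parse_protein_change("p.A4_K7del")
        assert (cls, pos, alt) == (VariantClass.INFRAME_DEL, 4, "")
        assert ref == "A??K"


class TestCdnaGrammar:
    def test_insertion(self):
        e = parse_cdna_change("c.6_7insC")
        assert (e.kind, e.pos, e.bases) == ("ins", 6, "C")

    def test_deletion_span(self):
        e = parse_cdna_change("c.5_6delAT")
        assert (e.kind, e.pos, e.bases) == ("del", 5, "AT")

    def test_single_base_deletion_without_bases(self):
        e = parse_cdna_change("c.5del")
        assert (e.kind, e.pos, len(e.bases)) == ("del", 5, 1)

    @pytest.mark.parametrize("text", ["c.6_8insC", "c.5_4delAT", "c.5_6delATG", "g.5del"])
    def test_rejected(self, text):
        with pytest.raises(VariantParseError):
            parse_cdna_change(text)


class TestVariantRecordInvariants:
    def test_missense_requires_single_differing_residues(self):
        with pytest.raises(VariantParseError):
            VariantRecord("v", "G", "T", "P", VariantClass.MISSENSE,
                          protein_pos=5, ref_aa="Y", alt_aa="Y")

    def test_frameshift_requires_frame_disrupting_edit(self):
        with pytest.raises(VariantParseError):
            VariantRecord("v", "G", "T", "P", VariantClass.FRAMESHIFT,
                          protein_pos=2, cdna_change="c.4_6delATG")

    def test_non_fusion_requires_position(self):
        with pytest.raises(VariantParseError):
            VariantRecord("v", "G", "T", "P", VariantClass.MISSENSE,
                          protein_pos=0, ref_aa="Y", alt_aa="F")


class TestFusionRecord:
    def test_junction_index_bounds(self):
        FusionRecord("f", "A", "B", "M" * 20, 10, FrameStatus.IN_FRAME)
        with pytest.raises(VariantParseError):
            FusionRecord("f", "A", "B", "M" * 20, 20, FrameStatus.IN_FRAME)
        with pytest.raises(VariantParseError):
            FusionRecord("f", "A", "B", "M" * 20, 0, FrameStatus.IN_FRAME)


class TestVariantTableParsing:
    def test_annovar_missense_row(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("Gene\tTranscript\tExonicFunc\tAAChange\n"
                     "GENE1\tNM_1\tnonsynonymous SNV\tp.Y5F\n")
        res = parse_variant_table(p, dialect="annovar")
        (rec,) = res.records
        assert rec.var_class is VariantClass.MISSENSE
        assert (rec.protein_pos, rec.ref_aa, rec.alt_aa) == (5, "Y", "F")

    def test_annovar_frameshift_records_cdna(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("Gene\tTranscript\tExonicFunc\tAAChange\tCdnaChange\n"
                     "GENE1\tNM_1\tframeshift insertion\tp.K3fs\tc.6_7insC\n")
        res = parse_variant_table(p, dialect="annovar")
        (rec,) = res.records
        assert rec.var_class is VariantClass.FRAMESHIFT
        assert rec.cdna_change == "c.6_7insC"

    def test_synonymous_rows_skipped_and_counted(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("Gene\tTranscript\tExonicFunc\tAAChange\n"
                     "G1\tT1\tsynonymous SNV\tp.Y5Y\n"
                     "G2\tT2\tnonsynonymous SNV\tp.A2C\n")
        res = parse_variant_table(p, dialect="annovar")
        assert len(res.records) == 1 and res.skipped == 1

    def test_unknown_class_token_rejected_not_dropped(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("Gene\tTranscript\tExonicFunc\tAAChange\n"
                     "G1\tT1\tstopgain\tp.Y5X\n")
        res = parse_variant_table(p, dialect="annovar")
        assert not res.records and len(res.rejects) == 1

    def test_missing_column_is_fatal_with_name(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("Gene\tTranscript\tAAChange\nG1\tT1\tp.Y5F\n")
        with pytest.raises(ValueError, match="ExonicFunc"):
            parse_variant_table(p, dialect="annovar")

    def test_empty_table(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("Gene\tTranscript\tExonicFunc\tAAChange\n")
        res = parse_variant_table(p, dialect="annovar")
        assert res.records == [] and res.rejects == []

    def test_simple_dialect_round_trip(self, tmp_path):
        records = [
            VariantRecord("v1", "G1", "T1", "P1", VariantClass.MISSENSE,
                          protein_pos=5, ref_aa="Y", alt_aa="F"),
            VariantRecord("v2", "G2", "T2", "P2", VariantClass.INFRAME_INS,
                          protein_pos=3, ref_aa="K", alt_aa="QQ"),
            VariantRecord("v3", "G3", "T3", "P3", VariantClass.INFRAME_DEL,
                          protein_pos=4, ref_aa="AY"),
            VariantRecord("v4", "G4", "T4", "P4", VariantClass.FRAMESHIFT,
                          protein_pos=2, cdna_change="c.6_7insC"),
        ]
        path = tmp_path / "rt.tsv"
        write_variant_table(records, path)
        res = parse_variant_table(path, dialect="simple")
        assert not res.rejects
        reparsed = {r.variant_id: r for r in res.records}
        for orig in records:
            got = reparsed[orig.variant_id]
            assert got.var_class is orig.var_class
            assert got.protein_pos == orig.protein_pos
            assert got.ref_aa == orig.ref_aa or orig.var_class is VariantClass.FRAMESHIFT
            assert got.alt_aa == orig.alt_aa
            assert got.cdna_change == orig.cdna_change

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_parser_never_emits_invariant_violating_records(self, tmp_path_factory, data):
        """Randomized rows either parse into class-consistent records or land
        in the rejects list — never a silently broken record."""
        aa = "ACDEFGHIKLMNPQRSTVWY"
        cls = data.draw(st.sampled_from(
            ["missense", "inframe_ins", "inframe_del", "frameshift", "bogus"]))
        pos = data.draw(st.integers(1, 50))
        r1, r2 = data.draw(st.sampled_from(aa)), data.draw(st.sampled_from(aa))
        change = {
            "missense": f"p.{r1}{pos}{r2}",
            "inframe_ins": f"p.{r1}{pos}ins{r2}",
            "inframe_del": f"p.{r1}{pos}del",
            "frameshift": f"p.{r1}{pos}fs",
            "bogus": data.draw(st.text(max_size=8)).replace("\t", "").replace("\n", ""),
        }[cls]
        cdna = "c.6_7insC" if data.draw(st.booleans()) else ""
        tmp = tmp_path_factory.mktemp("rows") / "v.tsv"
        tmp.write_text(
            "variant_id\tgene\ttranscript_id\tprotein_id\tvar_class\t"
            "protein_change\tcdna_change\n"
            f"v\tG\tT\tP\t{cls}\t{change}\t{cdna}\n")
        res = parse_variant_table(tmp, dialect="simple")
        assert len(res.records) + len(res.rejects) == 1
        for rec in res.records:
            # re-running the constructor re-validates every class invariant
            VariantRecord(**{f: getattr(rec, f) for f in (
                "variant_id", "gene", "transcript_id", "protein_id", "var_class",
                "protein_pos", "ref_aa", "alt_aa", "cdna_change")})


class TestExpression:
    def test_parse_and_duplicate_max_rule(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("target_id\ttpm\ntx1\t5.0\ntx2\t0.0\ntx1\t7.0\n")
        table = parse_expression(p)
        assert len(table) == 2
        assert table.get("tx1") == 7.0 and table.get("tx2") == 0.0

    def test_negative_tpm_fatal(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("target_id\ttpm\ntx1\t-1\n")
        with pytest.raises(ValueError):
            parse_expression(p)

    def test_direct_add_negative_rejected(self):
        with pytest.raises(ValueError):
            ExpressionTable({"t": -0.1})


class TestMSEvidence:
    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            MSEvidence(frozenset({"SHORT"}))
        MSEvidence(frozenset({"LNGPEPT"}))

    def test_parse_requires_sequence_column(self, tmp_path):
        p = tmp_path / "pep.tsv"
        p.write_text("Peptide\nAAAAAAA\n")
        with pytest.raises(ValueError, match="Sequence"):
            parse_ms_evidence(p)
        p.write_text("Sequence\nAAAAAAA\nKKKKKKKK\n")
        assert parse_ms_evidence(p).peptides == {"AAAAAAA", "KKKKKKKK"}


class TestNeoDB:
    def test_fasta_with_tiers(self, tmp_path):
        p = tmp_path / "db.fasta"
        p.write_text(">a tier=high\nSIINFEKL\n>b tier=medium\nKVAELVHFL\n"
                     ">c tier=high\nGLCTLVAML\n")
        entries = load_neodb(p)
        assert len(entries) == 3
        assert {e.tier for e in entries} == {NeoTier.HIGH, NeoTier.MEDIUM}

    def test_same_peptide_two_tiers_kept_distinct(self, tmp_path):
        p = tmp_path / "db.tsv"
        p.write_text("SIINFEKL\thigh\nSIINFEKL\tmedium\nSIINFEKL\thigh\n")
        entries = load_neodb(p)
        assert len(entries) == 2

    def test_invalid_characters_rejected_with_warning(self, tmp_path):
        p = tmp_path / "db.tsv"
        p.write_text("AB1CD\thigh\nSIINFEKL\thigh\n")
        entries = load_neodb(p)
        assert [e.peptide for e in entries] == ["SIINFEKL"]

    def test_entry_alphabet_invariant(self):
        with pytest.raises(ValueError):
            NeoDBEntry("AB1CD", NeoTier.HIGH)
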