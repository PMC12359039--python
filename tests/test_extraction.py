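"""Unit tests for text-evidence extraction."""

import pytest

from fairbadge.extraction import (ArticleDocument, DasClass, RetrievalStatus,
                                  NotDeterminableError, SequencingMethod,
                                  classify_das, classify_sequencing_method,
                                  detect_accessions, detect_code_links,
                                  detect_primers, extract_all)


class TestAccessions:
    @pytest.mark.parametrize("text,expected", [
        ("", []),
        ("Raw reads were deposited in the NCBI SRA under BioProject "
         "PRJNA765432 and runs SRR1000001.",
         [("PRJNA765432", "SRA", "bioproject"), ("SRR1000001", "SRA", "run")]),
        # gene symbols must not collide with accession prefixes
        ("the protein SRP54 localizes to membranes", []),
        ("samples SAMEA7654321 and SAMN12345678 under ERP123456",
         [("SAMEA7654321", "ENA", "sample"), ("SAMN12345678", "SRA", "sample"),
          ("ERP123456", "ENA", "study")]),
        ("metagenomes mgm4567890.3 on MG-RAST; GSA accession CRA001234",
         [("mgm4567890.3", "MG-RAST", "analysis"),
          ("CRA001234", "CNCB-NGDC", "study")]),
        ("dataset EGAD00001234567 at the EGA",
         [("EGAD00001234567", "EGA", "analysis")]),
        # token embedded in a longer word must not match
        ("gene XSRR123456Y was overexpressed", []),
    ])
    def test_catalogue(self, text, expected):
        hits = detect_accessions(text)
        assert [(h.token, h.registry, h.record_type) for h in hits] == expected

    def test_spans_dedup_and_order(self):
        text = "PRJEB11111 then ERR123456 then PRJEB11111 again"
        hits = detect_accessions(text)
        assert [h.token for h in hits] == ["PRJEB11111", "ERR123456"]
        for h in hits:
            assert text[h.span[0]:h.span[1]] == h.token

    def test_range_endpoints_flagged_not_expanded(self):
        hits = detect_accessions("runs SRR1000001 to SRR1000004 were uploaded")
        assert [h.token for h in hits] == ["SRR1000001", "SRR1000004"]
        assert all(h.is_range_endpoint for h in hits)
        # unrelated neighbours are not a range
        hits = detect_accessions("SRR1000001 was linked to sample SRS123456")
        assert not any(h.is_range_endpoint for h in hits)


class TestPrimers:
    def test_labeled_pair(self):
        text = ("amplified with primers 515F (GTGYCAGCMGCCGCGGTAA) and "
                "806R (GGACTACNVGGGTWTCTAAT)")
        hits = detect_primers(text)
        assert [(h.label, h.sequence) for h in hits] == [
            ("515F", "GTGYCAGCMGCCGCGGTAA"), ("806R", "GGACTACNVGGGTWTCTAAT")]
        for h in hits:
            assert text[h.span[0]:h.span[1]].upper() == h.sequence

    def test_no_candidate_sequence(self):
        assert detect_primers("the primer set targeted the V4 region") == []

    def test_context_guard_rejects_isolated_iupac_run(self):
        assert detect_primers("GenBank accession GGGGGGGGGGGGGGG was cited") == []

    def test_case_insensitive(self):
        upper = detect_primers("forward primer 27F (AGAGTTTGATCMTGGCTCAG)")
        lower = detect_primers("forward primer 27F (agagtttgatcmtggctcag)")
        assert [h.sequence for h in upper] == [h.sequence for h in lower] \
            == ["AGAGTTTGATCMTGGCTCAG"]

    def test_minimum_length(self):
        # 11-mer below the configured minimum of 12
        assert detect_primers("reverse primer (GGACTACNVGG)") == []


class TestSequencingMethod:
    @pytest.mark.parametrize("text,expected", [
        ("16S rRNA gene amplicon sequencing of the V4 region",
         SequencingMethod.MARKER_GENE),
        ("shotgun metagenomic sequencing libraries", SequencingMethod.METAGENOME),
        ("", SequencingMethod.UNKNOWN),
        ("both 16S profiling and shotgun libraries were prepared",
         SequencingMethod.BOTH),
        ("ITS2 metabarcoding of fungal communities", SequencingMethod.MARKER_GENE),
        # 'its' as an English word is not the ITS marker region
        ("the cohort and its dietary records", SequencingMethod.UNKNOWN),
    ])
    def test_lexicons(self, text, expected):
        assert classify_sequencing_method(text) is expected


class TestCodeLinks:
    @pytest.mark.parametrize("text,expected", [
        ("Code used for analysis and figure generation can be found at "
         "https://zenodo.org/records/16039307",
         ["https://zenodo.org/records/16039307"]),
        ("Scripts are available at https://github.com/lab/analysis",
         ["https://github.com/lab/analysis"]),
        ("see our institutional website", []),
        # non-catalogue host without code wording nearby
        ("survey hosted at https://example.org/form", []),
    ])
    def test_detection(self, text, expected):
        assert detect_code_links(text) == expected

    def test_dedup_preserves_first_occurrence(self):
        text = ("pipeline at https://github.com/lab/tool and again "
                "https://github.com/lab/tool (also https://gitlab.com/lab/b)")
        assert detect_code_links(text) == [
            "https://github.com/lab/tool", "https://gitlab.com/lab/b"]


class TestDas:
    @pytest.mark.parametrize("das,expected", [
        ("Data are available upon reasonable request from the corresponding "
         "author.", DasClass.UPON_REQUEST),
        ("Sequences were deposited in the ENA under PRJEB11111.",
         DasClass.PUBLIC_DEPOSIT),
        (None, DasClass.ABSENT),
        ("All data are included within the article.", DasClass.IN_PAPER_ONLY),
        ("Access is granted through a managed access procedure reviewed by "
         "the data access committee.", DasClass.RESTRICTED_WITH_PROCEDURE),
    ])
    def test_classes(self, das, expected):
        assert classify_das(das) is expected

    def test_precedence_deposit_beats_request(self):
        das = ("Reads were deposited in the SRA under PRJNA765432; further "
               "details are available upon reasonable request.")
        assert classify_das(das) is DasClass.PUBLIC_DEPOSIT

    def test_fallback_text_used_when_no_das(self):
        assert classify_das(None, "data available upon request from authors") \
            is DasClass.UPON_REQUEST


class TestExtractAll:
    def _doc(self):
        return ArticleDocument(
            "PMC1", sections=[
                ("Methods", "The V4 region of the 16S rRNA gene was amplified "
                            "with primers 515F (GTGYCAGCMGCCGCGGTAA)."),
                ("Data Availability",
                 "Reads were deposited in the SRA under PRJNA765432. Code at "
                 "https://github.com/lab/tool."),
            ],
            das_text="Reads were deposited in the SRA under PRJNA765432. "
                     "Code at https://github.com/lab/tool.")

    def test_composition(self):
        res = extract_all(self._doc())
        assert [h.token for h in res.accessions] == ["PRJNA765432"]
        assert res.sequencing_method is SequencingMethod.MARKER_GENE
        assert res.primers and res.code_links
        assert res.das_class is DasClass.PUBLIC_DEPOSIT

    def test_databases_superset_of_accession_registries(self):
        res = extract_all(self._doc())
        assert {h.registry for h in res.accessions} <= res.databases_mentioned

    def test_determinism(self):
        assert extract_all(self._doc()) == extract_all(self._doc())

    def test_not_determinable(self):
        doc = ArticleDocument("PMC2",
                              retrieval_status=RetrievalStatus.NO_FULLTEXT)
        with pytest.raises(NotDeterminableError):
            extract_all(doc)

    def test_upon_request_only_article(self):
        doc = ArticleDocument(
            "PMC3", sections=[("Data Availability", "Available upon request.")],
            das_text="Available upon request.")
        res = extract_all(doc)
        assert res.accessions == [] and res.das_class is DasClass.UPON_REQUEST
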