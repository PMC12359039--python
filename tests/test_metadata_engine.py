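"""Metadata harmonization, tier evaluation, and sparsity analytics."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from fairbadge.metadata_engine import (PopulationMatrix, SampleRecord,
                                       StudyMetadata, UnevaluableError,
                                       default_checklist,
                                       evaluate_metadata_tier,
                                       harmonize_attributes, is_missing,
                                       median_population, population_matrix,
                                       sparsity_histogram)
import pandas as pd


def study(study_id, attr_sets):
    return StudyMetadata(study_id, records=[
        SampleRecord(f"{study_id}.s{i}", dict(attrs))
        for i, attrs in enumerate(attr_sets)])


class TestHarmonize:
    def test_documented_submitter_variant(self):
        recs = harmonize_attributes([SampleRecord("s1", {"User_sample_ID": "S1"})])
        assert recs[0].attributes == {"sample name": "S1"}

    def test_unmapped_passthrough_verbatim(self):
        recs = harmonize_attributes([SampleRecord("s1", {"novel_attribute_x": "7"})])
        assert recs[0].attributes == {"novel_attribute_x": "7"}

    def test_idempotent(self):
        rec = SampleRecord("s1", {"Collection_Date": "2020-01-01",
                                  "weird one": "x"})
        once = harmonize_attributes([rec])
        twice = harmonize_attributes(once)
        assert once[0].attributes == twice[0].attributes

    def test_case_and_separator_insensitive(self):
        for raw in ("HOST-SEX", "host_sex", "Host Sex"):
            recs = harmonize_attributes([SampleRecord("s1", {raw: "female"})])
            assert recs[0].attributes == {"host sex": "female"}

    def test_collision_keeps_first_non_missing(self):
        rec = SampleRecord("s1", {"sample name": "not collected",
                                  "User_sample_ID": "S1"})
        recs = harmonize_attributes([rec])
        assert recs[0].attributes == {"sample name": "S1"}

    def test_never_increases_attribute_union(self):
        rng = random.Random(7)
        names = ["host_sex", "gender", "lat_lon", "custom attr", "TAXID"]
        records = [SampleRecord(f"s{i}",
                                {n: "v" for n in rng.sample(names, 3)})
                   for i in range(10)]
        before = {n for r in records for n in r.attributes}
        after = {n for r in harmonize_attributes(records) for n in r.attributes}
        assert len(after) <= len(before)


class TestIsMissing:
    @pytest.mark.parametrize("value,expected", [
        ("not collected", True), ("Homo sapiens gut metagenome", False),
        ("   ", True), ("NA", True), ("n/a", True), ("-", True),
        (None, True), ("0", False),
    ])
    def test_tokens(self, value, expected):
        assert is_missing(value) is expected


class TestTierEvaluation:
    def _fields(self, tier_index):
        return default_checklist()[tier_index].required_fields

    def test_bronze_study_blocked_by_sequencing_method(self):
        s = study("A", [{f: "v" for f in self._fields(0)}] * 3)
        res = evaluate_metadata_tier(s)
        assert res.tier_awarded.value == "bronze"
        assert res.blocking_fields[0] == "sequencing method"

    def test_silver_study_through_host_sex(self):
        s = study("B", [{f: "v" for f in self._fields(1)}] * 3)
        assert evaluate_metadata_tier(s).tier_awarded.value == "silver"

    def test_missing_collection_date_means_none(self):
        fields = [f for f in self._fields(0) if f != "collection date"]
        s = study("C", [{f: "v" for f in fields}] * 3)
        res = evaluate_metadata_tier(s)
        assert res.tier_awarded.value == "none"
        assert "collection date" in res.blocking_fields

    def test_gold_study_has_no_blockers(self):
        s = study("D", [{f: "v" for f in self._fields(2)}] * 2)
        res = evaluate_metadata_tier(s)
        assert res.tier_awarded.value == "gold" and res.blocking_fields == []

    def test_threshold_relaxation(self):
        rows = [{f: "v" for f in self._fields(0)} for _ in range(4)]
        rows[0]["collection date"] = "not collected"  # 3/4 populated
        s = study("E", rows)
        assert evaluate_metadata_tier(s).tier_awarded.value == "none"
        relaxed = evaluate_metadata_tier(s, completeness_threshold=0.75)
        assert relaxed.tier_awarded.value == "bronze"

    def test_empty_study_unevaluable(self):
        with pytest.raises(UnevaluableError):
            evaluate_metadata_tier(StudyMetadata("empty"))

    def test_adding_values_never_lowers_tier(self):
        rng = random.Random(13)
        gold_fields = self._fields(2)
        tiers = ["none", "bronze", "silver", "gold"]
        for _ in range(25):
            present = rng.sample(gold_fields, rng.randint(0, len(gold_fields)))
            s = study("F", [{f: "v" for f in present}] * 3)
            base = tiers.index(evaluate_metadata_tier(s).tier_awarded.value)
            extra = rng.choice([f for f in gold_fields if f not in present]
                               or gold_fields)
            s2 = study("F", [{**{f: "v" for f in present}, extra: "v"}] * 3)
            assert tiers.index(evaluate_metadata_tier(s2).tier_awarded.value) >= base


class TestPopulationMatrix:
    def test_proportions_count_studies_with_any_value(self):
        studies = [
            study("S1", [{"host sex": "female"}]),
            study("S2", [{"host diet": "omnivore"}]),
            study("S3", [{"host diet": "vegan", "host sex": ""}]),
        ]
        pm = population_matrix(studies)
        assert pm.proportions["host sex"] == pytest.approx(1 / 3)
        assert pm.proportions["host diet"] == pytest.approx(2 / 3)

    def test_missing_tokens_do_not_populate(self):
        studies = [study("S1", [{"host diet": "not collected"},
                                {"host diet": "NA"}]),
                   study("S2", [{"host diet": "vegan"}])]
        pm = population_matrix(studies)
        assert not pm.matrix.loc["host diet", "S1"]
        assert pm.matrix.loc["host diet", "S2"]

    def test_empty_input_unevaluable(self):
        with pytest.raises(UnevaluableError):
            population_matrix([])


class TestSparsityHistogram:
    def _matrix(self, proportions):
        n = len(proportions)
        df = pd.DataFrame(
            {f"S{j}": [j < round(p * 10) for p in proportions]
             for j in range(10)},
            index=[f"a{i}" for i in range(n)], dtype=bool)
        return PopulationMatrix(df)

    def test_worked_example(self):
        m = self._matrix([0.0, 0.5, 1.0])
        # realized proportions 0, 0.5, 1 over edges (0, .1, .5, 1]
        assert sparsity_histogram(m, [0, 0.1, 0.5, 1.0]) == [1, 1, 1]

    def test_all_full_in_last_bin(self):
        m = self._matrix([1.0, 1.0, 1.0])
        assert sparsity_histogram(m, [0, 0.5, 1.0]) == [0, 3]

    @given(st.lists(st.integers(min_value=0, max_value=10), min_size=1,
                    max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_conservation(self, tenths):
        m = self._matrix([t / 10 for t in tenths])
        counts = sparsity_histogram(m, [0, 0.1, 0.25, 0.5, 0.75, 1.0])
        assert sum(counts) == len(tenths)

    def test_invalid_edges_rejected(self):
        m = self._matrix([0.5])
        with pytest.raises(ValueError):
            sparsity_histogram(m, [0, 0.5, 0.5, 1.0])
        with pytest.raises(ValueError):
            sparsity_histogram(m, [0.1, 0.5, 1.0])


class TestMedianPopulation:
    def _matrix_from_bools(self, rows):
        df = pd.DataFrame(rows).T
        df.columns = [f"S{j}" for j in range(df.shape[1])]
        return PopulationMatrix(df.astype(bool))

    def test_single_study_rate_survey_condition(self):
        # every attribute populated in exactly 1 of 42 studies -> 1/42 = 2.4%
        rows = {f"a{i}": [j == i % 42 for j in range(42)] for i in range(5)}
        m = self._matrix_from_bools(rows)
        assert median_population(m) == pytest.approx(1 / 42)

    def test_even_count_mean_rule(self):
        rows = {"a": [False, False], "b": [True, True]}
        assert median_population(self._matrix_from_bools(rows)) == 0.5

    def test_odd_count_middle(self):
        rows = {"a": [True] + [False] * 9,
                "b": [True] * 4 + [False] * 6,
                "c": [True] * 9 + [False]}
        assert median_population(self._matrix_from_bools(rows)) == pytest.approx(0.4)
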