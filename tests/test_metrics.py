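"""Overlap metrics: worked examples, oracle equivalence, order properties."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from phenoeval.defmodel import (
    CodeCount,
    DefinitionRow,
    LogicLabel,
    ParameterError,
    PhenotypeDefinition,
    VocabularyId,
)
from phenoeval.metrics import (
    EMPTY_CANDIDATE,
    EvalConfig,
    MetricReport,
    aggregate,
    codes_overlap,
    evaluate_pair,
    logic_overlap,
    name_similarity,
    strings_overlap,
)

from conftest import definitions, pooled_codes

SNOMED = VocabularyId.resolve("SNOMED")


def make_candidate(codes, names=None, logic=None):
    names = names or [f"name {c}" for c in codes]
    logic = logic or [LogicLabel.INCLUSION] * len(codes)
    rows = tuple(
        DefinitionRow(lg, SNOMED, c, n, CodeCount.EXACTLY_ONCE)
        for c, n, lg in zip(codes, names, logic)
    )
    return PhenotypeDefinition("candidate", rows, source="candidate")


def brute_force_codes_overlap(candidate, reference):
    """Independent double-loop oracle over raw rows (no set machinery)."""
    cand_keys = []
    for row in candidate.rows:
        key = row.key()
        if key not in cand_keys:
            cand_keys.append(key)
    if not cand_keys:
        return 0.0
    hits = 0
    for key in cand_keys:
        for ref_row in reference.rows:
            if ref_row.key() == key:
                hits += 1
                break
    return 100.0 * hits / len(cand_keys)


class TestCodesOverlap:
    def test_three_of_four_codes_match(self, angina_reference):
        cand = make_candidate(["194823009", "61490001", "41334000", "99999999"])
        assert codes_overlap(cand, angina_reference) == pytest.approx(75.0)

    def test_identity_is_hundred(self, angina_reference):
        cand = angina_reference.with_rows(angina_reference.rows)
        assert codes_overlap(cand, angina_reference) == 100.0

    def test_disjoint_sets_are_zero(self, angina_reference):
        cand = make_candidate(["1", "2", "3"])
        assert codes_overlap(cand, angina_reference) == 0.0

    def test_empty_candidate_is_zero(self, angina_reference):
        empty = PhenotypeDefinition("x", (), source="candidate")
        assert codes_overlap(empty, angina_reference) == 0.0

    @given(candidate=definitions(codes=pooled_codes),
           reference=definitions(min_rows=1, codes=pooled_codes))
    def test_matches_brute_force_oracle(self, candidate, reference):
        assert codes_overlap(candidate, reference) == pytest.approx(
            brute_force_codes_overlap(candidate, reference)
        )

    @given(candidate=definitions(min_rows=1, codes=pooled_codes),
           reference=definitions(min_rows=1, codes=pooled_codes))
    def test_removing_non_matching_row_never_decreases(self, candidate, reference):
        base = codes_overlap(candidate, reference)
        ref_keys = reference.distinct_codes()
        keepable = [r for r in candidate.rows if r.key() in ref_keys]
        non_matching = [r for r in candidate.rows if r.key() not in ref_keys]
        if not non_matching:
            return
        slimmed = candidate.with_rows(keepable + non_matching[1:])
        assert codes_overlap(slimmed, reference) >= base - 1e-9


class TestLogicOverlap:
    def test_all_inclusion_match_on_codes(self, angina_reference):
        cand = make_candidate(["194823009"])
        assert logic_overlap(cand, angina_reference) == 100.0

    def test_half_flipped_pairs(self, angina_reference):
        codes = ["194823009", "61490001", "41334000", "85284003"]
        logic = [LogicLabel.INCLUSION, LogicLabel.INCLUSION,
                 LogicLabel.EXCLUSION, LogicLabel.EXCLUSION]
        cand = make_candidate(codes, logic=logic)
        assert logic_overlap(cand, angina_reference) == pytest.approx(50.0)

    def test_distribution_fallback_when_no_codes_match(self, angina_reference):
        cand = make_candidate(["1", "2"])  # disjoint codes, all inclusion
        assert logic_overlap(cand, angina_reference) == pytest.approx(100.0)

    def test_fallback_reflects_distribution_distance(self, angina_reference):
        cand = make_candidate(["1", "2"], logic=[LogicLabel.EXCLUSION] * 2)
        # reference is 100% inclusion, candidate 100% exclusion: TV = 1
        assert logic_overlap(cand, angina_reference) == pytest.approx(0.0)

    def test_fallback_can_be_disabled(self, angina_reference):
        cand = make_candidate(["1", "2"])
        assert logic_overlap(cand, angina_reference, fallback=False) == 0.0


class TestNameSimilarity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("Allergy to nuts", "Allergy to peanuts", 0.5),
            ("Angina, class I", "angina class i", 1.0),
            ("Acute coronary insufficiency", "Acute coronary insufficiency", 1.0),
            ("alpha beta", "gamma delta", 0.0),
            ("", "", 0.0),
            ("...", "!!!", 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert name_similarity(a, b) == pytest.approx(expected)
        assert name_similarity(b, a) == pytest.approx(expected)  # symmetric


class TestStringsOverlap:
    def test_identical_names_are_hundred(self, angina_reference):
        cand = angina_reference.with_rows(angina_reference.rows)
        assert strings_overlap(cand, angina_reference) == 100.0

    @pytest.mark.parametrize("threshold, expected", [(0.5, 100.0), (0.6, 0.0)])
    def test_nuts_vs_peanuts_flips_between_thresholds(self, threshold, expected):
        cand = make_candidate(["1"], names=["Allergy to nuts"])
        ref = PhenotypeDefinition(
            "r",
            (DefinitionRow(LogicLabel.INCLUSION, SNOMED, "2", "Allergy to peanuts",
                           CodeCount.EXACTLY_ONCE),),
        )
        assert strings_overlap(cand, ref, threshold) == pytest.approx(expected)

    def test_numeric_nonsense_names_are_zero(self, angina_reference):
        cand = make_candidate(["1", "2"], names=["1234 5678", "9876 5432"])
        assert strings_overlap(cand, angina_reference) == 0.0

    @pytest.mark.parametrize("threshold", [0.0, -0.5, 1.5])
    def test_threshold_domain(self, threshold, angina_reference):
        with pytest.raises(ParameterError):
            strings_overlap(angina_reference, angina_reference, threshold)

    @given(candidate=definitions(), reference=definitions(min_rows=1),
           lo=st.floats(0.05, 1.0), hi=st.floats(0.05, 1.0))
    def test_non_increasing_in_threshold(self, candidate, reference, lo, hi):
        lo, hi = min(lo, hi), max(lo, hi)
        assert strings_overlap(candidate, reference, lo) >= strings_overlap(
            candidate, reference, hi
        )


class TestAggregate:
    def test_avg_min_max(self):
        reports = [
            MetricReport(phenotype_name=f"p{i}", codes_overlap_pct=v)
            for i, v in enumerate([100.0, 50.0, 0.0])
        ]
        doc = aggregate(reports)
        agg = doc.aggregates["codes_overlap_pct"]
        assert (agg["average"], agg["min"], agg["max"]) == (50.0, 0.0, 100.0)

    def test_single_report_collapses(self):
        doc = aggregate([MetricReport(phenotype_name="p", logic_overlap_pct=80.0)])
        agg = doc.aggregates["logic_overlap_pct"]
        assert agg["average"] == agg["min"] == agg["max"] == 80.0

    def test_absent_metrics_excluded_pairwise(self):
        reports = [
            MetricReport(phenotype_name="a", codes_overlap_pct=10.0,
                         mapped_codes_overlap_pct=20.0),
            MetricReport(phenotype_name="b", codes_overlap_pct=30.0),
        ]
        doc = aggregate(reports)
        assert doc.aggregates["codes_overlap_pct"]["average"] == 20.0
        assert doc.aggregates["mapped_codes_overlap_pct"]["average"] == 20.0

    def test_empty_list_is_an_error(self):
        with pytest.raises(ParameterError):
            aggregate([])

    @given(st.lists(st.lists(st.floats(0, 100), min_size=1, max_size=6),
                    min_size=1, max_size=6))
    def test_min_le_avg_le_max(self, value_lists):
        reports = [
            MetricReport(phenotype_name=f"p{i}", codes_overlap_pct=vs[0],
                         strings_overlap_pct=vs[-1])
            for i, vs in enumerate(value_lists)
        ]
        for agg in aggregate(reports).aggregates.values():
            assert agg["min"] <= agg["average"] + 1e-9
            assert agg["average"] <= agg["max"] + 1e-9


class TestEvaluatePair:
    def test_identity_with_dictionary(self, angina_reference, angina_dictionaries):
        cand = angina_reference.with_rows(angina_reference.rows)
        report = evaluate_pair(cand, angina_reference, angina_dictionaries)
        assert report.codes_overlap_pct == 100.0
        assert report.logic_overlap_pct == 100.0
        assert report.strings_overlap_pct == 100.0
        assert report.hallucination_pct == 0.0

    def test_empty_candidate_reports_zero_with_diagnostic(self, angina_reference):
        empty = PhenotypeDefinition("x", (), source="candidate")
        report = evaluate_pair(empty, angina_reference)
        assert report.codes_overlap_pct == 0.0
        assert report.strings_overlap_pct == 0.0
        assert EMPTY_CANDIDATE in report.diagnostics

    @given(candidate=definitions(codes=pooled_codes),
           reference=definitions(min_rows=1, codes=pooled_codes))
    def test_composes_individual_metrics(self, candidate, reference):
        cfg = EvalConfig(strings_threshold=0.5)
        report = evaluate_pair(candidate, reference, config=cfg)
        assert report.codes_overlap_pct == codes_overlap(candidate, reference)
        assert report.logic_overlap_pct == logic_overlap(candidate, reference)
        assert report.strings_overlap_pct == strings_overlap(candidate, reference, 0.5)
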