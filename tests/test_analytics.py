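import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from padx._text import percentage
from padx.analytics import (
    DiagnosisRecord,
    build_knowledge_graph,
    chi_square_2x2,
    combination_patterns,
    dedupe_statements,
    frequency_and_diversity,
    missingness_analysis,
    normalize_statement,
)
from padx.extraction import ELEMENT_TYPES, ElementMention, ExtractionResult
from padx.segmenter import Span


def result(text, *element_values):
    mentions = []
    pos = 0
    for element, value in element_values:
        mentions.append(ElementMention(element, value, Span(pos, pos + max(len(value), 1))))
        pos += max(len(value), 1)
    return ExtractionResult(text, mentions)


class TestDedupe:
    def test_identical_texts_merge_with_count(self):
        records = [DiagnosisRecord("垂体腺瘤") for _ in range(5)]
        frame = dedupe_statements(records)
        assert len(frame) == 1
        assert frame.iloc[0]["count"] == 5

    def test_whitespace_variants_merge(self):
        records = [
            DiagnosisRecord(" 垂体 腺瘤 "),
            DiagnosisRecord("垂体 腺瘤"),
            DiagnosisRecord("垂体  腺瘤"),
        ]
        assert len(dedupe_statements(records)) == 1

    def test_random_fixture_matches_set_oracle(self):
        rng = random.Random(4)
        pool = ["垂体腺瘤", "无功能垂体腺瘤", "复发垂体大腺瘤", "垂体微腺瘤", "拟诊垂体腺瘤"]
        records = [DiagnosisRecord(rng.choice(pool)) for _ in range(50)]
        frame = dedupe_statements(records)
        assert len(frame) == len({normalize_statement(r.text) for r in records})
        assert frame["count"].sum() == 50


class TestFrequencyAndDiversity:
    def test_mention_counts_and_distinct_variants(self):
        results = [
            result("t1", ("endocrine_status", "ACTH")),
            result("t2", ("endocrine_status", "GH")),
            result("t3", ("endocrine_status", "ACTH")),
        ]
        report = frequency_and_diversity(results)
        assert report.frequency["endocrine_status"] == 3
        assert report.distinct_variants["endocrine_status"] == 2

    def test_empty_corpus_gives_zeros(self):
        report = frequency_and_diversity([])
        assert all(v == 0 for v in report.frequency.values())
        assert all(v == 0 for v in report.distinct_variants.values())

    def test_text_count_mode_counts_texts_not_mentions(self):
        bilateral = result(
            "t", ("knosp_grade", "左侧Knosp分级4级"), ("knosp_grade", "右侧Knosp分级0级")
        )
        assert frequency_and_diversity([bilateral]).frequency["knosp_grade"] == 2
        assert (
            frequency_and_diversity([bilateral], count_mode="text").frequency["knosp_grade"]
            == 1
        )

    @given(
        st.lists(
            st.lists(
                st.tuples(
                    st.sampled_from(ELEMENT_TYPES), st.sampled_from(["a", "b", "c"])
                ),
                max_size=4,
            ),
            max_size=8,
        )
    )
    def test_distinct_variants_never_exceed_frequency(self, corpus):
        results = [result(f"t{i}", *items) for i, items in enumerate(corpus)]
        report = frequency_and_diversity(results)
        for element in ELEMENT_TYPES:
            assert report.distinct_variants[element] <= max(report.frequency[element], 0) or (
                report.frequency[element] == 0 and report.distinct_variants[element] == 0
            )


class TestCombinationPatterns:
    def test_single_text_is_one_pattern_at_100_pct(self):
        frame = combination_patterns([result("t", ("histopathology", "腺瘤"))])
        assert len(frame) == 1
        assert frame.iloc[0]["pct"] == 100.0
        assert frame.iloc[0]["pattern"] == "histopathology"

    def test_ten_record_fixture_matches_brute_force(self):
        rng = random.Random(9)
        corpus = []
        for i in range(10):
            elements = rng.sample(ELEMENT_TYPES, rng.randint(1, 3))
            corpus.append(result(f"t{i}", *[(el, "x") for el in elements]))
        frame = combination_patterns(corpus)
        brute: dict[frozenset, int] = {}
        for res in corpus:
            key = frozenset(res.elements)
            brute[key] = brute.get(key, 0) + 1
        assert len(frame) == len(brute)
        for row in frame.itertuples():
            assert brute[frozenset(row.pattern.split("+"))] == row.count
        assert frame["count"].sum() == 10

    def test_counts_sum_to_texts_with_mentions(self):
        corpus = [result("t0"), result("t1", ("histopathology", "腺瘤"))]
        frame = combination_patterns(corpus)
        assert frame["count"].sum() == 1
        # percentage denominator is all texts
        assert frame.iloc[0]["pct"] == 50.0

    def test_pattern_key_uses_canonical_element_order(self):
        frame = combination_patterns(
            [result("t", ("histopathology", "腺瘤"), ("tumor_location", "垂体"))]
        )
        assert frame.iloc[0]["pattern"] == "tumor_location+histopathology"


class TestMissingness:
    def make_corpus(self):
        records, results = [], []
        # 4 principal: 1 missing size; 2 other: 1 missing size
        for i, (seq, has_size) in enumerate(
            [(1, True), (1, True), (1, True), (1, False), (2, True), (3, False)]
        ):
            records.append(DiagnosisRecord(f"t{i}", seq=seq))
            items = [("histopathology", "腺瘤")]
            if has_size:
                items.append(("tumor_size", "大"))
            results.append(result(f"t{i}", *items))
        return records, results

    def test_counts_and_percentages(self):
        records, results = self.make_corpus()
        table = missingness_analysis(records, results, ["tumor_size"])
        row = table.row("tumor_size")
        assert (row["missing_all"], row["missing_principal"], row["missing_other"]) == (2, 1, 1)
        assert row["pct_all"] == percentage(2, 6)
        assert row["pct_principal"] == 25.0
        assert row["pct_other"] == 50.0
        assert row["missing_all"] == row["missing_principal"] + row["missing_other"]

    def test_no_missing_gives_zero_and_skipped_test(self):
        records, results = self.make_corpus()
        table = missingness_analysis(records, results, ["histopathology"])
        row = table.row("histopathology")
        assert row["pct_all"] == 0.0
        assert row["p_value"] is None  # degenerate 2x2: nothing missing anywhere

    def test_large_contingency_table_is_highly_significant(self):
        p = chi_square_2x2([[686, 2999], [156, 169]])
        assert p is not None and p < 0.001


class TestKnowledgeGraph:
    def test_empty_corpus_gives_root_only(self):
        spec = build_knowledge_graph([])
        assert [n["id"] for n in spec.nodes] == ["root"]
        assert spec.edges == []

    def test_counts_match_enumeration(self):
        corpus = [
            result("t0", ("endocrine_status", "ACTH"), ("histopathology", "腺瘤")),
            result("t1", ("endocrine_status", "GH"), ("histopathology", "腺瘤")),
            result("t2", ("endocrine_status", "ACTH")),
        ]
        spec = build_knowledge_graph(corpus)
        distinct = {("endocrine_status", "ACTH"), ("endocrine_status", "GH"), ("histopathology", "腺瘤")}
        # root + 2 element nodes + one value node per distinct (element, value)
        assert len(spec.nodes) == 1 + 2 + len(distinct)
        assert len(spec.edges) == 2 + len(distinct)
        graph = spec.to_networkx()
        assert graph.number_of_nodes() == len(spec.nodes)

    def test_value_nodes_are_deduplicated(self):
        corpus = [result("t0", ("endocrine_status", "ACTH")), result("t1", ("endocrine_status", "ACTH"))]
        spec = build_knowledge_graph(corpus)
        value_nodes = [n for n in spec.nodes if n["kind"] == "value"]
        assert len(value_nodes) == 1


class TestPercentageConvention:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(2176, 4010, 54.3), (842, 4010, 21.0), (686, 3685, 18.6), (156, 325, 48.0)],
    )
    def test_reported_corpus_shares_reproduce(self, num, den, expected):
        assert percentage(num, den) == expected

    def test_half_up_at_the_boundary(self):
        assert percentage(1, 8, digits=1) == 12.5
        assert percentage(25, 1000) == 2.5
        assert percentage(5, 4000) == 0.1  # 0.125 -> 0.1
        assert percentage(15, 10000) == 0.2  # 0.15 rounds up, not to even
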