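import pytest

from padx.extraction import (
    ELEMENT_TYPES,
    match_elements,
    multilevel_segment,
    parse_knosp,
)
from padx.lexicon import LexiconEntry, build_prefix_lexicon
from padx.segmenter import segment


class TestMultilevelSegment:
    def test_compound_with_latin_part_decomposes_flat(self):
        """A compound disease term splits into organ + hormone + size morpheme
        + pathology word when exactly those parts are in the dictionary."""
        lex = build_prefix_lexicon(
            [
                LexiconEntry("ACTH垂体微腺瘤", 800, "disease"),
                LexiconEntry("垂体", 100, "organ"),
                LexiconEntry("ACTH", 100, "medicine"),
                LexiconEntry("微", 50, "other"),
                LexiconEntry("腺瘤", 100, "disease"),
            ]
        )
        (token,) = segment("ACTH垂体微腺瘤", lex)
        entity = multilevel_segment(token, lex)
        assert entity.to_dict() == {
            "word": "ACTH垂体微腺瘤",
            "entity_class": "disease",
            "value": [
                {"word": "ACTH", "entity_class": "medicine"},
                {"word": "垂体", "entity_class": "organ"},
                {"word": "微", "entity_class": "other"},
                {"word": "腺瘤", "entity_class": "disease"},
            ],
        }
        for node in entity.walk():
            if node.span is not None:
                assert node.word == "ACTH垂体微腺瘤"[node.span.start : node.span.end]

    def test_atomic_word_is_a_leaf(self):
        lex = build_prefix_lexicon([LexiconEntry("垂体", 100, "organ")])
        (token,) = segment("垂体", lex)
        assert multilevel_segment(token, lex).children == []

    def test_two_level_compound_nests(self):
        lex = build_prefix_lexicon(
            [
                LexiconEntry("甲乙丙丁", 100, "disease"),
                LexiconEntry("甲乙", 500, "other"),
                LexiconEntry("丙丁", 50, "other"),
                LexiconEntry("甲", 10, "other"),
                LexiconEntry("乙", 10, "other"),
            ]
        )
        (token,) = segment("甲乙丙丁", lex)
        entity = multilevel_segment(token, lex)
        assert [c.word for c in entity.children] == ["甲乙", "丙丁"]
        assert [g.word for g in entity.children[0].children] == ["甲", "乙"]
        assert entity.depth() == 3
        for node in entity.walk():
            if node.children:
                assert "".join(c.word for c in node.children) == node.word

    def test_depth_cap_limits_recursion(self):
        lex = build_prefix_lexicon(
            [
                LexiconEntry("甲乙丙丁", 100, "disease"),
                LexiconEntry("甲乙", 500, "other"),
                LexiconEntry("丙丁", 50, "other"),
                LexiconEntry("甲", 10, "other"),
                LexiconEntry("乙", 10, "other"),
            ]
        )
        (token,) = segment("甲乙丙丁", lex)
        assert multilevel_segment(token, lex, depth_cap=2).depth() == 2


class TestParseKnosp:
    def test_english_left_side_range(self):
        (m,) = parse_knosp("Left side Knosp grade 2–3")
        assert (m.side, m.grade_low, m.grade_high) == ("left", 2, 3)
        assert m.raw == "Left side Knosp grade 2–3"

    def test_bilateral_english_postfix_sides(self):
        mentions = parse_knosp("(Knosp grade 4 on the left, Knosp grade 0 on the right)")
        assert [(m.side, m.grade_low, m.grade_high) for m in mentions] == [
            ("left", 4, 4),
            ("right", 0, 0),
        ]

    def test_chinese_sides_and_range_separators(self):
        for sep in "–-~～":
            (m,) = parse_knosp(f"右侧Knosp分级1{sep}2级")
            assert (m.side, m.grade_low, m.grade_high) == ("right", 1, 2)
        (m,) = parse_knosp("双侧Knosp分级2级")
        assert m.side == "unspecified"

    def test_text_without_knosp_is_empty(self):
        assert parse_knosp("垂体大腺瘤") == []

    def test_out_of_range_grade_rejected_with_warning(self, caplog):
        assert parse_knosp("Knosp grade 5") == []
        assert "rejected" in caplog.text


# Manually labeled sample statements and their element decompositions
# (self-consistent readings; see docs for the two corrected typos).
TABLE_SAMPLES = [
    (
        "Recurrent ACTH-secreting pituitary adenoma",
        {
            "tumor_recurrence": ["Recurrent"],
            "tumor_location": ["pituitary"],
            "endocrine_status": ["ACTH"],
            "histopathology": ["adenoma"],
        },
    ),
    (
        "Highly suspected aggressive nonfunctioning giant pituitary adenoma",
        {
            "diagnostic_confirmation": ["Highly suspected"],
            "invasiveness": ["aggressive"],
            "endocrine_status": ["nonfunctioning"],
            "tumor_size": ["giant"],
            "tumor_location": ["pituitary"],
            "histopathology": ["adenoma"],
        },
    ),
    (
        "Nonfunctioning pituitary macroadenoma (Left side Knosp grade 2–3)",
        {
            "endocrine_status": ["Nonfunctioning"],
            "tumor_location": ["pituitary"],
            "tumor_size": ["macro"],
            "histopathology": ["adenoma"],
            "knosp_grade": ["Left side Knosp grade 2–3"],
        },
    ),
    (
        "Invasive nonfunctioning giant pituitary adenoma with incomplete resection",
        {
            "invasiveness": ["Invasive"],
            "endocrine_status": ["nonfunctioning"],
            "tumor_size": ["giant"],
            "tumor_location": ["pituitary"],
            "histopathology": ["adenoma"],
            "residual_tumor": ["incomplete resection"],
        },
    ),
    (
        "Ectopic adrenocorticotropic hormone-secreting pituitary microadenoma",
        {
            "tumor_location": ["Ectopic", "pituitary"],
            "endocrine_status": ["adrenocorticotropic hormone-secreting"],
            "tumor_size": ["micro"],
            "histopathology": ["adenoma"],
        },
    ),
    (
        "Refractory giant nonfunctioning pituitary adenoma",
        {
            "refractoriness": ["Refractory"],
            "endocrine_status": ["nonfunctioning"],
            "tumor_size": ["giant"],
            "tumor_location": ["pituitary"],
            "histopathology": ["adenoma"],
        },
    ),
]


class TestMatchElements:
    @pytest.mark.parametrize("text,expected", TABLE_SAMPLES, ids=range(len(TABLE_SAMPLES)))
    def test_labeled_sample_decompositions(self, lexicon, text, expected):
        result = match_elements(text, lexicon)
        got = {el: result.values(el) for el in result.elements}
        assert got == expected

    def test_full_worked_example_yields_seven_element_types(self, lexicon):
        text = (
            "Invasive recurrent giant growth hormone secreting pituitary adenoma "
            "(Knosp grade 4 on the left, Knosp grade 0 on the right)"
        )
        result = match_elements(text, lexicon)
        assert result.elements == {
            "tumor_recurrence",
            "invasiveness",
            "tumor_location",
            "endocrine_status",
            "tumor_size",
            "histopathology",
            "knosp_grade",
        }
        assert len(result.values("knosp_grade")) == 2

    def test_chinese_statement_decomposition(self, lexicon):
        result = match_elements("复发难治性侵袭性GH分泌型垂体大腺瘤（左侧Knosp分级3级），术后残留", lexicon)
        assert [(m.element, m.value) for m in result.mentions] == [
            ("tumor_recurrence", "复发"),
            ("refractoriness", "难治性"),
            ("invasiveness", "侵袭性"),
            ("endocrine_status", "GH分泌型"),
            ("tumor_location", "垂体"),
            ("tumor_size", "大"),
            ("histopathology", "腺瘤"),
            ("knosp_grade", "左侧Knosp分级3级"),
            ("residual_tumor", "术后残留"),
        ]

    def test_empty_text_gives_empty_result(self, lexicon):
        result = match_elements("", lexicon)
        assert result.mentions == []

    def test_mentions_are_verbatim_and_ordered(self, lexicon):
        text = "拟诊复发侵袭性ACTH分泌型异位垂体巨大腺瘤（左侧Knosp分级2-3级）"
        result = match_elements(text, lexicon)
        starts = [m.span.start for m in result.mentions]
        assert starts == sorted(starts)
        for m in result.mentions:
            assert m.value == text[m.span.start : m.span.end]
            assert m.element in ELEMENT_TYPES

    def test_extraction_is_idempotent(self, lexicon):
        text = "无功能垂体微腺瘤（Knosp分级1级）"
        assert match_elements(text, lexicon) == match_elements(text, lexicon)

    def test_no_overlapping_mentions(self, lexicon):
        text = "GH/TSH混合型垂体巨大腺瘤（双侧Knosp分级2级）"
        result = match_elements(text, lexicon)
        spans = sorted((m.span.start, m.span.end) for m in result.mentions)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        assert result.values("endocrine_status") == ["GH/TSH混合型"]
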