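# padx — structured elements from pituitary-adenoma discharge diagnoses

Discharge diagnoses for pituitary adenoma (PA) pack many facts into one
free-text phrase — "复发侵袭性GH分泌型垂体大腺瘤（左侧Knosp分级3级）" carries
recurrence status, invasiveness, hormonal (endocrine) type, anatomical
location, a size category, the histopathological entity and a lateralized
Knosp grade. Clinical practice writes these statements with no fixed order,
mixed Chinese/Latin vocabulary and hundreds of surface variants, which makes
the records hard to query, register or code consistently.

`padx` turns such statements into ten structured diagnostic elements:

> tumor recurrence · tumor location · invasiveness · endocrine status ·
> tumor size · histopathology · Knosp grade · residual tumor ·
> diagnostic confirmation · refractoriness

and ships the evaluation and corpus-profiling machinery around that task:
exact-match precision/recall/F1 scoring against gold annotations, statement
deduplication, element frequency and expression-diversity counts,
combination-pattern distributions, principal-vs-other missingness tests and
a knowledge-graph export. Because hospital EMR corpora cannot be
redistributed, a seeded synthetic-corpus generator reproduces the
statistical shape of such data (element inclusion rates, stratified
tumor-size missingness, variant pools, duplication, Latin-token typos) with
verbatim gold annotations, so the whole pipeline is testable end to end.

## How extraction works

1. **Prefix-lexicon word-graph scan.** A medical dictionary (surface,
   frequency, entity class) is closed under prefixes, so all dictionary
   words starting at each position of a sentence are found in one forward
   scan. This yields a word DAG: an edge (i, j) for every dictionary word
   `text[i:j]`, plus single-character fallbacks.
2. **Maximum-probability path.** Dynamic programming selects the
   segmentation maximizing `∑ log(freq(w)/T)` over chosen words, where `T`
   is the total dictionary frequency and unknown single characters get a
   floor frequency of 1. Scores are compared in exact integer arithmetic, and
   exact ties prefer the longer word at the first divergence, which favors
   long compound medical terms.
3. **Rule pre-pass for Latin/digit runs.** Maximal runs of letters and
   digits with the connectors `/ - – .` ("GH/TSH", "2–3", "Knosp") are
   atomic units — they are never split, though a dictionary compound may
   legitimately span them (e.g. `ACTH垂体微腺瘤`).
4. **BMES Viterbi fallback.** Runs of out-of-vocabulary characters are cut
   into words by a Begin/Middle/End/Single character-tagging HMM decoded
   with Viterbi (first tag ∈ {B,S}, last ∈ {E,S}).
5. **Multilevel (nested) entity extraction.** Compound tokens are
   recursively re-segmented into sub-entities until atomic, producing nested
   `{"word", "entity_class", "value"}` trees.
6. **Element matching.** A declarative ruleset (literal surfaces,
   entity-class conditions and regex phrases; Knosp grades via a dedicated
   side/range parser) maps tokens and sub-entities onto the ten elements,
   highest priority and longest match first, one element per span. Every
   mention is a verbatim substring with a character span.

Evaluation uses `P = TP/(TP+FP)`, `R = TP/(TP+FN)`, `F1 = 2PR/(P+R)` as
percentages rounded half-up to one decimal, with F1 computed from the
already-rounded P and R — the convention needed to reproduce published
evaluation tables of this kind.

## Worked example

```python
from padx import load_default_lexicon, match_elements

lexicon = load_default_lexicon()
result = match_elements("复发侵袭性GH分泌型垂体大腺瘤（左侧Knosp分级3级）", lexicon)
for m in result.mentions:
    print(f"{m.element:24s} {m.value!r}  [{m.span.start}:{m.span.end}]")
```

prints

```
tumor_recurrence         '复发'  [0:2]
invasiveness             '侵袭性'  [2:5]
endocrine_status         'GH分泌型'  [5:10]
tumor_location           '垂体'  [10:12]
tumor_size               '大'  [12:13]
histopathology           '腺瘤'  [13:15]
knosp_grade              '左侧Knosp分级3级'  [16:27]
```

i.e. a recurrent, invasive, growth-hormone-secreting pituitary macroadenoma
with left-sided Knosp grade 3 — each value a verbatim slice of the input at
the printed character offsets. The nested view of a compound term:

```python
from padx import segment, multilevel_segment
(token,) = segment("ACTH垂体微腺瘤", lexicon)
multilevel_segment(token, lexicon).to_dict()
```

```json
{"word": "ACTH垂体微腺瘤", "entity_class": "disease", "value": [
  {"word": "ACTH", "entity_class": "medicine"},
  {"word": "垂体微腺瘤", "entity_class": "disease", "value": [
    {"word": "垂体", "entity_class": "organ"},
    {"word": "微腺瘤", "entity_class": "disease"}]}]}
```

The same pipeline is available from the shell:

```bash
padx simulate --n 2000 --seed 7 --out work/      # corpus.jsonl + gold.jsonl
padx extract  --corpus work/corpus.jsonl --out work/extractions.jsonl
padx evaluate --gold work/gold.jsonl --predicted work/extractions.jsonl --out work/eval
padx analyze  --extractions work/extractions.jsonl --corpus work/corpus.jsonl --out work/analysis
```

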