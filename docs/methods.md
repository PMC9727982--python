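# Methods

This note documents the models and procedures implemented in `padx`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic corpus does and does not establish
about real data.

## Segmentation model

**Word DAG.** The dictionary is a prefix lexicon: every proper prefix of
every word is present in a prefix table (true words carry their frequency,
pure prefixes carry 0). Scanning a sentence grows a candidate word position
by position and stops as soon as the candidate leaves the table, so all
word-formation cases are found in time linear in the number of
(position, prefix) pairs. The result is a DAG whose edges are dictionary
words plus a single-character fallback at every position; any segmentation
is a path from the start of the sentence to its end.

**Path scoring.** A path is scored by the product of unigram probabilities
`freq(w)/T`, with `T` the sum of all dictionary frequencies and a floor
frequency of 1 for units absent from the dictionary. No smoothing beyond
the floor is applied: diagnosis statements are short and the dictionary is
curated, so interpolation would add parameters without changing outcomes.
Scores are compared in *exact integer arithmetic* — path `(f₁…f_k)` beats
path `(g₁…g_m)` iff `∏f · T^m > ∏g · T^k` — so equality of scores is exact,
not float-approximate. Exact ties are resolved toward the longer word at
the first point of divergence, matching the preference for long compound
medical terms; with the tie-break the output is a deterministic function of
(text, dictionary) on every platform.

**Protected runs.** Character-frequency machinery handles digits and Latin
case poorly, so a rule pre-pass marks maximal runs of `[A-Za-z0-9]` joined
by the connectors `/ - – .` (hyphen and en dash treated identically, since
grade ranges appear with both) as atomic units. Protected runs are never
split, but a dictionary word may span a protected run plus surrounding
characters: this is required for compounds embedding hormone abbreviations
(`ACTH垂体微腺瘤` is one dictionary token at the coarse level). Punctuation
and whitespace are emitted as single rule tokens and act as hard barriers
for both dictionary matching and the OOV fallback.

**Out-of-vocabulary fallback.** Maximal runs of unknown single characters
are decoded by a BMES (Begin/Middle/End/Single) character-tagging HMM with
the word grammar hard-coded in the transition support (B→{M,E}, M→{M,E},
E→{B,S}, S→{B,S}; first tag ∈ {B,S}, last ∈ {E,S}; all other transitions
−∞). The packaged parameters are maximum-likelihood estimates with add-one
smoothing from a small pre-segmented clinical-style corpus shipped with the
package (`data/hmm_corpus.txt`); characters unseen in training emit at a
per-state floor of `1/(N_s + V + 1)`. The true weights used in production
systems are not public, so these defaults make the OOV path *testable*
(exact agreement with exhaustive tag-sequence search is asserted up to
length 8) without claiming fidelity to any particular trained model; users
can supply their own parameter file (`HmmParams.from_file`).

**Coordinates.** All offsets are 0-based half-open character indices on the
NFC normalization of the input; every surface and dictionary entry is NFC-
normalized before comparison so mixed Chinese/Latin text compares bit-stably.

## Nested entities and element matching

A compound token decomposes when, after splitting at connector characters
and whitespace, its chunks re-segment into two or more dictionary words
(max-probability DP with the full-span word excluded; a best path containing
any unknown unit blocks decomposition). Decomposition recurses to a default
depth cap of 3, which covers compound-in-compound terms like
`垂体微腺瘤 → 垂体 + 微腺瘤 → 微 + 腺瘤`; deeper nesting has no clinical
reading in this domain.

Element matching applies a declarative ruleset (`data/rules.json`, editable
without touching code, mirroring how an annotation team iterates rules):
literal surface rules (case-insensitive), entity-class rules, and regex
rules over the raw text for multiword English phrases and hormone
combinations. Knosp expressions are parsed by a dedicated regex capturing
side (左/右/双侧, left/right before or after the grade), a single grade or a
range with any of `– - — ~ ～`, validated to 0–4 (out-of-range grades are
dropped with a warning, not an exception). Candidates are accepted greedily
by priority, then match length, then position, and accepted spans exclude
overlapping candidates, so each token or sub-entity feeds at most one
mention — this prevents double counting in the frequency analytics.
Multi-valued elements (bilateral Knosp grades) are kept as separate
mentions, never concatenated. Knosp runs at priority 100; phrase regexes at
20; literals and the hormone-combination regex at 10, so that the longer of
a literal mixed-type variant (`GH/TSH混合型`) and its embedded combination
(`GH/TSH`) wins.

## Evaluation conventions

Matching is exact (element, value) string agreement with multiset
semantics, per text. Span-level matching was deliberately not used: gold
spans are not generally available for this task, and value-level agreement
is what the review loop of an annotation team inspects. Precision, recall
and F1 are percentages rounded half-up at one decimal; **F1 is computed from
the rounded P and R**. This is not an aesthetic choice: published tables of
this kind only reproduce under the rounded-inputs convention (e.g. counts
TP = 477, FN = 19 give R = 96.169… → 96.2 and then F1 = 98.06… → 98.1,
whereas raw-input F1 would print 98.0). Metrics with an empty denominator
are reported as not-applicable and excluded from aggregates.

## Corpus analytics

Statement uniqueness is exact string equality after NFC, trimming and
internal-whitespace collapse. Element *frequency* counts mentions by
default (a bilateral Knosp statement counts twice); a text-level mode is a
flag, since either reading of "frequency" is defensible. *Diversity* is the
number of distinct mention values per element by default, with a text-level
alternative, for the same reason. Combination patterns are order-insensitive
element-type sets keyed in the fixed ten-element order; percentages use all
texts as denominator. Missingness compares principal (sequence 1) against
other (sequence 2–3) diagnoses with a Pearson chi-square test *without*
continuity correction; at the cell counts this package targets, the
correction cannot move a p-value across 0.001, and the uncorrected statistic
is the conventional default for large 2×2 tables. Degenerate tables (a zero
margin) skip the test with a warning. The knowledge graph keeps the root
concept plus all ten element dimensions as explicit nodes with deduplicated
value leaves; published hub-and-spoke renderings of this kind sometimes draw
only nine spokes, absorbing one element into the root — the export does not
replicate that collapse and keeps the layout decision with the consumer.

## Synthetic corpus: what it emulates, and what it does not

The generator draws each record's stratum (non-principal fraction 0.081),
then element slots by stratum-specific inclusion probabilities, then surface
variants from weighted pools, and assembles the statement with a fixed
grammar (confirmation → recurrence → refractoriness → invasiveness →
endocrine status → location + size morpheme + 腺瘤 → parenthetical Knosp →
residual suffix). Defaults are anchored to the observed corpus profile:
histopathology in every text; location inclusion 0.999/0.951
(principal/other), endocrine 0.979/0.840, tumor size 0.814/0.520 (i.e.
missing in 18.6% / 48.0%, overall ≈ 21%), recurrence 0.27, invasiveness
0.335, Knosp 0.095, confirmation 0.159, residual 0.008, refractoriness
0.003. The endocrine pool has 22 weighted variants and the Knosp pool 15
(including bilateral double-mention forms) — deliberately scaled-down
analogues of the much larger variant counts seen in real corpora, keeping
the rank order (endocrine most variable, Knosp second). Duplication
resamples earlier fresh records so unique statements are a configured
fraction (default 0.1436) of records; the misspelling process corrupts each
Latin run with one character edit (swap/drop/duplicate) at a configured
rate, and gold keeps the corrupted surface, flagged per element.

Three honest caveats. First, element slots are sampled *independently*
within a stratum; real documentation habits are correlated (the dominant
four-element pattern is more frequent in practice than independence
predicts), so pattern-share numbers from the generator are structurally
comparable but not numerically calibrated. Second, inclusion rates measured
over the full corpus are overdispersed relative to a binomial because
duplicates replicate whole statements; parameter-recovery checks therefore
measure rates over fresh (non-duplicate) draws, which are iid by
construction — `SyntheticRecord.duplicate_of` makes the distinction
observable. Third, the unique-statement ratio is a target from above: fresh
draws occasionally coincide by chance, so observed unique counts run
somewhat below `n × unique_ratio`. A perfect round trip on this corpus
shows that segmentation, nesting, rule matching and scoring compose
correctly and deterministically — it does not certify recall on real EMR
text, whose variant inventory is far larger than any packaged lexicon.

## Problem sizes and seeds

Unit tests run on fixtures of a few records; oracle-equivalence checks use
200 random dictionary/text instances (length ≤ 12) and 200 OOV fragments
(length ≤ 8), where exhaustive enumeration is exact; corpus-level round-trip
and parameter-recovery checks use 2000-record corpora at a fixed seed,
enough for exact binomial 99% intervals to be informative while the full
suite stays in seconds. All randomness flows through explicitly seeded
`random.Random` (Mersenne Twister) instances; regenerating with the same
(config, seed) reproduces corpora byte for byte.

## Known limitations

- The packaged lexicon (~170 terms) and ruleset cover the pituitary-adenoma
  domain of the fixtures and generator; applying the pipeline to another
  disease means supplying a domain dictionary and rules (both are plain data
  files).
- Literal bare-hormone rules (needed so "ACTH-secreting" yields the mention
  "ACTH") can fire on sub-entities of a *corrupted* mixed variant
  ("ACTH/GJ混合型" → child "ACTH"), so heavy misspelling can cost endocrine
  precision as well as recall.
- English multiword values that are interleaved with other elements
  ("Ectopic … pituitary") are emitted as separate verbatim mentions rather
  than one synthesized value, preserving the substring invariant.
- The extractor processes one diagnosis statement at a time; reconciling
  information across a patient's multiple diagnoses is out of scope.
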