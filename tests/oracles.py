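"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's DAG/DP/Viterbi code paths: paths are
enumerated recursively and scored with exact rational arithmetic, and tag
sequences are enumerated exhaustively.
"""

from fractions import Fraction
from itertools import product

from padx.segmenter import ALLOWED_TRANSITIONS, NEG_INF, STATES


def enumerate_segmentations(text, lexicon):
    """All segmentations where each step is a dictionary word or one char."""
    n = len(text)
    results = []

    def recurse(i, acc):
        if i == n:
            results.append(list(acc))
            return
        seen_ends = set()
        for j in range(i + 1, n + 1):
            word = text[i:j]
            if j == i + 1 or lexicon.lookup(word) is not None:
                if j in seen_ends:
                    continue
                seen_ends.add(j)
                acc.append(word)
                recurse(j, acc)
                acc.pop()

    recurse(0, [])
    return results


def score_path(path, lexicon, floor=1):
    """Exact path probability: product of freq(word)/T with floor for unknowns."""
    total = Fraction(max(lexicon.total_frequency, 1))
    score = Fraction(1)
    for word in path:
        entry = lexicon.lookup(word)
        freq = entry.frequency if entry is not None else floor
        score *= Fraction(freq) / total
    return score


def best_segmentation(text, lexicon):
    """Argmax over all segmentations; ties go to the path whose first
    divergent word is longer (lexicographic max on word lengths)."""
    paths = enumerate_segmentations(text, lexicon)
    return max(paths, key=lambda p: (score_path(p, lexicon), tuple(len(w) for w in p)))


def enumerate_tag_paths(length):
    """All feasible BMES tag sequences: first in {B,S}, last in {E,S},
    transitions restricted to the BMES word grammar."""
    for tags in product(STATES, repeat=length):
        if tags[0] not in ("B", "S") or tags[-1] not in ("E", "S"):
            continue
        if any(b not in ALLOWED_TRANSITIONS[a] for a, b in zip(tags, tags[1:])):
            continue
        yield tags


def best_tag_path(fragment, params):
    """Exhaustive-search argmax of the BMES tagging probability."""
    best, best_score = None, NEG_INF
    for tags in enumerate_tag_paths(len(fragment)):
        score = params.start[tags[0]] + params.emission(tags[0], fragment[0])
        for idx in range(1, len(fragment)):
            score += params.trans[tags[idx - 1]][tags[idx]]
            score += params.emission(tags[idx], fragment[idx])
        if score > best_score:
            best, best_score = tags, score
    return "".join(best) if best else ""


def tags_to_words(fragment, tags):
    words, start = [], 0
    for idx, tag in enumerate(tags):
        if tag in ("E", "S"):
            words.append(fragment[start : idx + 1])
            start = idx + 1
    if start < len(fragment):
        words.append(fragment[start:])
    return words
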