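"""Surface lexical similarity, the candidate-pair filter, and handcrafted
feature vectors for stacking.

The dataset-construction filter keeps sentence pairs whose mean of three
character/token-level similarities — Ratcliff/Obershelp matching, token
count-vector cosine, and max-length-normalized Levenshtein similarity —
is at least 0.45.  The medication features rest on a transparent
lexicon+regex extractor with the attribute schema (drug name, dosage,
duration, form, frequency, route, strength) used by full clinical
medication-extraction systems; phrasal features are the canonical n-gram
overlap / edit distance / longest-common-affix set.
"""
from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import edlib
import numpy as np

from .core import SentencePair

# ---------------------------------------------------------------------------
# lexical similarity metrics
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\w+")


def _tokens(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


def ratcliff_obershelp(a: str, b: str, lowercase: bool = True) -> float:
    """Ratcliff/Obershelp similarity 2M/(|a|+|b|), M = total characters in
    recursively matched longest common substrings.  Two empty strings are
    defined as identical (1.0).

    The raw matching-blocks recursion can break length ties differently
    depending on argument order; the metric is symmetrized by taking the
    larger of the two directions."""
    if lowercase:
        a, b = a.lower(), b.lower()
    forward = difflib.SequenceMatcher(None, a, b, autojunk=False).ratio()
    backward = difflib.SequenceMatcher(None, b, a, autojunk=False).ratio()
    return max(forward, backward)


def levenshtein_similarity(a: str, b: str, lowercase: bool = True) -> float:
    """1 − d(a,b)/max(|a|,|b|) with d the Levenshtein edit distance."""
    if lowercase:
        a, b = a.lower(), b.lower()
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def cosine_similarity(a: str, b: str) -> float:
    """Cosine of lowercase token-count vectors; tokenless side → 0."""
    ta, tb = _tokens(a), _tokens(b)
    if not ta or not tb:
        return 0.0
    vocab = sorted(set(ta) | set(tb))
    idx = {w: i for i, w in enumerate(vocab)}
    va = np.zeros(len(vocab))
    vb = np.zeros(len(vocab))
    for w in ta:
        va[idx[w]] += 1
    for w in tb:
        vb[idx[w]] += 1
    return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))


def mean_lexical_similarity(a: str, b: str) -> float:
    """Mean of the three surface lexical similarities."""
    return (ratcliff_obershelp(a, b)
            + cosine_similarity(a, b)
            + levenshtein_similarity(a, b)) / 3.0


def candidate_pair_filter(pairs: Sequence[SentencePair],
                          threshold: float = 0.45) -> list[SentencePair]:
    """Keep pairs whose mean lexical similarity is ≥ ``threshold``,
    attaching the mean to each kept pair."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0,1]")
    kept = []
    for pair in pairs:
        mean = mean_lexical_similarity(pair.text_a, pair.text_b)
        if mean >= threshold:
            kept.append(replace(pair, lexical_mean=mean))
    return kept


# ---------------------------------------------------------------------------
# medication extraction (lexicon + attribute rules)
# ---------------------------------------------------------------------------

@dataclass
class MedicationMention:
    drug: str
    span: tuple[int, int]
    dosage: Optional[str] = None
    duration: Optional[str] = None
    form: Optional[str] = None
    frequency: Optional[str] = None
    route: Optional[str] = None
    strength: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.drug:
            raise ValueError("drug name must be nonempty")
        if self.span[0] < 0 or self.span[1] <= self.span[0]:
            raise ValueError(f"bad span {self.span}")


ATTRIBUTE_NAMES = ("dosage", "duration", "form", "frequency", "route", "strength")

_DEFAULT_PATTERNS = {
    "strength": re.compile(
        r"\b(\d+(?:\.\d+)?(?:-\d+(?:\.\d+)?)?)\s*(mg|mcg|g|ml|units?|meq)\b", re.I),
    "dosage": re.compile(
        r"\b(\d+(?:\.\d+)?(?:-\d+(?:\.\d+)?)?)\s*(puffs?|tablets?|capsules?|drops?|sprays?|patch(?:es)?)\b",
        re.I),
    "form": re.compile(
        r"\b(tablet|capsule|aerosol|solution|cream|ointment|syrup|spray|patch|injection)s?\b",
        re.I),
    "route": re.compile(
        r"\bby\s+(mouth|inhalation|injection)\b"
        r"|\b(oral(?:ly)?|topical(?:ly)?|subcutaneous(?:ly)?|intravenous(?:ly)?|"
        r"inhalation|sublingual)\b", re.I),
    "frequency": re.compile(
        r"\b(daily|nightly|weekly|monthly|as\s+needed|at\s+bedtime|"
        r"every\s+\d+(?:-\d+)?\s+hours?|once\s+a\s+day|"
        r"(?:two|three|four|\d+)\s+times\s+(?:a|per)\s+day|twice\s+(?:a|per)\s+day)\b",
        re.I),
    "duration": re.compile(r"\bfor\s+\d+\s+(?:days?|weeks?|months?)\b", re.I),
}


def extract_medications(text: str, lexicon: Sequence[str],
                        patterns: Optional[dict] = None) -> list[MedicationMention]:
    """Case-insensitive, longest-match-first lexicon matching with rule-based
    attribute capture in the text window up to the next drug mention."""
    if not lexicon:
        raise ValueError("medication lexicon is empty")
    if patterns is None:
        patterns = _DEFAULT_PATTERNS
    lower = text.lower()
    spans: list[tuple[int, int, str]] = []
    taken = np.zeros(len(text), dtype=bool)
    for name in sorted(set(lexicon), key=len, reverse=True):
        start = 0
        needle = name.lower()
        while True:
            pos = lower.find(needle, start)
            if pos < 0:
                break
            end = pos + len(needle)
            boundary_ok = ((pos == 0 or not lower[pos - 1].isalnum())
                           and (end == len(lower) or not lower[end].isalnum()))
            if boundary_ok and not taken[pos:end].any():
                taken[pos:end] = True
                spans.append((pos, end, name.lower()))
            start = pos + 1
    spans.sort()
    mentions = []
    for i, (pos, end, name) in enumerate(spans):
        window_end = spans[i + 1][0] if i + 1 < len(spans) else len(text)
        window = text[pos:window_end]
        attrs: dict[str, Optional[str]] = {}
        for attr in ATTRIBUTE_NAMES:
            m = patterns[attr].search(window)
            if m:
                captured = next((g for g in m.groups() if g), m.group(0))
                attrs[attr] = re.sub(r"\s+", " ", captured.strip().lower())
                if attr in ("strength", "dosage"):
                    # keep the full "number unit" phrase for these
                    attrs[attr] = re.sub(r"\s+", " ", m.group(0).strip().lower())
            else:
                attrs[attr] = None
        mentions.append(MedicationMention(drug=name, span=(pos, end), **attrs))
    return mentions


# ---------------------------------------------------------------------------
# feature vectors
# ---------------------------------------------------------------------------

FeatureVector = dict[str, float]

MEDICATION_FEATURE_NAMES = ("med_both_have", "med_name_jaccard") + tuple(
    f"med_{a}_agreement" for a in ATTRIBUTE_NAMES)


def medication_features(pair: SentencePair, lexicon: Sequence[str],
                        patterns: Optional[dict] = None) -> FeatureVector:
    """Composite features from extracted medication attributes.

    Both-have indicator, drug-name Jaccard overlap (over name component
    tokens, so a combination product partially overlaps its single-agent
    component), and per-attribute agreement over name-matched drug pairs
    (all zero when neither side mentions a medication)."""
    ma = extract_medications(pair.text_a, lexicon, patterns)
    mb = extract_medications(pair.text_b, lexicon, patterns)
    feats = {name: 0.0 for name in MEDICATION_FEATURE_NAMES}
    if not ma and not mb:
        return feats
    names_a = {m.drug for m in ma}
    names_b = {m.drug for m in mb}
    components = lambda names: {t for n in names for t in _TOKEN_RE.findall(n)}
    comp_a, comp_b = components(names_a), components(names_b)
    feats["med_both_have"] = 1.0 if (ma and mb) else 0.0
    union = comp_a | comp_b
    feats["med_name_jaccard"] = len(comp_a & comp_b) / len(union) if union else 0.0
    shared = names_a & names_b
    if shared:
        by_name_a = {m.drug: m for m in ma}
        by_name_b = {m.drug: m for m in mb}
        for attr in ATTRIBUTE_NAMES:
            agree = [
                float(getattr(by_name_a[n], attr) == getattr(by_name_b[n], attr))
                for n in shared
            ]
            feats[f"med_{attr}_agreement"] = float(np.mean(agree))
    return feats


def _ngrams(tokens: list[str], n: int) -> set[tuple[str, ...]]:
    return {tuple(tokens[i:i + n]) for i in range(len(tokens) - n + 1)}


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for ca, cb in zip(a, b):
        if ca != cb:
            break
        n += 1
    return n


def _longest_common_substring_len(a: str, b: str) -> int:
    m = difflib.SequenceMatcher(None, a, b, autojunk=False)
    return m.find_longest_match(0, len(a), 0, len(b)).size


PHRASAL_FEATURE_NAMES = (
    "unigram_jaccard", "bigram_jaccard", "trigram_jaccard",
    "char_edit_similarity", "common_prefix", "common_suffix",
    "common_substring",
)


def phrasal_similarity_features(pair: SentencePair) -> FeatureVector:
    """N-gram overlap, character edit similarity, and normalized longest
    common prefix/suffix/substring lengths."""
    a, b = pair.text_a.lower(), pair.text_b.lower()
    ta, tb = _tokens(a), _tokens(b)
    max_len = max(len(a), len(b), 1)
    return {
        "unigram_jaccard": _jaccard(_ngrams(ta, 1), _ngrams(tb, 1)),
        "bigram_jaccard": _jaccard(_ngrams(ta, 2), _ngrams(tb, 2)),
        "trigram_jaccard": _jaccard(_ngrams(ta, 3), _ngrams(tb, 3)),
        "char_edit_similarity": levenshtein_similarity(a, b),
        "common_prefix": _common_prefix_len(a, b) / max_len,
        "common_suffix": _common_prefix_len(a[::-1], b[::-1]) / max_len,
        "common_substring": _longest_common_substring_len(a, b) / max_len,
    }


def featurize_pairs(pairs: Sequence[SentencePair], lexicon: Sequence[str],
                    include_medication: bool = True,
                    include_phrasal: bool = True):
    """Name-aligned feature table for a corpus of pairs (a DataFrame
    indexed by pair id); all values finite, safe for regression stacking."""
    import pandas as pd

    rows = []
    for pair in pairs:
        row: dict[str, float] = {}
        if include_medication:
            row.update(medication_features(pair, lexicon))
        if include_phrasal:
            row.update(phrasal_similarity_features(pair))
        rows.append(row)
    table = pd.DataFrame(rows, index=[p.id for p in pairs])
    if not np.isfinite(table.to_numpy(dtype=float)).all():
        raise ValueError("non-finite feature value produced")
    return table
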