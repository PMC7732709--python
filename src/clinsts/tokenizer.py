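"""Subword tokenization and input packing.

Text enters the model as a packed sequence of subword ids bracketed by a
classification marker (``[CLS]``) and separator markers (``[SEP]``), with
segment ids 0/1 distinguishing the two sentences of a pair.  A small
trainable WordPiece-style vocabulary (greedy frequency merges over a
corpus, greedy longest-prefix matching at encode time) is built in so the
whole pipeline runs without downloads; a pretrained vocabulary can be
loaded from a plain-text one-unit-per-line file.
"""
from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

CLS, SEP, UNK, PAD = "[CLS]", "[SEP]", "[UNK]", "[PAD]"
SPECIALS = (PAD, UNK, CLS, SEP)

_WORD_RE = re.compile(r"\w+|[^\w\s]")


def basic_tokenize(text: str, lowercase: bool = True) -> list[str]:
    """Split into word/punctuation tokens; the subword pass runs per word."""
    if lowercase:
        text = text.lower()
    return _WORD_RE.findall(text)


@dataclass
class Vocab:
    """Subword unit inventory with special markers.

    ``units[i]`` has id ``i``; the id map is a bijection onto ``0..V-1``.
    """

    units: list[str]
    lowercase: bool = True
    unit_to_id: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for marker in SPECIALS:
            if marker not in self.units:
                raise ValueError(f"special marker {marker} missing from vocabulary")
        if len(set(self.units)) != len(self.units):
            raise ValueError("vocabulary units are not unique")
        self.unit_to_id = {u: i for i, u in enumerate(self.units)}

    def __len__(self) -> int:
        return len(self.units)

    @property
    def cls_id(self) -> int:
        return self.unit_to_id[CLS]

    @property
    def sep_id(self) -> int:
        return self.unit_to_id[SEP]

    @property
    def unk_id(self) -> int:
        return self.unit_to_id[UNK]

    @property
    def pad_id(self) -> int:
        return self.unit_to_id[PAD]

    def encode_word(self, word: str) -> list[int]:
        """Greedy longest-prefix segmentation of one word into unit ids."""
        ids: list[int] = []
        pos = 0
        while pos < len(word):
            end = len(word)
            while end > pos and word[pos:end] not in self.unit_to_id:
                end -= 1
            if end == pos:  # character not in vocabulary
                ids.append(self.unk_id)
                pos += 1
            else:
                ids.append(self.unit_to_id[word[pos:end]])
                pos = end
        return ids

    def encode(self, text: str) -> list[int]:
        ids: list[int] = []
        for word in basic_tokenize(text, self.lowercase):
            ids.extend(self.encode_word(word))
        return ids

    def decode(self, ids: list[int]) -> list[str]:
        return [self.units[i] for i in ids]

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.units) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path, lowercase: bool = True) -> "Vocab":
        units = Path(path).read_text(encoding="utf-8").splitlines()
        return cls([u for u in units if u], lowercase=lowercase)


def train_subword_vocab(corpus: list[str], vocab_size: int,
                        lowercase: bool = True) -> Vocab:
    """Learn a WordPiece-style vocabulary by greedy pair merging.

    Starts from the corpus character inventory plus the special markers,
    then repeatedly merges the most frequent adjacent unit pair (ties
    broken lexicographically for determinism) until ``vocab_size`` units
    exist or no pair repeats.  The result tokenizes any string: characters
    outside the corpus fall back to the unknown marker.
    """
    if not corpus:
        raise ValueError("cannot train a vocabulary on an empty corpus")
    word_freq: Counter[str] = Counter()
    for sentence in corpus:
        word_freq.update(basic_tokenize(sentence, lowercase))
    chars = sorted({c for w in word_freq for c in w})
    base = list(SPECIALS) + chars
    if vocab_size < len(base):
        raise ValueError(
            f"vocab_size {vocab_size} below minimum {len(base)} "
            "(special markers + corpus characters)")

    # each word as a tuple of current units
    segmentations: dict[str, list[str]] = {w: list(w) for w in word_freq}
    units = list(base)
    while len(units) < vocab_size:
        pair_freq: Counter[tuple[str, str]] = Counter()
        for word, seg in segmentations.items():
            f = word_freq[word]
            for a, b in zip(seg, seg[1:]):
                pair_freq[(a, b)] += f
        if not pair_freq:
            break
        (a, b), count = min(pair_freq.items(), key=lambda kv: (-kv[1], kv[0]))
        if count < 2:
            break
        merged = a + b
        if merged in units:
            break
        units.append(merged)
        for word, seg in segmentations.items():
            i = 0
            while i < len(seg) - 1:
                if seg[i] == a and seg[i + 1] == b:
                    seg[i:i + 2] = [merged]
                else:
                    i += 1
    return Vocab(units, lowercase=lowercase)


@dataclass
class PackedInput:
    """A packed token-id sequence ready for the encoder.

    Invariants: ``len(token_ids) == len(segment_ids) <= max_len``; the
    first token is the classification marker, the last a separator;
    segment ids are nondecreasing (0 for the first text, 1 for the
    second).
    """

    token_ids: list[int]
    segment_ids: list[int]

    def __post_init__(self) -> None:
        if len(self.token_ids) != len(self.segment_ids):
            raise ValueError("token and segment sequences differ in length")

    @property
    def length(self) -> int:
        return len(self.token_ids)


def pack_single(text: str, vocab: Vocab, max_len: int = 512) -> PackedInput:
    """``[CLS] text [SEP]`` truncated to ``max_len``; markers always survive."""
    if max_len < 2:
        raise ValueError("max_len must be at least 2 for the two markers")
    body = vocab.encode(text)[: max_len - 2]
    ids = [vocab.cls_id] + body + [vocab.sep_id]
    return PackedInput(ids, [0] * len(ids))


def pack_pair(text_a: str, text_b: str, vocab: Vocab,
              max_len: int = 512) -> PackedInput:
    """``[CLS] a [SEP] b [SEP]`` with segment ids 0 through the first
    separator inclusive and 1 afterward.

    When the pair exceeds the budget, one subword is trimmed from the end
    of the currently longer text, repeatedly, until it fits (longest-first
    truncation keeps both sentences' content symmetrically).
    """
    if max_len < 3:
        raise ValueError("max_len must be at least 3 for the three markers")
    a = vocab.encode(text_a)
    b = vocab.encode(text_b)
    budget = max_len - 3
    while len(a) + len(b) > budget:
        if len(a) >= len(b):
            a.pop()
        else:
            b.pop()
    ids = [vocab.cls_id] + a + [vocab.sep_id] + b + [vocab.sep_id]
    segs = [0] * (len(a) + 2) + [1] * (len(b) + 1)
    return PackedInput(ids, segs)
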