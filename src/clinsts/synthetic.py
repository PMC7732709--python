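"""Synthetic multi-task corpora with closed-form ground truth.

Emulates the task mix around a clinical sentence-similarity target: a
sentence-pair similarity task scored 0-5 (the target), sentence-pair
classification (entailment / contradiction style), single-sentence topic
classification, token-level medication tagging, and a pure-noise pair
task for negative-transfer experiments.

Sentences are built from templates of m content-word slots; a paired
variant applies e edits (synonym swap from a generated synonym table,
deletion, substitution, insertion) so the latent similarity is the
closed-form 5·(m−e)/m.  Two independent annotators are simulated as the
latent score plus truncated Gaussian noise; their mean is the gold score.
A transfer-coupling knob controls what fraction of the auxiliary tasks'
content vocabulary is shared with the target task's: at coupling 0 the
auxiliary corpora share no content words with the target, so intermediate
training on them can carry no target-relevant signal.

Everything is deterministic under the config seed; each example keeps a
``latent`` record sufficient to recompute its label exactly (at σ=0).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import SentenceExample

DEFAULT_SIZES = {
    "sts": 200, "stsb": 320, "pairclass": 240, "topic": 240, "ner": 160,
    "noise": 240,
}
FILLERS = ("the", "of", "and", "with", "for", "on", "in", "at")
DEFAULT_TOPICS = ("MED", "SIGNORSYMPTOM", "EXPLAIN", "OTHER")
DEFAULT_NER_TAGS = ("O", "DRUG", "STRENGTH", "FORM", "FREQUENCY", "ROUTE")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic benchmark.

    ``coupling`` is the fraction of auxiliary-task content vocabulary
    drawn from the target task's pool; ``annotator_sigma`` the std-dev of
    each simulated annotator's truncated Gaussian noise (score points);
    ``edit_noise_rate`` the probability of uncounted surface noise
    (filler insertion, topic-keyword contamination).
    """

    seed: int = 0
    vocab_size: int = 60
    template_count: int = 40
    sizes: dict = field(default_factory=lambda: dict(DEFAULT_SIZES))
    edit_noise_rate: float = 0.2
    coupling: float = 0.7
    annotator_sigma: float = 0.25
    slot_range: tuple[int, int] = (6, 10)

    def __post_init__(self) -> None:
        if any(v < 1 for v in self.sizes.values()):
            raise ValueError("per-task sizes must be >= 1")
        for name in ("edit_noise_rate", "coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.annotator_sigma < 0:
            raise ValueError("annotator_sigma must be >= 0")


_SYLLABLES = [c + v for c in "bcdfglmnprstvz" for v in "aeiou"]


def _make_words(rng: np.random.Generator, count: int,
                taken: set[str]) -> list[str]:
    words = []
    while len(words) < count:
        n = rng.integers(2, 4)
        w = "".join(rng.choice(_SYLLABLES) for _ in range(n))
        if w not in taken:
            taken.add(w)
            words.append(w)
    return words


@dataclass
class WordBank:
    """All lexical resources of one synthetic world (seed-determined)."""

    sts_content: list[str]
    aux_content: list[str]
    synonyms: dict[str, str]
    antonyms: dict[str, str]
    drugs: list[str]
    topic_pools: dict[str, list[str]]

    @classmethod
    def build(cls, cfg: GeneratorConfig,
              topics: Sequence[str] = DEFAULT_TOPICS) -> "WordBank":
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 7919]).generate_state(1)[0])
        taken: set[str] = set(FILLERS)
        sts_content = _make_words(rng, cfg.vocab_size, taken)
        n_shared = int(round(cfg.coupling * cfg.vocab_size))
        shared = sts_content[:n_shared]
        aux_content = shared + _make_words(rng, cfg.vocab_size - n_shared, taken)
        all_content = sts_content + aux_content
        syn_words = _make_words(rng, len(set(all_content)), taken)
        synonyms = {w: s for w, s in zip(sorted(set(all_content)), syn_words)}
        ant_words = _make_words(rng, len(set(all_content)), taken)
        antonyms = {w: s for w, s in zip(sorted(set(all_content)), ant_words)}
        drugs = _make_words(rng, 12, taken)
        # topic keyword pools: disjoint partition, coupled words first
        per_topic = max(3, cfg.vocab_size // (2 * len(topics)))
        pool_words = aux_content[: per_topic * len(topics)]
        if len(pool_words) < per_topic * len(topics):
            pool_words = pool_words + _make_words(
                rng, per_topic * len(topics) - len(pool_words), taken)
        topic_pools = {
            t: pool_words[i * per_topic:(i + 1) * per_topic]
            for i, t in enumerate(topics)
        }
        return cls(sts_content, aux_content, synonyms, antonyms, drugs,
                   topic_pools)


def _rng_for(cfg: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, stream]).generate_state(1)[0])


def _render(rng: np.random.Generator, slots: list[str], noise_rate: float) -> str:
    """Join slot words, inserting uncounted filler words at ``noise_rate``."""
    words = []
    for w in slots:
        if rng.random() < noise_rate:
            words.append(FILLERS[rng.integers(0, len(FILLERS))])
        words.append(w)
    return " ".join(words)


def _edited_pair(rng: np.random.Generator, pool: list[str],
                 bank: WordBank, m: int, e: int,
                 noise_rate: float) -> tuple[str, str, list[str]]:
    """A template sentence and a variant with exactly ``e`` counted edits."""
    slots = list(rng.choice(pool, size=m, replace=False))
    variant: list[Optional[str] | tuple] = list(slots)
    edit_positions = rng.choice(m, size=e, replace=False)
    for pos in edit_positions:
        kind = rng.integers(0, 4)
        word = slots[pos]
        if kind == 0:      # synonym swap
            variant[pos] = bank.synonyms[word]
        elif kind == 1:    # deletion
            variant[pos] = None
        elif kind == 2:    # substitution with an unrelated pool word
            variant[pos] = pool[rng.integers(0, len(pool))]
        else:              # insertion of a random word before the slot
            variant[pos] = (pool[rng.integers(0, len(pool))], word)
    out: list[str] = []
    for v in variant:
        if v is None:
            continue
        if isinstance(v, tuple):
            out.extend(v)
        else:
            out.append(v)
    return (_render(rng, slots, noise_rate), _render(rng, out, noise_rate), slots)


def _truncated_annotator(rng: np.random.Generator, latent: float,
                         sigma: float) -> float:
    return float(np.clip(latent + rng.normal(0.0, sigma) if sigma > 0
                         else latent, 0.0, 5.0))


def generate_sts_pairs(cfg: GeneratorConfig,
                       bank: Optional[WordBank] = None,
                       task_name: str = "sts",
                       pool: str = "target") -> list[SentenceExample]:
    """Similarity-scored pairs: gold = mean of two noisy annotators around
    the closed-form latent similarity 5·(m−e)/m.

    ``pool="target"`` draws content words from the target task's
    vocabulary; ``pool="aux"`` from the auxiliary (coupling-controlled)
    vocabulary, emulating a general-domain similarity benchmark used as
    an intermediate task.
    """
    bank = bank or WordBank.build(cfg)
    rng = _rng_for(cfg, 1 if pool == "target" else 6)
    content = bank.sts_content if pool == "target" else bank.aux_content
    lo, hi = cfg.slot_range
    examples = []
    for i in range(cfg.sizes[task_name]):
        m = int(rng.integers(lo, hi + 1))
        e = int(rng.integers(0, m + 1))
        text_a, text_b, slots = _edited_pair(
            rng, content, bank, m, e, cfg.edit_noise_rate)
        latent = 5.0 * (m - e) / m
        a1 = _truncated_annotator(rng, latent, cfg.annotator_sigma)
        a2 = _truncated_annotator(rng, latent, cfg.annotator_sigma)
        gold = (a1 + a2) / 2.0
        examples.append(SentenceExample(
            id=f"{task_name}-{i:04d}", task=task_name, text_a=text_a,
            text_b=text_b,
            label=gold,
            latent={"m": m, "e": e, "latent": latent, "a1": a1, "a2": a2,
                    "slots": slots}))
    return examples


def generate_pair_classification(cfg: GeneratorConfig, scheme: str = "binary",
                                 bank: Optional[WordBank] = None,
                                 task_name: str = "pairclass",
                                 ) -> list[SentenceExample]:
    """Auxiliary pairs labeled by latent-similarity thresholds.

    ``binary``: entailment iff few slots were edited.  ``ternary`` adds a
    contradiction class built by antonym-slot substitution on an
    otherwise near-identical pair.  Labels are sampled uniformly, so the
    class balance is multinomial around uniform.
    """
    if scheme not in ("binary", "ternary"):
        raise ValueError("scheme must be 'binary' or 'ternary'")
    bank = bank or WordBank.build(cfg)
    rng = _rng_for(cfg, 2)
    lo, hi = cfg.slot_range
    labels = (("entailment", "not_entailment") if scheme == "binary"
              else ("entailment", "neutral", "contradiction"))
    examples = []
    for i in range(cfg.sizes["pairclass"]):
        m = int(rng.integers(lo, hi + 1))
        label = labels[rng.integers(0, len(labels))]
        if label == "entailment":
            e = int(rng.integers(0, max(1, m // 4) + 1))
        elif label == "neutral":
            e = int(rng.integers(m // 3, 2 * m // 3 + 1))
        else:  # not_entailment / contradiction
            e = int(rng.integers(3 * m // 4, m + 1))
        if label == "contradiction":
            e = int(rng.integers(0, max(1, m // 4) + 1))
            text_a, text_b, slots = _edited_pair(
                rng, bank.aux_content, bank, m, e, cfg.edit_noise_rate)
            # flip a slot word that survived the edits
            survivors = [w for w in text_b.split() if w in set(slots)]
            flip = survivors[rng.integers(0, len(survivors))]
            text_b = " ".join(
                bank.antonyms[w] if w == flip else w for w in text_b.split())
        else:
            text_a, text_b, slots = _edited_pair(
                rng, bank.aux_content, bank, m, e, cfg.edit_noise_rate)
        examples.append(SentenceExample(
            id=f"{task_name}-{i:04d}", task=task_name, text_a=text_a,
            text_b=text_b, label=label,
            latent={"m": m, "e": e, "latent": 5.0 * (m - e) / m}))
    return examples


def generate_topic_sentences(cfg: GeneratorConfig,
                             topics: Sequence[str] = DEFAULT_TOPICS,
                             bank: Optional[WordBank] = None,
                             ) -> list[SentenceExample]:
    """Single sentences whose label is the topic of their keyword pool.

    Each topic owns a disjoint keyword pool; a sentence mixes keywords
    from its topic with shared fillers.  At ``edit_noise_rate`` each
    keyword is contaminated with a draw from another topic's pool, so a
    majority keyword count still recovers the label.
    """
    if len(topics) < 2:
        raise ValueError("need at least 2 topics")
    bank = bank or WordBank.build(cfg, topics=topics)
    rng = _rng_for(cfg, 3)
    examples = []
    for i in range(cfg.sizes["topic"]):
        topic = topics[rng.integers(0, len(topics))]
        k = int(rng.integers(4, 9))
        words = []
        n_contaminated = 0
        for _ in range(k):
            if rng.random() < cfg.edit_noise_rate and len(topics) > 1:
                other = topics[rng.integers(0, len(topics))]
                while other == topic:
                    other = topics[rng.integers(0, len(topics))]
                pool = bank.topic_pools[other]
                n_contaminated += 1
            else:
                pool = bank.topic_pools[topic]
            words.append(pool[rng.integers(0, len(pool))])
        # a contaminated majority would make the label unrecoverable
        if n_contaminated * 2 >= k:
            words[: (n_contaminated * 2 - k + 1)] = [
                bank.topic_pools[topic][rng.integers(0, len(bank.topic_pools[topic]))]
                for _ in range(n_contaminated * 2 - k + 1)]
        text = _render(rng, words, cfg.edit_noise_rate)
        examples.append(SentenceExample(
            id=f"topic-{i:04d}", task="topic", text_a=text, label=topic,
            latent={"topic": topic, "keywords": words}))
    return examples


def generate_ner_sequences(cfg: GeneratorConfig,
                           tag_set: Sequence[str] = DEFAULT_NER_TAGS,
                           bank: Optional[WordBank] = None,
                           ) -> list[SentenceExample]:
    """Token sequences with medication slots tagged by attribute type.

    Tags align 1:1 with whitespace tokens; ``text_a`` is the joined
    token sequence and ``label`` the tag list.
    """
    if "O" not in tag_set:
        raise ValueError("tag set must include the outside tag 'O'")
    bank = bank or WordBank.build(cfg)
    rng = _rng_for(cfg, 4)
    strengths = ["10", "25", "50", "81", "100", "250"]
    units = ["mg", "mcg", "ml"]
    forms = ["tablet", "capsule", "aerosol", "solution"]
    freqs = ["daily", "nightly", "weekly"]
    routes = ["oral", "inhalation", "topical"]
    examples = []
    for i in range(cfg.sizes["ner"]):
        tokens: list[str] = []
        tags: list[str] = []
        n_lead = int(rng.integers(1, 5))
        for _ in range(n_lead):
            tokens.append(bank.aux_content[rng.integers(0, len(bank.aux_content))])
            tags.append("O")
        n_meds = int(rng.integers(0, 3))
        for _ in range(n_meds):
            tokens.append(bank.drugs[rng.integers(0, len(bank.drugs))])
            tags.append("DRUG" if "DRUG" in tag_set else "O")
            if "STRENGTH" in tag_set and rng.random() < 0.7:
                tokens.append(strengths[rng.integers(0, len(strengths))])
                tags.append("STRENGTH")
                tokens.append(units[rng.integers(0, len(units))])
                tags.append("STRENGTH")
            if "FORM" in tag_set and rng.random() < 0.5:
                tokens.append(forms[rng.integers(0, len(forms))])
                tags.append("FORM")
            if "ROUTE" in tag_set and rng.random() < 0.5:
                tokens.append(routes[rng.integers(0, len(routes))])
                tags.append("ROUTE")
            if "FREQUENCY" in tag_set and rng.random() < 0.5:
                tokens.append(freqs[rng.integers(0, len(freqs))])
                tags.append("FREQUENCY")
            n_gap = int(rng.integers(0, 3))
            for _ in range(n_gap):
                tokens.append(FILLERS[rng.integers(0, len(FILLERS))])
                tags.append("O")
        examples.append(SentenceExample(
            id=f"ner-{i:04d}", task="ner", text_a=" ".join(tokens),
            label=tags, latent={"n_meds": n_meds}))
    return examples


def generate_noise_task(cfg: GeneratorConfig,
                        bank: Optional[WordBank] = None,
                        ) -> list[SentenceExample]:
    """Pair-classification examples whose labels are independent coin
    flips — pure noise, for negative-transfer experiments."""
    bank = bank or WordBank.build(cfg)
    rng = _rng_for(cfg, 5)
    lo, hi = cfg.slot_range
    examples = []
    for i in range(cfg.sizes["noise"]):
        m = int(rng.integers(lo, hi + 1))
        e = int(rng.integers(0, m + 1))
        text_a, text_b, _ = _edited_pair(
            rng, bank.aux_content, bank, m, e, cfg.edit_noise_rate)
        label = ("yes", "no")[rng.integers(0, 2)]
        examples.append(SentenceExample(
            id=f"noise-{i:04d}", task="noise", text_a=text_a, text_b=text_b,
            label=label, latent={"m": m, "e": e}))
    return examples


def generate_all(cfg: GeneratorConfig,
                 topics: Sequence[str] = DEFAULT_TOPICS,
                 ) -> dict[str, list[SentenceExample]]:
    """All five corpora from one shared word bank."""
    bank = WordBank.build(cfg, topics=topics)
    return {
        "sts": generate_sts_pairs(cfg, bank),
        "stsb": generate_sts_pairs(cfg, bank, task_name="stsb", pool="aux"),
        "pairclass": generate_pair_classification(cfg, "ternary", bank),
        "topic": generate_topic_sentences(cfg, topics, bank),
        "ner": generate_ner_sequences(cfg, bank=bank),
        "noise": generate_noise_task(cfg, bank),
    }


def corpus_sentences(datasets: dict[str, list[SentenceExample]]) -> list[str]:
    """All raw sentences, for vocabulary training."""
    out = []
    for examples in datasets.values():
        for e in examples:
            out.append(e.text_a)
            if e.text_b is not None:
                out.append(e.text_b)
    return out
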