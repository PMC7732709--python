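import numpy as np
import pytest

from clinsts.core import TaskSpec
from clinsts.model import EncoderConfig, ModelState
from clinsts.tokenizer import train_subword_vocab


@pytest.fixture(scope="session")
def tiny_vocab():
    corpus = [
        "alpha beta gamma delta epsilon",
        "beta gamma zeta eta theta",
        "alpha delta theta iota kappa",
    ]
    return train_subword_vocab(corpus, 60)


@pytest.fixture(scope="session")
def four_tasks():
    return [
        TaskSpec("sts", "pair_similarity"),
        TaskSpec("topic", "single_classification", ("A", "B", "C")),
        TaskSpec("nli", "pair_classification", ("ent", "neu", "con")),
        TaskSpec("ner", "token_classification", ("O", "DRUG")),
    ]


@pytest.fixture()
def tiny_state(tiny_vocab, four_tasks):
    cfg = EncoderConfig(vocab_size=len(tiny_vocab), width=8, layers=1,
                        heads=2, ffn_width=16, max_len=32)
    return ModelState(cfg, four_tasks, seed=0)
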