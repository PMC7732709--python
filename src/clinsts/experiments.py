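"""Desk-scale benchmark experiments on the synthetic corpora.

These functions define the package's reference experiments: the
transfer/negative-transfer comparison (intermediate multi-task training
plus fine-tuning versus fine-tuning alone, and the effect of adding a
pure-noise auxiliary task) and the scorer-ensemble simulation.  The
configuration below is the benchmark's study condition: a 1-layer
width-32 encoder, the default synthetic corpora, 4 epochs of multi-task
training and 10 of fine-tuning.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .ensemble import PredictionSet, ablate_ensembles
from .evaluation import pearson_correlation, split_dataset
from .model import EncoderConfig, ModelState
from .synthetic import GeneratorConfig, corpus_sentences, generate_all
from .tokenizer import train_subword_vocab
from .training import TrainConfig, finetune_target, mtl_train, predict_scores

BENCHMARK_ENCODER = dict(width=32, layers=1, heads=2, ffn_width=64, max_len=48)
BENCHMARK_MTL = dict(epochs=4, batch_size=8, lr=5e-3, max_len=48)
BENCHMARK_FINETUNE = dict(epochs=10, batch_size=8, lr=5e-3, max_len=48)
BENCHMARK_SPLIT = (0.6, 0.2, 0.2)
FULL_PLAN = ("stsb", "pairclass", "topic", "ner")


def _target_pcc(seed: int, mtl_datasets: tuple[str, ...]) -> float:
    """One benchmark run: (optional) intermediate MTL, fine-tune, test PCC."""
    from .pipeline import TASK_SPECS

    cfg = GeneratorConfig(seed=seed)
    datasets = generate_all(cfg)
    vocab = train_subword_vocab(corpus_sentences(datasets), 400)
    enc = EncoderConfig(vocab_size=len(vocab), **BENCHMARK_ENCODER)
    train, _val, test = split_dataset(datasets["sts"], BENCHMARK_SPLIT, seed)
    state = ModelState(enc, [TASK_SPECS[n] for n in sorted(TASK_SPECS)],
                       seed=seed)
    if mtl_datasets:
        mtl_train(state, {n: datasets[n] for n in mtl_datasets},
                  TrainConfig(seed=seed, **BENCHMARK_MTL), vocab)
    finetune_target(state, train,
                    TrainConfig(seed=seed + 1, **BENCHMARK_FINETUNE), vocab)
    gold = np.array([float(e.label) for e in test])
    preds = predict_scores(state, test, vocab,
                           max_len=BENCHMARK_FINETUNE["max_len"])
    return pearson_correlation(gold, preds)


def transfer_benchmark(seeds: tuple[int, ...] = (1, 2, 3, 4, 5),
                       include_noise: bool = False) -> pd.DataFrame:
    """Per-seed test PCC of fine-tune-only vs intermediate-MTL + fine-tune.

    With ``include_noise`` a third arm adds the pure-noise auxiliary task
    to the full plan (the negative-transfer probe).
    """
    rows = []
    for seed in seeds:
        row = {"seed": seed,
               "finetune_only": _target_pcc(seed, ()),
               "mtl_finetune": _target_pcc(seed, FULL_PLAN)}
        if include_noise:
            row["mtl_noise_finetune"] = _target_pcc(seed, FULL_PLAN + ("noise",))
        rows.append(row)
    return pd.DataFrame(rows)


def noise_benchmark(seeds: tuple[int, ...] = (1, 2, 3, 4, 5)) -> pd.DataFrame:
    """Per-seed test PCC of the full plan vs the full plan plus noise."""
    rows = []
    for seed in seeds:
        rows.append({"seed": seed,
                     "mtl_finetune": _target_pcc(seed, FULL_PLAN),
                     "mtl_noise_finetune": _target_pcc(seed, FULL_PLAN + ("noise",))})
    return pd.DataFrame(rows)


def synthetic_scorers(seed: int, k: int = 3, n: int = 200,
                      noise_sigma: float = 1.0
                      ) -> tuple[list[PredictionSet], np.ndarray]:
    """k scorers = gold score + independent Gaussian noise, for ensemble
    simulations."""
    rng = np.random.default_rng(seed)
    gold = rng.uniform(0.0, 5.0, size=n)
    ids = tuple(f"p{i:04d}" for i in range(n))
    sets = [PredictionSet(f"scorer{j}", ids,
                          gold + rng.normal(0.0, noise_sigma, size=n))
            for j in range(k)]
    return sets, gold


def ensemble_benchmark(seeds: tuple[int, ...] = (1, 2, 3, 4, 5), k: int = 3,
                       ) -> pd.DataFrame:
    """Mean-ensemble vs singleton PCC over seeds (plus the ablation size)."""
    rows = []
    for seed in seeds:
        sets, gold = synthetic_scorers(seed, k=k)
        table = ablate_ensembles(sets, gold)
        singletons = table[table["size"] == 1]["pcc"]
        full = table[table["size"] == k]["pcc"].iloc[0]
        rows.append({"seed": seed, "mean_singleton_pcc": singletons.mean(),
                     "full_ensemble_pcc": full, "n_rows": len(table)})
    return pd.DataFrame(rows)
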