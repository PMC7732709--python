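"""End-to-end pipeline: simulate → iterate → fine-tune → ensemble → evaluate.

One structured config drives every stage; each stage writes its artifacts
under the output directory together with a machine-readable run log
(config hash, seeds, package versions) sufficient to reproduce the run
bit-for-bit.
"""
from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .core import SentenceExample, TaskSpec
from .ensemble import (PredictionSet, fit_stacker, mean_ensemble,
                       normalize_predictions, predict_stacker)
from .evaluation import evaluate, split_dataset
from .features import featurize_pairs
from .core import SentencePair
from .io import write_examples, write_predictions
from .model import EncoderConfig, ModelState
from .synthetic import (DEFAULT_NER_TAGS, DEFAULT_TOPICS, GeneratorConfig,
                        corpus_sentences, generate_all)
from .tokenizer import train_subword_vocab
from .training import (IterationPlan, TrainConfig, finetune_target, mtl_train,
                       predict_scores, run_iteration_plans)

TASK_SPECS = {
    "sts": TaskSpec("sts", "pair_similarity", domain_tag="clinical"),
    "stsb": TaskSpec("stsb", "pair_similarity", domain_tag="general"),
    "pairclass": TaskSpec("pairclass", "pair_classification",
                          ("entailment", "neutral", "contradiction"),
                          domain_tag="clinical"),
    "topic": TaskSpec("topic", "single_classification", DEFAULT_TOPICS,
                      domain_tag="clinical"),
    "ner": TaskSpec("ner", "token_classification", DEFAULT_NER_TAGS,
                    domain_tag="clinical"),
    "noise": TaskSpec("noise", "pair_classification", ("yes", "no"),
                      domain_tag="general"),
}

DATASET_FORMATS = {
    "sts": "tsv_pair_score",
    "stsb": "tsv_pair_score",
    "pairclass": "tsv_pair_class",
    "topic": "tsv_single_class",
    "ner": "conll_tokens",
    "noise": "tsv_pair_class",
}

DEFAULT_CONFIG = {
    "seed": 0,
    "generator": {},
    "split_fractions": [0.7503, 0.1498, 0.0999],
    "subword_vocab_size": 400,
    "encoder": {"width": 32, "layers": 1, "heads": 2, "ffn_width": 64,
                "max_len": 48},
    "mtl": {"epochs": 2, "batch_size": 8, "lr": 5e-3, "max_len": 48},
    "finetune": {"epochs": 6, "batch_size": 8, "lr": 5e-3, "max_len": 48},
    # incremental dataset selection ending with the pure-noise probe
    "plans": [
        {"index": 1, "datasets": ["stsb"]},
        {"index": 2, "datasets": ["stsb", "pairclass"]},
        {"index": 3, "datasets": ["stsb", "pairclass", "topic"]},
        {"index": 4, "datasets": ["stsb", "pairclass", "topic", "ner"]},
        {"index": 5, "datasets": ["stsb", "pairclass", "topic", "ner",
                                  "noise"]},
    ],
    "ensemble_method": "linear",
    "lexicon": ["aspirin", "albuterol", "metformin"],
}


def _merged_config(config: Optional[dict]) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: Optional[dict], outdir: str | Path) -> dict:
    """Execute the full synthetic pipeline; returns the run summary.

    Stages: generate the multi-task corpora; train the subword
    vocabulary; split the target pairs into train/validation/test;
    execute the declared iteration plans (intermediate multi-task
    training + fine-tuning, scored on the validation split); retrain the
    best plan and predict on the test split; stack model output with
    handcrafted features (fit on the validation split); evaluate.
    """
    cfg = _merged_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    log: dict = {"stages": [], "config_hash": _config_hash(cfg), "seed": seed,
                 "versions": {"clinsts": __version__,
                              "python": platform.python_version(),
                              "numpy": np.__version__}}

    def stage(name: str, **info) -> None:
        log["stages"].append({"stage": name, **info})

    # 1. simulate
    gen_cfg = GeneratorConfig(seed=seed, **cfg["generator"])
    datasets = generate_all(gen_cfg)
    for name, examples in datasets.items():
        write_examples(examples, outdir / f"data/{name}.tsv"
                       if DATASET_FORMATS[name] != "conll_tokens"
                       else outdir / f"data/{name}.conll",
                       DATASET_FORMATS[name])
    stage("simulate", sizes={k: len(v) for k, v in datasets.items()})

    # 2. vocabulary
    vocab = train_subword_vocab(corpus_sentences(datasets),
                                cfg["subword_vocab_size"])
    vocab.save(outdir / "vocab.txt")
    stage("vocab", size=len(vocab))

    # 3. split the target task
    sts = datasets["sts"]
    train, val, test = split_dataset(sts, tuple(cfg["split_fractions"]), seed)
    stage("split", sizes=[len(train), len(val), len(test)])

    # 4. iterate
    enc_cfg = EncoderConfig(vocab_size=len(vocab), **cfg["encoder"])
    tasks = [TASK_SPECS[n] for n in
             {"sts", *(d for p in cfg["plans"] for d in p["datasets"])}]
    base = ModelState(enc_cfg, sorted(tasks, key=lambda t: t.name), seed=seed)
    mtl_cfg = TrainConfig(seed=seed, **cfg["mtl"])
    ft_cfg = TrainConfig(seed=seed + 1, **cfg["finetune"])
    plans = [IterationPlan(p["index"], tuple(p["datasets"]))
             for p in cfg["plans"]]
    aux = {name: examples for name, examples in datasets.items()
           if name != "sts"}
    plans, best, report = run_iteration_plans(
        base, plans, aux, train, val, mtl_cfg, ft_cfg, vocab)
    report.to_csv(outdir / "iterations.tsv", sep="\t", index=False)
    stage("iterate", best=best.index,
          pcc={p.index: p.pcc for p in plans})

    # 5. retrain the best plan and predict on the held-out test split
    state = base.copy()
    mtl_train(state, {n: aux[n] for n in best.datasets}, mtl_cfg, vocab)
    finetune_target(state, train, ft_cfg, vocab)
    val_preds = PredictionSet("mtl_model", tuple(e.id for e in val),
                              predict_scores(state, val, vocab,
                                             max_len=ft_cfg.max_len))
    test_preds = PredictionSet("mtl_model", tuple(e.id for e in test),
                               predict_scores(state, test, vocab,
                                              max_len=ft_cfg.max_len))
    write_predictions(test_preds, outdir / "predictions_raw.tsv")
    stage("predict", n=len(test))

    # 6. features + ensemble (stacker fit on the validation split)
    lexicon = cfg["lexicon"]
    to_pairs = lambda exs: [SentencePair(e.id, e.text_a, e.text_b, float(e.label))
                            for e in exs]
    val_feats = featurize_pairs(to_pairs(val), lexicon)
    test_feats = featurize_pairs(to_pairs(test), lexicon)
    method = cfg["ensemble_method"]
    gold_test = np.array([float(e.label) for e in test])
    if method == "mean":
        final = normalize_predictions(test_preds)
    else:
        val_design = val_feats.copy()
        val_design.insert(0, "mtl_model", val_preds.scores)
        test_design = test_feats.copy()
        test_design.insert(0, "mtl_model", test_preds.scores)
        # zero-variance feature columns on the fit split carry no signal
        # and make the least-squares design rank-deficient
        keep = [c for c in val_design.columns if val_design[c].nunique() > 1]
        val_design, test_design = val_design[keep], test_design[keep]
        gold_val = np.array([float(e.label) for e in val])
        stacker = fit_stacker(val_design, gold_val, method)
        final = predict_stacker(stacker, test_design)
    write_predictions(final, outdir / "predictions_final.tsv")
    stage("ensemble", method=method)

    # 7. evaluate
    report_obj = evaluate(gold_test, final.scores)
    (outdir / "report.json").write_text(
        json.dumps(report_obj.to_dict(), indent=2))
    stage("evaluate", pcc=report_obj.pcc)

    log["generator"] = asdict(gen_cfg)
    (outdir / "runlog.json").write_text(json.dumps(log, indent=2))
    return {"report": report_obj, "log": log, "best_plan": best.index,
            "iteration_report": report}
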