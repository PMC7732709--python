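"""Multi-task training loop, target-task fine-tuning, and iteration plans.

The training algorithm: each selected dataset is cut into homogeneous
mini-batches, all batches are merged into one epoch schedule E and
shuffled; for every batch b_t the task-t objective alone is computed and
the shared encoder plus that task's head are updated.  "Equal-sized
subsamples" is read as the same batch size across datasets, so the number
of batches a dataset contributes is proportional to its size; remainder
examples form a final short batch, keeping the conservation invariant
(every example appears exactly once per epoch).

Iterative intermediate training: a list of declared iteration plans, each
naming a dataset set D.  For every plan the model is re-initialized from
the same base state, multi-task trained on D, fine-tuned on the target
sentence-similarity data, and scored by Pearson correlation on a held-out
split; the best plan is the argmax (ties to the lowest iteration index).
Dataset selection itself is manual/declared — the runner only executes
plans.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import SentenceExample, TaskSpec
from .model import ModelState, PackedBatch, encode, pair_similarity_score, task_loss
from .tokenizer import Vocab, pack_pair, pack_single


class TrainingError(RuntimeError):
    pass


@dataclass
class MiniBatch:
    """A homogeneous batch: every example belongs to one task."""

    task: str
    examples: list[SentenceExample]

    def __post_init__(self) -> None:
        if any(e.task != self.task for e in self.examples):
            raise ValueError("mini-batch mixes tasks")


EpochSchedule = list[MiniBatch]


@dataclass
class TrainConfig:
    epochs: int = 5
    batch_size: int = 8
    lr: float = 1e-2
    seed: int = 0
    optimizer: str = "adam"  # "adam" | "sgd"
    grad_clip: Optional[float] = 1.0
    max_len: int = 64

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class IterationPlan:
    """One iteration of intermediate training: the dataset set D."""

    index: int
    datasets: tuple[str, ...]
    pcc: Optional[float] = None
    predictions: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError(f"iteration {self.index}: dataset set D is empty")


def build_epoch_schedule(datasets: dict[str, list[SentenceExample]],
                         batch_size: int, seed: int) -> EpochSchedule:
    """Partition each dataset into shuffled batches of ≤ ``batch_size``,
    merge across datasets, and shuffle the merged order (same seed stream).
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    for name, examples in datasets.items():
        if not examples:
            raise ValueError(f"dataset {name!r} is empty")
    rng = np.random.default_rng(seed)
    schedule: EpochSchedule = []
    for name in sorted(datasets):
        examples = datasets[name]
        order = rng.permutation(len(examples))
        for start in range(0, len(examples), batch_size):
            chunk = [examples[i] for i in order[start:start + batch_size]]
            schedule.append(MiniBatch(task=chunk[0].task, examples=chunk))
    perm = rng.permutation(len(schedule))
    return [schedule[i] for i in perm]


# -- batch collation -----------------------------------------------------------

def collate(batch: MiniBatch, task: TaskSpec, vocab: Vocab,
            max_len: int) -> tuple[PackedBatch, np.ndarray]:
    """Pack a mini-batch into padded arrays plus a target array."""
    packed = []
    for e in batch.examples:
        if e.is_pair:
            packed.append(pack_pair(e.text_a, e.text_b, vocab, max_len))
        else:
            packed.append(pack_single(e.text_a, vocab, max_len))
    pb = PackedBatch.from_packed(packed, vocab)
    if task.head_type == "pair_similarity":
        targets = np.array([float(e.label) for e in batch.examples])
    elif task.head_type == "token_classification":
        targets = _align_tags(batch, task, pb, vocab)
    else:
        targets = np.array([task.class_index(e.label) for e in batch.examples])
    return pb, targets


def _align_tags(batch: MiniBatch, task: TaskSpec, pb: PackedBatch,
                vocab: Vocab) -> np.ndarray:
    """Project word-level tags onto subword positions.

    Each word's tag is repeated over its subword pieces; marker and pad
    positions get tag 0 (they are excluded from the loss anyway).
    """
    B, T = pb.token_ids.shape
    tags = np.zeros((B, T), dtype=np.int64)
    for i, e in enumerate(batch.examples):
        words = e.text_a.split()
        word_tags = list(e.label)
        if len(words) != len(word_tags):
            raise ValueError(
                f"example {e.id!r}: {len(words)} tokens vs {len(word_tags)} tags")
        pos = 1  # skip [CLS]
        for word, tag in zip(words, word_tags):
            n_pieces = len(vocab.encode(word))
            idx = task.class_index(tag)
            for _ in range(n_pieces):
                if pos < T - 1:
                    tags[i, pos] = idx
                pos += 1
    return tags


# -- optimizers ----------------------------------------------------------------

class _Optimizer:
    def __init__(self, lr: float):
        self.lr = lr

    def step(self, name: str, param, grad: np.ndarray) -> None:
        raise NotImplementedError


class _SGD(_Optimizer):
    """Plain stochastic gradient descent: θ ← θ − η ∇θ."""

    def step(self, name, param, grad):
        param.data -= self.lr * grad


class _Adam(_Optimizer):
    """Adaptive-moment SGD variant (default optimizer)."""

    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t: dict[str, int] = {}

    def step(self, name, param, grad):
        m = self.m.setdefault(name, np.zeros_like(param.data))
        v = self.v.setdefault(name, np.zeros_like(param.data))
        t = self.t.get(name, 0) + 1
        self.t[name] = t
        m[...] = self.beta1 * m + (1 - self.beta1) * grad
        v[...] = self.beta2 * v + (1 - self.beta2) * grad ** 2
        mhat = m / (1 - self.beta1 ** t)
        vhat = v / (1 - self.beta2 ** t)
        param.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _make_optimizer(config: TrainConfig) -> _Optimizer:
    if config.optimizer == "sgd":
        return _SGD(config.lr)
    if config.optimizer == "adam":
        return _Adam(config.lr)
    raise ValueError(f"unknown optimizer {config.optimizer!r}")


def _epoch_seed(seed: int, epoch: int) -> int:
    # distinct, deterministic, < 2^31
    return int(np.random.SeedSequence([seed, epoch]).generate_state(1)[0] % (2 ** 31))


# -- training loops ------------------------------------------------------------

def mtl_train(state: ModelState, datasets: dict[str, list[SentenceExample]],
              config: TrainConfig, vocab: Vocab,
              trainable: Optional[Callable[[str], list[str]]] = None,
              ) -> pd.DataFrame:
    """Run the multi-task loop in place; returns the per-epoch loss log.

    For each mini-batch only the task-t objective is computed and only the
    shared parameters plus task t's head are updated.  The schedule is
    re-shuffled every epoch with a per-epoch derived seed; identical
    config + seed reproduce bit-identical loss logs.
    """
    for name in datasets:
        task = state.tasks.get(_task_of(datasets[name], name))
        if task is None:
            raise ValueError(f"dataset {name!r} has no registered task")
    opt = _make_optimizer(config)
    if trainable is None:
        trainable = state.trainable_for
    rows = []
    for epoch in range(config.epochs):
        schedule = build_epoch_schedule(datasets, config.batch_size,
                                        _epoch_seed(config.seed, epoch))
        sums: dict[str, float] = {}
        counts: dict[str, int] = {}
        for b_idx, batch in enumerate(schedule):
            task = state.tasks[batch.task]
            pb, targets = collate(batch, task, vocab, config.max_len)
            state.zero_grad()
            loss = task_loss(state, task, pb, targets)
            value = loss.item()
            if not np.isfinite(value):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}, batch {b_idx} "
                    f"(task {batch.task!r})")
            loss.backward()
            for name in trainable(batch.task):
                p = state.params[name]
                if p.grad is None:
                    continue
                g = np.asarray(p.grad)
                if config.grad_clip is not None:
                    norm = np.linalg.norm(g)
                    if norm > config.grad_clip:
                        g = g * (config.grad_clip / norm)
                opt.step(name, p, g)
            sums[batch.task] = sums.get(batch.task, 0.0) + value
            counts[batch.task] = counts.get(batch.task, 0) + 1
        for tname in sorted(sums):
            rows.append({"epoch": epoch, "task": tname,
                         "mean_loss": sums[tname] / counts[tname]})
    return pd.DataFrame(rows, columns=["epoch", "task", "mean_loss"])


def _task_of(examples: list[SentenceExample], name: str) -> str:
    tasks = {e.task for e in examples}
    if len(tasks) != 1:
        raise ValueError(f"dataset {name!r} mixes tasks: {sorted(tasks)}")
    return tasks.pop()


def finetune_target(state: ModelState, sts_train: list[SentenceExample],
                    config: TrainConfig, vocab: Vocab,
                    task_name: Optional[str] = None) -> pd.DataFrame:
    """Single-task training on the target sentence-similarity data.

    Updates the shared layers and the pair-similarity head only; all
    other heads are untouched.
    """
    if task_name is None:
        candidates = [n for n, t in state.tasks.items()
                      if t.head_type == "pair_similarity"]
        if not candidates:
            raise ValueError("model has no pair_similarity head to fine-tune")
        task_name = candidates[0]
    if state.tasks[task_name].head_type != "pair_similarity":
        raise ValueError(f"task {task_name!r} is not a pair_similarity task")
    dataset = {task_name: [replace(e, task=task_name) for e in sts_train]}
    return mtl_train(state, dataset, config, vocab)


def predict_scores(state: ModelState, pairs: Sequence[SentenceExample],
                   vocab: Vocab, task_name: Optional[str] = None,
                   max_len: int = 64, batch_size: int = 32) -> np.ndarray:
    """Raw (unclipped) similarity scores for sentence pairs."""
    if task_name is None:
        task_name = next(n for n, t in state.tasks.items()
                         if t.head_type == "pair_similarity")
    W = state.params[f"head.{task_name}.W"]
    b = state.params.get(f"head.{task_name}.b")
    out = []
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start:start + batch_size]
        packed = [pack_pair(e.text_a, e.text_b, vocab, max_len) for e in chunk]
        pb = PackedBatch.from_packed(packed, vocab)
        enc = encode(pb, state)
        out.append(pair_similarity_score(enc.h_cls, W, b).data)
    return np.concatenate(out) if out else np.array([])


def run_iteration_plans(base_state: ModelState, plans: list[IterationPlan],
                        datasets: dict[str, list[SentenceExample]],
                        target_train: list[SentenceExample],
                        target_eval: list[SentenceExample],
                        mtl_config: TrainConfig, finetune_config: TrainConfig,
                        vocab: Vocab,
                        ) -> tuple[list[IterationPlan], IterationPlan, pd.DataFrame]:
    """Execute declared iteration plans from a common base state.

    Each plan: copy the base state → multi-task train on its D →
    fine-tune on the target training pairs → Pearson correlation on the
    held-out pairs.  Returns (filled plans, best plan, report table).
    """
    from .evaluation import pearson_correlation

    if not plans:
        raise ValueError("no iteration plans given")
    for plan in plans:
        missing = [d for d in plan.datasets if d not in datasets]
        if missing:
            raise ValueError(
                f"iteration {plan.index}: unknown dataset(s) {missing}")
    gold = np.array([float(e.label) for e in target_eval])
    for plan in plans:
        state = base_state.copy()
        subset = {name: datasets[name] for name in plan.datasets}
        mtl_train(state, subset, mtl_config, vocab)
        finetune_target(state, target_train, finetune_config, vocab)
        preds = predict_scores(state, target_eval, vocab,
                               max_len=finetune_config.max_len)
        plan.predictions = preds
        plan.pcc = pearson_correlation(gold, preds)
    best = max(plans, key=lambda p: (p.pcc, -p.index))
    report = pd.DataFrame(
        [{"iteration": p.index, "datasets": "+".join(p.datasets),
          "pcc": p.pcc, "best": p is best} for p in plans])
    return plans, best, report
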