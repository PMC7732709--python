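"""Shared transformer encoder with four task-specific heads.

One encoder (token + segment + position embeddings followed by
transformer blocks) produces contextual embeddings shared by all tasks.
Each registered task owns a lightweight head on top:

* ``pair_similarity`` — a fully connected layer on the classification
  marker's embedding h_cls produces an unbounded real score, trained with
  mean squared error against the 0-5 gold score;
* ``single_classification`` / ``pair_classification`` — softmax logistic
  regression on h_cls, trained with cross-entropy;
* ``token_classification`` — a position-wise softmax linear classifier on
  the token embeddings, trained with cross-entropy over non-special,
  non-padding positions.

The encoder is size-configurable; the desk-scale default (2 layers of
width 64) keeps the architecture shape of much larger pretrained encoders
while running in seconds on a CPU.  Shared parameters can be freshly
initialized from a seed or loaded from a checkpoint archive.
"""
from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .autodiff import Tensor, embedding, gelu, logsumexp, softmax, tensor
from .core import TaskSpec
from .tokenizer import PackedInput, Vocab

CHECKPOINT_VERSION = 1
LOGPROB_FLOOR = 1e-12  # numerical floor inside cross-entropy


@dataclass
class EncoderConfig:
    """Architecture shape of the shared layers."""

    vocab_size: int
    width: int = 64
    layers: int = 2
    heads: int = 2
    ffn_width: int = 256
    max_len: int = 512
    layer_norm_eps: float = 1e-5
    init_scale: float = 0.05

    def __post_init__(self) -> None:
        if self.width % self.heads:
            raise ValueError("width must be divisible by the number of heads")


@dataclass
class ContextualEncoding:
    """Per-token contextual embeddings plus the pooled h_cls vector."""

    h_tokens: Tensor  # (batch, seq, width)
    h_cls: Tensor     # (batch, width)
    mask: np.ndarray  # (batch, seq) 1.0 for real tokens, 0.0 for padding

    @property
    def width(self) -> int:
        return self.h_tokens.shape[-1]


class ModelState:
    """Shared encoder parameters plus one parameter block per task head."""

    def __init__(self, config: EncoderConfig, tasks: Iterable[TaskSpec],
                 seed: int = 0, use_bias: bool = True):
        self.config = config
        self.tasks: dict[str, TaskSpec] = {}
        self.use_bias = use_bias
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)
        self._init_encoder(rng)
        for task in tasks:
            self.register_task(task, rng)

    # -- parameter construction ----------------------------------------------
    def _param(self, name: str, shape: tuple[int, ...], rng: np.random.Generator,
               zero: bool = False) -> Tensor:
        data = (np.zeros(shape) if zero
                else rng.normal(0.0, self.config.init_scale, size=shape))
        p = tensor(data, requires_grad=True, name=name)
        self.params[name] = p
        return p

    def _init_encoder(self, rng: np.random.Generator) -> None:
        c = self.config
        self._param("enc.tok_emb", (c.vocab_size, c.width), rng)
        self._param("enc.seg_emb", (2, c.width), rng)
        self._param("enc.pos_emb", (c.max_len, c.width), rng)
        for i in range(c.layers):
            pre = f"enc.block{i}."
            for proj in ("q", "k", "v", "o"):
                self._param(pre + f"W{proj}", (c.width, c.width), rng)
                self._param(pre + f"b{proj}", (c.width,), rng, zero=True)
            self._param(pre + "W1", (c.width, c.ffn_width), rng)
            self._param(pre + "b1", (c.ffn_width,), rng, zero=True)
            self._param(pre + "W2", (c.ffn_width, c.width), rng)
            self._param(pre + "b2", (c.width,), rng, zero=True)
            for ln in ("ln1", "ln2"):
                self.params[pre + ln + ".g"] = tensor(
                    np.ones(c.width), requires_grad=True, name=pre + ln + ".g")
                self._param(pre + ln + ".b", (c.width,), rng, zero=True)

    def register_task(self, task: TaskSpec,
                      rng: Optional[np.random.Generator] = None) -> None:
        """Attach a randomly initialized head for ``task``."""
        if task.name in self.tasks:
            raise ValueError(f"task {task.name!r} already registered")
        if rng is None:
            rng = np.random.default_rng(abs(hash(task.name)) % (2 ** 31))
        self.tasks[task.name] = task
        out = 1 if task.head_type == "pair_similarity" else task.num_classes
        pre = f"head.{task.name}."
        self._param(pre + "W", (self.config.width, out), rng)
        if self.use_bias:
            self._param(pre + "b", (out,), rng, zero=True)

    # -- parameter bookkeeping -----------------------------------------------
    def shared_param_names(self) -> list[str]:
        return [n for n in self.params if n.startswith("enc.")]

    def head_param_names(self, task_name: str) -> list[str]:
        pre = f"head.{task_name}."
        return [n for n in self.params if n.startswith(pre)]

    def trainable_for(self, task_name: str) -> list[str]:
        """Parameters updated by a mini-batch of ``task_name``: the shared
        encoder plus that task's head only."""
        return self.shared_param_names() + self.head_param_names(task_name)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def copy(self) -> "ModelState":
        clone = ModelState.__new__(ModelState)
        clone.config = self.config
        clone.tasks = dict(self.tasks)
        clone.use_bias = self.use_bias
        clone.params = {n: tensor(p.data.copy(), requires_grad=True, name=n)
                        for n, p in self.params.items()}
        return clone

    # -- checkpointing --------------------------------------------------------
    def save(self, path: str | Path, vocab: Optional[Vocab] = None) -> None:
        """Write a versioned archive of named arrays (+ optional vocab)."""
        path = Path(path)
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": asdict(self.config),
            "use_bias": self.use_bias,
            "tasks": [asdict(t) for t in self.tasks.values()],
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            for name, p in self.params.items():
                zf.writestr(f"param/{name}.json",
                            json.dumps({"shape": p.shape, "data": p.data.reshape(-1).tolist()}))
            if vocab is not None:
                zf.writestr("vocab.txt", "\n".join(vocab.units) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> tuple["ModelState", Optional[Vocab]]:
        path = Path(path)
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta["version"] != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['version']}")
            config = EncoderConfig(**meta["config"])
            tasks = [TaskSpec(**t) for t in meta["tasks"]]
            for t in tasks:
                t.label_space = tuple(t.label_space)
            state = cls(config, [], use_bias=meta["use_bias"])
            state.tasks = {t.name: t for t in tasks}
            state.params = {}
            for info in zf.namelist():
                if not info.startswith("param/"):
                    continue
                name = info[len("param/"):-len(".json")]
                blob = json.loads(zf.read(info))
                data = np.array(blob["data"]).reshape(blob["shape"])
                state.params[name] = tensor(data, requires_grad=True, name=name)
            vocab = None
            if "vocab.txt" in zf.namelist():
                units = zf.read("vocab.txt").decode("utf-8").splitlines()
                vocab = Vocab([u for u in units if u])
        return state, vocab


# -- batching -----------------------------------------------------------------

@dataclass
class PackedBatch:
    """Padded arrays for a homogeneous mini-batch."""

    token_ids: np.ndarray    # (B, T) int
    segment_ids: np.ndarray  # (B, T) int
    mask: np.ndarray         # (B, T) float, 1 real / 0 pad
    special: np.ndarray      # (B, T) float, 1 at CLS/SEP/pad positions

    @classmethod
    def from_packed(cls, packed: list[PackedInput], vocab: Vocab) -> "PackedBatch":
        T = max(p.length for p in packed)
        B = len(packed)
        ids = np.full((B, T), vocab.pad_id, dtype=np.int64)
        segs = np.zeros((B, T), dtype=np.int64)
        mask = np.zeros((B, T))
        special = np.ones((B, T))
        for i, p in enumerate(packed):
            L = p.length
            ids[i, :L] = p.token_ids
            segs[i, :L] = p.segment_ids
            mask[i, :L] = 1.0
            for j, t in enumerate(p.token_ids):
                if t not in (vocab.cls_id, vocab.sep_id):
                    special[i, j] = 0.0
        return cls(ids, segs, mask, special)


def _layer_norm(x: Tensor, g: Tensor, b: Tensor, eps: float) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * ((var + eps) ** -0.5) * g + b


def encode(batch: PackedBatch, state: ModelState) -> ContextualEncoding:
    """Run the shared layers; deterministic given (batch, state).

    h_cls is the first position of the token embeddings (the
    classification marker always occupies position 0).
    """
    c = state.config
    ids = batch.token_ids
    if ids.size and ids.max() >= c.vocab_size:
        raise ValueError(
            f"token id {ids.max()} out of range for vocabulary of {c.vocab_size}")
    P = state.params
    B, T = ids.shape
    x = (embedding(P["enc.tok_emb"], ids)
         + embedding(P["enc.seg_emb"], batch.segment_ids)
         + P["enc.pos_emb"][:T, :])
    # additive attention mask: large negative at padded keys
    att_mask = ((1.0 - batch.mask) * -1e9)[:, None, None, :]  # (B,1,1,T)
    H = c.heads
    dh = c.width // H
    scale = 1.0 / np.sqrt(dh)
    for i in range(c.layers):
        pre = f"enc.block{i}."
        q = (x @ P[pre + "Wq"] + P[pre + "bq"]).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
        k = (x @ P[pre + "Wk"] + P[pre + "bk"]).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
        v = (x @ P[pre + "Wv"] + P[pre + "bv"]).reshape(B, T, H, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale + att_mask
        attn = softmax(scores)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, c.width)
        x = _layer_norm(x + ctx @ P[pre + "Wo"] + P[pre + "bo"],
                        P[pre + "ln1.g"], P[pre + "ln1.b"], c.layer_norm_eps)
        ff = gelu(x @ P[pre + "W1"] + P[pre + "b1"]) @ P[pre + "W2"] + P[pre + "b2"]
        x = _layer_norm(x + ff, P[pre + "ln2.g"], P[pre + "ln2.b"], c.layer_norm_eps)
    return ContextualEncoding(h_tokens=x, h_cls=x[:, 0, :], mask=batch.mask)


# -- heads and objectives ------------------------------------------------------

def _head_tensors(state: ModelState, task_name: str) -> tuple[Tensor, Optional[Tensor]]:
    W = state.params[f"head.{task_name}.W"]
    b = state.params.get(f"head.{task_name}.b")
    return W, b


def pair_similarity_score(h_cls: Tensor, W: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """Fully connected layer on h_cls: the unbounded real similarity score."""
    if h_cls.shape[-1] != W.shape[0]:
        raise ValueError(
            f"encoding width {h_cls.shape[-1]} does not match head width {W.shape[0]}")
    out = h_cls @ W
    if b is not None:
        out = out + b
    return out.reshape(-1) if out.ndim > 1 else out


def mse_loss(scores: Tensor, targets: np.ndarray) -> Tensor:
    """Mean squared error, averaged over the mini-batch."""
    diff = scores - np.asarray(targets, dtype=np.float64)
    return (diff * diff).mean()


def class_logits(h: Tensor, W: Tensor, b: Optional[Tensor] = None) -> Tensor:
    if h.shape[-1] != W.shape[0]:
        raise ValueError(
            f"encoding width {h.shape[-1]} does not match head width {W.shape[0]}")
    out = h @ W
    if b is not None:
        out = out + b
    return out


def class_probabilities(h: Tensor, W: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """Softmax logistic regression on an encoding vector (or batch)."""
    return softmax(class_logits(h, W, b))


def cross_entropy_loss(probs: np.ndarray | Tensor, true_class: np.ndarray | int) -> float:
    """−log p[true] (mean over a batch), with a numerical floor on p."""
    p = probs.data if isinstance(probs, Tensor) else np.asarray(probs, dtype=np.float64)
    idx = np.atleast_1d(np.asarray(true_class, dtype=np.int64))
    p2 = np.atleast_2d(p)
    picked = np.maximum(p2[np.arange(len(idx)), idx], LOGPROB_FLOOR)
    return float(-np.log(picked).mean())


def _nll_from_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Differentiable mean negative log-likelihood from raw logits."""
    logp = logits - logsumexp(logits)
    K = logits.shape[-1]
    onehot = np.eye(K)[np.asarray(targets, dtype=np.int64)]
    return -(logp * onehot).sum(axis=-1).mean()


def token_class_probabilities(enc: ContextualEncoding, W: Tensor,
                              b: Optional[Tensor] = None) -> Tensor:
    """Position-wise softmax classifier over the token embeddings."""
    return softmax(class_logits(enc.h_tokens, W, b))


def task_loss(state: ModelState, task: TaskSpec, batch: PackedBatch,
              targets: np.ndarray,
              special_mask: Optional[np.ndarray] = None) -> Tensor:
    """The task-t objective on one homogeneous mini-batch.

    ``targets``: float scores for pair_similarity; class indices for the
    classification heads; (B, T) tag-index matrix for token
    classification (positions at special markers / padding are excluded
    from the loss via ``batch.special``).
    """
    enc = encode(batch, state)
    W, b = _head_tensors(state, task.name)
    if task.head_type == "pair_similarity":
        return mse_loss(pair_similarity_score(enc.h_cls, W, b), targets)
    if task.head_type in ("single_classification", "pair_classification"):
        logits = class_logits(enc.h_cls, W, b)
        return _nll_from_logits(logits, targets)
    # token classification: mean NLL over real, non-special positions
    logits = class_logits(enc.h_tokens, W, b)
    logp = logits - logsumexp(logits)
    K = logits.shape[-1]
    tags = np.asarray(targets, dtype=np.int64)
    onehot = np.eye(K)[tags]  # (B, T, K)
    keep = batch.mask * (1.0 - batch.special)
    if special_mask is not None:
        keep = keep * special_mask
    total = keep.sum()
    if total == 0:
        raise ValueError("token-classification batch has no scorable positions")
    per_pos = -(logp * onehot).sum(axis=-1)
    return (per_pos * keep).sum() * (1.0 / total)
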