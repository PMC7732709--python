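"""Shared domain types used across the pipeline.

A labeled instance of any task is a :class:`SentenceExample`; a task is
declared by a :class:`TaskSpec` binding a dataset to one of the four head
types of the multi-task model.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

Label = Union[float, str, Sequence[str]]

HEAD_TYPES = (
    "pair_similarity",
    "single_classification",
    "pair_classification",
    "token_classification",
)


@dataclass
class TaskSpec:
    """A task's head type, label space and objective.

    ``head_type`` determines the objective: mean squared error for
    ``pair_similarity`` (a continuous 0-5 score), cross-entropy for the
    three classification head types.  ``label_space`` is the ordered list
    of class names and must be empty exactly when the task is a
    regression.
    """

    name: str
    head_type: str
    label_space: tuple[str, ...] = ()
    domain_tag: str = "general"

    def __post_init__(self) -> None:
        if self.head_type not in HEAD_TYPES:
            raise ValueError(
                f"unknown head_type {self.head_type!r}; expected one of {HEAD_TYPES}"
            )
        is_classification = self.head_type != "pair_similarity"
        if is_classification and not self.label_space:
            raise ValueError(f"task {self.name!r}: classification needs a label_space")
        if not is_classification and self.label_space:
            raise ValueError(f"task {self.name!r}: pair_similarity takes no label_space")

    @property
    def objective(self) -> str:
        return "mse" if self.head_type == "pair_similarity" else "cross_entropy"

    @property
    def num_classes(self) -> int:
        return len(self.label_space)

    def class_index(self, label: str) -> int:
        try:
            return self.label_space.index(label)
        except ValueError:
            raise ValueError(
                f"label {label!r} outside label space of task {self.name!r}: "
                f"{list(self.label_space)}"
            ) from None


@dataclass
class SentenceExample:
    """One labeled instance: single sentence, sentence pair, or token sequence.

    For token-classification tasks ``text_a`` holds the whitespace-joined
    tokens and ``label`` the per-token tag list.  ``latent`` carries the
    hidden ground truth of synthetic examples (never consumed by models;
    used only by tests and analyses).
    """

    id: str
    task: str
    text_a: str
    text_b: Optional[str] = None
    label: Optional[Label] = None
    latent: Optional[dict] = None

    @property
    def is_pair(self) -> bool:
        return self.text_b is not None


@dataclass
class SentencePair:
    """A raw sentence pair, optionally gold-scored on the 0-5 scale."""

    id: str
    text_a: str
    text_b: str
    score: Optional[float] = None
    lexical_mean: Optional[float] = field(default=None)

    def __post_init__(self) -> None:
        if self.score is not None and not (self.text_a and self.text_b):
            raise ValueError(f"pair {self.id!r}: scored pairs need nonempty texts")
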