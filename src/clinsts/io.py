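"""Dataset readers and writers.

Tabular datasets are UTF-8 TSV with a header row; token-classification
data is two-column CoNLL (token TAB tag, blank line between sentences).
Readers validate labels against the bound task and reject malformed rows
with their line numbers rather than coercing them.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import SentenceExample, TaskSpec
from .ensemble import PredictionSet

FORMATS = ("tsv_pair_score", "tsv_pair_class", "tsv_single_class", "conll_tokens")

_FORMAT_FOR_HEAD = {
    "pair_similarity": "tsv_pair_score",
    "pair_classification": "tsv_pair_class",
    "single_classification": "tsv_single_class",
    "token_classification": "conll_tokens",
}

DEFAULT_COLUMNS = {
    "tsv_pair_score": {"id": "id", "text_a": "sentence1", "text_b": "sentence2",
                       "label": "score"},
    "tsv_pair_class": {"id": "id", "text_a": "sentence1", "text_b": "sentence2",
                       "label": "label"},
    "tsv_single_class": {"id": "id", "text_a": "sentence", "label": "label"},
}


class DatasetFormatError(ValueError):
    pass


@dataclass
class DatasetManifest:
    """Binds a dataset file to a task and a column map."""

    name: str
    task: TaskSpec
    path: Path
    format: str
    columns: Optional[dict] = None

    def __post_init__(self) -> None:
        self.path = Path(self.path)
        if self.format not in FORMATS:
            raise ValueError(f"unknown format {self.format!r}")
        expected = _FORMAT_FOR_HEAD[self.task.head_type]
        if self.format != expected:
            raise ValueError(
                f"dataset {self.name!r}: format {self.format!r} does not match "
                f"head type {self.task.head_type!r} (expected {expected!r})")
        if self.columns is None and self.format != "conll_tokens":
            self.columns = dict(DEFAULT_COLUMNS[self.format])


def read_dataset(manifest: DatasetManifest) -> list[SentenceExample]:
    """Parse and validate a dataset file into examples with stable ids."""
    if not manifest.path.exists():
        raise FileNotFoundError(f"dataset {manifest.name!r}: {manifest.path}")
    if manifest.format == "conll_tokens":
        return _read_conll(manifest)
    return _read_tsv(manifest)


def _read_tsv(manifest: DatasetManifest) -> list[SentenceExample]:
    cols = manifest.columns
    task = manifest.task
    examples: list[SentenceExample] = []
    with manifest.path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise DatasetFormatError(f"{manifest.path}: empty file, no header")
        needed = [cols[k] for k in cols if k != "id" or cols["id"] in reader.fieldnames]
        missing = [c for c in needed if c not in reader.fieldnames]
        if missing:
            raise DatasetFormatError(
                f"{manifest.path}: missing column(s) {missing}")
        bad_labels = []
        for lineno, row in enumerate(reader, start=2):
            if any(row.get(c) is None for c in needed):
                raise DatasetFormatError(
                    f"{manifest.path}: malformed row at line {lineno}")
            ex_id = row.get(cols.get("id", "id")) or f"{manifest.name}-{lineno - 2:04d}"
            raw_label = row[cols["label"]]
            if task.head_type == "pair_similarity":
                try:
                    label: object = float(raw_label)
                except ValueError:
                    raise DatasetFormatError(
                        f"{manifest.path}: non-numeric score {raw_label!r} "
                        f"at line {lineno}") from None
                if not 0.0 <= label <= 5.0:
                    raise DatasetFormatError(
                        f"{manifest.path}: score {label} outside [0,5] "
                        f"at line {lineno}")
            else:
                if raw_label not in task.label_space:
                    bad_labels.append((lineno, raw_label))
                    continue
                label = raw_label
            examples.append(SentenceExample(
                id=ex_id, task=task.name,
                text_a=row[cols["text_a"]],
                text_b=row[cols["text_b"]] if "text_b" in cols else None,
                label=label))
        if bad_labels:
            listing = ", ".join(f"line {ln}: {lab!r}" for ln, lab in bad_labels[:10])
            raise DatasetFormatError(
                f"{manifest.path}: labels outside the space of task "
                f"{task.name!r}: {listing}")
    return examples


def _read_conll(manifest: DatasetManifest) -> list[SentenceExample]:
    task = manifest.task
    examples = []
    tokens: list[str] = []
    tags: list[str] = []
    bad: list[tuple[int, str]] = []

    def flush(idx: int) -> None:
        if tokens:
            examples.append(SentenceExample(
                id=f"{manifest.name}-{idx:04d}", task=task.name,
                text_a=" ".join(tokens), label=list(tags)))
            tokens.clear()
            tags.clear()

    with manifest.path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush(len(examples))
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DatasetFormatError(
                    f"{manifest.path}: expected 'token<TAB>tag' at line {lineno}")
            token, tag = parts
            if tag not in task.label_space:
                bad.append((lineno, tag))
            tokens.append(token)
            tags.append(tag)
    flush(len(examples))
    if bad:
        listing = ", ".join(f"line {ln}: {t!r}" for ln, t in bad[:10])
        raise DatasetFormatError(
            f"{manifest.path}: tags outside the space of task "
            f"{task.name!r}: {listing}")
    return examples


def write_examples(examples: Sequence[SentenceExample], path: str | Path,
                   fmt: str) -> None:
    """Write examples in the same formats the readers consume."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "conll_tokens":
        with path.open("w", encoding="utf-8") as fh:
            for e in examples:
                for token, tag in zip(e.text_a.split(), e.label):
                    fh.write(f"{token}\t{tag}\n")
                fh.write("\n")
        return
    cols = DEFAULT_COLUMNS[fmt]
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        header = [cols["id"], cols["text_a"]]
        if "text_b" in cols:
            header.append(cols["text_b"])
        header.append(cols["label"])
        writer.writerow(header)
        for e in examples:
            row = [e.id, e.text_a]
            if "text_b" in cols:
                row.append(e.text_b or "")
            row.append(f"{e.label:.4f}" if isinstance(e.label, float) else e.label)
            writer.writerow(row)


def write_predictions(preds: PredictionSet, path: str | Path) -> None:
    """Two-column tab-delimited id/score file, 4 decimal places."""
    if not np.isfinite(preds.scores).all():
        raise ValueError("refusing to write non-finite scores")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["id", "score"])
        for ex_id, score in zip(preds.ids, preds.scores):
            writer.writerow([ex_id, f"{score:.4f}"])


def read_predictions(path: str | Path, name: Optional[str] = None) -> PredictionSet:
    """Read a two-column id/score file (the adapter through which external
    scorers' outputs enter the ensemble)."""
    path = Path(path)
    ids: list[str] = []
    scores: list[float] = []
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise DatasetFormatError(f"{path}: expected an id<TAB>score header")
        for lineno, row in enumerate(reader, start=2):
            if len(row) < 2:
                raise DatasetFormatError(f"{path}: malformed row at line {lineno}")
            ids.append(row[0])
            try:
                scores.append(float(row[1]))
            except ValueError:
                raise DatasetFormatError(
                    f"{path}: non-numeric score at line {lineno}") from None
    return PredictionSet(name or path.stem, tuple(ids), np.array(scores))
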