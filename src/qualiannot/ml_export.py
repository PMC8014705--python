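"""Classification ground truth from annotation tables.

Covers the data side of training an image classifier from manual
annotations: 1-hot label matrices, seeded stratified train/validation/test
splits, export of the images into the ``split/class/image`` folder layout
that classification trainers consume, and confusion-matrix evaluation.
"""

from __future__ import annotations

import csv
import shutil
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation_model import AnnotationRecord, AnnotationTable, Modality
from .errors import ConfigurationError, UnsupportedOperationError, ValidationError


class Split(Enum):
    TRAIN = "train"
    VAL = "val"
    TEST = "test"


RecordId = tuple[str, str, str, str]


def record_id(record: AnnotationRecord) -> RecordId:
    """Identity of a record for splitting: folder, image, slice position, ROI.

    The ROI component lets ROI-level classes split correctly; the slice
    component separates per-slice annotations of one stack file.
    """
    slice_repr = ",".join(f"{axis}={idx}" for axis, idx in record.slice_index)
    roi = record.roi_names[0] if record.roi_names else ""
    return (record.folder, record.image, slice_repr, roi)


def _record_class(record: AnnotationRecord, feature: str | None) -> str:
    if record.category is not None:
        return record.category
    if record.choices is not None and feature is not None:
        return record.choices[feature]
    raise UnsupportedOperationError("record has no single class label")


def _class_labels(table: AnnotationTable, feature: str | None) -> tuple[str, ...]:
    config = table.config
    if config.modality is Modality.SINGLE:
        return config.keywords
    if config.modality is Modality.FEATURES:
        if feature is None:
            raise UnsupportedOperationError(
                "dropdown tables must name the feature to export (one feature at a time)"
            )
        for fdef in config.features:
            if fdef.label == feature:
                return fdef.choices
        raise ValidationError(f"unknown feature {feature!r}")
    raise UnsupportedOperationError(
        "multi-label (checkbox) tables have no single class per row; "
        "export the boolean keyword columns directly instead"
    )


def to_one_hot(table: AnnotationTable, feature: str | None = None) -> tuple[np.ndarray, tuple[str, ...]]:
    """Encode a single-class table as an n×k 0/1 matrix plus class labels.

    Each row has exactly one 1 — the probability-vector form classification
    trainers expect. Column order equals the configured keyword (or choice)
    order. Dropdown tables are exported one feature at a time via
    ``feature=``.
    """
    labels = _class_labels(table, feature)
    index = {label: j for j, label in enumerate(labels)}
    matrix = np.zeros((len(table), len(labels)), dtype=int)
    for i, record in enumerate(table.records):
        matrix[i, index[_record_class(record, feature)]] = 1
    return matrix, labels


@dataclass(frozen=True)
class SplitAssignment:
    """Deterministic record→{train,val,test} assignment."""

    assignment: tuple[tuple[RecordId, Split], ...]
    fractions: tuple[float, float, float]
    seed: int

    def as_dict(self) -> dict[RecordId, Split]:
        return dict(self.assignment)

    def counts(self) -> dict[Split, int]:
        out = {s: 0 for s in Split}
        for _, split in self.assignment:
            out[split] += 1
        return out


def _largest_remainder(n: int, fractions: Sequence[float],
                       deficits: Sequence[float] | None = None) -> list[int]:
    """Apportion n items to fractions, flooring then topping up by remainder.

    Exact remainder ties break toward the split with the largest running
    global deficit (so half-remainders alternate across classes and the
    overall counts also match the fractions), then by declared order
    (train before val before test)."""
    exact = [n * f for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    leftover = n - sum(base)
    remainders = [e - b for e, b in zip(exact, base)]
    deficits = list(deficits) if deficits is not None else [0.0] * len(fractions)
    for _ in range(leftover):
        i = max(range(len(fractions)), key=lambda j: (remainders[j], deficits[j], -j))
        base[i] += 1
        remainders[i] -= 1.0
        deficits[i] -= 1.0
    return base


def stratified_split(
    table: AnnotationTable,
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
    feature: str | None = None,
) -> SplitAssignment:
    """Split a single-class table per class into train/val/test.

    Deterministic given the seed; within each class the counts follow the
    fractions with largest-remainder rounding, so per-class counts deviate
    from the exact products by less than one record.
    """
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ConfigurationError("fractions must be three non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions must sum to 1, got {sum(fractions)}")
    labels = _class_labels(table, feature)
    by_class: dict[str, list[RecordId]] = {label: [] for label in labels}
    seen: set[RecordId] = set()
    for record in table.records:
        rid = record_id(record)
        if rid in seen:
            raise ValidationError(f"duplicate record identity {rid}; cannot split unambiguously")
        seen.add(rid)
        by_class[_record_class(record, feature)].append(rid)

    rng = np.random.default_rng(seed)
    assignment: list[tuple[RecordId, Split]] = []
    cum_exact = [0.0, 0.0, 0.0]
    cum_count = [0, 0, 0]
    for label in labels:
        ids = by_class[label]
        if not ids:
            continue
        perm = rng.permutation(len(ids))
        shuffled = [ids[i] for i in perm]
        deficits = [e - c for e, c in zip(cum_exact, cum_count)]
        n_train, n_val, n_test = _largest_remainder(len(ids), fractions, deficits)
        for i, (f, c) in enumerate(zip(fractions, (n_train, n_val, n_test))):
            cum_exact[i] += len(ids) * f
            cum_count[i] += c
        for rid in shuffled[:n_train]:
            assignment.append((rid, Split.TRAIN))
        for rid in shuffled[n_train : n_train + n_val]:
            assignment.append((rid, Split.VAL))
        for rid in shuffled[n_train + n_val :]:
            assignment.append((rid, Split.TEST))
    return SplitAssignment(tuple(assignment), tuple(float(f) for f in fractions), seed)


def export_class_folders(
    table: AnnotationTable,
    split: SplitAssignment,
    out_dir,
    feature: str | None = None,
    copy: bool = True,
) -> tuple[Path, list[str]]:
    """Materialize ``out/{train,val,test}/<class>/<image>`` from a split.

    Writes a ``manifest.csv`` (one row per record) beside the tree. Missing
    source images are collected in the returned error list (and
    ``errors.csv``), never fatal. With ``copy=False`` only the manifest is
    written — a link manifest for pipelines that stage files themselves.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lookup = split.as_dict()
    errors: list[str] = []
    manifest_rows = []
    for record in table.records:
        rid = record_id(record)
        part = lookup[rid]
        cls = _record_class(record, feature)
        src = Path(record.folder) / record.image
        dst = out_dir / part.value / cls / record.image
        manifest_rows.append([record.folder, record.image, rid[2], rid[3], cls, part.value, str(dst)])
        if copy:
            if not src.is_file():
                errors.append(f"missing image: {src}")
                continue
            dst.parent.mkdir(parents=True, exist_ok=True)
            shutil.copyfile(src, dst)
    with open(out_dir / "manifest.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Folder", "Image", "Slice", "Roi", "Class", "Split", "Destination"])
        writer.writerows(manifest_rows)
    if errors:
        with open(out_dir / "errors.csv", "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["Error"])
            writer.writerows([[e] for e in errors])
    return out_dir, errors


@dataclass(frozen=True)
class ConfusionMatrix:
    """Class-by-class tally of true vs predicted labels (rows = true)."""

    labels: tuple[str, ...]
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total) if self.total else 0.0

    def __getitem__(self, pair: tuple[str, str]) -> int:
        true, pred = pair
        return int(self.counts[self.labels.index(true), self.labels.index(pred)])


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str],
              labels: Sequence[str] | None = None) -> ConfusionMatrix:
    """Tally ``counts[i, j] = #(true == labels[i] and pred == labels[j])``.

    Without an explicit label order, classes appear in first-appearance
    order over the true then predicted sequences.
    """
    if len(true_labels) != len(predicted_labels):
        raise ValidationError(
            f"length mismatch: {len(true_labels)} true vs {len(predicted_labels)} predicted"
        )
    if labels is None:
        ordered: list[str] = []
        for label in list(true_labels) + list(predicted_labels):
            if label not in ordered:
                ordered.append(label)
        labels = ordered
    labels = tuple(labels)
    index = {label: i for i, label in enumerate(labels)}
    unknown = {l for l in list(true_labels) + list(predicted_labels)} - set(labels)
    if unknown:
        raise ValidationError(f"labels outside the class set: {sorted(unknown)}")
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(labels, counts)
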