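"""Annotation sessions, modalities, events and in-memory tables.

The model is a headless counterpart of button/checkbox/dropdown annotation
panels: a :class:`SessionConfig` fixes the modality and the ordered keyword
or feature vocabulary, a :class:`Session` accumulates
:class:`AnnotationRecord` rows in an :class:`AnnotationTable` (one row per
annotation event, one event row per referenced ROI) and registers newly
drawn ROIs in a ROI store.

Three modalities exist:

* ``SINGLE`` — exactly one category keyword per event (button panel);
  exported either as a single category column or one-hot, one binary
  column per keyword.
* ``MULTI``  — an independent boolean per keyword (checkbox panel).
* ``FEATURES`` — one choice per named feature, from per-feature choice
  lists (dropdown panel).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import roi_io
from .errors import (
    ConfigurationError,
    UnmappedSlotError,
    UnsupportedOperationError,
    ValidationError,
)
from .measurements import DEFAULT_MEASUREMENTS, Measurement, full_mask, measure, rasterize
from .roi_io import Roi, RoiStore


class Modality(Enum):
    SINGLE = "single"
    MULTI = "multi"
    FEATURES = "features"


class SingleEncoding(Enum):
    SINGLE_COLUMN = "single_column"
    ONE_HOT = "one_hot"


class BrowseMode(Enum):
    STACK = "stack"
    DIRECTORY = "directory"
    NONE = "none"


#: sentinel returned by :func:`advance` when the listing is exhausted
AT_END = object()

MAX_SHORTCUT_SLOTS = 12  # F1..F12


@dataclass(frozen=True)
class FeatureDef:
    """One dropdown feature: a column label plus its ordered choice list."""

    label: str
    choices: tuple[str, ...]

    def __post_init__(self) -> None:
        label = self.label.strip()
        if not label:
            raise ConfigurationError("feature label must be non-empty")
        object.__setattr__(self, "label", label)
        choices = tuple(c.strip() for c in self.choices)
        if not choices or any(not c for c in choices):
            raise ConfigurationError(f"feature {label!r} needs >= 1 non-empty choice")
        dup = _first_duplicate(choices)
        if dup is not None:
            raise ConfigurationError(f"duplicate choice {dup!r} in feature {label!r}")
        object.__setattr__(self, "choices", choices)


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return None


@dataclass(frozen=True)
class SessionConfig:
    """Everything that defines an annotation session.

    ``keywords`` drive SINGLE/MULTI sessions, ``features`` drive FEATURES
    sessions. ``single_encoding`` only matters for SINGLE.
    ``advance_dimension`` names the stack axis stepped by auto-advance in
    STACK browsing. When ``run_measure`` is on, each event also reports the
    measurements in ``measure_spec`` over the ROI pixels (whole image when
    no ROI is selected).
    """

    modality: Modality
    keywords: tuple[str, ...] = ()
    features: tuple[FeatureDef, ...] = ()
    single_encoding: SingleEncoding = SingleEncoding.SINGLE_COLUMN
    browse_mode: BrowseMode = BrowseMode.NONE
    advance_dimension: str = "t"
    run_measure: bool = False
    measure_spec: frozenset[Measurement] = DEFAULT_MEASUREMENTS

    def __post_init__(self) -> None:
        object.__setattr__(self, "keywords", tuple(k.strip() for k in self.keywords))
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "measure_spec", frozenset(self.measure_spec))
        if self.modality in (Modality.SINGLE, Modality.MULTI):
            if not self.keywords:
                raise ConfigurationError(f"{self.modality.value} session requires >= 1 keyword")
            if any(not k for k in self.keywords):
                raise ConfigurationError("keywords must be non-empty after trimming")
            dup = _first_duplicate(self.keywords)
            if dup is not None:
                raise ConfigurationError(f"duplicate keyword {dup!r}")
        else:
            if not self.features:
                raise ConfigurationError("features session requires >= 1 feature")
            dup = _first_duplicate(f.label for f in self.features)
            if dup is not None:
                raise ConfigurationError(f"duplicate feature label {dup!r}")

    @property
    def feature_labels(self) -> tuple[str, ...]:
        return tuple(f.label for f in self.features)

    def fingerprint(self) -> str:
        """Stable hash of the schema-determining parts of the config.

        Tables carry this fingerprint and refuse records produced under a
        different schema.
        """
        parts = {
            "modality": self.modality.value,
            "keywords": list(self.keywords),
            "features": [[f.label, list(f.choices)] for f in self.features],
            "encoding": self.single_encoding.value if self.modality is Modality.SINGLE else None,
        }
        digest = hashlib.sha256(json.dumps(parts, sort_keys=True).encode()).hexdigest()
        return digest[:16]


@dataclass(frozen=True)
class ImageLocator:
    """Where an annotation applies: directory, filename, optional slice position.

    ``slice_index`` maps stack axis names to 1-based indices, matching
    ImageJ's slice convention.
    """

    folder: str
    image: str
    slice_index: tuple[tuple[str, int], ...] = ()

    @staticmethod
    def of(folder: str, image: str, **axes: int) -> "ImageLocator":
        return ImageLocator(folder, image, tuple(axes.items()))

    def slices(self) -> dict[str, int]:
        return dict(self.slice_index)


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotation event row.

    Exactly one of ``category`` (SINGLE), ``flags`` (MULTI) or ``choices``
    (FEATURES) is set; ``measurements`` is empty unless the session has
    *run Measure* enabled.
    """

    folder: str
    image: str
    slice_index: tuple[tuple[str, int], ...] = ()
    roi_names: tuple[str, ...] = ()
    category: str | None = None
    flags: Mapping[str, bool] | None = None
    choices: Mapping[str, str] | None = None
    comment: str = ""
    measurements: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        set_values = [v is not None for v in (self.category, self.flags, self.choices)]
        if sum(set_values) != 1:
            raise ValidationError("record must carry exactly one of category/flags/choices")

    def slices(self) -> dict[str, int]:
        return dict(self.slice_index)


def validate_record(config: SessionConfig, record: AnnotationRecord) -> None:
    """Check a record against the session vocabulary; raise ValidationError if it fails."""
    if config.modality is Modality.SINGLE:
        if record.category is None:
            raise ValidationError("single-class record requires a category")
        if record.category not in config.keywords:
            raise ValidationError(f"unknown category {record.category!r}")
    elif config.modality is Modality.MULTI:
        if record.flags is None:
            raise ValidationError("multi-class record requires keyword flags")
        if set(record.flags) != set(config.keywords):
            missing = set(config.keywords) - set(record.flags)
            extra = set(record.flags) - set(config.keywords)
            raise ValidationError(f"flag keys mismatch (missing={sorted(missing)}, extra={sorted(extra)})")
    else:
        if record.choices is None:
            raise ValidationError("features record requires per-feature choices")
        if set(record.choices) != set(config.feature_labels):
            raise ValidationError("choice keys must equal the configured feature labels")
        for fdef in config.features:
            value = record.choices[fdef.label]
            if value not in fdef.choices:
                raise ValidationError(f"invalid choice {value!r} for feature {fdef.label!r}")


class AnnotationTable:
    """Insertion-ordered list of validated records sharing one schema."""

    def __init__(self, config: SessionConfig) -> None:
        self.config = config
        self.config_fingerprint = config.fingerprint()
        self._records: list[AnnotationRecord] = []

    @property
    def records(self) -> tuple[AnnotationRecord, ...]:
        return tuple(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __getitem__(self, index: int) -> AnnotationRecord:
        return self._records[index]

    def append(self, record: AnnotationRecord) -> None:
        validate_record(self.config, record)
        self._records.append(record)

    def extend(self, records: Iterable[AnnotationRecord]) -> None:
        for record in records:
            self.append(record)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return (
            self.config_fingerprint == other.config_fingerprint
            and self._records == other._records
        )


@dataclass
class Session:
    """A running annotation session: config + table + ROI store + browsing state.

    ``file_listing`` (DIRECTORY mode) is the sorted list of image filenames
    to step through; ``stack_sizes`` (STACK mode) maps axis names to their
    extents so auto-advance knows where the stack ends.
    """

    config: SessionConfig
    table: AnnotationTable
    rois: RoiStore
    file_listing: tuple[str, ...] = ()
    stack_sizes: dict[str, int] = field(default_factory=dict)


def create_session(
    config: SessionConfig,
    file_listing: Sequence[str] = (),
    stack_sizes: Mapping[str, int] | None = None,
) -> Session:
    """Start a session with an empty table; directory listings are sorted
    lexicographically (case-sensitive) for a stable browsing order."""
    return Session(
        config=config,
        table=AnnotationTable(config),
        rois=RoiStore(),
        file_listing=tuple(sorted(file_listing)),
        stack_sizes=dict(stack_sizes or {}),
    )


def add_category(session: Session, keyword: str) -> Session:
    """Append a keyword to a SINGLE/MULTI session, in place.

    Existing MULTI records gain ``flags[keyword] = False``; for one-hot
    output the new binary column reads 0 on prior rows because the encoding
    is derived from the stored category at write time.
    """
    keyword = keyword.strip()
    if session.config.modality is Modality.FEATURES:
        raise UnsupportedOperationError("add_category is undefined for dropdown sessions")
    if not keyword:
        raise ConfigurationError("keyword must be non-empty")
    if keyword in session.config.keywords:
        raise ConfigurationError(f"duplicate keyword {keyword!r}")
    new_config = replace(session.config, keywords=session.config.keywords + (keyword,))
    session.config = new_config
    old_records = session.table.records
    session.table = AnnotationTable(new_config)
    for record in old_records:
        if record.flags is not None:
            record = replace(record, flags={**dict(record.flags), keyword: False})
        session.table.append(record)
    return session


def _normalize_selection(config: SessionConfig, selection) -> dict[str, object]:
    """Turn a user selection into record value fields, validating as we go."""
    if config.modality is Modality.SINGLE:
        if not isinstance(selection, str):
            raise ValidationError("single-class selection must be a keyword string")
        return {"category": selection}
    if config.modality is Modality.MULTI:
        if isinstance(selection, str):
            selection = {selection: True}
        flags = {kw: bool(dict(selection).get(kw, False)) for kw in config.keywords}
        extra = set(selection) - set(config.keywords)
        if extra:
            raise ValidationError(f"unknown keywords {sorted(extra)}")
        return {"flags": flags}
    return {"choices": dict(selection)}


def record_event(
    session: Session,
    locator: ImageLocator,
    selection,
    comment: str = "",
    rois: Sequence[Roi] = (),
    pixels: np.ndarray | None = None,
) -> list[AnnotationRecord]:
    """Commit one annotation event.

    Appends one record per referenced ROI (one record with no ROI name when
    no ROI is given), registers new ROIs in the session store, copies the
    qualitative values into each ROI's property map, and — when the session
    has *run Measure* on — computes the configured measurements over each
    ROI (the whole image without a ROI). Returns the appended records.
    """
    config = session.config
    value = _normalize_selection(config, selection)
    if config.run_measure and pixels is None:
        raise ValidationError("run_measure is enabled but no pixel data was supplied")

    appended: list[AnnotationRecord] = []

    def build(roi_names: tuple[str, ...], mask) -> AnnotationRecord:
        meas: dict[str, float] = {}
        if config.run_measure:
            meas = measure(pixels, mask, config.measure_spec)
        return AnnotationRecord(
            folder=locator.folder,
            image=locator.image,
            slice_index=locator.slice_index,
            roi_names=roi_names,
            comment=comment,
            measurements=meas,
            **value,
        )

    if not rois:
        record = build((), None)
        session.table.append(record)
        return [record]

    for roi in rois:
        if not roi.name or roi.name not in session.rois:
            roi = session.rois.add(roi)
        record = build((roi.name,), rasterize(roi, pixels.shape) if config.run_measure else None)
        session.table.append(record)
        annotated = roi_io.attach_annotations(roi, record)
        session.rois.replace(annotated)
        appended.append(record)
    return appended


def delete_row(table: AnnotationTable, index: int) -> AnnotationTable:
    """Remove one record by 0-based index, preserving the order of the rest."""
    if not 0 <= index < len(table):
        raise IndexError(f"row {index} out of range for a {len(table)}-row table")
    table._records.pop(index)
    return table


def shortcut_to_keyword(config: SessionConfig, slot: int) -> str:
    """Map a function-key slot (1-based, F1..F12) to its category keyword.

    Slot *i* is the *i*-th button, so F1 is the leftmost category.
    """
    if config.modality is not Modality.SINGLE:
        raise UnsupportedOperationError("keyboard shortcuts map buttons of single-class sessions")
    if not 1 <= slot <= MAX_SHORTCUT_SLOTS:
        raise ValidationError(f"slot must be in 1..{MAX_SHORTCUT_SLOTS}, got {slot}")
    if slot > len(config.keywords):
        raise UnmappedSlotError(f"slot {slot} is unmapped ({len(config.keywords)} keywords)")
    return config.keywords[slot - 1]


def advance(session: Session, current: ImageLocator):
    """Step to the next slice (STACK) or next file (DIRECTORY).

    Returns the next :class:`ImageLocator`, or the :data:`AT_END` sentinel
    when the listing or stack axis is exhausted — never wraps around.
    """
    mode = session.config.browse_mode
    if mode is BrowseMode.NONE:
        raise UnsupportedOperationError("advance requires a stack or directory browse mode")
    if mode is BrowseMode.STACK:
        axis = session.config.advance_dimension
        slices = current.slices()
        if axis not in slices:
            raise ValidationError(f"locator has no slice index for axis {axis!r}")
        nxt = slices[axis] + 1
        size = session.stack_sizes.get(axis)
        if size is not None and nxt > size:
            return AT_END
        slices[axis] = nxt
        return ImageLocator(current.folder, current.image, tuple(slices.items()))
    # DIRECTORY
    try:
        pos = session.file_listing.index(current.image)
    except ValueError:
        raise ValidationError(f"{current.image!r} is not in the session file listing") from None
    if pos + 1 >= len(session.file_listing):
        return AT_END
    return ImageLocator(current.folder, session.file_listing[pos + 1], current.slice_index)
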