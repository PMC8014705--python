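"""CSV serialization of annotation tables and the dropdown-configuration CSV.

The table layout mirrors the result tables produced by annotation panels in
an image-analysis context: metadata columns (``Index,Folder,Image``,
optional slice axes, ``Comment,Roi``), then the qualitative columns (one
``Category`` column, one-hot keyword columns, one column per keyword, or
one column per feature), then the measurement columns. The header is a pure
function of the session configuration, so identical configs and records
give byte-identical files.

Files are UTF-8, comma-separated, RFC-4180 quoted; comments may contain
commas, quotes and newlines. Boolean cells are written as ``0/1`` by
default, with a ``True/False`` dialect offered; both dialects are read back
transparently. The row-index column is 1-based and regenerated on write.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd

from .annotation_model import (
    AnnotationRecord,
    AnnotationTable,
    BrowseMode,
    FeatureDef,
    Modality,
    SessionConfig,
    SingleEncoding,
)
from .errors import ConfigurationError, SchemaError, ValidationError
from .measurements import measurement_columns

CATEGORY_COLUMN = "Category"
ROI_SEPARATOR = ";"


class BooleanStyle(Enum):
    ZERO_ONE = ("0", "1")
    TRUE_FALSE = ("False", "True")

    def render(self, value: bool) -> str:
        return self.value[1] if value else self.value[0]


_TRUTHY = {"1", "true"}
_FALSY = {"0", "false"}


def _parse_bool(cell: str, row_number: int, column: str) -> bool:
    lowered = cell.strip().lower()
    if lowered in _TRUTHY:
        return True
    if lowered in _FALSY:
        return False
    raise ValidationError(f"row {row_number}: {column!r} cell {cell!r} is not a 0/1/True/False value")


@dataclass(frozen=True)
class TableSchema:
    """Ordered column layout derived deterministically from a SessionConfig."""

    metadata_columns: tuple[str, ...]
    slice_axes: tuple[str, ...]
    qualitative_columns: tuple[str, ...]
    measurement_cols: tuple[str, ...]

    @property
    def columns(self) -> tuple[str, ...]:
        return self.metadata_columns + self.qualitative_columns + self.measurement_cols


def build_schema(config: SessionConfig) -> TableSchema:
    """Derive the CSV schema for a session configuration."""
    slice_axes: tuple[str, ...] = ()
    if config.browse_mode is BrowseMode.STACK:
        slice_axes = (config.advance_dimension,)
    metadata = ("Index", "Folder", "Image") + slice_axes + ("Comment", "Roi")
    if config.modality is Modality.SINGLE:
        if config.single_encoding is SingleEncoding.ONE_HOT:
            qualitative = config.keywords
        else:
            qualitative = (CATEGORY_COLUMN,)
    elif config.modality is Modality.MULTI:
        qualitative = config.keywords
    else:
        qualitative = config.feature_labels
    meas = tuple(measurement_columns(config.measure_spec)) if config.run_measure else ()
    columns = metadata + qualitative + meas
    if len(set(columns)) != len(columns):
        raise ConfigurationError("keyword/feature names collide with reserved column names")
    return TableSchema(metadata, slice_axes, qualitative, meas)


def _record_cells(schema: TableSchema, config: SessionConfig, index: int,
                  record: AnnotationRecord, style: BooleanStyle) -> list[str]:
    slices = record.slices()
    cells = [str(index), record.folder, record.image]
    for axis in schema.slice_axes:
        cells.append(str(slices.get(axis, "")))
    cells.append(record.comment)
    cells.append(ROI_SEPARATOR.join(record.roi_names))
    if config.modality is Modality.SINGLE:
        if config.single_encoding is SingleEncoding.ONE_HOT:
            cells.extend(style.render(kw == record.category) for kw in config.keywords)
        else:
            cells.append(record.category or "")
    elif config.modality is Modality.MULTI:
        flags = dict(record.flags or {})
        cells.extend(style.render(bool(flags.get(kw, False))) for kw in config.keywords)
    else:
        choices = dict(record.choices or {})
        cells.extend(choices[label] for label in config.feature_labels)
    meas = dict(record.measurements)
    cells.extend(repr(float(meas[name])) if name in meas else "" for name in schema.measurement_cols)
    return cells


def write_csv(table: AnnotationTable, path, boolean_style: BooleanStyle = BooleanStyle.ZERO_ONE,
              schema: TableSchema | None = None) -> TableSchema:
    """Write an annotation table to CSV; returns the schema used."""
    schema = schema or build_schema(table.config)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\r\n")
        writer.writerow(schema.columns)
        for i, record in enumerate(table.records, start=1):
            writer.writerow(_record_cells(schema, table.config, i, record, boolean_style))
    return schema


def read_csv(path, config: SessionConfig) -> tuple[AnnotationTable, TableSchema]:
    """Read a CSV written by :func:`write_csv` (or edited externally) back
    into a validated table. Malformed rows are reported with their 1-based
    data-row number."""
    schema = build_schema(config)
    with open(path, "r", newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, no header") from None
        if tuple(header) != schema.columns:
            raise SchemaError(
                f"{path}: header {header} does not match the declared configuration "
                f"(expected {list(schema.columns)})"
            )
        table = AnnotationTable(config)
        for row_number, row in enumerate(reader, start=1):
            if len(row) != len(schema.columns):
                raise ValidationError(
                    f"row {row_number}: expected {len(schema.columns)} cells, got {len(row)}"
                )
            table.append(_parse_row(schema, config, row, row_number))
    return table, schema


def _parse_row(schema: TableSchema, config: SessionConfig, row: Sequence[str],
               row_number: int) -> AnnotationRecord:
    cells = dict(zip(schema.columns, row))
    slice_index = []
    for axis in schema.slice_axes:
        cell = cells[axis].strip()
        if cell:
            try:
                slice_index.append((axis, int(cell)))
            except ValueError:
                raise ValidationError(f"row {row_number}: slice index {cell!r} is not an integer") from None
    roi_cell = cells["Roi"]
    roi_names = tuple(roi_cell.split(ROI_SEPARATOR)) if roi_cell else ()

    value: dict[str, object] = {}
    if config.modality is Modality.SINGLE:
        if config.single_encoding is SingleEncoding.ONE_HOT:
            hot = [kw for kw in config.keywords if _parse_bool(cells[kw], row_number, kw)]
            if len(hot) != 1:
                raise ValidationError(
                    f"row {row_number}: one-hot cells must sum to 1, found {len(hot)} set"
                )
            value["category"] = hot[0]
        else:
            category = cells[CATEGORY_COLUMN]
            if category not in config.keywords:
                raise ValidationError(f"row {row_number}: unknown category {category!r}")
            value["category"] = category
    elif config.modality is Modality.MULTI:
        value["flags"] = {kw: _parse_bool(cells[kw], row_number, kw) for kw in config.keywords}
    else:
        choices = {}
        for fdef in config.features:
            cell = cells[fdef.label]
            if cell not in fdef.choices:
                raise ValidationError(
                    f"row {row_number}: invalid choice {cell!r} for feature {fdef.label!r}"
                )
            choices[fdef.label] = cell
        value["choices"] = choices

    measurements = {}
    for name in schema.measurement_cols:
        cell = cells[name].strip()
        if cell:
            try:
                measurements[name] = float(cell)
            except ValueError:
                raise ValidationError(f"row {row_number}: measurement {name!r}={cell!r} is not numeric") from None

    return AnnotationRecord(
        folder=cells["Folder"],
        image=cells["Image"],
        slice_index=tuple(slice_index),
        roi_names=roi_names,
        comment=cells["Comment"],
        measurements=measurements,
        **value,
    )


def to_dataframe(table: AnnotationTable, boolean_style: BooleanStyle = BooleanStyle.ZERO_ONE) -> pd.DataFrame:
    """Render a table to a pandas DataFrame with the CSV column layout.

    Boolean cells become ints (ZERO_ONE) or bools (TRUE_FALSE) rather than
    strings, so downstream tallies behave naturally.
    """
    schema = build_schema(table.config)
    rows = []
    for i, record in enumerate(table.records, start=1):
        cells = _record_cells(schema, table.config, i, record, boolean_style)
        rows.append(cells)
    df = pd.DataFrame(rows, columns=list(schema.columns))
    boolean_cols: tuple[str, ...] = ()
    if table.config.modality is Modality.MULTI or (
        table.config.modality is Modality.SINGLE
        and table.config.single_encoding is SingleEncoding.ONE_HOT
    ):
        boolean_cols = table.config.keywords
    for col in boolean_cols:
        if boolean_style is BooleanStyle.ZERO_ONE:
            df[col] = df[col].astype(int)
        else:
            df[col] = df[col] == "True"
    for col in schema.measurement_cols:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


# -- dropdown configuration CSV ----------------------------------------


@dataclass(frozen=True)
class DropdownConfig:
    """Parsed dropdown-menu configuration: ordered feature definitions."""

    features: tuple[FeatureDef, ...]


def parse_dropdown_config(path) -> DropdownConfig:
    """Parse the user-written dropdown CSV.

    Layout: one feature per column; the header cell is the feature label
    and the cells below are its choices. Blank cells (ragged column ends)
    are ignored.
    """
    with open(path, "r", newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh)]
    rows = [row for row in rows if any(cell.strip() for cell in row)]
    if not rows:
        raise ConfigurationError(f"{path}: empty dropdown configuration")
    header = [cell.strip() for cell in rows[0]]
    labels = [label for label in header if label]
    dup = next((l for l in labels if labels.count(l) > 1), None)
    if dup is not None:
        raise ConfigurationError(f"duplicate feature label {dup!r}")
    features = []
    for col, label in enumerate(header):
        if not label:
            continue
        choices = []
        for row in rows[1:]:
            cell = row[col].strip() if col < len(row) else ""
            if cell:
                choices.append(cell)
        if not choices:
            raise ConfigurationError(f"feature {label!r} has no choices")
        features.append(FeatureDef(label, tuple(choices)))
    return DropdownConfig(tuple(features))
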