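"""ImageJ ROI interchange: binary ``.roi`` codec, ``RoiSet.zip`` archives,
and attachment of qualitative annotations as ROI string properties.

The binary layout follows the public ImageJ ROI file format: a 64-byte
big-endian header starting with the magic ``Iout``, an optional block of
vertex coordinates stored as 16-bit offsets from the bounding box, and a
64-byte "header 2" block holding offsets to the UTF-16BE encoded name and
properties strings. Annotation keywords are written into the properties
block as newline-separated ``key=value`` pairs, namespaced ``qa.`` so they
never collide with properties set by other tools.

Interoperability with live ImageJ is best-effort: the codec is exercised by
encode/decode round-trips and one frozen byte fixture, not by running Fiji.
"""

from __future__ import annotations

import struct
import zipfile
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator

from .errors import RoiFormatError, UnsupportedRoiTypeError, ValidationError

HEADER_SIZE = 64
HEADER2_SIZE = 64
MAGIC = b"Iout"
VERSION = 228

#: namespace prefix for annotation-derived ROI properties
PROPERTY_PREFIX = "qa."


class RoiKind(Enum):
    """Supported geometric ROI kinds with their ImageJ type codes."""

    POLYGON = 0
    RECTANGLE = 1
    OVAL = 2
    LINE = 3
    FREEHAND = 7
    POINT = 10


_KIND_BY_CODE = {k.value: k for k in RoiKind}


@dataclass(frozen=True)
class Roi:
    """A named region of interest in 0-based pixel coordinates.

    ``bounds`` is ``(left, top, width, height)`` with origin at the image
    top-left, x rightward, y downward. Vertex-based kinds (polygon,
    freehand, point, line) carry absolute integer vertices; the bounds are
    the tight bounding box of the vertices.
    """

    kind: RoiKind
    bounds: tuple[int, int, int, int]
    vertices: tuple[tuple[int, int], ...] = ()
    name: str = ""
    properties: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        left, top, width, height = self.bounds
        if width < 0 or height < 0:
            raise ValidationError(f"negative ROI extent: {self.bounds}")
        if self.kind is RoiKind.POLYGON and len(self.vertices) < 3:
            raise ValidationError("polygon ROI requires >= 3 vertices")
        if self.kind is RoiKind.FREEHAND and len(self.vertices) < 3:
            raise ValidationError("freehand ROI requires >= 3 vertices")
        if self.kind is RoiKind.LINE and len(self.vertices) != 2:
            raise ValidationError("line ROI requires exactly 2 vertices")
        if self.kind is RoiKind.POINT and len(self.vertices) < 1:
            raise ValidationError("point ROI requires >= 1 vertex")
        if self.vertices:
            xs = [x for x, _ in self.vertices]
            ys = [y for _, y in self.vertices]
            tight = (min(xs), min(ys), max(xs) - min(xs), max(ys) - min(ys))
            if tight != self.bounds:
                raise ValidationError(
                    f"bounds {self.bounds} do not match vertex bounding box {tight}"
                )

    # -- constructors -------------------------------------------------

    @staticmethod
    def rectangle(left: int, top: int, width: int, height: int, name: str = "") -> "Roi":
        return Roi(RoiKind.RECTANGLE, (left, top, width, height), name=name)

    @staticmethod
    def oval(left: int, top: int, width: int, height: int, name: str = "") -> "Roi":
        return Roi(RoiKind.OVAL, (left, top, width, height), name=name)

    @staticmethod
    def _from_vertices(kind: RoiKind, points: Iterable[tuple[int, int]], name: str) -> "Roi":
        pts = tuple((int(x), int(y)) for x, y in points)
        if not pts:
            raise ValidationError("vertex-based ROI requires at least one vertex")
        xs = [x for x, _ in pts]
        ys = [y for _, y in pts]
        bounds = (min(xs), min(ys), max(xs) - min(xs), max(ys) - min(ys))
        return Roi(kind, bounds, vertices=pts, name=name)

    @staticmethod
    def polygon(points: Iterable[tuple[int, int]], name: str = "") -> "Roi":
        return Roi._from_vertices(RoiKind.POLYGON, points, name)

    @staticmethod
    def freehand(points: Iterable[tuple[int, int]], name: str = "") -> "Roi":
        return Roi._from_vertices(RoiKind.FREEHAND, points, name)

    @staticmethod
    def point(points: Iterable[tuple[int, int]], name: str = "") -> "Roi":
        return Roi._from_vertices(RoiKind.POINT, points, name)

    @staticmethod
    def line(p1: tuple[int, int], p2: tuple[int, int], name: str = "") -> "Roi":
        return Roi._from_vertices(RoiKind.LINE, [p1, p2], name)

    # -- convenience --------------------------------------------------

    def properties_dict(self) -> dict[str, str]:
        return dict(self.properties)

    def with_name(self, name: str) -> "Roi":
        return replace(self, name=name)

    def with_properties(self, props: dict[str, str]) -> "Roi":
        return replace(self, properties=tuple(props.items()))


class RoiStore:
    """Ordered, name-unique collection of ROIs (the ROI-Manager equivalent)."""

    def __init__(self, rois: Iterable[Roi] = ()) -> None:
        self._rois: dict[str, Roi] = {}
        for roi in rois:
            self.add(roi)

    def add(self, roi: Roi) -> Roi:
        """Add a ROI, assigning a zero-padded sequential name if unnamed."""
        if not roi.name:
            roi = roi.with_name(f"{len(self._rois) + 1:04d}")
        if roi.name in self._rois:
            raise ValidationError(f"duplicate ROI name: {roi.name!r}")
        self._rois[roi.name] = roi
        return roi

    def replace(self, roi: Roi) -> None:
        """Replace an existing ROI in place, preserving its position."""
        if roi.name not in self._rois:
            raise KeyError(roi.name)
        self._rois[roi.name] = roi

    def __getitem__(self, name: str) -> Roi:
        return self._rois[name]

    def __contains__(self, name: str) -> bool:
        return name in self._rois

    def __len__(self) -> int:
        return len(self._rois)

    def __iter__(self) -> Iterator[Roi]:
        return iter(self._rois.values())

    def names(self) -> list[str]:
        return list(self._rois)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RoiStore):
            return NotImplemented
        return list(self) == list(other)


# -- binary codec ------------------------------------------------------

# header-2 field offsets, relative to the header-2 block start
_H2_NAME_OFFSET = 16
_H2_NAME_LENGTH = 20
_H2_PROPS_OFFSET = 40
_H2_PROPS_LENGTH = 44


def _encode_properties(props: tuple[tuple[str, str], ...]) -> str:
    return "\n".join(f"{k}={v}" for k, v in props)


def _decode_properties(text: str) -> tuple[tuple[str, str], ...]:
    pairs = []
    for line in text.split("\n"):
        if not line:
            continue
        key, sep, value = line.partition("=")
        if not sep:
            raise RoiFormatError(f"malformed property line: {line!r}")
        pairs.append((key, value))
    return tuple(pairs)


def encode_roi(roi: Roi) -> bytes:
    """Serialize a :class:`Roi` to ImageJ ``.roi`` bytes (big-endian)."""
    left, top, width, height = roi.bounds
    bottom, right = top + height, left + width
    has_coords = roi.kind in (RoiKind.POLYGON, RoiKind.FREEHAND, RoiKind.POINT)
    n = len(roi.vertices) if has_coords else 0

    header = bytearray(HEADER_SIZE)
    header[0:4] = MAGIC
    struct.pack_into(">h", header, 4, VERSION)
    header[6] = roi.kind.value
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    if roi.kind is RoiKind.LINE:
        (x1, y1), (x2, y2) = roi.vertices
        struct.pack_into(">4f", header, 18, float(x1), float(y1), float(x2), float(y2))

    coords = bytearray()
    if n:
        for x, _ in roi.vertices:
            coords += struct.pack(">h", x - left)
        for _, y in roi.vertices:
            coords += struct.pack(">h", y - top)

    hdr2_offset = HEADER_SIZE + len(coords)
    struct.pack_into(">i", header, 60, hdr2_offset)

    name_bytes = roi.name.encode("utf-16-be")
    props_text = _encode_properties(roi.properties)
    props_bytes = props_text.encode("utf-16-be")

    header2 = bytearray(HEADER2_SIZE)
    name_offset = hdr2_offset + HEADER2_SIZE if roi.name else 0
    props_offset = hdr2_offset + HEADER2_SIZE + len(name_bytes) if props_text else 0
    struct.pack_into(">i", header2, _H2_NAME_OFFSET, name_offset)
    struct.pack_into(">i", header2, _H2_NAME_LENGTH, len(roi.name))
    struct.pack_into(">i", header2, _H2_PROPS_OFFSET, props_offset)
    struct.pack_into(">i", header2, _H2_PROPS_LENGTH, len(props_text))

    return bytes(header) + bytes(coords) + bytes(header2) + name_bytes + props_bytes


def decode_roi(data: bytes) -> Roi:
    """Parse ImageJ ``.roi`` bytes back into a :class:`Roi`.

    Raises :class:`RoiFormatError` on bad magic or truncation, and
    :class:`UnsupportedRoiTypeError` on type codes outside the supported
    subset (never skipped silently).
    """
    if len(data) < HEADER_SIZE:
        raise RoiFormatError(f"ROI stream too short ({len(data)} bytes)")
    if data[0:4] != MAGIC:
        raise RoiFormatError(f"bad magic {data[0:4]!r}, expected {MAGIC!r}")
    type_code = data[6]
    kind = _KIND_BY_CODE.get(type_code)
    if kind is None:
        raise UnsupportedRoiTypeError(f"unsupported ImageJ ROI type code {type_code}")
    top, left, bottom, right = struct.unpack_from(">4h", data, 8)
    (n,) = struct.unpack_from(">h", data, 16)
    bounds = (left, top, right - left, bottom - top)

    vertices: tuple[tuple[int, int], ...] = ()
    if kind is RoiKind.LINE:
        x1, y1, x2, y2 = struct.unpack_from(">4f", data, 18)
        vertices = ((int(round(x1)), int(round(y1))), (int(round(x2)), int(round(y2))))
    elif n:
        end = HEADER_SIZE + 4 * n
        if len(data) < end:
            raise RoiFormatError("coordinate block truncated")
        xs = struct.unpack_from(f">{n}h", data, HEADER_SIZE)
        ys = struct.unpack_from(f">{n}h", data, HEADER_SIZE + 2 * n)
        vertices = tuple((left + x, top + y) for x, y in zip(xs, ys))

    name = ""
    properties: tuple[tuple[str, str], ...] = ()
    (hdr2_offset,) = struct.unpack_from(">i", data, 60)
    if hdr2_offset > 0:
        if len(data) < hdr2_offset + HEADER2_SIZE:
            raise RoiFormatError("header-2 block truncated")
        (name_offset,) = struct.unpack_from(">i", data, hdr2_offset + _H2_NAME_OFFSET)
        (name_length,) = struct.unpack_from(">i", data, hdr2_offset + _H2_NAME_LENGTH)
        (props_offset,) = struct.unpack_from(">i", data, hdr2_offset + _H2_PROPS_OFFSET)
        (props_length,) = struct.unpack_from(">i", data, hdr2_offset + _H2_PROPS_LENGTH)
        if name_offset > 0 and name_length > 0:
            raw = data[name_offset : name_offset + 2 * name_length]
            if len(raw) < 2 * name_length:
                raise RoiFormatError("name block truncated")
            name = raw.decode("utf-16-be")
        if props_offset > 0 and props_length > 0:
            raw = data[props_offset : props_offset + 2 * props_length]
            if len(raw) < 2 * props_length:
                raise RoiFormatError("properties block truncated")
            properties = _decode_properties(raw.decode("utf-16-be"))

    return Roi(kind, bounds, vertices=vertices, name=name, properties=properties)


def write_roi(roi: Roi, path) -> None:
    with open(path, "wb") as fh:
        fh.write(encode_roi(roi))


def read_roi(path) -> Roi:
    with open(path, "rb") as fh:
        return decode_roi(fh.read())


def write_roiset(store: RoiStore, path) -> None:
    """Write a ROI-Manager-style ``RoiSet.zip``: one ``<name>.roi`` entry per ROI."""
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for roi in store:
            zf.writestr(f"{roi.name}.roi", encode_roi(roi))


def read_roiset(path) -> RoiStore:
    """Read a ``RoiSet.zip`` preserving entry order; non-``.roi`` entries are rejected."""
    store = RoiStore()
    with zipfile.ZipFile(path) as zf:
        for info in zf.infolist():
            if not info.filename.endswith(".roi"):
                raise RoiFormatError(f"unexpected archive entry {info.filename!r}")
            roi = decode_roi(zf.read(info))
            if not roi.name:
                roi = roi.with_name(info.filename[: -len(".roi")])
            store.add(roi)
    return store


def attach_annotations(roi: Roi, record) -> Roi:
    """Copy a record's qualitative values into the ROI property map.

    Single-class records set ``qa.category``; multi-class records set one
    ``qa.<keyword>=true`` per asserted keyword; feature records set
    ``qa.<label>=<choice>``. Pre-existing ``qa.*`` keys are replaced as a
    group; unrelated properties are preserved. Idempotent for a given
    record.
    """
    kept = [(k, v) for k, v in roi.properties if not k.startswith(PROPERTY_PREFIX)]
    new: list[tuple[str, str]] = []
    if record.category is not None:
        new.append((PROPERTY_PREFIX + "category", record.category))
    elif record.flags is not None:
        new.extend((PROPERTY_PREFIX + kw, "true") for kw, on in record.flags.items() if on)
    elif record.choices is not None:
        new.extend((PROPERTY_PREFIX + label, choice) for label, choice in record.choices.items())
    return replace(roi, properties=tuple(kept + new))
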