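"""Synthetic images, ROIs and ground-truth tables for the three annotation
use cases: per-slice mitotic stages in a time-lapse stack, per-well
phenotype checkboxes over a directory of images, and per-embryo feature
triplets on a multi-object image.

Every generator is deterministic under a fixed seed (bit-identical
output). The numeric choices — intensities, noise levels, axis ratios —
are the package's own; they are set so that the generated classes are
cleanly separable by the measurements module (dark vs clear mean
intensities differ by at least three pooled standard deviations, and an
axis-ratio threshold of 1.3 separates circles from ellipses exactly),
which makes the fixtures usable as an end-to-end classification sanity
benchmark with a known answer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .annotation_model import (
    AnnotationRecord,
    AnnotationTable,
    BrowseMode,
    FeatureDef,
    Modality,
    SessionConfig,
)
from .errors import ConfigurationError
from .roi_io import Roi, RoiStore

# -- embryo fixture parameters ----------------------------------------

BACKGROUND_MEAN = 20.0
BACKGROUND_NOISE = 2.0
DARK_MEAN = 60.0          # "dark" pigmentation mean intensity
CLEAR_MEAN = 180.0        # "clear" pigmentation mean intensity
SMOOTH_NOISE = 2.0        # additive sigma inside smooth-textured objects
GRANULAR_CV = 0.12        # multiplicative coefficient of variation, granular
ELLIPSE_AXIS_RATIO = 1.8  # circles are exactly 1.0; threshold below separates them
AXIS_RATIO_THRESHOLD = 1.3

TEXTURES = ("granular", "smooth")
SHAPES = ("circle", "ellipse")
PIGMENTATIONS = ("dark", "clear")

MITOTIC_STAGES = ("interphase", "prophase", "metaphase", "anaphase")
WELL_KEYWORDS = ("normal", "cystic", "out_of_focus", "empty")


def embryo_session_config(run_measure: bool = False) -> SessionConfig:
    """Dropdown config with the texture/shape/pigmentation feature triplet."""
    return SessionConfig(
        modality=Modality.FEATURES,
        features=(
            FeatureDef("texture", TEXTURES),
            FeatureDef("shape", SHAPES),
            FeatureDef("pigmentation", PIGMENTATIONS),
        ),
        run_measure=run_measure,
    )


@dataclass(frozen=True)
class PhenotypeSpec:
    """One synthetic embryo: its phenotype triplet plus placement."""

    texture: str
    pigmentation: str
    shape: str
    position: tuple[float, float]
    size: float = 18.0

    def __post_init__(self) -> None:
        if self.texture not in TEXTURES:
            raise ConfigurationError(f"texture must be one of {TEXTURES}")
        if self.pigmentation not in PIGMENTATIONS:
            raise ConfigurationError(f"pigmentation must be one of {PIGMENTATIONS}")
        if self.shape not in SHAPES:
            raise ConfigurationError(f"shape must be one of {SHAPES}")

    @property
    def semi_axes(self) -> tuple[float, float]:
        ratio = ELLIPSE_AXIS_RATIO if self.shape == "ellipse" else 1.0
        return self.size, self.size / ratio


def worked_example_specs() -> list[PhenotypeSpec]:
    """Three embryos with the classic worked-example phenotype triplets:
    smooth/clear/circle, granular/clear/ellipse, smooth/dark/circle."""
    return [
        PhenotypeSpec("smooth", "clear", "circle", (50.0, 60.0)),
        PhenotypeSpec("granular", "clear", "ellipse", (128.0, 60.0)),
        PhenotypeSpec("smooth", "dark", "circle", (200.0, 60.0)),
    ]


def random_specs(n: int, shape: tuple[int, int] = (256, 256), seed: int = 0) -> list[PhenotypeSpec]:
    """n embryos on a jittered grid with uniformly drawn phenotypes."""
    rng = np.random.default_rng(seed)
    h, w = shape
    cols = int(math.ceil(math.sqrt(n)))
    rows = int(math.ceil(n / cols))
    size = max(8.0, min(w / cols, h / rows) / 2.8)
    specs = []
    for i in range(n):
        r, c = divmod(i, cols)
        cx = (c + 0.5) * w / cols + rng.uniform(-2, 2)
        cy = (r + 0.5) * h / rows + rng.uniform(-2, 2)
        specs.append(
            PhenotypeSpec(
                texture=TEXTURES[rng.integers(2)],
                pigmentation=PIGMENTATIONS[rng.integers(2)],
                shape=SHAPES[rng.integers(2)],
                position=(float(cx), float(cy)),
                size=size,
            )
        )
    return specs


def _ellipse_polygon(spec: PhenotypeSpec, n_vertices: int = 32) -> Roi:
    cx, cy = spec.position
    a, b = spec.semi_axes
    pts = []
    for k in range(n_vertices):
        theta = 2 * math.pi * k / n_vertices
        pts.append((int(round(cx + a * math.cos(theta))), int(round(cy + b * math.sin(theta)))))
    # drop consecutive duplicates from rounding
    dedup = [p for i, p in enumerate(pts) if i == 0 or p != pts[i - 1]]
    if dedup[-1] == dedup[0]:
        dedup.pop()
    return Roi.polygon(dedup)


def make_embryo_image(
    specs: list[PhenotypeSpec],
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> tuple[np.ndarray, RoiStore, AnnotationTable]:
    """Render embryos into a 32-bit image; return image, polygon ROIs and
    the matching dropdown ground-truth table.

    Granular texture is high-frequency multiplicative noise; smooth is a
    low additive noise floor. Dark and clear pigmentations are separated by
    more than three pooled standard deviations so a mean-intensity
    threshold classifies them without error. Overlapping embryos trigger a
    warning, never a failure.
    """
    h, w = shape
    for spec in specs:
        cx, cy = spec.position
        a, b = spec.semi_axes
        if cx - a < 0 or cx + a > w or cy - b < 0 or cy + b > h:
            raise ConfigurationError(f"embryo at {spec.position} does not fit a {shape} image")
    for i, s1 in enumerate(specs):
        for s2 in specs[i + 1 :]:
            d = math.dist(s1.position, s2.position)
            if d < 0.8 * (max(s1.semi_axes) + max(s2.semi_axes)):
                warnings.warn(f"embryos at {s1.position} and {s2.position} overlap", stacklevel=2)

    rng = np.random.default_rng(seed)
    image = BACKGROUND_MEAN + rng.normal(0.0, BACKGROUND_NOISE, size=shape)
    yy, xx = np.mgrid[0:h, 0:w]
    for spec in specs:
        cx, cy = spec.position
        a, b = spec.semi_axes
        inside = ((xx + 0.5 - cx) / a) ** 2 + ((yy + 0.5 - cy) / b) ** 2 < 1.0
        mean = DARK_MEAN if spec.pigmentation == "dark" else CLEAR_MEAN
        n_in = int(inside.sum())
        if spec.texture == "granular":
            values = mean * (1.0 + rng.normal(0.0, GRANULAR_CV, size=n_in))
        else:
            values = mean + rng.normal(0.0, SMOOTH_NOISE, size=n_in)
        image[inside] = np.clip(values, 0.0, None)

    config = embryo_session_config()
    table = AnnotationTable(config)
    store = RoiStore()
    for i, spec in enumerate(specs, start=1):
        roi = store.add(_ellipse_polygon(spec).with_name(f"embryo-{i:03d}"))
        table.append(
            AnnotationRecord(
                folder=".",
                image="embryos.tif",
                roi_names=(roi.name,),
                choices={
                    "texture": spec.texture,
                    "shape": spec.shape,
                    "pigmentation": spec.pigmentation,
                },
            )
        )
    return image.astype(np.float32), store, table


# -- mitosis stack ------------------------------------------------------


def mitosis_session_config() -> SessionConfig:
    return SessionConfig(
        modality=Modality.SINGLE,
        keywords=MITOTIC_STAGES,
        browse_mode=BrowseMode.STACK,
        advance_dimension="t",
    )


def _render_stage(frame: np.ndarray, stage: str, rng: np.random.Generator) -> None:
    h, w = frame.shape
    cy, cx = h / 2, w / 2
    yy, xx = np.mgrid[0:h, 0:w]

    def blob(x0: float, y0: float, a: float, b: float, amp: float) -> None:
        frame[:] += amp * np.exp(-(((xx - x0) / a) ** 2 + ((yy - y0) / b) ** 2))

    if stage == "interphase":
        blob(cx, cy, 9.0, 9.0, 120.0)
    elif stage == "prophase":
        blob(cx, cy, 7.0, 7.0, 150.0)
        for _ in range(12):  # condensing-chromatin speckles
            blob(cx + rng.uniform(-5, 5), cy + rng.uniform(-5, 5), 1.2, 1.2, 60.0)
    elif stage == "metaphase":
        blob(cx, cy, 3.5, 11.0, 170.0)  # aligned plate: strongly elongated
    elif stage == "anaphase":
        blob(cx - 9, cy, 4.5, 6.0, 140.0)
        blob(cx + 9, cy, 4.5, 6.0, 140.0)
    else:
        raise ConfigurationError(f"unknown stage {stage!r}; stages are {MITOTIC_STAGES}")


def make_mitosis_stack(
    n_slices: int = 4,
    stage_sequence: tuple[str, ...] | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
) -> tuple[np.ndarray, AnnotationTable]:
    """A (t, y, x) stack with one nucleus per frame whose elongation and
    splitting encode the mitotic stage, plus the single-class truth table
    (one row per slice, 1-based t index)."""
    if stage_sequence is None:
        stage_sequence = tuple(MITOTIC_STAGES[i % len(MITOTIC_STAGES)] for i in range(n_slices))
    if len(stage_sequence) != n_slices:
        raise ConfigurationError(
            f"stage_sequence length {len(stage_sequence)} != n_slices {n_slices}"
        )
    rng = np.random.default_rng(seed)
    stack = rng.normal(12.0, 2.0, size=(n_slices,) + shape)
    config = mitosis_session_config()
    table = AnnotationTable(config)
    for t, stage in enumerate(stage_sequence, start=1):
        _render_stage(stack[t - 1], stage, rng)
        table.append(
            AnnotationRecord(
                folder=".",
                image="mitosis.tif",
                slice_index=(("t", t),),
                category=stage,
            )
        )
    return stack.astype(np.float32), table


# -- well-plate directory -----------------------------------------------


def well_session_config() -> SessionConfig:
    return SessionConfig(
        modality=Modality.MULTI,
        keywords=WELL_KEYWORDS,
        browse_mode=BrowseMode.DIRECTORY,
    )


def make_well_directory(
    n_images: int,
    out_dir,
    cystic_prob: float = 0.4,
    error_probs: dict[str, float] | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (96, 96),
) -> tuple[list[Path], AnnotationTable]:
    """Write n well images as TIFFs and return paths plus the checkbox
    ground-truth table (normal / cystic / out_of_focus / empty flags).

    Filenames are zero-padded so the lexicographic directory listing
    matches the table row order. ``error_probs`` holds the per-image
    probabilities of the two acquisition-error flags (both default 0).
    """
    error_probs = {"out_of_focus": 0.0, "empty": 0.0, **(error_probs or {})}
    unknown = set(error_probs) - {"out_of_focus", "empty"}
    if unknown:
        raise ConfigurationError(f"unknown error flags {sorted(unknown)}")
    if not 0.0 <= cystic_prob <= 1.0 or any(not 0.0 <= p <= 1.0 for p in error_probs.values()):
        raise ConfigurationError("probabilities must lie in [0, 1]")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    config = well_session_config()
    table = AnnotationTable(config)
    paths: list[Path] = []

    for i in range(n_images):
        empty = bool(rng.random() < error_probs["empty"])
        out_of_focus = bool(rng.random() < error_probs["out_of_focus"])
        cystic = bool(rng.random() < cystic_prob) and not empty
        image = rng.normal(15.0, 2.0, size=shape)
        if not empty:
            cy, cx = h / 2 + rng.uniform(-4, 4), w / 2 + rng.uniform(-4, 4)
            r2 = (xx - cx) ** 2 + (yy - cy) ** 2
            image += 150.0 * np.exp(-r2 / (2 * (h / 5.0) ** 2))
            if cystic:  # dark fluid-filled holes inside the organ
                for _ in range(3):
                    hx = cx + rng.uniform(-h / 6, h / 6)
                    hy = cy + rng.uniform(-h / 6, h / 6)
                    hole = (xx - hx) ** 2 + (yy - hy) ** 2 < (h / 14.0) ** 2
                    image[hole] = rng.normal(10.0, 1.0, size=int(hole.sum()))
        if out_of_focus:
            from scipy.ndimage import gaussian_filter

            image = gaussian_filter(image, sigma=3.0)
        path = out_dir / f"well_{i:03d}.tif"
        tifffile.imwrite(path, image.astype(np.float32))
        paths.append(path)
        table.append(
            AnnotationRecord(
                folder=str(out_dir),
                image=path.name,
                flags={
                    "normal": not cystic and not empty,
                    "cystic": cystic,
                    "out_of_focus": out_of_focus,
                    "empty": empty,
                },
            )
        )
    return paths, table
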