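"""Radiograph loading, ROI manifest parsing, and graded ROI extraction.

Coordinate convention (used everywhere in this package): 0-based, half-open
rectangles ``[x0, x1) x [y0, y1)`` with ``x`` indexing columns and ``y``
indexing rows, so a rectangle's pixel matrix has shape ``(y1 - y0, x1 - x0)``.

Intensities are kept on their native integer scale at load time; any
normalization is the responsibility of the downstream filter / texture stages.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .exceptions import BoundsError, SchemaError, ValidationError

#: ITU-R BT.601 luminance weights used to collapse RGB inputs to grayscale.
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)

VALID_TEETH = (101, 201)
VALID_GRADES = (0, 1, 2, 3)

MANIFEST_COLUMNS = ("horse_id", "tooth", "grade", "image", "x0", "y0", "x1", "y1")


@dataclass(frozen=True)
class Radiograph:
    """A single-channel radiograph with its native bit depth."""

    pixels: np.ndarray  # (rows, cols), float64, non-negative
    bit_depth: int  # 8 or 16
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("radiograph must be a non-empty 2-D matrix")
        if self.bit_depth not in (8, 16):
            raise ValidationError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0 or hi > 2**self.bit_depth - 1:
            raise ValidationError(
                f"intensities [{lo}, {hi}] outside [0, {2**self.bit_depth - 1}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ROIRect:
    """Rectangular ROI, 0-based half-open: ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValidationError(
                f"degenerate rectangle ({self.x0},{self.y0},{self.x1},{self.y1}): "
                "require x1 > x0 and y1 > y0"
            )
        if self.x0 < 0 or self.y0 < 0:
            raise ValidationError("rectangle coordinates must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the extracted matrix."""
        return (self.y1 - self.y0, self.x1 - self.x0)


@dataclass
class GradedROI:
    """A tooth ROI pixel matrix tagged with horse, Triadan tooth number, and
    EOTRH grade (0 normal ... 3 severe)."""

    horse_id: str
    tooth: int
    grade: int
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.tooth not in VALID_TEETH:
            raise ValidationError(f"tooth must be one of {VALID_TEETH}, got {self.tooth}")
        if self.grade not in VALID_GRADES:
            raise ValidationError(f"grade must be in {VALID_GRADES}, got {self.grade}")
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("ROI pixels must form a non-empty 2-D matrix")


@dataclass(frozen=True)
class ManifestRecord:
    """One row of the ROI manifest."""

    horse_id: str
    tooth: int
    grade: int
    image_path: str
    rect: ROIRect


def load_radiograph(path: str | Path) -> Radiograph:
    """Load a PNG/JPEG radiograph as a single-channel matrix.

    RGB inputs are collapsed with fixed BT.601 luminance weights; 8- and
    16-bit grayscale are passed through without rescaling.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode in ("RGB", "RGBA", "P"):
                arr = np.asarray(im.convert("RGB"), dtype=np.float64)
                w = np.asarray(LUMINANCE_WEIGHTS)
                pixels = arr @ w
                bit_depth = 8
            elif mode in ("I;16", "I;16B", "I;16L", "I"):
                pixels = np.asarray(im, dtype=np.float64)
                bit_depth = 16
            elif mode == "L":
                pixels = np.asarray(im, dtype=np.float64)
                bit_depth = 8
            else:
                raise ValidationError(f"unsupported image mode {mode!r} in {path}")
    except (OSError, UnidentifiedImageError) as exc:
        raise IOError(f"cannot read radiograph {path}: {exc}") from exc
    if pixels.size == 0:
        raise ValidationError(f"zero-size image: {path}")
    return Radiograph(pixels=pixels, bit_depth=bit_depth, source_path=str(path))


def read_manifest(path: str | Path) -> list[ManifestRecord]:
    """Parse a ROI manifest CSV into validated records.

    The CSV must carry a header with columns
    ``horse_id, tooth, grade, image, x0, y0, x1, y1``. A row violating the
    grade, tooth or rectangle invariants raises :class:`ValidationError`
    citing the 1-based data row number.
    """
    path = Path(path)
    records: list[ManifestRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in MANIFEST_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"manifest {path} missing columns: {missing}")
        for i, row in enumerate(reader, start=1):
            try:
                tooth = int(row["tooth"])
                grade = int(row["grade"])
                coords = {k: int(row[k]) for k in ("x0", "y0", "x1", "y1")}
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"manifest row {i}: non-integer field ({exc})") from exc
            if grade not in VALID_GRADES:
                raise ValidationError(f"manifest row {i}: grade {grade} outside 0-3")
            if tooth not in VALID_TEETH:
                raise ValidationError(f"manifest row {i}: tooth {tooth} not in {VALID_TEETH}")
            try:
                rect = ROIRect(**coords)
            except ValidationError as exc:
                raise ValidationError(f"manifest row {i}: {exc}") from exc
            records.append(
                ManifestRecord(
                    horse_id=row["horse_id"],
                    tooth=tooth,
                    grade=grade,
                    image_path=row["image"],
                    rect=rect,
                )
            )
    return records


def write_manifest(records: list[ManifestRecord], path: str | Path) -> None:
    """Write records to CSV in the exact schema ``read_manifest`` consumes."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        for rec in records:
            r = rec.rect
            writer.writerow(
                [rec.horse_id, rec.tooth, rec.grade, rec.image_path, r.x0, r.y0, r.x1, r.y1]
            )


def extract_roi(img: Radiograph | np.ndarray, rect: ROIRect) -> np.ndarray:
    """Cut the rectangle out of the image; returns an owned copy of shape
    ``(y1 - y0, x1 - x0)``."""
    pixels = img.pixels if isinstance(img, Radiograph) else np.asarray(img)
    rows, cols = pixels.shape
    if rect.x1 > cols or rect.y1 > rows:
        raise BoundsError(
            f"rectangle ({rect.x0},{rect.y0},{rect.x1},{rect.y1}) exceeds "
            f"image of shape {rows}x{cols}"
        )
    return pixels[rect.y0 : rect.y1, rect.x0 : rect.x1].copy()
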