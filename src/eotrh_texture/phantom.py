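"""Synthetic tooth-ROI phantom generator.

Real EOTRH radiographs show a bright, roughly tooth-shaped incisor on a
darker background; disease adds an alternating mosaic of low-radiopacity
resorption lucencies and high-radiopacity hypercementosis blobs (the latter
concentrated around the apex), with lesion count, size and contrast — and
hence overall image irregularity — increasing with grade 0..3. The phantom
reproduces exactly that statistical structure: a superellipse tooth mask,
Gaussian-profile dark and bright blobs at seeded random in-mask positions,
and grade-scaled additive Gaussian noise. It does not attempt anatomical
realism (enamel/dentine layering, projection physics, neighbouring teeth).

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .exceptions import ParameterError, ValidationError
from .imageio_roi import GradedROI, ManifestRecord, ROIRect, write_manifest

#: Grade-scaled defaults: lesion counts and noise encode the radiographic
#: progression from normal (grade 0) to severe (grade 3).
DEFAULT_N_RESORPTION = {0: 0, 1: 2, 2: 5, 3: 9}
DEFAULT_N_HYPERCEMENTOSIS = {0: 0, 1: 1, 2: 3, 3: 6}
DEFAULT_NOISE_SD = {0: 4.0, 1: 6.0, 2: 8.0, 3: 12.0}

#: The clinical cohort structure: group sizes per EOTRH grade.
DEFAULT_GROUP_SIZES = {0: 37, 1: 94, 2: 20, 3: 8}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic graded tooth ROI.

    ``n_resorption`` / ``n_hypercementosis`` / ``noise_sd`` default to the
    grade-scaled tables above when left as None.
    """

    grade: int
    width: int = 96
    height: int = 160
    n_resorption: int | None = None
    n_hypercementosis: int | None = None
    lesion_radius_range: tuple[float, float] = (3.0, 10.0)
    dark_contrast: float = -0.45  # fraction of tooth intensity
    bright_contrast: float = 0.45
    base_tooth_intensity: float = 180.0
    background_intensity: float = 60.0
    noise_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grade not in (0, 1, 2, 3):
            raise ValidationError(f"grade must be 0-3, got {self.grade}")
        if self.width < 8 or self.height < 8:
            raise ParameterError("phantom must be at least 8x8")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ParameterError("lesion_radius_range must satisfy 0 < lo <= hi")
        if hi >= min(self.width, self.height) / 2:
            raise ParameterError("lesion radii must be < min(width, height)/2")
        for v in (self.base_tooth_intensity, self.background_intensity):
            if not 0 <= v <= 255:
                raise ParameterError("intensities must lie in [0, 255]")
        if (self.n_resorption is not None and self.n_resorption < 0) or (
            self.n_hypercementosis is not None and self.n_hypercementosis < 0
        ):
            raise ParameterError("lesion counts must be >= 0")

    @property
    def resorption_count(self) -> int:
        return DEFAULT_N_RESORPTION[self.grade] if self.n_resorption is None else self.n_resorption

    @property
    def hypercementosis_count(self) -> int:
        return (
            DEFAULT_N_HYPERCEMENTOSIS[self.grade]
            if self.n_hypercementosis is None
            else self.n_hypercementosis
        )

    @property
    def noise(self) -> float:
        return DEFAULT_NOISE_SD[self.grade] if self.noise_sd is None else self.noise_sd


@dataclass
class PhantomDataset:
    """A generated cohort: graded ROIs plus per-image provenance."""

    rois: list[GradedROI]
    specs: list[PhantomSpec]
    records: list[ManifestRecord] = field(default_factory=list)


def tooth_mask(height: int, width: int) -> np.ndarray:
    """Axis-aligned rounded tooth silhouette (superellipse, long axis
    vertical, apex at the top)."""
    y, x = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    b, a = 0.46 * height, 0.36 * width
    return (np.abs((x - cx) / a) ** 4 + np.abs((y - cy) / b) ** 4) <= 1.0


def _add_blob(img: np.ndarray, y0: float, x0: float, radius: float, amplitude: float) -> None:
    y, x = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    sigma = radius / 2.0
    img += amplitude * np.exp(-((y - y0) ** 2 + (x - x0) ** 2) / (2.0 * sigma**2))


def generate_phantom(spec: PhantomSpec) -> GradedROI:
    """Render one phantom ROI; deterministic for a fixed spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    mask = tooth_mask(h, w)
    if not mask.any():
        raise ParameterError("tooth mask is empty; image too small")
    img = np.full((h, w), spec.background_intensity, dtype=np.float64)
    img[mask] = spec.base_tooth_intensity

    ys, xs = np.nonzero(mask)
    apical = ys < h / 3.0  # apex at the top third
    if spec.hypercementosis_count > 0 and not apical.any():
        raise ParameterError("no apical in-mask pixels available for bright blobs")

    r_lo, r_hi = spec.lesion_radius_range
    for _ in range(spec.resorption_count):
        k = rng.integers(len(ys))
        radius = rng.uniform(r_lo, r_hi)
        _add_blob(img, ys[k], xs[k], radius, spec.dark_contrast * spec.base_tooth_intensity)
    ay, ax = ys[apical], xs[apical]
    for _ in range(spec.hypercementosis_count):
        k = rng.integers(len(ay))
        radius = rng.uniform(r_lo, r_hi)
        _add_blob(img, ay[k], ax[k], radius, spec.bright_contrast * spec.base_tooth_intensity)

    if spec.noise > 0:
        img += rng.normal(0.0, spec.noise, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    tooth = 101 if spec.seed % 2 == 0 else 201
    return GradedROI(horse_id=f"P{spec.seed}", tooth=tooth, grade=spec.grade, pixels=img)


def generate_cohort(
    group_sizes: dict[int, int] | None = None,
    base_seed: int = 0,
    out_dir: str | Path | None = None,
    **spec_overrides,
) -> PhantomDataset:
    """Generate a graded cohort (defaults mirror the 37/94/20/8 clinical
    group sizes, 159 teeth in total).

    When ``out_dir`` is given, 8-bit grayscale PNGs and a manifest CSV
    (``manifest.csv``) consumable by :func:`imageio_roi.read_manifest` are
    written there; regeneration with the same ``base_seed`` is
    byte-identical.
    """
    sizes = DEFAULT_GROUP_SIZES if group_sizes is None else group_sizes
    for g, n in sizes.items():
        if n < 1:
            raise ValidationError(f"group size for grade {g} must be >= 1, got {n}")

    rois: list[GradedROI] = []
    specs: list[PhantomSpec] = []
    records: list[ManifestRecord] = []
    idx = 0
    for grade in sorted(sizes):
        for _ in range(sizes[grade]):
            seed = base_seed * 100_000 + idx
            spec = PhantomSpec(grade=grade, seed=seed, **spec_overrides)
            roi = generate_phantom(spec)
            horse = f"H{idx // 2 + 1:03d}"
            tooth = 101 if idx % 2 == 0 else 201
            roi.horse_id, roi.tooth = horse, tooth
            rois.append(roi)
            specs.append(spec)
            h, w = roi.pixels.shape
            records.append(
                ManifestRecord(
                    horse_id=horse,
                    tooth=tooth,
                    grade=grade,
                    image_path=f"phantom_{idx:04d}.png",
                    rect=ROIRect(0, 0, w, h),
                )
            )
            idx += 1

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for roi, rec in zip(rois, records):
            Image.fromarray(roi.pixels, mode="L").save(out_dir / rec.image_path)
        write_manifest(records, out_dir / "manifest.csv")
    return PhantomDataset(rois=rois, specs=specs, records=records)
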