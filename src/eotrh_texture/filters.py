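"""The three preprocessing filters applied to ROI matrices before texture
extraction: Normalize (zero mean / unit variance rescale), Median (rank
filter), and Laplacian sharpening (edge enhancement).

All filters preserve shape. Border handling for the neighborhood filters is
edge replication, so no artificial zeros leak into the ROI margins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy import ndimage

from .exceptions import DegenerateInputWarning, ParameterError, ValidationError

FILTER_NAMES = ("normalize", "median", "laplacian_sharpen")

#: 4-neighbor Laplacian kernel used by the sharpening filter.
LAPLACIAN_KERNEL = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


@dataclass(frozen=True)
class FilterSpec:
    """Which filter to apply and its parameters.

    ``median_radius`` is only meaningful for the median filter (neighborhood
    side ``2*radius + 1``); ``laplacian_weight`` only for sharpening
    (``out = in - weight * Laplacian(in)``).
    """

    name: str
    median_radius: int = 1
    laplacian_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in FILTER_NAMES:
            raise ParameterError(f"unknown filter {self.name!r}; expected one of {FILTER_NAMES}")
        if self.median_radius < 1:
            raise ParameterError("median_radius must be >= 1")
        if self.laplacian_weight <= 0:
            raise ParameterError("laplacian_weight must be > 0")

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"name": self.name}
        if self.name == "median":
            d["median_radius"] = self.median_radius
        elif self.name == "laplacian_sharpen":
            d["laplacian_weight"] = self.laplacian_weight
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "FilterSpec":
        return cls(**d)


def _as_matrix(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValidationError("filter input must be a non-empty 2-D matrix")
    return img


def filter_normalize(img: np.ndarray) -> np.ndarray:
    """Rescale so the pixel set has zero mean and unit (population) variance.

    A constant input has no variance to rescale; it maps to all zeros and a
    :class:`DegenerateInputWarning` is emitted.
    """
    img = _as_matrix(img)
    mu = img.mean()
    sd = img.std()  # population SD: "unit variance" of the pixel set
    if sd == 0:
        warnings.warn("constant image: normalize returns all zeros", DegenerateInputWarning)
        return np.zeros_like(img)
    return (img - mu) / sd


def filter_median(img: np.ndarray, radius: int = 1) -> np.ndarray:
    """Median over the ``(2*radius+1)**2`` neighborhood, edge-replicated."""
    if radius < 1:
        raise ParameterError("median radius must be >= 1")
    img = _as_matrix(img)
    return ndimage.median_filter(img, size=2 * radius + 1, mode="nearest")


def filter_laplacian_sharpen(img: np.ndarray, weight: float = 1.0) -> np.ndarray:
    """Unsharp-by-Laplacian: ``out = in - weight * Laplacian(in)`` with the
    4-neighbor kernel and edge-replicated borders."""
    if weight <= 0:
        raise ParameterError("laplacian weight must be > 0")
    img = _as_matrix(img)
    lap = ndimage.convolve(img, LAPLACIAN_KERNEL, mode="nearest")
    return img - weight * lap


def apply_filter(img: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Dispatch to the filter named in ``spec``."""
    if spec.name == "normalize":
        return filter_normalize(img)
    if spec.name == "median":
        return filter_median(img, spec.median_radius)
    if spec.name == "laplacian_sharpen":
        return filter_laplacian_sharpen(img, spec.laplacian_weight)
    raise ParameterError(f"unknown filter {spec.name!r}")  # pragma: no cover


#: The default filter bank, in reporting order.
DEFAULT_FILTERS = (
    FilterSpec("normalize"),
    FilterSpec("median", median_radius=1),
    FilterSpec("laplacian_sharpen", laplacian_weight=1.0),
)
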