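"""Gray-level co-occurrence matrix (GLCM) features used as the comparison
baseline: Cluster Prominence, Contrast, Difference Average, Difference
Entropy, Difference Variance, Inverse Variance.

The image is min-max quantized to ``n_levels`` gray levels, co-occurring
level pairs are counted at a fixed pixel offset per direction
(0/45/90/135 degrees), symmetrized and normalized to a probability matrix
``p(i, j)``; the six features are moments of ``p`` and of its difference
marginal ``p_{x-y}(k)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError, ValidationError

#: (row, col) unit offsets per direction angle in degrees.
DIRECTION_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GLCM_FEATURE_NAMES = (
    "ClusterProminence",
    "Contrast",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "InverseVariance",
)


@dataclass(frozen=True)
class GLCMParams:
    n_levels: int = 32
    distance: int = 1
    directions: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True
    averaging: str = "average_features"  # or "average_matrices"

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ParameterError("n_levels must be >= 2")
        if self.distance < 1:
            raise ParameterError("distance must be >= 1")
        if not self.directions:
            raise ParameterError("at least one direction required")
        bad = [a for a in self.directions if a not in DIRECTION_OFFSETS]
        if bad:
            raise ParameterError(f"unknown directions {bad}; allowed {list(DIRECTION_OFFSETS)}")
        if self.averaging not in ("average_matrices", "average_features"):
            raise ParameterError("averaging must be 'average_matrices' or 'average_features'")


@dataclass(frozen=True)
class GLCMFeatures:
    cluster_prominence: float
    contrast: float
    difference_average: float
    difference_entropy: float
    difference_variance: float
    inverse_variance: float

    def as_dict(self) -> dict[str, float]:
        return {
            "ClusterProminence": self.cluster_prominence,
            "Contrast": self.contrast,
            "DifferenceAverage": self.difference_average,
            "DifferenceEntropy": self.difference_entropy,
            "DifferenceVariance": self.difference_variance,
            "InverseVariance": self.inverse_variance,
        }


def quantize(img: np.ndarray, n_levels: int) -> np.ndarray:
    """Equal-width min-max binning into integer levels 1..n_levels; a constant
    image maps entirely to level 1."""
    if n_levels < 2:
        raise ParameterError("n_levels must be >= 2")
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValidationError("quantize input must be a non-empty 2-D matrix")
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.ones(img.shape, dtype=np.int64)
    q = np.floor((img - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
    return np.clip(q, 1, n_levels)


def cooccurrence(q: np.ndarray, p: GLCMParams) -> list[np.ndarray]:
    """One normalized co-occurrence probability matrix per direction.

    Entry ``P[i-1, j-1]`` is the probability of levels (i, j) co-occurring at
    the direction's offset scaled by ``p.distance``; symmetrized when
    ``p.symmetric``.
    """
    q = np.asarray(q)
    rows, cols = q.shape
    L = p.n_levels
    if q.min() < 1 or q.max() > L:
        raise ValidationError("quantized levels must lie in [1, n_levels]")
    mats = []
    for angle in p.directions:
        dr, dc = DIRECTION_OFFSETS[angle]
        dr, dc = dr * p.distance, dc * p.distance
        if abs(dr) >= rows or abs(dc) >= cols:
            raise ValidationError(
                f"offset ({dr},{dc}) does not fit image {rows}x{cols}"
            )
        # source/target slices of the shifted overlap
        rs = slice(max(0, -dr), rows - max(0, dr))
        cs = slice(max(0, -dc), cols - max(0, dc))
        rt = slice(max(0, dr), rows - max(0, -dr))
        ct = slice(max(0, dc), cols - max(0, -dc))
        a = q[rs, cs].ravel() - 1
        b = q[rt, ct].ravel() - 1
        counts = np.bincount(a * L + b, minlength=L * L).reshape(L, L).astype(np.float64)
        if p.symmetric:
            counts = counts + counts.T
        total = counts.sum()
        if total == 0:
            raise ValidationError("no co-occurring pairs at this offset")
        mats.append(counts / total)
    return mats


def glcm_features(P: np.ndarray) -> GLCMFeatures:
    """The six features of one normalized co-occurrence matrix."""
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValidationError("P must be a square matrix")
    if abs(P.sum() - 1.0) > 1e-8:
        raise ValidationError("P must be normalized to sum 1")
    L = P.shape[0]
    i = np.arange(1, L + 1)[:, None]
    j = np.arange(1, L + 1)[None, :]
    mu_x = float((i * P).sum())
    mu_y = float((j * P).sum())

    contrast = float(((i - j) ** 2 * P).sum())
    cluster_prominence = float(((i + j - mu_x - mu_y) ** 4 * P).sum())

    # difference marginal p_{x-y}(k), k = 0..L-1
    k = np.abs(i - j)
    p_diff = np.bincount(k.ravel(), weights=P.ravel(), minlength=L)[:L]
    ks = np.arange(L, dtype=np.float64)
    difference_average = float((ks * p_diff).sum())
    nz = p_diff > 0
    difference_entropy = float(-(p_diff[nz] * np.log2(p_diff[nz])).sum())
    difference_variance = float(((ks - difference_average) ** 2 * p_diff).sum())

    off = i != j
    with np.errstate(divide="ignore"):
        inv = np.where(off, P / np.where(off, (i - j) ** 2, 1), 0.0)
    inverse_variance = float(inv.sum())

    return GLCMFeatures(
        cluster_prominence=cluster_prominence,
        contrast=contrast,
        difference_average=difference_average,
        difference_entropy=difference_entropy,
        difference_variance=difference_variance,
        inverse_variance=inverse_variance,
    )


def glcm_suite(img: np.ndarray, p: GLCMParams = GLCMParams()) -> GLCMFeatures:
    """Quantize, count, and reduce over directions per the averaging mode:
    either average the matrices first, or average the per-direction
    features."""
    q = quantize(img, p.n_levels)
    mats = cooccurrence(q, p)
    if p.averaging == "average_matrices":
        return glcm_features(np.mean(mats, axis=0))
    feats = [glcm_features(P) for P in mats]
    return GLCMFeatures(
        **{
            name: float(np.mean([getattr(f, name) for f in feats]))
            for name in (
                "cluster_prominence",
                "contrast",
                "difference_average",
                "difference_entropy",
                "difference_variance",
                "inverse_variance",
            )
        }
    )
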