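"""Five two-dimensional entropy measures of image irregularity.

* ``SampEn2D`` — negative log of the conditional probability that windows
  similar at size ``m`` (Chebyshev distance <= r) stay similar at ``m+1``.
* ``FuzzEn2D`` — same construction with a continuous exponential similarity
  ``exp(-d^n / r)`` on mean-subtracted windows.
* ``PermEn2D`` — Shannon entropy of ordinal (rank-order) patterns of
  ``dm x dn`` sub-matrices.
* ``DispEn2D`` — Shannon entropy of dispersion patterns: pixels are mapped
  through the normal CDF of the image's own mean/SD and quantized to ``c``
  classes.
* ``DistEn2D`` — entropy of the empirical distribution (ePDF, ``M`` bins) of
  pairwise inter-window Chebyshev distances, in bits, normalized by
  ``log2(M)`` by default.

All five are shift invariant (``img + b``): the tolerance ``r`` scales with
the image SD, windows are mean-subtracted (fuzzy), ordinal patterns depend
only on ranks, the dispersion mapping standardizes by mean/SD, and distance
binning spans the observed range. All but FuzzEn2D are also scale invariant
(``a*img``, a > 0); the fuzzy similarity ``exp(-d^nf / r)`` scales ``d^nf``
by ``a^nf`` but ``r`` only by ``a``, so FuzzEn2D is scale invariant only for
``nf = 1``.

Pairwise window comparison is quadratic in the number of windows, so inputs
larger than a configurable pixel budget (default 64x64) are block-downsampled
by local mean first; the applied factor is recorded on the result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import ndtr  # standard normal CDF

from .exceptions import DegenerateInputWarning, ParameterError, ValidationError

MEASURE_NAMES = ("SampEn2D", "FuzzEn2D", "PermEn2D", "DispEn2D", "DistEn2D")

_PAIR_CHUNK = 256  # rows of the pairwise distance matrix computed at once


@dataclass(frozen=True)
class EntropyParams:
    """Free parameters of the five measures.

    m : window side for SampEn2D / FuzzEn2D / DistEn2D (templates are m x m,
        extended to (m+1) x (m+1) for the conditional measures).
    r_coeff : tolerance coefficient; the similarity tolerance is
        ``r = r_coeff * population SD`` of the matrix.
    nf : fuzzy exponent of the exponential similarity function.
    dm, dn : sub-matrix dimensions for PermEn2D / DispEn2D patterns.
    c : number of dispersion classes.
    M : number of ePDF histogram bins for DistEn2D.
    logbase : 'natural' or 'base2' for PermEn2D / DispEn2D (SampEn2D and
        FuzzEn2D are defined with the natural log; DistEn2D with log2).
    normalize_perm / normalize_disp / normalize_dist : per-measure
        normalization switches (max-entropy denominators ln((dm*dn)!),
        ln(c**(dm*dn)), log2(M)).
    window_count_prefactor : opt-in reciprocal-window-count prefactor on
        PermEn2D / DispEn2D (makes values image-size dependent; off by
        default).
    pixel_budget : (rows, cols) cap before block-downsampling.
    """

    m: int = 2
    r_coeff: float = 0.2
    nf: float = 2.0
    dm: int = 2
    dn: int = 2
    c: int = 6
    M: int = 512
    logbase: str = "natural"
    normalize_perm: bool = False
    normalize_disp: bool = False
    normalize_dist: bool = True
    window_count_prefactor: bool = False
    pixel_budget: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ParameterError("m must be >= 1")
        if self.r_coeff <= 0:
            raise ParameterError("r_coeff must be > 0")
        if self.nf <= 0:
            raise ParameterError("fuzzy exponent nf must be > 0")
        if self.dm < 2 or self.dn < 2:
            raise ParameterError("dm and dn must be >= 2")
        if self.c < 2:
            raise ParameterError("number of dispersion classes c must be >= 2")
        if self.M < 2:
            raise ParameterError("number of ePDF bins M must be >= 2")
        if self.logbase not in ("natural", "base2"):
            raise ParameterError("logbase must be 'natural' or 'base2'")
        if min(self.pixel_budget) < 4:
            raise ParameterError("pixel_budget sides must be >= 4")


@dataclass(frozen=True)
class EntropyResult:
    """Value of one measure; ``value is None`` marks an undefined result
    (e.g. SampEn2D with zero template matches)."""

    measure: str
    value: float | None
    params: EntropyParams
    note: str = ""

    @property
    def defined(self) -> bool:
        return self.value is not None


def windows(img: np.ndarray, a: int, b: int) -> np.ndarray:
    """All contiguous ``a x b`` sub-matrices in row-major scan order,
    flattened to shape ``(n_windows, a*b)``."""
    img = np.asarray(img, dtype=np.float64)
    rows, cols = img.shape
    if a > rows or b > cols:
        raise ValidationError(f"window {a}x{b} larger than image {rows}x{cols}")
    view = sliding_window_view(img, (a, b))
    return view.reshape(-1, a * b)


def block_downsample(img: np.ndarray, budget: tuple[int, int]) -> tuple[np.ndarray, int]:
    """Local-mean downsampling by the smallest integer factor that brings the
    image within ``budget``; trailing rows/cols that do not fill a block are
    dropped. Returns (image, factor); factor 1 means untouched."""
    img = np.asarray(img, dtype=np.float64)
    rows, cols = img.shape
    br, bc = budget
    k = max(-(-rows // br), -(-cols // bc))  # ceil division
    if k <= 1:
        return img, 1
    r2, c2 = rows // k, cols // k
    trimmed = img[: r2 * k, : c2 * k]
    out = trimmed.reshape(r2, k, c2, k).mean(axis=(1, 3))
    return out, k


def _prepare(img: np.ndarray, p: EntropyParams) -> tuple[np.ndarray, str]:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValidationError("entropy input must be a non-empty 2-D matrix")
    img, k = block_downsample(img, p.pixel_budget)
    note = f"block-downsampled by {k}" if k > 1 else ""
    return img, note


def _log(x: np.ndarray, base: str) -> np.ndarray:
    return np.log2(x) if base == "base2" else np.log(x)


def _count_close_pairs(W: np.ndarray, r: float) -> int:
    """Ordered pairs (i != j) of window rows with Chebyshev distance <= r."""
    n = W.shape[0]
    total = 0
    for start in range(0, n, _PAIR_CHUNK):
        block = W[start : start + _PAIR_CHUNK]
        d = np.abs(block[:, None, :] - W[None, :, :]).max(axis=2)
        total += int((d <= r).sum())
    return total - n  # remove self-pairs (distance 0)


def _sum_similarity(W: np.ndarray, r: float, nf: float) -> float:
    """Sum over ordered pairs (i != j) of exp(-d^nf / r).

    Self-pairs are zeroed before summation (subtracting their exp(0)=1
    afterwards would catastrophically cancel when all similarities are
    tiny)."""
    n = W.shape[0]
    total = 0.0
    for start in range(0, n, _PAIR_CHUNK):
        block = W[start : start + _PAIR_CHUNK]
        d = np.abs(block[:, None, :] - W[None, :, :]).max(axis=2)
        sim = np.exp(-(d**nf) / r)
        rows = np.arange(block.shape[0])
        sim[rows, start + rows] = 0.0
        total += float(sim.sum())
    return total


def _pairwise_distances(W: np.ndarray) -> np.ndarray:
    """Chebyshev distances of all unordered window pairs (i < j)."""
    n = W.shape[0]
    parts = []
    for i in range(0, n, _PAIR_CHUNK):
        block = W[i : i + _PAIR_CHUNK]
        d = np.abs(block[:, None, :] - W[None, :, :]).max(axis=2)
        for bi in range(block.shape[0]):
            parts.append(d[bi, i + bi + 1 :])
    return np.concatenate(parts) if parts else np.empty(0)


def _common_grid_windows(img: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """m- and (m+1)-windows restricted to the positions where both fit, so
    the conditional probability compares like with like."""
    rows, cols = img.shape
    if rows < m + 1 or cols < m + 1:
        raise ValidationError(f"image {rows}x{cols} too small for (m+1)={m + 1} windows")
    Wm_full = sliding_window_view(img, (m, m))
    Wm = Wm_full[: rows - m, : cols - m].reshape(-1, m * m)
    Wm1 = sliding_window_view(img, (m + 1, m + 1)).reshape(-1, (m + 1) * (m + 1))
    return Wm, Wm1


def samp_en_2d(img: np.ndarray, p: EntropyParams = EntropyParams()) -> EntropyResult:
    """Two-dimensional sample entropy: ``-ln(B/A)`` where A and B count
    ordered window pairs within tolerance at sizes m and m+1."""
    img, note = _prepare(img, p)
    r = p.r_coeff * img.std()
    Wm, Wm1 = _common_grid_windows(img, p.m)
    A = _count_close_pairs(Wm, r)
    B = _count_close_pairs(Wm1, r)
    if A == 0 or B == 0:
        return EntropyResult(
            "SampEn2D", None, p, note=(note + "; " if note else "") + "no template matches"
        )
    return EntropyResult("SampEn2D", float(-math.log(B / A)), p, note=note)


def fuzz_en_2d(img: np.ndarray, p: EntropyParams = EntropyParams()) -> EntropyResult:
    """Two-dimensional fuzzy entropy: as SampEn2D but windows are
    mean-subtracted and matching is graded by ``exp(-d^nf / r)``."""
    img, note = _prepare(img, p)
    sd = img.std()
    if sd == 0:
        warnings.warn("constant image: FuzzEn2D is 0", DegenerateInputWarning)
        return EntropyResult("FuzzEn2D", 0.0, p, note=note)
    r = p.r_coeff * sd
    Wm, Wm1 = _common_grid_windows(img, p.m)
    Wm = Wm - Wm.mean(axis=1, keepdims=True)
    Wm1 = Wm1 - Wm1.mean(axis=1, keepdims=True)
    n = Wm.shape[0]
    if n < 2:
        return EntropyResult("FuzzEn2D", None, p, note="fewer than two windows")
    denom = n * (n - 1)
    phi_m = _sum_similarity(Wm, r, p.nf) / denom
    phi_m1 = _sum_similarity(Wm1, r, p.nf) / denom
    return EntropyResult("FuzzEn2D", float(-math.log(phi_m1 / phi_m)), p, note=note)


def _pattern_entropy(patterns: np.ndarray, p: EntropyParams) -> float:
    """Shannon entropy of row-pattern frequencies, with the optional
    normalization and window-count prefactor applied."""
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    probs = counts / counts.sum()
    h = float(-(probs * _log(probs, p.logbase)).sum())
    if p.window_count_prefactor:
        h /= patterns.shape[0]
    return h


def perm_en_2d(img: np.ndarray, p: EntropyParams = EntropyParams()) -> EntropyResult:
    """Two-dimensional permutation entropy: Shannon entropy of the ordinal
    patterns (stable argsort; ties broken by position) of dm x dn windows."""
    img, note = _prepare(img, p)
    W = windows(img, p.dm, p.dn)
    patterns = np.argsort(W, axis=1, kind="stable")
    h = _pattern_entropy(patterns, p)
    if p.normalize_perm:
        h /= _log(np.array(math.factorial(p.dm * p.dn)), p.logbase)
    return EntropyResult("PermEn2D", float(h), p, note=note)


def disp_en_2d(img: np.ndarray, p: EntropyParams = EntropyParams()) -> EntropyResult:
    """Two-dimensional dispersion entropy: pixels are standardized through the
    normal CDF (image mean/SD), quantized to classes
    ``z = round(c*v + 0.5)`` clipped to [1, c], and the entropy of the
    dm x dn class-pattern distribution is returned."""
    img, note = _prepare(img, p)
    sd = img.std()
    if sd == 0:
        warnings.warn("constant image: single dispersion class", DegenerateInputWarning)
        return EntropyResult("DispEn2D", 0.0, p, note=note)
    v = ndtr((img - img.mean()) / sd)
    z = np.clip(np.round(p.c * v + 0.5), 1, p.c).astype(np.int64)
    W = windows(z, p.dm, p.dn)
    h = _pattern_entropy(W, p)
    if p.normalize_disp:
        h /= (p.dm * p.dn) * _log(np.array(float(p.c)), p.logbase)
    return EntropyResult("DispEn2D", float(h), p, note=note)


def dist_en_2d(img: np.ndarray, p: EntropyParams = EntropyParams()) -> EntropyResult:
    """Two-dimensional distribution entropy: Shannon entropy (bits) of the
    M-bin histogram of all pairwise inter-window Chebyshev distances,
    normalized by log2(M) when ``normalize_dist`` (the default)."""
    img, note = _prepare(img, p)
    rows, cols = img.shape
    if rows < p.m or cols < p.m:
        raise ValidationError(f"image {rows}x{cols} too small for m={p.m} windows")
    W = windows(img, p.m, p.m)
    d = _pairwise_distances(W)
    if d.size == 0:
        return EntropyResult("DistEn2D", None, p, note="fewer than two windows")
    dmax = float(d.max())
    if dmax == 0:
        return EntropyResult("DistEn2D", 0.0, p, note=note)
    counts, _ = np.histogram(d, bins=p.M, range=(0.0, dmax))
    probs = counts[counts > 0] / d.size
    h = float(-(probs * np.log2(probs)).sum())
    if p.normalize_dist:
        h /= math.log2(p.M)
    return EntropyResult("DistEn2D", h, p, note=note)


_MEASURE_FUNCS = {
    "SampEn2D": samp_en_2d,
    "FuzzEn2D": fuzz_en_2d,
    "PermEn2D": perm_en_2d,
    "DispEn2D": disp_en_2d,
    "DistEn2D": dist_en_2d,
}


def entropy_suite(img: np.ndarray, p: EntropyParams = EntropyParams()) -> list[EntropyResult]:
    """All five measures in fixed order (SampEn2D, FuzzEn2D, PermEn2D,
    DispEn2D, DistEn2D); undefined markers are propagated, not raised."""
    return [_MEASURE_FUNCS[name](img, p) for name in MEASURE_NAMES]
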