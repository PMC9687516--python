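"""Independent brute-force reference implementations used as oracles.

Everything here is deliberately written with plain Python loops and the
definitions spelled out directly (pair enumeration, pattern tallies,
double-loop GLCM), sharing no code with the vectorized package
implementations they check.
"""

from __future__ import annotations

import math
from collections import Counter


def _submatrices(img, a, b):
    rows, cols = len(img), len(img[0])
    out = []
    for i in range(rows - a + 1):
        for j in range(cols - b + 1):
            out.append([img[i + di][j + dj] for di in range(a) for dj in range(b)])
    return out


def _submatrices_common(img, m):
    """m- and (m+1)-windows at the common grid of positions."""
    rows, cols = len(img), len(img[0])
    wm, wm1 = [], []
    for i in range(rows - m):
        for j in range(cols - m):
            wm.append([img[i + di][j + dj] for di in range(m) for dj in range(m)])
            wm1.append([img[i + di][j + dj] for di in range(m + 1) for dj in range(m + 1)])
    return wm, wm1


def _cheb(u, v):
    return max(abs(a - b) for a, b in zip(u, v))


def _pop_sd(img):
    flat = [x for row in img for x in row]
    mu = sum(flat) / len(flat)
    return math.sqrt(sum((x - mu) ** 2 for x in flat) / len(flat))


def sampen2d_brute(img, m=2, r_coeff=0.2):
    """Returns the value, or None when undefined (zero matches)."""
    r = r_coeff * _pop_sd(img)
    wm, wm1 = _submatrices_common(img, m)
    A = sum(1 for i in range(len(wm)) for j in range(len(wm)) if i != j and _cheb(wm[i], wm[j]) <= r)
    B = sum(
        1 for i in range(len(wm1)) for j in range(len(wm1)) if i != j and _cheb(wm1[i], wm1[j]) <= r
    )
    if A == 0 or B == 0:
        return None
    return -math.log(B / A)


def fuzzen2d_brute(img, m=2, r_coeff=0.2, nf=2.0):
    sd = _pop_sd(img)
    if sd == 0:
        return 0.0
    r = r_coeff * sd
    wm, wm1 = _submatrices_common(img, m)

    def centered(ws):
        return [[x - sum(w) / len(w) for x in w] for w in ws]

    def phi(ws):
        n = len(ws)
        terms = [
            math.exp(-(_cheb(ws[i], ws[j]) ** nf) / r)
            for i in range(n)
            for j in range(n)
            if i != j
        ]
        return math.fsum(terms) / (n * (n - 1))

    return -math.log(phi(centered(wm1)) / phi(centered(wm)))


def permen2d_brute(img, dm=2, dn=2, normalize=False):
    pats = Counter()
    for w in _submatrices(img, dm, dn):
        order = tuple(sorted(range(len(w)), key=lambda i: (w[i], i)))  # stable ties
        pats[order] += 1
    total = sum(pats.values())
    h = -sum((c / total) * math.log(c / total) for c in pats.values())
    if normalize:
        h /= math.log(math.factorial(dm * dn))
    return h


def _norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def dispen2d_brute(img, c=6, dm=2, dn=2, normalize=False):
    flat = [x for row in img for x in row]
    mu = sum(flat) / len(flat)
    sd = _pop_sd(img)
    if sd == 0:
        return 0.0
    z = [
        [min(c, max(1, round(c * _norm_cdf((x - mu) / sd) + 0.5))) for x in row] for row in img
    ]
    pats = Counter(tuple(w) for w in _submatrices(z, dm, dn))
    total = sum(pats.values())
    h = -sum((k / total) * math.log(k / total) for k in pats.values())
    if normalize:
        h /= (dm * dn) * math.log(c)
    return h


def disten2d_brute(img, m=2, M=512, normalize=True):
    ws = _submatrices(img, m, m)
    dists = [_cheb(ws[i], ws[j]) for i in range(len(ws)) for j in range(i + 1, len(ws))]
    if not dists:
        return None
    dmax = max(dists)
    if dmax == 0:
        return 0.0
    counts = [0] * M
    for d in dists:
        t = min(int(d / dmax * M), M - 1)
        counts[t] += 1
    total = len(dists)
    h = -sum((c / total) * math.log2(c / total) for c in counts if c > 0)
    if normalize:
        h /= math.log2(M)
    return h


def glcm_reference(levels, n_levels, distance=1, directions=(0, 45, 90, 135), symmetric=True):
    """Naive double-loop co-occurrence + features; returns a dict of the six
    features averaged over directions (feature averaging)."""
    offsets = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
    rows, cols = len(levels), len(levels[0])
    per_dir = []
    for angle in directions:
        dr, dc = offsets[angle]
        dr, dc = dr * distance, dc * distance
        counts = [[0.0] * n_levels for _ in range(n_levels)]
        for i in range(rows):
            for j in range(cols):
                i2, j2 = i + dr, j + dc
                if 0 <= i2 < rows and 0 <= j2 < cols:
                    a, b = levels[i][j], levels[i2][j2]
                    counts[a - 1][b - 1] += 1
                    if symmetric:
                        counts[b - 1][a - 1] += 1
        total = sum(sum(r) for r in counts)
        P = [[c / total for c in r] for r in counts]
        per_dir.append(_glcm_features_ref(P))
    keys = per_dir[0].keys()
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in keys}


def _glcm_features_ref(P):
    L = len(P)
    mu_x = sum((i + 1) * P[i][j] for i in range(L) for j in range(L))
    mu_y = sum((j + 1) * P[i][j] for i in range(L) for j in range(L))
    contrast = sum((i - j) ** 2 * P[i][j] for i in range(L) for j in range(L))
    prominence = sum(
        (i + 1 + j + 1 - mu_x - mu_y) ** 4 * P[i][j] for i in range(L) for j in range(L)
    )
    p_diff = [0.0] * L
    for i in range(L):
        for j in range(L):
            p_diff[abs(i - j)] += P[i][j]
    diff_avg = sum(k * p_diff[k] for k in range(L))
    diff_ent = -sum(p * math.log2(p) for p in p_diff if p > 0)
    diff_var = sum((k - diff_avg) ** 2 * p_diff[k] for k in range(L))
    inv_var = sum(P[i][j] / (i - j) ** 2 for i in range(L) for j in range(L) if i != j)
    return {
        "ClusterProminence": prominence,
        "Contrast": contrast,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": diff_ent,
        "DifferenceVariance": diff_var,
        "InverseVariance": inv_var,
    }
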