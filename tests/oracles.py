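"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle recomputes a quantity by direct enumeration, deliberately
avoiding the vectorized code paths of the package under test.
"""

import math

import numpy as np
from skimage.filters import threshold_otsu


def brute_force_threshold_mask(img01, params):
    """Per-pixel windowed thresholding by direct summation over each window.

    Reflect-pads the image (edge pixel included, matching the package's
    border convention), then for every pixel gathers its centered window with
    explicit loops and applies the Niblack / Phansalkar / Otsu rule.
    """
    h, w = img01.shape
    half = params.window_px // 2
    padded = np.pad(img01, half, mode="symmetric")
    k = params.k_effective
    mask = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            window = padded[i : i + 2 * half + 1, j : j + 2 * half + 1]
            vals = [window[a, b] for a in range(window.shape[0]) for b in range(window.shape[1])]
            n = len(vals)
            m = sum(vals) / n
            var = sum((v - m) ** 2 for v in vals) / n
            s = math.sqrt(var)
            if params.method == "niblack":
                t = m + k * s
            elif params.method == "phansalkar":
                t = m * (1.0 + params.p_coef * math.exp(-params.q_coef * m)
                         + k * (s / params.r - 1.0))
            elif params.method == "otsu_local":
                t = window.flat[0] if max(vals) == min(vals) else threshold_otsu(window)
            else:
                raise ValueError(params.method)
            mask[i, j] = img01[i, j] > t
    return mask


def brute_force_region_count(skel, region_mask):
    """Skeleton-pixel count inside a region by an explicit double loop."""
    count = 0
    total = 0
    for i in range(skel.shape[0]):
        for j in range(skel.shape[1]):
            if region_mask[i, j]:
                total += 1
                if skel[i, j]:
                    count += 1
    return count, total


def brute_force_bh(pvals):
    """Benjamini-Hochberg step-up adjustment straight from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [None] * m
    for rank_index, i in enumerate(order):
        candidates = []
        for later_rank in range(rank_index, m):
            j = order[later_rank]
            candidates.append(pvals[j] * m / (later_rank + 1))
        adj[i] = min(1.0, min(candidates))
    return adj


def brute_force_chi2_2x2(a, b, c, d):
    """Pearson chi-square on a 2x2 table via N(ad - bc)^2 / (r1 r2 c1 c2)."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def brute_force_chi2_general(table):
    """Sum (O - E)^2 / E over all cells."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def random_blob_mask(rng, n=64):
    """Random union of discs and bars, for skeleton-contract sweeps."""
    m = np.zeros((n, n), dtype=bool)
    for _ in range(int(rng.integers(3, 10))):
        if rng.integers(2) == 0:
            ci, cj = int(rng.integers(5, n - 5)), int(rng.integers(5, n - 5))
            r = int(rng.integers(2, 7))
            ii, jj = np.mgrid[:n, :n]
            m |= (ii - ci) ** 2 + (jj - cj) ** 2 <= r * r
        else:
            i0, j0 = int(rng.integers(0, n - 20)), int(rng.integers(0, n - 20))
            length, width = int(rng.integers(10, 20)), int(rng.integers(1, 4))
            if rng.integers(2) == 0:
                m[i0 : i0 + width, j0 : j0 + length] = True
            else:
                m[i0 : i0 + length, j0 : j0 + width] = True
    return m


def star_polygon(rng, n_vert=60, r0=70.0, irregularity=0.25, center=(100.0, 100.0)):
    """Random simple star-shaped polygon (radius modulated by low harmonics)."""
    theta = np.linspace(0.0, 2.0 * math.pi, n_vert, endpoint=False)
    mod = np.zeros(n_vert)
    for h in (2, 3, 4, 5):
        mod += rng.normal(0.0, 0.1) * np.cos(h * theta + rng.uniform(0.0, 2.0 * math.pi))
    r = np.maximum(r0 * (1.0 + irregularity * mod / 0.3), 10.0)
    return np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])
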