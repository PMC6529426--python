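"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where feasible, the
libraries) used by the package itself: exhaustive search for Otsu,
breadth-first flood fill for labeling, permutation enumeration for the
Mann-Whitney null, and direct min/max window scans for grayscale opening.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np


def otsu_bruteforce(values: np.ndarray) -> int:
    """Exhaustive maximization of between-class variance over all 256 cuts.

    Returns the lowest cut level k (foreground = intensity > k) attaining
    the maximum.  Pure-python loop over histogram cuts.
    """
    hist = np.bincount(np.asarray(values).ravel().astype(int), minlength=256)[:256]
    total = hist.sum()
    best_k, best_var = None, -1.0
    for k in range(256):
        w0 = hist[: k + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: k + 1] * np.arange(k + 1)).sum() / w0
        mu1 = (hist[k + 1 :] * np.arange(k + 1, 256)).sum() / w1
        var = w0 / total * w1 / total * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_k = var, k
    return best_k


def flood_fill_count(mask: np.ndarray, connectivity: int) -> int:
    """Count connected foreground components by breadth-first search."""
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    count = 0
    for i in range(H):
        for j in range(W):
            if mask[i, j] and not seen[i, j]:
                count += 1
                queue = deque([(i, j)])
                seen[i, j] = True
                while queue:
                    r, c = queue.popleft()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            queue.append((rr, cc))
    return count


def mann_whitney_enumerate(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating all group labelings.

    Requires a tie-free pooled sample.  The p-value counts labelings whose
    U is at least as far from the null mean n_a*n_b/2 as the observed U.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    assert np.unique(pooled).size == pooled.size, "oracle requires no ties"
    n_a, n_b = len(a), len(b)
    ranks = pooled.argsort().argsort() + 1  # 1-based ranks
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    mean_u = n_a * n_b / 2.0
    n_extreme = 0
    total = 0
    rank_values = np.sort(ranks)
    for combo in combinations(range(n_a + n_b), n_a):
        u = sum(rank_values[i] for i in combo) - n_a * (n_a + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9:
            n_extreme += 1
    return float(u_obs), n_extreme / total


def opening_bruteforce(img: np.ndarray, footprint: np.ndarray, heights: np.ndarray) -> np.ndarray:
    """Grayscale opening with a non-flat structuring element, by direct
    min/max window scans with edge replication."""
    img = np.asarray(img, float)
    r = footprint.shape[0] // 2
    offs = [
        (dy, dx, heights[dy + r, dx + r])
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if footprint[dy + r, dx + r]
    ]
    H, W = img.shape

    def scan(f, op, sign):
        padded = np.pad(f, r, mode="edge")
        out = np.empty_like(f)
        for i in range(H):
            for j in range(W):
                out[i, j] = op(
                    padded[i + r + dy, j + r + dx] + sign * h for dy, dx, h in offs
                )
        return out

    eroded = scan(img, min, -1.0)
    return scan(eroded, max, +1.0)


def percentile_linear(values, q) -> float:
    """Linear-interpolation percentile from sorted order statistics."""
    xs = np.sort(np.asarray(values, float))
    n = xs.size
    if n == 1:
        return float(xs[0])
    pos = q / 100.0 * (n - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return float(xs[lo] * (1 - frac) + xs[hi] * frac)
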