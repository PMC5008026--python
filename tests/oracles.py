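"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (scalar loops, all-pairs distances,
BFS flood fill) and shares no code path with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def naive_ratio_field(px: np.ndarray, w: int, n: int, directions) -> np.ndarray:
    """Per-pixel, per-direction loop evaluation of the maximal |R_c|.

    Block sums accumulate sequentially in row-major order.  NaN in the
    border margin.
    """
    h, wid = px.shape
    m = w // 2 + n // 2 + 1
    half = w // 2
    hn = n // 2
    out = np.full(px.shape, np.nan)
    for r in range(m, h - m):
        for c in range(m, wid - m):
            best = 0.0
            for theta in directions:
                rad = math.radians(theta)
                dr = -int(round(math.sin(rad)))
                dc = int(round(math.cos(rad)))
                rr, cc = r + dr, c + dc
                v = px[rr, cc]
                means = []
                for sgn in (1, -1):
                    br, bc = rr + sgn * half * dr, cc + sgn * half * dc
                    s = 0.0
                    for i in range(br - hn, br + hn + 1):
                        for j in range(bc - hn, bc + hn + 1):
                            s += px[i, j]
                    means.append(s / (n * n))
                rc = (means[0] + means[1] - 2.0 * v) / (2.0 * v)
                best = max(best, abs(rc))
            out[r, c] = best
    return out


def naive_block_mean(px: np.ndarray, center, n: int) -> float:
    r, c = center
    s = 0.0
    for i in range(r - n // 2, r + n // 2 + 1):
        for j in range(c - n // 2, c + n // 2 + 1):
            s += px[i, j]
    return s / (n * n)


def naive_median_filter(px: np.ndarray, window: int) -> np.ndarray:
    """Sort-based per-pixel median with edge replication."""
    h = window // 2
    padded = np.pad(px, h, mode="edge")
    out = np.empty_like(px, dtype=np.float64)
    for r in range(px.shape[0]):
        for c in range(px.shape[1]):
            block = np.sort(padded[r : r + window, c : c + window], axis=None)
            out[r, c] = block[len(block) // 2]
    return out


def flood_fill_components(mask: np.ndarray, connectivity: int = 8):
    """BFS connected components; returns (labels, sizes dict)."""
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    labels = np.zeros(mask.shape, dtype=np.int64)
    sizes = {}
    nxt = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and labels[r, c] == 0:
                nxt += 1
                labels[r, c] = nxt
                q = deque([(r, c)])
                count = 0
                while q:
                    rr, cc = q.popleft()
                    count += 1
                    for dr, dc in nbrs:
                        ar, ac = rr + dr, cc + dc
                        if (
                            0 <= ar < mask.shape[0]
                            and 0 <= ac < mask.shape[1]
                            and mask[ar, ac]
                            and labels[ar, ac] == 0
                        ):
                            labels[ar, ac] = nxt
                            q.append((ar, ac))
                sizes[nxt] = count
    return labels, sizes


def brute_confusion(pred: np.ndarray, ref: np.ndarray):
    """Per-pixel double-loop confusion counts (tp, tn, fp, fn)."""
    tp = tn = fp = fn = 0
    for r in range(pred.shape[0]):
        for c in range(pred.shape[1]):
            p, g = pred[r, c], ref[r, c]
            if p and g:
                tp += 1
            elif p and not g:
                fp += 1
            elif not p and g:
                fn += 1
            else:
                tn += 1
    return tp, tn, fp, fn


def _border_pixels(mask: np.ndarray):
    pts = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ar, ac = r + dr, c + dc
                if not (0 <= ar < h and 0 <= ac < w) or not mask[ar, ac]:
                    pts.append((r, c))
                    break
    return pts


def brute_surface_distances(pred: np.ndarray, ref: np.ndarray, spacing=(1.0, 1.0)):
    """All-pairs symmetric surface distances -> (asd, rmsd, msd)."""
    bp = _border_pixels(pred)
    br = _border_pixels(ref)
    sr, sc = spacing
    pooled = []
    for src, dst in ((bp, br), (br, bp)):
        for r, c in src:
            best = math.inf
            for r2, c2 in dst:
                d = math.hypot((r - r2) * sr, (c - c2) * sc)
                if d < best:
                    best = d
            pooled.append(best)
    arr = np.asarray(pooled)
    return float(arr.mean()), float(np.sqrt((arr**2).mean())), float(arr.max())
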