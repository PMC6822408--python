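"""Brute-force reference implementations used only as test oracles.

Each function recomputes an operation by direct per-pixel definition,
independently of the library's vectorised/scipy-based code paths.
"""

from __future__ import annotations

import numpy as np


def flood_fill_label(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label connected components by explicit breadth-first flood fill."""
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    labels = np.zeros((H, W), dtype=int)
    current = 0
    for si in range(H):
        for sj in range(W):
            if mask[si, sj] and labels[si, sj] == 0:
                current += 1
                stack = [(si, sj)]
                labels[si, sj] = current
                while stack:
                    i, j = stack.pop()
                    for di, dj in nbrs:
                        ni, nj = i + di, j + dj
                        if 0 <= ni < H and 0 <= nj < W and mask[ni, nj] and labels[ni, nj] == 0:
                            labels[ni, nj] = current
                            stack.append((ni, nj))
    return labels


def component_areas(mask: np.ndarray, connectivity: int = 8) -> list[int]:
    labels = flood_fill_label(mask, connectivity)
    return [int((labels == k).sum()) for k in range(1, labels.max() + 1)]


def area_filter(mask: np.ndarray, min_area: int, connectivity: int = 8) -> np.ndarray:
    """Keep components with area >= min_area (flood-fill oracle)."""
    labels = flood_fill_label(mask, connectivity)
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    for k in range(1, labels.max() + 1):
        comp = labels == k
        if comp.sum() >= min_area:
            out |= comp
    return out


def min_filter_erode(mask: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Per-pixel erosion: pixel survives iff the element fits inside the
    foreground (out-of-image treated as background)."""
    mask = np.asarray(mask, dtype=bool)
    r = element.shape[0] // 2
    padded = np.pad(mask, r, constant_values=False)
    out = np.zeros_like(mask)
    H, W = mask.shape
    for i in range(H):
        for j in range(W):
            window = padded[i : i + 2 * r + 1, j : j + 2 * r + 1]
            out[i, j] = bool(window[element].all())
    return out


def max_filter_dilate(mask: np.ndarray, element: np.ndarray) -> np.ndarray:
    """Per-pixel dilation by the (symmetric) element."""
    mask = np.asarray(mask, dtype=bool)
    r = element.shape[0] // 2
    padded = np.pad(mask, r, constant_values=False)
    out = np.zeros_like(mask)
    H, W = mask.shape
    for i in range(H):
        for j in range(W):
            window = padded[i : i + 2 * r + 1, j : j + 2 * r + 1]
            out[i, j] = bool(window[element].any())
    return out


def neighbor_scan_contour(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with >= 1 background 4-neighbour (border = bg)."""
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    out = np.zeros_like(mask)
    for i in range(H):
        for j in range(W):
            if not mask[i, j]:
                continue
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < H and 0 <= nj < W) or not mask[ni, nj]:
                    out[i, j] = True
                    break
    return out


def exhaustive_otsu(gray: np.ndarray) -> int:
    """Threshold by explicit search over all 256 candidate levels,
    maximising between-class variance; ties take the lowest level."""
    gray = np.asarray(gray).astype(np.uint8).ravel()
    n = gray.size
    best_t, best_var = 0, -1.0
    for t in range(256):
        lo = gray[gray <= t]
        hi = gray[gray > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / n, hi.size / n
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


def normal_equation_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Solve least squares through the explicit normal equations."""
    Xd = np.column_stack([X, np.ones(len(X))])
    return np.linalg.solve(Xd.T @ Xd, Xd.T @ y)


def zhang_suen_thin(mask: np.ndarray) -> np.ndarray:
    """Reference Zhang-Suen iterative thinning."""
    m = np.pad(np.asarray(mask, dtype=np.uint8), 1)

    def neighbours(i: int, j: int) -> list[int]:
        return [m[i - 1, j], m[i - 1, j + 1], m[i, j + 1], m[i + 1, j + 1],
                m[i + 1, j], m[i + 1, j - 1], m[i, j - 1], m[i - 1, j - 1]]

    changed = True
    while changed:
        changed = False
        for step in (0, 1):
            to_remove = []
            for i in range(1, m.shape[0] - 1):
                for j in range(1, m.shape[1] - 1):
                    if not m[i, j]:
                        continue
                    P = neighbours(i, j)
                    if not 2 <= sum(P) <= 6:
                        continue
                    transitions = sum(
                        1 for k in range(8) if P[k] == 0 and P[(k + 1) % 8] == 1
                    )
                    if transitions != 1:
                        continue
                    p2, _, p4, _, p6, _, p8, _ = P
                    if step == 0:
                        if p2 * p4 * p6 == 0 and p4 * p6 * p8 == 0:
                            to_remove.append((i, j))
                    elif p2 * p4 * p8 == 0 and p2 * p6 * p8 == 0:
                        to_remove.append((i, j))
            for ij in to_remove:
                m[ij] = 0
            changed = changed or bool(to_remove)
    return m[1:-1, 1:-1].astype(bool)
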