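"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by direct enumeration or a
different algorithm than the implementation under test.
"""

from __future__ import annotations

import heapq

import numpy as np

SQRT2 = float(np.sqrt(2.0))
NEIGHBORS = [
    (-1, -1, SQRT2), (-1, 0, 1.0), (-1, 1, SQRT2),
    (0, -1, 1.0), (0, 1, 1.0),
    (1, -1, SQRT2), (1, 0, 1.0), (1, 1, SQRT2),
]


def dijkstra_propagate(seed_lab: np.ndarray, guide: np.ndarray, lam: float,
                       foreground: np.ndarray | None = None) -> np.ndarray:
    """Heap-based multi-source Dijkstra with lexicographic (cost, label) order.

    Seed pixels are frozen at their own label; ties in accumulated cost go
    to the lower seed label.
    """
    H, W = seed_lab.shape
    fg = np.ones((H, W), bool) if foreground is None else (foreground | (seed_lab > 0))
    dist = np.full((H, W), np.inf)
    label = np.zeros((H, W), np.int32)
    is_seed = seed_lab > 0
    heap = []
    for r, c in np.argwhere(is_seed):
        dist[r, c] = 0.0
        label[r, c] = seed_lab[r, c]
        heapq.heappush(heap, (0.0, int(seed_lab[r, c]), int(r), int(c)))
    while heap:
        d, l, r, c = heapq.heappop(heap)
        if (d, l) != (dist[r, c], label[r, c]):
            continue  # stale entry
        for dr, dc, s in NEIGHBORS:
            q_r, q_c = r + dr, c + dc
            if not (0 <= q_r < H and 0 <= q_c < W) or not fg[q_r, q_c]:
                continue
            if is_seed[q_r, q_c]:
                continue
            nd = d + np.sqrt((guide[r, c] - guide[q_r, q_c]) ** 2 + (lam * s) ** 2)
            if nd < dist[q_r, q_c] or (nd == dist[q_r, q_c] and l < label[q_r, q_c]):
                dist[q_r, q_c] = nd
                label[q_r, q_c] = l
                heapq.heappush(heap, (nd, l, q_r, q_c))
    label[~fg] = 0
    return label


def brute_force_opening(img: np.ndarray, selem: np.ndarray) -> np.ndarray:
    """Grey erosion then dilation by explicit min/max over SE offsets."""
    offsets = np.argwhere(selem) - np.array(selem.shape) // 2

    def _apply(arr, fn):
        H, W = arr.shape
        pad = int(np.abs(offsets).max())
        padded = np.pad(arr, pad, mode="reflect")
        stack = np.stack(
            [padded[pad + dr: pad + dr + H, pad + dc: pad + dc + W] for dr, dc in offsets]
        )
        return fn(stack, axis=0)

    return _apply(_apply(img, np.min), np.max)


def brute_force_tophat(img: np.ndarray, selem: np.ndarray) -> np.ndarray:
    return img - brute_force_opening(img, selem)


def exhaustive_otsu(img: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold by exhaustive between-class-variance scan."""
    hist, edges = np.histogram(img.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    best_t, best_v = centers[0], -1.0
    total = hist.sum()
    for k in range(1, nbins):
        w0 = hist[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:k] * centers[:k]).sum() / w0
        mu1 = (hist[k:] * centers[k:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, (centers[k - 1] + centers[k]) / 2
    return float(best_t)


def all_pairs_feret(coords: np.ndarray) -> float:
    """Exact max pairwise pixel-center distance over every pixel pair."""
    pts = np.asarray(coords, float)
    if len(pts) < 2:
        return 0.0
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def enumerate_expansion(labels: np.ndarray, n_px: int) -> np.ndarray:
    """Nearest-label assignment by direct enumeration; ties to lower label."""
    out = labels.copy()
    fg = np.argwhere(labels > 0)
    if not len(fg) or n_px == 0:
        return out
    fg_labels = labels[labels > 0]
    for r, c in np.argwhere(labels == 0):
        d2 = (fg[:, 0] - r) ** 2 + (fg[:, 1] - c) ** 2
        m = d2.min()
        if m <= n_px * n_px:
            out[r, c] = fg_labels[d2 == m].min()
    return out


def boundary_pixels(labels: np.ndarray) -> np.ndarray:
    """Label pixels with an 8-neighbor of different value (incl. off-image)."""
    H, W = labels.shape
    out = np.zeros((H, W), bool)
    for r in range(H):
        for c in range(W):
            if labels[r, c] == 0:
                continue
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < H and 0 <= cc < W) or labels[rr, cc] != labels[r, c]:
                        out[r, c] = True
    return out
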