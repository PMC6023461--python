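"""Independent brute-force oracles used to cross-check the implementation.

Each oracle evaluates the mathematical definition directly (per-pixel
loops, exhaustive search, flood fill, direct accumulation) without
sharing code with the package internals.
"""

from collections import deque

import numpy as np


def opening_subtract_oracle(image: np.ndarray, radius: int) -> np.ndarray:
    """Rolling-ball subtraction by direct erosion-then-dilation.

    Evaluates min/max over the ball structuring element pixel by pixel in
    float32 (the arithmetic precision of the production path), treating
    pixels outside the image as +/- infinity.
    """
    img = np.asarray(image, np.float32)
    H, W = img.shape
    offs = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            d2 = dy * dy + dx * dx
            if d2 <= radius * radius:
                offs.append((dy, dx, np.float32(np.sqrt(np.float32(radius * radius - d2)))))
    eroded = np.empty_like(img)
    for r in range(H):
        for c in range(W):
            best = np.float32(np.inf)
            for dy, dx, h in offs:
                rr, cc = r + dy, c + dx
                if 0 <= rr < H and 0 <= cc < W:
                    v = img[rr, cc] - h
                    if v < best:
                        best = v
            eroded[r, c] = best
    opened = np.empty_like(img)
    for r in range(H):
        for c in range(W):
            best = np.float32(-np.inf)
            for dy, dx, h in offs:
                rr, cc = r - dy, c - dx
                if 0 <= rr < H and 0 <= cc < W:
                    v = eroded[rr, cc] + h
                    if v > best:
                        best = v
            opened[r, c] = best
    return np.maximum(img - opened, np.float32(0.0))


def otsu_partition_oracle(image: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Foreground mask by exhaustive search over all histogram cut points,
    minimizing the within-class variance of the binned values."""
    img = np.asarray(image, float).ravel()
    lo, hi = img.min(), img.max()
    counts, edges = np.histogram(img, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    bins = np.clip(np.digitize(img, edges[1:-1]), 0, nbins - 1)
    best_cut, best_within = None, np.inf
    for cut in range(nbins - 1):  # background bins 0..cut
        w0 = counts[: cut + 1].sum()
        w1 = counts[cut + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        c0, c1 = centers[: cut + 1], centers[cut + 1 :]
        n0, n1 = counts[: cut + 1], counts[cut + 1 :]
        mu0 = (n0 * c0).sum() / w0
        mu1 = (n1 * c1).sum() / w1
        var0 = (n0 * (c0 - mu0) ** 2).sum() / w0
        var1 = (n1 * (c1 - mu1) ** 2).sum() / w1
        within = (w0 * var0 + w1 * var1) / (w0 + w1)
        if within < best_within:
            best_within, best_cut = within, cut
    return (bins > best_cut).reshape(np.asarray(image).shape)


def flood_fill_label_oracle(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Connected-component labelling by breadth-first flood fill."""
    mask = np.asarray(mask, bool)
    H, W = mask.shape
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    out = np.zeros((H, W), int)
    nxt = 0
    for r0 in range(H):
        for c0 in range(W):
            if mask[r0, c0] and out[r0, c0] == 0:
                nxt += 1
                queue = deque([(r0, c0)])
                out[r0, c0] = nxt
                while queue:
                    r, c = queue.popleft()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < H and 0 <= cc < W and mask[rr, cc] and out[rr, cc] == 0:
                            out[rr, cc] = nxt
                            queue.append((rr, cc))
    return out


def sliding_mean_oracle(image: np.ndarray, window: int) -> np.ndarray:
    """Windowed mean with symmetric-reflect padding, by direct summation."""
    img = np.asarray(image, float)
    half = window // 2
    pad = np.pad(img, half, mode="symmetric")
    out = np.empty_like(img)
    H, W = img.shape
    for r in range(H):
        for c in range(W):
            out[r, c] = pad[r : r + window, c : c + window].mean()
    return out


def ring_owner_oracle(labels: np.ndarray, width: int) -> np.ndarray:
    """Perinuclear ring map by per-pixel evaluation of the definition:
    pixel belongs to the ring of the label whose footprint is within
    chessboard distance ``width`` and whose centroid is nearest."""
    labels = np.asarray(labels)
    H, W = labels.shape
    K = int(labels.max())
    cents = {}
    for k in range(1, K + 1):
        rr, cc = np.nonzero(labels == k)
        if len(rr):
            cents[k] = (rr.mean(), cc.mean())
    out = np.zeros_like(labels)
    for r in range(H):
        for c in range(W):
            if labels[r, c] != 0:
                continue
            best_k, best_d = 0, np.inf
            for k, (cr, cc_) in cents.items():
                r0, r1 = max(r - width, 0), min(r + width + 1, H)
                c0, c1 = max(c - width, 0), min(c + width + 1, W)
                if np.any(labels[r0:r1, c0:c1] == k):
                    d = (r - cr) ** 2 + (c - cc_) ** 2
                    if d < best_d:
                        best_d, best_k = d, k
            out[r, c] = best_k
    return out


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff two label maps induce the same partition of the foreground
    (identical up to label renumbering)."""
    a, b = np.asarray(a), np.asarray(b)
    if (a > 0).sum() != (b > 0).sum() or not np.array_equal(a > 0, b > 0):
        return False
    pairs = set(zip(a[a > 0].ravel(), b[b > 0].ravel()))
    return len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})
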