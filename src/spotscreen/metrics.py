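"""Detection and classification quality metrics against generator truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["match_centroids", "detection_scores", "class_recall"]


def match_centroids(
    labels: np.ndarray, centroids: np.ndarray, tolerance: int = 0
) -> np.ndarray:
    """Label hit by each true centroid (0 = unmatched).

    A centroid matches the component whose footprint contains it; with
    ``tolerance`` > 0, a centroid falling on background is assigned the
    nearest non-zero label within a (2*tol+1)^2 neighbourhood.
    """
    labels = np.asarray(labels)
    H, W = labels.shape
    out = np.zeros(len(centroids), dtype=int)
    for i, (r, c) in enumerate(np.asarray(centroids, float)):
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < H and 0 <= ci < W):
            continue
        lab = labels[ri, ci]
        if lab == 0 and tolerance > 0:
            r0, r1 = max(ri - tolerance, 0), min(ri + tolerance + 1, H)
            c0, c1 = max(ci - tolerance, 0), min(ci + tolerance + 1, W)
            win = labels[r0:r1, c0:c1]
            nz = win[win > 0]
            if len(nz):
                rr, cc = np.nonzero(win > 0)
                d2 = (rr + r0 - r) ** 2 + (cc + c0 - c) ** 2
                lab = win[rr[np.argmin(d2)], cc[np.argmin(d2)]]
        out[i] = lab
    return out


def detection_scores(
    labels: np.ndarray, centroids: np.ndarray
) -> tuple[float, float]:
    """(recall, precision) of nucleus detection.

    Recall: fraction of true centroids lying inside some footprint.
    Precision: fraction of detected components hit by >= 1 true centroid.
    """
    n_true = len(centroids)
    n_det = int(labels.max())
    if n_true == 0:
        return (float("nan"), 1.0 if n_det == 0 else 0.0)
    matched = match_centroids(labels, centroids)
    recall = float(np.sum(matched > 0)) / n_true
    precision = len(np.unique(matched[matched > 0])) / n_det if n_det else float("nan")
    return recall, precision


def class_recall(true_classes: pd.Series, predicted: pd.Series) -> dict[str, float]:
    """Per-class recall of phenotype classification on matched nuclei."""
    out = {}
    t = np.asarray(true_classes, dtype=object)
    p = np.asarray(predicted, dtype=object)
    for c in np.unique(t):
        sel = t == c
        out[str(c)] = float(np.mean(p[sel] == c)) if sel.any() else float("nan")
    return out
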