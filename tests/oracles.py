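"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: plain-loop Lloyd
iteration over raw pixels, pixel enumeration for disc centroids, and
exhaustive multiset search for ordinal score summaries.
"""

from __future__ import annotations

import numpy as np


def brute_force_lloyd(pixels: np.ndarray, centers0: np.ndarray,
                      max_iter: int = 300):
    """Plain Lloyd iteration on raw pixel rows until assignments stabilise.

    Returns (means, labels, inertia). Empty clusters keep their previous
    center. Independent of the package's sklearn-backed weighted route.
    """
    pixels = np.asarray(pixels, dtype=float)
    centers = np.array(centers0, dtype=float, copy=True)
    k = len(centers)
    labels = np.full(len(pixels), -1)
    for _ in range(max_iter):
        d2 = ((pixels[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            member = pixels[labels == j]
            if len(member):
                centers[j] = member.mean(axis=0)
    inertia = float(((pixels - centers[labels]) ** 2).sum())
    return centers, labels, inertia


def disc_pixel_centroid(cx: float, cy: float, radius: float):
    """Centroid of all integer pixels inside a disc, by direct enumeration."""
    xs, ys = [], []
    for y in range(int(np.floor(cy - radius)) - 1, int(np.ceil(cy + radius)) + 2):
        for x in range(int(np.floor(cx - radius)) - 1, int(np.ceil(cx + radius)) + 2):
            if (x - cx) ** 2 + (y - cy) ** 2 <= radius ** 2:
                xs.append(x)
                ys.append(y)
    return float(np.mean(xs)), float(np.mean(ys)), len(xs)
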