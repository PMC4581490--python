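"""Independent reference implementations used only to check the package.

These deliberately recompute everything the slow, obvious way: the UPGMA
oracle re-derives every cluster-cluster distance as the mean over leaf pairs
of the original matrix at every step, and pixel membership is decided by
shapely rather than the package's own point-in-polygon path.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Point, Polygon


def brute_force_upgma(dist: np.ndarray) -> list:
    """Average-linkage merge sequence recomputed from leaf distances each step.

    Node ids follow creation order (leaves 0..n-1, merge m creates n+m); ties
    resolve to the lexicographically smallest (id_a, id_b) pair.  Returns
    [(a, b, height, size), ...].
    """
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    for m in range(n - 1):
        best = None
        ids = sorted(clusters)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                d = np.mean([dist[x, y] for x in clusters[a] for y in clusters[b]])
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        new = n + m
        clusters[new] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, float(d), len(clusters[new])))
    return merges


def pixels_in_quad(quad: np.ndarray, image_shape: tuple) -> list:
    """(row, col) of every pixel whose center lies inside the quad (shapely)."""
    poly = Polygon(quad)
    h, w = image_shape
    x0 = max(int(np.floor(quad[:, 0].min())) - 1, 0)
    x1 = min(int(np.ceil(quad[:, 0].max())) + 1, w - 1)
    y0 = max(int(np.floor(quad[:, 1].min())) - 1, 0)
    y1 = min(int(np.ceil(quad[:, 1].max())) + 1, h - 1)
    out = []
    for y in range(y0, y1 + 1):
        for x in range(x0, x1 + 1):
            if poly.contains(Point(x, y)):
                out.append((y, x))
    return out


def rasterized_band_area(inner: np.ndarray, outer: np.ndarray, step: float = 0.25) -> float:
    """Area between two index-paired polylines by fine-grid point counting."""
    ring = np.vstack([inner, outer[::-1]])
    poly = Polygon(ring)
    xmin, ymin, xmax, ymax = poly.bounds
    xs = np.arange(xmin, xmax + step, step)
    ys = np.arange(ymin, ymax + step, step)
    count = 0
    for y in ys:
        for x in xs:
            if poly.contains(Point(x, y)):
                count += 1
    return count * step * step
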