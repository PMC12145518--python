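"""Ground-truth heatmap construction and local peak detection.

Each annotated papilla center contributes a unit-peak isotropic Gaussian
``exp(-d^2 / (2 sigma^2))``; contributions are combined pixelwise (maximum
by default) so the regression target stays in [0, 1] even where papillae
crowd together. Peak detection is the inverse operation: local maxima of a
continuous map under a square neighborhood, thresholded relative to the map
maximum with an absolute floor, reported at integer grid positions with a
deterministic (row, then col) tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import Heatmap, PointSet
from .errors import ValidationError


@dataclass
class HeatmapConfig:
    """Parameters of target construction and peak extraction.

    sigma
        Gaussian kernel width in px. Default 3 at the standard 250x250
        working resolution, matching the apparent papilla radius there.
    combine_mode
        'max' (default) keeps targets bounded under overlap; 'sum' gives an
        additive density map, clipped back to [0, 1].
    peak_min_distance
        Half-width of the square local-maximum neighborhood; also the
        suppression radius between reported peaks.
    peak_threshold_rel
        Fraction of the map maximum below which maxima are discarded.
    peak_threshold_abs
        Absolute floor that suppresses noise peaks on near-empty maps.
    """

    sigma: float = 3.0
    combine_mode: str = "max"
    peak_min_distance: int = 3
    peak_threshold_rel: float = 0.2
    peak_threshold_abs: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        if self.combine_mode not in ("max", "sum"):
            raise ValidationError("combine_mode must be 'max' or 'sum'")
        if self.peak_min_distance < 1:
            raise ValidationError("peak_min_distance must be >= 1")
        if not 0 < self.peak_threshold_rel < 1:
            raise ValidationError("peak_threshold_rel must be in (0, 1)")


def points_to_heatmap(
    points: PointSet, shape: tuple[int, int], config: HeatmapConfig
) -> Heatmap:
    """Render point annotations into a continuous target map.

    Each point places ``exp(-d^2/(2 sigma^2))`` with unit peak at its
    (possibly sub-pixel) position; kernels are truncated at 4 sigma.
    Permutation-invariant in the input points.
    """
    rows, cols = int(shape[0]), int(shape[1])
    if rows < 1 or cols < 1:
        raise ValidationError(f"empty heatmap shape {shape}")
    out = np.zeros((rows, cols), dtype=np.float64)
    sigma = config.sigma
    halo = int(np.ceil(4 * sigma))
    for r, c in points:
        r0, r1 = max(0, int(np.floor(r)) - halo), min(rows, int(np.ceil(r)) + halo + 1)
        c0, c1 = max(0, int(np.floor(c)) - halo), min(cols, int(np.ceil(c)) + halo + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rr = np.arange(r0, r1, dtype=np.float64)[:, None]
        cc = np.arange(c0, c1, dtype=np.float64)[None, :]
        g = np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * sigma * sigma))
        if config.combine_mode == "max":
            np.maximum(out[r0:r1, c0:c1], g, out=out[r0:r1, c0:c1])
        else:
            out[r0:r1, c0:c1] += g
    return Heatmap(np.clip(out, 0.0, 1.0).astype(np.float32))


def detect_peaks(heatmap: Heatmap, config: HeatmapConfig) -> PointSet:
    """Extract spot coordinates as thresholded local maxima.

    A pixel is a candidate when it equals the maximum of its
    ``(2 d + 1)``-square neighborhood (``d = peak_min_distance``) and its
    value reaches both ``peak_threshold_rel * max(map)`` and the absolute
    floor. Candidates are accepted in order of decreasing value (ties: by
    smaller row, then smaller col), suppressing any candidate within
    ``d`` (Chebyshev) of an already-accepted peak, so plateaus yield one
    peak each.
    """
    v = np.asarray(heatmap.values, dtype=np.float64)
    if v.size == 0 or v.max() <= 0:
        return PointSet(np.empty((0, 2)))
    d = config.peak_min_distance
    size = 2 * d + 1
    local_max = ndimage.maximum_filter(v, size=size, mode="constant", cval=-np.inf)
    thresh = max(config.peak_threshold_rel * v.max(), config.peak_threshold_abs)
    rows, cols = np.nonzero((v >= local_max) & (v >= thresh))
    if rows.size == 0:
        return PointSet(np.empty((0, 2)))
    order = np.lexsort((cols, rows, -v[rows, cols]))
    accepted: list[tuple[int, int]] = []
    for i in order:
        r, c = int(rows[i]), int(cols[i])
        if all(max(abs(r - ar), abs(c - ac)) > d for ar, ac in accepted):
            accepted.append((r, c))
    accepted.sort()
    return PointSet(np.asarray(accepted, dtype=np.float64))
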