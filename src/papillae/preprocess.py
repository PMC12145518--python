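"""Preprocessing chain: stain-ellipse detection, crop, resize, CLAHE.

A stained tongue photograph is reduced to the standard analysis frame in
four steps: (1) segment the blue-stained region and fit an ellipse to it,
(2) crop a square centered on the ellipse, (3) resize to the standard
working resolution (250 x 250 by default), and (4) apply Contrast Limited
Adaptive Histogram Equalization to enhance papilla visibility. Point
annotations ride along analytically through the recorded geometric
transforms — they are never resampled.

Ellipse detection is stain-color segmentation: pixels are projected onto a
stain-contrast axis (blue-dominance by default), thresholded with Otsu,
morphologically closed, and the largest connected component is summarized
by its second-order moments (for a filled ellipse the semi-axes are twice
the principal standard deviations). Orientation is the angle of the major
axis measured from the +col axis toward +row, normalized to [0, pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color, exposure, filters, measure, morphology, transform

from .core import (AnnotatedSample, GeometricTransform, ImageGrid, PointSet,
                   transform_points)
from .errors import DetectionError, StageError, ValidationError


@dataclass
class PreprocessConfig:
    """Knobs of the preprocessing chain.

    ``stain_channel_weights`` projects RGB onto a stain-contrast axis; the
    default (-0.5, -0.5, 1.0) measures blue dominance. ``clahe_clip_limit``
    follows the normalized convention of
    :func:`skimage.exposure.equalize_adapthist` (fraction, typical 0.01).
    """

    target_side: int = 250
    clahe_clip_limit: float = 0.01
    clahe_tile_grid: tuple[int, int] = (8, 8)
    clahe_on_luminance: bool = True
    stain_channel_weights: tuple[float, float, float] = (-0.5, -0.5, 1.0)
    crop_margin: float = 0.05
    min_component_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.target_side < 32:
            raise ValidationError("target_side must be >= 32")
        if self.clahe_clip_limit <= 0:
            raise ValidationError("clahe_clip_limit must be > 0")


@dataclass
class EllipseRegion:
    """Fitted stain ellipse: center (row, col), semi-axes a >= b > 0,
    major-axis orientation in radians within [0, pi)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if not (a >= b > 0):
            raise ValidationError("semi-axes must satisfy a >= b > 0")


def stain_mask(image: ImageGrid, config: PreprocessConfig) -> np.ndarray:
    """Binary mask of the largest stain-consistent component."""
    if image.channels != 3:
        raise ValidationError("stain detection needs a 3-channel image")
    w = np.asarray(config.stain_channel_weights, dtype=np.float64)
    proj = image.pixels.astype(np.float64) @ w
    thresh = filters.threshold_otsu(proj)
    mask = proj > thresh
    mask = morphology.closing(mask, morphology.disk(5))
    labels = measure.label(mask)
    if labels.max() == 0:
        raise DetectionError("no stain-consistent component found")
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < config.min_component_fraction * mask.size:
        raise DetectionError(
            f"largest stain component covers {sizes[best - 1] / mask.size:.2%}"
            f" of the image (< {config.min_component_fraction:.0%})")
    return labels == best


def detect_ellipse(image: ImageGrid, config: PreprocessConfig) -> EllipseRegion:
    """Fit an ellipse to the stained region from second-order moments."""
    mask = stain_mask(image, config)
    rr, cc = np.nonzero(mask)
    center = (float(rr.mean()), float(cc.mean()))
    cov = np.cov(np.stack([rr, cc]).astype(np.float64))
    evals, evecs = np.linalg.eigh(cov)
    # eigh returns ascending order: evals[1] is the major axis variance
    a = 2.0 * float(np.sqrt(max(evals[1], 1e-12)))
    b = 2.0 * float(np.sqrt(max(evals[0], 1e-12)))
    v = evecs[:, 1]  # (d_row, d_col) of the major axis
    theta = float(np.arctan2(v[0], v[1])) % np.pi
    return EllipseRegion(center=center, semi_axes=(a, b), orientation=theta)


def crop_square(
    image: ImageGrid, ellipse: EllipseRegion, margin: float = 0.05
) -> tuple[ImageGrid, GeometricTransform]:
    """Crop a square of side 2 (1+margin) max(a, b) centered on the ellipse.

    The window is clamped inside the image while staying square (shrunk to
    min(H, W) if necessary). Returns the crop and the point transform.
    """
    a, b = ellipse.semi_axes
    if a <= 0 or b <= 0:
        raise ValidationError("degenerate ellipse")
    h, w = image.shape
    side = int(round(2.0 * (1.0 + margin) * max(a, b)))
    side = max(1, min(side, h, w))
    r0 = int(round(ellipse.center[0] - side / 2.0))
    c0 = int(round(ellipse.center[1] - side / 2.0))
    r0 = min(max(r0, 0), h - side)
    c0 = min(max(c0, 0), w - side)
    crop = ImageGrid(image.pixels[r0:r0 + side, c0:c0 + side])
    t = GeometricTransform(crop_offset=(float(r0), float(c0)))
    return crop, t


def resize_to_standard(
    image: ImageGrid, config: PreprocessConfig
) -> tuple[ImageGrid, GeometricTransform]:
    """Bilinear resize of a square image to target_side x target_side."""
    h, w = image.shape
    if h != w:
        raise ValidationError(f"resize_to_standard needs a square input; got {h}x{w}")
    side = config.target_side
    if h == side:
        return image, GeometricTransform.identity()
    scale = side / h
    out = transform.resize(
        image.pixels, (side, side, image.channels), order=1,
        anti_aliasing=scale < 1, preserve_range=True, mode="reflect",
    ).astype(np.float32)
    return (ImageGrid(np.clip(out, 0, 1)),
            GeometricTransform(scale=(scale, scale)))


def clahe_normalize(image: ImageGrid, config: PreprocessConfig) -> ImageGrid:
    """CLAHE on the luminance channel (default) or per channel."""
    px = image.pixels.astype(np.float64)
    kernel = (max(1, image.height // config.clahe_tile_grid[0]),
              max(1, image.width // config.clahe_tile_grid[1]))
    if np.ptp(px) < 1e-9:
        return image  # constant image: flat histogram, nothing to equalize
    if image.channels == 3 and config.clahe_on_luminance:
        lab = color.rgb2lab(px)
        lum = lab[:, :, 0] / 100.0
        if np.ptp(lum) >= 1e-9:
            lab[:, :, 0] = exposure.equalize_adapthist(
                np.clip(lum, 0, 1), kernel_size=kernel,
                clip_limit=config.clahe_clip_limit) * 100.0
        out = color.lab2rgb(lab)
    else:
        out = np.empty_like(px)
        for ch in range(image.channels):
            band = px[:, :, ch]
            if np.ptp(band) < 1e-9:
                out[:, :, ch] = band
            else:
                out[:, :, ch] = exposure.equalize_adapthist(
                    band, kernel_size=kernel,
                    clip_limit=config.clahe_clip_limit)
    return ImageGrid(np.clip(out, 0, 1).astype(np.float32))


def preprocess_sample(
    raw: AnnotatedSample, config: PreprocessConfig | None = None
) -> AnnotatedSample:
    """Full chain: detect ellipse -> crop -> resize -> CLAHE.

    Annotations are mapped through the composed transform; points falling
    outside the crop are dropped and counted in ``meta['dropped_points']``.
    Stage failures re-raise as :class:`StageError` naming the stage.
    """
    config = config or PreprocessConfig()
    if raw.image.channels != 3:
        raise ValidationError("preprocess_sample needs a 3-channel image")

    def run(stage, fn):
        try:
            return fn()
        except (ValidationError, DetectionError) as exc:
            raise StageError(stage, exc) from exc

    ellipse = run("detect_ellipse", lambda: detect_ellipse(raw.image, config))
    cropped, t_crop = run("crop_square",
                          lambda: crop_square(raw.image, ellipse, config.crop_margin))
    resized, t_scale = run("resize_to_standard",
                           lambda: resize_to_standard(cropped, config))
    final = run("clahe_normalize", lambda: clahe_normalize(resized, config))

    pts, dropped_crop = transform_points(raw.annotations, t_crop, cropped.shape)
    pts, dropped_scale = transform_points(pts, t_scale, final.shape)
    return AnnotatedSample(
        image=final,
        annotations=pts,
        sample_id=raw.sample_id,
        transform_log=raw.transform_log + [t_crop, t_scale],
        meta={**raw.meta, "dropped_points": dropped_crop + dropped_scale,
              "ellipse": ellipse},
    )
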