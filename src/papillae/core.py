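"""Domain types, coordinate conventions, and file I/O.

Conventions used project-wide
-----------------------------
* Coordinates are ``(row, col)``, 0-based, with pixel centers at integer
  positions. All point coordinates are real-valued (sub-pixel annotations
  are accepted).
* Image intensities live in ``[0, 1]`` as float32, shape ``(H, W, C)`` with
  ``C`` in {1, 3}. Heatmaps are single-channel ``(H, W)`` float32 in [0, 1].
* Annotation files are CSV with a ``row,col`` header, or a JSON list of
  ``[row, col]`` pairs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import FormatError, PointParseError, ValidationError

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


@dataclass
class ImageGrid:
    """A 2-D image with 1 or 3 channels, intensities in [0, 1].

    ``pixels`` has shape (H, W, C), dtype float32.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3 or px.shape[2] not in (1, 3):
            raise ValidationError(
                f"image must be (H, W, 1|3); got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("image height and width must be >= 1")
        if not np.all(np.isfinite(px)):
            raise ValidationError("image contains non-finite values")
        if px.min() < -1e-6 or px.max() > 1 + 1e-6:
            raise ValidationError("image intensities must lie in [0, 1]")
        self.pixels = np.clip(px, 0.0, 1.0)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class PointSet:
    """An ordered set of real-valued (row, col) coordinates."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=np.float64)
        if c.size == 0:
            c = c.reshape(0, 2)
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValidationError(f"points must be (n, 2); got shape {c.shape}")
        if not np.all(np.isfinite(c)):
            raise ValidationError("point coordinates must be finite")
        self.coords = c

    @classmethod
    def from_list(cls, points: Sequence[Sequence[float]]) -> "PointSet":
        return cls(np.asarray(list(points), dtype=np.float64).reshape(-1, 2))

    def __len__(self) -> int:
        return self.coords.shape[0]

    def __iter__(self) -> Iterator[tuple[float, float]]:
        for r, c in self.coords:
            yield (float(r), float(c))

    def within_bounds(self, shape: tuple[int, int]) -> bool:
        if len(self) == 0:
            return True
        r, c = self.coords[:, 0], self.coords[:, 1]
        return bool(
            (r >= 0).all() and (c >= 0).all()
            and (r <= shape[0] - 1).all() and (c <= shape[1] - 1).all()
        )

    def min_separation(self) -> float:
        """Smallest pairwise Euclidean distance; inf for < 2 points."""
        if len(self) < 2:
            return float("inf")
        d = self.coords[:, None, :] - self.coords[None, :, :]
        dist = np.sqrt((d ** 2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        return float(dist.min())


@dataclass
class Heatmap:
    """Single-channel continuous map in [0, 1], shape (H, W) float32."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float32)
        if v.ndim != 2:
            raise ValidationError(f"heatmap must be 2-D; got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("heatmap contains non-finite values")
        if v.min() < -1e-6 or v.max() > 1 + 1e-6:
            raise ValidationError("heatmap values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GeometricTransform:
    """Crop-then-scale (or scale-then-crop) point mapping.

    With ``crop_then_scale=True`` a point ``p`` maps to
    ``(p - crop_offset) * scale``; with ``False`` to
    ``p * scale - crop_offset``. ``inverse()`` returns the exact inverse
    mapping in the opposite order.
    """

    crop_offset: tuple[float, float] = (0.0, 0.0)
    scale: tuple[float, float] = (1.0, 1.0)
    crop_then_scale: bool = True

    def __post_init__(self) -> None:
        if self.scale[0] <= 0 or self.scale[1] <= 0:
            raise ValidationError("scale factors must be positive")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=np.float64).reshape(-1, 2)
        off = np.asarray(self.crop_offset, dtype=np.float64)
        sc = np.asarray(self.scale, dtype=np.float64)
        if self.crop_then_scale:
            return (coords - off) * sc
        return coords * sc - off

    def inverse(self) -> "GeometricTransform":
        sr, sc = self.scale
        orr, oc = self.crop_offset
        if self.crop_then_scale:
            # q/scale + offset  ==  q * (1/s) - (-offset)
            return GeometricTransform(
                crop_offset=(-orr, -oc), scale=(1 / sr, 1 / sc),
                crop_then_scale=False,
            )
        return GeometricTransform(
            crop_offset=(-orr, -oc), scale=(1 / sr, 1 / sc),
            crop_then_scale=True,
        )

    @staticmethod
    def identity() -> "GeometricTransform":
        return GeometricTransform()


@dataclass
class AnnotatedSample:
    """An image paired with its papilla-center annotations."""

    image: ImageGrid
    annotations: PointSet
    sample_id: str = ""
    transform_log: list[GeometricTransform] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.annotations.within_bounds(self.image.shape):
            raise ValidationError(
                f"sample '{self.sample_id}': annotations out of image bounds"
            )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> ImageGrid:
    """Read a PNG/JPEG/TIFF image, rescaled to [0, 1].

    8-bit images divide by 255, 16-bit by 65535; float inputs are assumed
    already in [0, 1]. An alpha channel, if present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() not in _IMAGE_SUFFIXES:
        raise FormatError(f"unsupported image format: {path.suffix!r}")
    raw = iio.imread(path)
    if raw.ndim == 3 and raw.shape[2] == 4:
        raw = raw[:, :, :3]
    if raw.dtype == np.uint8:
        px = raw.astype(np.float32) / 255.0
    elif raw.dtype == np.uint16:
        px = raw.astype(np.float32) / 65535.0
    else:
        px = raw.astype(np.float32)
    return ImageGrid(px)


def write_image(path: str | Path, image: ImageGrid) -> None:
    """Write an image as 8-bit PNG/JPEG or 16-bit TIFF by suffix."""
    path = Path(path)
    px = image.pixels
    if px.shape[2] == 1:
        px = px[:, :, 0]
    if path.suffix.lower() in (".tif", ".tiff"):
        data = np.round(px * 65535.0).astype(np.uint16)
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, np.round(px * 255.0).astype(np.uint8))


def read_heatmap(path: str | Path) -> Heatmap:
    """Read a float TIFF heatmap."""
    return Heatmap(tifffile.imread(Path(path)).astype(np.float32))


def write_heatmap(path: str | Path, heatmap: Heatmap) -> None:
    """Persist a heatmap as 32-bit float TIFF (lossless)."""
    tifffile.imwrite(Path(path), heatmap.values.astype(np.float32))


def read_points(path: str | Path) -> PointSet:
    """Read annotations from CSV (``row,col`` header) or JSON.

    Order is preserved from the file. Malformed rows raise
    :class:`PointParseError` naming the line; negative coordinates raise
    :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        pts = [(float(p[0]), float(p[1])) for p in data]
    else:
        pts = []
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip().lower() for h in header[:2]] != ["row", "col"]:
                raise PointParseError(f"{path}: expected 'row,col' header")
            for lineno, row in enumerate(reader, start=2):
                if not row or all(not c.strip() for c in row):
                    continue
                try:
                    pts.append((float(row[0]), float(row[1])))
                except (ValueError, IndexError) as exc:
                    raise PointParseError(
                        f"{path}: malformed row at line {lineno}: {row!r}"
                    ) from exc
    arr = np.asarray(pts, dtype=np.float64).reshape(-1, 2)
    if arr.size and arr.min() < 0:
        raise ValidationError(f"{path}: negative coordinate in annotations")
    return PointSet(arr)


def write_points(path: str | Path, points: PointSet) -> None:
    """Write annotations as CSV (``row,col``) or JSON by suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps([[r, c] for r, c in points]))
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col"])
        for r, c in points:
            writer.writerow([repr(r), repr(c)])


def transform_points(
    points: PointSet,
    transform: GeometricTransform,
    bounds: tuple[int, int] | None = None,
) -> tuple[PointSet, int]:
    """Map points through a transform, dropping those that leave ``bounds``.

    Returns the mapped point set and the number of dropped points.
    Dropping is reported, never raised.
    """
    mapped = transform.apply(points.coords)
    if bounds is None or mapped.size == 0:
        return PointSet(mapped), 0
    r, c = mapped[:, 0], mapped[:, 1]
    keep = (r >= 0) & (c >= 0) & (r <= bounds[0] - 1) & (c <= bounds[1] - 1)
    return PointSet(mapped[keep]), int((~keep).sum())
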