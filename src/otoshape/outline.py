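"""Otolith outline extraction and resampling.

An otolith image is reduced to an ordered closed boundary (:class:`Outline`),
standardised to unit area, and resampled as equally spaced centroid-to-edge
radii (:class:`RadiiProfile`) — the input to the dyadic wavelet transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "Outline",
    "RadiiProfile",
    "OutlineError",
    "extract_outline",
    "area_centroid",
    "normalize_area",
    "sample_radii",
]


class OutlineError(ValueError):
    """Raised for degenerate or unusable outlines/images."""


@dataclass(frozen=True)
class Outline:
    """Closed planar boundary of one otolith.

    Parameters
    ----------
    points : (n, 2) ndarray
        Vertex coordinates in order; the closing edge from the last back to
        the first vertex is implicit (first point is not repeated).
    normalized : bool
        True once coordinates are centroid-centred and scaled to unit area.
    """

    points: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 32:
            raise OutlineError(
                f"outline needs >= 32 (x, y) points, got shape {pts.shape}"
            )
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class RadiiProfile:
    """Equally spaced centroid-to-boundary distances.

    ``radii[i]`` is the distance along the ray at angle ``2*pi*i/n`` measured
    counterclockwise from the positive x-axis, from ``centroid``.
    """

    radii: np.ndarray
    centroid: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        n = len(r)
        if n < 2 or (n & (n - 1)) != 0:
            raise ValueError(f"number of radii must be a power of two, got {n}")
        if not np.all(r > 0):
            raise ValueError("all radii must be positive")
        object.__setattr__(self, "radii", r)

    def __len__(self) -> int:
        return len(self.radii)

    @property
    def angles(self) -> np.ndarray:
        n = len(self.radii)
        return 2.0 * np.pi * np.arange(n) / n

    def to_outline(self) -> Outline:
        """Convert back to (x, y) vertices around the stored centroid."""
        th = self.angles
        cx, cy = self.centroid
        pts = np.column_stack(
            [cx + self.radii * np.cos(th), cy + self.radii * np.sin(th)]
        )
        return Outline(pts)


def _signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def extract_outline(image: np.ndarray, threshold: float | str = "otsu") -> Outline:
    """Extract the closed boundary of the largest foreground object.

    The image is binarised (Otsu by default), the largest connected
    component is selected, and its boundary is traced as a subpixel contour.
    Coordinates are returned in mathematical convention: x to the right,
    y upward (the raster row axis is flipped), ordered counterclockwise.

    Parameters
    ----------
    image : 2-D ndarray
        Greyscale or binary raster, one otolith per image.
    threshold : float or "otsu"
        Intensity threshold; foreground is ``image > threshold``.

    Raises
    ------
    OutlineError
        If no foreground object >= 100 px exists, or the object touches the
        image border (its outline would be clipped).
    """
    img = np.asarray(image)
    if img.ndim == 3:  # RGB(A): luminance
        img = img[..., :3].mean(axis=-1)
    img = img.astype(float)
    if threshold == "otsu":
        if img.min() == img.max():
            raise OutlineError("image is constant: no object found")
        thr = float(threshold_otsu(img))
    else:
        thr = float(threshold)
    mask = img > thr
    if not mask.any():
        raise OutlineError("no foreground object found after thresholding")

    labels = measure.label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    lab = int(sizes.argmax())
    if sizes[lab] < 100:
        raise OutlineError(
            f"largest foreground component has {sizes[lab]} px (< 100 px)"
        )
    obj = labels == lab
    rows, cols = np.nonzero(obj)
    h, w = obj.shape
    if rows.min() == 0 or cols.min() == 0 or rows.max() == h - 1 or cols.max() == w - 1:
        raise OutlineError("object touches the image border; outline is clipped")

    contours = measure.find_contours(obj.astype(float), 0.5)
    contour = max(contours, key=len)
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    # (row, col) -> (x, y) with y up
    pts = np.column_stack([contour[:, 1], (h - 1) - contour[:, 0]])
    if _signed_area(pts) < 0:
        pts = pts[::-1]
    return Outline(pts)


def area_centroid(o: Outline) -> tuple[float, tuple[float, float]]:
    """Shoelace area (positive) and polygon centroid of an outline."""
    pts = o.points
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * float(np.sum(cross))
    if abs(a) < 1e-12:
        raise OutlineError("degenerate outline: zero area")
    cx = float(np.sum((x + xn) * cross) / (6.0 * a))
    cy = float(np.sum((y + yn) * cross) / (6.0 * a))
    return abs(a), (cx, cy)


def normalize_area(o: Outline) -> Outline:
    """Standardise to unit area: centre on the centroid, divide by sqrt(area)."""
    a, (cx, cy) = area_centroid(o)
    pts = (o.points - np.array([cx, cy])) / np.sqrt(a)
    return replace(o, points=pts, normalized=True)


def _point_in_polygon(pts: np.ndarray, p: np.ndarray) -> bool:
    x, y = pts[:, 0] - p[0], pts[:, 1] - p[1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    # ray casting along +x
    crosses = ((y > 0) != (yn > 0)) & (x - y * (xn - x) / (yn - y) > 0)
    return bool(np.count_nonzero(crosses) % 2)


def sample_radii(
    o: Outline, n: int = 512, center: tuple[float, float] | None = None
) -> RadiiProfile:
    """Sample the outline as `n` equally spaced radii from its centroid.

    Rays are cast at angles ``2*pi*i/n`` counterclockwise from the positive
    x-axis. For a star-shaped outline each ray crosses the boundary once;
    if a ray crosses several times the farthest crossing is kept and a
    warning is issued (the outline is not star-shaped about its centroid).
    ``center`` overrides the polygon centroid as ray origin.
    """
    if n < 16 or (n & (n - 1)) != 0:
        raise ValueError(f"n must be a power of two >= 16, got {n}")
    if center is None:
        _, (cx, cy) = area_centroid(o)
    else:
        cx, cy = map(float, center)
    c = np.array([cx, cy])
    if not _point_in_polygon(o.points, c):
        raise OutlineError("centroid lies outside the outline; cannot sample radii")

    p = o.points - c
    q = np.roll(p, -1, axis=0)
    d = q - p
    radii = np.empty(n)
    multi = False
    for i in range(n):
        th = 2.0 * np.pi * i / n
        dx, dy = np.cos(th), np.sin(th)
        # Solve p + t*d = s*(dx,dy), t in [0,1), s > 0
        denom = d[:, 0] * dy - d[:, 1] * dx
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (p[:, 1] * dx - p[:, 0] * dy) / denom
            s = np.where(
                np.abs(dx) > np.abs(dy),
                (p[:, 0] + t * d[:, 0]) / dx,
                (p[:, 1] + t * d[:, 1]) / dy,
            )
        # tolerance admits rays passing exactly through a vertex (the hit
        # then registers on both adjacent edges at the same distance)
        ok = (np.abs(denom) > 1e-300) & (t >= -1e-9) & (t <= 1.0 + 1e-9) & (s > 0.0)
        hits = s[ok]
        if hits.size == 0:
            raise OutlineError(f"ray at angle {th:.4f} does not cross the outline")
        if hits.size > 1 and np.ptp(hits) > 1e-9 * hits.max():
            multi = True
        radii[i] = hits.max()
    if multi:
        warnings.warn(
            "outline is not star-shaped about its centroid; "
            "farthest ray crossings kept",
            stacklevel=2,
        )
    return RadiiProfile(radii, centroid=(cx, cy))
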