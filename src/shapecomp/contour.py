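"""Closed 2D contours: I/O, canonicalization, resampling, rasterization.

A :class:`Contour` is an ordered list of (x, y) vertices of a closed
polygon.  The closing edge (last vertex back to the first) is implicit:
the first vertex is never duplicated at the end.  The canonical form used
throughout the package is

* a fixed number of vertices (default 384), equally spaced in arc length,
* coordinates normalized to [0, 1] with ``min x = min y = 0``, scaled by a
  single joint maximum so the aspect ratio is preserved,
* counter-clockwise orientation,
* the first vertex at the leftmost point of the outline (ties between
  equally-leftmost vertices broken by a seeded random draw, so that
  start-dependent descriptors are reproducible).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from PIL import Image
from skimage import draw as _skdraw
from skimage import measure as _skmeasure

from .errors import (
    AmbiguousInputError,
    DegenerateShapeError,
    InvalidInputError,
)

DEFAULT_N_POINTS = 384
DEFAULT_GRID = 256

__all__ = [
    "Contour",
    "BinaryMask",
    "load_contour",
    "save_contour",
    "resample_uniform",
    "normalize_coords",
    "canonicalize_start",
    "canonicalize",
    "ensure_ccw",
    "rasterize",
    "trace_mask",
    "signed_area",
    "polygon_area",
    "perimeter",
    "polygon_moments",
    "is_simple",
]


@dataclass(frozen=True)
class Contour:
    """An ordered closed polygon; the last->first edge is implicit."""

    points: np.ndarray  # (N, 2) float64
    meta: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidInputError(f"points must be (N, 2), got {pts.shape}")
        if len(pts) < 3:
            raise InvalidInputError(f"a contour needs >= 3 points, got {len(pts)}")
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("contour contains non-finite coordinates")
        nxt = np.roll(pts, -1, axis=0)
        if np.any(np.all(pts == nxt, axis=1)):
            pts = _dedupe_consecutive(pts)
            if len(pts) < 3:
                raise InvalidInputError("contour degenerate after removing duplicate points")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass(frozen=True)
class BinaryMask:
    """Rasterized silhouette on a square grid covering the unit square."""

    grid: np.ndarray  # (H, W) bool; row 0 = y in [0, 1/H)
    resolution: int  # pixels per unit of normalized coordinate
    self_intersecting: bool = False

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=bool)
        if g.ndim != 2 or min(g.shape) < 8:
            raise InvalidInputError("mask must be 2-D with H, W >= 8")
        g.setflags(write=False)
        object.__setattr__(self, "grid", g)

    @property
    def area_fraction(self) -> float:
        return float(self.grid.mean())


def _dedupe_consecutive(pts: np.ndarray) -> np.ndarray:
    keep = np.any(pts != np.roll(pts, 1, axis=0), axis=1)
    return np.array(pts[keep], dtype=np.float64)


# ---------------------------------------------------------------------------
# basic polygon geometry


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area; positive for counter-clockwise traversal."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(points: np.ndarray) -> float:
    return abs(signed_area(points))


def perimeter(points: np.ndarray) -> float:
    d = np.roll(points, -1, axis=0) - points
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def polygon_moments(points: np.ndarray) -> dict[str, float]:
    """Area, centroid, and second-order central moments of a filled polygon.

    Uses the exact Green's-theorem formulas, so values do not depend on
    vertex density.  Moments are reported for CCW orientation regardless of
    input direction.
    """
    x, y = points[:, 0], points[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-14:
        raise DegenerateShapeError("polygon has (near-)zero area")
    cx = np.sum((x + x1) * cross) / (6.0 * a)
    cy = np.sum((y + y1) * cross) / (6.0 * a)
    # second moments about the origin
    ixx = np.sum((y * y + y * y1 + y1 * y1) * cross) / 12.0
    iyy = np.sum((x * x + x * x1 + x1 * x1) * cross) / 12.0
    ixy = np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross) / 24.0
    sign = 1.0 if a > 0 else -1.0
    a_abs = abs(a)
    mu20 = sign * iyy - a_abs * cx * cx
    mu02 = sign * ixx - a_abs * cy * cy
    mu11 = sign * ixy - a_abs * cx * cy
    return {
        "area": a_abs,
        "cx": float(cx),
        "cy": float(cy),
        "mu20": float(mu20),
        "mu02": float(mu02),
        "mu11": float(mu11),
    }


def is_simple(c: Contour) -> bool:
    """True when the closed polyline has no self-intersection."""
    ring = np.vstack([c.points, c.points[:1]])
    return bool(shapely.LineString(ring).is_simple)


# ---------------------------------------------------------------------------
# I/O


def load_contour(path: str | Path, format: str | None = None) -> Contour:
    """Read a contour from CSV (two columns x,y), JSON, or a PNG mask.

    The result is in source coordinates; run :func:`canonicalize` before
    computing descriptors.  PNG masks are traced along the outer boundary
    of their single foreground component, returned counter-clockwise.
    """
    path = Path(path)
    if format is None:
        format = {".csv": "csv", ".json": "json", ".png": "png-mask"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise InvalidInputError(f"cannot infer format from suffix: {path.name}")
    if format == "csv":
        try:
            df = pd.read_csv(path, header=None, comment="#")
        except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
            raise InvalidInputError(f"unreadable contour CSV {path}: {exc}") from exc
        if isinstance(df.iloc[0, 0], str):  # header row present
            df = df.iloc[1:]
        pts = df.iloc[:, :2].to_numpy(dtype=np.float64)
        return Contour(pts, meta=path.stem)
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        pts = np.asarray(payload["points"], dtype=np.float64)
        return Contour(pts, meta=payload.get("meta", path.stem))
    if format == "png-mask":
        img = np.asarray(Image.open(path).convert("L"))
        return trace_mask(img >= 128, meta=path.stem)
    raise InvalidInputError(f"unknown contour format: {format!r}")


def save_contour(c: Contour, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        pd.DataFrame(c.points, columns=["x", "y"]).to_csv(path, index=False)
    elif path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump({"points": c.points.tolist(), "meta": c.meta}, fh)
    else:
        raise InvalidInputError(f"unsupported output format: {path.suffix}")


def trace_mask(mask: np.ndarray, meta: str | None = None) -> Contour:
    """Trace the outer boundary of a single-component binary mask.

    Returns the boundary as an (x, y) contour in pixel coordinates with
    x = column, y = row, oriented counter-clockwise in that frame.
    """
    mask = np.asarray(mask, dtype=bool)
    n_components = int(_skmeasure.label(mask, connectivity=1).max())
    if n_components != 1:
        raise AmbiguousInputError(
            f"mask must contain exactly 1 foreground component, found {n_components}"
        )
    padded = np.pad(mask, 1)
    rings = _skmeasure.find_contours(padded.astype(float), 0.5)
    outer = max(rings, key=len)
    pts = np.column_stack([outer[:, 1], outer[:, 0]]) - 1.0  # (x=col, y=row)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    c = Contour(_dedupe_consecutive(pts), meta=meta)
    return ensure_ccw(c)


# ---------------------------------------------------------------------------
# canonical form


def resample_uniform(c: Contour, n: int = DEFAULT_N_POINTS) -> Contour:
    """Resample to ``n`` points equally spaced in arc length.

    The start point is preserved (target arc position 0 coincides with
    ``points[0]``) and total perimeter is preserved up to the piecewise
    linear approximation of the outline.
    """
    if n < 3:
        raise InvalidInputError(f"need n >= 3 resample points, got {n}")
    ring = np.vstack([c.points, c.points[:1]])
    seg = np.hypot(*np.diff(ring, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise DegenerateShapeError("contour has zero perimeter")
    target = np.arange(n) * (total / n)
    out = np.column_stack(
        [np.interp(target, s, ring[:, 0]), np.interp(target, s, ring[:, 1])]
    )
    return Contour(out, meta=c.meta)


def normalize_coords(c: Contour) -> Contour:
    """Shift the per-axis minima to zero and scale by the joint maximum.

    Both axes are divided by the same factor (the largest coordinate left
    after the shift) so the aspect ratio survives normalization; the longer
    bounding-box side maps exactly onto [0, 1].  Idempotent.
    """
    pts = c.points - c.points.min(axis=0)
    top = pts.max()
    if top <= 0:
        raise DegenerateShapeError("all contour points coincide")
    return Contour(pts / top, meta=c.meta)


def ensure_ccw(c: Contour) -> Contour:
    """Force counter-clockwise traversal (positive shoelace area)."""
    if signed_area(c.points) < 0:
        return Contour(c.points[::-1], meta=c.meta)
    return c


def canonicalize_start(c: Contour, seed: int = 0) -> Contour:
    """Rotate the point order so the leftmost vertex comes first.

    The contour is first forced counter-clockwise; then the vertex with the
    smallest x becomes ``points[0]``.  When several vertices tie for the
    smallest x (within 1e-12), one of them is chosen uniformly at random
    with the given seed, mirroring how shapes with repeated leftmost points
    are handled in practice.
    """
    c = ensure_ccw(c)
    x = c.points[:, 0]
    ties = np.flatnonzero(x <= x.min() + 1e-12)
    if len(ties) == 1:
        start = int(ties[0])
    else:
        start = int(np.random.default_rng(seed).choice(ties))
    return Contour(np.roll(c.points, -start, axis=0), meta=c.meta)


def canonicalize(
    c: Contour, n: int = DEFAULT_N_POINTS, seed: int = 0
) -> Contour:
    """Full canonical form: resample, normalize, orient CCW, fix start."""
    return canonicalize_start(normalize_coords(resample_uniform(c, n)), seed=seed)


# ---------------------------------------------------------------------------
# rasterization


def rasterize(c: Contour, grid: int = DEFAULT_GRID) -> BinaryMask:
    """Fill the polygon interior on a ``grid`` x ``grid`` raster of [0,1]^2.

    A pixel belongs to the foreground when its center falls inside the
    polygon (even-odd rule).  Self-intersecting outlines are filled anyway
    and flagged on the returned mask.
    """
    if grid < 8:
        raise InvalidInputError(f"grid must be >= 8, got {grid}")
    # pixel (r, c) has center ((c + 0.5)/grid, (r + 0.5)/grid)
    cols = c.points[:, 0] * grid - 0.5
    rows = c.points[:, 1] * grid - 0.5
    rr, cc = _skdraw.polygon(rows, cols, shape=(grid, grid))
    m = np.zeros((grid, grid), dtype=bool)
    m[rr, cc] = True
    return BinaryMask(m, resolution=grid, self_intersecting=not is_simple(c))
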