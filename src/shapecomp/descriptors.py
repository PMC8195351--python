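"""A bank of complementary 2D shape descriptors.

Shapes can be described in many partially redundant ways — global region
statistics (area, solidity, compactness), boundary statistics (curvature,
centroid-distance signatures, Fourier amplitudes), point-set statistics
(shape context, chord-length histograms) and part structure (skeleton
branch counts).  Each descriptor is sensitive to some deformations of the
outline and blind to others, which is exactly why combining them is
useful: the default bank registers ~50 descriptors spanning seven families
so that a composite distance picks up whatever any single family misses.

Descriptors are either scalars or fixed-length vectors.  A handful depend
on where traversal of the closed outline begins (flagged
``start_dependent``); those are only comparable between contours whose
start point was fixed by :func:`shapecomp.contour.canonicalize_start`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import cached_property
from typing import Callable, Iterator

import networkx as nx
import numpy as np
from scipy.fft import rfft
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure as _skmeasure
from skimage.morphology import skeletonize

from .contour import (
    DEFAULT_GRID,
    BinaryMask,
    Contour,
    perimeter,
    polygon_area,
    polygon_moments,
    rasterize,
)
from .errors import DegenerateShapeError, InsufficientPointsError

__all__ = [
    "DescriptorDefinition",
    "DescriptorBank",
    "DescriptorVector",
    "ShapeAnalysis",
    "default_bank",
    "basic_descriptors",
    "curvature_features",
    "fourier_descriptors",
    "shape_context_features",
    "chord_lengths",
    "skeleton_features",
    "compute_descriptor_vector",
]

CURVATURE_SIGMA = 2.0  # contour points; matches the blob generator's blur
N_HARMONICS = 20
SC_N_R = 5
SC_N_THETA = 12
CHORD_BINS = 16
SKELETON_GRID = DEFAULT_GRID


# ---------------------------------------------------------------------------
# shared lazy geometry cache


class ShapeAnalysis:
    """Lazily computed intermediates shared by many descriptors.

    Constructing one per shape lets e.g. the convex hull or the pairwise
    chord set be computed once even though several descriptors use it.
    """

    def __init__(self, contour: Contour, grid: int = SKELETON_GRID):
        self.contour = contour
        self.grid = grid

    @cached_property
    def pts(self) -> np.ndarray:
        return self.contour.points

    @cached_property
    def area(self) -> float:
        a = polygon_area(self.pts)
        if a < 1e-12:
            raise DegenerateShapeError("zero-area contour")
        return a

    @cached_property
    def perim(self) -> float:
        return perimeter(self.pts)

    @cached_property
    def hull(self) -> ConvexHull:
        return ConvexHull(self.pts)

    @cached_property
    def moments(self) -> dict[str, float]:
        return polygon_moments(self.pts)

    @cached_property
    def inertia_eigvals(self) -> tuple[float, float]:
        m = self.moments
        mu20, mu02, mu11 = m["mu20"] / m["area"], m["mu02"] / m["area"], m["mu11"] / m["area"]
        t = 0.5 * (mu20 + mu02)
        d = np.hypot(0.5 * (mu20 - mu02), mu11)
        return (t + d, max(t - d, 0.0))  # lam1 >= lam2 >= 0

    @cached_property
    def centroid(self) -> np.ndarray:
        m = self.moments
        return np.array([m["cx"], m["cy"]])

    @cached_property
    def radial(self) -> np.ndarray:
        """Centroid-distance signature r(t)."""
        d = self.pts - self.centroid
        return np.hypot(d[:, 0], d[:, 1])

    @cached_property
    def fourier_amps(self) -> np.ndarray:
        """Harmonic amplitudes of r(t), scale-normalized by the DC term."""
        spec = np.abs(rfft(self.radial))
        if spec[0] < 1e-12:
            raise DegenerateShapeError("zero mean radius")
        return spec[1:] / spec[0]

    @cached_property
    def curvature(self) -> np.ndarray:
        return _signed_curvature(self.pts, CURVATURE_SIGMA)

    @cached_property
    def arc_ds(self) -> np.ndarray:
        nxt = np.roll(self.pts, -1, axis=0)
        prv = np.roll(self.pts, 1, axis=0)
        return 0.5 * (np.hypot(*(nxt - self.pts).T) + np.hypot(*(self.pts - prv).T))

    @cached_property
    def chords(self) -> np.ndarray:
        return pdist(self.pts)

    @cached_property
    def shape_context(self) -> np.ndarray:
        return _shape_context_histograms(self.pts, SC_N_R, SC_N_THETA)

    @cached_property
    def mask(self) -> BinaryMask:
        return rasterize(self.contour, grid=self.grid)

    @cached_property
    def hu_moments(self) -> np.ndarray:
        mom = _skmeasure.moments(self.mask.grid.astype(np.float64))
        cen = _skmeasure.moments_central(self.mask.grid.astype(np.float64))
        nu = _skmeasure.moments_normalized(cen)
        hu = _skmeasure.moments_hu(nu)
        # log-compress: Hu invariants span many orders of magnitude
        return np.sign(hu) * np.log10(np.abs(hu) + 1e-30)

    @cached_property
    def skeleton_stats(self) -> dict[str, float]:
        return skeleton_features(self.mask)


# ---------------------------------------------------------------------------
# descriptor families


def basic_descriptors(c: Contour) -> dict[str, float]:
    """Global region statistics of the filled outline.

    Returns area, perimeter, solidity (area over convex-hull area),
    compactness (4*pi*area/perimeter^2, 1 for a circle), convexity (hull
    perimeter over perimeter), eccentricity and major-axis orientation in
    degrees from the second-order central moments, aspect ratio,
    rectangularity (area over bounding-box area), circular variance of the
    radial signature, and the centroid offset from the bounding-box center.
    """
    sa = ShapeAnalysis(c)
    return {k: f(sa) for k, f in _BASIC_FUNCS.items()}


def _orientation_deg(sa: ShapeAnalysis) -> float:
    m = sa.moments
    ang = 0.5 * np.degrees(np.arctan2(2.0 * m["mu11"], m["mu20"] - m["mu02"]))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return float(ang)


def _eccentricity(sa: ShapeAnalysis) -> float:
    lam1, lam2 = sa.inertia_eigvals
    return float(np.sqrt(max(1.0 - lam2 / lam1, 0.0))) if lam1 > 0 else 0.0


def _circular_variance(sa: ShapeAnalysis) -> float:
    r = sa.radial
    mean = r.mean()
    return float(((r - mean) ** 2).mean() / mean**2)


def _centroid_offset(sa: ShapeAnalysis) -> float:
    lo, hi = sa.pts.min(axis=0), sa.pts.max(axis=0)
    return float(np.linalg.norm(sa.centroid - 0.5 * (lo + hi)) / np.linalg.norm(hi - lo))


_BASIC_FUNCS: dict[str, Callable[[ShapeAnalysis], float]] = {
    "area": lambda sa: sa.area,
    "perimeter": lambda sa: sa.perim,
    "solidity": lambda sa: sa.area / sa.hull.volume,
    "compactness": lambda sa: 4.0 * np.pi * sa.area / sa.perim**2,
    "convexity": lambda sa: sa.hull.area / sa.perim,  # hull.area = 2D hull perimeter
    "eccentricity": _eccentricity,
    "major_axis_orientation": _orientation_deg,
    "aspect_ratio": lambda sa: float(
        np.sqrt(sa.inertia_eigvals[0] / max(sa.inertia_eigvals[1], 1e-30))
    ),
    "rectangularity": lambda sa: sa.area / float(np.prod(np.ptp(sa.pts, axis=0))),
    "circular_variance": _circular_variance,
    "centroid_offset": _centroid_offset,
}


def _signed_curvature(pts: np.ndarray, sigma: float) -> np.ndarray:
    """Signed curvature along the closed outline, positive where convex
    in the counter-clockwise frame.  Coordinates are Gaussian-smoothed along
    the parameter (sigma in contour points, periodic) before
    differentiation, which guards the speed term against noise-level
    wiggles."""
    if sigma > 0:
        xs = gaussian_filter1d(pts[:, 0], sigma, mode="wrap")
        ys = gaussian_filter1d(pts[:, 1], sigma, mode="wrap")
    else:
        xs, ys = pts[:, 0], pts[:, 1]
    dx = _periodic_gradient(xs)
    dy = _periodic_gradient(ys)
    ddx = _periodic_gradient(dx)
    ddy = _periodic_gradient(dy)
    speed2 = dx * dx + dy * dy
    speed2 = np.maximum(speed2, 1e-18)
    return (dx * ddy - dy * ddx) / speed2**1.5


def _periodic_gradient(v: np.ndarray) -> np.ndarray:
    return 0.5 * (np.roll(v, -1) - np.roll(v, 1))


def curvature_features(
    c: Contour, smooth_sigma: float = CURVATURE_SIGMA
) -> tuple[np.ndarray, dict[str, float]]:
    """Signed curvature profile plus scalar summaries.

    Returns the per-point signed curvature (smoothed with ``smooth_sigma``
    contour points) and scalars: mean absolute curvature, curvature
    standard deviation, total absolute turning (integral of |kappa| ds,
    2*pi for any convex outline), the number of local extrema of the
    profile, and bending energy (integral of kappa^2 ds).
    """
    kappa = _signed_curvature(c.points, smooth_sigma)
    sa = ShapeAnalysis(c)
    ds = sa.arc_ds
    scalars = {
        "curvature_mean_abs": float(np.abs(kappa).mean()),
        "curvature_std": float(kappa.std()),
        "total_abs_turning": float(np.sum(np.abs(kappa) * ds)),
        "curvature_extrema_count": float(_count_extrema(kappa)),
        "bending_energy": float(np.sum(kappa**2 * ds)),
    }
    return kappa, scalars


def _count_extrema(v: np.ndarray) -> int:
    d = np.sign(np.diff(np.concatenate([v, v[:1]])))
    d = d[d != 0]
    if len(d) < 2:
        return 0
    return int(np.sum(d != np.roll(d, 1)))


def fourier_descriptors(c: Contour, n_harmonics: int = N_HARMONICS) -> np.ndarray:
    """Amplitudes of harmonics 1..n of the centroid-distance signature.

    Amplitudes are divided by the DC amplitude so the result is scale
    invariant; phase is discarded so the result does not depend on where
    traversal starts.  A circle gives (near-)zero amplitudes everywhere; a
    2:1 ellipse peaks at harmonic 2.
    """
    n = len(c)
    if not 1 <= n_harmonics <= n // 2:
        raise InsufficientPointsError(
            f"n_harmonics must be in [1, {n // 2}], got {n_harmonics}"
        )
    return ShapeAnalysis(c).fourier_amps[:n_harmonics].copy()


def _shape_context_histograms(
    pts: np.ndarray, n_r: int, n_theta: int
) -> np.ndarray:
    """Log-polar histogram of relative point positions, one per point.

    Radii are normalized by the mean pairwise distance; the five radial
    bins are log-spaced with the innermost edge at 0 and the outermost at
    infinity so every neighbour lands in some bin (each histogram sums to
    N-1).  Angles are absolute (not tangent-relative), so per-point
    histograms rotate with the shape while radial marginals do not.
    """
    n = len(pts)
    if n < 8:
        raise InsufficientPointsError(f"shape context needs >= 8 points, got {n}")
    diff = pts[None, :, :] - pts[:, None, :]
    r = np.hypot(diff[..., 0], diff[..., 1])
    mean_r = r[r > 0].mean()
    r = r / mean_r
    theta = np.mod(np.arctan2(diff[..., 1], diff[..., 0]), 2 * np.pi)
    # log-spaced interior edges between r/8 and 2r (Belongie-style), open ends
    r_edges = np.concatenate([[0.0], 0.125 * 2.0 ** np.arange(n_r - 1), [np.inf]])
    r_idx = np.searchsorted(r_edges, r, side="right") - 1
    t_idx = np.minimum((theta / (2 * np.pi) * n_theta).astype(int), n_theta - 1)
    flat = r_idx * n_theta + t_idx
    hists = np.zeros((n, n_r * n_theta))
    rows = np.repeat(np.arange(n), n)
    mask = ~np.eye(n, dtype=bool).ravel()
    np.add.at(hists, (rows[mask], flat.ravel()[mask]), 1.0)
    return hists


def shape_context_features(
    c: Contour, n_r: int = SC_N_R, n_theta: int = SC_N_THETA
) -> dict[str, np.ndarray | float]:
    """Per-point log-polar histograms plus pooled summaries.

    Returns the (N, n_r*n_theta) per-point histograms, their mean (a
    start-independent shape summary), the histogram at the canonical start
    point, the chord-length histogram over all point pairs (lengths
    normalized by the mean chord, 16 fixed bins on [0, 3], mass-normalized
    so the summary is scale invariant), and raw chord mean/std.
    """
    sa = ShapeAnalysis(c)
    hists = _shape_context_histograms(sa.pts, n_r, n_theta)
    chords = sa.chords
    rel = chords / chords.mean()
    edges = np.linspace(0.0, 3.0, CHORD_BINS + 1)
    edges[-1] = np.inf
    hist, _ = np.histogram(rel, bins=edges)
    return {
        "per_point": hists,
        "sc_mean": hists.mean(axis=0),
        "sc_origin": hists[0].copy(),
        "chord_hist": hist / hist.sum(),
        "chord_mean": float(chords.mean()),
        "chord_std": float(chords.std()),
    }


def chord_lengths(c: Contour) -> np.ndarray:
    """All pairwise point distances (the chord set), unsorted."""
    return pdist(c.points)


# -- skeleton ---------------------------------------------------------------


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pixels = set(zip(rows.tolist(), cols.tolist()))
    for r, c in pixels:
        g.add_node((r, c))
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if (dr or dc) and (r + dr, c + dc) in pixels:
                    g.add_edge((r, c), (r + dr, c + dc))
    return g


def _prune_graph(g: nx.Graph, prune_px: int) -> nx.Graph:
    """Iteratively strip leaf branches shorter than prune_px pixels."""
    g = g.copy()
    changed = True
    while changed and g.number_of_nodes() > 1:
        changed = False
        for tip in [n for n in g.nodes if g.degree(n) == 1]:
            if tip not in g:
                continue
            path = [tip]
            while g.degree(path[-1]) <= 2:
                nbrs = [n for n in g.neighbors(path[-1]) if n not in path]
                if not nbrs:
                    break
                path.append(nbrs[0])
                if g.degree(path[-1]) >= 3:
                    break
            branch = path[:-1] if g.degree(path[-1]) >= 3 else path
            if len(branch) < prune_px and len(branch) < g.number_of_nodes():
                g.remove_nodes_from(branch)
                changed = True
    return g


def skeleton_features(m: BinaryMask, prune_px: int | None = None) -> dict[str, float]:
    """Topology counts of the pruned medial-axis skeleton.

    The mask is thinned to a one-pixel-wide skeleton, converted to a pixel
    adjacency graph, and leaf branches shorter than ``prune_px`` (default
    3% of the mask diagonal) are removed — raw thinning sprouts a spurious
    spur at almost every boundary bump.  Returns endpoint, junction and
    branch counts, skeleton length relative to the outline perimeter, and
    a rib count (leaf branches hanging off junctions, i.e. limb-like
    spokes).
    """
    grid = m.grid
    if not grid.any():
        raise DegenerateShapeError("empty mask")
    if prune_px is None:
        prune_px = max(2, int(0.03 * np.hypot(*grid.shape)))
    skel = skeletonize(np.array(grid))  # copy: masks are stored read-only
    g = _prune_graph(_skeleton_graph(skel), prune_px)
    deg = dict(g.degree())
    endpoints = [n for n, d in deg.items() if d == 1]
    junction_pixels = {n for n, d in deg.items() if d >= 3}
    # merge adjacent junction pixels into single junction nodes
    n_junctions = (
        nx.number_connected_components(g.subgraph(junction_pixels))
        if junction_pixels
        else 0
    )
    skel_len = sum(np.hypot(a[0] - b[0], a[1] - b[1]) for a, b in g.edges)
    # branches = paths between nodes of degree != 2 in the compressed graph
    n_branches = _count_branches(g)
    ribs = sum(1 for _ in endpoints) if junction_pixels else 0
    bound_len = np.count_nonzero(grid ^ np.roll(grid, 1, 0)) + np.count_nonzero(
        grid ^ np.roll(grid, 1, 1)
    )
    return {
        "skel_endpoint_count": float(len(endpoints)),
        "skel_junction_count": float(n_junctions),
        "skel_branch_count": float(n_branches),
        "skel_length_ratio": float(skel_len / max(bound_len, 1)),
        "skel_rib_count": float(ribs),
    }


def _count_branches(g: nx.Graph) -> int:
    """Branches = connected runs of non-junction pixels.

    Removing the junction clusters splits the skeleton into its arms and
    connecting segments; each surviving component is one branch.  A
    junction-free skeleton (path or cycle) counts as a single branch.
    """
    if g.number_of_nodes() == 0:
        return 0
    non_junction = [v for v in g.nodes if g.degree(v) < 3]
    if not non_junction:
        return 0
    return nx.number_connected_components(g.subgraph(non_junction))


# ---------------------------------------------------------------------------
# registry


@dataclass(frozen=True)
class DescriptorDefinition:
    """One registered descriptor: an id, a family, and an evaluator."""

    id: str
    family: str  # basic | curvature | fourier | signature | shape_context | skeleton | moments
    arity: int  # 1 for scalars, vector length otherwise
    func: Callable[[ShapeAnalysis], float | np.ndarray]
    start_dependent: bool = False
    units: str = "dimensionless"


class DescriptorBank:
    """Ordered registry of descriptor definitions.

    ``version`` is a content hash of the registered ids, so a serialized
    shape space can detect that it is being queried with a different bank.
    """

    def __init__(self, definitions: list[DescriptorDefinition]):
        ids = [d.id for d in definitions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate descriptor ids in bank")
        self._defs = {d.id: d for d in definitions}

    def __iter__(self) -> Iterator[DescriptorDefinition]:
        return iter(self._defs.values())

    def __len__(self) -> int:
        return len(self._defs)

    def __contains__(self, id: str) -> bool:
        return id in self._defs

    def __getitem__(self, id: str) -> DescriptorDefinition:
        return self._defs[id]

    @property
    def ids(self) -> list[str]:
        return list(self._defs)

    @property
    def families(self) -> set[str]:
        return {d.family for d in self}

    @property
    def version(self) -> str:
        payload = ",".join(f"{d.id}:{d.arity}" for d in self)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def subset(self, ids: list[str]) -> "DescriptorBank":
        return DescriptorBank([self._defs[i] for i in ids])


@dataclass
class DescriptorVector:
    """Evaluated descriptor values for one shape."""

    shape_id: str
    values: dict[str, np.ndarray]  # id -> 1-D array (length = arity)
    bank_version: str
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        return not self.errors

    def __getitem__(self, id: str) -> np.ndarray:
        return self.values[id]


def _scalar(id, family, func, start_dependent=False, units="dimensionless"):
    return DescriptorDefinition(id, family, 1, func, start_dependent, units)


def default_bank() -> DescriptorBank:
    """The default ~50-descriptor bank spanning all seven families."""
    defs: list[DescriptorDefinition] = []

    for name, f in _BASIC_FUNCS.items():
        units = "degrees" if name == "major_axis_orientation" else "dimensionless"
        defs.append(_scalar(name, "basic", f, units=units))

    def _curv(key):
        return lambda sa: curvature_features(sa.contour)[1][key]

    for key in (
        "curvature_mean_abs",
        "curvature_std",
        "total_abs_turning",
        "curvature_extrema_count",
        "bending_energy",
    ):
        defs.append(_scalar(key, "curvature", _curv(key)))

    for k in range(1, 9):
        defs.append(
            _scalar(f"fourier_amp_{k}", "fourier", lambda sa, k=k: float(sa.fourier_amps[k - 1]))
        )
    defs.append(
        DescriptorDefinition(
            "fourier_spectrum", "fourier", N_HARMONICS,
            lambda sa: sa.fourier_amps[:N_HARMONICS].copy(),
        )
    )
    defs.append(_scalar("fourier_low_energy", "fourier", lambda sa: float(np.sum(sa.fourier_amps[:5] ** 2))))
    defs.append(_scalar("fourier_entropy", "fourier", _fourier_entropy))

    defs += [
        _scalar("radial_mean", "signature", lambda sa: float(sa.radial.mean())),
        _scalar("radial_cv", "signature", lambda sa: float(sa.radial.std() / sa.radial.mean())),
        _scalar("radial_minmax", "signature", lambda sa: float(sa.radial.min() / sa.radial.max())),
        _scalar("radial_zero_crossings", "signature", _radial_zero_crossings),
        _scalar("radial_skewness", "signature", _radial_skewness),
        DescriptorDefinition(
            "radial_signature", "signature", 64, _radial_signature, start_dependent=True
        ),
    ]

    defs += [
        DescriptorDefinition(
            "sc_mean", "shape_context", SC_N_R * SC_N_THETA,
            lambda sa: sa.shape_context.mean(axis=0),
        ),
        DescriptorDefinition(
            "sc_origin", "shape_context", SC_N_R * SC_N_THETA,
            lambda sa: sa.shape_context[0].copy(), start_dependent=True,
        ),
        DescriptorDefinition("chord_hist", "shape_context", CHORD_BINS, _chord_hist),
        _scalar("chord_mean", "shape_context", lambda sa: float(sa.chords.mean())),
        _scalar("chord_std", "shape_context", lambda sa: float(sa.chords.std())),
    ]

    def _skel(key):
        return lambda sa: sa.skeleton_stats[key]

    for key in (
        "skel_endpoint_count",
        "skel_junction_count",
        "skel_branch_count",
        "skel_length_ratio",
        "skel_rib_count",
    ):
        defs.append(_scalar(key, "skeleton", _skel(key), units="count" if "count" in key else "dimensionless"))

    for k in range(7):
        defs.append(
            _scalar(f"hu_{k + 1}", "moments", lambda sa, k=k: float(sa.hu_moments[k]), units="log10")
        )

    return DescriptorBank(defs)


def _fourier_entropy(sa: ShapeAnalysis) -> float:
    p = sa.fourier_amps[:N_HARMONICS] ** 2
    tot = p.sum()
    if tot <= 0:
        return 0.0
    p = p / tot
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _radial_zero_crossings(sa: ShapeAnalysis) -> float:
    r = sa.radial - sa.radial.mean()
    s = np.sign(r)
    s = s[s != 0]
    return float(np.sum(s != np.roll(s, 1))) if len(s) else 0.0


def _radial_skewness(sa: ShapeAnalysis) -> float:
    r = sa.radial
    sd = r.std()
    if sd < 1e-12:
        return 0.0
    return float(np.mean(((r - r.mean()) / sd) ** 3))


def _radial_signature(sa: ShapeAnalysis) -> np.ndarray:
    r = sa.radial / sa.radial.mean()
    idx = np.linspace(0, len(r), 64, endpoint=False).astype(int)
    return r[idx]


def _chord_hist(sa: ShapeAnalysis) -> np.ndarray:
    rel = sa.chords / sa.chords.mean()
    edges = np.linspace(0.0, 3.0, CHORD_BINS + 1)
    edges[-1] = np.inf
    hist, _ = np.histogram(rel, bins=edges)
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# evaluation


def compute_descriptor_vector(
    c: Contour,
    bank: DescriptorBank | None = None,
    shape_id: str | None = None,
) -> DescriptorVector:
    """Evaluate every registered descriptor on a canonical contour.

    A failing descriptor is recorded under ``errors`` (keyed by id) and the
    vector is marked incomplete rather than aborting, so a caller can decide
    whether to drop the shape or the descriptor.
    """
    if bank is None:
        bank = default_bank()
    sa = ShapeAnalysis(c)
    values: dict[str, np.ndarray] = {}
    errors: dict[str, str] = {}
    for d in bank:
        try:
            v = np.atleast_1d(np.asarray(d.func(sa), dtype=np.float64))
            if v.shape != (d.arity,):
                raise ValueError(f"expected arity {d.arity}, got shape {v.shape}")
            if not np.all(np.isfinite(v)):
                raise ValueError("non-finite value")
            values[d.id] = v
        except Exception as exc:  # noqa: BLE001 - per-descriptor fault isolation
            errors[d.id] = f"{type(exc).__name__}: {exc}"
    return DescriptorVector(
        shape_id=shape_id or (c.meta or "shape"),
        values=values,
        bank_version=bank.version,
        errors=errors,
    )
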