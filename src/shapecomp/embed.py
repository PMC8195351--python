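"""Embedding novel shapes into an existing space, and similarity statistics.

A built :class:`~shapecomp.space.ShapeSpace` fixes a coordinate frame for
its corpus, but classical MDS cannot place a new shape directly — the
embedding depends on the whole distance matrix.  The local-MDS +
Procrustes trick sidesteps a full rebuild: take a reference subset of the
corpus, form the (n_ref + 1)-shape combined distance matrix (new shape
included, normalized by the *stored* corpus maxima), run classical MDS on
it, then find the similarity transform (translation, rotation/reflection,
uniform scale) that best maps the reference shapes' local coordinates
onto their stored coordinates, and push the new shape's local row through
that transform.  The residual of the Procrustes fit is reported so
callers can judge embedding quality.

Also here: plain Euclidean distance in the reduced space, the full-model
(pre-MDS) distance between two descriptor vectors, raster
intersection-over-union, and the triplet relative-proximity ratio
min(a, b) / (a + b) used to quantify how equally far two test shapes are
from a sample shape (0.5 = equidistant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .contour import BinaryMask, Contour
from .descriptors import (
    DescriptorBank,
    DescriptorVector,
    compute_descriptor_vector,
    default_bank,
)
from .errors import InvalidInputError, UndefinedMetricError
from .space import ShapeSpace, classical_mds

__all__ = [
    "EmbeddingResult",
    "TripletRecord",
    "embed_new_shape",
    "shapecomp_distance",
    "full_model_distance",
    "iou",
    "triplet_ratio",
]

DEFAULT_N_REF = 500


@dataclass(frozen=True)
class EmbeddingResult:
    """Coordinates of a novel shape in a reference space frame."""

    coordinates: np.ndarray  # (K,)
    procrustes_residual: float  # RMS error of the reference mapping
    n_ref: int
    seed: int


def _similarity_procrustes(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray, float]:
    """Best-fit similarity transform mapping X onto Y (least squares).

    Returns (R, s, x_mean, y_mean, rms) such that
    ``s * (X - x_mean) @ R + y_mean`` approximates Y.  Reflections are
    allowed: MDS axes carry an arbitrary sign, so restricting to proper
    rotations could lock the fit into a mirrored frame.  The residual is
    the RMS over rows of the per-row mapping error norm, i.e. the typical
    coordinate-space displacement of a reference shape under the fit.
    """
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xm, Y - ym
    U, sv, Vt = np.linalg.svd(Xc.T @ Yc)
    R = U @ Vt
    denom = (Xc * Xc).sum()
    s = sv.sum() / denom if denom > 0 else 1.0
    fitted = s * Xc @ R + ym
    rms = float(np.sqrt(np.mean(np.sum((fitted - Y) ** 2, axis=1))))
    return R, float(s), xm, ym, rms


def embed_new_shape(
    space: ShapeSpace,
    c: Contour | DescriptorVector,
    n_ref: int | None = None,
    seed: int = 0,
    bank: DescriptorBank | None = None,
) -> EmbeddingResult:
    """Estimate a novel shape's coordinates in a pre-built space.

    ``n_ref`` reference shapes are drawn uniformly (seeded) from the
    space's corpus; the default 500 is auto-reduced with the corpus size.
    Per-descriptor distances between the new shape and the references are
    normalized by the space's stored maxima — a raw distance beyond the
    stored maximum is allowed (normalized value above 1) since novel
    shapes may fall outside the corpus range.  ``c`` may be a
    canonical contour or an already-computed descriptor vector.
    """
    n = space.n_shapes
    if n_ref is None:
        n_ref = min(DEFAULT_N_REF, n)
    if n_ref > n:
        raise InvalidInputError(f"n_ref={n_ref} exceeds corpus size {n}")
    if n_ref < space.K + 1:
        raise InvalidInputError(f"n_ref must be >= K+1 = {space.K + 1}")
    if isinstance(c, DescriptorVector):
        vec = c
    else:
        if bank is None:
            bank = default_bank()
        vec = compute_descriptor_vector(c, bank)
    if vec.bank_version != space.bank_version and set(space.descriptor_ids) - set(
        vec.values
    ):
        raise InvalidInputError("descriptor vector lacks ids required by the space")

    rng = np.random.default_rng(seed)
    ref_idx = np.sort(rng.choice(n, size=n_ref, replace=False))

    total = None
    for k in space.descriptor_ids:
        nk = space.norms[k]
        feats = np.vstack([space.features[k][ref_idx], vec.values[k][None, :]])
        d = squareform(pdist(feats)) / nk
        total = d * d if total is None else total + d * d
    D = np.sqrt(total)

    local = classical_mds(D, space.K).coordinates
    k_eff = local.shape[1]
    if k_eff < space.K:  # pad rank-deficient local solutions
        local = np.hstack([local, np.zeros((local.shape[0], space.K - k_eff))])
    R, s, xm, ym, rms = _similarity_procrustes(
        local[:-1], space.coordinates[ref_idx]
    )
    coords = s * (local[-1] - xm) @ R + ym
    return EmbeddingResult(
        coordinates=coords, procrustes_residual=rms, n_ref=n_ref, seed=seed
    )


def shapecomp_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Euclidean distance between two reduced-space coordinate vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise InvalidInputError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.linalg.norm(u - v))


def full_model_distance(
    va: DescriptorVector, vb: DescriptorVector, norms: dict[str, float]
) -> float:
    """Combined pre-MDS distance between two descriptor vectors.

    Identical to one entry of the corpus combined-distance matrix:
    sqrt of the sum over descriptors of the squared, max-normalized value
    differences.  ``norms`` come from a built space.
    """
    if va.bank_version != vb.bank_version:
        raise InvalidInputError("descriptor vectors from different banks")
    if not norms:
        raise InvalidInputError("missing normalization maxima")
    total = 0.0
    for k, nk in norms.items():
        if nk <= 0:
            continue
        if k not in va.values or k not in vb.values:
            raise InvalidInputError(f"descriptor {k!r} missing from a vector")
        diff = np.linalg.norm(va.values[k] - vb.values[k]) / nk
        total += diff * diff
    return float(np.sqrt(total))


def iou(ma: BinaryMask, mb: BinaryMask) -> tuple[float, float]:
    """Intersection-over-union of two silhouette masks.

    Masks must share the raster grid; no spatial registration is applied —
    both silhouettes are compared as placed in the common normalized frame.
    Returns ``(iou, jaccard_distance)`` where jaccard_distance = 1 - IoU,
    so both the similarity and the dissimilarity reading are available
    under unambiguous names.
    """
    if ma.grid.shape != mb.grid.shape:
        raise InvalidInputError(
            f"mask grids differ: {ma.grid.shape} vs {mb.grid.shape}"
        )
    union = np.logical_or(ma.grid, mb.grid).sum()
    if union == 0:
        raise UndefinedMetricError("IoU undefined: both masks are empty")
    inter = np.logical_and(ma.grid, mb.grid).sum()
    value = float(inter / union)
    return value, 1.0 - value


def triplet_ratio(a: float, b: float) -> float:
    """Relative proximity of a sample to two test shapes: min(a,b)/(a+b).

    0 means one test shape coincides with the sample; the maximum 0.5 means
    both tests are equally far from the sample.
    """
    if a < 0 or b < 0:
        raise InvalidInputError("distances must be nonnegative")
    if a + b == 0:
        raise UndefinedMetricError("triplet ratio undefined for a + b = 0")
    return min(a, b) / (a + b)


@dataclass(frozen=True)
class TripletRecord:
    """A sample shape compared against two test shapes."""

    sample_id: str
    test_a_id: str
    test_b_id: str
    a: float  # reduced-space distance sample -> test A
    b: float  # reduced-space distance sample -> test B
    iou_a: float
    iou_b: float

    @property
    def ratio(self) -> float:
        return triplet_ratio(self.a, self.b)
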