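"""Composite shape spaces via corpus-normalized distances and classical MDS.

The core construction: for every descriptor k, compute the matrix of
pairwise distances d_k(i, j) between all corpus shapes (absolute
difference for scalar descriptors, Euclidean norm of the value difference
for vector-valued ones) and divide it by its largest entry so every
descriptor contributes on a common [0, 1] scale regardless of units.
The combined "Full Model" distance is then the Euclidean combination

    D(i, j) = sqrt( sum_k  d_k(i, j)^2 / max_k^2 ),

which is a genuine metric (it is the Euclidean distance between the
per-descriptor difference profiles).  Classical (Torgerson) MDS of D —
eigendecomposition of the double-centered squared-distance matrix —
yields an orthogonal coordinate system; retaining the top K dimensions
(default 22) gives a compact composite space in which plain Euclidean
distance approximates the full combined distance.

The stored per-descriptor maxima are part of the space: novel shapes are
always normalized by the *corpus* maxima, never refit, so coordinates of
new shapes remain comparable with the reference frame.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.cluster import AffinityPropagation

from .contour import Contour
from .descriptors import (
    DescriptorBank,
    DescriptorVector,
    compute_descriptor_vector,
    default_bank,
)
from .errors import (
    DegenerateCorpusError,
    IncompatibleBankError,
    InvalidInputError,
)

__all__ = [
    "DistanceStack",
    "MDSResult",
    "ShapeSpace",
    "descriptor_matrix",
    "descriptor_distance_stack",
    "combined_distance_matrix",
    "classical_mds",
    "build_space",
    "compare_spaces",
    "cluster_descriptors",
]

DEFAULT_K = 22


def descriptor_matrix(
    vectors: list[DescriptorVector],
) -> dict[str, np.ndarray]:
    """Stack per-shape values into one (n_shapes, arity) array per id.

    Only descriptors present (error-free) in every vector are kept.
    """
    if len(vectors) < 2:
        raise InvalidInputError("need at least two descriptor vectors")
    versions = {v.bank_version for v in vectors}
    if len(versions) != 1:
        raise IncompatibleBankError(f"mixed bank versions: {sorted(versions)}")
    common = [k for k in vectors[0].values if all(k in v.values for v in vectors)]
    return {k: np.vstack([v.values[k] for v in vectors]) for k in common}


@dataclass
class DistanceStack:
    """Per-descriptor pairwise distances plus their corpus maxima."""

    per_descriptor: dict[str, np.ndarray]  # id -> (n, n) raw distances
    norms: dict[str, float]  # id -> max pairwise distance
    constant_ids: list[str]  # zero-variation descriptors, excluded downstream

    @property
    def ids(self) -> list[str]:
        return [k for k in self.per_descriptor if k not in self.constant_ids]

    def normalized(self, id: str) -> np.ndarray:
        return self.per_descriptor[id] / self.norms[id]


def descriptor_distance_stack(
    vectors: list[DescriptorVector],
) -> DistanceStack:
    """Raw and max-normalized per-descriptor distance matrices.

    Descriptors whose values never differ across the corpus have a zero
    maximum; they carry no information and are flagged ``constant`` and
    excluded from combined distances (with a warning) instead of producing
    0/0.
    """
    feats = descriptor_matrix(vectors)
    per: dict[str, np.ndarray] = {}
    norms: dict[str, float] = {}
    constant: list[str] = []
    for k, mat in feats.items():
        d = squareform(pdist(mat))
        per[k] = d
        m = float(d.max())
        norms[k] = m
        if m <= 0.0:
            constant.append(k)
    if constant:
        warnings.warn(
            f"{len(constant)} constant descriptor(s) excluded: {constant[:5]}...",
            stacklevel=2,
        )
    return DistanceStack(per_descriptor=per, norms=norms, constant_ids=constant)


def combined_distance_matrix(stack: DistanceStack) -> np.ndarray:
    """Euclidean combination of the normalized per-descriptor distances."""
    ids = stack.ids
    if not ids:
        raise DegenerateCorpusError("every descriptor is constant on this corpus")
    total = None
    for k in ids:
        d = stack.normalized(k)
        total = d * d if total is None else total + d * d
    return np.sqrt(total)


def _combined_from_features(
    feats: dict[str, np.ndarray], norms: dict[str, float]
) -> np.ndarray:
    """Combined distance computed descriptor-by-descriptor with given norms.

    Memory-friendly path: only one n x n matrix is alive at a time, so large
    corpora never materialize the full n^2 x K stack.
    """
    total = None
    for k, mat in feats.items():
        nk = norms.get(k, 0.0)
        if nk <= 0.0:
            continue
        d = squareform(pdist(mat)) / nk
        total = d * d if total is None else total + d * d
    if total is None:
        raise DegenerateCorpusError("no usable descriptors")
    return np.sqrt(total)


@dataclass
class MDSResult:
    coordinates: np.ndarray  # (n, k_eff), columns scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all n, sorted descending
    variance_explained: np.ndarray  # per retained dimension, of positive spectrum


def classical_mds(D: np.ndarray, K: int) -> MDSResult:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers the squared distance matrix, B = -1/2 J D^2 J, and
    eigendecomposes it.  Coordinates are the top-K eigenvectors scaled by
    the square root of their (positive) eigenvalues; if fewer than K
    eigenvalues are positive the embedding has fewer columns and a warning
    is emitted.  Variance explained is relative to the positive spectrum.
    Each retained eigenvector's largest-magnitude entry is made positive so
    results are reproducible across runs and platforms.
    """
    D = np.asarray(D, dtype=np.float64)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-10):
        raise InvalidInputError("D must be a symmetric square matrix")
    if not 1 <= K <= n - 1:
        raise InvalidInputError(f"K must be in [1, {n - 1}], got {K}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    B = 0.5 * (B + B.T)
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(-vals, kind="stable")
    vals, vecs = vals[order], vecs[:, order]
    n_pos = int(np.sum(vals > max(vals.max(), 0) * 1e-12)) if vals.max() > 0 else 0
    k_eff = min(K, n_pos)
    if k_eff < K:
        warnings.warn(
            f"only {k_eff} positive MDS dimensions available (K={K})", stacklevel=2
        )
    if k_eff == 0:
        raise DegenerateCorpusError("no positive eigenvalues; all shapes identical?")
    top_vecs = vecs[:, :k_eff].copy()
    sign = np.sign(top_vecs[np.abs(top_vecs).argmax(axis=0), np.arange(k_eff)])
    top_vecs *= np.where(sign == 0, 1.0, sign)
    coords = top_vecs * np.sqrt(vals[:k_eff])
    pos_total = vals[vals > 0].sum()
    return MDSResult(
        coordinates=coords,
        eigenvalues=vals,
        variance_explained=vals[:k_eff] / pos_total,
    )


@dataclass
class ShapeSpace:
    """A built composite shape space and everything needed to extend it."""

    bank_version: str
    descriptor_ids: list[str]
    features: dict[str, np.ndarray]  # id -> (n, arity) corpus values
    norms: dict[str, float]  # corpus per-descriptor max distances
    K: int
    coordinates: np.ndarray  # (n, K) reference coordinates
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_shapes(self) -> int:
        return self.coordinates.shape[0]

    # -- serialization ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write a directory bundle: space.json + arrays.npz (bit-exact)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "bank_version": self.bank_version,
            "descriptor_ids": self.descriptor_ids,
            "norms": self.norms,
            "K": self.K,
            "meta": self.meta,
        }
        (directory / "space.json").write_text(json.dumps(meta, indent=1))
        arrays = {f"feat_{k}": v for k, v in self.features.items()}
        arrays.update(
            coordinates=self.coordinates,
            eigenvalues=self.eigenvalues,
            variance_explained=self.variance_explained,
        )
        np.savez(directory / "arrays.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "ShapeSpace":
        directory = Path(directory)
        meta = json.loads((directory / "space.json").read_text())
        with np.load(directory / "arrays.npz") as z:
            features = {
                k[len("feat_"):]: z[k] for k in z.files if k.startswith("feat_")
            }
            return cls(
                bank_version=meta["bank_version"],
                descriptor_ids=meta["descriptor_ids"],
                features=features,
                norms=meta["norms"],
                K=meta["K"],
                coordinates=z["coordinates"],
                eigenvalues=z["eigenvalues"],
                variance_explained=z["variance_explained"],
                meta=meta["meta"],
            )


def build_space(
    corpus: list[Contour],
    bank: DescriptorBank | None = None,
    K: int = DEFAULT_K,
    vectors: list[DescriptorVector] | None = None,
) -> ShapeSpace:
    """Build a composite shape space from a corpus of canonical contours.

    Pipeline: descriptor vectors -> per-descriptor max-normalized distance
    stack -> combined distance -> classical MDS, keeping the top K
    dimensions (auto-reduced with a warning when the corpus is too small
    to support K).  Pass precomputed ``vectors`` to skip re-evaluating
    descriptors.
    """
    if bank is None:
        bank = default_bank()
    if vectors is None:
        vectors = [
            compute_descriptor_vector(c, bank, shape_id=str(i))
            for i, c in enumerate(corpus)
        ]
    n = len(vectors)
    if n < 3:
        raise InvalidInputError("corpus too small")
    K_eff = min(K, n - 1)
    if K_eff < K:
        warnings.warn(f"K reduced from {K} to {K_eff} for n={n}", stacklevel=2)
    feats = descriptor_matrix(vectors)
    norms = {k: float(pdist(m).max()) for k, m in feats.items()}
    usable = {k: m for k, m in feats.items() if norms[k] > 0}
    D = _combined_from_features(usable, norms)
    mds = classical_mds(D, K_eff)
    return ShapeSpace(
        bank_version=bank.version,
        descriptor_ids=list(usable),
        features=usable,
        norms={k: norms[k] for k in usable},
        K=mds.coordinates.shape[1],
        coordinates=mds.coordinates,
        eigenvalues=mds.eigenvalues,
        variance_explained=mds.variance_explained,
        meta={"n_shapes": n},
    )


def compare_spaces(
    space_a: ShapeSpace,
    space_b: ShapeSpace,
    test_shapes: list[Contour],
    bank: DescriptorBank | None = None,
    n_ref: int | None = None,
    seed: int = 0,
) -> float:
    """Pearson correlation of test-shape distance structure across spaces.

    Each test shape is embedded into both spaces; within each space the
    pairwise Euclidean distances between the embedded test shapes are
    collected and the two strict upper triangles correlated.  Values near 1
    mean the two spaces order shape similarity the same way even if they
    were built from different corpora or descriptor subsets.
    """
    from .embed import embed_new_shape  # local import to avoid a cycle

    if len(test_shapes) < 3:
        raise InvalidInputError("need >= 3 test shapes")
    if bank is None:
        bank = default_bank()
    vectors = [compute_descriptor_vector(c, bank) for c in test_shapes]
    dists = []
    for space in (space_a, space_b):
        coords = np.vstack(
            [
                embed_new_shape(space, v, n_ref=n_ref, seed=seed).coordinates
                for v in vectors
            ]
        )
        dists.append(pdist(coords))
    return float(pearsonr(dists[0], dists[1]).statistic)


def cluster_descriptors(
    vectors: list[DescriptorVector],
    damping: float = 0.5,
    random_state: int = 0,
) -> dict:
    """Group correlated descriptors by affinity propagation.

    Each descriptor is represented by its profile of normalized pairwise
    distances across the corpus (well-defined for scalar and vector-valued
    descriptors alike); the similarity between two descriptors is the
    absolute Pearson correlation of their profiles, so descriptors that
    order shape pairs the same way land in one cluster.  The affinity
    propagation preference defaults to the median similarity.
    Returns labels, exemplars and the similarity
    matrix.  If affinity propagation fails to converge the fit is retried
    once with damping 0.9.
    """
    stack = descriptor_distance_stack(vectors)
    ids = stack.ids
    if len(ids) < 3:
        raise InvalidInputError("need >= 3 non-constant descriptors")
    n = stack.per_descriptor[ids[0]].shape[0]
    iu = np.triu_indices(n, k=1)
    profiles = np.vstack([stack.normalized(k)[iu] for k in ids])
    sim = np.abs(np.corrcoef(profiles))
    sim = np.nan_to_num(sim, nan=0.0)
    for damp in (damping, 0.9):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ap = AffinityPropagation(
                affinity="precomputed",
                damping=damp,
                preference=np.median(sim),
                random_state=random_state,
                max_iter=500,
            ).fit(sim)
        if ap.labels_[0] != -1 and len(ap.cluster_centers_indices_) > 0:
            break
        warnings.warn("affinity propagation did not converge; retrying damping=0.9")
    labels = ap.labels_
    exemplars = [ids[i] for i in ap.cluster_centers_indices_]
    return {
        "labels": {d: int(l) for d, l in zip(ids, labels)},
        "exemplars": exemplars,
        "n_clusters": len(exemplars),
        "similarity": sim,
        "ids": ids,
    }
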