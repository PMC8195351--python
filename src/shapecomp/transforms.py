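"""Parametric contour transformations and descriptor sensitivity analysis.

Four transformations probe how strongly each descriptor reacts to a
controlled change of the outline:

* **rotation** by an angle about the area centroid (an isometry),
* **shear** along y by factor ``a`` about the centroid (area preserving),
* **bloat** — every point's centroid radius r is replaced by r^0.75
  (angles untouched), which inflates concavities; applied iteratively for
  increasing magnitude, the result re-normalized to [0, 1],
* **contour noise** — i.i.d. Gaussian displacement of every vertex with
  sigma given as a fraction of the shape's maximum chord length.

For a set of category exemplar shapes, ``sensitivity_table`` sweeps each
transformation over its magnitudes, measures the absolute descriptor
change between the original and each variant, min-max normalizes those
changes per (category, descriptor) across the variants of *all*
transformations jointly, and averages.  The resulting score S in [0, 1]
is 0 for a descriptor invariant to the transformation (relative to how
much other transformations move it) and 1 for the most sensitive case;
a descriptor that never changes at all yields NaN for that category and
is excluded from the cross-category mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .contour import Contour, canonicalize_start, normalize_coords, polygon_moments
from .descriptors import DescriptorBank, compute_descriptor_vector, default_bank
from .errors import InvalidInputError

__all__ = [
    "TransformSpec",
    "SensitivityTable",
    "apply_rotation",
    "apply_shear",
    "apply_bloat",
    "apply_noise",
    "sweep_variants",
    "default_specs",
    "sensitivity_table",
]

KINDS = ("rotation", "shear", "bloat", "noise")


@dataclass(frozen=True)
class TransformSpec:
    """A transformation kind plus the ordered magnitudes to sweep.

    Magnitudes are degrees for rotation, the shear factor a, the iteration
    count for bloat, and the noise fraction of the maximum chord length.
    """

    kind: str
    magnitudes: tuple[float, ...]
    seed: int = 0  # noise only

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InvalidInputError(f"unknown transform kind {self.kind!r}")
        mags = np.asarray(self.magnitudes, dtype=float)
        if len(mags) == 0 or np.any(np.diff(mags) <= 0):
            raise InvalidInputError("magnitudes must be nonempty and strictly increasing")
        if self.kind == "rotation" and not np.all((mags > 0) & (mags < 360)):
            raise InvalidInputError("rotation magnitudes must lie in (0, 360) degrees")
        if self.kind == "bloat" and not np.all(mags == mags.astype(int)):
            raise InvalidInputError("bloat magnitudes are iteration counts")
        if self.kind == "noise" and not np.all((mags > 0) & (mags <= 0.1)):
            raise InvalidInputError("noise fractions must lie in (0, 0.1]")


def _centroid(c: Contour) -> np.ndarray:
    m = polygon_moments(c.points)
    return np.array([m["cx"], m["cy"]])


def apply_rotation(c: Contour, theta: float) -> Contour:
    """Rotate by ``theta`` degrees about the area centroid."""
    t = np.radians(theta)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    ctr = _centroid(c)
    return Contour((c.points - ctr) @ rot.T + ctr, meta=c.meta)


def apply_shear(c: Contour, a: float) -> Contour:
    """Shear along y by factor ``a`` about the centroid: (x, y) -> (x, ax + y)."""
    if a < 0:
        raise InvalidInputError("shear factor must be >= 0")
    ctr = _centroid(c)
    pts = c.points - ctr
    out = np.column_stack([pts[:, 0], a * pts[:, 0] + pts[:, 1]])
    return Contour(out + ctr, meta=c.meta)


def apply_bloat(c: Contour, iterations: int = 1) -> Contour:
    """Replace each centroid radius r by r^0.75, ``iterations`` times.

    Radii are measured in the normalized [0, 1] frame, where r < 1 for
    typical shapes, so the power map pushes points outward and inflates
    concavities.  The result is re-normalized to [0, 1] after each pass.
    """
    if iterations < 1:
        raise InvalidInputError("iterations must be >= 1")
    out = c
    for _ in range(iterations):
        ctr = _centroid(out)
        d = out.points - ctr
        r = np.hypot(d[:, 0], d[:, 1])
        scale = np.where(r > 0, r**0.75 / np.maximum(r, 1e-30), 1.0)
        out = normalize_coords(Contour(ctr + d * scale[:, None], meta=c.meta))
    return out


def apply_noise(c: Contour, level_fraction: float, seed: int = 0) -> Contour:
    """Add i.i.d. Gaussian jitter to every vertex coordinate.

    sigma = ``level_fraction`` times the maximum distance between any two
    contour points, so the level is relative to shape extent.
    """
    if not 0 < level_fraction <= 0.1:
        raise InvalidInputError("level_fraction must lie in (0, 0.1]")
    sigma = level_fraction * float(pdist(c.points).max())
    rng = np.random.default_rng(seed)
    return Contour(c.points + rng.normal(0.0, sigma, c.points.shape), meta=c.meta)


def default_specs(seed: int = 0) -> list[TransformSpec]:
    """The default sweep: rotation every 15 deg (23 variants, identity
    excluded), shear a in {0.2..1.0}, bloat 1-4 iterations, and 8
    log-spaced noise fractions between 0.5% and 4% of the max chord."""
    return [
        TransformSpec("rotation", tuple(np.arange(15.0, 360.0, 15.0))),
        TransformSpec("shear", (0.2, 0.4, 0.6, 0.8, 1.0)),
        TransformSpec("bloat", (1, 2, 3, 4)),
        TransformSpec("noise", tuple(np.geomspace(0.005, 0.04, 8)), seed=seed),
    ]


def sweep_variants(c: Contour, spec: TransformSpec) -> list[Contour]:
    """Apply the transform at every magnitude of the spec."""
    out = []
    for i, m in enumerate(spec.magnitudes):
        if spec.kind == "rotation":
            out.append(apply_rotation(c, m))
        elif spec.kind == "shear":
            out.append(apply_shear(c, m))
        elif spec.kind == "bloat":
            out.append(apply_bloat(c, int(m)))
        else:
            out.append(apply_noise(c, m, seed=spec.seed + i))
    return out


@dataclass
class SensitivityTable:
    """Descriptor x transform sensitivity scores.

    ``table`` holds the cross-category mean S (NaN-aware); ``per_category``
    is the underlying (category, descriptor, transform) tensor.
    """

    table: pd.DataFrame  # index: descriptor id, columns: transform kind
    per_category: np.ndarray  # (n_categories, n_descriptors, n_transforms)
    descriptor_ids: list[str]
    transform_kinds: list[str]
    n_categories_used: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view (descriptor, transform, sensitivity, n)."""
        rows = []
        for d in self.table.index:
            for t in self.table.columns:
                rows.append(
                    {
                        "descriptor": d,
                        "transform": t,
                        "sensitivity": self.table.loc[d, t],
                        "n_categories_used": int(self.n_categories_used.loc[d, t]),
                    }
                )
        return pd.DataFrame(rows)


def _descriptor_diffs(
    original: dict[str, np.ndarray], variant: dict[str, np.ndarray], ids: list[str]
) -> np.ndarray:
    return np.array(
        [
            np.linalg.norm(original[i] - variant[i]) if i in variant and i in original else np.nan
            for i in ids
        ]
    )


def sensitivity_table(
    shapes: list[Contour],
    bank: DescriptorBank | None = None,
    specs: list[TransformSpec] | None = None,
    start_seed: int = 0,
) -> SensitivityTable:
    """Sensitivity of every descriptor to every transformation.

    ``shapes`` are canonical category exemplars (one per category).  At
    least two transformations are required: each descriptor's changes are
    min-max normalized across the pooled variants of all transformations,
    so with a single transformation the normalization is vacuous (every
    score would be forced to span [0, 1] within that same transform).
    """
    if specs is None:
        specs = default_specs()
    if len(specs) < 2:
        raise InvalidInputError("sensitivity normalization needs >= 2 transforms")
    if len(shapes) < 1:
        raise InvalidInputError("need at least one category shape")
    if bank is None:
        bank = default_bank()
    ids = bank.ids
    kinds = [s.kind for s in specs]
    per_cat = np.full((len(shapes), len(ids), len(specs)), np.nan)

    for ci, shape in enumerate(shapes):
        base = compute_descriptor_vector(shape, bank).values
        diffs_by_spec = []
        for spec in specs:
            block = []
            for variant in sweep_variants(shape, spec):
                v = compute_descriptor_vector(
                    canonicalize_start(variant, seed=start_seed), bank
                ).values
                block.append(_descriptor_diffs(base, v, ids))
            diffs_by_spec.append(np.vstack(block))  # (n_variants, n_descriptors)
        pooled = np.vstack(diffs_by_spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d_min = np.nanmin(pooled, axis=0)
            d_max = np.nanmax(pooled, axis=0)
            span = d_max - d_min
            for ti, block in enumerate(diffs_by_spec):
                with np.errstate(invalid="ignore", divide="ignore"):
                    norm = (block - d_min) / span
                per_cat[ci, :, ti] = np.nanmean(norm, axis=0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_cat, axis=0)
    counts = np.sum(~np.isnan(per_cat), axis=0)
    return SensitivityTable(
        table=pd.DataFrame(mean, index=ids, columns=kinds),
        per_category=per_cat,
        descriptor_ids=ids,
        transform_kinds=kinds,
        n_categories_used=pd.DataFrame(counts, index=ids, columns=kinds),
    )
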