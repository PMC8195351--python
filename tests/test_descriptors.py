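import numpy as np
import pytest
import shapely
from hypothesis import given, settings
from hypothesis import strategies as st

from shapecomp import (
    BlobParams,
    Contour,
    apply_rotation,
    canonicalize,
    canonicalize_start,
    generate_blob,
    rasterize,
)
from shapecomp.contour import normalize_coords, polygon_area, trace_mask
from shapecomp.descriptors import (
    basic_descriptors,
    chord_lengths,
    compute_descriptor_vector,
    curvature_features,
    default_bank,
    fourier_descriptors,
    shape_context_features,
    skeleton_features,
)
from shapecomp.errors import InsufficientPointsError

from conftest import circle_contour, ellipse_contour, square_contour, star_contour

ROTATION_INVARIANT = ["solidity", "compactness", "eccentricity", "chord_hist"]


class TestBasicDescriptors:
    def test_convex_polygon_solidity_one(self):
        d = basic_descriptors(canonicalize(square_contour(), n=64))
        assert d["solidity"] == pytest.approx(1.0, abs=1e-9)

    def test_circle_compactness_one(self, canonical_circle):
        d = basic_descriptors(canonical_circle)
        assert d["compactness"] == pytest.approx(1.0, abs=1e-3)

    def test_star_solidity_against_hull_oracle(self):
        """Solidity of a 5-point star equals shoelace area / hull area
        computed independently with shapely."""
        star = star_contour(5, r_out=1.0, r_in=0.4)
        d = basic_descriptors(star)
        poly = shapely.Polygon(star.points)
        expected = poly.area / poly.convex_hull.area
        assert d["solidity"] == pytest.approx(expected, abs=1e-9)

    def test_ellipse_orientation_and_aspect(self):
        e = ellipse_contour(a=1.0, b=0.5)
        d = basic_descriptors(e)
        assert d["major_axis_orientation"] == pytest.approx(0.0, abs=0.5)
        assert d["aspect_ratio"] == pytest.approx(2.0, rel=1e-2)
        assert 0.8 < d["eccentricity"] < 0.9  # sqrt(1 - (b/a)^2) = 0.866

    def test_orientation_range(self, blobs5):
        for b in blobs5:
            ang = basic_descriptors(b)["major_axis_orientation"]
            assert -90.0 < ang <= 90.0


class TestCurvature:
    def test_circle_curvature_is_inverse_radius(self):
        c = circle_contour(n=384, r=0.5)
        kappa, _ = curvature_features(c, smooth_sigma=2.0)
        np.testing.assert_allclose(kappa, 2.0, rtol=0.02)

    def test_convex_blob_total_turning_2pi(self):
        c = generate_blob(BlobParams(seed=2, n_lobes=0, spikiness=0.0, elongation=1.3))
        _, s = curvature_features(c)
        assert s["total_abs_turning"] == pytest.approx(2 * np.pi, rel=0.02)

    def test_rotation_invariance_of_mean_abs(self, blob):
        _, s0 = curvature_features(blob)
        _, s1 = curvature_features(apply_rotation(blob, 90.0))
        assert s1["curvature_mean_abs"] == pytest.approx(
            s0["curvature_mean_abs"], abs=1e-6
        )


class TestFourier:
    def test_circle_all_harmonics_tiny(self, canonical_circle):
        amps = fourier_descriptors(canonical_circle, 20)
        assert np.all(amps < 1e-6)

    def test_ellipse_harmonic_two_dominates(self):
        """Oracle: the exact centroid-distance signature of a 2:1 ellipse is
        pi-periodic, so all odd harmonics vanish and harmonic 2 carries the
        largest amplitude — checked against a direct DFT of the signature."""
        e = ellipse_contour(a=1.0, b=0.5, n=384)
        amps = fourier_descriptors(e, 20)
        assert np.argmax(amps) == 1  # harmonic 2 (index 1)
        # independent DFT oracle on the raw signature
        t = np.linspace(0, 2 * np.pi, 384, endpoint=False)
        r = np.hypot(np.cos(t), 0.5 * np.sin(t))
        spec = np.abs(np.fft.rfft(r))
        oracle = spec[1:21] / spec[0]
        np.testing.assert_allclose(amps, oracle, atol=1e-12)

    def test_amplitudes_discard_start_phase(self, blob):
        rolled = Contour(np.roll(blob.points, 37, axis=0))
        np.testing.assert_allclose(
            fourier_descriptors(blob, 20), fourier_descriptors(rolled, 20), atol=1e-9
        )

    def test_harmonic_bounds(self, blob):
        with pytest.raises(InsufficientPointsError):
            fourier_descriptors(blob, len(blob))


class TestShapeContext:
    def test_histograms_sum_to_n_minus_1(self, blob):
        f = shape_context_features(blob)
        np.testing.assert_allclose(f["per_point"].sum(axis=1), len(blob) - 1)

    def test_square_chord_enumeration(self):
        """4 unit-square corners: 6 chords {1,1,1,1,sqrt2,sqrt2}."""
        chords = np.sort(chord_lengths(square_contour()))
        np.testing.assert_allclose(chords, [1, 1, 1, 1, np.sqrt(2), np.sqrt(2)])
        assert chords.mean() == pytest.approx((4 + 2 * np.sqrt(2)) / 6)

    def test_scale_invariant_histograms(self, blob):
        f0 = shape_context_features(blob)
        f1 = shape_context_features(Contour(blob.points * 7.5))
        np.testing.assert_allclose(f0["per_point"], f1["per_point"], atol=1e-9)
        np.testing.assert_allclose(f0["chord_hist"], f1["chord_hist"], atol=1e-9)

    def test_too_few_points(self):
        with pytest.raises(InsufficientPointsError):
            shape_context_features(square_contour())


class TestSkeleton:
    def test_disk_degenerate_skeleton(self):
        m = rasterize(circle_contour(n=128, r=0.45), grid=128)
        s = skeleton_features(m)
        assert s["skel_endpoint_count"] <= 2
        assert s["skel_junction_count"] == 0

    def test_cross_topology(self):
        """Plus-sign mask: 4 endpoints, 1 junction."""
        img = np.zeros((64, 64), bool)
        img[28:36, 8:56] = True
        img[8:56, 28:36] = True
        c = normalize_coords(trace_mask(img))
        m = rasterize(c, grid=128)
        s = skeleton_features(m)
        assert s["skel_endpoint_count"] == 4
        assert s["skel_junction_count"] == 1
        assert s["skel_branch_count"] == 4

    def test_rotation_by_right_angle_preserves_counts(self, blob):
        m0 = rasterize(blob, grid=128)
        rot = canonicalize(apply_rotation(blob, 90.0), n=len(blob))
        m1 = rasterize(rot, grid=128)
        s0, s1 = skeleton_features(m0), skeleton_features(m1)
        assert s0["skel_endpoint_count"] == s1["skel_endpoint_count"]
        assert s0["skel_junction_count"] == s1["skel_junction_count"]


class TestDescriptorVector:
    def test_completeness_and_determinism(self, blob, bank):
        v1 = compute_descriptor_vector(blob, bank)
        v2 = compute_descriptor_vector(blob, bank)
        assert v1.complete
        assert set(v1.values) == set(bank.ids)
        for k in bank.ids:
            np.testing.assert_array_equal(v1[k], v2[k])
            assert np.all(np.isfinite(v1[k]))

    def test_rotation_invariance_dichotomy(self, blob, bank):
        """Solidity/compactness/chord histogram survive a 37-degree rotation
        unchanged while the major-axis orientation shifts by 37 degrees."""
        v0 = compute_descriptor_vector(blob, bank)
        rot = canonicalize_start(apply_rotation(blob, 37.0), seed=0)
        v1 = compute_descriptor_vector(rot, bank)
        for k in ROTATION_INVARIANT:
            np.testing.assert_allclose(v1[k], v0[k], atol=1e-6, err_msg=k)
        delta = v1["major_axis_orientation"][0] - v0["major_axis_orientation"][0]
        delta = (delta + 90) % 180 - 90
        assert abs(delta - 37.0) < 0.5 or abs(delta + 143.0) < 0.5

    def test_bank_registry(self, bank):
        assert len(bank) >= 40
        assert bank.families == {
            "basic", "curvature", "fourier", "signature",
            "shape_context", "skeleton", "moments",
        }
        assert any(d.start_dependent for d in bank)
        sub = bank.subset(["solidity", "area"])
        assert sub.ids == ["solidity", "area"]
        assert sub.version != bank.version

    def test_start_dependent_flag_is_real(self, blob, bank):
        """Start-dependent descriptors change under a cyclic shift of the
        start point; start-independent ones do not."""
        rolled = Contour(np.roll(blob.points, len(blob) // 3, axis=0))
        v0 = compute_descriptor_vector(blob, bank)
        v1 = compute_descriptor_vector(rolled, bank)
        dep = [d.id for d in bank if d.start_dependent]
        assert dep
        for k in dep:
            assert not np.allclose(v0[k], v1[k], atol=1e-9), k
        np.testing.assert_allclose(v0["sc_mean"], v1["sc_mean"], atol=1e-9)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 5_000))
def test_all_descriptors_finite_on_fuzzed_blobs(seed):
    bank = default_bank()
    rng = np.random.default_rng(seed)
    p = BlobParams(
        seed=seed,
        n_points=256,
        elongation=float(rng.uniform(1.0, 3.0)),
        n_lobes=int(rng.integers(0, 8)),
        lobe_amplitude=float(rng.uniform(0.0, 0.5)),
        spikiness=float(rng.uniform(0.0, 0.12)),
    )
    v = compute_descriptor_vector(generate_blob(p), bank)
    assert v.complete, v.errors
    for k, val in v.values.items():
        assert np.all(np.isfinite(val)), k
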