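import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from shapecomp import (
    CorpusSpec,
    ShapeSpace,
    build_space,
    classical_mds,
    cluster_descriptors,
    combined_distance_matrix,
    descriptor_distance_stack,
    generate_corpus,
)
from shapecomp.descriptors import (
    DescriptorBank,
    DescriptorDefinition,
    DescriptorVector,
    compute_descriptor_vector,
    default_bank,
)
from shapecomp.errors import (
    DegenerateCorpusError,
    IncompatibleBankError,
    InvalidInputError,
)


def _toy_vectors(values_by_id: dict[str, list], version="toy") -> list[DescriptorVector]:
    n = len(next(iter(values_by_id.values())))
    return [
        DescriptorVector(
            shape_id=str(i),
            values={k: np.atleast_1d(np.asarray(v[i], float)) for k, v in values_by_id.items()},
            bank_version=version,
        )
        for i in range(n)
    ]


@pytest.fixture(scope="module")
def small_corpus_vectors(bank):
    shapes, _ = generate_corpus(CorpusSpec(n_shapes=30, n_categories=3, seed=11))
    return shapes, [compute_descriptor_vector(c, bank) for c in shapes]


class TestDistanceStack:
    def test_single_pair_defines_max(self):
        vecs = _toy_vectors({"f": [0.2, 0.7]})
        stack = descriptor_distance_stack(vecs)
        assert stack.per_descriptor["f"][0, 1] == pytest.approx(0.5)
        assert stack.normalized("f")[0, 1] == pytest.approx(1.0)

    def test_clone_corpus_all_constant(self):
        vecs = _toy_vectors({"f": [1.0, 1.0, 1.0], "g": [2.0, 2.0, 2.0]})
        with pytest.warns(UserWarning, match="constant"):
            stack = descriptor_distance_stack(vecs)
        assert set(stack.constant_ids) == {"f", "g"}
        with pytest.raises(DegenerateCorpusError):
            combined_distance_matrix(stack)

    def test_normalization_contract_random_vectors(self):
        rng = np.random.default_rng(0)
        vecs = _toy_vectors({f"d{k}": rng.normal(size=10) for k in range(4)})
        stack = descriptor_distance_stack(vecs)
        for k in stack.ids:
            m = stack.normalized(k)
            assert m.max() == pytest.approx(1.0)
            np.testing.assert_allclose(np.diag(m), 0.0)
            np.testing.assert_allclose(m, m.T)

    def test_mixed_banks_rejected(self):
        a = _toy_vectors({"f": [0.0, 1.0]}, version="a")
        b = _toy_vectors({"f": [0.0, 1.0]}, version="b")
        with pytest.raises(IncompatibleBankError):
            descriptor_distance_stack([a[0], b[1]])


class TestCombinedDistance:
    def test_three_four_five(self):
        vecs = _toy_vectors({"f": [0.0, 0.6], "g": [0.0, 0.8]})
        stack = descriptor_distance_stack(vecs)
        # per-pair normalized distances are 1.0 each (single pair sets max);
        # rescale by hand to the 3-4-5 case via raw matrices
        d = np.sqrt(0.6**2 + 0.8**2)
        raw = np.sqrt(
            stack.per_descriptor["f"] ** 2 + stack.per_descriptor["g"] ** 2
        )
        assert raw[0, 1] == pytest.approx(d)
        assert combined_distance_matrix(stack)[0, 1] == pytest.approx(np.sqrt(2.0))

    def test_upper_bound_sqrt_k(self):
        rng = np.random.default_rng(1)
        vecs = _toy_vectors({f"d{k}": rng.normal(size=12) for k in range(5)})
        D = combined_distance_matrix(descriptor_distance_stack(vecs))
        assert D.max() <= np.sqrt(5) + 1e-12

    def test_triangle_inequality_exhaustive(self):
        """Combined distance is Euclidean on per-descriptor difference
        profiles, hence a metric: check all triples of a 12-shape corpus."""
        rng = np.random.default_rng(2)
        vecs = _toy_vectors({f"d{k}": rng.normal(size=12) for k in range(6)})
        D = combined_distance_matrix(descriptor_distance_stack(vecs))
        for i, j, k in itertools.permutations(range(12), 3):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


class TestClassicalMDS:
    def test_three_collinear_points(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        res = classical_mds(D, 1)
        d_fit = pdist(res.coordinates)
        np.testing.assert_allclose(np.sort(d_fit), [1, 1, 2], atol=1e-9)
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-9)

    def test_exact_recovery_of_euclidean_configuration(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 5))
        D = squareform(pdist(X))
        with pytest.warns(UserWarning, match="positive"):
            res = classical_mds(D, 19)  # only 5 dimensions are real
        np.testing.assert_allclose(squareform(pdist(res.coordinates)), D, atol=1e-8)

    def test_square_variance_splits_evenly(self):
        """The 4 vertices of a unit square: symmetry forces two equal
        eigenvalues, so the 2-D embedding splits variance 50/50."""
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        res = classical_mds(squareform(pdist(pts)), 2)
        np.testing.assert_allclose(res.variance_explained, [0.5, 0.5], atol=1e-9)

    def test_k_exceeding_positive_rank_warns(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)  # rank-1 config
        with pytest.warns(UserWarning, match="positive"):
            res = classical_mds(D, 2)
        assert res.coordinates.shape[1] == 1

    def test_input_validation(self):
        with pytest.raises(InvalidInputError):
            classical_mds(np.arange(6.0).reshape(2, 3), 1)
        with pytest.raises(InvalidInputError):
            classical_mds(np.zeros((3, 3)), 3)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        D = squareform(pdist(rng.normal(size=(10, 3))))
        a = classical_mds(D, 3).coordinates
        b = classical_mds(D, 3).coordinates
        np.testing.assert_array_equal(a, b)
        for col in a.T:
            assert col[np.abs(col).argmax()] > 0


class TestBuildSpace:
    def test_shapes_and_monotone_fit(self, small_corpus_vectors, bank):
        shapes, vectors = small_corpus_vectors
        space = build_space(shapes, bank=bank, K=10, vectors=vectors)
        assert space.coordinates.shape == (30, 10)
        assert np.all(space.variance_explained >= 0)
        assert space.variance_explained.sum() <= 1 + 1e-12
        # truncated-MDS fit improves with K
        from shapecomp.space import _combined_from_features, descriptor_matrix

        D = _combined_from_features(space.features, space.norms)
        iu = np.triu_indices(30, 1)
        r10 = pearsonr(pdist(space.coordinates), D[iu]).statistic
        r5 = pearsonr(pdist(space.coordinates[:, :5]), D[iu]).statistic
        assert r10 >= r5

    def test_determinism(self, small_corpus_vectors, bank):
        shapes, vectors = small_corpus_vectors
        a = build_space(shapes, bank=bank, K=8, vectors=vectors)
        b = build_space(shapes, bank=bank, K=8, vectors=vectors)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_k_autoreduced_small_corpus(self, small_corpus_vectors, bank):
        shapes, vectors = small_corpus_vectors
        with pytest.warns(UserWarning, match="K reduced"):
            space = build_space(shapes[:10], bank=bank, K=22, vectors=vectors[:10])
        assert space.K <= 9

    def test_corpus_order_invariance(self, small_corpus_vectors, bank):
        """Coordinates of the same shape agree regardless of corpus order,
        thanks to the fixed eigenvector sign convention."""
        shapes, vectors = small_corpus_vectors
        a = build_space(shapes, bank=bank, K=5, vectors=vectors)
        perm = np.random.default_rng(0).permutation(30)
        b = build_space(
            [shapes[i] for i in perm], bank=bank, K=5, vectors=[vectors[i] for i in perm]
        )
        np.testing.assert_allclose(
            a.coordinates[perm], b.coordinates, atol=1e-6
        )

    def test_roundtrip_serialization(self, small_corpus_vectors, bank, tmp_path):
        shapes, vectors = small_corpus_vectors
        space = build_space(shapes, bank=bank, K=6, vectors=vectors)
        space.save(tmp_path / "space")
        back = ShapeSpace.load(tmp_path / "space")
        np.testing.assert_array_equal(back.coordinates, space.coordinates)
        np.testing.assert_array_equal(back.eigenvalues, space.eigenvalues)
        assert back.norms == space.norms
        assert back.descriptor_ids == space.descriptor_ids
        assert back.bank_version == space.bank_version
        for k in space.features:
            np.testing.assert_array_equal(back.features[k], space.features[k])


class TestClusterDescriptors:
    def test_duplicate_descriptor_lands_in_same_cluster(self, small_corpus_vectors):
        _, vectors = small_corpus_vectors
        dup = [
            DescriptorVector(
                v.shape_id,
                {**v.values, "solidity_copy": v.values["solidity"].copy()},
                v.bank_version,
            )
            for v in vectors
        ]
        res = cluster_descriptors(dup)
        assert res["labels"]["solidity"] == res["labels"]["solidity_copy"]
        assert 1 <= res["n_clusters"] <= len(res["ids"])

    def test_planted_two_group_structure(self):
        """Two blocks of descriptors with within-group correlation ~0.95 and
        zero across-group correlation are recovered as exactly 2 clusters."""
        rng = np.random.default_rng(5)
        n = 200
        base1, base2 = rng.normal(size=n), rng.normal(size=n)
        values = {}
        for g, base in enumerate((base1, base2)):
            for j in range(4):
                values[f"g{g}_d{j}"] = base + 0.32 * rng.normal(size=n)
        vecs = _toy_vectors(values)
        res = cluster_descriptors(vecs, random_state=0)
        assert res["n_clusters"] == 2
        for g in (0, 1):
            labs = {res["labels"][f"g{g}_d{j}"] for j in range(4)}
            assert len(labs) == 1
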