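import numpy as np
import pandas as pd
import pytest
import scipy.spatial.distance
import skbio.diversity.alpha
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from omicsconcord.diversity import (
    DistanceMatrix,
    bray_curtis,
    chao1,
    distance_matrix,
    pcoa,
    relative_abundance,
    shannon,
    simpson,
    sqrt_transform,
)
from omicsconcord.io_model import FeatureTable, ValidationError

positive_counts = arrays(
    np.int64, st.integers(2, 20), elements=st.integers(0, 50)
).filter(lambda a: a.sum() > 0)


class TestRelativeAbundance:
    def test_single_feature(self):
        table = FeatureTable(pd.DataFrame({"s1": [7.0]}, index=["f1"]), "counts")
        assert relative_abundance(table).data.loc["f1", "s1"] == 1.0

    def test_direct_normalization(self):
        table = FeatureTable(
            pd.DataFrame({"s1": [2.0, 2.0, 4.0]}, index=list("abc")), "counts"
        )
        out = relative_abundance(table)
        assert out.kind == "proportion"
        np.testing.assert_allclose(out.data["s1"], [0.25, 0.25, 0.5])

    def test_zero_column_is_error(self):
        table = FeatureTable(
            pd.DataFrame({"s1": [1.0], "s2": [0.0]}, index=["f1"]), "counts"
        )
        with pytest.raises(ValidationError, match="zero-total"):
            relative_abundance(table)


class TestSqrtTransform:
    def test_values(self):
        table = FeatureTable(
            pd.DataFrame({"s1": [0.25, 0.75], "s2": [0.0, 1.0]}, index=["a", "b"]),
            "proportion",
        )
        out = sqrt_transform(table)
        assert out.data.loc["a", "s1"] == 0.5
        assert out.data.loc["a", "s2"] == 0.0
        assert out.data.loc["b", "s2"] == 1.0
        assert out.kind == "transformed"

    def test_requires_proportions(self, small_counts):
        with pytest.raises(ValidationError):
            sqrt_transform(small_counts)


class TestAlphaIndices:
    def test_shannon_uniform(self):
        assert shannon([1, 1, 1, 1]) == pytest.approx(np.log(4))

    def test_shannon_single_feature(self):
        assert shannon([5]) == 0.0

    def test_shannon_derived(self):
        # -sum(p ln p) with p = (0.25, 0.25, 0.5)
        assert shannon([1, 1, 2]) == pytest.approx(1.0397, abs=1e-4)

    def test_simpson_uniform(self):
        assert simpson([1, 1, 1, 1]) == pytest.approx(0.75)

    def test_simpson_single(self):
        assert simpson([3]) == 0.0

    def test_simpson_derived(self):
        assert simpson([1, 1, 2]) == pytest.approx(0.625)

    def test_chao1_no_singletons(self):
        assert chao1([2, 3, 5]) == 3.0

    def test_chao1_derived(self):
        assert chao1([1, 1, 2, 2, 5]) == pytest.approx(5 + 2 * 1 / (2 * 3))
        assert chao1([1, 1, 1]) == pytest.approx(6.0)

    def test_all_zero_is_error(self):
        for fn in (shannon, simpson, chao1):
            with pytest.raises(ValidationError):
                fn([0, 0])

    @given(positive_counts)
    @settings(max_examples=50, deadline=None)
    def test_matches_skbio(self, counts):
        assert shannon(counts) == pytest.approx(
            float(skbio.diversity.alpha.shannon(counts, base=np.e)), abs=1e-9
        )
        assert simpson(counts) == pytest.approx(
            float(skbio.diversity.alpha.simpson(counts)), abs=1e-9
        )
        assert chao1(counts) == pytest.approx(
            float(skbio.diversity.alpha.chao1(counts, bias_corrected=True)), abs=1e-9
        )

    @given(positive_counts, st.integers(2, 7))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, counts, factor):
        assert shannon(counts * factor) == pytest.approx(shannon(counts))
        assert simpson(counts * factor) == pytest.approx(simpson(counts))

    @given(positive_counts)
    @settings(max_examples=30, deadline=None)
    def test_chao1_at_least_observed_richness(self, counts):
        assert chao1(counts) >= (counts > 0).sum()


class TestBrayCurtis:
    def test_identical(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint(self):
        assert bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    def test_derived(self):
        assert bray_curtis([1, 0, 3], [0, 2, 2]) == pytest.approx(0.5)

    def test_both_zero_is_error(self):
        with pytest.raises(ValidationError):
            bray_curtis([0, 0], [0, 0])

    @given(
        arrays(np.float64, 5, elements=st.floats(0, 100)),
        arrays(np.float64, 5, elements=st.floats(0, 100)),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_symmetry(self, x, y):
        if (x + y).sum() == 0:
            return
        d = bray_curtis(x, y)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(bray_curtis(y, x))
        if np.array_equal(x, y):
            assert d == 0.0


class TestDistanceMatrix:
    def test_identical_samples(self):
        table = FeatureTable(
            pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]}, index=["f1", "f2"]),
            "counts",
        )
        dm = distance_matrix(table)
        assert dm.between("a", "b") == 0.0

    def test_shape_and_symmetry(self, small_counts):
        dm = distance_matrix(small_counts.select_samples(["s1", "s2"]))
        assert dm.values.shape == (2, 2)

    def test_matches_elementwise_and_scipy(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 30, size=(6, 5)).astype(float)
        table = FeatureTable(
            pd.DataFrame(X, index=[f"f{i}" for i in range(6)],
                         columns=[f"s{j}" for j in range(5)]),
            "counts",
        )
        dm = distance_matrix(table)
        for i in range(5):
            for j in range(5):
                if i != j:
                    assert dm.values[i, j] == pytest.approx(
                        bray_curtis(X[:, i], X[:, j])
                    )
        expected = scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(X.T, metric="braycurtis")
        )
        np.testing.assert_allclose(dm.values, expected, atol=1e-12)

    def test_round_trip_tsv(self, tmp_path, small_counts):
        dm = distance_matrix(small_counts)
        dm.write_tsv(tmp_path / "d.tsv")
        back = DistanceMatrix.read_tsv(tmp_path / "d.tsv")
        np.testing.assert_allclose(back.values, dm.values)
        assert back.sample_ids == dm.sample_ids


class TestPcoa:
    def test_two_samples(self):
        dm = DistanceMatrix(np.array([[0.0, 3.0], [3.0, 0.0]]), ["a", "b"])
        res = pcoa(dm, n_axes=1)
        coords = res.coordinates["PC1"].to_numpy()
        np.testing.assert_allclose(np.sort(np.abs(coords)), [1.5, 1.5])

    def test_equilateral_three_points(self):
        D = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(D, ["a", "b", "c"]), n_axes=2)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
        assert res.eigenvalues[0] > 0

    def test_euclidean_reconstruction(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(10, 2))
        D = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(pts))
        res = pcoa(DistanceMatrix(D, [f"s{i}" for i in range(10)]), n_axes=2)
        recon = scipy.spatial.distance.squareform(
            scipy.spatial.distance.pdist(res.coordinates.to_numpy())
        )
        np.testing.assert_allclose(recon, D, atol=1e-8)

    def test_eigenvalues_sorted_and_proportions(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        D = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(pts))
        res = pcoa(DistanceMatrix(D, [f"s{i}" for i in range(8)]), n_axes=3)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)
        pos = res.eigenvalues > 1e-12
        assert res.proportion_explained[pos].sum() <= 1 + 1e-9

    def test_n_axes_limit(self):
        dm = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ["a", "b"])
        with pytest.raises(ValidationError, match="n_axes"):
            pcoa(dm, n_axes=2)
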