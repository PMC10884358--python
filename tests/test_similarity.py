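"""Shared variance, dissimilarity closed forms, similarity matrix, MDS."""

import numpy as np
import pytest

import msx
from msx.similarity import dissimilarity_matrix, mds_embed, sv_to_dissimilarity
from conftest import orthonormal_canonical_set


def _tmap(values, montage, label="x"):
    return msx.TemplateMap(label, np.asarray(values, dtype=float), montage)


class TestSharedVariance:
    def test_identity_and_negation(self, prototypes19):
        u = prototypes19[0]
        assert msx.spatial_correlation(u, u) == pytest.approx(1.0, abs=1e-12)
        assert msx.spatial_correlation(u, u.flipped()) == pytest.approx(-1.0, abs=1e-12)
        assert msx.shared_variance(u, u) == pytest.approx(100.0, abs=1e-9)
        assert msx.shared_variance(u, u.flipped()) == pytest.approx(100.0, abs=1e-9)

    def test_orthogonal_pair_hand_oracle(self, m19):
        pad = [0.0] * 11
        u = _tmap(msx.canonicalize_map([1, -1, 1, -1, 0, 0, 0, 0] + pad), m19)
        v = _tmap(msx.canonicalize_map([1, 1, -1, -1, 0, 0, 0, 0] + pad), m19)
        # hand dot product: (1)(1)+(-1)(1)+(1)(-1)+(-1)(-1) = 0
        assert msx.spatial_correlation(u, v) == pytest.approx(0.0, abs=1e-12)
        assert msx.shared_variance(u, v) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_and_argument_order_invariant(self, prototypes19):
        u, v = prototypes19[0], prototypes19[1]
        assert msx.shared_variance(u, v) == pytest.approx(msx.shared_variance(v, u), abs=1e-12)


class TestDissimilarity:
    def test_polarity_invariant_closed_forms(self, prototypes19, m19):
        u = prototypes19[0]
        assert msx.dissimilarity(u, u) == pytest.approx(0.0, abs=1e-9)
        assert msx.dissimilarity(u, u.flipped()) == pytest.approx(0.0, abs=1e-9)
        rows = orthonormal_canonical_set(19, 2, seed=1)
        a, b = _tmap(rows[0], m19), _tmap(rows[1], m19)
        assert msx.dissimilarity(a, b) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_equals_min_distance_over_polarities(self, m19):
        rng = np.random.default_rng(6)
        for _ in range(20):
            u = _tmap(msx.canonicalize_map(rng.standard_normal(19)), m19)
            v = _tmap(msx.canonicalize_map(rng.standard_normal(19)), m19)
            brute = min(
                np.linalg.norm(u.values - v.values), np.linalg.norm(u.values + v.values)
            )
            assert msx.dissimilarity(u, v) == pytest.approx(brute, abs=1e-12)

    def test_signed_variant_is_plain_distance(self, m19):
        rng = np.random.default_rng(7)
        u = _tmap(msx.canonicalize_map(rng.standard_normal(19)), m19)
        v = _tmap(msx.canonicalize_map(rng.standard_normal(19)), m19)
        assert msx.dissimilarity(u, v, polarity_invariant=False) == pytest.approx(
            np.linalg.norm(u.values - v.values), abs=1e-12
        )

    def test_sv_conversion_is_monotone(self):
        svs = np.linspace(0, 100, 50)
        d = sv_to_dissimilarity(svs)
        assert np.all(np.diff(d) < 0)
        assert d[0] == pytest.approx(np.sqrt(2))
        assert d[-1] == pytest.approx(0.0)


class TestSimilarityMatrix:
    def test_map_and_negation_within_one_study(self, m19, prototypes19):
        u = prototypes19[0]
        study = msx.StudySet(
            study_id="S", montage=m19, maps=[u, msx.TemplateMap("B", -u.values, m19)],
            n_subjects=5,
        )
        sim = msx.similarity_matrix([study])
        np.testing.assert_allclose(sim.values, 100.0, atol=1e-9)

    def test_cross_montage_copies_recovered(self, m19, m64):
        """The same smooth field sampled at 19 and 64 channels: cross-study
        same-class pairs keep SV >= 99 after spline resampling."""
        from msx.synthetic import make_prototype_fields

        fields = make_prototype_fields(3, seed=0)
        s19 = msx.StudySet(
            study_id="low",
            montage=m19,
            maps=[_tmap(f.evaluate(m19), m19, str(i)) for i, f in enumerate(fields)],
            n_subjects=10,
        )
        s64 = msx.StudySet(
            study_id="high",
            montage=m64,
            maps=[_tmap(f.evaluate(m64), m64, str(i)) for i, f in enumerate(fields)],
            n_subjects=10,
        )
        sim = msx.similarity_matrix([s19, s64])
        cross = sim.values[:3, 3:]
        assert np.all(np.diag(cross) >= 99.0)
        # invariants: symmetry, diagonal, range
        np.testing.assert_allclose(sim.values, sim.values.T, atol=1e-9)
        np.testing.assert_allclose(np.diag(sim.values), 100.0, atol=1e-9)
        assert sim.values.min() >= 0 and sim.values.max() <= 100

    def test_orthogonal_maps_give_zero_off_diagonal(self, m19):
        rows = orthonormal_canonical_set(19, 3, seed=2)
        study = msx.StudySet(
            study_id="S",
            montage=m19,
            maps=[_tmap(r, m19, str(i)) for i, r in enumerate(rows)],
            n_subjects=5,
        )
        sim = msx.similarity_matrix([study])
        off = sim.values[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-9)


class TestMds:
    def test_right_triangle_is_reproduced(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        emb = mds_embed(D, dims=2)
        got = np.linalg.norm(
            emb.coordinates[:, None, :] - emb.coordinates[None, :, :], axis=-1
        )
        np.testing.assert_allclose(got, D, atol=1e-9)

    def test_known_3d_points_recovered(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 2, 0], [0.3, 0.7, 1.5]])
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = mds_embed(D, dims=3)
        got = np.linalg.norm(
            emb.coordinates[:, None, :] - emb.coordinates[None, :, :], axis=-1
        )
        np.testing.assert_allclose(got, D, atol=1e-9)

    def test_all_zero_distances_embed_at_origin(self):
        with pytest.warns(UserWarning):
            emb = mds_embed(np.zeros((4, 4)), dims=2)
        np.testing.assert_allclose(emb.coordinates, 0.0, atol=1e-12)

    def test_deterministic_sign_convention(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        a = mds_embed(D, dims=2).coordinates
        b = mds_embed(D, dims=2).coordinates
        np.testing.assert_array_equal(a, b)
        for axis in a.T:
            assert axis[np.argmax(np.abs(axis))] >= 0

    def test_dissimilarities_euclidean_without_polarity_ambiguity(self, m19):
        """On one montage, when every pairwise correlation is positive the
        polarity folding is inactive and d^2 is exactly Euclidean: the
        double-centered -d^2/2 matrix has no negative eigenvalues."""
        atlas = msx.make_atlas(
            msx.FixtureSpec(seed=6, n_studies=12, n_prototypes=1, channels=(19,),
                            angular_noise_sd=0.3)
        )
        sim = msx.similarity_matrix(atlas)
        maps = np.stack([m.values for _, m in atlas.iter_maps()])
        assert (maps @ maps.T).min() > 0  # fixture is polarity-unambiguous
        D = dissimilarity_matrix(sim)
        emb = mds_embed(D, dims=3, map_index=sim.map_index)
        assert emb.eigenvalues[-1] > -1e-6

    def test_prototype_clouds_stay_separated(self, small_atlas):
        """5 well-separated prototype clouds keep silhouette > 0.6 in 3-D."""
        from sklearn.metrics import silhouette_score

        sim = msx.similarity_matrix(small_atlas)
        D = dissimilarity_matrix(sim)
        emb = mds_embed(D, dims=3, map_index=sim.map_index)
        labels = [
            int(small_atlas.get_study(sid).metadata[f"truth_{lab}"])
            for sid, lab in sim.map_index
        ]
        assert silhouette_score(emb.coordinates, labels) > 0.6
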