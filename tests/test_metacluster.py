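"""Weighted polarity-invariant modified k-means and cross-K alignment."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import msx
from msx.errors import ValidationError
from msx.metacluster import (
    _dominant_map,
    align_solutions,
    modified_kmeans,
    prepare_items,
    run_range,
    solution_from_maps,
)
from conftest import orthonormal_canonical_set


def best_match_sv(found: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-truth-map shared variance under the optimal one-to-one matching."""
    sv = 100.0 * (truth @ found.T) ** 2
    rows, cols = linear_sum_assignment(-sv)
    return sv[rows, cols]


class TestPrepareItems:
    def test_items_resampled_and_weighted(self, small_atlas, m19):
        X, w, index = prepare_items(small_atlas, m19)
        assert X.shape == (small_atlas.n_maps, 19)
        np.testing.assert_allclose(X.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(np.linalg.norm(X, axis=1), 1.0, atol=1e-10)
        k = 0
        for study in small_atlas:
            for _ in study.maps:
                assert w[k] == study.n_subjects
                k += 1

    def test_items_equal_per_map_resampling(self, small_atlas, m19):
        from msx.spline import build_interpolator, resample_map

        X, _, index = prepare_items(small_atlas, m19)
        study = small_atlas.studies[2]  # a 64-channel study
        op = build_interpolator(study.montage, m19)
        for m in study.maps:
            expected = resample_map(m, op).values
            i = index.index((study.study_id, m.label))
            np.testing.assert_allclose(X[i], expected, atol=1e-12)


class TestModifiedKmeans:
    def test_noiseless_prototype_copies_are_fixed_point(self, m19):
        protos = orthonormal_canonical_set(19, 2, seed=0)
        items = np.concatenate([protos, -protos, protos])  # copies incl. flips
        sol = modified_kmeans(items, None, K=2, restarts=5, seed=0, montage=m19)
        assert sol.objective == pytest.approx(1.0, abs=1e-12)
        sv = best_match_sv(sol.maps, protos)
        np.testing.assert_allclose(sv, 100.0, atol=1e-9)

    def test_single_item_single_class(self, m19, prototypes19):
        item = prototypes19[0].values[None, :]
        sol = modified_kmeans(item, None, K=1, restarts=1, seed=0, montage=m19)
        assert sol.objective == pytest.approx(1.0, abs=1e-12)
        assert msx.shared_variance(sol.template_maps[0], prototypes19[0]) == pytest.approx(
            100.0, abs=1e-9
        )

    def test_matches_exhaustive_assignment_search(self, m19):
        """8 items / K=2: the algorithm attains the objective of brute-force
        enumeration over all label vectors."""
        rng = np.random.default_rng(12)
        protos = orthonormal_canonical_set(19, 2, seed=3)
        items = []
        for i in range(8):
            base = protos[i % 2]
            noisy = base + 0.4 * rng.standard_normal(19)
            noisy -= noisy.mean()
            items.append(noisy / np.linalg.norm(noisy))
        X = np.stack(items)
        w = rng.integers(1, 20, size=8).astype(float)

        best = -1.0
        for labels in itertools.product([0, 1], repeat=8):
            L = np.array(labels)
            if len(set(labels)) < 2:
                continue
            obj = 0.0
            for k in (0, 1):
                Xk, wk = X[L == k], w[L == k]
                t = _dominant_map(Xk, wk)
                obj += float(np.sum(wk * (Xk @ t) ** 2))
            best = max(best, obj / w.sum())

        sol = modified_kmeans(X, w, K=2, restarts=20, seed=0, montage=m19)
        assert sol.objective == pytest.approx(best, abs=1e-9)

    def test_recovers_prototypes_from_noisy_atlas(self, m19):
        """20 studies x 5 noisy prototype maps: K=5 meta-maps recover the
        ground truth with SV >= 95 on average."""
        spec = msx.FixtureSpec(seed=0, n_studies=20, angular_noise_sd=0.3)
        atlas = msx.make_atlas(spec)
        X, w, idx = prepare_items(atlas, m19)
        sol = modified_kmeans(X, w, K=5, restarts=50, seed=0, montage=m19)
        truth = np.stack([p.values for p in msx.make_prototypes(5, m19, seed=0)])
        assert best_match_sv(sol.maps, truth).mean() >= 95.0

    def test_weight_equals_item_replication(self, m19):
        """A weight-2 item and two weight-1 copies induce the same objective
        landscape: exhaustive best objectives coincide, and the algorithm
        attains them."""
        rng = np.random.default_rng(5)
        X = np.stack([msx.canonicalize_map(rng.standard_normal(19)) for _ in range(6)])
        w2 = np.array([2.0, 1, 1, 1, 1, 1])
        X_dup = np.concatenate([X[:1], X])

        def exhaustive_best(items, weights):
            n = items.shape[0]
            best = -1.0
            for labels in itertools.product([0, 1], repeat=n):
                L = np.array(labels)
                if len(set(labels)) < 2:
                    continue
                obj = sum(
                    float(
                        np.sum(
                            weights[L == k]
                            * (items[L == k] @ _dominant_map(items[L == k], weights[L == k])) ** 2
                        )
                    )
                    for k in (0, 1)
                )
                best = max(best, obj / weights.sum())
            return best

        best_w = exhaustive_best(X, w2)
        best_dup = exhaustive_best(X_dup, np.ones(7))
        assert best_w == pytest.approx(best_dup, abs=1e-12)
        sol_w = modified_kmeans(X, w2, K=2, restarts=30, seed=1, montage=m19)
        assert sol_w.objective == pytest.approx(best_w, abs=1e-9)

    def test_objective_invariant_to_polarity_flips(self, m19):
        rng = np.random.default_rng(9)
        X = np.stack([msx.canonicalize_map(rng.standard_normal(19)) for _ in range(10)])
        flip = np.where(rng.random(10) < 0.5, -1.0, 1.0)
        sol_a = modified_kmeans(X, None, K=3, restarts=20, seed=2, montage=m19)
        sol_b = modified_kmeans(X * flip[:, None], None, K=3, restarts=20, seed=2, montage=m19)
        assert sol_a.objective == pytest.approx(sol_b.objective, abs=1e-9)

    def test_k_larger_than_items_rejected(self, m19, prototypes19):
        X = np.stack([p.values for p in prototypes19])
        with pytest.raises(ValidationError):
            modified_kmeans(X, None, K=6, restarts=1, seed=0, montage=m19)


@pytest.fixture(scope="module")
def run(m19):
    atlas = msx.make_atlas(msx.FixtureSpec(seed=3, n_studies=10))
    return run_range(atlas, m19, k_min=4, k_max=7, restarts=20, seed=3)


class TestRunRange:
    def test_one_solution_per_k(self, run):
        assert run.k_values == [4, 5, 6, 7]
        for k, sol in run.solutions.items():
            assert sol.K == k
            # every class non-empty
            assert set(sol.assignments) == set(range(k))

    def test_objective_monotone_in_k(self, run):
        objs = [run.solutions[k].objective for k in run.k_values]
        assert all(b >= a - 1e-9 for a, b in zip(objs, objs[1:]))

    def test_elbow_at_true_prototype_count(self, run):
        """Objective gain when adding a class drops sharply after K=5 for a
        5-prototype atlas."""
        objs = {k: run.solutions[k].objective for k in run.k_values}
        gain_to_5 = objs[5] - objs[4]
        gain_after_5 = max(objs[6] - objs[5], objs[7] - objs[6])
        assert gain_to_5 > 3 * gain_after_5

    def test_rerun_is_bit_identical(self, run, m19):
        atlas = msx.make_atlas(msx.FixtureSpec(seed=3, n_studies=10))
        rerun = run_range(atlas, m19, k_min=4, k_max=7, restarts=20, seed=3)
        for k in run.k_values:
            np.testing.assert_array_equal(run.solutions[k].maps, rerun.solutions[k].maps)
            np.testing.assert_array_equal(
                run.solutions[k].assignments, rerun.solutions[k].assignments
            )

    def test_single_k_range(self, m19, small_atlas):
        run = run_range(small_atlas, m19, k_min=4, k_max=4, restarts=5, seed=0)
        assert run.k_values == [4]

    def test_roundtrip_through_json(self, run, tmp_path):
        from msx.metacluster import load_run, save_run

        save_run(run, tmp_path / "run.json")
        loaded = load_run(tmp_path / "run.json")
        assert loaded.k_values == run.k_values
        for k in run.k_values:
            np.testing.assert_allclose(
                loaded.solutions[k].maps, run.solutions[k].maps, atol=1e-12
            )


class TestAlignment:
    def test_added_orthogonal_class_goes_last(self, m19):
        protos = orthonormal_canonical_set(19, 4, seed=4)
        sol3 = solution_from_maps(protos[:3], m19)
        sol3.assignments = np.array([0, 0, 0, 1, 1, 2])  # weights order 0,1,2
        sol4 = solution_from_maps(protos[[3, 0, 1, 2]], m19)  # new map first
        run = msx.MetaClusterRun(solutions={3: sol3, 4: sol4})
        aligned = align_solutions(run)
        np.testing.assert_allclose(aligned.solutions[4].maps[:3], protos[:3], atol=1e-12)
        np.testing.assert_allclose(aligned.solutions[4].maps[3], protos[3], atol=1e-12)

    def test_reference_equal_to_own_maps_gives_identity(self, m19, prototypes19):
        sol = solution_from_maps(prototypes19[:4], m19)
        run = msx.MetaClusterRun(solutions={4: sol})
        aligned = align_solutions(run, reference_maps=prototypes19[:4])
        assert aligned.alignment[4] == [0, 1, 2, 3]

    def test_recovers_exhaustive_permutation_matching(self, m19):
        """Hungarian alignment of a shuffled K+1 solution equals brute-force
        search over all injections of K classes into K+1 classes."""
        rng = np.random.default_rng(8)
        protos = orthonormal_canonical_set(19, 6, seed=5)
        noisy = protos[:5] + 0.2 * rng.standard_normal((5, 19))
        noisy -= noisy.mean(axis=1, keepdims=True)
        noisy /= np.linalg.norm(noisy, axis=1, keepdims=True)
        sol5 = solution_from_maps(noisy, m19)
        perm = rng.permutation(6)
        sol6 = solution_from_maps(protos[perm], m19)
        run = msx.MetaClusterRun(solutions={5: sol5, 6: sol6})
        sol5.assignments = np.arange(5)  # keep base order as-is
        aligned = align_solutions(run, overrides={5: [0, 1, 2, 3, 4]})

        sv = 100.0 * (noisy @ protos[perm].T) ** 2
        best_total, best_cols = -1.0, None
        for cols in itertools.permutations(range(6), 5):
            total = sum(sv[i, c] for i, c in enumerate(cols))
            if total > best_total:
                best_total, best_cols = total, cols
        assert aligned.alignment[6][:5] == list(best_cols)

    def test_invalid_override_rejected(self, m19, prototypes19):
        sol = solution_from_maps(prototypes19[:4], m19)
        run = msx.MetaClusterRun(solutions={4: sol})
        with pytest.raises(ValidationError):
            align_solutions(run, overrides={4: [0, 0, 1, 2]})
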