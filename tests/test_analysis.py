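import numpy as np
import pytest
from sklearn.decomposition import PCA

from morphrep.analysis import (
    VOLUME_BIN_EDGES,
    archetypes,
    closest_real_example,
    pca_latent_walk,
    perturbation_stats,
    volume_bin_profile,
)
from morphrep.types import InvalidInputError

from conftest import random_rotation

rng = np.random.default_rng(0)


class TestLatentWalk:
    def test_center_is_mean_and_steps_match_pca_oracle(self):
        r = np.random.default_rng(1)
        Z = r.normal(size=(50, 4)) * np.array([3.0, 1.0, 0.2, 0.1])
        res = pca_latent_walk(Z, n_components=2, map_points=(-2, 0, 2))
        # middle map point sits at the data mean for every component
        assert np.allclose(res.walk_vectors[0, 1], Z.mean(axis=0))
        assert np.allclose(res.walk_vectors[1, 1], Z.mean(axis=0))
        # steps are +/- 2 sd along the fitted principal axes
        p = PCA(n_components=2).fit(Z)
        for c in range(2):
            want = 2.0 * np.sqrt(p.explained_variance_[c]) * p.components_[c]
            got = res.walk_vectors[c, 2] - res.walk_vectors[c, 1]
            assert np.allclose(np.abs(got @ want) / (np.linalg.norm(want) ** 2), 1.0)
            assert np.allclose(np.linalg.norm(got), np.linalg.norm(want))

    def test_explained_variance_ratio_matches_oracle(self):
        r = np.random.default_rng(2)
        Z = r.normal(size=(40, 5)) @ np.diag([5.0, 2.0, 1.0, 0.5, 0.1])
        res = pca_latent_walk(Z, n_components=3)
        p = PCA(n_components=3).fit(Z)
        assert np.allclose(res.explained_variance_ratio, p.explained_variance_ratio_)

    def test_rank_error(self):
        Z = rng.normal(size=(3, 5))
        with pytest.raises(InvalidInputError):
            pca_latent_walk(Z, n_components=3)

    def test_decode_round_trip(self):
        r = np.random.default_rng(3)
        Z = r.normal(size=(30, 3))
        res = pca_latent_walk(Z, n_components=1, decode_fn=lambda z: z * 2.0)
        assert res.nearest_ids is None
        assert np.allclose(res.decoded[0][1], 2.0 * Z.mean(axis=0))

    def test_nearest_ids_without_decoder(self):
        Z = np.array([[0.0, 0], [10.0, 0], [-10.0, 0], [0.1, 0]])
        res = pca_latent_walk(Z, n_components=1, map_points=(0.0,))
        assert res.decoded is None
        # the mean (0.025, 0) is closest to row 0
        assert res.nearest_ids[0, 0] == 0


class TestClosestReal:
    def test_exact_match(self):
        Z = rng.normal(size=(20, 4))
        assert closest_real_example(Z, Z[7]) == 7

    def test_tie_lowest_index(self):
        Z = np.array([[1.0, 0], [1.0, 0], [5.0, 0]])
        assert closest_real_example(Z, np.array([0.0, 0.0])) == 0

    def test_matches_scan_oracle(self):
        r = np.random.default_rng(4)
        Z = r.normal(size=(50, 6))
        for _ in range(10):
            q = r.normal(size=6)
            want = min(range(50), key=lambda i: np.linalg.norm(Z[i] - q))
            assert closest_real_example(Z, q) == want

    def test_empty_errors(self):
        with pytest.raises(InvalidInputError):
            closest_real_example(np.empty((0, 3)), np.zeros(3))


class TestArchetypes:
    @staticmethod
    def _simplex_data(V, seed=5, n=200):
        """Convex combinations of planted vertices, vertices included."""
        r = np.random.default_rng(seed)
        W = r.dirichlet(np.ones(len(V)), size=n)
        return np.vstack([V, W @ V])

    def test_recovers_planted_vertices(self):
        V = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 10.0, 5.0]])
        X = self._simplex_data(V)
        res = archetypes(X, 3, seed=0)
        # each planted vertex matched by some archetype within 1e-2
        d = np.linalg.norm(res.archetypes[:, None] - V[None], axis=-1)
        assert d.min(axis=0).max() < 1e-2

    def test_factors_are_convex_rows(self):
        V = np.array([[0.0, 0.0], [6.0, 0.0], [0.0, 6.0]])
        X = self._simplex_data(V, seed=6, n=100)
        res = archetypes(X, 3, seed=0)
        assert np.all(res.weights >= -1e-12)
        assert np.allclose(res.weights.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(res.archetype_coefficients >= -1e-12)
        assert np.allclose(res.archetype_coefficients.sum(axis=1), 1.0, atol=1e-9)
        # reconstruction identity: rss == ||X - A B X||^2
        assert res.rss == pytest.approx(
            float(np.sum((X - res.weights @ res.archetype_coefficients @ X) ** 2))
        )

    def test_k_equals_n_near_zero_residual(self):
        # with one archetype per sample the fit is exact up to the
        # sublinear Frank-Wolfe convergence of the interior weights
        r = np.random.default_rng(7)
        X = r.normal(size=(6, 3))
        total = float(np.sum((X - X.mean(axis=0)) ** 2))
        assert archetypes(X, 6, seed=0).rss < 1e-4 * total

    def test_residual_monotone_in_k_on_square(self):
        V = np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0], [8.0, 8.0]])
        X = self._simplex_data(V, seed=8, n=150)
        rs = [archetypes(X, k, seed=0).rss for k in (1, 2, 3, 4)]
        assert all(rs[i + 1] <= rs[i] + 1e-9 for i in range(3))
        # four archetypes recover the square: residual tiny vs data scale
        total = float(np.sum((X - X.mean(axis=0)) ** 2))
        assert rs[3] < 1e-3 * total

    def test_deterministic(self):
        V = np.array([[0.0, 0.0], [5.0, 1.0], [1.0, 5.0]])
        X = self._simplex_data(V, seed=9, n=80)
        a = archetypes(X, 3, seed=1)
        b = archetypes(X, 3, seed=1)
        assert np.array_equal(a.archetypes, b.archetypes)
        assert a.rss == b.rss

    def test_too_many_archetypes_errors(self):
        with pytest.raises(InvalidInputError):
            archetypes(rng.normal(size=(5, 2)), 6)


class TestVolumeBins:
    def test_reported_bin_edges_and_labels(self):
        assert VOLUME_BIN_EDGES == (390.0, 533.0, 676.0, 818.0)
        r = np.random.default_rng(10)
        prof = volume_bin_profile(
            r.normal(size=(200, 3)), r.uniform(300, 900, size=200)
        )
        assert prof.bin_labels == ["<390", "390-533", "533-676", "676-818", ">818"]

    def test_clip_and_partition(self):
        r = np.random.default_rng(10)
        vols = r.uniform(300, 900, size=200)
        prof = volume_bin_profile(r.normal(size=(200, 3)), vols)
        # retained samples partition exactly into the five bins
        assert prof.counts.sum() == len(prof.retained_idx)
        lo, hi = np.percentile(vols, [2.5, 97.5])
        want_keep = np.nonzero((vols >= lo) & (vols <= hi))[0]
        assert np.array_equal(prof.retained_idx, want_keep)
        assert prof.clip_range == (lo, hi)

    def test_bin_assignment_oracle(self):
        Z = np.eye(5)
        vols = np.array([100.0, 400.0, 600.0, 700.0, 850.0])
        prof = volume_bin_profile(Z, vols, clip_percentiles=(0.0, 100.0))
        assert prof.counts.tolist() == [1, 1, 1, 1, 1]
        for b in range(5):
            assert np.allclose(prof.mean_embeddings[b], Z[b])
            # singleton bins represent themselves
            assert prof.representatives[b] == b

    def test_representatives_are_global_member_indices(self):
        r = np.random.default_rng(11)
        Z = r.normal(size=(100, 4))
        vols = r.uniform(350, 880, size=100)
        prof = volume_bin_profile(Z, vols)
        for b, rep in enumerate(prof.representatives):
            members = prof.retained_idx[prof.bin_assignment == b]
            if prof.counts[b] == 0:
                assert rep is None
            else:
                assert rep in members

    def test_decode_fn_used_for_representatives(self):
        r = np.random.default_rng(12)
        Z = r.normal(size=(40, 3))
        vols = r.uniform(350, 880, size=40)
        prof = volume_bin_profile(Z, vols, decode_fn=lambda mu: ("decoded", mu.sum()))
        for b, rep in enumerate(prof.representatives):
            if prof.counts[b] > 0:
                assert rep[0] == "decoded"

    def test_empty_bin_allowed(self):
        Z = rng.normal(size=(10, 2))
        vols = np.full(10, 500.0)  # all land in 390-533
        prof = volume_bin_profile(Z, vols, clip_percentiles=(0.0, 100.0))
        assert prof.counts.tolist() == [0, 10, 0, 0, 0]
        assert prof.representatives[0] is None

    def test_validation(self):
        with pytest.raises(InvalidInputError):
            volume_bin_profile(rng.normal(size=(5, 2)), np.ones(4))
        with pytest.raises(InvalidInputError):
            volume_bin_profile(rng.normal(size=(3, 2)), np.array([1.0, -2.0, 3.0]))


class TestPerturbation:
    @staticmethod
    def _embed_labels(shift, seed=12, n=8):
        r = np.random.default_rng(seed)
        # control is isotropic noise at the origin (random directions);
        # treated shifts along +x, making its cosine neighborhood tight
        treated = r.normal(0, 0.05, size=(n, 3)) + np.array([shift, 0.0, 0.0])
        control = r.normal(0, 0.05, size=(n, 3))
        z = np.vstack([treated, control])
        y = np.array(["hit"] * n + ["ctrl"] * n)
        return z, y

    def test_planted_shift_map_one_min_p(self):
        z, y = self._embed_labels(shift=10.0)
        res = perturbation_stats(z, y, "ctrl", n_permutations=199, seed=0)
        assert res.conditions == ["hit"]
        assert res.map_scores[0] == pytest.approx(1.0)
        # add-one permutation p cannot go below 1/(n_perm+1)
        assert res.p_values[0] == pytest.approx(1.0 / 200.0)
        assert res.n_treated[0] == 8 and res.n_control == 8

    def test_null_q_nonsignificant(self):
        z, y = self._embed_labels(shift=0.0, seed=13)  # same distribution
        res = perturbation_stats(z, y, "ctrl", n_permutations=199, seed=1)
        assert res.q_values[0] >= 0.05

    def test_map_isometry_invariant(self):
        z, y = self._embed_labels(shift=10.0, seed=14)
        Q = random_rotation(15)
        a = perturbation_stats(z, y, "ctrl", n_permutations=49, seed=2)
        b = perturbation_stats(z @ Q.T, y, "ctrl", n_permutations=49, seed=2)
        assert a.map_scores[0] == pytest.approx(b.map_scores[0])

    def test_bh_adjustment_matches_hand_stepup(self):
        r = np.random.default_rng(16)
        z = np.vstack(
            [
                r.normal(0, 0.05, (6, 2)) + 8.0,  # a: separated
                r.normal(size=(6, 2)),  # b: null
                r.normal(size=(6, 2)),  # c: null
                r.normal(size=(6, 2)),  # ctrl
            ]
        )
        y = np.repeat(["a", "b", "c", "ctrl"], 6)
        res = perturbation_stats(z, y, "ctrl", n_permutations=99, seed=3)
        p = res.p_values
        order = np.argsort(p)
        m = len(p)
        want = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            prev = min(prev, p[order[rank - 1]] * m / rank)
            want[order[rank - 1]] = prev
        assert np.allclose(res.q_values, want)

    def test_few_permutations_warns(self):
        z, y = self._embed_labels(shift=10.0, seed=17)
        with pytest.warns(UserWarning):
            perturbation_stats(z, y, "ctrl", n_permutations=10, seed=0)

    def test_validation(self):
        z = rng.normal(size=(6, 3))
        with pytest.raises(InvalidInputError):  # single treated cell
            perturbation_stats(
                z, np.array(["x"] + ["c"] * 5), "c", n_permutations=100
            )
        with pytest.raises(InvalidInputError):  # empty control
            perturbation_stats(
                z, np.array(["x"] * 6), "c", n_permutations=100
            )
        with pytest.raises(InvalidInputError):  # no treated conditions
            perturbation_stats(
                z, np.array(["c"] * 6), "c", n_permutations=100
            )
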