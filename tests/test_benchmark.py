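import numpy as np
import pytest

from morphrep.benchmark import (
    benchmark_report,
    compactness,
    evolution_energy,
    interpolation_distance,
    jaccard_similarity,
    piece_features,
    probe_classification,
    probe_regression,
    rotation_invariance_error,
    rotation_z,
)
from morphrep.types import InvalidInputError

rng = np.random.default_rng(0)


class TestInvarianceError:
    def test_hand_case_sqrt2_over_2(self):
        pts = np.array([[1.0, 0.0, 0.0]])

        def embed(p, s):
            return np.array([1.0, 0.0]) if np.allclose(p, pts) else np.array([0.0, 1.0])

        err = rotation_invariance_error(embed, [pts], rotations_deg=(90.0,))
        assert err == pytest.approx(np.sqrt(2) / 2)

    def test_constant_embedder_zero(self):
        err = rotation_invariance_error(
            lambda p, s: np.array([1.0, 2.0]), [rng.normal(size=(5, 3))]
        )
        assert err == 0.0

    def test_scale_invariance_of_ratio(self):
        base = rng.normal(size=(10, 3))

        def make_embed(c):
            return lambda p, s: c * p.sum(axis=0)

        e1 = rotation_invariance_error(make_embed(1.0), [base])
        e2 = rotation_invariance_error(make_embed(7.5), [base])
        assert e1 == pytest.approx(e2)

    def test_bounded_unit_interval(self):
        embed = lambda p, s: p.sum(axis=0)  # noqa: E731
        err = rotation_invariance_error(embed, [rng.normal(size=(8, 3))])
        assert 0.0 <= err <= 1.0

    def test_both_zero_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            with pytest.raises(InvalidInputError):
                rotation_invariance_error(
                    lambda p, s: np.zeros(3), [rng.normal(size=(4, 3))]
                )

    def test_quarter_turn_convention(self):
        q = rotation_z(90.0)
        assert np.allclose(q @ np.array([1.0, 0, 0]), [0, 1, 0], atol=1e-15)


class TestEvolutionEnergy:
    def test_constant_decoder_energy_one(self):
        z = np.array([[0.0], [1.0]])
        decode = lambda v: v  # noqa: E731
        metric = lambda a, b: abs(float(a[0] - b[0]))  # noqa: E731
        assert evolution_energy(decode, z, metric, n_pairs=3, seed=0) == pytest.approx(1.0)

    def test_hand_one_point_clouds(self):
        # x_t = t on a line, chamfer-squared convention d = (a-b)^2:
        # e_t = (t^2 + (1-t)^2) / 1; mean over t = k/10, k=1..10
        z = np.array([[0.0], [1.0]])
        decode = lambda v: v  # noqa: E731
        metric = lambda a, b: float((a[0] - b[0]) ** 2)  # noqa: E731
        ts = (np.arange(10) + 1) / 10
        want = np.mean(ts**2 + (1 - ts) ** 2)
        got = evolution_energy(decode, z, metric, n_pairs=2, n_interp=10, seed=0)
        assert got == pytest.approx(want)

    def test_at_least_one_under_triangle_metric(self):
        z = rng.normal(size=(8, 4))
        decode = lambda v: np.concatenate([v, [float(np.sum(v**2))]])  # noqa: E731
        metric = lambda a, b: float(np.linalg.norm(a - b))  # noqa: E731
        assert evolution_energy(decode, z, metric, n_pairs=10, seed=1) >= 1.0

    def test_degenerate_pairs_error(self):
        z = np.zeros((3, 2))
        decode = lambda v: v  # noqa: E731
        metric = lambda a, b: float(np.linalg.norm(a - b))  # noqa: E731
        with pytest.raises(InvalidInputError):
            evolution_energy(decode, z, metric, n_pairs=1, seed=0, max_resample=5)


class TestInterpolationDistance:
    def test_collinear_hand_case(self):
        # two embeddings 0 and 1; grid t = 0, 0.5, 1 -> distances 0, 0.5, 0
        z = np.array([[0.0], [1.0]])
        d = interpolation_distance(z, n_pairs=1, n_interp=3, seed=0)
        assert d == pytest.approx(0.5 / 3)

    def test_agrees_with_brute_force(self):
        z = rng.normal(size=(20, 5))
        seed = 3
        got = interpolation_distance(z, n_pairs=4, n_interp=7, seed=seed)
        r = np.random.default_rng(seed)
        ts = np.linspace(0, 1, 7)
        acc = []
        for _ in range(4):
            i, j = r.choice(20, size=2, replace=False)
            for t in ts:
                q = (1 - t) * z[i] + t * z[j]
                acc.append(min(np.linalg.norm(q - z[k]) for k in range(20)))
        assert got == pytest.approx(np.mean(acc))

    def test_endpoints_zero(self):
        z = rng.normal(size=(5, 3))
        d = interpolation_distance(z, n_pairs=3, n_interp=2, seed=0)
        assert d == pytest.approx(0.0)


class TestCompactness:
    def test_planted_3_manifold(self):
        r = np.random.default_rng(1)
        X = r.uniform(size=(1000, 3)) @ r.normal(size=(3, 10))
        assert 2.5 <= compactness(X) <= 3.5

    def test_planted_line(self):
        r = np.random.default_rng(2)
        X = r.uniform(size=(500, 1)) * np.ones((1, 5))
        assert 0.8 <= compactness(X) <= 1.2

    def test_isometry_invariance(self):
        from conftest import random_rotation

        r = np.random.default_rng(3)
        X = r.normal(size=(200, 3))
        Q = random_rotation(4)
        assert compactness(X) == pytest.approx(compactness(X @ Q.T + 5.0))

    def test_duplicates_removed_with_warning(self):
        r = np.random.default_rng(5)
        X = r.normal(size=(200, 3))
        with pytest.warns(UserWarning):
            got = compactness(np.vstack([X, X[:10]]))
        assert got == pytest.approx(compactness(X))


class TestProbes:
    def test_separable_blobs_near_one(self):
        r = np.random.default_rng(6)
        X = np.vstack([r.normal(0, 0.1, (40, 4)), r.normal(5, 0.1, (40, 4))])
        y = np.array([0] * 40 + [1] * 40)
        res = probe_classification(X, y, seed=0)
        assert res.mean >= 0.99
        assert len(res.per_fold) == 5

    def test_permuted_labels_near_chance(self):
        r = np.random.default_rng(7)
        X = r.normal(size=(200, 4))
        y = r.integers(0, 2, size=200)  # independent of X
        acc = probe_classification(X, y, seed=0).mean
        # binomial 99% CI around 0.5 at n=200
        assert abs(acc - 0.5) < 0.12

    def test_top2_at_least_top1(self):
        r = np.random.default_rng(8)
        X = r.normal(size=(90, 4))
        y = np.repeat([0, 1, 2], 30)
        top1 = probe_classification(X, y, top_k=1, seed=1).mean
        top2 = probe_classification(X, y, top_k=2, seed=1).mean
        assert top2 >= top1

    def test_small_class_error_names_class(self):
        X = rng.normal(size=(23, 3))
        y = np.array(["big"] * 20 + ["rare"] * 3)
        with pytest.raises(InvalidInputError, match="rare"):
            probe_classification(X, y)

    def test_regression_noiseless_linear(self):
        r = np.random.default_rng(9)
        X = r.normal(size=(100, 4))
        w = r.normal(size=4)
        assert probe_regression(X, X @ w, seed=0).mean >= 0.999

    def test_regression_null_near_zero(self):
        r = np.random.default_rng(10)
        X = r.normal(size=(300, 4))
        t = r.normal(size=300)
        assert probe_regression(X, t, seed=0).mean <= 0.05

    def test_regression_constant_target_errors(self):
        with pytest.raises(InvalidInputError):
            probe_regression(rng.normal(size=(30, 3)), np.ones(30))

    def test_seeded_reproducibility(self):
        r = np.random.default_rng(11)
        X = r.normal(size=(60, 3))
        y = np.repeat([0, 1], 30)
        a = probe_classification(X, y, seed=42)
        b = probe_classification(X, y, seed=42)
        assert a.per_fold == b.per_fold


class TestPieceFeatures:
    def test_two_cubes_hand_case(self):
        seg = np.zeros((30, 10, 10), dtype=bool)
        seg[2:7, 2:7, 2:7] = True
        seg[12:17, 2:7, 2:7] = True
        row = piece_features(seg)
        assert row.piece_count == 2
        assert row.volume_mean == 125.0
        assert row.centroid_distance_mean == pytest.approx(10.0)
        assert row.piece_class == "2"
        assert row.distances_valid

    def test_single_piece_class_and_flag(self):
        seg = np.zeros((8, 8, 8), dtype=bool)
        seg[3:5, 3:5, 3:5] = True
        row = piece_features(seg)
        assert row.piece_class == "1"
        assert not row.distances_valid
        assert row.centroid_distance_mean == 0.0

    def test_six_blobs_class_ge5(self):
        seg = np.zeros((30, 10, 5), dtype=bool)
        for i in range(6):
            seg[5 * i : 5 * i + 2, 2:4, 2:4] = True
        assert piece_features(seg).piece_class == ">=5"

    def test_agrees_with_component_counter_on_random_masks(self, multipiece):
        from scipy.ndimage import label

        r = np.random.default_rng(12)
        for _ in range(20):
            seg = r.uniform(size=(12, 12, 12)) < 0.2
            if not seg.any():
                continue
            want = label(seg, structure=np.ones((3, 3, 3)))[1]
            assert piece_features(seg).piece_count == want

    def test_empty_errors(self):
        with pytest.raises(InvalidInputError):
            piece_features(np.zeros((4, 4, 4)))


class TestReport:
    def test_hand_zscores_and_flip(self):
        rep = benchmark_report(
            {
                "a": {"recon": 1.0, "classification_accuracy": 0.5},
                "b": {"recon": 2.0, "classification_accuracy": 0.6},
                "c": {"recon": 3.0, "classification_accuracy": 0.7},
            }
        )
        # population z-scores of (1,2,3) are (-1.2247, 0, 1.2247);
        # recon flips, accuracy does not
        assert rep.zscored["recon"].tolist() == pytest.approx(
            [1.224745, 0.0, -1.224745], abs=1e-6
        )
        assert rep.zscored["classification_accuracy"].tolist() == pytest.approx(
            [-1.224745, 0.0, 1.224745], abs=1e-6
        )
        assert "recon" in rep.flipped_metrics
        assert "classification_accuracy" not in rep.flipped_metrics

    def test_columns_mean_zero(self):
        rep = benchmark_report(
            {m: {"x": v, "y": 2 * v} for m, v in zip("abcd", [1.0, 4.0, 2.0, 7.0])}
        )
        assert np.abs(rep.zscored.mean(axis=0)).max() < 1e-9

    def test_single_model_refuses_zview(self):
        rep = benchmark_report({"only": {"x": 1.0}})
        assert rep.zscored is None
        assert "two models" in rep.message

    def test_long_format_and_save(self, tmp_path):
        rep = benchmark_report(
            {"a": {"x": 1.0, "y": 2.0}, "b": {"x": 3.0, "y": 1.0}}
        )
        long = rep.to_long()
        assert set(long.columns) == {"model", "metric", "value"}
        assert len(long) == 4
        rep.save(str(tmp_path / "rep"))
        assert (tmp_path / "rep_raw.csv").exists()
        assert (tmp_path / "rep_zscored.csv").exists()
        assert (tmp_path / "rep.json").exists()


def test_jaccard_identity_and_empty():
    a = np.zeros((3, 3, 3), dtype=bool)
    a[1, 1, 1] = True
    assert jaccard_similarity(a, a) == 1.0
    assert jaccard_similarity(a, np.zeros_like(a)) == 0.0
    assert jaccard_similarity(np.zeros_like(a), np.zeros_like(a)) == 1.0
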