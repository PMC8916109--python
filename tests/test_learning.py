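"""Feature extraction, balanced RF training, metrics, uncertainty
ranking and the active-learning loop."""

import numpy as np
import pytest

from fieldmapper import learning as ln


class TestFeatures:
    def test_24_bands_in_fixed_order(self):
        rng = np.random.default_rng(0)
        g, d = rng.random((4, 10, 10)), rng.random((4, 10, 10))
        f = ln.extract_features(g, d)
        assert f.shape == (24, 10, 10)
        assert f[:4] == pytest.approx(g)
        assert f[4:8] == pytest.approx(d)

    def test_constant_composite_mean_constant_std_zero(self):
        g = np.full((4, 12, 12), 0.3)
        d = np.full((4, 12, 12), 0.5)
        f = ln.extract_features(g, d)
        assert f[8:16] == pytest.approx(np.concatenate([g, d]))
        assert f[16:] == pytest.approx(0.0, abs=1e-12)

    def test_unit_impulse_mean_window(self):
        g = np.zeros((4, 32, 32))
        g[0, 16, 16] = 1.0
        f = ln.extract_features(g, np.zeros((4, 32, 32)))
        mean_band = f[8]
        assert mean_band[16, 16] == pytest.approx(1 / 121)
        assert mean_band[16, 16 + 5] == pytest.approx(1 / 121)
        assert mean_band[16, 16 + 6] == pytest.approx(0.0)

    def test_matches_brute_force_window_oracle(self):
        rng = np.random.default_rng(3)
        g, d = rng.random((4, 32, 32)), rng.random((4, 32, 32))
        f = ln.extract_features(g, d)
        raw = np.concatenate([g, d])
        pad = 5
        for b in range(8):
            padded = np.pad(raw[b], pad, mode="symmetric")
            for i, j in [(0, 0), (3, 17), (31, 31), (15, 2)]:
                win = padded[i : i + 11, j : j + 11]
                assert f[8 + b, i, j] == pytest.approx(win.mean(), abs=1e-10)
        pad = 2
        for b in range(8):
            padded = np.pad(raw[b], pad, mode="symmetric")
            for i, j in [(0, 0), (3, 17), (31, 31)]:
                win = padded[i : i + 5, j : j + 5]
                assert f[16 + b, i, j] == pytest.approx(win.std(), abs=1e-10)

    def test_coregistration_enforced(self):
        with pytest.raises(ValueError):
            ln.extract_features(np.zeros((4, 8, 8)), np.zeros((4, 9, 9)))


class TestTrainingAssembly:
    def test_majority_downsampled(self):
        X = np.arange(1250 * 2, dtype=float).reshape(1250, 2)
        y = np.r_[np.ones(250, bool), np.zeros(1000, bool)]
        Xb, yb = ln.assemble_training(X, y, seed=0)
        assert yb.sum() == 250 and (~yb).sum() == 250

    def test_balanced_sample_unchanged(self):
        X = np.random.default_rng(0).random((20, 3))
        y = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        Xb, yb = ln.assemble_training(X, y, seed=1)
        assert Xb == pytest.approx(X) and np.array_equal(yb, y)

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(5)
        X, y = rng.random((300, 4)), rng.random(300) < 0.2
        a = ln.assemble_training(X, y, seed=9)
        b = ln.assemble_training(X, y, seed=9)
        assert a[0] == pytest.approx(b[0]) and np.array_equal(a[1], b[1])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ln.assemble_training(np.zeros((5, 2)), np.ones(5, bool), 0)


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 1, (100, 24)), rng.normal(4, 1, (100, 24))])
    y = np.r_[np.zeros(100, bool), np.ones(100, bool)]
    return X, y


class TestClassifier:

    def test_default_hyperparameters(self, toy):
        m = ln.fit_classifier(*toy, seed=0)
        assert m.hyper.n_trees == 60 and m.hyper.max_depth == 15
        assert len(m.forest.estimators_) == 60

    def test_refit_reproduces_predictions_exactly(self, toy):
        X, y = toy
        probe = np.random.default_rng(1).normal(2, 2, (50, 24))
        p1 = ln.predict_probabilities(ln.fit_classifier(X, y, seed=3), probe)
        p2 = ln.predict_probabilities(ln.fit_classifier(X, y, seed=3), probe)
        assert np.max(np.abs(p1 - p2)) == 0.0

    def test_separable_toy_training_accuracy_one(self, toy):
        X, y = toy
        m = ln.fit_classifier(X, y, seed=0)
        p = ln.predict_probabilities(m, X)
        assert ((p > 0.5) == y).mean() == 1.0

    def test_probabilities_are_vote_fractions(self, toy):
        X, y = toy
        m = ln.fit_classifier(X, y, seed=0)
        probe = np.random.default_rng(2).normal(2, 2, (80, 24))
        p = ln.predict_probabilities(m, probe)
        votes = p * 60
        assert votes == pytest.approx(np.round(votes), abs=1e-9)

    def test_nodata_propagates(self, toy):
        X, y = toy
        m = ln.fit_classifier(X, y, seed=0)
        stack = np.random.default_rng(3).normal(2, 2, (24, 4, 4))
        nodata = np.zeros((4, 4), bool)
        nodata[1, 2] = True
        p = ln.predict_probabilities(m, stack, nodata_mask=nodata)
        assert np.isnan(p[1, 2]) and np.isfinite(p[0, 0])


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        p = y.astype(float)
        m = ln.evaluate(p, y)
        assert m["accuracy"] == m["auc"] == m["f1"] == 1.0 and m["fpr"] == 0.0

    def test_all_positive_on_balanced_set(self):
        y = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        m = ln.evaluate(np.ones(20), y)
        assert m["accuracy"] == 0.5 and m["fpr"] == 1.0

    def test_confusion_arithmetic(self):
        # TP=30, FP=20, FN=10, TN=40
        y = np.r_[np.ones(40, bool), np.zeros(60, bool)]
        p = np.r_[np.ones(30), np.zeros(10), np.ones(20), np.zeros(40)]
        m = ln.evaluate(p, y)
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["f1"] == pytest.approx(2 / 3)
        assert m["fpr"] == pytest.approx(1 / 3)

    def test_single_class_validation_rejected(self):
        with pytest.raises(ValueError):
            ln.evaluate(np.ones(5), np.ones(5, bool))


class TestUncertainty:
    def test_all_half_is_maximally_uncertain(self):
        assert ln.site_uncertainty(np.full(200, 0.5)) == 0.0

    def test_confident_cell_reaches_upper_bound(self):
        p = np.r_[np.ones(60), np.zeros(40)]
        assert ln.site_uncertainty(p) == pytest.approx(25.0)

    def test_small_example(self):
        assert ln.site_uncertainty(np.array([0.1, 0.5, 0.9])) == pytest.approx(0.32)

    def test_bounds_hold_on_random_maps(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(rng.integers(10, 2000))
            q = ln.site_uncertainty(p, n_sample=1000, seed=1)
            n = min(1000, p.size)
            assert 0.0 <= q <= 0.25 * n + 1e-12

    def test_no_valid_pixels_rejected(self):
        with pytest.raises(ValueError):
            ln.site_uncertainty(np.full(5, np.nan))


class TestSelection:
    def _scores(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return [(f"c{i}", float(q)) for i, q in enumerate(rng.random(n) * 100)]

    def test_selection_confined_to_most_uncertain_30_percent(self):
        scores = self._scores()
        low30 = {c for c, _ in sorted(scores, key=lambda t: t[1])[:30]}
        chosen = ln.select_active_sites(scores, k=10, seed=1)
        assert len(chosen) == 10 and set(chosen) <= low30

    def test_k_equal_to_pool_returns_whole_pool(self):
        scores = self._scores()
        low30 = {c for c, _ in sorted(scores, key=lambda t: t[1])[:30]}
        assert set(ln.select_active_sites(scores, k=30, seed=2)) == low30

    def test_fixed_seed_reproducible(self):
        scores = self._scores(seed=3)
        assert ln.select_active_sites(scores, 5, seed=7) == ln.select_active_sites(
            scores, 5, seed=7
        )

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            ln.select_active_sites([], 5)


class TestActiveLoop:
    def test_training_size_grows_by_batch_each_iteration(self):
        world = ln.make_demo_world(3, n_tiles=(1, 1))
        rng = np.random.default_rng(0)
        cells = list(world.cells)
        rng.shuffle(cells)
        val, rest = cells[:20], cells[20:]
        cfg = ln.ActiveLearningConfig(
            cells_per_iteration=10, max_iterations=2, pixels_per_cell=30,
            f1_gain_tol=-1.0,
        )
        logs, p_map, model = ln.run_active_loop(
            world.features, world.windows, lambda c: world.truth,
            rest[:15], rest[15:], val, lambda c: world.truth, cfg, seed=0,
        )
        assert [l.n_training_cells for l in logs] == [15, 25, 35]
        assert p_map.shape == world.truth.shape
        sizes = [l.n_training_cells for l in logs]
        assert sizes == sorted(sizes)

    def test_zero_iterations_is_plain_train_evaluate(self):
        world = ln.make_demo_world(3, n_tiles=(1, 1))
        rng = np.random.default_rng(0)
        cells = list(world.cells)
        rng.shuffle(cells)
        cfg = ln.ActiveLearningConfig(max_iterations=0, pixels_per_cell=30)
        logs, _, _ = ln.run_active_loop(
            world.features, world.windows, lambda c: world.truth,
            cells[20:40], cells[40:], cells[:20], lambda c: world.truth,
            cfg, seed=0,
        )
        assert len(logs) == 1 and not logs[0].selected

    def test_final_f1_not_worse_than_start_on_average(self, selection_experiment):
        gains = [
            f - s
            for f, s in zip(
                selection_experiment["active_f1"],
                selection_experiment["active_f1_start"],
            )
        ]
        assert np.mean(gains) >= 0.0


def test_active_selection_beats_random_on_average(selection_experiment):
    """Qualitative mirror of the production result: final-iteration F1 of
    uncertainty-guided selection exceeds matched random selection, with a
    one-sided sign test at alpha = 0.1."""
    from scipy import stats

    act = np.array(selection_experiment["active_f1"])
    rnd = np.array(selection_experiment["random_f1"])
    assert act.mean() >= rnd.mean()
    wins = int((act > rnd).sum())
    n = int((act != rnd).sum())
    p = stats.binomtest(wins, n, 0.5, alternative="greater").pvalue
    assert p < 0.1


def test_consensus_training_beats_worst_labeller(label_quality_experiment):
    """Label-error mirror: consensus-trained models outperform models
    trained on the least accurate labeller's masks."""
    res = label_quality_experiment
    assert res["consensus"]["f1"] >= res["worst"]["f1"]
    assert res["consensus"]["accuracy"] >= res["worst"]["accuracy"]
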