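"""Loss, analytic BPTT gradients, training loop and evaluation protocol."""

import numpy as np
import pytest

from fallrnn import FallDetectorRNN, TrainConfig, kfold_cv, subject_split, train
from fallrnn import GeneratorProfile, generate_dataset
from fallrnn.rnncore import init_model
from fallrnn.training import (
    DEFAULT_GRID,
    batch_loss,
    cross_entropy,
    gradients,
    grid_search,
)
from fallrnn.windowing import SegmentationConfig, blocks_to_arrays, build_block_datasets


class TestCrossEntropy:
    def test_confident_correct_prediction(self):
        assert cross_entropy(np.array([1.0, 0.0, 0.0]), "BKG") <= 1e-7 * 300

    def test_uniform_scores_give_log3(self):
        assert cross_entropy(np.full(3, 1 / 3), "FALL") == pytest.approx(np.log(3))

    def test_batch_mean_matches_per_item_sum(self, rng):
        m = init_model("1xGRU", n_units=4, rng=rng)
        X = rng.normal(size=(6, 5, 3))
        y = ["BKG", "ALERT", "FALL", "BKG", "BKG", "FALL"]
        from fallrnn.rnncore import forward_batch

        per_item = [cross_entropy(forward_batch(m, X[i : i + 1])[0], y[i]) for i in range(6)]
        assert batch_loss(m, X, y) == pytest.approx(np.mean(per_item), abs=1e-10)

    def test_non_probability_scores_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            cross_entropy(np.array([0.5, 0.2, 0.1]), "BKG")


def _randomized(arch, rng, n_units=4, peepholes=False):
    m = init_model(arch, n_units=n_units, rng=rng, peepholes_enabled=peepholes)
    for _, arr in m.named_params():
        arr += rng.normal(0, 0.3, arr.shape)
    m.batchnorm.running_mean = rng.normal(0, 0.2, 3)
    m.batchnorm.running_var = rng.uniform(0.5, 2.0, 3)
    return m


class TestGradients:
    @pytest.mark.parametrize(
        "arch,peepholes",
        [("1xLSTM", False), ("1xLSTM", True), ("2xLSTM", False),
         ("1xGRU", False), ("2xGRU", False)],
    )
    def test_analytic_matches_central_finite_differences(self, arch, peepholes):
        """Every parameter's gradient agrees with (L(p+h)-L(p-h))/2h."""
        rng = np.random.default_rng(99)
        m = _randomized(arch, rng, peepholes=peepholes)
        X = rng.normal(size=(3, 5, 3))
        y = ["BKG", "FALL", "ALERT"]
        mask = (rng.random((3, 4)) < 0.8) / 0.8
        g = gradients(m, X, y, mask)
        params = dict(m.named_params())
        assert set(g) == set(params)
        h = 1e-5
        for name, arr in params.items():
            flat = arr.reshape(-1)
            for k in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[k]
                flat[k] = orig + h
                lp = batch_loss(m, X, y, mask)
                flat[k] = orig - h
                lm = batch_loss(m, X, y, mask)
                flat[k] = orig
                fd = (lp - lm) / (2 * h)
                rel = abs(g[name].reshape(-1)[k] - fd) / max(abs(fd), 1e-8)
                assert rel < 1e-4, f"{name}[{k}]: analytic vs FD rel err {rel:.2e}"

    def test_dense_bias_gradient_sums_to_zero(self, rng):
        # softmax-CE: gradient over the class logits always sums to zero
        m = _randomized("1xGRU", rng)
        X = rng.normal(size=(9, 5, 3))
        y = ["BKG", "ALERT", "FALL"] * 3
        g = gradients(m, X, y)
        assert g["dense.b"].sum() == pytest.approx(0.0, abs=1e-12)

    def test_all_bkg_batch_pushes_bkg_logit_up(self, rng):
        m = _randomized("1xGRU", rng)
        X = rng.normal(size=(5, 5, 3))
        y = ["BKG"] * 5
        g = gradients(m, X, y)
        assert g["dense.b"][0] < 0  # descending the gradient raises the BKG bias
        base = batch_loss(m, X, y)
        m.dense.b[0] += 1e-3
        assert batch_loss(m, X, y) < base

    def test_empty_batch_rejected(self, rng):
        m = _randomized("1xGRU", rng)
        with pytest.raises(ValueError, match="non-empty"):
            gradients(m, np.zeros((0, 5, 3)), [])


class TestTrain:
    def test_overfits_a_tiny_dataset(self, small_blocks):
        X, y, _ = blocks_to_arrays(small_blocks)
        sel = np.r_[
            np.flatnonzero(y == "BKG")[:8],
            np.flatnonzero(y == "ALERT")[:6],
            np.flatnonzero(y == "FALL")[:6],
        ]
        cfg = TrainConfig(epochs=150, learning_rate=0.003, n_units=16, batch_size=8, seed=1)
        model, history = train("1xGRU", X[sel], y[sel], cfg)
        from fallrnn.rnncore import predict_batch

        pred, _ = predict_batch(model, X[sel])
        assert np.mean(pred == y[sel]) == 1.0

    def test_loss_decreases_on_separable_toy(self, rng):
        # class signatures are constant offsets: linearly separable
        X = np.concatenate(
            [rng.normal(loc, 0.05, size=(15, 6, 3)) for loc in (-1.0, 0.0, 1.0)]
        )
        y = np.array(["BKG"] * 15 + ["ALERT"] * 15 + ["FALL"] * 15)
        _, history = train("1xGRU", X, y, TrainConfig(epochs=15, n_units=4, seed=0))
        losses = [h["loss"] for h in history]
        upticks = sum(b > a * 1.05 for a, b in zip(losses, losses[1:]))
        assert upticks <= max(1, int(0.05 * len(losses)) + 1)
        assert losses[-1] < losses[0]

    def test_seeded_training_is_bit_reproducible(self, small_blocks):
        X, y, _ = blocks_to_arrays(small_blocks[:40])
        cfg = TrainConfig(epochs=3, n_units=4, seed=5, dropout=0.2)
        m1, h1 = train("1xLSTM", X, y, cfg)
        m2, h2 = train("1xLSTM", X, y, cfg)
        for (n1, a1), (n2, a2) in zip(m1.named_params(), m2.named_params()):
            assert n1 == n2 and np.array_equal(a1, a2)
        assert h1 == h2

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train("1xGRU", np.zeros((0, 8, 3)), [])


class TestSubjectSplit:
    def test_cohort_38_subjects_splits_30_8(self):
        p = GeneratorProfile(recording_duration_s=1.0,
                             event_rates={"fall": 0.0, "hazard": 0.0})
        ds = generate_dataset(p)
        tr, te = subject_split(ds, 0.8, seed=0)
        assert len(tr) == 30 and len(te) == 8
        adults_tr = sum(1 for s in tr if s.startswith("SA"))
        assert adults_tr == 18  # 23 * 0.8 rounded; elderly contribute 12
        assert not set(tr) & set(te)

    def test_two_subjects_at_half(self):
        p = GeneratorProfile(n_adults=2, n_elderly=0, recording_duration_s=1.0,
                             event_rates={"fall": 0.0, "hazard": 0.0})
        ds = generate_dataset(p)
        tr, te = subject_split(ds, 0.5, seed=0, balance_age_groups=False)
        assert len(tr) == 1 and len(te) == 1

    def test_no_recording_spans_both_sides(self, small_dataset):
        tr, te = subject_split(small_dataset, 0.67, seed=1)
        rec_train = {r.recording_id for s in tr for r in small_dataset[s]}
        rec_test = {r.recording_id for s in te for r in small_dataset[s]}
        assert not rec_train & rec_test

    def test_single_subject_rejected(self):
        p = GeneratorProfile(n_adults=1, n_elderly=0, recording_duration_s=1.0,
                             event_rates={"fall": 0.0, "hazard": 0.0})
        with pytest.raises(ValueError, match="two subjects"):
            subject_split(generate_dataset(p))


def _blocks_by_subject(dataset, level=3):
    datasets = build_block_datasets(dataset, SegmentationConfig(), levels=level)
    out: dict = {}
    for b in datasets[level]:
        out.setdefault(b.recording_id.split("_")[0], []).append(b)
    return out


class TestKFold:
    def test_folds_partition_subjects(self):
        p = GeneratorProfile(n_adults=4, n_elderly=2, recording_duration_s=20.0, seed=2)
        bbs = _blocks_by_subject(generate_dataset(p))
        cfg = TrainConfig(epochs=2, n_units=4, seed=0)
        cv = kfold_cv("1xGRU", bbs, k=3, cfg=cfg)
        folds = cv["folds"]
        union = {s for f in folds for s in f}
        assert union == set(bbs)
        assert sum(len(f) for f in folds) == len(bbs)  # pairwise disjoint
        assert cv["macro_f1_mean"] == pytest.approx(
            np.mean([r.macro_f1 for r in cv["reports"]])
        )

    def test_too_few_subjects_rejected(self, small_dataset):
        bbs = _blocks_by_subject(small_dataset)
        with pytest.raises(ValueError, match="folds"):
            kfold_cv("1xGRU", bbs, k=10)


class TestGridSearch:
    def test_default_grid_has_27_points(self):
        import itertools

        combos = list(itertools.product(*DEFAULT_GRID.values()))
        assert len(combos) == 27

    def test_argmax_property_and_single_point(self):
        p = GeneratorProfile(n_adults=3, n_elderly=0, recording_duration_s=20.0, seed=4)
        bbs = _blocks_by_subject(generate_dataset(p))
        cfg = TrainConfig(epochs=2, n_units=4, seed=0)
        tiny_grid = {"learning_rate": [0.01, 0.001], "batch_size": [16]}
        res = grid_search("1xGRU", bbs, grid=tiny_grid, k=3, cfg=cfg)
        assert len(res.results) == 2
        assert res.best_score >= max(r[1] for r in res.results) - 1e-12
        single = grid_search(
            "1xGRU", bbs, grid={"learning_rate": [0.005]}, k=3, cfg=cfg
        )
        assert single.best_config == {"learning_rate": 0.005}

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            grid_search("1xGRU", {}, grid={"learning_rate": []})


class TestEstimator:
    def test_fit_predict_api(self, small_blocks):
        X, y, _ = blocks_to_arrays(small_blocks)
        est = FallDetectorRNN(arch="1xGRU", n_units=8, epochs=5, random_state=0)
        est.fit(X, y)
        assert hasattr(est, "model_") and hasattr(est, "history_")
        assert list(est.classes_) == ["BKG", "ALERT", "FALL"]
        pred = est.predict(X)
        assert pred.shape == y.shape
        probs = est.predict_proba(X)
        assert probs.shape == (len(X), 3)
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_get_set_params_clone(self):
        from sklearn.base import clone

        est = FallDetectorRNN(arch="2xLSTM", dropout=0.2)
        params = est.get_params()
        assert params["arch"] == "2xLSTM" and params["dropout"] == 0.2
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_invalid_inputs_rejected(self, small_blocks):
        X, y, _ = blocks_to_arrays(small_blocks)
        with pytest.raises(ValueError, match="arch"):
            FallDetectorRNN(arch="nope").fit(X, y)
        with pytest.raises(ValueError, match=r"\(n_blocks, width, 3\)"):
            FallDetectorRNN().fit(X[:, :, :2], y)
        with pytest.raises(RuntimeError, match="not fitted"):
            FallDetectorRNN().predict(X)
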