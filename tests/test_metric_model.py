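import numpy as np
import pytest

from ambumetric.metric_model import (
    EarlyStopping,
    ModelConfig,
    _sgd_step,
    build_model,
    count_parameters,
    embed,
    feature_loss,
    fine_tune_split,
    predict,
    regression_loss,
    train,
)
from ambumetric.pairing import form_pairs
from ambumetric.preprocessing import apply_minmax, fit_minmax, \
    interpolate_dataset

from conftest import make_dataset


def naive_feature_loss(emb_a, emb_b, yhat_a, yhat_b, weight):
    """Reference loop: per-pair scalar arithmetic, no vectorization."""
    total = 0.0
    for i in range(len(emb_a)):
        d = sum((float(x) - float(y)) ** 2
                for x, y in zip(emb_a[i], emb_b[i])) ** 0.5
        total += weight[i] * abs(d - abs(yhat_a[i] - yhat_b[i]))
    return total


def naive_regression_loss(pred, y, weight):
    return sum(w * (p - t) ** 2 for w, p, t in zip(weight, pred, y))


class TestLosses:
    def test_identical_pair_zero(self):
        e = np.array([1.0, 2.0])
        assert feature_loss(e, e, 0.5, 0.5) == 0.0

    def test_three_four_five_arithmetic(self):
        out = feature_loss(np.array([0.0, 0.0]), np.array([3.0, 4.0]),
                           0.5, 0.0, weight=1.0)
        np.testing.assert_allclose(out, 4.5)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=4), rng.normal(size=4)
        np.testing.assert_allclose(feature_loss(a, b, 0.1, 0.3),
                                   feature_loss(-a, -b, 0.1, 0.3))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            feature_loss(np.zeros(3), np.zeros(4), 0.0, 0.0)

    def test_regression_loss_values(self):
        assert regression_loss(3.0, 3.0) == 0.0
        assert regression_loss(2.0, 3.0) == 1.0
        assert regression_loss(0.0, 5.0, weight=2.0) == 50.0

    def test_batched_matches_naive_loop(self):
        rng = np.random.default_rng(1)
        n = 100
        ea, eb = rng.normal(size=(n, 8)), rng.normal(size=(n, 8))
        ya, yb = rng.normal(size=n), rng.normal(size=n)
        w = rng.uniform(0.5, 2.0, size=n)
        batched = feature_loss(ea, eb, ya, yb, weight=w).sum()
        np.testing.assert_allclose(batched,
                                   naive_feature_loss(ea, eb, ya, yb, w),
                                   rtol=1e-6)
        pred, y = rng.normal(size=n), rng.normal(size=n)
        np.testing.assert_allclose(regression_loss(pred, y, w).sum(),
                                   naive_regression_loss(pred, y, w),
                                   rtol=1e-6)

    def test_trainer_batch_loss_matches_reference(self):
        """The SGD step's reported loss equals the reference per-pair sum."""
        cfg = ModelConfig(dropout=0.0, l2_penalty=0.0, seed=0,
                          learning_rate=1e-9)
        model = build_model(cfg, input_dim=5)
        rng = np.random.default_rng(2)
        n = 50
        Xa, Xb = rng.normal(size=(n, 5)), rng.normal(size=(n, 5))
        ya, yb = rng.normal(size=n), rng.normal(size=n)
        yha, yhb = rng.normal(size=n), rng.normal(size=n)
        w = rng.uniform(0.5, 2.0, size=n)
        ea = model.forward_shared(Xa)
        eb = model.forward_shared(Xb)
        pa, pb = model.predict_head(ea), model.predict_head(eb)
        expected = (naive_feature_loss(ea, eb, yha, yhb, w)
                    + naive_regression_loss(pa, ya, w)
                    + naive_regression_loss(pb, yb, w)) / n
        got = _sgd_step(model, Xa, Xb, ya, yb, yha, yhb, w,
                        np.random.default_rng(0))
        np.testing.assert_allclose(got, expected, rtol=1e-6)


class TestBuildModel:
    def test_parameter_count_12865(self):
        model = build_model(ModelConfig(n_shared_layers=3), input_dim=69)
        # 69*64+64 + 2*(64*64+64) + 64+1
        assert count_parameters(model) == 12865

    def test_same_seed_identical_weights(self):
        m1 = build_model(ModelConfig(seed=5), input_dim=10)
        m2 = build_model(ModelConfig(seed=5), input_dim=10)
        for a, b in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(a, b)

    def test_augmented_input_shape(self):
        model = build_model(ModelConfig(), input_dim=83)
        assert model.weights[0].shape == (83, 64)

    @pytest.mark.parametrize("kwargs", [
        {"n_shared_layers": 2}, {"n_shared_layers": 6},
        {"dropout": 0.5}, {"patience": 4}, {"batch_size": 100},
        {"learning_rate": 0.0}, {"loss_mix": -1.0},
    ])
    def test_config_out_of_range(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)


class TestGradients:
    def test_finite_difference_check(self):
        """Analytic gradients match central finite differences."""
        cfg = ModelConfig(dropout=0.0, l2_penalty=0.0, seed=3,
                          learning_rate=1.0)
        rng = np.random.default_rng(4)
        n = 12
        Xa, Xb = rng.normal(size=(n, 4)), rng.normal(size=(n, 4))
        ya, yb = rng.normal(size=n), rng.normal(size=n)
        yha, yhb = 0.2 * rng.normal(size=n), 0.2 * rng.normal(size=n)
        w = np.ones(n)

        def loss_of(model):
            ea = model.forward_shared(Xa)
            eb = model.forward_shared(Xb)
            lf = feature_loss(ea, eb, yha, yhb, weight=w).sum()
            lr = (regression_loss(model.predict_head(ea), ya, w).sum()
                  + regression_loss(model.predict_head(eb), yb, w).sum())
            return (lf + lr) / n

        model = build_model(cfg, input_dim=4)
        before = model.get_state()
        _sgd_step(model, Xa, Xb, ya, yb, yha, yhb, w,
                  np.random.default_rng(0))
        after = model.get_state()
        # gradient = (w_before - w_after) / lr for a handful of entries
        probe = build_model(cfg, input_dim=4)
        eps = 1e-6
        checked = 0
        for layer in range(len(before[0])):
            W0, W1 = before[0][layer], after[0][layer]
            for idx in [(0, 0), (1, 2)]:
                analytic = (W0[idx] - W1[idx]) / cfg.learning_rate
                probe.set_state(before)
                probe.weights[layer][idx] = W0[idx] + eps
                up = loss_of(probe)
                probe.weights[layer][idx] = W0[idx] - eps
                dn = loss_of(probe)
                numeric = (up - dn) / (2 * eps)
                np.testing.assert_allclose(analytic, numeric, rtol=1e-4,
                                           atol=1e-7)
                checked += 1
        assert checked >= 6


class TestEarlyStopping:
    def test_strictly_worsening_stops_after_patience(self):
        stopper = EarlyStopping(patience=3)
        rs = [0.5, 0.4, 0.3, 0.2, 0.1]
        stops = [stopper.update(r) for r in rs[:4]]
        assert stops == [False, False, False, True]
        assert stopper.best_epoch == 1
        assert stopper.epoch == 4

    def test_improvement_resets_patience(self):
        stopper = EarlyStopping(patience=3)
        for r in [0.1, 0.05, 0.2, 0.1, 0.1]:
            assert not stopper.update(r)
        assert stopper.best_epoch == 3
        assert stopper.update(0.15)  # 3rd consecutive non-improvement

    def test_nan_never_improves(self):
        stopper = EarlyStopping(patience=3)
        assert not stopper.update(float("nan"))
        assert not stopper.update(float("nan"))
        assert stopper.update(float("nan"))
        assert stopper.best_epoch == 0


@pytest.fixture(scope="module")
def trained_siamese(signal_cohort):
    ds, _ = signal_cohort
    ds = interpolate_dataset(ds)
    train_p = ds.participants[:14]
    val_p = ds.participants[14:]
    tr = ds.subset(train_p)
    stats = fit_minmax(tr)
    tr_n = apply_minmax(tr, stats)
    va_n = apply_minmax(ds.subset(val_p), stats)
    cfg = ModelConfig(max_epochs=30, patience=3, seed=0)
    pairs = form_pairs(tr_n, "stress").subsample(3000, seed=0)
    cols = ds.feature_schema.names
    model = build_model(cfg, input_dim=len(cols))
    trained = train(model, pairs, va_n.frame[cols].to_numpy(float),
                    va_n.frame["stress"].to_numpy(float), cfg)
    return trained, tr_n, va_n, cols


class TestTraining:
    def test_learns_synthetic_signal(self, trained_siamese):
        trained, _, va_n, cols = trained_siamese
        pred = predict(trained, va_n.frame[cols].to_numpy(float))
        r = np.corrcoef(pred, va_n.frame["stress"])[0, 1]
        assert r > 0.5

    def test_shuffled_labels_no_signal(self, signal_cohort):
        ds, _ = signal_cohort
        ds = interpolate_dataset(ds)
        frame = ds.frame.copy()
        rng = np.random.default_rng(0)
        frame["stress"] = rng.permutation(frame["stress"].to_numpy())
        ds = ds.replace_frame(frame)
        tr = apply_minmax(ds.subset(ds.participants[:14]),
                          fit_minmax(ds.subset(ds.participants[:14])))
        va = apply_minmax(ds.subset(ds.participants[14:]),
                          fit_minmax(ds.subset(ds.participants[:14])))
        cfg = ModelConfig(max_epochs=10, patience=3, seed=1)
        pairs = form_pairs(tr, "stress").subsample(2000, seed=0)
        cols = ds.feature_schema.names
        model = build_model(cfg, input_dim=len(cols))
        trained = train(model, pairs, va.frame[cols].to_numpy(float),
                        va.frame["stress"].to_numpy(float), cfg)
        pred = predict(trained, va.frame[cols].to_numpy(float))
        n_val = len(pred)
        r = np.corrcoef(pred, va.frame["stress"])[0, 1]
        assert abs(r) < 3 / np.sqrt(n_val) + 0.1

    def test_metric_loss_alone_decreases(self, signal_cohort):
        """With loss_mix=0 the feature loss still drops on a fixed batch."""
        ds, _ = signal_cohort
        ds = interpolate_dataset(ds)
        tr = apply_minmax(ds, fit_minmax(ds))
        cfg = ModelConfig(max_epochs=1, dropout=0.0, loss_mix=0.0, seed=2)
        pairs = form_pairs(tr, "stress").subsample(1000, seed=0)
        cols = ds.feature_schema.names
        model = build_model(cfg, input_dim=len(cols))
        ia, ib = pairs.idx_a, pairs.idx_b

        def lf():
            ea = model.forward_shared(pairs.X[ia])
            eb = model.forward_shared(pairs.X[ib])
            return feature_loss(ea, eb, pairs.yhat[ia], pairs.yhat[ib],
                                weight=pairs.weights).sum()

        before = lf()
        rng = np.random.default_rng(0)
        for _ in range(20):
            sel = rng.choice(len(pairs), 128, replace=False)
            _sgd_step(model, pairs.X[ia[sel]], pairs.X[ib[sel]],
                      pairs.y[ia[sel]], pairs.y[ib[sel]],
                      pairs.yhat[ia[sel]], pairs.yhat[ib[sel]],
                      pairs.weights[sel], rng)
        assert lf() < before

    def test_history_recorded_and_best_restored(self, trained_siamese):
        trained, _, va_n, cols = trained_siamese
        assert len(trained.history) >= 1
        assert 1 <= trained.best_epoch <= len(trained.history)
        pred = predict(trained, va_n.frame[cols].to_numpy(float))
        r = np.corrcoef(pred, va_n.frame["stress"])[0, 1]
        np.testing.assert_allclose(r, max(trained.history), atol=1e-9)


class TestPredictEmbed:
    def test_embedding_width_64(self, trained_siamese):
        trained, tr_n, _, cols = trained_siamese
        X = tr_n.frame[cols].to_numpy(float)[:5]
        assert embed(trained, X).shape == (5, 64)

    def test_inference_deterministic(self, trained_siamese):
        trained, tr_n, _, cols = trained_siamese
        X = tr_n.frame[cols].to_numpy(float)[:5]
        np.testing.assert_array_equal(predict(trained, X),
                                      predict(trained, X))

    def test_predict_is_head_of_embed(self, trained_siamese):
        trained, tr_n, _, cols = trained_siamese
        X = tr_n.frame[cols].to_numpy(float)[:5]
        np.testing.assert_allclose(
            predict(trained, X),
            trained.model.predict_head(embed(trained, X)))

    def test_dimension_mismatch_raises(self, trained_siamese):
        trained, *_ = trained_siamese
        with pytest.raises(ValueError):
            predict(trained, np.zeros((3, 7)))


class TestPersistence:
    def test_save_load_round_trip(self, trained_siamese, tmp_path):
        from ambumetric.metric_model import load_trained, save_trained
        trained, tr_n, _, cols = trained_siamese
        path = tmp_path / "model.json"
        save_trained(trained, path)
        loaded = load_trained(path)
        X = tr_n.frame[cols].to_numpy(float)[:8]
        np.testing.assert_allclose(predict(loaded, X),
                                   predict(trained, X), rtol=1e-12)
        assert loaded.best_epoch == trained.best_epoch
        assert loaded.history == trained.history


class TestFineTuneSplit:
    def test_fraction_zero_identity(self, tiny_dataset):
        ft, reduced = fine_tune_split(tiny_dataset, 0.0, seed=0)
        assert ft.n_records == 0
        assert reduced == tiny_dataset

    def test_floor_rule(self):
        ds = make_dataset({"a": [1] * 10})
        ft, reduced = fine_tune_split(ds, 0.5, seed=0)
        assert ft.n_records == 5 and reduced.n_records == 5
        ft2, red2 = fine_tune_split(ds, 0.39, seed=0)
        assert ft2.n_records == 3  # floor(0.39 * 10)

    def test_partition_property(self):
        ds = make_dataset({"a": [1] * 7, "b": [2] * 9})
        ft, reduced = fine_tune_split(ds, 0.4, seed=1)
        keys = lambda d: set(zip(d.frame["participant_id"],
                                 d.frame["day_index"]))
        assert keys(ft) | keys(reduced) == keys(ds)
        assert not keys(ft) & keys(reduced)

    def test_fraction_above_limit_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            fine_tune_split(tiny_dataset, 0.95)

    def test_seed_determinism(self):
        ds = make_dataset({"a": [1] * 10})
        a1, _ = fine_tune_split(ds, 0.5, seed=3)
        a2, _ = fine_tune_split(ds, 0.5, seed=3)
        assert a1 == a2
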