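"""Loss, training loop and nested cross-validation protocol."""

import math

import numpy as np
import pytest

from sigunet import (
    CVPlan,
    NetworkConfig,
    SyntheticSpec,
    TrainConfig,
    encode_records,
    generate_dataset,
    loss,
    nested_cv,
    stratified_folds,
    train_model,
)


def one_hot_n(L=96):
    y = np.zeros((L, 3))
    y[:, 2] = 1.0
    return y


class TestLoss:
    def test_exact_prediction_gives_zero(self):
        y = one_hot_n()
        assert loss(y, y) == pytest.approx(0.0)

    def test_uniform_prediction_closed_form(self):
        y = one_hot_n()
        h = np.full((96, 3), 1 / 3)
        assert loss(y, h) == pytest.approx(96 * math.log(3))

    def test_single_half_probability_position(self):
        y = one_hot_n()
        h = y.copy()
        h[17] = [0.25, 0.25, 0.5]
        assert loss(y, h) == pytest.approx(math.log(2))

    def test_clipping_keeps_loss_finite(self):
        y = one_hot_n()
        h = np.zeros((96, 3))
        h[:, 0] = 1.0  # true class probability exactly 0 everywhere
        val = loss(y, h)
        assert np.isfinite(val)
        assert val == pytest.approx(96 * -math.log(1e-7))

    def test_mask_padding_skips_padded_positions(self):
        y = one_hot_n()
        h = y.copy()
        h[90] = [0.5, 0.25, 0.25]  # error inside the padding
        assert loss(y, h, mask_padding=True, n_real=50) == pytest.approx(0.0)
        assert loss(y, h) > 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss(one_hot_n(), np.full((4, 3), 1 / 3))

    def test_nonnegative_on_random_inputs(self, rng):
        for _ in range(20):
            y = np.zeros((96, 3))
            y[np.arange(96), rng.integers(0, 3, 96)] = 1.0
            h = rng.random((96, 3)) + 1e-9
            h /= h.sum(axis=1, keepdims=True)
            assert loss(y, h) >= 0.0


@pytest.fixture(scope="module")
def toy_samples():
    recs = generate_dataset(SyntheticSpec(n_sp=10, n_tm=5, n_other=5, seed=7))
    return encode_records(recs)


class TestTrainModel:
    NET = NetworkConfig(m=6, n=6, depth=2, convs_per_level=1)

    def test_loss_decreases_on_toy_problem(self, toy_samples):
        net = NetworkConfig(m=8, n=8, depth=2, convs_per_level=2)
        tc = TrainConfig(
            learning_rate=3e-3, max_epochs=60, patience=60, seed=1, batch_size=8
        )
        _, hist = train_model(toy_samples, toy_samples, net, tc)
        assert hist["train_loss"][-1] < 0.1 * hist["train_loss"][0]

    def test_same_seed_reproduces_history(self, toy_samples):
        tc = TrainConfig(max_epochs=3, patience=3, seed=42, batch_size=8)
        _, h1 = train_model(toy_samples[:12], toy_samples[12:], self.NET, tc)
        _, h2 = train_model(toy_samples[:12], toy_samples[12:], self.NET, tc)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_early_stopping_bookkeeping(self, toy_samples):
        tc = TrainConfig(max_epochs=30, patience=1, seed=3, batch_size=8)
        model, hist = train_model(toy_samples, toy_samples, self.NET, tc)
        n = len(hist["val_loss"])
        assert n <= 30
        assert hist["best_val_loss"] == min(hist["val_loss"])
        # restored weights reproduce the best validation loss
        xv = np.stack([s.x for s in toy_samples])
        yv = np.stack([s.y for s in toy_samples])
        probs = model.forward(xv)
        val = float(
            -(yv * np.log(np.clip(probs, 1e-7, 1))).sum() / len(toy_samples)
        )
        assert val == pytest.approx(hist["best_val_loss"], rel=1e-9)

    def test_empty_split_rejected(self, toy_samples):
        tc = TrainConfig(max_epochs=1, patience=1)
        with pytest.raises(ValueError):
            train_model([], toy_samples, self.NET, tc)


class StubModel:
    """Constant-output model: every position gets the same probability row."""

    def __init__(self, row):
        self.row = np.asarray(row, dtype=float)

    def predict(self, x):
        return np.tile(self.row, (x.shape[0], x.shape[1], 1))


class TestStratifiedFolds:
    def test_partition_properties(self, small_samples):
        folds = stratified_folds(small_samples, 5, seed=0)
        all_idx = [i for f in folds for i in f]
        assert sorted(all_idx) == list(range(len(small_samples)))
        assert len(set(all_idx)) == len(small_samples)
        # stratification: every fold sees at least one positive
        for f in folds:
            assert any(small_samples[i].true_is_sp for i in f)


class TestNestedCV:
    @pytest.fixture(scope="class")
    @staticmethod
    def cv_samples():
        recs = generate_dataset(SyntheticSpec(n_sp=40, n_tm=30, n_other=30, seed=21))
        return encode_records(recs)

    def test_protocol_with_stub_models(self, cv_samples):
        """Leakage freedom, ensemble size k-1 and exact prediction averaging."""
        calls_log = []
        stub_rows = iter(
            [[0.8, 0.1, 0.1], [0.6, 0.2, 0.2], [0.4, 0.3, 0.3], [0.2, 0.4, 0.4]] * 100
        )

        def stub_train(train, val, cfg, tc):
            train_ids = {s.source_id for s in train}
            val_ids = {s.source_id for s in val}
            calls_log.append((train_ids, val_ids))
            return StubModel(next(stub_rows))

        plan = CVPlan(
            k=5,
            hyper_grid=[(NetworkConfig(m=4, n=4, depth=1, convs_per_level=1), 0.5)],
            seed=9,
        )
        tc = TrainConfig(max_epochs=1, patience=1)
        result = nested_cv(cv_samples, plan, tc, train_fn=stub_train)

        # 5 outer folds x 4 inner splits, one architecture -> 20 trainings
        assert len(calls_log) == 20
        by_id = {s.source_id: s for s in cv_samples}
        start = 0
        for fr in result.folds:
            test_ids = set(fr.test_ids)
            fold_calls = calls_log[start : start + 4]
            start += 4
            for train_ids, val_ids in fold_calls:
                assert not (test_ids & train_ids)
                assert not (test_ids & val_ids)
            # averaged test prediction equals the mean of the 4 constant rows
            rows = np.array([[0.8, 0.1, 0.1], [0.6, 0.2, 0.2],
                             [0.4, 0.3, 0.3], [0.2, 0.4, 0.4]])
            expected = np.broadcast_to(rows.mean(axis=0), fr.avg_probs.shape)
            np.testing.assert_allclose(fr.avg_probs, expected, atol=1e-12)
            np.testing.assert_allclose(fr.avg_probs.sum(axis=2), 1.0, atol=1e-5)

        # outer folds are disjoint and cover the dataset
        all_test = [i for fr in result.folds for i in fr.test_ids]
        assert sorted(all_test) == sorted(by_id)

    def test_threshold_candidates_share_models(self, cv_samples):
        n_trainings = []

        def counting_stub(train, val, cfg, tc):
            n_trainings.append(1)
            return StubModel([0.5, 0.25, 0.25])

        cfg = NetworkConfig(m=4, n=4, depth=1, convs_per_level=1)
        plan = CVPlan(k=5, hyper_grid=[(cfg, t) for t in (0.3, 0.5, 0.7)], seed=9)
        nested_cv(cv_samples, plan, TrainConfig(), train_fn=counting_stub)
        # thresholds are decision-rule parameters: no extra trainings
        assert sum(n_trainings) == 20

    def test_empty_grid_rejected(self, cv_samples):
        with pytest.raises(ValueError):
            nested_cv(cv_samples, CVPlan(k=5, hyper_grid=[]), TrainConfig())
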