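"""Architecture construction, channel schedules and weight counting."""

import numpy as np
import pytest

from sigunet import (
    SIGUNET_DEFAULT,
    SIGUNET_LIGHT_DEFAULT,
    UNET1D_DEFAULT,
    NetworkConfig,
    build_network,
    channel_schedule,
    count_parameters,
)


class TestChannelSchedule:
    @pytest.mark.parametrize(
        "m,n,level,expected",
        [(24, 24, 0, 24), (24, 24, 2, 72), (20, 20, 3, 80), (8, 0, 3, 8)],
    )
    def test_linear(self, m, n, level, expected):
        cfg = NetworkConfig(m=m, n=n, depth=3)
        assert channel_schedule(cfg, level) == expected

    @pytest.mark.parametrize("level,expected", [(0, 64), (1, 128), (2, 256), (3, 512)])
    def test_doubling(self, level, expected):
        cfg = NetworkConfig(m=64, n=0, depth=3, schedule="doubling")
        assert channel_schedule(cfg, level) == expected

    def test_level_beyond_depth_rejected(self):
        with pytest.raises(ValueError):
            channel_schedule(NetworkConfig(depth=2), 3)


class TestConfigValidation:
    def test_depth_must_divide_96(self):
        with pytest.raises(ValueError):
            NetworkConfig(depth=6)  # 96 is not divisible by 2^6

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(kernel_size=4)


class TestCountParameters:
    def test_single_1x1_conv_formula(self):
        # the final layer alone contributes c_in*3 + 3
        cfg = NetworkConfig(m=20, n=0, depth=1, kernel_size=1, convs_per_level=1)
        # closed form must match enumeration whatever the config
        assert count_parameters(cfg) == build_network(cfg).num_parameters()

    @pytest.mark.parametrize("cfg", [SIGUNET_DEFAULT, SIGUNET_LIGHT_DEFAULT, UNET1D_DEFAULT])
    def test_closed_form_matches_enumeration_defaults(self, cfg):
        assert count_parameters(cfg) == build_network(cfg).num_parameters()

    def test_closed_form_matches_enumeration_random_sweep(self):
        rng = np.random.default_rng(99)
        for _ in range(12):
            cfg = NetworkConfig(
                m=int(rng.integers(4, 65)),
                n=int(rng.integers(0, 65)),
                depth=int(rng.integers(1, 5)),
                kernel_size=int(rng.choice([1, 3, 5])),
                convs_per_level=int(rng.integers(1, 4)),
                pooling=str(rng.choice(["average", "max"])),
            )
            assert count_parameters(cfg) == build_network(cfg).num_parameters(), cfg

    def test_default_sizes_inside_published_ranges(self):
        assert 100_000 <= count_parameters(SIGUNET_DEFAULT) <= 300_000
        assert 60_000 <= count_parameters(SIGUNET_LIGHT_DEFAULT) <= 200_000

    def test_pooling_choice_does_not_change_weight_count(self):
        avg = NetworkConfig(pooling="average")
        mx = NetworkConfig(pooling="max")
        assert count_parameters(avg) == count_parameters(mx)
        assert build_network(avg).num_parameters() == build_network(mx).num_parameters()


class TestModelBehaviour:
    def test_output_rows_are_probabilities(self, rng):
        model = build_network(NetworkConfig(m=8, n=8, depth=2), seed=1)
        x = rng.random((3, 96, 20))
        p = model.forward(x)
        assert p.shape == (3, 96, 3)
        np.testing.assert_allclose(p.sum(axis=2), 1.0, atol=1e-5)
        assert (p >= 0).all()

    def test_constant_input_gives_position_independent_output(self):
        # no position-dependent weights: a constant input must give
        # identical probability rows at every position
        model = build_network(NetworkConfig(m=8, n=8, depth=2), seed=2)
        p = model.predict(np.zeros((96, 20)))
        np.testing.assert_allclose(p, np.tile(p[0], (96, 1)), atol=1e-10)

    def test_avg_and_max_pool_agree_on_constant_windows(self, rng):
        # when every pooled pair is constant the two operators coincide;
        # (inside the network, zero same-padding breaks window constancy at
        # the borders, so the equivalence is an operator-level property)
        from sigunet.nn import AvgPool2, MaxPool2

        x = np.repeat(rng.random((2, 48, 6)), 2, axis=1)  # constant pairs
        np.testing.assert_allclose(
            AvgPool2().forward(x), MaxPool2().forward(x), atol=1e-14
        )

    def test_gradients_match_numerical_differentiation(self):
        cfg = NetworkConfig(m=4, n=4, depth=2, convs_per_level=1)
        model = build_network(cfg, seed=3)
        rng = np.random.default_rng(0)
        x = rng.random((2, 96, 20))
        y = np.zeros((2, 96, 3))
        y[..., 2] = 1

        def total_loss():
            p = model.forward(x)
            return -(y * np.log(np.clip(p, 1e-7, 1))).sum()

        p = model.forward(x)
        model.backward(p - y)
        grads = [g.copy() for g in model.gradients()]
        params = model.parameters()
        eps = 1e-6
        check = np.random.default_rng(7)
        for pi in range(len(params)):
            flat = params[pi].ravel()
            for _ in range(2):
                j = int(check.integers(flat.size))
                old = flat[j]
                flat[j] = old + eps
                lp = total_loss()
                flat[j] = old - eps
                lm = total_loss()
                flat[j] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[pi].ravel()[j]
                assert abs(num - ana) <= 1e-4 * max(1.0, abs(num))

    def test_save_load_round_trip(self, tmp_path, rng):
        model = build_network(NetworkConfig(m=8, n=8, depth=2), seed=4)
        x = rng.random((96, 20))
        before = model.predict(x)
        model.save(tmp_path / "ckpt.npz")
        from sigunet import Model

        loaded = Model.load(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(loaded.predict(x), before)
        assert loaded.config == model.config
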