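"""Latent perturbations: bounds, masking semantics, determinism."""

import numpy as np
import pytest

from ctrseg import perturb


class TestFNoise:
    def test_zero_latent_unchanged(self):
        z = np.zeros((3, 3, 2))
        out = perturb.f_noise(z, np.random.default_rng(0))
        assert np.array_equal(out, z)

    def test_replays_seeded_uniform_stream(self):
        z = np.ones((2, 2, 1))
        out = perturb.f_noise(z, np.random.default_rng(123))
        n = np.random.default_rng(123).uniform(-0.3, 0.3, size=(2, 2, 1))
        assert np.allclose(out, 1.0 + n)

    def test_relative_change_bounded(self):
        rng = np.random.default_rng(9)
        z = rng.standard_normal((10, 10, 8)) + 0.5
        for seed in range(50):
            out = perturb.f_noise(z, np.random.default_rng(seed))
            rel = np.abs(out / z - 1.0)
            assert rel.max() <= 0.3 + 1e-12


class TestFDrop:
    def test_dominant_position_survives_alone(self):
        # one spatial position dominates every channel mean
        z = np.full((2, 2, 3), 0.1)
        z[1, 0, :] = 5.0
        for seed in range(10):
            out = perturb.f_drop(z, np.random.default_rng(seed))
            survived = np.any(out != 0, axis=-1)
            expected = np.zeros((2, 2), dtype=bool)
            expected[1, 0] = True
            assert np.array_equal(survived, expected)

    def test_ramp_thresholded_exactly(self):
        # channel mean is a ramp 0..1 over 11 positions; gamma forced
        # via a degenerate range
        vals = np.linspace(0, 1, 11)
        z = np.tile(vals[None, :, None], (1, 1, 4))
        out = perturb.f_drop(z, np.random.default_rng(0),
                             low=0.9, high=0.9)
        survived = np.any(out != 0, axis=-1)[0]
        assert np.array_equal(survived, vals > 0.9)

    def test_masked_positions_fully_zero(self):
        rng = np.random.default_rng(4)
        z = rng.random((5, 5, 6))
        out = perturb.f_drop(z, np.random.default_rng(1))
        dropped = np.all(out == 0, axis=-1)
        kept = ~dropped
        assert np.array_equal(out[kept], z[kept])

    def test_constant_latent_drops_everything(self):
        z = np.full((3, 3, 2), 2.5)
        out = perturb.f_drop(z, np.random.default_rng(0))
        assert np.all(out == 0)

    def test_invert_flips_mask(self):
        z = np.full((2, 2, 3), 0.1)
        z[0, 1, :] = 5.0
        out = perturb.f_drop(z, np.random.default_rng(2), invert=True)
        assert np.all(out[0, 1] == 0)
        assert np.array_equal(out[1, 0], z[1, 0])


class TestRandDropout:
    def test_zero_latent_unchanged(self):
        z = np.zeros((4, 4, 2))
        assert np.array_equal(
            perturb.rand_dropout(z, np.random.default_rng(0)), z)

    def test_empirical_drop_rate_matches_sampled_r(self):
        rng = np.random.default_rng(77)
        r = rng.uniform(0.1, 0.7)  # replay the first draw
        z = np.ones((100, 100, 10))
        out = perturb.rand_dropout(z, np.random.default_rng(77))
        frac = np.mean(out == 0)
        se = np.sqrt(r * (1 - r) / z.size)
        assert abs(frac - r) < 3 * se

    def test_deterministic_under_seed(self):
        z = np.random.default_rng(1).random((6, 6, 3))
        a = perturb.rand_dropout(z, np.random.default_rng(5))
        b = perturb.rand_dropout(z, np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestPerturbationSet:
    def test_default_order_and_shapes(self):
        params = perturb.PerturbationParams(k=3)
        fns = perturb.make_perturbation_set(params,
                                            np.random.default_rng(0))
        z = np.random.default_rng(1).random((4, 4, 6))
        outs = [f(z) for f in fns]
        assert len(outs) == 3
        assert all(o.shape == z.shape for o in outs)

    @pytest.mark.parametrize("k,expected", [
        (1, ["noise"]),
        (3, ["noise", "drop", "dropout"]),
        (6, ["noise", "drop", "dropout", "noise", "drop", "dropout"]),
    ])
    def test_cycling_convention(self, k, expected):
        assert perturb.perturbation_names(k) == expected

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            perturb.PerturbationParams(k=0)
        with pytest.raises(ValueError):
            perturb.perturbation_names(0)

    def test_pure_functions_leave_input_unmodified(self):
        z = np.random.default_rng(3).random((5, 5, 4))
        snapshot = z.copy()
        rng = np.random.default_rng(0)
        for name in perturb.perturbation_names(3):
            perturb.apply_perturbation_vjp(
                name, z, rng, perturb.PerturbationParams())
        assert np.array_equal(z, snapshot)

    def test_fixed_rng_makes_set_deterministic(self):
        z = np.random.default_rng(2).random((3, 3, 5))
        params = perturb.PerturbationParams()
        outs1 = [perturb.apply_perturbation_vjp(
            n, z, np.random.default_rng(11), params)[0]
            for n in perturb.perturbation_names(3)]
        outs2 = [perturb.apply_perturbation_vjp(
            n, z, np.random.default_rng(11), params)[0]
            for n in perturb.perturbation_names(3)]
        for a, b in zip(outs1, outs2):
            assert np.array_equal(a, b)

    def test_batched_vjp_matches_masking(self):
        # gradients pass through exactly where values survived
        z = np.random.default_rng(6).random((2, 4, 3, 3))  # NCHW batch
        g = np.ones_like(z)
        out, vjp = perturb.f_drop_vjp(z, np.random.default_rng(1),
                                      channel_axis=1, batch_axis=0)
        back = vjp(g)
        assert np.array_equal(back != 0, out != 0)
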