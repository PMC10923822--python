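"""Loss functions and ramp-up schedule against hand/brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctrseg import evalmetrics, losses


def bce_oracle(y, p, eps=1e-7):
    """Per-pixel loop oracle."""
    total = 0.0
    for yi, pi in zip(np.ravel(y), np.ravel(p)):
        pc = min(max(pi, eps), 1 - eps)
        total += -(yi * math.log(pc) + (1 - yi) * math.log(1 - pc))
    return total / np.size(y)


class TestBCE:
    def test_near_perfect_prediction_near_zero(self):
        y = np.array([[1, 0], [0, 1]], dtype=float)
        p = np.where(y == 1, 1 - 1e-7, 1e-7)
        assert losses.bce(y, p) < 1e-5

    def test_uninformative_half_gives_ln2(self):
        y = np.array([[1, 0], [1, 1]], dtype=float)
        assert losses.bce(y, np.full((2, 2), 0.5)) == pytest.approx(
            math.log(2), rel=1e-12)

    def test_matches_per_pixel_oracle(self):
        y = np.array([[1, 0], [0, 1]], dtype=float)
        p = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert losses.bce(y, p) == pytest.approx(bce_oracle(y, p))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            losses.bce(np.zeros((2, 2)), np.full((3, 3), 0.5))


class TestDice:
    def test_perfect_overlap_zero(self):
        y = np.zeros((4, 4))
        y[1:3, 1:3] = 1
        assert losses.dice_loss(y, y) == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_near_one(self):
        y = np.zeros((4, 4))
        y[0, 0] = 1
        p = np.zeros((4, 4))
        p[3, 3] = 1
        assert losses.dice_loss(y, p) == pytest.approx(1.0, abs=1e-5)

    def test_half_confidence_gives_one_third(self):
        y = np.zeros((4, 4))
        y[0:2, 0:2] = 1
        p = y * 0.5
        assert losses.dice_loss(y, p) == pytest.approx(1 / 3, abs=1e-6)

    def test_jaccard_dice_relation_on_binary_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = (rng.random((8, 8)) > 0.5).astype(float)
            p = (rng.random((8, 8)) > 0.5).astype(float)
            if not (y + p).any():
                continue
            d = 1 - losses.dice_loss(y, p)
            j = evalmetrics.jaccard(y, p)
            assert j == pytest.approx(d / (2 - d), abs=1e-4)


class TestSupervisedLoss:
    def test_perfect_batch_near_zero(self):
        y = np.zeros((3, 3))
        y[1, 1] = 1
        p = np.where(y == 1, 1 - 1e-7, 1e-7)
        assert losses.supervised_loss([(y, p)] * 4) < 1e-4

    def test_single_pair_is_bce_plus_dice(self):
        y = np.array([[1, 0], [0, 1]], dtype=float)
        p = np.array([[0.9, 0.1], [0.2, 0.8]])
        assert losses.supervised_loss([(y, p)]) == pytest.approx(
            losses.bce(y, p) + losses.dice_loss(y, p))

    def test_two_pairs_average(self):
        y1 = np.array([[1.0, 0.0]])
        p1 = np.array([[0.8, 0.3]])
        y2 = np.array([[0.0, 1.0]])
        p2 = np.array([[0.4, 0.6]])
        a = losses.bce(y1, p1) + losses.dice_loss(y1, p1)
        b = losses.bce(y2, p2) + losses.dice_loss(y2, p2)
        assert losses.supervised_loss([(y1, p1), (y2, p2)]) == \
            pytest.approx((a + b) / 2)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            losses.supervised_loss([])


class TestUnsupervisedLoss:
    def test_identical_outputs_zero(self):
        m = np.random.default_rng(0).random((5, 5))
        assert losses.unsupervised_loss([m], [[m, m, m]]) == 0.0

    def test_single_pixel_difference(self):
        m = np.zeros((4, 4))
        a = m.copy()
        a[2, 1] = 0.25
        assert losses.unsupervised_loss([m], [[a]]) == pytest.approx(0.25**2)

    def test_constant_offset_survives_averaging(self):
        # bs_u=2, k=3, every aux map differs by c: loss = N * c^2
        n, c = 16, 0.1
        m = [np.zeros((4, 4)), np.ones((4, 4))]
        aux = [[mi + c] * 3 for mi in m]
        assert losses.unsupervised_loss(m, aux, k=3) == pytest.approx(n * c**2)

    def test_invariant_to_permuting_aux_maps(self):
        rng = np.random.default_rng(1)
        m = rng.random((3, 3))
        maps = [rng.random((3, 3)) for _ in range(3)]
        v1 = losses.unsupervised_loss([m], [maps])
        v2 = losses.unsupervised_loss([m], [maps[::-1]])
        assert v1 == pytest.approx(v2)

    def test_ragged_aux_rejected(self):
        m = np.zeros((2, 2))
        with pytest.raises(ValueError):
            losses.unsupervised_loss([m, m], [[m], [m, m]], k=1)


class TestRampUp:
    def test_boundary_and_beyond_is_one(self):
        assert losses.rampup_weight(50, 50) == 1.0
        assert losses.rampup_weight(120, 50) == 1.0

    def test_start_value(self):
        assert losses.rampup_weight(0, 50) == pytest.approx(math.exp(-5))

    def test_non_decreasing_on_integer_grid(self):
        vals = [losses.rampup_weight(t, 50) for t in range(0, 101)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    @given(st.integers(0, 200), st.integers(1, 100))
    @settings(max_examples=50, deadline=None)
    def test_bounded_in_unit_interval(self, t, L):
        w = losses.rampup_weight(t, L)
        assert 0 < w <= 1


class TestTotalLoss:
    def test_past_ramp_plain_sum(self):
        terms = losses.total_loss(1.5, 2.0, t=60, L=50)
        assert terms.total == pytest.approx(3.5)
        assert terms.weight == 1.0

    def test_zero_unsupervised_reduces_to_supervised(self):
        for t in (0, 10, 100):
            assert losses.total_loss(1.2, 0.0, t, 50).total == \
                pytest.approx(1.2)

    def test_early_epoch_composition(self):
        terms = losses.total_loss(1.0, 2.0, t=0, L=50)
        assert terms.total == pytest.approx(1.0 + 2.0 * math.exp(-5))
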