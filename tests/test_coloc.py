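import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucoloc import (CostesConfig, costes_test, kendall_taub, manders_pair,
                     spearman_rho)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def manders_oracle(reference, query):
    """Direct-summation Manders coefficients (element loop, no reuse)."""
    ref = np.asarray(reference, dtype=float).ravel()
    qry = np.asarray(query, dtype=float).ravel()
    num1 = den1 = num2 = den2 = 0.0
    for r, q in zip(ref, qry):
        if q > 0:
            den1 += q
            if r > 0:
                num1 += q
        if r > 0:
            den2 += r
            if q > 0:
                num2 += r
    m1 = num1 / den1 if den1 else float("nan")
    m2 = num2 / den2 if den2 else float("nan")
    return m1, m2


def taub_oracle(x, y):
    """Kendall tau-b by exhaustive O(n²) pair counting with tie terms."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    conc = disc = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    denom = np.sqrt((conc + disc + ties_x) * (conc + disc + ties_y))
    return (conc - disc) / denom if denom else float("nan")


def spearman_sum_d2(x, y):
    """Spearman rho via 1 - 6Σd²/(n(n²-1)); valid only without ties."""
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    n = len(x)
    return 1 - 6 * np.sum((rx - ry) ** 2) / (n * (n ** 2 - 1))


# ---------------------------------------------------------------------------
# Manders split coefficients
# ---------------------------------------------------------------------------

class TestManders:
    def test_identical_masks_give_one(self):
        rng = np.random.default_rng(0)
        mask = rng.random((32, 32)) < 0.3
        m1, m2 = manders_pair(mask, mask)
        assert m1 == 1.0 and m2 == 1.0

    def test_disjoint_supports_give_zero(self):
        a = np.zeros((32, 32))
        b = np.zeros((32, 32))
        a[:10], b[20:] = 5.0, 7.0
        m1, m2 = manders_pair(a, b)
        assert m1 == 0.0 and m2 == 0.0

    def test_worked_example(self):
        ref = np.array([0.0, 1.0])
        qry = np.array([10.0, 30.0])
        m1, _ = manders_pair(ref, qry)
        assert m1 == pytest.approx(30 / 40)  # fraction of query intensity on ref

    def test_empty_query_is_flagged_nan_not_zero(self):
        ref = np.ones((4, 4))
        m1, m2 = manders_pair(ref, np.zeros((4, 4)))
        assert np.isnan(m1) and m2 == 0.0

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            manders_pair(np.zeros((4, 4)), np.zeros((4, 4)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            manders_pair(np.ones((3, 3)), np.ones((4, 4)))

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_direct_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(2, 8), rng.integers(2, 8))
        ref = rng.integers(0, 5, size=shape).astype(float)
        qry = rng.integers(0, 5, size=shape).astype(float)
        if not ref.any() and not qry.any():
            return
        got = manders_pair(ref, qry)
        want = manders_oracle(ref, qry)
        np.testing.assert_allclose(got, want, rtol=1e-12, equal_nan=True)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_role_swap_symmetry_exact(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, size=(6, 6)).astype(float)
        b = rng.integers(0, 4, size=(6, 6)).astype(float)
        if not a.any() or not b.any():
            return
        assert manders_pair(a, b)[0] == manders_pair(b, a)[1]
        assert manders_pair(a, b)[1] == manders_pair(b, a)[0]

    def test_invariance_to_positive_scaling(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 9, size=(10, 10)).astype(float)
        b = rng.integers(0, 9, size=(10, 10)).astype(float)
        base = manders_pair(a, b)
        assert manders_pair(7.3 * a, b) == pytest.approx(base)
        assert manders_pair(a, 0.2 * b) == pytest.approx(base)


# ---------------------------------------------------------------------------
# Rank correlations
# ---------------------------------------------------------------------------

class TestRankCorrelations:
    def test_perfect_agreement_and_reversal(self):
        a = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        assert spearman_rho(a, a) == pytest.approx(1.0)
        assert spearman_rho(a, 255 - a) == pytest.approx(-1.0)
        assert kendall_taub(a, a) == pytest.approx(1.0)
        assert kendall_taub(a, 255 - a) == pytest.approx(-1.0)

    def test_rho_worked_example_sum_d2(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 3.0, 2.0, 4.0])
        assert spearman_rho(a, b) == pytest.approx(spearman_sum_d2(a, b))
        assert spearman_rho(a, b) == pytest.approx(0.8)

    def test_taub_worked_example_with_ties(self):
        a = np.array([1.0, 2.0, 2.0, 3.0])
        b = np.array([1.0, 2.0, 3.0, 3.0])
        assert kendall_taub(a, b) == pytest.approx(taub_oracle(a, b))

    def test_constant_channel_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(spearman_rho(np.ones(5), np.arange(5.0)))
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(kendall_taub(np.ones(5), np.arange(5.0)))

    def test_too_few_voxels(self):
        with pytest.raises(ValueError):
            spearman_rho(np.array([1.0, 2.0]), np.array([2.0, 1.0]))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(5, 200))
    def test_taub_matches_pair_count_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 12, size=n).astype(float)  # many ties
        y = rng.integers(0, 12, size=n).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        assert kendall_taub(x, y) == pytest.approx(taub_oracle(x, y), abs=1e-12)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        x = rng.random(60)
        y = x + 0.3 * rng.random(60)
        assert spearman_rho(np.exp(x), y) == pytest.approx(spearman_rho(x, y))
        assert kendall_taub(x ** 3, y) == pytest.approx(kendall_taub(x, y))

    def test_tau_and_rho_agree_in_sign_on_monotone_data(self):
        rng = np.random.default_rng(5)
        x = rng.random(80)
        up = x + 0.1 * rng.random(80)
        down = -x + 0.1 * rng.random(80)
        assert np.sign(kendall_taub(x, up)) == np.sign(spearman_rho(x, up)) == 1
        assert np.sign(kendall_taub(x, down)) == np.sign(spearman_rho(x, down)) == -1

    def test_roi_restriction(self):
        a = np.arange(16.0).reshape(4, 4)
        b = a.copy()
        b[0, 0] = 99  # outside roi: must not matter
        roi = np.ones((4, 4), dtype=bool)
        roi[0, 0] = False
        assert spearman_rho(a, b, roi=roi) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Costes randomization
# ---------------------------------------------------------------------------

def textured_image(seed, size=64):
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, size=(size, size)).astype(float)
    return img


class TestCostes:
    def test_self_pairing_yields_hundred(self):
        img = textured_image(1)
        roi = np.ones(img.shape, dtype=bool)
        p = costes_test(img, img, roi, CostesConfig(seed=9))
        assert p == 100.0

    def test_deterministic_under_seed(self):
        a, b = textured_image(2), textured_image(3)
        roi = np.ones(a.shape, dtype=bool)
        cfg = CostesConfig(n_scrambles=20, seed=77)
        assert costes_test(a, b, roi, cfg) == costes_test(a, b, roi, cfg)

    def test_independent_channels_roughly_uniform(self):
        roi = np.ones((64, 64), dtype=bool)
        ps = [costes_test(textured_image(2 * k), textured_image(2 * k + 1), roi,
                          CostesConfig(n_scrambles=50, seed=k))
              for k in range(50)]
        assert np.mean(ps) == pytest.approx(50.0, abs=12.0)
        assert min(ps) < 40 and max(ps) > 60

    def test_too_small_roi_rejected(self):
        roi = np.zeros((10, 10), dtype=bool)
        roi[:6, :6] = True  # 2x2 blocks of 3 -> 4 < 16
        with pytest.raises(ValueError, match="block"):
            costes_test(np.ones((10, 10)), np.ones((10, 10)), roi, CostesConfig())

    def test_min_scrambles_enforced(self):
        with pytest.raises(ValueError):
            CostesConfig(n_scrambles=5)
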