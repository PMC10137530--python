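"""Block-level contracts: focus bijection, attention oracles, shape laws."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glyolite import blocks
from glyolite.tensor import Tensor, no_grad


def t(arr):
    return Tensor(np.asarray(arr, dtype=np.float32))


# ------------------------------------------------------------------- focus

class TestFocus:
    def test_two_by_two_enumeration(self):
        x = t(np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2))
        out = blocks.focus_slice(x).data
        # fixed lattice order: even/even, odd/even, even/odd, odd/odd
        assert out.shape == (1, 4, 1, 1)
        np.testing.assert_array_equal(out.ravel(), [1.0, 3.0, 2.0, 4.0])

    def test_shapes_640(self):
        x = t(np.zeros((1, 3, 640, 640)))
        with no_grad():
            assert blocks.focus_slice(x).shape == (1, 12, 320, 320)

    def test_rejects_odd_dims(self):
        with pytest.raises(ValueError, match="even"):
            blocks.focus_slice(t(np.zeros((1, 1, 3, 4))))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.sampled_from([2, 4, 8]),
           st.sampled_from([1, 3]))
    def test_bijection(self, seed, size, channels):
        x = np.random.default_rng(seed).standard_normal(
            (1, channels, size, size)
        ).astype(np.float32)
        sliced = blocks.focus_slice(t(x))
        np.testing.assert_array_equal(blocks.focus_unslice(sliced), x)

    def test_forward_shape_and_channel_check(self, rng):
        f = blocks.Focus(3, 32, 3, rng=rng)
        with no_grad():
            out = f(t(rng.standard_normal((1, 3, 64, 64))))
        assert out.shape == (1, 32, 32, 32)

    def test_identity_conv_returns_sliced_input(self, rng):
        """A unit-weight 1x1 conv after slicing reproduces the slices."""
        f = blocks.Focus(1, 4, 1, rng=rng)
        f.cv.conv.weight.data = np.eye(4, dtype=np.float32).reshape(4, 4, 1, 1)
        f.cv.bn.eval()
        f.cv.bn.eps = 0.0
        f.cv.act = blocks.nn.Identity()
        x = t(rng.standard_normal((1, 1, 6, 6)))
        with no_grad():
            out = f(x)
            sliced = blocks.focus_slice(x)
        np.testing.assert_allclose(out.data, sliced.data, atol=1e-6)


# -------------------------------------------------------------------- stem

class TestStem:
    def test_stride_four(self, rng):
        s = blocks.Stem(3, 16, rng=rng)
        with no_grad():
            out = s(t(rng.standard_normal((1, 3, 64, 64))))
        assert out.shape == (1, 16, 16, 16)

    def test_rejects_indivisible(self, rng):
        s = blocks.Stem(3, 16, rng=rng)
        with pytest.raises(ValueError, match="divisible"):
            s(t(np.zeros((1, 3, 30, 30))))

    def test_branch_concat_width(self, rng):
        s = blocks.Stem(3, 16, rng=rng)
        assert s.proj.conv.c1 == s.branch_b.conv.c2 + s.cv1.conv.c2


# --------------------------------------------------------------------- CoT

class TestCoT:
    def test_preserves_shape(self, rng):
        cot = blocks.CoT(8, rng=rng)
        with no_grad():
            out = cot(t(rng.standard_normal((2, 8, 5, 7))))
        assert out.shape == (2, 8, 5, 7)

    def test_concat_doubles_channels(self, rng):
        cot = blocks.CoT(8, rng=rng)
        assert cot.attn_reduce.conv.c1 == 16

    def test_rejects_even_kernel(self, rng):
        with pytest.raises(ValueError, match="odd"):
            blocks.CoT(8, k=2, rng=rng)

    def test_rejects_group_mismatch(self, rng):
        with pytest.raises(ValueError, match="groups"):
            blocks.CoT(6, rng=rng)

    def test_aggregation_matches_naive_loop(self, rng):
        """Vectorised local matrix multiplication vs per-position oracle."""
        dim, h, w = 8, 4, 4
        cot = blocks.CoT(dim, rng=rng)
        x = rng.standard_normal((1, dim, h, w)).astype(np.float32)
        with no_grad():
            out = cot(t(x)).data[0]
            k_static = cot.key_embed(t(x)).data[0]
            v = cot.value_embed(t(x)).data[0]
            att = cot.attn_expand(
                cot.attn_reduce(
                    Tensor(np.concatenate([k_static[None], x], axis=1))
                )
            ).data[0].reshape(dim, 9, h, w)
        vp = np.pad(v, ((0, 0), (1, 1), (1, 1)))
        expected = np.empty((dim, h, w))
        for c in range(dim):
            for i in range(h):
                for j in range(w):
                    weights = att[c, :, i, j]
                    weights = np.exp(weights - weights.max())
                    weights /= weights.sum()
                    neigh = vp[c, i : i + 3, j : j + 3].ravel()
                    expected[c, i, j] = k_static[c, i, j] + weights @ neigh
        np.testing.assert_allclose(out, expected, atol=1e-5)


# ------------------------------------------------------------------- SimAM

class TestSimAM:
    def test_constant_channel_uniform_scaling(self):
        x = t(np.full((1, 2, 4, 4), 3.0))
        out = blocks.SimAM(1e-4)(x).data
        expected = 3.0 / (1.0 + np.exp(-0.5))  # gate = logistic(1/2) exactly
        np.testing.assert_allclose(out, expected, rtol=1e-6)

    def test_gates_match_numerical_energy_minimisation(self):
        """Closed form vs scalar minimisation of the per-neuron energy."""
        from scipy.optimize import minimize

        vals = np.array([1.0, 2.0, 3.0, 4.0])
        lam = 1e-4
        out = blocks.SimAM(lam)(t(vals.reshape(1, 1, 2, 2))).data.ravel()
        gates = out / vals
        for k in range(4):
            target, others = vals[k], np.delete(vals, k)

            def energy(wb, target=target, others=others):
                w, b = wb
                return (
                    (1 - (w * target + b)) ** 2
                    + np.mean((-1 - (w * others + b)) ** 2)
                    + lam * w * w
                )

            res = minimize(energy, [0.1, 0.1], method="Nelder-Mead",
                           options={"xatol": 1e-13, "fatol": 1e-15,
                                    "maxiter": 20000})
            oracle_gate = 1.0 / (1.0 + np.exp(-1.0 / res.fun))
            assert gates[k] == pytest.approx(oracle_gate, abs=1e-6)

    def test_zero_parameters(self):
        assert blocks.SimAM().num_parameters() == 0

    def test_gates_strictly_inside_unit_interval(self, rng):
        x = rng.standard_normal((2, 3, 6, 6)).astype(np.float32)
        out = blocks.SimAM()(t(x)).data
        gates = out / np.where(np.abs(x) < 1e-12, 1.0, x)
        valid = np.abs(x) >= 1e-12
        assert np.all(gates[valid] > 0) and np.all(gates[valid] < 1)

    def test_rejects_bad_lambda(self):
        with pytest.raises(ValueError, match="lambda"):
            blocks.SimAM(0.0)


# --------------------------------------------------------------------- SPP

class TestSPP:
    def test_table_shape(self, rng):
        spp = blocks.SPP(64, 128, (5, 9, 13), rng=rng)
        with no_grad():
            out = spp(t(rng.standard_normal((1, 64, 10, 10))))
        assert out.shape == (1, 128, 10, 10)

    def test_equal_input_pools_to_itself(self, rng):
        spp = blocks.SPP(8, 8, (5,), rng=rng)
        x = t(np.full((1, 8, 6, 6), 2.5))
        with no_grad():
            y = spp.cv1(x)
            pooled = spp.pools[0](y)
        np.testing.assert_allclose(pooled.data, y.data, atol=1e-6)

    def test_single_kernel_concat_width(self, rng):
        spp = blocks.SPP(8, 8, (5,), rng=rng)
        assert spp.cv2.conv.c1 == 2 * spp.cv1.conv.c2

    def test_rejects_even_kernel(self, rng):
        with pytest.raises(ValueError, match="odd"):
            blocks.SPP(8, 8, (4,), rng=rng)


# ---------------------------------------------------- shape-preserving laws

@pytest.mark.parametrize("factory", [
    lambda rng: blocks.CoT(8, rng=rng),
    lambda rng: blocks.CoT3(8, 8, 1, rng=rng),
    lambda rng: blocks.SimAM(),
    lambda rng: blocks.SPP(8, 8, (5, 9, 13), rng=rng),
])
def test_spatial_dims_preserved(rng, factory):
    m = factory(rng)
    x = t(rng.standard_normal((1, 8, 6, 10)))
    with no_grad():
        out = m(x)
    assert out.shape[2:] == (6, 10)


def test_cot3_repeat_one_is_single_pass(rng):
    m = blocks.CoT3(16, 16, 1, rng=rng)
    assert len(m.m) == 1


def test_cot3_table_output_channels(rng):
    m = blocks.CoT3(64, 128, 3, rng=rng)
    with no_grad():
        out = m(t(rng.standard_normal((1, 64, 8, 8))))
    assert out.shape[1] == 128
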