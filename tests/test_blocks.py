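"""Block contracts: shapes, receptive fields, equivariance, parameter costs."""

import numpy as np
import pytest

from ducknet import blocks as B
from ducknet.nn import Tensor

rng = np.random.default_rng(7)


def build(kind, in_channels, filters, **kw):
    spec = B.BlockSpec(kind, filters, **kw)
    return B.make_block(spec, in_channels, rng=np.random.default_rng(11))


ALL_KINDS = ["residual", "midscope", "widescope", "separated", "duck", "simple_conv"]


class TestShapeContracts:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    @pytest.mark.parametrize("h,w,cin,filters", [(16, 16, 3, 8), (20, 12, 8, 8), (32, 32, 1, 4)])
    def test_shape_preserving(self, kind, h, w, cin, filters):
        block = build(kind, cin, filters).eval()
        x = Tensor(rng.random((2, h, w, cin), dtype=np.float32))
        out = block(x).data
        assert out.shape == (2, h, w, filters)
        assert np.isfinite(out).all()

    def test_functional_wrappers_shapes(self):
        x = rng.random((64, 64, 8), dtype=np.float32)
        assert B.residual_block(x, 16).shape == (64, 64, 16)
        assert B.residual_chain(rng.random((32, 32, 4), dtype=np.float32), 4, 1).shape == (32, 32, 4)
        assert B.midscope_block(rng.random((64, 64, 3), dtype=np.float32), 17).shape == (64, 64, 17)
        assert B.widescope_block(rng.random((32, 32, 8), dtype=np.float32), 8).shape == (32, 32, 8)
        assert B.separated_block(rng.random((16, 16, 2), dtype=np.float32), 4, 3).shape == (16, 16, 4)
        assert B.duck_block(rng.random((88, 88, 34), dtype=np.float32), 34).shape == (88, 88, 34)
        assert B.simple_conv_block(x, 8).shape == (64, 64, 8)

    def test_strided_downsample_shapes(self):
        assert B.strided_downsample(rng.random((352, 352, 3), dtype=np.float32), 5).shape == (176, 176, 5)
        assert B.strided_downsample(rng.random((22, 22, 4), dtype=np.float32), 8).shape == (11, 11, 8)

    def test_strided_downsample_rejects_odd(self):
        with pytest.raises(ValueError, match="even spatial"):
            B.strided_downsample(rng.random((11, 11, 4), dtype=np.float32), 8)

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_invalid_filters_rejected(self, kind):
        with pytest.raises(ValueError):
            build(kind, 3, 0)

    def test_invalid_repeats_and_length(self):
        with pytest.raises(ValueError):
            B.BlockSpec("residual", 4, residual_repeats=4)
        with pytest.raises(ValueError):
            B.BlockSpec("separated", 4, separated_length=4)
        with pytest.raises(ValueError):
            B.SeparatedBlock(3, 4, n=6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            B.residual_block(np.zeros((0, 4, 3), np.float32), 4)


class TestReceptiveFields:
    """The 'simulated kernel size' claims, via the gradient-footprint oracle."""

    @pytest.mark.parametrize("repeats,expected", [(1, 5), (2, 9), (3, 13)])
    def test_residual_chain(self, repeats, expected):
        spec = B.BlockSpec("residual", 4, residual_repeats=repeats)
        assert B.measure_receptive_field(spec, probe_size=31) == (expected, expected)

    def test_midscope(self):
        assert B.measure_receptive_field(B.BlockSpec("midscope", 4), 31) == (7, 7)

    def test_widescope(self):
        assert B.measure_receptive_field(B.BlockSpec("widescope", 4), 41) == (15, 15)

    @pytest.mark.parametrize("n", [3, 7, 13])
    def test_separated(self, n):
        spec = B.BlockSpec("separated", 4, separated_length=n)
        assert B.measure_receptive_field(spec, 41) == (n, n)

    def test_simple_conv(self):
        assert B.measure_receptive_field(B.BlockSpec("simple_conv", 4), 21) == (5, 5)

    def test_duck_is_max_of_branches(self):
        assert B.measure_receptive_field(B.BlockSpec("duck", 4), 41) == (15, 15)

    def test_single_conv_footprint_is_kernel(self):
        from ducknet.nn import Conv2d
        assert B.measure_receptive_field(Conv2d(1, 1, 3), 11) == (3, 3)

    def test_probe_saturation_reported(self):
        with pytest.raises(B.ProbeTooSmallError):
            B.measure_receptive_field(B.BlockSpec("widescope", 4), probe_size=15)


class TestTranslationEquivariance:
    RADII = {"residual": 2, "midscope": 3, "widescope": 7, "separated": 6,
             "duck": 7, "simple_conv": 2}

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_interior_shift_match(self, kind):
        block = build(kind, 2, 4).eval()
        big = rng.random((1, 20, 20, 2), dtype=np.float32)
        out_a = block(Tensor(big[:, 0:16, 0:16])).data
        out_b = block(Tensor(big[:, 1:17, 1:17])).data
        m = self.RADII[kind]
        inner_b = out_b[:, m:15 - m, m:15 - m]
        inner_a = out_a[:, m + 1:16 - m, m + 1:16 - m]
        assert np.allclose(inner_a, inner_b, atol=1e-5)


class TestDuckStructure:
    def test_six_branches(self):
        assert B.DuckBlock.N_BRANCHES == 6
        block = B.DuckBlock(3, 4, rng=np.random.default_rng(0))
        x = Tensor(rng.random((1, 12, 12, 3), dtype=np.float32))
        assert len(block.branch_outputs(x)) == 6

    def test_output_is_branch_sum_without_norm(self):
        block = B.DuckBlock(3, 4, norm=False, rng=np.random.default_rng(0)).eval()
        x = Tensor(rng.random((1, 12, 12, 3), dtype=np.float32))
        manual = sum(o.data for o in block.branch_outputs(x))
        assert np.allclose(block(x).data, manual, atol=1e-6)


class TestParameterCounts:
    def count_convs(self, module):
        return sum(p.data.size for name, p in module.named_parameters())

    def test_midscope_cheaper_than_dense_7x7(self):
        block = B.MidscopeBlock(8, 8, rng=np.random.default_rng(0))
        dense = 7 * 7 * 8 * 8 + 8
        assert self.count_convs(block) < dense

    def test_widescope_cheaper_than_dense_15x15(self):
        block = B.WidescopeBlock(8, 8, rng=np.random.default_rng(0))
        dense = 15 * 15 * 8 * 8 + 8
        assert self.count_convs(block) < dense

    def test_separated_cheaper_than_dense_nxn(self):
        n = 13
        block = B.SeparatedBlock(8, 8, n, rng=np.random.default_rng(0))
        dense = n * n * 8 * 8 + 8
        assert self.count_convs(block) < dense


class TestSeparatedDiagonality:
    def test_rank1_cannot_fit_diagonal_kernel(self):
        """Least-squares fit of (1x3)(3x1) pairs to a diagonal 3x3 kernel.

        A separable pair realizes exactly the outer products u v^T; the best
        Frobenius fit to a kernel K is its rank-1 SVD truncation.  For the
        diagonal kernel the residual is strictly positive, while for any
        outer-product kernel it is zero.
        """
        diag = np.eye(3)
        u_, s, v_ = np.linalg.svd(diag)
        residual = np.sqrt((s[1:] ** 2).sum())
        assert residual > 0.5

        separable = np.outer([1.0, 2.0, -1.0], [0.5, 1.0, 0.25])
        _, s2, _ = np.linalg.svd(separable)
        assert np.sqrt((s2[1:] ** 2).sum()) < 1e-12

    def test_brute_force_fit_agrees_with_svd_bound(self):
        from scipy.optimize import minimize

        diag = np.eye(3)

        def objective(p):
            return ((np.outer(p[:3], p[3:]) - diag) ** 2).sum()

        best = np.inf
        for seed in range(8):
            r = np.random.default_rng(seed)
            res = minimize(objective, r.standard_normal(6), method="BFGS")
            best = min(best, res.fun)
        _, s, _ = np.linalg.svd(diag)
        assert best == pytest.approx((s[1:] ** 2).sum(), abs=1e-6)
        assert best > 0.5
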