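"""Volterra processors: coefficient-domain evaluation vs direct quadrature."""

import numpy as np
import pytest

from divnorm.spaces import Kernel1, Kernel2, Signal, eval_signal, make_space
from divnorm.volterra import MVP, VolterraProcessor, make_lowrank_kernel2, mvp_apply, vp_apply

from conftest import unit_kernel1
from test_spaces import random_real_signal


def quadrature_vp_oracle(T, u, t_points, n=2048):
    """Brute-force evaluation of b + int h1(s)u(t-s)ds + iint h2(s1,s2)u(t-s1)u(t-s2)."""
    space = T.space_in
    s_grid = space.grid(n)
    ds = space.S / n
    out = []
    for t in t_points:
        acc = T.b
        u_shift = eval_signal(u, t - s_grid)
        if T.h1 is not None:
            h1_vals = eval_signal(Kernel1(space, T.h1.coeffs), s_grid)
            acc += np.sum(h1_vals * u_shift) * ds
        if T.h2 is not None:
            E = space.basis_matrix(s_grid)
            h2_vals = np.real(E @ T.h2.tensor @ E.T)  # h2(s1, s2) on grid x grid
            acc += u_shift @ h2_vals @ u_shift * ds * ds
        out.append(acc)
    return np.array(out)


class TestVPApply:
    def test_constant_processor(self, space5):
        T = VolterraProcessor(b=3.25, space_in=space5)
        u = random_real_signal(space5, seed=0)
        grid = space5.grid(64)
        assert np.all(vp_apply(T, u, grid) == 3.25)

    def test_rank1_second_order_equals_squared_convolution(self):
        s = make_space(4, 40 * np.pi)
        g = unit_kernel1(s, 5)
        T2 = VolterraProcessor(b=0.0, h2=make_lowrank_kernel2([1.0], [g]), space_in=s)
        T1 = VolterraProcessor(b=0.0, h1=g, space_in=s)
        u = random_real_signal(s, seed=7)
        grid = s.grid(128)
        quad = vp_apply(T2, u, grid)
        lin = vp_apply(T1, u, grid)
        assert np.max(np.abs(quad - lin**2)) < 1e-10

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_quadrature_oracle(self, seed):
        s = make_space(4, 40 * np.pi)
        rng = np.random.default_rng(seed)
        T = VolterraProcessor(
            b=float(rng.standard_normal()),
            h1=Kernel1(s, 1.3 * unit_kernel1(s, seed + 100).coeffs),
            h2=make_lowrank_kernel2([0.7, -0.4], _ortho_pair(s, seed)),
            space_in=s,
        )
        u = random_real_signal(s, seed=seed + 50, sigma=0.8)
        t_pts = rng.uniform(0, s.S, 5)
        fast = vp_apply(T, u, t_pts)
        slow = quadrature_vp_oracle(T, u, t_pts)
        assert np.max(np.abs(fast - slow)) <= 1e-6 * max(1.0, np.max(np.abs(slow)))

    def test_first_order_linearity(self):
        s = make_space(3, 30 * np.pi)
        T = VolterraProcessor(b=0.0, h1=unit_kernel1(s, 1), space_in=s)
        u1 = random_real_signal(s, seed=2)
        u2 = random_real_signal(s, seed=3)
        grid = s.grid(64)
        lhs = vp_apply(T, Signal(s, 2.0 * u1.coeffs + u2.coeffs), grid)
        rhs = 2.0 * vp_apply(T, u1, grid) + vp_apply(T, u2, grid)
        assert np.max(np.abs(lhs - rhs)) < 1e-10

    def test_second_order_quadratic_scaling(self):
        s = make_space(3, 30 * np.pi)
        T = VolterraProcessor(b=0.7, h2=make_lowrank_kernel2([0.5], [unit_kernel1(s, 4)]), space_in=s)
        u = random_real_signal(s, seed=6)
        grid = s.grid(64)
        base = vp_apply(T, u, grid) - 0.7
        scaled = vp_apply(T, Signal(s, 2.0 * u.coeffs), grid) - 0.7
        assert np.max(np.abs(scaled - 4.0 * base)) < 1e-9

    def test_space_mismatch_raises(self, space5):
        other = make_space(3, 30 * np.pi)
        T = VolterraProcessor(b=0.0, h1=unit_kernel1(space5, 1), space_in=space5)
        with pytest.raises(ValueError):
            vp_apply(T, random_real_signal(other, seed=0), space5.grid(16))


def _ortho_pair(space, seed):
    g1 = unit_kernel1(space, seed + 200).coeffs
    g2 = unit_kernel1(space, seed + 300).coeffs
    g2 = g2 - (g1.conj() @ g2) * g1
    g2 /= np.linalg.norm(g2)
    return [Kernel1(space, g1), Kernel1(space, g2)]


class TestMVP:
    def test_all_kernels_absent(self):
        s = make_space(3, 30 * np.pi)
        M = MVP(N=2, b4=1.5, space=s)
        v = [random_real_signal(s, seed=i) for i in range(2)]
        assert np.all(mvp_apply(M, v, s.grid(32)) == 1.5)

    def test_single_channel_reduces_to_vp(self):
        s = make_space(3, 30 * np.pi)
        h1 = unit_kernel1(s, 8)
        h2 = make_lowrank_kernel2([0.6], [unit_kernel1(s, 9)])
        M = MVP(N=1, b4=0.2, h1_list=[h1], h2_grid=[[h2]], space=s)
        T = VolterraProcessor(b=0.2, h1=h1, h2=h2, space_in=s)
        u = random_real_signal(s, seed=10)
        grid = s.grid(64)
        assert np.max(np.abs(mvp_apply(M, [u], grid) - vp_apply(T, u, grid))) < 1e-12

    def test_constant_inputs_match_quadrature_oracle(self):
        """With unit-constant inputs the MVP output is b4 + sum int h1 + sum iint h2."""
        from divnorm.examples import example3_model

        model = example3_model()
        s = model.space_out
        mvp = model.mvp
        const = np.zeros(s.dim, dtype=complex)
        const[s.L] = np.sqrt(s.S)  # constant 1
        v = [Signal(s, const.copy()) for _ in range(4)]
        got = mvp_apply(mvp, v, np.array([0.123]))[0]
        # oracle: trapezoid integrals of the kernels themselves
        n = 2048
        g = s.grid(n)
        ds = s.S / n
        expect = mvp.b4
        for k in mvp.h1_list:
            expect += np.sum(eval_signal(Signal(s, k.coeffs), g)) * ds
        E = s.basis_matrix(g)
        for row in mvp.h2_grid:
            for k in row:
                vals = np.real(E @ k.tensor @ E.T)
                expect += np.sum(vals) * ds * ds
        assert got == pytest.approx(expect, rel=1e-6)

    def test_wrong_channel_count(self):
        s = make_space(2, 20 * np.pi)
        M = MVP(N=3, b4=0.0, space=s)
        with pytest.raises(ValueError):
            mvp_apply(M, [random_real_signal(s, seed=0)], s.grid(16))


class TestLowRankConstructor:
    def test_single_component_rank1(self):
        s = make_space(4, 40 * np.pi)
        k = make_lowrank_kernel2([1.0], [unit_kernel1(s, 3)])
        assert k.numerical_rank(1e-10) == 1

    def test_empty_weights_zero_kernel(self):
        s = make_space(3, 30 * np.pi)
        k = make_lowrank_kernel2([], [], space=s)
        assert np.all(k.coeffs == 0)

    def test_singular_values_equal_weights(self):
        s = make_space(4, 40 * np.pi)
        k = make_lowrank_kernel2([2.0, 1.0], _ortho_pair(s, 0))
        sv = k.singular_values()
        assert sv[0] == pytest.approx(2.0, abs=1e-9)
        assert sv[1] == pytest.approx(1.0, abs=1e-9)
        assert sv[2] < 1e-10

    def test_rejects_nonorthogonal_or_unnormalized(self):
        s = make_space(3, 30 * np.pi)
        g = unit_kernel1(s, 1)
        with pytest.raises(ValueError, match="orthogonal"):
            make_lowrank_kernel2([1.0, 1.0], [g, g])
        with pytest.raises(ValueError, match="unit norm"):
            make_lowrank_kernel2([1.0], [Kernel1(s, 2.0 * g.coeffs)])

    def test_symmetric_and_real(self):
        s = make_space(4, 40 * np.pi)
        k = make_lowrank_kernel2([0.5, -0.2], _ortho_pair(s, 7))
        rng = np.random.default_rng(0)
        t1, t2 = rng.uniform(0, s.S, 2)
        assert np.imag(k(t1, t2)) == pytest.approx(0.0, abs=1e-10)
        assert np.real(k(t1, t2)) == pytest.approx(np.real(k(t2, t1)), abs=1e-10)
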