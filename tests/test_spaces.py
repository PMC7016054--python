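"""Trigonometric-polynomial space algebra: bases, projections, shifts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from divnorm.spaces import (
    Kernel1,
    Signal,
    eval_signal,
    make_space,
    project1,
    project2,
    reversed_shift_coeffs,
    signal_from_samples,
)


def random_real_signal(space, seed=0, sigma=1.0):
    rng = np.random.default_rng(seed)
    L, d = space.L, space.dim
    c = np.zeros(d, dtype=complex)
    c[L] = sigma * rng.standard_normal()
    c[L + 1 :] = sigma * (rng.standard_normal(L) + 1j * rng.standard_normal(L)) / np.sqrt(2)
    c[:L] = np.conj(c[L + 1 :][::-1])
    return Signal(space, c)


class TestMakeSpace:
    @pytest.mark.parametrize(
        "L, Omega, S, dim",
        [
            (10, 100 * np.pi, 0.2, 21),
            (8, 40 * np.pi, 0.4, 17),
        ],
    )
    def test_period_and_dimension(self, L, Omega, S, dim):
        s = make_space(L, Omega)
        assert s.S == pytest.approx(S, rel=1e-12)
        assert s.dim == dim

    def test_constant_only_space(self):
        s = make_space(0, 1.0, S_override=1.0)
        assert s.dim == 1
        sig = Signal(s, [np.sqrt(s.S)])
        assert eval_signal(sig, 0.37) == pytest.approx(1.0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_space(-1, 1.0)
        with pytest.raises(ValueError):
            make_space(3, -2.0)
        with pytest.raises(ValueError):
            make_space(0, 1.0)  # missing period
        with pytest.raises(ValueError):
            make_space(3, 1.0, S_override=2.0)  # override only for L=0

    def test_basis_orthonormal(self):
        s = make_space(4, 20 * np.pi)
        n = 1024
        E = s.basis_matrix(s.grid(n))
        gram = E.conj().T @ E * (s.S / n)
        assert np.max(np.abs(gram - np.eye(s.dim))) < 1e-10


class TestEvalSignal:
    def test_zero_and_constant(self):
        s = make_space(3, 30 * np.pi)
        assert eval_signal(Signal(s, np.zeros(7)), 0.01) == 0.0
        c = np.zeros(7, dtype=complex)
        c[3] = np.sqrt(s.S)
        assert eval_signal(Signal(s, c), 0.013) == pytest.approx(1.0, abs=1e-12)

    def test_matches_termwise_summation_oracle(self):
        s = make_space(5, 50 * np.pi)
        sig = random_real_signal(s, seed=3)
        t = 0.0734
        # independent term-by-term sum of a_l exp(i l w0 t)/sqrt(S)
        acc = 0.0 + 0.0j
        for idx, a in enumerate(sig.coeffs):
            l = idx - s.L
            acc += a * np.exp(1j * l * (2 * np.pi / s.S) * t) / np.sqrt(s.S)
        assert eval_signal(sig, t) == pytest.approx(acc.real, abs=1e-12)
        assert abs(acc.imag) < 1e-12

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(-0.5, 0.5), st.integers(0, 10_000))
    def test_periodic_extension(self, t, seed):
        s = make_space(4, 40 * np.pi)
        sig = random_real_signal(s, seed=seed)
        assert eval_signal(sig, t) == pytest.approx(eval_signal(sig, t + s.S), abs=1e-9)

    def test_real_signal_conjugate_symmetry(self):
        s = make_space(6, 60 * np.pi)
        sig = random_real_signal(s, seed=9)
        assert sig.is_real
        vals = eval_signal(sig, s.grid(64))
        assert np.isrealobj(vals)


class TestProjection:
    def test_idempotent_on_space_members(self):
        s = make_space(5, 50 * np.pi)
        for seed in range(5):
            sig = random_real_signal(s, seed=seed)
            proj = project1(lambda t, sig=sig: eval_signal(sig, t), s)
            assert np.max(np.abs(proj.coeffs - sig.coeffs)) < 1e-10

    def test_zero_function(self):
        s = make_space(3, 30 * np.pi)
        proj = project1(lambda t: np.zeros_like(np.asarray(t)), s)
        assert np.all(proj.coeffs == 0)

    def test_matches_quadrature_oracle(self):
        """Photoreceptor-style gamma-cosine kernel vs explicit trapezoid."""
        s = make_space(10, 100 * np.pi)

        def h(t):
            t = np.asarray(t, dtype=float)
            return 2.472e10 * t**3 * np.exp(-100 * np.pi * t) * np.cos(36 * np.pi * t)

        proj = project1(h, s)
        # oracle: high-resolution trapezoid of f(t) conj(e_l(t)) on [0, S]
        n = 65536
        t = np.linspace(0.0, s.S, n + 1)
        f = h(t)
        for l in (-10, -3, 0, 4, 10):
            basis = np.exp(-1j * l * (2 * np.pi / s.S) * t) / np.sqrt(s.S)
            ref = np.trapezoid(f * basis, t)
            got = proj.coeffs[l + s.L]
            assert abs(got - ref) <= 1e-6 * max(1.0, abs(ref))

    def test_aliasing_guard(self):
        s = make_space(8, 80 * np.pi)
        with pytest.raises(ValueError, match="aliasing"):
            project1(np.zeros(32), s)

    def test_project2_separable_rank1(self):
        s = make_space(3, 30 * np.pi)
        g = random_real_signal(s, seed=5)
        k2 = project2(lambda t1, t2: eval_signal(g, t1) * eval_signal(g, t2), s, n_quad=256)
        expect = np.outer(g.coeffs, g.coeffs)[:, ::-1]
        assert np.max(np.abs(k2.coeffs - expect)) < 1e-8
        assert k2.numerical_rank(1e-8) == 1

    def test_project2_zero(self):
        s = make_space(2, 20 * np.pi)
        k2 = project2(lambda t1, t2: np.zeros(np.broadcast(t1, t2).shape), s, n_quad=128)
        assert np.all(k2.coeffs == 0)

    def test_project2_rank2_sum_of_separable(self):
        """A sum of two separable gamma-cosine products projects to rank <= 2."""
        s = make_space(5, 100 * np.pi)
        a = 100 * np.pi

        def f(t1, t2):
            e1 = t1**3 * np.exp(-a * t1) * np.cos(52 * np.pi * t1) * t2**3 * np.exp(-a * t2) * np.cos(52 * np.pi * t2)
            e2 = t1**3 * np.exp(-a * t1) * np.cos(100 * np.pi * t1) * t2**3 * np.exp(-a * t2) * np.cos(100 * np.pi * t2)
            return 9.0e19 * e1 + 5.3e14 * e2

        k2 = project2(f, s, n_quad=512)
        sv = k2.singular_values()
        assert sv[2] <= 1e-8 * sv[0]


class TestReversedShift:
    def test_constant_unchanged(self):
        s = make_space(0, 1.0, S_override=1.0)
        sig = Signal(s, [2.5])
        assert reversed_shift_coeffs(sig, 0.3)[0] == pytest.approx(2.5)

    def test_pure_basis_moves_to_negative_index(self):
        s = make_space(3, 30 * np.pi)
        c = np.zeros(7, dtype=complex)
        c[s.L + 2] = 1.0  # e_2
        out = reversed_shift_coeffs(Signal(s, c), 0.0)
        expect = np.zeros(7, dtype=complex)
        expect[s.L - 2] = 1.0  # e_{-2}
        assert np.max(np.abs(out - expect)) < 1e-12

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.floats(0.0, 0.19), st.integers(0, 1000))
    def test_pointwise_against_direct_evaluation(self, t_k, seed):
        s = make_space(4, 40 * np.pi)
        sig = random_real_signal(s, seed=seed)
        shifted = Signal(s, reversed_shift_coeffs(sig, t_k))
        for t in np.linspace(0, s.S, 100, endpoint=False):
            assert eval_signal(shifted, t) == pytest.approx(eval_signal(sig, t_k - t), abs=1e-10)


class TestHilbertSpaceInvariants:
    def test_reproducing_property(self):
        """<f, K1(.;t)> = f(t): the kernel of the orthonormal basis reproduces."""
        s = make_space(5, 50 * np.pi)
        rng = np.random.default_rng(1)
        for seed in range(5):
            f = random_real_signal(s, seed=seed)
            t = rng.uniform(0, s.S)
            # K1(.;t) has coefficients conj(e_l(t))
            k_coeffs = np.conj(s.basis_matrix(np.array([t]))[0])
            ip = np.vdot(k_coeffs, f.coeffs)  # <f, K(.;t)>
            assert ip.real == pytest.approx(eval_signal(f, t), abs=1e-9)
            assert abs(ip.imag) < 1e-9

    def test_parseval(self):
        s = make_space(6, 60 * np.pi)
        f = random_real_signal(s, seed=21)
        n = 4096
        vals = eval_signal(f, s.grid(n))
        l2 = np.sum(vals**2) * s.S / n
        assert l2 == pytest.approx(np.sum(np.abs(f.coeffs) ** 2), rel=1e-9)

    def test_projection_from_samples_roundtrip(self):
        s = make_space(4, 40 * np.pi)
        f = random_real_signal(s, seed=33)
        vals = eval_signal(f, s.grid(512))
        back = signal_from_samples(vals, s)
        assert np.max(np.abs(back - f.coeffs)) < 1e-10
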