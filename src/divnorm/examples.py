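"""Benchmark DNP fixtures and synthetic stimulus generation.

Two reference circuits are provided.  The *temporal* fixture is a
single-photoreceptor DNP whose six kernels are damped gamma-cosine
profiles (t^3 exp(-100 pi t) envelopes) with rank-2 second-order kernels;
it lives in the order-10, 100*pi rad/s space (period 0.2 s).  The
*spatio-temporal* fixture is a four-channel circuit with shared
feedforward filters and an amacrine-type MVP whose spatial profile decays
as a Gaussian in channel distance; it lives in the order-8, 40*pi rad/s
space (period 0.4 s) and all its second-order feedback kernels are rank
one and pairwise symmetric.

Stimuli are random elements of the input space with i.i.d. Gaussian basis
coefficients (conjugate-symmetric completion keeps them real-valued).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .measurement import TrialSet
from .spaces import Kernel1, Kernel2, Signal, TrigSpace, make_space, project1
from .volterra import MVP, VolterraProcessor, make_lowrank_kernel2
from .simulate import SpatioTemporalDNP, TemporalDNP, simulate_spatiotemporal, simulate_temporal

__all__ = [
    "example1_spaces",
    "example1_model",
    "example1_scaled_model",
    "example3_spaces",
    "example3_model",
    "random_stimuli",
    "simulate_trials",
    "gamma_cos",
]


def gamma_cos(amplitude: float, decay: float, freq: float, power: int = 3):
    """t^power * exp(-decay*t) * cos(freq*t) profile, the photoreceptor-style
    impulse response family used by both fixtures."""

    def f(t):
        t = np.asarray(t, dtype=float)
        return amplitude * t**power * np.exp(-decay * t) * np.cos(freq * t)

    return f


def _separable_kernel2(space: TrigSpace, terms, n_quad: int | None = None) -> Kernel2:
    """sum_k A_k f_k(t1) f_k(t2) projected onto the tensor space.

    Separability makes the projection a sum of coefficient outer products,
    which is both faster and better conditioned than a 2-D quadrature.
    """
    coeffs = np.zeros((space.dim, space.dim), dtype=complex)
    for amp, f in terms:
        p = project1(f, space, n_quad=n_quad).coeffs
        coeffs += amp * np.outer(p, p)[:, ::-1]
    return Kernel2(space, coeffs, symmetric=True)


def example1_spaces() -> tuple[TrigSpace, TrigSpace]:
    """Input and output spaces of the temporal benchmark (L = Lo = 10,
    Omega = Omegao = 100*pi, S = 0.2 s)."""
    s = make_space(10, 100.0 * np.pi)
    return s, s


def example1_model(spaces: tuple[TrigSpace, TrigSpace] | None = None) -> TemporalDNP:
    """The temporal benchmark DNP.

    Kernels (time in seconds):

    - h1_1 = 2.472e10 t^3 e^{-100 pi t} cos(36 pi t)
    - h1_2 = 3.117e8  t^3 e^{-100 pi t} cos(20 pi t)
    - h1_3 = 4.753e8  t^3 e^{-100 pi t} cos(52 pi t)
    - h2_1 = 9.038e19 [cos 52pi x cos 52pi] + 5.3467e14 [cos 100pi x cos 100pi]
    - h2_2 = 1.533e19 [cos 68pi x cos 68pi] + 5.970e14 [cos 84pi x cos 84pi]
    - h2_3 = 6.771e19 [cos 100pi x cos 100pi] + 5.970e16 [cos 84pi x cos 84pi]

    where [c1 x c2] abbreviates t1^3 t2^3 e^{-100 pi (t1+t2)} c1(t1) c2(t2);
    every second-order kernel is a sum of two separable terms, hence rank <= 2.
    The zeroth-order kernels, not part of the published set, default to
    b1 = 0 and the normalization split b2 = b3 = 0.5.
    """
    if spaces is None:
        spaces = example1_spaces()
    h_in, h_out = spaces
    a = 100.0 * np.pi
    h11 = project1(gamma_cos(2.472e10, a, 36 * np.pi), h_in)
    h12 = project1(gamma_cos(3.117e8, a, 20 * np.pi), h_in)
    h13 = project1(gamma_cos(4.753e8, a, 52 * np.pi), h_out)

    def env(freq):
        def f(t):
            t = np.asarray(t, dtype=float)
            return t**3 * np.exp(-a * t) * np.cos(freq * t)

        return f

    h21 = _separable_kernel2(h_in, [(9.038e19, env(52 * np.pi)), (5.3467e14, env(100 * np.pi))])
    h22 = _separable_kernel2(h_in, [(1.533e19, env(68 * np.pi)), (5.970e14, env(84 * np.pi))])
    h23 = _separable_kernel2(h_out, [(6.771e19, env(100 * np.pi)), (5.970e16, env(84 * np.pi))])

    T1 = VolterraProcessor(b=0.0, h1=h11, h2=h21, space_in=h_in)
    T2 = VolterraProcessor(b=0.5, h1=h12, h2=h22, space_in=h_in)
    T3 = VolterraProcessor(b=0.5, h1=h13, h2=h23, space_in=h_out)
    return TemporalDNP(T1, T2, T3, h_in, h_out)


def example3_spaces() -> tuple[TrigSpace, TrigSpace]:
    """Spaces of the spatio-temporal benchmark: Omega = Omegao = 40*pi with
    a 0.4 s period, i.e. order L = Lo = 8 and 17 coefficients per filter."""
    s = make_space(8, 40.0 * np.pi)
    return s, s


def example3_model(N: int = 4, spaces: tuple[TrigSpace, TrigSpace] | None = None) -> SpatioTemporalDNP:
    """The four-channel spatio-temporal benchmark DNP.

    - h1_1 = h1_2 = 25 t e^{-25 t} (shared across channels)
    - h1_i4 = exp(-(i-2)^2/4) (25 - 600 t) e^{-25 t}
    - h2_ij4 = 5000 exp(-(i-2)^2/4) exp(-(j-2)^2/4) (25 t1 e^{-25 t1})(25 t2 e^{-25 t2})

    All other Volterra kernels are zero; the normalization split is b2 = 1,
    b3 = b4 = 0.  Every h2_ij4 is a single separable product (rank 1) and
    h2_ij4 = h2_ji4, which the MVP records via ``symmetric_pairs``.
    """
    if spaces is None:
        spaces = example3_spaces()
    h_in, h_out = spaces

    def alpha(t):
        t = np.asarray(t, dtype=float)
        return 25.0 * t * np.exp(-25.0 * t)

    def beta(t):
        t = np.asarray(t, dtype=float)
        return (25.0 - 600.0 * t) * np.exp(-25.0 * t)

    w = [math.exp(-0.25 * (i - 2) ** 2) for i in range(1, N + 1)]
    h11 = project1(alpha, h_in)
    h12 = Kernel1(h_in, h11.coeffs.copy())

    h1_list = [Kernel1(h_out, wi * project1(beta, h_out).coeffs, label=f"h1_{i+1}4") for i, wi in enumerate(w)]
    p_alpha_o = project1(alpha, h_out).coeffs
    base = np.outer(p_alpha_o, p_alpha_o)[:, ::-1]
    h2_grid: list[list[Kernel2]] = [[None] * N for _ in range(N)]
    for i in range(N):
        for j in range(i, N):
            k = Kernel2(h_out, 5000.0 * w[i] * w[j] * base, symmetric=True, label=f"h2_{i+1}{j+1}4")
            h2_grid[i][j] = k
            h2_grid[j][i] = k

    T1 = VolterraProcessor(b=0.0, h1=h11, space_in=h_in)
    T2 = VolterraProcessor(b=1.0, h1=h12, space_in=h_in)
    T3 = VolterraProcessor(b=0.0, space_in=h_out)
    mvp = MVP(N=N, b4=0.0, h1_list=h1_list, h2_grid=h2_grid, symmetric_pairs=True, space=h_out)
    return SpatioTemporalDNP(N, T1, T2, T3, mvp, h_in, h_out)


def random_stimuli(
    space: TrigSpace,
    M: int,
    sigma: float = 1.0,
    seed: int | np.random.Generator = 0,
    label: str = "u",
) -> list[Signal]:
    """M real-valued random stimuli with i.i.d. Gaussian basis coefficients.

    Coefficients for l >= 1 are complex Gaussian with E|a_l|^2 = sigma^2
    (real and imaginary parts N(0, sigma^2/2)); a_0 is real N(0, sigma^2);
    negative harmonics follow by conjugate symmetry.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    L, d = space.L, space.dim
    for m in range(M):
        coeffs = np.zeros(d, dtype=complex)
        coeffs[L] = sigma * rng.standard_normal()
        if L > 0:
            re = rng.standard_normal(L) * (sigma / np.sqrt(2.0))
            im = rng.standard_normal(L) * (sigma / np.sqrt(2.0))
            coeffs[L + 1 :] = re + 1j * im
            coeffs[:L] = np.conj(coeffs[L + 1 :][::-1])
        out.append(Signal(space, coeffs, label=f"{label}{m}"))
    return out


def _unit_projection(f, space: TrigSpace) -> np.ndarray:
    c = project1(f, space).coeffs
    return c / np.linalg.norm(c)


def _ortho_pair_kernel2(space: TrigSpace, f1, f2, w1: float, w2: float) -> Kernel2:
    """Rank-2 kernel from two gamma-cosine profiles, Gram-Schmidt orthonormalized."""
    g1 = _unit_projection(f1, space)
    g2 = _unit_projection(f2, space)
    g2 = g2 - (g1.conj() @ g2) * g1
    g2 = g2 / np.linalg.norm(g2)
    return make_lowrank_kernel2([w1, w2], [Kernel1(space, g1), Kernel1(space, g2)])


def example1_scaled_model(L: int = 5, Omega: float = 100.0 * np.pi) -> TemporalDNP:
    """Reduced-order temporal benchmark with well-conditioned rank-2 kernels.

    Same gamma-cosine component profiles as the full temporal benchmark,
    but in an order-``L`` space (default period 0.1 s) and with balanced
    separable weights (second component ~0.3 of the first), so that both
    components of every second-order kernel carry identifiable energy.
    Kernel norms are O(1) and the normalization denominator keeps a wide
    positive margin for stimuli with coefficient scale ~0.3.
    """
    s = make_space(L, Omega)
    a = 100.0 * np.pi

    def env(freq):
        def f(t):
            t = np.asarray(t, dtype=float)
            return t**3 * np.exp(-a * t) * np.cos(freq * t)

        return f

    h11 = Kernel1(s, 1.5 * _unit_projection(env(36 * np.pi), s))
    h12 = Kernel1(s, 0.3 * _unit_projection(env(20 * np.pi), s))
    h13 = Kernel1(s, 0.2 * _unit_projection(env(52 * np.pi), s))
    h21 = _ortho_pair_kernel2(s, env(52 * np.pi), env(100 * np.pi), 0.8, 0.25)
    h22 = _ortho_pair_kernel2(s, env(68 * np.pi), env(84 * np.pi), 0.3, 0.1)
    h23 = _ortho_pair_kernel2(s, env(100 * np.pi), env(84 * np.pi), 0.2, 0.07)
    T1 = VolterraProcessor(b=0.0, h1=h11, h2=h21, space_in=s)
    T2 = VolterraProcessor(b=0.5, h1=h12, h2=h22, space_in=s)
    T3 = VolterraProcessor(b=0.5, h1=h13, h2=h23, space_in=s)
    return TemporalDNP(T1, T2, T3, s, s)


def simulate_trials(
    model: TemporalDNP | SpatioTemporalDNP,
    stimuli: list,
    T: int = 8,
    grid: int | None = None,
    tol: float = 1e-13,
    max_iter: int = 400,
    stagger_channels: bool = True,
) -> TrialSet:
    """Run the forward model on every stimulus and package a :class:`TrialSet`.

    Sample times are ``T`` uniform points per period; for multi-channel
    circuits they are staggered across channels by default
    (``t_k^(n) = (k + n/N) S/T``) so that the shared amacrine feedback is
    probed at N*T distinct times rather than T.  The dense grid is chosen
    as a multiple of the sample-time grid so that measurements are exact
    sample reads.
    """
    spatio = isinstance(model, SpatioTemporalDNP)
    N = model.N if spatio else 1
    S = model.space_in.S
    base = T * N if (spatio and stagger_channels) else T
    c = max(1, int(np.ceil(max(2048, 16 * model.space_in.dim) / base)))
    n_grid = base * c
    responses = []
    inputs = []
    for stim in stimuli:
        if spatio:
            res = simulate_spatiotemporal(model, stim, grid=n_grid, tol=tol, max_iter=max_iter)
            responses.append(res.v)
            inputs.append(list(stim))
        else:
            u = stim if isinstance(stim, Signal) else stim[0]
            res = simulate_temporal(model, u, grid=n_grid, tol=tol, max_iter=max_iter)
            responses.append(res.v[None, :])
            inputs.append([u])
    if spatio and stagger_channels:
        tk = np.array([[(k + n / N) * S / T for k in range(T)] for n in range(N)])
    else:
        tk = np.arange(T) * S / T
    return TrialSet(model.space_in, model.space_out, inputs, np.array(responses), model.space_in.grid(n_grid), tk)
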