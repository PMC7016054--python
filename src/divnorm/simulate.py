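"""Forward simulation of divisive normalization processors (DNPs).

The temporal DNP is the implicit feedback equation

    v = (T1 u) / (T2 u + T3 v),

where T1, T2 are feedforward Volterra processors on the input space and T3
is a feedback VP on the output space.  The spatio-temporal DNP adds the
multi-input amacrine block L4 acting on all channel outputs:

    v_n = (T1 u_n) / (T2 u_n + T3 v_n + L4 v).

The output of a divisive circuit is not band-limited, so trajectories are
represented as samples on a dense uniform grid over one period.  Before
entering the feedback paths the trajectory is orthogonally projected onto
the output space H1o: the feedback kernels live in H1o/H2o, so their
response to the projected output equals their response to the raw output,
while the projection keeps the feedback state finite-dimensional.

The implicit equation is solved on whole trajectories: damped Picard
iteration (the block-diagram semantics) warms up a Newton solve of the
residual map ``R(v) = v * den(v) - num``.  Because the feedback enters only
through the projected coefficients, the Newton Jacobian is diagonal plus a
rank-``2*N*(2Lo+1)`` correction and each step is solved exactly via the
Woodbury identity.  The returned residual is the worst-case violation of
``v * denominator - numerator`` over the grid, so convergence is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spaces import Signal, TrigSpace, signal_from_samples
from .volterra import MVP, VolterraProcessor, mvp_apply, vp_apply

__all__ = [
    "TemporalDNP",
    "SpatioTemporalDNP",
    "SimResult",
    "DenominatorDegeneracyError",
    "NoFixedPointError",
    "simulate_temporal",
    "simulate_spatiotemporal",
]

EPS_DEN_DEFAULT = 1e-9


class DenominatorDegeneracyError(ArithmeticError):
    """The normalization denominator approached zero on the grid."""


class NoFixedPointError(RuntimeError):
    """The trajectory solver did not converge: no stable fixed point found."""


def _check_b_sum(total: float, expect: str) -> None:
    if abs(total - 1.0) > 1e-12:
        raise ValueError(f"normalization requires {expect} = 1, got {total!r}")


@dataclass
class TemporalDNP:
    """Temporal DNP (T1, T2 on H1; T3 on H1o) with b2 + b3 = 1."""

    T1: VolterraProcessor
    T2: VolterraProcessor
    T3: VolterraProcessor
    space_in: TrigSpace
    space_out: TrigSpace

    def __post_init__(self) -> None:
        _check_b_sum(self.T2.b + self.T3.b, "b2 + b3")

    def scaled(self, alpha: float) -> "TemporalDNP":
        """Numerator and denominator jointly scaled; the output is invariant."""
        dnp = TemporalDNP.__new__(TemporalDNP)
        dnp.T1, dnp.T2, dnp.T3 = (T.scaled(alpha) for T in (self.T1, self.T2, self.T3))
        dnp.space_in, dnp.space_out = self.space_in, self.space_out
        return dnp


@dataclass
class SpatioTemporalDNP:
    """N-channel DNP with shared per-channel T1, T2, T3 and amacrine MVP.

    Normalization: b2 + b3 + b4 = 1.
    """

    N: int
    T1: VolterraProcessor
    T2: VolterraProcessor
    T3: VolterraProcessor
    mvp: MVP
    space_in: TrigSpace
    space_out: TrigSpace

    def __post_init__(self) -> None:
        if self.mvp.N != self.N:
            raise ValueError("MVP channel count does not match DNP")
        _check_b_sum(self.T2.b + self.T3.b + self.mvp.b4, "b2 + b3 + b4")

    def scaled(self, alpha: float) -> "SpatioTemporalDNP":
        dnp = SpatioTemporalDNP.__new__(SpatioTemporalDNP)
        dnp.N = self.N
        dnp.T1, dnp.T2, dnp.T3 = (T.scaled(alpha) for T in (self.T1, self.T2, self.T3))
        dnp.mvp = self.mvp.scaled(alpha)
        dnp.space_in, dnp.space_out = self.space_in, self.space_out
        return dnp


@dataclass
class SimResult:
    """Converged DNP trajectory with fixed-point diagnostics.

    ``v`` has shape (n_grid,) for temporal runs and (N, n_grid) for
    spatio-temporal ones; ``residual`` is ``max |v*den - num|`` over the grid.
    """

    v: np.ndarray
    grid: np.ndarray
    iterations: int
    residual: float
    converged: bool
    min_denominator: float

    def output_signal(self, space: TrigSpace, channel: int | None = None) -> Signal:
        """Orthogonal projection of the trajectory onto ``space``."""
        samples = self.v if self.v.ndim == 1 else self.v[channel if channel is not None else 0]
        return Signal(space, signal_from_samples(samples, space))


def _resolve_grid(space: TrigSpace, grid) -> np.ndarray:
    if grid is None:
        return space.grid(16 * space.dim)
    if np.isscalar(grid):
        return space.grid(int(grid))
    grid = np.asarray(grid, dtype=float)
    n = grid.size
    expect = space.grid(n)
    if not np.allclose(grid, expect, atol=1e-12 * space.S):
        raise ValueError("simulation grid must be uniform over [0, S) starting at 0")
    return grid


class _FeedbackMap:
    """Feedback denominators and their Jacobian for C coupled channels.

    State is v with shape (C, n).  The feedback term for channel c is
    G_c(p_1..p_C) with p_m the H1o-coefficients of channel m; this class
    evaluates G and the complex partials dG_c/dp_m needed for Newton steps.
    """

    def __init__(self, dnp, space_out: TrigSpace, grid: np.ndarray, C: int):
        self.space = space_out
        self.grid = grid
        self.C = C
        n = grid.size
        d = space_out.dim
        self.F = np.exp(1j * space_out.w0 * np.outer(grid, space_out.ells))  # phases
        self.E = self.F / np.sqrt(space_out.S)
        # projection matrix P: grid samples -> coefficients (d x n)
        self.P = (np.sqrt(space_out.S) / n) * np.conj(self.F.T)
        if isinstance(dnp, TemporalDNP):
            self.T3 = dnp.T3
            self.mvp = None
        else:
            self.T3 = dnp.T3
            self.mvp = dnp.mvp
        self.b_fb = self.T3.b + (self.mvp.b4 if self.mvp is not None else 0.0)

    def project(self, v: np.ndarray) -> list[np.ndarray]:
        return [signal_from_samples(v[c], self.space) for c in range(self.C)]

    def value(self, p: list[np.ndarray]) -> np.ndarray:
        """G_c stacked, shape (C, n); includes the constant b terms."""
        out = np.zeros((self.C, self.grid.size))
        for c in range(self.C):
            out[c] = self.T3.b if self.T3.is_constant else vp_apply(self.T3, p[c], self.grid)
        if self.mvp is not None:
            out += mvp_apply(self.mvp, p, self.grid)[None, :]
        return out

    def _vp_partial(self, T: VolterraProcessor, p: np.ndarray) -> np.ndarray:
        """d(T p)(grid)/dp as an (n x d) complex matrix."""
        n, d = self.grid.size, self.space.dim
        out = np.zeros((n, d), dtype=complex)
        if T.h1 is not None:
            out += self.E * (np.sqrt(self.space.S) * T.h1.coeffs)[None, :]
        if T.h2 is not None:
            c = T.h2.tensor
            out += self.F * ((self.F * p[None, :]) @ (c + c.T).T)
        return out

    def _pair_partial(self, cten: np.ndarray, pj: np.ndarray, side: str) -> np.ndarray:
        # bilinear(p_i, p_j) with tensor c: partial wrt p_i ('left') or p_j ('right')
        Zj = self.F * pj[None, :]
        mat = Zj @ (cten.T if side == "left" else cten)
        return self.F * mat

    def jacobian_blocks(self, p: list[np.ndarray]) -> np.ndarray:
        """U[c][m]: (n x d) complex partials dG_c/dp_m."""
        n, d = self.grid.size, self.space.dim
        U = np.zeros((self.C, self.C, n, d), dtype=complex)
        for c in range(self.C):
            if not self.T3.is_constant:
                U[c, c] += self._vp_partial(self.T3, p[c])
        if self.mvp is not None:
            mvp = self.mvp
            common = np.zeros((self.C, n, d), dtype=complex)
            for m in range(self.C):
                if mvp.h1_list and mvp.h1_list[m] is not None:
                    common[m] += self.E * (np.sqrt(self.space.S) * mvp.h1_list[m].coeffs)[None, :]
                if mvp.h2_grid:
                    for j in range(self.C):
                        if mvp.h2_grid[m][j] is not None:
                            common[m] += self._pair_partial(mvp.h2_grid[m][j].tensor, p[j], "left")
                        if mvp.h2_grid[j][m] is not None:
                            common[m] += self._pair_partial(mvp.h2_grid[j][m].tensor, p[j], "right")
            U += common[None, :, :, :]
        return U


def _solve_fixed_point(num, den_ff, fb: _FeedbackMap, tol, max_iter, eps_den, theta, strict, grid):
    """num, den_ff: (C, n).  Returns SimResult with v of shape (C, n)."""
    C, n = num.shape
    d = fb.space.dim

    def full_den(v):
        return den_ff + fb.value(fb.project(v))

    def resid_vec(v, den):
        return v * den - num

    den = den_ff + fb.b_fb
    _guard(den, eps_den)
    v = num / den
    best = np.inf
    it = 0
    # damped Picard warm-up
    while it < min(40, max_iter):
        it += 1
        den = full_den(v)
        _guard(den, eps_den)
        r = float(np.max(np.abs(resid_vec(v, den))))
        if r <= tol:
            return SimResult(v, grid, it, r, True, float(den.min()))
        if r > best:
            theta = max(theta * 0.5, 1.0 / 64)
        best = min(best, r)
        v = (1 - theta) * v + theta * num / den
        if r < 1e-2 * max(1.0, float(np.max(np.abs(num)))):
            break
    # Newton with Woodbury-structured Jacobian and backtracking
    while it < max_iter:
        it += 1
        p = fb.project(v)
        den = den_ff + fb.value(p)
        _guard(den, eps_den)
        R = resid_vec(v, den)
        r = float(np.max(np.abs(R)))
        if r <= tol:
            return SimResult(v, grid, it, r, True, float(den.min()))
        U4 = fb.jacobian_blocks(p)  # (C, C, n, d)
        # J = diag(den_flat) + Ur @ Wr  (real, rank 2*C*d)
        Ublocks = U4 * v[:, None, :, None]  # diag(v_c) dG_c/dp_m
        Ur = np.concatenate(
            [
                np.concatenate([Ublocks[c, m].real for m in range(C)], axis=1)
                for c in range(C)
            ],
            axis=0,
        )
        Ui = np.concatenate(
            [
                np.concatenate([Ublocks[c, m].imag for m in range(C)], axis=1)
                for c in range(C)
            ],
            axis=0,
        )
        Ur_full = np.concatenate([Ur, Ui], axis=1)  # (Cn, 2Cd)
        Pr = np.kron(np.eye(C), fb.P.real)
        Pi = np.kron(np.eye(C), fb.P.imag)
        Wr_full = np.concatenate([Pr, -Pi], axis=0)  # (2Cd, Cn)
        dflat = den.ravel()
        rflat = R.ravel()
        Dinv_r = rflat / dflat
        Dinv_U = Ur_full / dflat[:, None]
        K = np.eye(2 * C * d) + Wr_full @ Dinv_U
        step = Dinv_r - Dinv_U @ np.linalg.solve(K, Wr_full @ Dinv_r)
        step = step.reshape(C, n)
        alpha = 1.0
        for _ in range(30):
            v_try = v - alpha * step
            den_try = full_den(v_try)
            if np.min(den_try) > eps_den:
                r_try = float(np.max(np.abs(resid_vec(v_try, den_try))))
                if r_try < r:
                    v = v_try
                    break
            alpha *= 0.5
        else:
            break  # no progress possible
    den = full_den(v)
    r = float(np.max(np.abs(resid_vec(v, den))))
    if r <= tol:
        return SimResult(v, grid, it, r, True, float(den.min()))
    if strict:
        raise NoFixedPointError(
            f"no stable fixed point found after {it} iterations (residual {r:.3e} > tol {tol:.1e})"
        )
    return SimResult(v, grid, it, r, False, float(den.min()))


def simulate_temporal(
    dnp: TemporalDNP,
    u: Signal,
    grid=None,
    tol: float = 1e-12,
    max_iter: int = 500,
    eps_den: float = EPS_DEN_DEFAULT,
    theta: float = 1.0,
    strict: bool = True,
) -> SimResult:
    """Solve ``v = T1u / (T2u + T3 v)`` on a dense uniform grid.

    Starts from ``v0 = T1u / (T2u + b3)`` (feedback kernels off); damped
    Picard iterations are followed by exact Newton steps until the
    fixed-point residual ``max |v*den - num|`` falls below ``tol``.
    """
    g = _resolve_grid(dnp.space_in, grid)
    num = vp_apply(dnp.T1, u, g)[None, :]
    den_ff = vp_apply(dnp.T2, u, g)[None, :]
    fb = _FeedbackMap(dnp, dnp.space_out, g, C=1)
    res = _solve_fixed_point(num, den_ff, fb, tol, max_iter, eps_den, theta, strict, g)
    res.v = res.v[0]
    return res


def simulate_spatiotemporal(
    dnp: SpatioTemporalDNP,
    u: list[Signal],
    grid=None,
    tol: float = 1e-12,
    max_iter: int = 500,
    eps_den: float = EPS_DEN_DEFAULT,
    theta: float = 1.0,
    strict: bool = True,
) -> SimResult:
    """Joint trajectory solve for all channels of the spatio-temporal DNP."""
    if len(u) != dnp.N:
        raise ValueError(f"expected {dnp.N} input channels, got {len(u)}")
    g = _resolve_grid(dnp.space_in, grid)
    num = np.stack([vp_apply(dnp.T1, un, g) for un in u])
    den_ff = np.stack([vp_apply(dnp.T2, un, g) for un in u])
    fb = _FeedbackMap(dnp, dnp.space_out, g, C=dnp.N)
    return _solve_fixed_point(num, den_ff, fb, tol, max_iter, eps_den, theta, strict, g)


def _guard(den: np.ndarray, eps_den: float) -> None:
    if np.min(den) <= eps_den:
        raise DenominatorDegeneracyError(
            f"denominator degeneracy: min denominator {np.min(den):.3e} <= {eps_den:.1e}"
        )
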