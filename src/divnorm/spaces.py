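"""Trigonometric-polynomial reproducing-kernel Hilbert spaces.

Every object in this package lives in (or maps between) finite-dimensional
spaces of periodic band-limited functions

    u(t) = sum_{l=-L}^{L} a_l e_l(t),   e_l(t) = exp(i l w0 t) / sqrt(S),

with fundamental frequency ``w0 = Omega / L = 2*pi/S`` and period
``S = 2*pi*L/Omega``.  The basis ``{e_l}`` is orthonormal under the plain
L2[0, S] inner product ``<f, g> = int f conj(g) dt`` (conjugate-linear in the
second argument), so coefficient vectors carry the full Hilbert-space
geometry: inner products are coefficient dot products and the reproducing
kernel is ``K1(t; t') = sum_l e_l(t) conj(e_l(t'))``.

Second-order (bivariate) kernels live in the tensor square of such a space.
Their coefficient matrices are stored in the *reconstruction index map*
used throughout the identification stage: the entry at (row ``l1+L``,
column ``L-l2``) (0-based) multiplies ``e_{l1}(t1) e_{l2}(t2)``.  Under this
map a real-valued, exchange-symmetric kernel becomes a Hermitian matrix
whose rank equals the number of terms in its separable expansion -- the
property the sparse identification algorithm exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "TrigSpace",
    "Signal",
    "Kernel1",
    "Kernel2",
    "make_space",
    "eval_signal",
    "project1",
    "project2",
    "reversed_shift_coeffs",
    "signal_from_samples",
    "tensor_to_matrix",
    "matrix_to_tensor",
]

_CONJ_SYM_TOL = 1e-12


@dataclass(frozen=True)
class TrigSpace:
    """A trigonometric-polynomial space of order ``L`` and bandwidth ``Omega``.

    Parameters
    ----------
    L : int
        Order of the space; the highest harmonic retained.  ``dim = 2L+1``.
    Omega : float
        Bandwidth in rad/s.
    S : float
        Period in seconds, equal to ``2*pi*L/Omega`` except in the
        degenerate constant-only case ``L = 0`` where it must be supplied.
    """

    L: int
    Omega: float
    S: float

    @property
    def dim(self) -> int:
        return 2 * self.L + 1

    @property
    def w0(self) -> float:
        """Fundamental angular frequency 2*pi/S."""
        return 2.0 * np.pi / self.S

    @property
    def ells(self) -> np.ndarray:
        """Harmonic indices -L..L aligned with coefficient storage."""
        return np.arange(-self.L, self.L + 1)

    def basis_matrix(self, t: np.ndarray) -> np.ndarray:
        """E[g, j] = e_{j-L}(t_g); evaluation is ``E @ coeffs``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.exp(1j * self.w0 * np.outer(t, self.ells)) / np.sqrt(self.S)

    def grid(self, n: int) -> np.ndarray:
        """n uniform points on [0, S)."""
        return np.arange(n) * (self.S / n)

    def same_geometry(self, other: "TrigSpace") -> bool:
        return self.L == other.L and abs(self.S - other.S) <= 1e-12 * self.S


def make_space(L: int, Omega: float, S_override: float | None = None) -> TrigSpace:
    """Construct a trigonometric-polynomial space.

    ``S = 2*pi*L/Omega``; for the constant-only space ``L = 0`` the period
    carries no spectral meaning and must be supplied via ``S_override``.
    """
    if L < 0:
        raise ValueError(f"order L must be nonnegative, got {L}")
    if Omega <= 0:
        raise ValueError(f"bandwidth Omega must be positive, got {Omega}")
    if L == 0:
        if S_override is None:
            raise ValueError("L = 0 requires an explicit period S_override")
        if S_override <= 0:
            raise ValueError("period must be positive")
        return TrigSpace(L=0, Omega=Omega, S=float(S_override))
    if S_override is not None:
        raise ValueError("S_override is only allowed for L = 0")
    return TrigSpace(L=int(L), Omega=float(Omega), S=2.0 * np.pi * L / Omega)


def _check_conj_sym(coeffs: np.ndarray, tol: float = _CONJ_SYM_TOL) -> bool:
    return bool(np.max(np.abs(coeffs - np.conj(coeffs[::-1]))) <= tol * max(1.0, np.max(np.abs(coeffs))))


@dataclass
class Signal:
    """An element of a :class:`TrigSpace`, stored by basis coefficients.

    ``coeffs[j]`` multiplies ``e_{j-L}``.  Real-valued signals satisfy the
    conjugate symmetry ``a_{-l} = conj(a_l)``.
    """

    space: TrigSpace
    coeffs: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=complex)
        if self.coeffs.shape != (self.space.dim,):
            raise ValueError(
                f"coefficient vector has shape {self.coeffs.shape}, expected ({self.space.dim},)"
            )

    @property
    def is_real(self) -> bool:
        return _check_conj_sym(self.coeffs)

    def __call__(self, t):
        return eval_signal(self, t)

    def norm(self) -> float:
        return float(np.linalg.norm(self.coeffs))

    def inner(self, other: "Signal") -> complex:
        """L2[0,S] inner product, conjugate-linear in ``other``."""
        return complex(np.vdot(other.coeffs, self.coeffs))

    def copy(self) -> "Signal":
        return replace(self, coeffs=self.coeffs.copy())


class Kernel1(Signal):
    """A first-order Volterra kernel; same storage as :class:`Signal`."""


@dataclass
class Kernel2:
    """A second-order Volterra kernel in the tensor square of ``space``.

    ``coeffs`` is the (2L+1)x(2L+1) matrix in the reconstruction index map:
    ``coeffs[l1+L, L-l2]`` multiplies ``e_{l1}(t1) e_{l2}(t2)``.  For a
    real-valued kernel that is symmetric under ``(t1, t2)`` exchange this
    matrix is Hermitian and its eigendecomposition recovers the separable
    expansion ``h2 = sum_k lambda_k g_k(t1) g_k(t2)``.
    """

    space: TrigSpace
    coeffs: np.ndarray
    symmetric: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=complex)
        d = self.space.dim
        if self.coeffs.shape != (d, d):
            raise ValueError(f"coefficient matrix has shape {self.coeffs.shape}, expected ({d},{d})")

    @property
    def tensor(self) -> np.ndarray:
        """Natural tensor ``c[l1+L, l2+L]`` multiplying e_{l1}(t1)e_{l2}(t2)."""
        return self.coeffs[:, ::-1]

    def __call__(self, t1, t2):
        """Evaluate the bivariate kernel at (t1, t2) (broadcastable)."""
        t1 = np.asarray(t1, dtype=float)
        t2 = np.asarray(t2, dtype=float)
        E1 = self.space.basis_matrix(np.ravel(t1))
        E2 = self.space.basis_matrix(np.ravel(t2))
        vals = np.einsum("gi,ij,gj->g", E1, self.tensor, E2)
        return vals.reshape(np.broadcast(t1, t2).shape) if t1.shape else vals[0]

    def singular_values(self) -> np.ndarray:
        return np.linalg.svd(self.coeffs, compute_uv=False)

    def numerical_rank(self, rel_tol: float = 1e-6) -> int:
        s = self.singular_values()
        if s[0] == 0:
            return 0
        return int(np.sum(s > rel_tol * s[0]))

    def norm(self) -> float:
        return float(np.linalg.norm(self.coeffs))

    def copy(self) -> "Kernel2":
        return Kernel2(self.space, self.coeffs.copy(), self.symmetric, self.label)


def tensor_to_matrix(tensor: np.ndarray) -> np.ndarray:
    """Natural tensor c[l1+L, l2+L] -> reconstruction-map matrix."""
    return np.asarray(tensor)[:, ::-1]


def matrix_to_tensor(matrix: np.ndarray) -> np.ndarray:
    return np.asarray(matrix)[:, ::-1]


def eval_signal(sig: Signal, t) -> np.ndarray | float:
    """Evaluate ``sig`` at time(s) ``t`` (periodic extension).

    Returns a real array/scalar when the coefficients are conjugate
    symmetric, complex otherwise.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    vals = sig.space.basis_matrix(t_arr) @ sig.coeffs
    if _check_conj_sym(sig.coeffs, tol=1e-9):
        vals = vals.real
    if np.isscalar(t) or np.ndim(t) == 0:
        return vals[0]
    return vals.reshape(np.shape(t))


def signal_from_samples(samples: np.ndarray, space: TrigSpace) -> np.ndarray:
    """Coefficients of the orthogonal projection onto ``space`` from uniform samples.

    ``samples`` are values on ``space.grid(n)``.  For an S-periodic function
    the rectangle rule is the trapezoid rule and converges spectrally;
    ``a_l = sqrt(S)/n * DFT(samples)[l mod n]``.
    """
    samples = np.asarray(samples)
    n = samples.shape[-1]
    if n < 8 * space.dim:
        raise ValueError(
            f"grid too coarse for order {space.L}: {n} points < 8*dim = {8 * space.dim} (aliasing guard)"
        )
    spec = np.fft.fft(samples, axis=-1) * (np.sqrt(space.S) / n)
    idx = np.arange(-space.L, space.L + 1) % n
    return np.take(spec, idx, axis=-1)


def _sample_callable(f: Callable, space: TrigSpace, n: int) -> np.ndarray:
    return np.asarray([f(t) for t in space.grid(n)], dtype=float) if not _vectorized(f) else np.asarray(f(space.grid(n)), dtype=float)


def _vectorized(f: Callable) -> bool:
    try:
        out = f(np.asarray([0.0, 1e-9]))
        return np.shape(out) == (2,)
    except Exception:
        return False


def project1(f, space: TrigSpace, n_quad: int | None = None) -> Kernel1:
    """Orthogonal projection of an integrable function onto ``space``.

    ``f`` is either a callable on [0, S) or a vector of uniform samples.
    Quadrature is the periodic trapezoid rule on ``n_quad`` points (default
    ``max(4096, 32*dim)``); idempotent on space members.
    """
    if callable(f):
        n = n_quad or max(4096, 32 * space.dim)
        samples = _sample_callable(f, space, n)
    else:
        samples = np.asarray(f, dtype=float)
    return Kernel1(space, signal_from_samples(samples, space))


def project2(f, space: TrigSpace, n_quad: int | None = None, symmetric: bool = False) -> Kernel2:
    """Bivariate analogue of :func:`project1`.

    ``f`` is a callable ``f(t1, t2)`` (vectorized over broadcast arrays) or an
    ``n x n`` sample matrix on the uniform grid.  The natural coefficient
    tensor is the 2-D DFT; it is then stored in the reconstruction index map.
    """
    if callable(f):
        n = n_quad or max(1024, 32 * space.dim)
        g = space.grid(n)
        samples = np.asarray(f(g[:, None], g[None, :]), dtype=float)
    else:
        samples = np.asarray(f, dtype=float)
        n = samples.shape[0]
        if samples.shape != (n, n):
            raise ValueError("sample matrix must be square")
    n = samples.shape[0]
    if n < 8 * space.dim:
        raise ValueError(f"grid too coarse: {n} < 8*dim = {8 * space.dim} (aliasing guard)")
    spec = np.fft.fft2(samples) * (space.S / n**2)
    idx = np.arange(-space.L, space.L + 1) % n
    tensor = spec[np.ix_(idx, idx)]
    return Kernel2(space, tensor_to_matrix(tensor), symmetric=symmetric)


def reversed_shift_coeffs(sig: Signal, t_k: float) -> np.ndarray:
    """Coefficients of ``t -> sig(t_k - t)`` as an element of the same space.

    With ``u = sum a_l e_l`` one has ``u(t_k - t) = sum_l w_l e_l(t)`` where
    ``w_l = sqrt(S) * a_{-l} * e_{-l}(t_k)``.
    """
    space = sig.space
    a_rev = sig.coeffs[::-1]  # a_{-l} at slot l
    phases = np.exp(-1j * space.w0 * space.ells * t_k) / np.sqrt(space.S)
    return np.sqrt(space.S) * a_rev * phases
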