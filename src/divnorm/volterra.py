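"""First/second-order Volterra processors evaluated in the coefficient domain.

A Volterra processor (VP) maps a periodic input ``u`` to

    (T u)(t) = b + int_D h1(s) u(t-s) ds + int_{D^2} h2(s1,s2) u(t-s1) u(t-s2) ds1 ds2,

with all integrals over one period ``D = [0, S]`` and periodic (circular)
convolution semantics.  For ``u`` in a trigonometric-polynomial space the
first-order term has coefficients ``sqrt(S) * h_l * a_l``; the second-order
term contains harmonics up to twice the space bandwidth, so it is returned
as grid samples rather than silently band-limited.

The multi-input Volterra processor (MVP) is the amacrine-cell feedback
block: per-channel linear filters plus second-order filters on all ordered
pairs of channel outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spaces import Kernel1, Kernel2, Signal, TrigSpace

__all__ = ["VolterraProcessor", "MVP", "vp_apply", "mvp_apply", "make_lowrank_kernel2"]


@dataclass
class VolterraProcessor:
    """A (b, h1, h2) triple acting on signals in ``space_in``.

    Absent kernels (``None``) behave as exact zeros.
    """

    b: float = 0.0
    h1: Kernel1 | None = None
    h2: Kernel2 | None = None
    space_in: TrigSpace | None = None

    def __post_init__(self) -> None:
        if self.space_in is None:
            for k in (self.h1, self.h2):
                if k is not None:
                    self.space_in = k.space
                    break
        for k in (self.h1, self.h2):
            if k is not None and self.space_in is not None and not k.space.same_geometry(self.space_in):
                raise ValueError("kernel space does not match processor input space")

    @property
    def is_constant(self) -> bool:
        return self.h1 is None and self.h2 is None

    def scaled(self, alpha: float) -> "VolterraProcessor":
        """All kernels (including b) multiplied by ``alpha``."""
        return VolterraProcessor(
            b=alpha * self.b,
            h1=None if self.h1 is None else Kernel1(self.h1.space, alpha * self.h1.coeffs),
            h2=None if self.h2 is None else Kernel2(self.h2.space, alpha * self.h2.coeffs, self.h2.symmetric),
            space_in=self.space_in,
        )


def _first_order_grid(h1: Kernel1, coeffs: np.ndarray, E: np.ndarray) -> np.ndarray:
    # (h1 * u)(t) = sum_l sqrt(S) h_l a_l e_l(t)
    return (E @ (np.sqrt(h1.space.S) * h1.coeffs * coeffs)).real


def _second_order_grid(h2: Kernel2, coeffs: np.ndarray, F: np.ndarray) -> np.ndarray:
    # y(t) = sum_{l1,l2} c[l1,l2] a_{l1} a_{l2} exp(i(l1+l2) w0 t), with c the
    # natural tensor; F[g, j] = exp(i l_j w0 t_g) (unnormalized phases).
    Z = F * coeffs[None, :]
    return np.einsum("gi,ij,gj->g", Z, h2.tensor, Z).real


def _phase_matrix(space: TrigSpace, grid: np.ndarray) -> np.ndarray:
    return np.exp(1j * space.w0 * np.outer(grid, space.ells))


def vp_apply(T: VolterraProcessor, u: Signal | np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Evaluate ``(T u)`` on ``grid``.

    ``u`` may be a :class:`Signal` or a raw coefficient vector in
    ``T.space_in``.
    """
    grid = np.asarray(grid, dtype=float)
    if T.is_constant:
        return np.full(grid.shape, float(T.b))
    space = T.space_in
    coeffs = u.coeffs if isinstance(u, Signal) else np.asarray(u, dtype=complex)
    if isinstance(u, Signal) and not u.space.same_geometry(space):
        raise ValueError("input signal space does not match processor space")
    out = np.full(grid.shape, float(T.b))
    F = _phase_matrix(space, grid)
    E = F / np.sqrt(space.S)
    if T.h1 is not None:
        out = out + _first_order_grid(T.h1, coeffs, E)
    if T.h2 is not None:
        out = out + _second_order_grid(T.h2, coeffs, F)
    return out


@dataclass
class MVP:
    """Multi-input second-order Volterra block (amacrine-cell feedback).

    ``h1_list[i]`` filters channel ``i``; ``h2_grid[i][j]`` acts on the
    ordered pair ``(v_i, v_j)``.  When ``symmetric_pairs`` is set the (i, j)
    and (j, i) kernels are the same object.
    """

    N: int
    b4: float = 0.0
    h1_list: list = field(default_factory=list)
    h2_grid: list = field(default_factory=list)
    symmetric_pairs: bool = False
    space: TrigSpace | None = None

    def __post_init__(self) -> None:
        if self.h1_list and len(self.h1_list) != self.N:
            raise ValueError("h1_list must have N entries")
        if self.h2_grid and (len(self.h2_grid) != self.N or any(len(row) != self.N for row in self.h2_grid)):
            raise ValueError("h2_grid must be N x N")
        if self.space is None:
            for k in list(self.h1_list) + [k for row in self.h2_grid for k in row]:
                if k is not None:
                    self.space = k.space
                    break
        if self.symmetric_pairs:
            for i in range(self.N):
                for j in range(i + 1, self.N):
                    if self.h2_grid and self.h2_grid[i][j] is not self.h2_grid[j][i]:
                        raise ValueError("symmetric_pairs requires h2_grid[i][j] is h2_grid[j][i]")

    @property
    def is_zero(self) -> bool:
        return (
            self.b4 == 0.0
            and all(k is None for k in self.h1_list or [])
            and all(k is None for row in self.h2_grid or [] for k in row)
        )

    def scaled(self, alpha: float) -> "MVP":
        h1 = [None if k is None else Kernel1(k.space, alpha * k.coeffs) for k in self.h1_list] if self.h1_list else []
        h2 = []
        if self.h2_grid:
            cache: dict[int, Kernel2] = {}
            for row in self.h2_grid:
                new_row = []
                for k in row:
                    if k is None:
                        new_row.append(None)
                    else:
                        if id(k) not in cache:
                            cache[id(k)] = Kernel2(k.space, alpha * k.coeffs, k.symmetric)
                        new_row.append(cache[id(k)])
                h2.append(new_row)
        return MVP(self.N, alpha * self.b4, h1, h2, self.symmetric_pairs, self.space)


def mvp_apply(M: MVP, v: Sequence[Signal | np.ndarray], grid: np.ndarray) -> np.ndarray:
    """Evaluate the MVP output ``(L4 v)`` on ``grid`` for channel inputs ``v``."""
    if len(v) != M.N:
        raise ValueError(f"expected {M.N} channel inputs, got {len(v)}")
    grid = np.asarray(grid, dtype=float)
    out = np.full(grid.shape, float(M.b4))
    if M.is_zero:
        return out
    space = M.space
    coeffs = [vi.coeffs if isinstance(vi, Signal) else np.asarray(vi, dtype=complex) for vi in v]
    F = _phase_matrix(space, grid)
    E = F / np.sqrt(space.S)
    for i in range(M.N):
        if M.h1_list and M.h1_list[i] is not None:
            out = out + _first_order_grid(M.h1_list[i], coeffs[i], E)
    if M.h2_grid:
        Z = [F * c[None, :] for c in coeffs]
        for i in range(M.N):
            for j in range(M.N):
                k = M.h2_grid[i][j]
                if k is not None:
                    out = out + np.einsum("gi,ij,gj->g", Z[i], k.tensor, Z[j]).real
    return out


def make_lowrank_kernel2(
    weights: Sequence[float],
    components: Sequence[Kernel1],
    orth_tol: float = 1e-8,
    space: TrigSpace | None = None,
) -> Kernel2:
    """Assemble ``h2(t1,t2) = sum_k lambda_k g_k(t1) g_k(t2)`` from unit-norm,
    mutually orthogonal components.

    In the reconstruction index map the result is ``sum_k lambda_k p_k p_k^H``
    with ``p_k`` the coefficient vector of ``g_k`` (real components), so the
    matrix rank equals the number of nonzero weights.
    """
    if len(weights) != len(components):
        raise ValueError("weights and components must have equal length")
    if not components:
        if space is None:
            raise ValueError("empty component list requires an explicit space")
        return Kernel2(space, np.zeros((space.dim, space.dim), dtype=complex), symmetric=True)
    space = components[0].space
    mats = []
    for g in components:
        if not g.space.same_geometry(space):
            raise ValueError("components must share one space")
        if abs(g.norm() - 1.0) > 1e-6:
            raise ValueError(f"component '{g.label}' is not unit norm (|g| = {g.norm():.3e})")
    for a in range(len(components)):
        for b in range(a + 1, len(components)):
            ip = abs(components[a].inner(components[b]))
            if ip > orth_tol:
                raise ValueError(f"components {a} and {b} are not orthogonal (|<g,g>| = {ip:.3e})")
    coeffs = np.zeros((space.dim, space.dim), dtype=complex)
    for lam, g in zip(weights, components):
        p = g.coeffs
        # natural tensor lam * outer(p, p); columns reversed for storage
        coeffs += lam * np.outer(p, p)[:, ::-1]
    return Kernel2(space, coeffs, symmetric=True)
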