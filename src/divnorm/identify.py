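"""Sparse (low-rank) identification of DNP components.

The generalized-sampling system is underdetermined whenever fewer samples
are collected than the ``O(dim^2)`` unknown kernel coefficients.  Because
second-order Volterra kernels of sensory circuits are *sparse* -- their
separable expansions have few terms, so their coefficient matrices have
low rank -- the identification is posed as nuclear-norm minimization:

    minimize   ||C2||_* + lambda1 ||c1||^2 + lambda2 ||eps||_2
    subject to measurement equalities with slack eps, 1'eps = 0,
               structural zero blocks of C2, and Hermitian H2^1..3.

The zero blocks are imposed structurally (those variables are never
created), which also splits the nuclear norm into the two column blocks of
C2: the input-space stack [H2^1; H2^2] and the output-space stack
[H2^3; H2^114; ...; H2^NN4].  Real-valuedness of the kernels is likewise
built into the parametrization (conjugate-symmetric vectors, Hermitian or
centro-Hermitian matrices); directions violating it are invisible to the
measurements and would only inflate the objective.

The solver is ADMM with singular-value thresholding.  An optional *polish*
stage then refines the solution on the tight rank-r parametrization of
every block (its separable expansion) by trust-region Gauss-Newton,
growing the ranks greedily from one until the measurement equations are
satisfied; on consistent (noise-free) data this refines the first-order
solution to near machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .measurement import Layout, MeasurementSystem
from .spaces import Kernel1, Kernel2, TrigSpace

__all__ = [
    "IdentConfig",
    "IdentResult",
    "solve_temporal",
    "solve_spatiotemporal",
    "solve_system",
    "reconstruct_kernels",
    "assemble_c1_C2",
    "snr_db",
]


def snr_db(truth: np.ndarray, estimate: np.ndarray, cap: float = 300.0) -> float:
    """Recovery SNR: 10 log10(||truth||^2 / ||truth - estimate||^2), in dB.

    Capped at ``cap`` for (numerically) exact matches; raises on zero truth.
    """
    truth = np.asarray(truth)
    estimate = np.asarray(estimate)
    if truth.shape != estimate.shape:
        raise ValueError("shape mismatch")
    p = float(np.linalg.norm(truth) ** 2)
    if p == 0.0:
        raise ValueError("zero-norm truth has no SNR")
    err = float(np.linalg.norm(truth - estimate) ** 2)
    if err == 0.0:
        return cap
    return min(cap, 10.0 * np.log10(p / err))


@dataclass
class IdentConfig:
    """Hyperparameters of the identification solver.

    - ``lambda1``: ridge weight on the first-order coefficient vector c1.
    - ``lambda2``: weight of the slack norm; ``None`` uses 1e6 * max|q|,
      which on noise-free data makes the measurement equalities effectively
      hard (the slack prox returns exactly zero).  Lower it for noisy
      recordings.
    - ``rho``: ADMM penalty; adapted automatically within [rho/64, rho*64].
    - ``polish``: run the rank-constrained Gauss-Newton refinement.
    - ``rank_tol``: relative singular-value cutoff when *reporting* ranks.
    - ``polish_iters``: function-evaluation budget per Gauss-Newton solve.
    - ``max_rank_rounds``: extra polish rounds with all ranks incremented,
      used when the measurement residual reveals undershot ranks.
    """

    lambda1: float = 1e-3
    lambda2: float | None = None
    rho: float = 1.0
    max_iter: int = 3000
    eps_abs: float = 1e-9
    eps_rel: float = 1e-7
    polish: bool = True
    rank_tol: float = 1e-6
    polish_iters: int = 500
    polish_target: float = 1e-11
    max_rank_rounds: int = 2

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or (self.lambda2 is not None and self.lambda2 < 0):
            raise ValueError("lambda1, lambda2 must be nonnegative")


@dataclass
class IdentResult:
    """Solution of the identification problem.

    ``kernels`` maps block names (b1, h11, h12, h13, h14_i, H21, H22, H23,
    H24_i_j) to floats / :class:`Kernel1` / :class:`Kernel2`.  ``snr``
    holds per-kernel recovery SNRs when a ground-truth model was supplied.
    """

    layout: Layout
    theta: np.ndarray
    values: dict
    kernels: dict
    c1_hat: np.ndarray
    C2_hat: np.ndarray
    slack: np.ndarray
    ranks: dict
    constraint_report: dict
    measurement_residual: float
    admm_iterations: int
    admm_primal: float
    admm_dual: float
    polished: bool
    snr: dict = field(default_factory=dict)

    @property
    def mean_snr(self) -> float:
        return float(np.mean(list(self.snr.values()))) if self.snr else np.nan


# ---------------------------------------------------------------------------
# stacked low-rank structure


class _Stack:
    """Vertical stack of k2 blocks sharing a column space ('in' or 'out').

    Provides the sparse complex map theta -> vec(stack); tied feedback
    blocks contribute a second, conjugate-transposed copy so the stack is
    exactly the corresponding column block of the full unknown matrix C2.
    """

    def __init__(self, layout: Layout, side: str):
        self.side = side
        d = (layout.space_in if side == "in" else layout.space_out).dim
        self.d = d
        rows = []
        self.slices: dict[str, slice] = {}
        r0 = 0
        for b in layout.k2_blocks():
            if b.space != side:
                continue
            P = layout.pmat(b.name)
            Pfull = sp.lil_matrix((P.shape[0], layout.n_params), dtype=complex)
            Pfull[:, b.param_off : b.param_off + b.n_params] = P
            rows.append(sp.csr_matrix(Pfull))
            self.slices[b.name] = slice(r0, r0 + d)
            r0 += d
            if b.tied:
                # vec(H^H)[r*d+c] = conj(H[c*d+r])
                idx = np.arange(d * d).reshape(d, d).T.ravel()
                rows.append(sp.csr_matrix(np.conj(Pfull.toarray()[idx, :])))
                r0 += d
        self.n_rows = r0
        self.P = sp.vstack(rows, format="csr") if rows else None

    @property
    def empty(self) -> bool:
        return self.P is None

    def matrix(self, theta: np.ndarray) -> np.ndarray:
        return (self.P @ theta).reshape(self.n_rows, self.d)


def _svt(X: np.ndarray, tau: float) -> np.ndarray:
    U, s, Vh = np.linalg.svd(X, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    nz = s > 0
    return (U[:, nz] * s[nz]) @ Vh[nz]


# ---------------------------------------------------------------------------
# ADMM


def _admm(system: MeasurementSystem, cfg: IdentConfig):
    lay = system.layout
    G, q = system.G, system.q
    n_params = lay.n_params
    lam2 = cfg.lambda2 if cfg.lambda2 is not None else 1e6 * max(1.0, float(np.max(np.abs(q))))
    stacks = [s for s in (_Stack(lay, "in"), _Stack(lay, "out")) if not s.empty]

    dc = np.zeros(n_params)
    sl = lay.c1_param_slice()
    Pc = lay.param_matrix()[:, sl]
    dc[sl] = np.asarray(np.abs(Pc.multiply(Pc.conj())).sum(axis=0)).ravel().real
    dab = np.zeros(n_params)
    for s in stacks:
        dab += np.asarray(np.abs(s.P.multiply(s.P.conj())).sum(axis=0)).ravel().real

    GtG = G.T @ G
    rho = cfg.rho

    def factor(rho):
        M = rho * (GtG + np.diag(dab)) + np.diag(cfg.lambda1 * dc)
        M[np.diag_indices_from(M)] += 1e-12 * max(1.0, M.diagonal().max())
        return scipy.linalg.cho_factor(M, check_finite=False)

    cho = factor(rho)
    theta = np.zeros(n_params)
    Z = [np.zeros((s.n_rows, s.d), dtype=complex) for s in stacks]
    U = [np.zeros_like(z) for z in Z]
    eps = np.zeros_like(q)
    ug = np.zeros_like(q)
    q_scale = max(1.0, float(np.linalg.norm(q)))
    primal = dual = np.inf
    it = 0
    for it in range(1, cfg.max_iter + 1):
        rhs = rho * (G.T @ (q + eps - ug))
        for s, z, u in zip(stacks, Z, U):
            rhs += rho * np.real(s.P.conj().T @ (z - u).ravel())
        theta = scipy.linalg.cho_solve(cho, rhs, check_finite=False)

        primal = 0.0
        dual = 0.0
        Aths = []
        for i, s in enumerate(stacks):
            Ath = s.matrix(theta)
            Aths.append(Ath)
            Znew = _svt(Ath + U[i], 1.0 / rho)
            dual = max(dual, rho * float(np.linalg.norm(Znew - Z[i])))
            Z[i] = Znew
            U[i] = U[i] + Ath - Z[i]
            primal = max(primal, float(np.linalg.norm(Ath - Z[i])))
        w = G @ theta - q + ug
        w0 = w - w.mean()
        nw = float(np.linalg.norm(w0))
        eps_new = np.zeros_like(w0) if nw <= lam2 / rho else (1 - lam2 / (rho * nw)) * w0
        dual = max(dual, rho * float(np.linalg.norm(eps_new - eps)))
        eps = eps_new
        rg = G @ theta - q - eps
        ug = ug + rg
        primal = max(primal, float(np.linalg.norm(rg)))

        scale = max(q_scale, max(float(np.linalg.norm(z)) for z in Z) if Z else 1.0)
        if primal <= cfg.eps_abs + cfg.eps_rel * scale and dual <= cfg.eps_abs + cfg.eps_rel * scale:
            break
        if it % 50 == 0:
            if primal > 10 * dual and rho < cfg.rho * 64:
                rho *= 2.0
                U = [u / 2.0 for u in U]
                ug = ug / 2.0
                cho = factor(rho)
            elif dual > 10 * primal and rho > cfg.rho / 64:
                rho /= 2.0
                U = [u * 2.0 for u in U]
                ug = ug * 2.0
                cho = factor(rho)
    return theta, stacks, Z, eps, it, primal, dual


# ---------------------------------------------------------------------------
# polish: rank-truncated nonlinear least-squares refinement


def _project_structure(H: np.ndarray, structure: str) -> np.ndarray:
    """Orthogonal projection onto the structural subspace of a block.

    The measurement functionals see exactly the structured component of a
    coefficient matrix (exchange-antisymmetric and reality-violating parts
    contribute nothing to any real measurement), so this projection never
    changes the fit -- it only removes unidentifiable junk.
    """
    J = H[::-1, ::-1]
    if structure in ("hermsym", "hermitian"):
        # average over the commuting involutions H -> H^H and H -> J H^T J
        return 0.25 * (H + H.conj().T + J.T + np.conj(J))
    return 0.5 * (H + np.conj(J))  # centro-Hermitian: real kernel


def _conj_sym_phase(u: np.ndarray) -> np.ndarray:
    """Rotate a vector by a global phase so that u[::-1] = conj(u) (best fit)."""
    alpha = complex(u @ u[::-1])
    if abs(alpha) < 1e-30:
        return u
    return u * np.exp(-0.5j * np.angle(alpha))


class _RankParam:
    """Tight rank-r parametrization of one second-order block.

    hermsym: H = sum_k lam_k p_k p_k^H with conjugate-symmetric p_k and free
    real weights lam_k (r*(d+1) real parameters -- the symmetric separable
    expansion with signed weights).
    centro:  H = sum_k u_k v_k^H with conjugate-symmetric u_k, v_k
    (2*r*d real parameters -- a real, possibly asymmetric kernel).
    """

    def __init__(self, block, d: int, r: int, seed: np.ndarray, Pk1: sp.csr_matrix):
        self.name = block.name
        self.hermsym = block.structure in ("hermsym", "hermitian")
        self.d, self.r = d, r
        self.Pk1 = Pk1  # d real params -> conj-symmetric complex vector
        self.Pk1d = Pk1.toarray()
        seed = _project_structure(np.asarray(seed, dtype=complex), block.structure)
        if self.hermsym:
            w, V = np.linalg.eigh(seed)
            order = np.argsort(-np.abs(w))[:r]
            scale = np.sqrt(np.abs(w[order[0]]) + 1e-30)
            vecs = [_conj_sym_phase(V[:, j]) * scale for j in order]
            lams = np.array([w[j] for j in order]) / scale**2
            self.x0 = np.concatenate([np.concatenate([[lam], self._vec_to_params(v)]) for lam, v in zip(lams, vecs)])
        else:
            U, sv, Vh = np.linalg.svd(seed)
            floor = 1e-8 * (sv[0] + 1e-30)
            us = [_conj_sym_phase(U[:, j]) * np.sqrt(max(sv[j], floor)) for j in range(r)]
            vs = [_conj_sym_phase(Vh[j].conj()) * np.sqrt(max(sv[j], floor)) for j in range(r)]
            self.x0 = np.concatenate(
                [np.concatenate([self._vec_to_params(u), self._vec_to_params(v)]) for u, v in zip(us, vs)]
            )

    @property
    def n_params(self) -> int:
        return self.r * (self.d + 1) if self.hermsym else 2 * self.r * self.d

    def _vec_to_params(self, v: np.ndarray) -> np.ndarray:
        col2 = np.asarray(np.abs(self.Pk1.multiply(self.Pk1.conj())).sum(axis=0)).ravel().real
        return np.real(self.Pk1.conj().T @ v) / col2

    def components(self, x: np.ndarray):
        d = self.d
        if self.hermsym:
            out = []
            for k in range(self.r):
                off = k * (d + 1)
                out.append((float(x[off]), self.Pk1d @ x[off + 1 : off + 1 + d]))
            return out
        out = []
        for k in range(self.r):
            off = 2 * k * d
            out.append((self.Pk1d @ x[off : off + d], self.Pk1d @ x[off + d : off + 2 * d]))
        return out

    def matrix(self, x: np.ndarray) -> np.ndarray:
        H = np.zeros((self.d, self.d), dtype=complex)
        if self.hermsym:
            for lam, p in self.components(x):
                H += lam * np.outer(p, np.conj(p))
        else:
            for u, v in self.components(x):
                H += np.outer(u, np.conj(v))
        return H

    def contribution(self, x: np.ndarray, W3: np.ndarray) -> np.ndarray:
        out = np.zeros(W3.shape[0])
        if self.hermsym:
            for lam, p in self.components(x):
                out += lam * np.real(np.einsum("krc,r,c->k", W3, p, np.conj(p)))
        else:
            for u, v in self.components(x):
                out += np.real(np.einsum("krc,r,c->k", W3, u, np.conj(v)))
        return out

    def jacobian(self, x: np.ndarray, W3: np.ndarray) -> np.ndarray:
        cols = []
        if self.hermsym:
            for lam, p in self.components(x):
                Wp = np.einsum("krc,c->kr", W3, np.conj(p))
                cols.append(np.real(np.einsum("kr,r->k", Wp, p))[:, None])  # d/dlam
                B1 = Wp @ self.Pk1d
                B2 = np.einsum("krc,r->kc", W3, p) @ np.conj(self.Pk1d)
                cols.append(lam * np.real(B1 + B2))
        else:
            for u, v in self.components(x):
                cols.append(np.real(np.einsum("krc,c->kr", W3, np.conj(v)) @ self.Pk1d))
                cols.append(np.real(np.einsum("krc,r->kc", W3, u) @ np.conj(self.Pk1d)))
        return np.concatenate(cols, axis=1)


def _polish(system: MeasurementSystem, cfg: IdentConfig, values: dict, ranks: dict):
    """Rank-constrained refinement: nonlinear LS on the separable expansions.

    Unknowns are c1 plus the separable components of every second-order
    block at its assigned rank; a trust-region Gauss-Newton solve
    (scipy.optimize.least_squares with analytic Jacobian) drives the
    measurement residual to numerical zero on consistent data.  The tight
    parametrization keeps the degrees of freedom at O(r*d) per block, so
    the refinement stays overdetermined far below the dense sampling bound.
    """
    from scipy.optimize import least_squares
    from .measurement import _k1_param_matrix

    lay = system.layout
    G, W, q = system.G, system.W, system.q
    csl = lay.c1_param_slice()
    Gc = G[:, csl]
    k2 = lay.k2_blocks()
    W3 = {}
    blocks = []
    offs = [csl.stop]
    for b in k2:
        d = (lay.space_in if b.space == "in" else lay.space_out).dim
        W3[b.name] = W[:, b.entry_off : b.entry_off + b.n_entries].reshape(-1, d, d)
        rp = _RankParam(b, d, ranks[b.name], values[b.name], _k1_param_matrix(d))
        blocks.append((b, rp))
        offs.append(offs[-1] + rp.n_params)

    thc0 = lay.encode({b.name: values[b.name] for b in lay if b.kind != "k2"})[csl]
    x0 = np.concatenate([thc0] + [rp.x0 for _, rp in blocks])

    def fun(x):
        r = Gc @ x[: csl.stop] - q
        for (b, rp), o0, o1 in zip(blocks, offs[:-1], offs[1:]):
            r = r + rp.contribution(x[o0:o1], W3[b.name])
        return r

    def jac(x):
        out = [Gc]
        for (b, rp), o0, o1 in zip(blocks, offs[:-1], offs[1:]):
            out.append(rp.jacobian(x[o0:o1], W3[b.name]))
        return np.concatenate(out, axis=1)

    qn = max(1.0, float(np.linalg.norm(q)))
    sol = least_squares(
        fun,
        x0,
        jac=jac,
        method="trf",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=cfg.polish_iters,
    )
    resid = float(np.linalg.norm(sol.fun))
    out = {}
    c1_vals = lay.decode(np.concatenate([sol.x[: csl.stop], np.zeros(lay.n_params - csl.stop)]))
    for b in lay:
        if b.kind != "k2":
            out[b.name] = c1_vals[b.name]
    for (b, rp), o0, o1 in zip(blocks, offs[:-1], offs[1:]):
        out[b.name] = rp.matrix(sol.x[o0:o1])
    return out, resid


def _augment_seed(system: MeasurementSystem, values: dict) -> dict:
    """Greedy rank-continuation seed: add to every block a small component
    along the top eigen-direction of the structure-projected residual
    gradient (the steepest-descent rank-1 update of matrix pursuit)."""
    lay = system.layout
    theta = lay.encode(values)
    r = system.q - system.G @ theta
    out = dict(values)
    for b in lay.k2_blocks():
        d = (lay.space_in if b.space == "in" else lay.space_out).dim
        W3 = system.W[:, b.entry_off : b.entry_off + b.n_entries].reshape(-1, d, d)
        grad = _project_structure(np.einsum("k,krc->rc", r, np.conj(W3)), b.structure)
        H = np.asarray(values[b.name], dtype=complex)
        if b.structure in ("hermsym", "hermitian"):
            w, V = np.linalg.eigh(grad)
            j = int(np.argmax(np.abs(w)))
            direction = w[j] * np.outer(V[:, j], np.conj(V[:, j]))
        else:
            U, sv, Vh = np.linalg.svd(grad)
            direction = sv[0] * np.outer(U[:, 0], Vh[0])
        nd = np.linalg.norm(direction)
        if nd > 0:
            out[b.name] = H + 0.1 * max(np.linalg.norm(H), 1e-6) / nd * direction
    return out


# ---------------------------------------------------------------------------
# assembly / reconstruction


def assemble_c1_C2(values: dict, layout: Layout) -> tuple[np.ndarray, np.ndarray]:
    """Paper-layout (c1, C2) from per-block values; zero blocks included."""
    d, do = layout.space_in.dim, layout.space_out.dim
    N = layout.N
    c1 = [np.atleast_1d(np.asarray(values.get("b1", 0.0), dtype=complex))]
    names1 = ["h11", "h12", "h13"] + ([f"h14_{i + 1}" for i in range(N)] if layout.mode == "spatiotemporal" else [])
    for nm in names1:
        dim = d if nm in ("h11", "h12") else do
        c1.append(np.asarray(values.get(nm, np.zeros(dim)), dtype=complex))
    c1 = np.concatenate(c1)

    def blk(nm, dim):
        return np.asarray(values.get(nm, np.zeros((dim, dim))), dtype=complex)

    n2 = N * N if layout.mode == "spatiotemporal" else 0
    C2 = np.zeros((2 * d + (1 + n2) * do, d + do), dtype=complex)
    C2[:d, :d] = blk("H21", d)
    C2[d : 2 * d, :d] = blk("H22", d)
    C2[2 * d : 2 * d + do, d:] = blk("H23", do)
    r = 2 * d + do
    if layout.mode == "spatiotemporal":
        for i in range(N):
            for j in range(N):
                if layout.tie_symmetric and i > j:
                    H = blk(f"H24_{j + 1}_{i + 1}", do).conj().T
                else:
                    H = blk(f"H24_{i + 1}_{j + 1}", do)
                C2[r : r + do, d:] = H
                r += do
    return c1, C2


def reconstruct_kernels(
    c1_hat: np.ndarray,
    C2_hat: np.ndarray,
    layout: Layout,
    spaces: tuple[TrigSpace, TrigSpace] | None = None,
) -> dict:
    """Slice (c1, C2) into named kernels per the reconstruction theorems.

    Inverse of :func:`assemble_c1_C2`; wraps slices as :class:`Kernel1` /
    :class:`Kernel2` in the given (input, output) spaces.
    """
    s_in = spaces[0] if spaces else layout.space_in
    s_out = spaces[1] if spaces else layout.space_out
    d, do = s_in.dim, s_out.dim
    N = layout.N
    out: dict = {"b1": float(np.real(c1_hat[0]))}
    off = 1
    for nm in ["h11", "h12", "h13"] + ([f"h14_{i + 1}" for i in range(N)] if layout.mode == "spatiotemporal" else []):
        space = s_in if nm in ("h11", "h12") else s_out
        out[nm] = Kernel1(space, c1_hat[off : off + space.dim], label=nm)
        off += space.dim
    out["H21"] = Kernel2(s_in, C2_hat[:d, :d], symmetric=True, label="H21")
    out["H22"] = Kernel2(s_in, C2_hat[d : 2 * d, :d], symmetric=True, label="H22")
    out["H23"] = Kernel2(s_out, C2_hat[2 * d : 2 * d + do, d:], symmetric=True, label="H23")
    if layout.mode == "spatiotemporal":
        r = 2 * d + do
        for i in range(N):
            for j in range(N):
                nm = f"H24_{i + 1}_{j + 1}"
                if not (layout.tie_symmetric and i > j):
                    out[nm] = Kernel2(s_out, C2_hat[r : r + do, d:], label=nm)
                r += do
    return out


def _canonicalize_pairs(values: dict, layout: Layout) -> None:
    """Pick the balanced representative of each untied (i, j)/(j, i) pair.

    The measurements see only the combination H_ij + H_ji^H (both kernels
    act on the same product v_i(t-s1) v_j(t-s2)), so the anti-tied
    direction (D, -D^H) is exactly invisible.  Splitting the identified
    sum evenly is the minimum-Frobenius representative and never changes
    the fit.
    """
    if layout.mode != "spatiotemporal" or layout.tie_symmetric:
        return
    for i in range(layout.N):
        for j in range(i + 1, layout.N):
            a, b = f"H24_{i + 1}_{j + 1}", f"H24_{j + 1}_{i + 1}"
            if layout.has(a) and layout.has(b):
                mean = 0.5 * (np.asarray(values[a]) + np.asarray(values[b]).conj().T)
                values[a] = mean
                values[b] = mean.conj().T


def _constraint_report(values: dict, layout: Layout, slack: np.ndarray, system: MeasurementSystem, theta: np.ndarray) -> dict:
    rep = {"zero_blocks": 0.0, "slack_mean": float(abs(np.sum(slack)))}
    for nm in ("H21", "H22", "H23"):
        if layout.has(nm):
            H = values[nm]
            rep[f"hermitian_{nm}"] = float(np.max(np.abs(H - H.conj().T)))
    rep["measurement_eq"] = float(np.max(np.abs(system.G @ theta - system.q - slack)))
    return rep


def _compute_snr(values: dict, truth_theta: np.ndarray, layout: Layout) -> dict:
    truth = layout.decode(truth_theta)
    out = {}
    for b in layout:
        t = np.atleast_1d(np.asarray(truth[b.name]))
        e = np.atleast_1d(np.asarray(values[b.name]))
        if np.linalg.norm(t) == 0:
            continue
        out[b.name] = snr_db(t, e)
    return out


def solve_system(
    system: MeasurementSystem,
    cfg: IdentConfig | None = None,
    truth: np.ndarray | None = None,
) -> IdentResult:
    """Run the nuclear-norm program (and optional polish) on an assembled system.

    ``truth`` is an optional ground-truth parameter vector (from
    ``system.encode_model``) used only for recovery-SNR diagnostics.
    """
    cfg = cfg or IdentConfig()
    lay = system.layout
    theta, stacks, Z, eps, it, primal, dual = _admm(system, cfg)

    # kernels from the thresholded (exactly low-rank) stack iterates
    values = lay.decode(theta)
    for s, z in zip(stacks, Z):
        for name, rows in s.slices.items():
            values[name] = z[rows]

    polished = False
    if cfg.polish and lay.k2_blocks():
        # two polish seeds: the unthresholded ADMM iterate (keeps small
        # singular components that SVT removed) and the min-norm dense
        # least-squares backprojection (spectral initialization)
        seeds = [lay.decode(theta)]
        th_mn, *_ = np.linalg.lstsq(system.G, system.q, rcond=1e-12)
        seeds.append(lay.decode(th_mn))
        # parsimony-first rank search: fit at rank 1, then grow all ranks
        # until the measurement equations are satisfied
        qn = max(1.0, float(np.linalg.norm(system.q)))
        ranks = {b.name: 1 for b in lay.k2_blocks()}
        best_vals, best_resid = None, np.inf
        rounds = 0
        while True:
            round_seeds = list(seeds)
            if best_vals is not None:
                # greedy continuation: previous best fit plus a residual-
                # gradient component seeds the next rank
                round_seeds.append(_augment_seed(system, best_vals))
            for seed_vals in round_seeds:
                cand_vals, cand_resid = _polish(system, cfg, seed_vals, ranks)
                if cand_resid < best_resid:
                    best_vals, best_resid = cand_vals, cand_resid
            if best_resid <= cfg.polish_target * qn or rounds >= cfg.max_rank_rounds:
                break
            rounds += 1
            ranks = {k: v + 1 for k, v in ranks.items()}
        if best_resid <= np.linalg.norm(system.G @ theta - system.q):
            values = best_vals
            theta = lay.encode(values)
            eps = np.zeros_like(eps)
            polished = True

    _canonicalize_pairs(values, lay)
    ranks = {}
    for b in lay.k2_blocks():
        sv = np.linalg.svd(values[b.name], compute_uv=False)
        ranks[b.name] = int(np.sum(sv > cfg.rank_tol * sv[0])) if sv[0] > 0 else 0

    c1_hat, C2_hat = assemble_c1_C2(values, lay)
    kernels = reconstruct_kernels(c1_hat, C2_hat, lay)
    res = IdentResult(
        layout=lay,
        theta=theta,
        values=values,
        kernels=kernels,
        c1_hat=c1_hat,
        C2_hat=C2_hat,
        slack=eps,
        ranks=ranks,
        constraint_report=_constraint_report(values, lay, eps, system, theta),
        measurement_residual=float(np.max(np.abs(system.G @ theta - system.q))),
        admm_iterations=it,
        admm_primal=primal,
        admm_dual=dual,
        polished=polished,
    )
    if truth is not None:
        res.snr = _compute_snr(values, truth, lay)
    return res


def solve_temporal(system: MeasurementSystem, cfg: IdentConfig | None = None, truth=None) -> IdentResult:
    """Identify a temporal DNP from an assembled single-channel system."""
    if system.layout.mode != "temporal":
        raise ValueError("system was not built in temporal mode")
    return solve_system(system, cfg, truth)


def solve_spatiotemporal(system: MeasurementSystem, cfg: IdentConfig | None = None, truth=None) -> IdentResult:
    """Identify a spatio-temporal DNP (shared T1..T3 plus the MVP block)."""
    if system.layout.mode != "spatiotemporal":
        raise ValueError("system was not built in spatiotemporal mode")
    return solve_system(system, cfg, truth)
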