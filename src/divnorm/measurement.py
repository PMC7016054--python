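"""Generalized-sampling systems for DNP identification.

Sampling the implicit equation ``v (T2 u + T3 v + L4 v) = T1 u`` at times
``t_k`` and rearranging under the normalization ``b2 + b3 (+ b4) = 1``
turns every sample into one *linear* equation in the unknown kernels:

    b1 + <h1_1, phi_11> + <h1_2, phi_12> + <h1_3, phi_13> [+ sum_i <h1_i4, phi_14^i>]
       + <h2_1, phi_21> + <h2_2, phi_22> + <h2_3, phi_23> [+ sum_ij <h2_ij4, phi_24^ij>]
       = q^{nmk},

with sampling functions built from reversed shifts of the stimulus
``u(t_k - t)`` and of the band-limited output projection
``(P1o v)(t_k - t)``, scaled by ``-q^{nmk} = -v^{nm}(t_k)``.

This module assembles those equations into numeric form.  Internally every
unknown is parametrized by its free *real* degrees of freedom (real-valued
kernels have conjugate-symmetric coefficient vectors; exchange-symmetric
second-order kernels are Hermitian matrices in the reconstruction index
map; real non-symmetric feedback kernels are centro-Hermitian).  The
predicted measurement is then a real linear map ``q_pred = G theta``, and
plugging a ground-truth model's coefficients into ``G`` provides the
residual oracle that validates every convention choice at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .simulate import SpatioTemporalDNP, TemporalDNP
from .spaces import Kernel1, Kernel2, Signal, TrigSpace, reversed_shift_coeffs, signal_from_samples
from .volterra import MVP, VolterraProcessor

__all__ = [
    "TrialSet",
    "Block",
    "Layout",
    "MeasurementSystem",
    "build_temporal_system",
    "build_spatiotemporal_system",
    "count_unknowns",
]


# ---------------------------------------------------------------------------
# trials


@dataclass
class TrialSet:
    """M stimulus/response trials on a dense grid, plus sample times.

    ``inputs[m][n]`` is the stimulus of channel ``n`` in trial ``m`` (a list
    of one for temporal circuits); ``responses[m, n]`` are the recorded
    output samples on ``grid``.  ``q(n, m, k)`` reads the response at
    ``t_k`` -- exactly when the sample times lie on the grid, otherwise by
    trigonometric interpolation of the (smooth, periodic) trajectory.
    """

    space_in: TrigSpace
    space_out: TrigSpace
    inputs: list
    responses: np.ndarray  # (M, N, n_grid)
    grid: np.ndarray
    sample_times: np.ndarray  # (T,) shared or (N, T) per channel

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim == 2:
            self.responses = self.responses[:, None, :]
        self.M = self.responses.shape[0]
        self.N = self.responses.shape[1]
        st = np.asarray(self.sample_times, dtype=float)
        # Per-channel sample times matter for multi-channel circuits: the
        # amacrine feedback L4 v is common to every cell, so sampling all
        # cells at identical times would probe the same feedback functional
        # repeatedly and leave the MVP under-constrained.
        self.sample_times = np.broadcast_to(st if st.ndim == 2 else st[None, :], (self.N, st.shape[-1])).copy()
        if np.any(self.sample_times < 0) or np.any(self.sample_times >= self.space_in.S):
            raise ValueError("sample times must lie in [0, S)")
        self.T = self.sample_times.shape[1]
        n = self.grid.size
        # grid indices of sample times, if exact
        idx = self.sample_times / (self.space_in.S / n)
        self._exact_idx = np.rint(idx).astype(int) if np.allclose(idx, np.rint(idx), atol=1e-9) else None

    def sample_time(self, n: int, k: int) -> float:
        return float(self.sample_times[n, k])

    def q(self, n: int, m: int, k: int) -> float:
        if self._exact_idx is not None:
            return float(self.responses[m, n, self._exact_idx[n, k]])
        return float(self._interp(self.responses[m, n], self.sample_times[n, k]))

    def _interp(self, samples: np.ndarray, t: float) -> float:
        ng = samples.size
        spec = np.fft.fft(samples) / ng
        freqs = np.fft.fftfreq(ng, d=1.0 / ng)  # integer harmonics
        return float(np.real(np.sum(spec * np.exp(2j * np.pi * freqs * t / self.space_in.S))))

    def output_projection(self, n: int, m: int) -> Signal:
        """P1o v^{nm}: band-limited projection of the recorded output."""
        return Signal(self.space_out, signal_from_samples(self.responses[m, n], self.space_out))


# ---------------------------------------------------------------------------
# unknown layout


@dataclass
class Block:
    """One unknown of the identification problem.

    ``kind``: 'scalar' | 'k1' | 'k2'.  ``structure`` for k2 blocks:
    'hermitian' (real exchange-symmetric kernel) or 'centro' (real,
    possibly asymmetric kernel).  ``tied`` marks an (i, j)/(j, i) feedback
    pair folded into a single unknown.
    """

    name: str
    kind: str
    space: str  # 'in' | 'out'
    structure: str = ""
    tied: bool = False
    n_entries: int = 0
    n_params: int = 0
    entry_off: int = 0
    param_off: int = 0


def _k1_param_matrix(d: int) -> sp.csr_matrix:
    """Map d real params -> conjugate-symmetric complex coefficient vector."""
    L = d // 2
    rows, cols, vals = [], [], []
    rows.append(L), cols.append(0), vals.append(1.0)
    p = 1
    for j in range(1, L + 1):
        rows += [L + j, L - j]
        cols += [p, p]
        vals += [1.0, 1.0]
        rows += [L + j, L - j]
        cols += [p + 1, p + 1]
        vals += [1j, -1j]
        p += 2
    return sp.csr_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(d, d), dtype=complex))


def _hermitian_param_matrix(d: int) -> sp.csr_matrix:
    """Map d^2 real params -> row-major vec of a d x d Hermitian matrix."""
    rows, cols, vals = [], [], []
    p = 0
    for r in range(d):
        rows.append(r * d + r), cols.append(p), vals.append(1.0)
        p += 1
    for r in range(d):
        for c in range(r + 1, d):
            rows += [r * d + c, c * d + r]
            cols += [p, p]
            vals += [1.0, 1.0]
            rows += [r * d + c, c * d + r]
            cols += [p + 1, p + 1]
            vals += [1j, -1j]
            p += 2
    return sp.csr_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(d * d, p), dtype=complex))


def _hermsym_param_matrix(d: int) -> sp.csr_matrix:
    """Map -> vec of a Hermitian *and* persymmetric d x d matrix.

    This is the matrix form of a real, exchange-symmetric kernel -- the
    unique symmetric representation of a second-order Volterra kernel.
    The exchange-antisymmetric directions dropped here are annihilated by
    every stimulus (u(t-s1)u(t-s2) is symmetric in (s1, s2)), so they are
    unidentifiable in principle; including them would only add nullspace.
    Free parameter count: d(d+1)/2.
    """
    L = d // 2
    orbits: dict[tuple, list[tuple]] = {}
    for i1 in range(d):
        for i2 in range(d):
            l1, l2 = i1 - L, i2 - L
            orb = {(l1, l2), (l2, l1)}
            rep = max(orb | {(-l1, -l2), (-l2, -l1)})
            orbits.setdefault(rep, []).append((l1, l2))
    rows, cols, vals = [], [], []
    p = 0
    for rep, members in sorted(orbits.items()):
        a, b = rep
        self_conj = (-a, -b) in ((a, b), (b, a))
        for l1, l2 in members:
            r, c = l1 + L, L - l2  # storage index map
            conj = (l1, l2) not in ((a, b), (b, a))
            rows.append(r * d + c), cols.append(p), vals.append(1.0)
            if not self_conj:
                rows.append(r * d + c), cols.append(p + 1), vals.append(-1j if conj else 1j)
        p += 1 if self_conj else 2
    return sp.csr_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(d * d, p), dtype=complex))


def _centro_param_matrix(d: int) -> sp.csr_matrix:
    """Map d^2 real params -> vec of a centro-Hermitian matrix
    (H[r, c] = conj(H[d-1-r, d-1-c]), the matrix form of a real kernel)."""
    rows, cols, vals = [], [], []
    p = 0
    seen = set()
    for r in range(d):
        for c in range(d):
            if (r, c) in seen:
                continue
            rb, cb = d - 1 - r, d - 1 - c
            if (rb, cb) == (r, c):
                rows.append(r * d + c), cols.append(p), vals.append(1.0)
                p += 1
            else:
                seen.add((rb, cb))
                rows += [r * d + c, rb * d + cb]
                cols += [p, p]
                vals += [1.0, 1.0]
                rows += [r * d + c, rb * d + cb]
                cols += [p + 1, p + 1]
                vals += [1j, -1j]
                p += 2
    return sp.csr_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(d * d, p), dtype=complex))


def _params_from_complex(P: sp.csr_matrix, vec: np.ndarray) -> np.ndarray:
    """Least-squares inverse of the (orthogonal-column) parametrization."""
    col_norm2 = np.asarray(np.abs(P.multiply(P.conj())).sum(axis=0)).ravel().real
    return np.real(P.conj().T @ vec) / col_norm2


@dataclass
class Layout:
    """Ordered unknown blocks with their real-parameter offsets."""

    mode: str  # 'temporal' | 'spatiotemporal'
    N: int
    space_in: TrigSpace
    space_out: TrigSpace
    blocks: list = field(default_factory=list)
    tie_symmetric: bool = False

    def __post_init__(self) -> None:
        e_off = p_off = 0
        self._pmats: dict[str, sp.csr_matrix] = {}
        for b in self.blocks:
            d = (self.space_in if b.space == "in" else self.space_out).dim
            if b.kind == "scalar":
                P = sp.csr_matrix(np.array([[1.0 + 0j]]))
            elif b.kind == "k1":
                P = _k1_param_matrix(d)
            elif b.structure == "hermsym":
                P = _hermsym_param_matrix(d)
            elif b.structure == "hermitian":
                P = _hermitian_param_matrix(d)
            else:
                P = _centro_param_matrix(d)
            b.n_entries, b.n_params = P.shape
            b.entry_off, b.param_off = e_off, p_off
            e_off += b.n_entries
            p_off += b.n_params
            self._pmats[b.name] = P
        self.n_entries = e_off
        self.n_params = p_off

    def __iter__(self):
        return iter(self.blocks)

    def get(self, name: str) -> Block:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def has(self, name: str) -> bool:
        return any(b.name == name for b in self.blocks)

    def pmat(self, name: str) -> sp.csr_matrix:
        return self._pmats[name]

    def param_matrix(self) -> sp.csr_matrix:
        """Block-diagonal theta -> complex-entry-vector map."""
        return sp.block_diag([self._pmats[b.name] for b in self.blocks], format="csr")

    def k1_blocks(self):
        return [b for b in self.blocks if b.kind == "k1"]

    def k2_blocks(self):
        return [b for b in self.blocks if b.kind == "k2"]

    def c1_param_slice(self) -> slice:
        stop = 0
        for b in self.blocks:
            if b.kind == "k2":
                break
            stop = b.param_off + b.n_params
        return slice(0, stop)

    # -- encode/decode -----------------------------------------------------
    def encode(self, values: dict[str, float | np.ndarray]) -> np.ndarray:
        """Real parameter vector theta from per-block complex values.

        ``values[name]`` is a scalar (b1), a coefficient vector (k1) or a
        coefficient matrix in the reconstruction index map (k2); missing
        blocks encode as zero.
        """
        theta = np.zeros(self.n_params)
        for b in self.blocks:
            if b.name not in values:
                continue
            vec = np.asarray(values[b.name], dtype=complex).reshape(-1)
            theta[b.param_off : b.param_off + b.n_params] = _params_from_complex(self._pmats[b.name], vec)
        return theta

    def decode(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Per-block complex values from a real parameter vector."""
        out: dict[str, np.ndarray] = {}
        d_in, d_out = self.space_in.dim, self.space_out.dim
        for b in self.blocks:
            vec = self._pmats[b.name] @ theta[b.param_off : b.param_off + b.n_params]
            if b.kind == "scalar":
                out[b.name] = vec[0].real
            elif b.kind == "k1":
                out[b.name] = vec
            else:
                d = d_in if b.space == "in" else d_out
                out[b.name] = vec.reshape(d, d)
        return out


def temporal_layout(space_in: TrigSpace, space_out: TrigSpace, assume_zero=()) -> Layout:
    blocks = [
        Block("b1", "scalar", "in"),
        Block("h11", "k1", "in"),
        Block("h12", "k1", "in"),
        Block("h13", "k1", "out"),
        Block("H21", "k2", "in", "hermsym"),
        Block("H22", "k2", "in", "hermsym"),
        Block("H23", "k2", "out", "hermsym"),
    ]
    blocks = [b for b in blocks if b.name not in set(assume_zero)]
    return Layout("temporal", 1, space_in, space_out, blocks)


def spatiotemporal_layout(
    space_in: TrigSpace,
    space_out: TrigSpace,
    N: int,
    tie_symmetric: bool = False,
    assume_zero=(),
) -> Layout:
    blocks = [
        Block("b1", "scalar", "in"),
        Block("h11", "k1", "in"),
        Block("h12", "k1", "in"),
        Block("h13", "k1", "out"),
    ]
    blocks += [Block(f"h14_{i + 1}", "k1", "out") for i in range(N)]
    blocks += [Block("H21", "k2", "in", "hermsym"), Block("H22", "k2", "in", "hermsym"), Block("H23", "k2", "out", "hermsym")]
    if tie_symmetric:
        for i in range(N):
            for j in range(i, N):
                # diagonal pairs act on (v_i, v_i): only the symmetric part is
                # identifiable, so they share the symmetric parametrization
                struct = "hermsym" if i == j else "centro"
                blocks.append(Block(f"H24_{i + 1}_{j + 1}", "k2", "out", struct, tied=(i != j)))
    else:
        for i in range(N):
            for j in range(N):
                blocks.append(Block(f"H24_{i + 1}_{j + 1}", "k2", "out", "centro"))
    blocks = [b for b in blocks if b.name not in set(assume_zero)]
    return Layout("spatiotemporal", N, space_in, space_out, blocks, tie_symmetric)


# ---------------------------------------------------------------------------
# system assembly


class MeasurementSystem:
    """Assembled sampling system: ``q_pred(theta) = G theta``.

    ``W`` (complex, n_meas x n_entries) holds, per measurement, the
    conjugated sampling coefficients so that the predicted measurement is
    ``Re(W @ (P theta))`` with ``P`` the layout's real parametrization.
    The block-layout sampling vector Phi and block matrix Xi for any
    (n, m, k) are available from the stored per-measurement pieces.
    """

    def __init__(self, layout: Layout, trials: TrialSet):
        self.layout = layout
        self.trials = trials
        self.space_in = layout.space_in
        self.space_out = layout.space_out
        self._assemble()

    # -- assembly ----------------------------------------------------------
    def _assemble(self) -> None:
        tr, lay = self.trials, self.layout
        d, do = self.space_in.dim, self.space_out.dim
        N, M, T = tr.N, tr.M, tr.T
        if lay.mode == "temporal" and N != 1:
            raise ValueError("temporal systems require single-channel trials")
        n_meas = N * M * T
        self.q = np.empty(n_meas)
        self._u_rs = np.empty((n_meas, d), dtype=complex)  # rev-shift stimulus coeffs
        self._w_rs = np.empty((n_meas, N, do), dtype=complex)  # rev-shift P1o v, all channels
        self._meta = []  # (n, m, k)
        pv = [[tr.output_projection(n, m) for n in range(N)] for m in range(M)]
        row = 0
        for n in range(N):
            for m in range(M):
                u_nm = tr.inputs[m][n] if isinstance(tr.inputs[m], (list, tuple)) else tr.inputs[m]
                for k in range(T):
                    tk = tr.sample_time(n, k)
                    self.q[row] = tr.q(n, m, k)
                    self._u_rs[row] = reversed_shift_coeffs(u_nm, tk)
                    for i in range(N):
                        self._w_rs[row, i] = reversed_shift_coeffs(pv[m][i], tk)
                    self._meta.append((n, m, k))
                    row += 1
        self._dims = (N, M, T)
        self.W = self._build_W()
        self.P = lay.param_matrix()
        self.G = np.asarray(np.real(self.W @ self.P))
        self._check_budget()

    @classmethod
    def from_arrays(cls, layout: Layout, q, u_rs, w_rs, meta) -> "MeasurementSystem":
        """Rebuild a system from its serialized per-measurement pieces."""
        obj = cls.__new__(cls)
        obj.layout = layout
        obj.trials = None
        obj.space_in = layout.space_in
        obj.space_out = layout.space_out
        obj.q = np.asarray(q, dtype=float)
        obj._u_rs = np.asarray(u_rs, dtype=complex)
        obj._w_rs = np.asarray(w_rs, dtype=complex)
        obj._meta = [tuple(int(x) for x in m) for m in meta]
        ns, ms, ks = zip(*obj._meta)
        obj._dims = (max(ns) + 1, max(ms) + 1, max(ks) + 1)
        obj.W = obj._build_W()
        obj.P = layout.param_matrix()
        obj.G = np.asarray(np.real(obj.W @ obj.P))
        return obj

    def _build_W(self) -> np.ndarray:
        lay, tr = self.layout, self.trials
        n_meas = self.q.size
        W = np.zeros((n_meas, lay.n_entries), dtype=complex)
        q = self.q
        for b in lay:
            sl = slice(b.entry_off, b.entry_off + b.n_entries)
            if b.name == "b1":
                W[:, sl] = 1.0
            elif b.name == "h11":
                W[:, sl] = np.conj(self._u_rs)
            elif b.name == "h12":
                W[:, sl] = -q[:, None] * np.conj(self._u_rs)
            elif b.name == "h13":
                wn = self._w_rs[np.arange(n_meas), [mt[0] for mt in self._meta]]
                W[:, sl] = -q[:, None] * np.conj(wn)
            elif b.name.startswith("h14_"):
                i = int(b.name.split("_")[1]) - 1
                W[:, sl] = -q[:, None] * np.conj(self._w_rs[:, i])
            elif b.name in ("H21", "H22"):
                p = self._u_rs
                # Xi block = scale * p p^H; W row = conj(vec(Xi))
                outer = np.einsum("kr,kc->krc", np.conj(p), p).reshape(n_meas, -1)
                W[:, sl] = outer if b.name == "H21" else -q[:, None] * outer
            elif b.name == "H23":
                wn = self._w_rs[np.arange(n_meas), [mt[0] for mt in self._meta]]
                outer = np.einsum("kr,kc->krc", np.conj(wn), wn)
                W[:, sl] = -q[:, None] * outer.reshape(n_meas, -1)
            elif b.name.startswith("H24_"):
                i, j = (int(x) - 1 for x in b.name.split("_")[1:])
                wi, wj = self._w_rs[:, i], self._w_rs[:, j]
                outer = np.einsum("kr,kc->krc", np.conj(wi), wj)
                factor = -2.0 if b.tied else -1.0
                W[:, sl] = factor * q[:, None] * outer.reshape(n_meas, -1)
            else:  # pragma: no cover
                raise AssertionError(b.name)
        return W

    def _check_budget(self) -> None:
        d = self.space_in.dim
        M, T = self.trials.M, self.trials.T
        if M < 3 + 2 * d:
            warnings.warn(
                f"M = {M} trials is below the dense-solvability bound 3 + 2*dim(H1) = {3 + 2 * d}; "
                "the sparse (low-rank) solver may still succeed",
                stacklevel=3,
            )

    # -- public API --------------------------------------------------------
    @property
    def n_measurements(self) -> int:
        return self.q.size

    def predict(self, theta: np.ndarray) -> np.ndarray:
        return self.G @ theta

    def residual(self, theta: np.ndarray) -> float:
        """max_k |q_pred - q|: the sampling-identity residual oracle."""
        return float(np.max(np.abs(self.predict(theta) - self.q)))

    def encode_model(self, model: TemporalDNP | SpatioTemporalDNP) -> np.ndarray:
        """theta of a ground-truth DNP in this layout (for the residual oracle)."""
        vals: dict[str, np.ndarray | float] = {"b1": model.T1.b}
        def put_k1(name, k):
            if self.layout.has(name) and k is not None:
                vals[name] = k.coeffs
        def put_k2(name, k):
            if self.layout.has(name) and k is not None:
                vals[name] = k.coeffs
        put_k1("h11", model.T1.h1)
        put_k1("h12", model.T2.h1)
        put_k1("h13", model.T3.h1)
        put_k2("H21", model.T1.h2)
        put_k2("H22", model.T2.h2)
        put_k2("H23", model.T3.h2)
        if isinstance(model, SpatioTemporalDNP):
            mvp = model.mvp
            for i in range(model.N):
                if mvp.h1_list:
                    put_k1(f"h14_{i + 1}", mvp.h1_list[i])
            if mvp.h2_grid:
                for i in range(model.N):
                    for j in range(model.N):
                        k = mvp.h2_grid[i][j]
                        if k is None:
                            continue
                        if self.layout.tie_symmetric:
                            if i <= j:
                                put_k2(f"H24_{i + 1}_{j + 1}", k)
                        else:
                            put_k2(f"H24_{i + 1}_{j + 1}", k)
        return self.layout.encode(vals)

    # -- block-layout sampling vectors --------------------------------------
    def phi_vector(self, n: int, m: int, k: int) -> np.ndarray:
        """Phi^{nmk}: [1; u; -q u; -q v_n (; -q v_1 .. -q v_N)]."""
        row = self._row(n, m, k)
        q = self.q[row]
        parts = [np.array([1.0 + 0j]), self._u_rs[row], -q * self._u_rs[row], -q * self._w_rs[row, n]]
        if self.layout.mode == "spatiotemporal":
            parts += [-q * self._w_rs[row, i] for i in range(self._dims[0])]
        return np.concatenate(parts)

    def xi_matrix(self, n: int, m: int, k: int) -> np.ndarray:
        """Xi^{nmk} in the full block layout (zero blocks included)."""
        row = self._row(n, m, k)
        q = self.q[row]
        d, do = self.space_in.dim, self.space_out.dim
        p = self._u_rs[row]
        U2 = np.outer(p, np.conj(p))
        if self.layout.mode == "temporal":
            X = np.zeros((2 * d + do, d + do), dtype=complex)
            X[:d, :d] = U2
            X[d : 2 * d, :d] = -q * U2
            wn = self._w_rs[row, n]
            X[2 * d :, d:] = -q * np.outer(wn, np.conj(wn))
            return X
        N = self._dims[0]
        X = np.zeros((2 * d + (N * N + 1) * do, d + do), dtype=complex)
        X[:d, :d] = U2
        X[d : 2 * d, :d] = -q * U2
        wn = self._w_rs[row, n]
        X[2 * d : 2 * d + do, d:] = -q * np.outer(wn, np.conj(wn))
        r = 2 * d + do
        for i in range(N):
            for j in range(N):
                X[r : r + do, d:] = -q * np.outer(self._w_rs[row, i], np.conj(self._w_rs[row, j]))
                r += do
        return X

    @property
    def phi(self) -> np.ndarray:
        """All Phi vectors stacked, (n_meas x phi_len)."""
        return np.stack([self.phi_vector(*meta) for meta in self._meta])

    def _row(self, n: int, m: int, k: int) -> int:
        _, M, T = self._dims
        return (n * M + m) * T + k


def build_temporal_system(trials: TrialSet, assume_zero=()) -> MeasurementSystem:
    """Assemble the single-channel generalized-sampling system."""
    lay = temporal_layout(trials.space_in, trials.space_out, assume_zero)
    return MeasurementSystem(lay, trials)


def build_spatiotemporal_system(trials: TrialSet, tie_symmetric: bool = False, assume_zero=()) -> MeasurementSystem:
    """Assemble the N-channel system, optionally tying h2_ij4 = h2_ji4."""
    lay = spatiotemporal_layout(trials.space_in, trials.space_out, trials.N, tie_symmetric, assume_zero)
    return MeasurementSystem(lay, trials)


def count_unknowns(L: int, L_o: int, N: int = 1, mode: str = "temporal", tie_symmetric: bool = False) -> int:
    """Number of scalar unknowns of the dense generalized-sampling problem.

    Temporal: 1 + 2(2L+1) + (2Lo+1) + 2(2L+1)^2 + (2Lo+1)^2.
    Spatio-temporal adds N first-order and N^2 (or N(N+1)/2 tied)
    second-order feedback blocks on the output space.
    """
    if L < 0 or L_o < 0 or N < 1:
        raise ValueError("invalid orders")
    d, do = 2 * L + 1, 2 * L_o + 1
    total = 1 + 2 * d + do + 2 * d * d + do * do
    if mode == "spatiotemporal":
        pairs = N * (N + 1) // 2 if tie_symmetric else N * N
        total += N * do + pairs * do * do
    elif mode != "temporal":
        raise ValueError(f"unknown mode {mode!r}")
    return total
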