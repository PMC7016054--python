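"""NPZ / HDF5 / CSV serialization of signals, kernels, models and systems.

NPZ containers are flat dictionaries of arrays plus scalar metadata; HDF5
is used for structured circuit models (nested Volterra processors and the
MVP grid).  All containers carry the space parameters (L, Omega, S) so
objects round-trip without external context.
"""

from __future__ import annotations

import csv
import json

import h5py
import numpy as np

from .measurement import Layout, MeasurementSystem, TrialSet, spatiotemporal_layout, temporal_layout
from .simulate import SimResult, SpatioTemporalDNP, TemporalDNP
from .spaces import Kernel1, Kernel2, Signal, TrigSpace, make_space
from .volterra import MVP, VolterraProcessor

__all__ = [
    "save_signal_npz",
    "load_signal_npz",
    "save_stimuli_npz",
    "load_stimuli_npz",
    "save_response_npz",
    "load_response_npz",
    "save_model_hdf5",
    "load_model_hdf5",
    "save_system_npz",
    "load_system_npz",
    "kernel_table_csv",
]


def _space_meta(space: TrigSpace) -> dict:
    return {"L": space.L, "Omega": space.Omega, "S": space.S}


def _space_from_meta(L, Omega, S) -> TrigSpace:
    L = int(L)
    return make_space(L, float(Omega), S_override=float(S) if L == 0 else None)


def save_signal_npz(path, obj: Signal | Kernel1 | Kernel2) -> None:
    kind = "kernel2" if isinstance(obj, Kernel2) else ("kernel1" if isinstance(obj, Kernel1) else "signal")
    np.savez(
        path,
        coeffs=obj.coeffs,
        kind=kind,
        label=getattr(obj, "label", ""),
        symmetric=getattr(obj, "symmetric", False),
        **_space_meta(obj.space),
    )


def load_signal_npz(path) -> Signal | Kernel1 | Kernel2:
    with np.load(path, allow_pickle=False) as z:
        space = _space_from_meta(z["L"], z["Omega"], z["S"])
        kind = str(z["kind"])
        label = str(z["label"])
        if kind == "kernel2":
            return Kernel2(space, z["coeffs"], symmetric=bool(z["symmetric"]), label=label)
        cls = Kernel1 if kind == "kernel1" else Signal
        return cls(space, z["coeffs"], label=label)


def save_stimuli_npz(path, stimuli: list) -> None:
    """Stimuli as (M, N, dim) coefficient array; accepts flat or per-channel lists."""
    rows = [s if isinstance(s, (list, tuple)) else [s] for s in stimuli]
    space = rows[0][0].space
    arr = np.array([[sig.coeffs for sig in row] for row in rows])
    np.savez(path, coeffs=arr, **_space_meta(space))


def load_stimuli_npz(path) -> list:
    with np.load(path) as z:
        space = _space_from_meta(z["L"], z["Omega"], z["S"])
        arr = z["coeffs"]
    return [[Signal(space, c) for c in row] for row in arr]


def save_response_npz(path, result: SimResult) -> None:
    np.savez(
        path,
        v=result.v,
        grid=result.grid,
        iterations=result.iterations,
        residual=result.residual,
        converged=result.converged,
        min_denominator=result.min_denominator,
    )


def load_response_npz(path) -> SimResult:
    with np.load(path) as z:
        return SimResult(
            v=z["v"],
            grid=z["grid"],
            iterations=int(z["iterations"]),
            residual=float(z["residual"]),
            converged=bool(z["converged"]),
            min_denominator=float(z["min_denominator"]),
        )


# ---------------------------------------------------------------------------
# circuit models (HDF5)


def _write_vp(grp: h5py.Group, vp: VolterraProcessor) -> None:
    grp.attrs["b"] = vp.b
    if vp.h1 is not None:
        grp.create_dataset("h1", data=vp.h1.coeffs)
    if vp.h2 is not None:
        ds = grp.create_dataset("h2", data=vp.h2.coeffs)
        ds.attrs["symmetric"] = vp.h2.symmetric


def _read_vp(grp: h5py.Group, space: TrigSpace) -> VolterraProcessor:
    h1 = Kernel1(space, grp["h1"][...]) if "h1" in grp else None
    h2 = None
    if "h2" in grp:
        h2 = Kernel2(space, grp["h2"][...], symmetric=bool(grp["h2"].attrs.get("symmetric", False)))
    return VolterraProcessor(b=float(grp.attrs["b"]), h1=h1, h2=h2, space_in=space)


def save_model_hdf5(path, model: TemporalDNP | SpatioTemporalDNP) -> None:
    with h5py.File(path, "w") as f:
        for key, val in _space_meta(model.space_in).items():
            f.attrs[f"in_{key}"] = val
        for key, val in _space_meta(model.space_out).items():
            f.attrs[f"out_{key}"] = val
        f.attrs["kind"] = "spatiotemporal" if isinstance(model, SpatioTemporalDNP) else "temporal"
        for name in ("T1", "T2", "T3"):
            _write_vp(f.create_group(name), getattr(model, name))
        if isinstance(model, SpatioTemporalDNP):
            g = f.create_group("mvp")
            g.attrs["N"] = model.N
            g.attrs["b4"] = model.mvp.b4
            g.attrs["symmetric_pairs"] = model.mvp.symmetric_pairs
            for i, k in enumerate(model.mvp.h1_list or []):
                if k is not None:
                    g.create_dataset(f"h1/{i + 1}", data=k.coeffs)
            for i, row in enumerate(model.mvp.h2_grid or []):
                for j, k in enumerate(row):
                    if k is not None:
                        g.create_dataset(f"h2/{i + 1}_{j + 1}", data=k.coeffs)


def load_model_hdf5(path) -> TemporalDNP | SpatioTemporalDNP:
    with h5py.File(path, "r") as f:
        s_in = _space_from_meta(f.attrs["in_L"], f.attrs["in_Omega"], f.attrs["in_S"])
        s_out = _space_from_meta(f.attrs["out_L"], f.attrs["out_Omega"], f.attrs["out_S"])
        T1 = _read_vp(f["T1"], s_in)
        T2 = _read_vp(f["T2"], s_in)
        T3 = _read_vp(f["T3"], s_out)
        if f.attrs["kind"] == "temporal":
            return TemporalDNP(T1, T2, T3, s_in, s_out)
        g = f["mvp"]
        N = int(g.attrs["N"])
        sym = bool(g.attrs["symmetric_pairs"])
        h1 = [Kernel1(s_out, g[f"h1/{i + 1}"][...]) if f"h1/{i + 1}" in g else None for i in range(N)]
        h2 = [[None] * N for _ in range(N)]
        for i in range(N):
            for j in range(N):
                key = f"h2/{i + 1}_{j + 1}"
                if key in g:
                    h2[i][j] = Kernel2(s_out, g[key][...])
        if sym:
            for i in range(N):
                for j in range(i + 1, N):
                    h2[j][i] = h2[i][j]
        mvp = MVP(N=N, b4=float(g.attrs["b4"]), h1_list=h1, h2_grid=h2, symmetric_pairs=sym, space=s_out)
        return SpatioTemporalDNP(N, T1, T2, T3, mvp, s_in, s_out)


# ---------------------------------------------------------------------------
# assembled measurement systems


def save_system_npz(path, system: MeasurementSystem) -> None:
    lay = system.layout
    layout_json = json.dumps(
        {
            "mode": lay.mode,
            "N": lay.N,
            "tie_symmetric": lay.tie_symmetric,
            "space_in": _space_meta(lay.space_in),
            "space_out": _space_meta(lay.space_out),
            "blocks": [b.name for b in lay.blocks],
        }
    )
    np.savez(
        path,
        q=system.q,
        u_rs=system._u_rs,
        w_rs=system._w_rs,
        meta=np.array(system._meta, dtype=np.int64),
        layout=layout_json,
    )


def load_system_npz(path) -> MeasurementSystem:
    with np.load(path, allow_pickle=False) as z:
        spec = json.loads(str(z["layout"]))
        s_in = _space_from_meta(**spec["space_in"])
        s_out = _space_from_meta(**spec["space_out"])
        all_names = {"b1", "h11", "h12", "h13", "H21", "H22", "H23"} | {
            f"h14_{i + 1}" for i in range(spec["N"])
        } | {f"H24_{i + 1}_{j + 1}" for i in range(spec["N"]) for j in range(spec["N"])}
        drop = tuple(all_names - set(spec["blocks"]))
        if spec["mode"] == "temporal":
            lay = temporal_layout(s_in, s_out, assume_zero=drop)
        else:
            lay = spatiotemporal_layout(s_in, s_out, spec["N"], spec["tie_symmetric"], assume_zero=drop)
        return MeasurementSystem.from_arrays(lay, z["q"], z["u_rs"], z["w_rs"], [tuple(m) for m in z["meta"]])


def kernel_table_csv(path, obj: Kernel1 | Kernel2) -> None:
    """Coefficient table: columns l1, l2 (blank for first-order), real, imag."""
    L = obj.space.L
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        if isinstance(obj, Kernel2):
            w.writerow(["l1", "l2", "real", "imag"])
            ten = obj.tensor
            for i1 in range(obj.space.dim):
                for i2 in range(obj.space.dim):
                    c = ten[i1, i2]
                    w.writerow([i1 - L, i2 - L, f"{c.real:.17g}", f"{c.imag:.17g}"])
        else:
            w.writerow(["l", "real", "imag"])
            for i, c in enumerate(obj.coeffs):
                w.writerow([i - L, f"{c.real:.17g}", f"{c.imag:.17g}"])
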