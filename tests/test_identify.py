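"""Nuclear-norm identification: metrics, reconstruction, recovery."""

import numpy as np
import pytest

from divnorm.examples import random_stimuli, simulate_trials
from divnorm.identify import (
    IdentConfig,
    assemble_c1_C2,
    reconstruct_kernels,
    snr_db,
    solve_spatiotemporal,
    solve_system,
    solve_temporal,
)
from divnorm.measurement import build_spatiotemporal_system, build_temporal_system, temporal_layout
from divnorm.spaces import make_space

from conftest import toy_dnp


class TestSnrDb:
    def test_exact_match_caps(self):
        x = np.arange(5.0)
        assert snr_db(x, x) == 300.0

    def test_zero_estimate_is_zero_db(self):
        x = np.arange(1.0, 4.0)
        assert snr_db(x, np.zeros_like(x)) == pytest.approx(0.0)

    def test_relative_error_1e3_is_60db(self):
        x = np.array([1.0, 0.0])
        e = np.array([1.0 - 1e-3, 0.0])
        assert snr_db(x, e) == pytest.approx(60.0, abs=1e-9)

    def test_zero_truth_raises(self):
        with pytest.raises(ValueError):
            snr_db(np.zeros(3), np.ones(3))


class TestReconstruction:
    def test_roundtrip_through_c1_C2(self, toy, toy_system):
        lay = toy_system.layout
        vals = lay.decode(toy_system.encode_model(toy))
        c1, C2 = assemble_c1_C2(vals, lay)
        d = lay.space_in.dim
        assert c1.shape == (1 + 2 * d + lay.space_out.dim,)
        kern = reconstruct_kernels(c1, C2, lay)
        assert np.max(np.abs(kern["h11"].coeffs - toy.T1.h1.coeffs)) < 1e-12
        assert np.max(np.abs(kern["H23"].coeffs - toy.T3.h2.coeffs)) < 1e-12
        assert kern["b1"] == pytest.approx(toy.T1.b)

    def test_unit_entry_maps_to_basis_product(self):
        """A single unit entry at (l1+L, L-l2) reconstructs e_{l1}(t1) e_{l2}(t2)."""
        s = make_space(2, 20 * np.pi)
        lay = temporal_layout(s, s)
        d = s.dim
        C2 = np.zeros((2 * d + d, 2 * d), dtype=complex)
        l1, l2 = 1, -2
        C2[l1 + s.L, s.L - l2] = 1.0  # inside the H21 block
        kern = reconstruct_kernels(np.zeros(1 + 3 * d), C2, lay)
        t1, t2 = 0.013, 0.047
        e = s.basis_matrix(np.array([t1]))[0][l1 + s.L] * s.basis_matrix(np.array([t2]))[0][l2 + s.L]
        assert complex(kern["H21"](t1, t2)) == pytest.approx(e, abs=1e-12)


class TestSolveTemporal:
    def test_dense_regime_matches_least_squares_oracle(self, toy, toy_trials, toy_system):
        """With more measurements than unknowns the solution equals dense LS."""
        th_ls, *_ = np.linalg.lstsq(toy_system.G, toy_system.q, rcond=1e-10)
        res = solve_temporal(toy_system, IdentConfig(max_iter=800), truth=toy_system.encode_model(toy))
        assert np.linalg.norm(res.theta - th_ls) <= 1e-6 * max(1.0, np.linalg.norm(th_ls))

    def test_structural_constraints_at_solution(self, toy, toy_system):
        res = solve_temporal(toy_system, IdentConfig(max_iter=400))
        rep = res.constraint_report
        assert rep["zero_blocks"] == 0.0
        for nm in ("H21", "H22", "H23"):
            assert rep[f"hermitian_{nm}"] <= 1e-8
        assert rep["slack_mean"] <= 1e-8
        # the assembled full C2 carries the structural zeros explicitly
        d, do = toy_system.layout.space_in.dim, toy_system.layout.space_out.dim
        assert np.all(res.C2_hat[: 2 * d, d:] == 0)
        assert np.all(res.C2_hat[2 * d :, :d] == 0)

    def test_recovers_toy_circuit(self, toy, toy_system):
        res = solve_temporal(toy_system, IdentConfig(max_iter=800), truth=toy_system.encode_model(toy))
        assert min(res.snr.values()) >= 60.0
        assert res.ranks == {"H21": 1, "H22": 1, "H23": 1}

    def test_mode_mismatch_raises(self, toy_system):
        with pytest.raises(ValueError):
            solve_spatiotemporal(toy_system)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            IdentConfig(lambda1=-1.0)


class TestNuclearNormObjective:
    def test_relaxing_symmetry_never_increases_optimum(self, toy_trials):
        """Dropping the exchange-symmetry constraint can only lower the
        nuclear-norm optimum (larger feasible set)."""
        from divnorm.identify import _Stack, _admm
        from divnorm.measurement import Block, Layout, MeasurementSystem

        sys_con = build_temporal_system(toy_trials)
        lay = sys_con.layout
        relaxed_blocks = []
        for b in lay.blocks:
            struct = "centro" if b.kind == "k2" else b.structure
            relaxed_blocks.append(Block(b.name, b.kind, b.space, struct))
        lay_rel = Layout(lay.mode, lay.N, lay.space_in, lay.space_out, relaxed_blocks)
        sys_rel = MeasurementSystem(lay_rel, toy_trials)
        cfg = IdentConfig(max_iter=1500, polish=False)

        def objective(sysm):
            theta, stacks, Z, eps, *_ = _admm(sysm, cfg)
            nn = sum(np.linalg.svd(z, compute_uv=False).sum() for z in Z)
            return nn

        assert objective(sys_rel) <= objective(sys_con) + 1e-3


class TestSpatioTemporal:
    def test_null_feedback_recovery(self, toy):
        """Data from a circuit with zero MVP identifies ~zero feedback kernels."""
        from divnorm.simulate import SpatioTemporalDNP
        from divnorm.volterra import MVP

        s = toy.space_in
        mvp = MVP(N=2, b4=0.0, space=s)
        model = SpatioTemporalDNP(2, toy.T1, toy.T2, toy.T3, mvp, s, s)
        stims = [random_stimuli(s, 2, 0.3, 300 + m) for m in range(14)]
        tr = simulate_trials(model, stims, T=6, grid=672)
        sysm = build_spatiotemporal_system(tr, tie_symmetric=False)
        res = solve_spatiotemporal(sysm, IdentConfig(max_iter=800))
        biggest = max(np.linalg.norm(np.atleast_1d(v)) for v in res.values.values())
        for i in range(2):
            for j in range(2):
                fb = np.linalg.norm(res.values[f"H24_{i + 1}_{j + 1}"])
                assert fb <= 1e-6 * biggest

    def test_reduced_scale_recovery(self):
        """Two-channel circuit with rank-1 feedback kernels, full recovery."""
        from divnorm.examples import example3_model

        model = example3_model(N=2)
        stims = [random_stimuli(model.space_in, 2, 1.0, 500 + m) for m in range(20)]
        tr = simulate_trials(model, stims, T=8)
        sysm = build_spatiotemporal_system(
            tr, tie_symmetric=True, assume_zero=("h13", "H21", "H22", "H23")
        )
        res = solve_spatiotemporal(sysm, IdentConfig(max_iter=800), truth=sysm.encode_model(model))
        assert min(res.snr.values()) >= 40.0
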