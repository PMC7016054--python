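"""Generalized-sampling assembly: layouts, dimensions, residual oracles."""

import numpy as np
import pytest

from divnorm.examples import example3_model, random_stimuli, simulate_trials
from divnorm.measurement import (
    TrialSet,
    build_spatiotemporal_system,
    build_temporal_system,
    count_unknowns,
    spatiotemporal_layout,
    temporal_layout,
)
from divnorm.spaces import make_space

from conftest import toy_dnp


def _dummy_trials(space_in, space_out, M=2, T=2, N=1, seed=0):
    """Synthetic trials (random responses) for pure dimension checks."""
    rng = np.random.default_rng(seed)
    stims = [random_stimuli(space_in, N, 1.0, rng) for _ in range(M)]
    n = max(8 * max(space_in.dim, space_out.dim), 64)
    resp = rng.standard_normal((M, N, n))
    tk = np.arange(T) * space_in.S / T
    return TrialSet(space_in, space_out, stims, resp, space_in.grid(n), tk)


class TestDimensions:
    def test_phi_first_entry_is_one(self, toy_system):
        phi = toy_system.phi_vector(0, 0, 0)
        assert phi[0] == 1.0

    @pytest.mark.parametrize("L,Lo", [(2, 2), (3, 1), (1, 4), (5, 3)])
    def test_temporal_phi_xi_shapes(self, L, Lo):
        s_in = make_space(L, 10 * np.pi * max(L, 1))
        s_out = make_space(Lo, 2 * np.pi * Lo / s_in.S) if Lo else s_in
        tr = _dummy_trials(s_in, s_out)
        sysm = build_temporal_system(tr)
        assert sysm.phi_vector(0, 0, 0).shape == (4 * L + 2 * Lo + 4,)
        assert sysm.xi_matrix(0, 0, 0).shape == (4 * L + 2 * Lo + 3, 2 * L + 2 * Lo + 2)

    @pytest.mark.parametrize("L,Lo,N", [(2, 2, 2), (3, 2, 3), (2, 3, 4)])
    def test_spatiotemporal_phi_shape(self, L, Lo, N):
        s_in = make_space(L, 10 * np.pi * L)
        s_out = make_space(Lo, 2 * np.pi * Lo / s_in.S)
        tr = _dummy_trials(s_in, s_out, N=N)
        sysm = build_spatiotemporal_system(tr)
        assert sysm.phi_vector(0, 0, 0).shape == (4 * L + 2 * (N + 1) * Lo + N + 4,)
        assert sysm.xi_matrix(0, 0, 0).shape == (
            4 * L + 2 * (N * N + 1) * Lo + N * N + 3,
            2 * L + 2 * Lo + 2,
        )

    def test_example3_phi_length(self):
        # N=4, L=Lo=8: 32 + 2*5*8 + 4 + 4 = 120
        s = make_space(8, 40 * np.pi)
        tr = _dummy_trials(s, s, N=4)
        sysm = build_spatiotemporal_system(tr)
        assert sysm.phi_vector(0, 0, 0).shape == (120,)

    def test_sample_time_out_of_range(self):
        s = make_space(2, 20 * np.pi)
        with pytest.raises(ValueError, match="sample times"):
            _tr = TrialSet(s, s, [[x] for x in random_stimuli(s, 1, 1.0, 0)],
                           np.zeros((1, 1, 64)), s.grid(64), np.array([s.S * 1.5]))

    def test_low_trial_count_warns(self):
        s = make_space(3, 30 * np.pi)
        with pytest.warns(UserWarning, match="below the dense-solvability bound"):
            build_temporal_system(_dummy_trials(s, s, M=2))


class TestResidualOracle:
    def test_temporal_truth_satisfies_system(self, toy, toy_system):
        """Sampling-identity residual oracle: true coefficients reproduce q exactly."""
        theta = toy_system.encode_model(toy)
        assert toy_system.residual(theta) <= 1e-6

    def test_zero_stimulus_zero_b1(self):
        toy = toy_dnp()
        s = toy.space_in
        from divnorm.simulate import TemporalDNP
        from divnorm.volterra import VolterraProcessor

        dnp = TemporalDNP(
            VolterraProcessor(b=0.0, h1=toy.T1.h1, h2=toy.T1.h2, space_in=s),
            toy.T2,
            toy.T3,
            s,
            s,
        )
        zero = random_stimuli(s, 1, sigma=0.0, seed=0)
        tr = simulate_trials(dnp, zero, T=5, grid=640)
        sysm = build_temporal_system(tr)
        assert np.max(np.abs(sysm.q)) == 0.0
        b = sysm.layout.get("h11")
        assert np.max(np.abs(sysm.W[:, b.entry_off : b.entry_off + b.n_entries])) == 0.0

    def test_spatiotemporal_truth_satisfies_system(self):
        model = example3_model()
        stims = [random_stimuli(model.space_in, 4, 1.0, 100 + m) for m in range(3)]
        tr = simulate_trials(model, stims, T=5)
        for tie in (False, True):
            sysm = build_spatiotemporal_system(tr, tie_symmetric=tie)
            theta = sysm.encode_model(model)
            assert sysm.residual(theta) <= 1e-6

    def test_overdetermined_consistency(self, toy):
        """More samples than the dense bound leave the LS solution unchanged."""
        stim = random_stimuli(toy.space_in, 30, sigma=0.3, seed=5)
        tr1 = simulate_trials(toy, stim, T=12, grid=960)
        tr2 = simulate_trials(toy, stim, T=16, grid=960)
        th1, *_ = np.linalg.lstsq(build_temporal_system(tr1).G, build_temporal_system(tr1).q, rcond=1e-10)
        sys2 = build_temporal_system(tr2)
        th2, *_ = np.linalg.lstsq(sys2.G, sys2.q, rcond=1e-10)
        scale = np.linalg.norm(th1)
        assert np.linalg.norm(th1 - th2) <= 1e-8 * max(1.0, scale)


class TestCountUnknowns:
    def test_full_order_dense_requirement(self):
        assert count_unknowns(10, 10) == 1387

    def test_degenerate_orders(self):
        assert count_unknowns(0, 0) == 7

    def test_tied_spatiotemporal_matches_block_enumeration(self):
        got = count_unknowns(8, 8, N=4, mode="spatiotemporal", tie_symmetric=True)
        # oracle: enumerate layout blocks and sum their complex entry counts
        s = make_space(8, 40 * np.pi)
        lay = spatiotemporal_layout(s, s, 4, tie_symmetric=True)
        total = 0
        for b in lay:
            d = (s if b.space == "in" else s).dim
            total += 1 if b.kind == "scalar" else (d if b.kind == "k1" else d * d)
        assert got == total == 1 + 2 * 17 + 17 + 4 * 17 + 2 * 289 + 289 + 10 * 289

    def test_invalid(self):
        with pytest.raises(ValueError):
            count_unknowns(-1, 0)
        with pytest.raises(ValueError):
            count_unknowns(1, 1, mode="bogus")


class TestLayout:
    def test_encode_decode_roundtrip(self, toy, toy_system):
        theta = toy_system.encode_model(toy)
        vals = toy_system.layout.decode(theta)
        assert np.max(np.abs(vals["h11"] - toy.T1.h1.coeffs)) < 1e-12
        assert np.max(np.abs(vals["H21"] - toy.T1.h2.coeffs)) < 1e-12
        assert vals["b1"] == pytest.approx(toy.T1.b)

    def test_assume_zero_drops_blocks(self):
        s = make_space(3, 30 * np.pi)
        lay = temporal_layout(s, s, assume_zero=("h13", "H23"))
        names = [b.name for b in lay]
        assert "h13" not in names and "H23" not in names
        assert "H21" in names

    def test_structured_parametrizations_satisfy_their_symmetries(self):
        s = make_space(4, 40 * np.pi)
        lay = spatiotemporal_layout(s, s, 2, tie_symmetric=True)
        rng = np.random.default_rng(0)
        vals = lay.decode(rng.standard_normal(lay.n_params))
        for nm in ("H21", "H22", "H23", "H24_1_1"):
            H = vals[nm]
            assert np.max(np.abs(H - H.conj().T)) < 1e-12  # Hermitian
            assert np.max(np.abs(H - H[::-1, ::-1].T)) < 1e-12  # persymmetric
        H = vals["H24_1_2"]  # real kernel, possibly asymmetric
        assert np.max(np.abs(H - np.conj(H[::-1, ::-1]))) < 1e-12
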