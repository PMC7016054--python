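"""scikit-learn style estimators for DNP identification.

The identification problem is fit-shaped: given stimulus/response trials
(`X` = a :class:`~divnorm.measurement.TrialSet`), ``fit`` recovers every
circuit component; ``predict`` simulates the identified circuit on new
stimuli; ``score`` returns the mean recovery SNR against a reference model
(or, without one, the negative measurement residual).  Both estimators are
plain ``BaseEstimator`` subclasses, so ``get_params``/``set_params``,
cloning and grid search compose in the usual way.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .identify import IdentConfig, IdentResult, solve_system
from .measurement import TrialSet, build_spatiotemporal_system, build_temporal_system
from .simulate import SpatioTemporalDNP, TemporalDNP, simulate_spatiotemporal, simulate_temporal
from .volterra import MVP, VolterraProcessor

__all__ = ["TemporalDNPIdentifier", "SpatioTemporalDNPIdentifier"]


class _BaseIdentifier(BaseEstimator):
    def __init__(
        self,
        lambda1: float = 1e-3,
        lambda2: float | None = None,
        rho: float = 1.0,
        max_iter: int = 1500,
        polish: bool = True,
        rank_tol: float = 1e-6,
        max_rank_rounds: int = 2,
        assume_zero: tuple = (),
    ):
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.rho = rho
        self.max_iter = max_iter
        self.polish = polish
        self.rank_tol = rank_tol
        self.max_rank_rounds = max_rank_rounds
        self.assume_zero = assume_zero

    def _config(self) -> IdentConfig:
        return IdentConfig(
            lambda1=self.lambda1,
            lambda2=self.lambda2,
            rho=self.rho,
            max_iter=self.max_iter,
            polish=self.polish,
            rank_tol=self.rank_tol,
            max_rank_rounds=self.max_rank_rounds,
        )

    def _post_fit(self, system, truth_model) -> None:
        truth = system.encode_model(truth_model) if truth_model is not None else None
        res: IdentResult = solve_system(system, self._config(), truth=truth)
        self.system_ = system
        self.result_ = res
        self.kernels_ = res.kernels
        self.c1_ = res.c1_hat
        self.C2_ = res.C2_hat
        self.ranks_ = res.ranks
        self.snr_ = res.snr

    def score(self, X: TrialSet | None = None, y=None) -> float:
        """Mean recovery SNR (dB) if fitted with a reference model, else
        the negative measurement residual of the fit."""
        if self.snr_:
            return float(np.mean(list(self.snr_.values())))
        return -self.result_.measurement_residual

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "result_")


class TemporalDNPIdentifier(_BaseIdentifier):
    """Identify a single-photoreceptor (temporal) DNP from trials.

    Parameters mirror :class:`~divnorm.identify.IdentConfig`;
    ``assume_zero`` lists unknown blocks known to vanish (e.g.
    ``("h13", "H23")`` for a feedforward-only circuit).

    Attributes (after ``fit``): ``kernels_``, ``c1_``, ``C2_``, ``ranks_``,
    ``result_``, ``model_`` (a simulatable :class:`TemporalDNP`).
    """

    def fit(self, X: TrialSet, y=None, truth_model: TemporalDNP | None = None):
        system = build_temporal_system(X, assume_zero=self.assume_zero)
        self._post_fit(system, truth_model)
        k = self.kernels_
        # any b2/b3 split with b2+b3=1 yields the same denominator constant
        T1 = VolterraProcessor(b=k["b1"], h1=k["h11"], h2=k["H21"], space_in=X.space_in)
        T2 = VolterraProcessor(b=1.0, h1=k["h12"], h2=k["H22"], space_in=X.space_in)
        T3 = VolterraProcessor(b=0.0, h1=k["h13"], h2=k["H23"], space_in=X.space_out)
        self.model_ = TemporalDNP(T1, T2, T3, X.space_in, X.space_out)
        return self

    def predict(self, X, grid=None, tol: float = 1e-10) -> np.ndarray:
        """Simulate the identified circuit on stimuli (list of Signals)."""
        return np.array([simulate_temporal(self.model_, u, grid=grid, tol=tol).v for u in X])


class SpatioTemporalDNPIdentifier(_BaseIdentifier):
    """Identify an N-channel DNP (shared T1..T3 plus amacrine MVP).

    ``tie_symmetric`` declares the pairwise symmetry h2_ij4 = h2_ji4 and
    halves the number of quadratic feedback unknowns.
    """

    def __init__(
        self,
        lambda1: float = 1e-3,
        lambda2: float | None = None,
        rho: float = 1.0,
        max_iter: int = 1500,
        polish: bool = True,
        rank_tol: float = 1e-6,
        max_rank_rounds: int = 2,
        assume_zero: tuple = (),
        tie_symmetric: bool = False,
    ):
        super().__init__(lambda1, lambda2, rho, max_iter, polish, rank_tol, max_rank_rounds, assume_zero)
        self.tie_symmetric = tie_symmetric

    def fit(self, X: TrialSet, y=None, truth_model: SpatioTemporalDNP | None = None):
        system = build_spatiotemporal_system(X, tie_symmetric=self.tie_symmetric, assume_zero=self.assume_zero)
        self._post_fit(system, truth_model)
        k = self.kernels_
        N = X.N
        T1 = VolterraProcessor(b=k["b1"], h1=k["h11"], h2=k["H21"], space_in=X.space_in)
        T2 = VolterraProcessor(b=1.0, h1=k["h12"], h2=k["H22"], space_in=X.space_in)
        T3 = VolterraProcessor(b=0.0, h1=k["h13"], h2=k["H23"], space_in=X.space_out)
        h1_list = [k[f"h14_{i + 1}"] for i in range(N)]
        from .spaces import Kernel2

        h2 = [[None] * N for _ in range(N)]
        for i in range(N):
            for j in range(N):
                nm = f"H24_{i + 1}_{j + 1}"
                if nm in k:
                    h2[i][j] = k[nm]
                else:
                    # tied pair: h2_ji(t1,t2) = h2_ij(t2,t1), i.e. the
                    # conjugate-transposed coefficient matrix
                    src = k[f"H24_{j + 1}_{i + 1}"]
                    h2[i][j] = Kernel2(src.space, src.coeffs.conj().T)
        mvp = MVP(N=N, b4=0.0, h1_list=h1_list, h2_grid=h2, space=X.space_out)
        self.model_ = SpatioTemporalDNP(N, T1, T2, T3, mvp, X.space_in, X.space_out)
        return self

    def predict(self, X, grid=None, tol: float = 1e-10) -> np.ndarray:
        """Simulate the identified circuit on per-trial stimulus lists."""
        return np.array([simulate_spatiotemporal(self.model_, stim, grid=grid, tol=tol).v for stim in X])
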