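# Methods

This note records the model conventions, numerical choices and known
limitations of the package, in the spirit of a statistical-software
methods appendix.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal model

Stimuli and kernels are elements of finite-dimensional spaces of
trigonometric polynomials: `u(t) = Σ_{l=-L}^{L} a_l e_l(t)` with
`e_l(t) = exp(i l ω₀ t)/√S`, `ω₀ = Ω/L = 2π/S`.  `Ω` (rad/s) is the
bandwidth, `L` the order, `S = 2πL/Ω` the period; the dimension is
`2L+1`.  The basis is orthonormal under the plain `L²[0,S]` inner
product `⟨f,g⟩ = ∫ f ḡ dt` (conjugate-linear in the second argument), so
the reproducing kernel is `K₁(t;t') = Σ_l e_l(t) ē_l(t')` and evaluation,
inner products and projections are coefficient-vector operations.  A
commonly printed variant of this kernel, `Σ_l e_l(t−t')`, equals `√S`
times the orthonormal-basis kernel; we use the orthonormal form because
it is the one for which the reproducing property and projection
idempotence hold exactly (both are asserted in the test suite).

Real-valued signals have conjugate-symmetric coefficients
(`a_{−l} = ā_l`).  Second-order kernels live in the tensor square; their
coefficient matrices are stored in the *reconstruction index map* — entry
`(l₁+L, L−l₂)` (0-based) multiplies `e_{l₁}(t₁)e_{l₂}(t₂)` — under which
a real, exchange-symmetric kernel is a Hermitian matrix whose
eigendecomposition is exactly the separable expansion
`h₂ = Σ_k λ_k g_k(t₁)g_k(t₂)`, and whose rank is the number of terms.

## Forward model and fixed-point solver

The temporal circuit is `v = T¹u / (T²u + T³v)` with second-order
Volterra processors `Tˡ`; the spatio-temporal circuit adds the shared
multi-input amacrine block `L⁴v` to every denominator.  All integrals are
over one period with circular convolution semantics.  The output of a
divisive circuit is not band-limited, so trajectories are represented as
samples on a dense uniform grid (default 16·(2L+1) points, configurable;
the shipped experiments use ≥ 2048).  Before entering the feedback paths
the trajectory is orthogonally projected onto the output space `H₁ᵒ`;
because the feedback kernels live in `H₁ᵒ`/`H₂ᵒ` and periodic signals
have lattice spectra, this projection does not change the feedback
response — it only keeps the feedback state finite-dimensional.

The implicit equation is solved per trajectory: damped Picard iteration
(`v ← (1−θ)v + θ·num/den`, θ halved on oscillation) warms up an exact
Newton solve of `R(v) = v·den(v) − num`.  The Jacobian is diagonal plus a
rank-`2N(2Lᵒ+1)` correction (feedback enters only through the projected
coefficients), so Newton steps are solved exactly with the Woodbury
identity; convergence is quadratic and the returned diagnostic is the
worst-case residual `max_t |v·den − num|` (tolerance 1e−12 by default,
1e−13 in the shipped experiments).  Two failure modes are detected and
raised rather than patched: denominator values below 1e−9 (the model
assumes a bounded-input bounded-output circuit, not a positive
denominator, so we fail loudly instead of producing poles) and
non-convergence within the iteration budget.

## Measurement assembly

Sampling `v·(T²u + T³v + L⁴v) = T¹u` at `t_k` under the normalization
`b² + b³ (+ b⁴) = 1` gives one linear equation per sample in all
kernels, with sampling functions built from reversed shifts `u(t_k − t)`
and `(P₁ᵒv)(t_k − t)`, the second-order ones being their outer products,
scaled by `−q = −v(t_k)`.  Sample times default to a uniform grid over
one period chosen to lie on the dense simulation grid, so `q` is an
exact sample read (off-grid times fall back to trigonometric
interpolation of the smooth periodic trajectory).

Two identifiability facts shape the assembly:

- **Only symmetric kernels are identifiable.**  The stimulus products
  `u(t−s₁)u(t−s₂)` are exchange-symmetric, so the antisymmetric part of
  any second-order kernel is invisible to every possible measurement
  (an exact `d(d−1)/2`-dimensional nullspace per kernel, verified
  numerically).  The package therefore parametrizes the symmetric
  second-order kernels by Hermitian **and** persymmetric matrices — the
  matrix form of a real exchange-symmetric kernel, i.e. the unique
  symmetric representative.  Feedback kernels `h₂ⁱʲ⁴` may be asymmetric
  between channels and keep full centro-Hermitian (real-kernel) freedom;
  the diagonal pairs `(i,i)` act on a single channel and are symmetric
  like the others.  Reality is likewise built in (conjugate-symmetric
  vectors), since reality-violating directions contribute nothing to any
  real measurement.  With these parametrizations the Hermitian
  constraints of the identification algorithm hold by construction, and
  the nuclear-norm program has no structural nullspace.
- **Per-cell sample times must differ.**  The amacrine feedback `L⁴v` is
  common to all channels, so sampling every cell at the same times
  probes the same feedback functional repeatedly and leaves an exact
  model degeneracy (verified numerically: zero-residual solutions with
  wrong feedback kernels).  Multi-channel experiments therefore stagger
  sample times across cells, `t_k⁽ⁿ⁾ = (k + n/N)·S/T`, giving `N·T`
  distinct probe times per trial.

Untied `(i,j)/(j,i)` feedback pairs carry one more exact invariance: the
data see only `H^{ij} + (H^{ji})ᴴ`.  After solving, the package reports
the balanced (minimum-Frobenius) representative of each pair; this never
changes the fit.

Plugging a ground-truth model's coefficients into the assembled system
(the *residual oracle*) validates every convention — conjugations, index
maps, `−q` scalings — at once; the test suite requires residual ≤ 1e−6
at full benchmark scale and observes ~1e−9 (temporal, limited by
out-of-band aliasing of the dense grid) and ~1e−14 (spatio-temporal).

## Identification solver

The convex stage minimizes `‖C₂‖* + λ₁‖c₁‖² + λ₂‖ε‖₂` subject to the
measurement equalities with zero-mean slack.  Choices:

- Structural zero blocks of `C₂` are never created as variables; this
  also splits the nuclear norm over the two column blocks (the stacks
  `[H₂¹; H₂²]` and `[H₂³; H₂ⁱʲ⁴…]`), which the ADMM splitting exploits.
  Tied feedback pairs contribute their conjugate-transposed copy to the
  stack so its nuclear norm equals that of the full `C₂`.
- `λ₁ = 1e−3` (ridge on `c₁`; the squared norm keeps the ADMM θ-update a
  single Cholesky solve).  `λ₂` defaults to `1e6·max|q|`: on noise-free
  data this makes the equalities effectively hard — the slack prox
  returns exactly zero — which matters because with a soft penalty the
  program measurably trades slack against nuclear norm and shrinks the
  weakly-sensed feedback kernels (their measurement columns scale like
  `q²`).  For noisy recordings `λ₂` should be lowered; it is a config
  field.
- ADMM: singular-value thresholding on the stacks, penalty ρ adapted by
  the standard primal/dual balancing rule, 1500–3000 iterations.

First-order convergence alone reaches roughly 40–80 dB.  The *polish*
stage then refines on the tight rank-`r` parametrization of each block —
`Σ_k λ_k p_k p_kᴴ` with conjugate-symmetric `p_k` and free real weights
for symmetric kernels (freezing the weight signs creates spurious local
minima), `Σ_k u_k v_kᴴ` for asymmetric ones — by trust-region
Gauss-Newton with analytic Jacobians (`scipy.optimize.least_squares`).
Ranks are grown greedily from one: each round seeds from the ADMM
iterate, from the min-norm dense backprojection, and from the previous
best fit augmented with the top eigen-direction of the
structure-projected residual gradient (greedy rank-one pursuit); rounds
stop when the relative measurement residual falls below 1e−11.  On
consistent data this reaches machine precision; reported kernel ranks use
a 1e−6 relative singular-value cutoff.

## Benchmark fixtures and study conditions

The synthetic fixtures define the conditions under which the method is
exercised; they are fixed, not tuned per run.

- **Temporal, full order** (`example1_model`): order-10 spaces at
  `Ω = 100π` (period 0.2 s, 21 coefficients, 441 per second-order
  kernel).  Six gamma-cosine kernels (`t³e^{−100πt}cos ωt` envelopes)
  with printed amplitudes; every second-order kernel is a sum of two
  separable terms (rank 2).  The constants are not part of the published
  set; the fixture uses `b¹ = 0`, `b² = b³ = 0.5`.  Stimulus coefficient
  scale σ = 0.05: at these kernel amplitudes the circuit loses its
  stable fixed point for σ ≳ 0.1 (0/100 trial failures at 0.05, first
  failures at 0.1), and the identification model assumes the circuit is
  BIBO stable.  At this σ the 25×17-sample budget is *not* sufficient
  for nuclear-norm recovery — the program has exact-fit solutions with
  nuclear norm ~3× smaller than the truth's — so the shipped
  `example1_full` scenario samples T = 41 times per trial (1025
  measurements, 74% of the 1387 dense unknowns), where recovery is
  exact.  The stimulus scale, constants, sample placement, solver and
  regularization weights of the original experiment are unknown, so the
  smaller historical budget cannot be checked against a complete
  specification.
- **Temporal, reduced order** (`example1_scaled_model`): order-5 spaces,
  same gamma-cosine component profiles, but with balanced rank-2
  weights (second component ~0.3 of the first) and O(1) kernel norms;
  σ = 0.3.  This is the regime the sparsity premise describes — every
  retained separable component carries identifiable energy — and the
  benchmark for recovery at 44% of the dense unknown count (25 stimuli ×
  7 samples = 175 of 397).  Recovery was verified across independent
  stimulus seeds before the scenario seed was fixed.
- **Spatio-temporal** (`example3_model`): four channels, `Ω = Ωᵒ = 40π`,
  period 0.4 s (order 8, 17 coefficients per filter).  Shared
  `h₁¹ = h₁² = 25te^{−25t}`, feedback filters
  `h₁ⁱ⁴ = e^{−(i−2)²/4}(25−600t)e^{−25t}` and rank-one
  `h₂ⁱʲ⁴ = 5000·e^{−(i−2)²/4}e^{−(j−2)²/4}(25t₁e^{−25t₁})(25t₂e^{−25t₂})`
  with `h₂ⁱʲ⁴ = h₂ʲⁱ⁴`; all other kernels zero, `b² = 1`.  With the
  known zero/symmetry structure the identification solves for six linear
  and ten quadratic filters from 31 trials × 9 staggered samples × 4
  cells = 1116 measurements.  σ = 1.0 (wide stability margin).

The stimulus generator draws i.i.d. complex-Gaussian basis coefficients
(`E|a_l|² = σ²`) with conjugate-symmetric completion.  What the
synthetic data do *not* model: measurement noise, trial-to-trial
variability, non-periodic stimuli, and model mismatch (recorded kernels
outside the chosen spaces).  Passing benchmarks therefore demonstrate
correctness of the estimator under its own assumptions, not robustness
to real recording artifacts; the slack term and configurable `λ₂` are
the intended entry point for noisy data.

## Numerical conventions

- Projections from callables use the periodic trapezoid rule (≥ 32×
  the space dimension; spectrally convergent for smooth periodic
  integrands); separable kernels are projected factor-by-factor.
- Aliasing guard: projections from samples require ≥ 8 points per
  coefficient.
- Degenerate inputs: zero-norm truth has no SNR (raises); empty
  component lists build zero kernels only with an explicit space; the
  constant-only space `L = 0` requires an explicit period.
- Recovery SNR `10·log₁₀(‖truth‖²/‖truth−estimate‖²)` is capped at
  300 dB for numerically exact matches.
- All randomness flows through seeded `numpy` generators; scenario
  regeneration is bit-identical for a given seed.

## Known limitations

- No third- or higher-order Volterra terms; no spatio-temporal kernels
  inside the per-channel processors.
- No noise model in the forward simulator; identification of noisy data
  is supported only through the slack term.
- Stability is detected, not analyzed: the solver reports
  non-convergence or denominator degeneracy but offers no stability
  margins.
- The gain-control demonstration (`dnp demo gain-control`) is
  qualitative: it shows the response-curve shift with background
  intensity and the compression of output RMS contrast using the
  spatio-temporal fixture, whose parameters are illustrative.
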