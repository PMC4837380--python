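# Methods

## Model

Each of N nodes of an undirected simple graph carries s_i ∈ {0, 1}. In
continuous time, a node of degree k_i flips to the opposite state at
rate

    π_i = a + (h / k_i) · #{j ∈ nn(i) : s_j ≠ s_i},

i.e. spontaneous switching at rate `a` per direction plus voter-model
copying at rate `h` per unit fraction of disagreeing neighbours. Both
rates have units of inverse time; only a/h matters up to a rescaling of
time, and the numerical work fixes h = 1. At a = 0 the homogeneous
configurations are absorbing (pure voter model); for a > 0 the chain is
ergodic and time averages equal ensemble averages. The global
observables are n = Σ_i s_i and the interface density ρ (fraction of
edges with disagreeing endpoints, computed on the actual adjacency).

Two fixed points of the transcription are worth stating because they
pin all prefactor conventions:

* on the complete graph the induced birth–death chain on n is exactly
  uniform at a = h/(N−1) — matching the mean-field critical point
  a_c = h/N to first order (the `exact` module verifies this by
  detailed balance, and the test suite gates on it);
* with h = 0 each node is an independent two-state flipper with
  relaxation rate 2a, so the autocorrelation of n decays as e^(−2aτ).

## Annealed approximation

For uncorrelated configuration-ensemble graphs below the structural
cutoff (k_max ≤ √(μ_k N)), the adjacency is replaced by connection
probabilities w_ij = k_i k_j/(N μ_k). Row sums preserve the degrees
(up to the excluded self-term k_i²/(N μ_k) under the zero-diagonal
convention adopted here; analytic whole-network sums keep the
self-term, which is O(1/N) and immaterial at that order). Under this
replacement every node sees the same degree-weighted magnetization
M = Σ_j k_j s_j / (N μ_k), and the moment hierarchy closes.

Writing c_j = k_j/(N μ_k), the stationary pair covariances solve
σ_ij = φ_i + φ_j (i ≠ j) with

    φ_j = h (Φ + c_j/4) / (4a + h + 2 h c_j),    Φ = Σ_j c_j φ_j.

This scalar self-consistency is implemented verbatim in
`theory.variance_st_annealed_exact` (it needs the full degree
sequence) and serves as the internal oracle for the closed forms,
which expand the denominators to first order in c_j and keep degree
information only through μ_k and γ = σ_k²/μ_k². With β = 4a + h and
Δ = 4aNβ + 2h²(1+γ):

* Var_st[n] = N/4 + 2(N−1) h (Φ E₀ + E₁/4), Φ = hβ(1+γ)/(4Δ),
  E₀ = (Nβ−2h)/β², E₁ = (Nβ−2h(1+γ))/(Nβ²). The existence condition
  is Δ > 0, true whenever h > 0 or a > 0; at a = 0 exactly the voter
  limit N²/4 is returned with a non-stationarity flag rather than an
  error, since only ergodicity (not the formula's algebra) breaks
  there.
* Asymptotic branches: N²h²(1+γ)/(2Δ) for aN = O(√N) or smaller
  ("small a"), and (N/4)(1 + 2h/β + h²(1+γ)/(2aβ)) for aN of order
  √N or larger ("large a"). The crossover a* minimizes
  |ln v_small − ln v_large| (coarse log-grid scan over
  a/h ∈ [10⁻⁶, 10³] plus bounded refinement, relative tolerance 10⁻⁶;
  the distance has no stated tolerance in the source material, so the
  tolerance is this package's convention). For γ = 0 the crossover
  scales as N^(−1/2).
* Critical point: solving v_small(a_c) = N(N+2)/12 (the variance of
  the discrete uniform distribution on 0..N) gives the closed form
  a_c = (h/8)[√(1 + 16(1+γ)(N−1)/(N(N+2))) − 1] ≈ (h/N)(1+γ). The
  exact quadratic root is kept rather than its first-order expansion;
  they differ at O(1/N²).
* Interface density: ⟨ρ⟩_st = 1/2 − hβ(1+γ)/Δ, obtained by evaluating
  the annealed expectation of ρ with the covariance solution and
  dropping O(1/N) terms (equivalently 1/2 − 2β·v_small/(hN²), i.e. it
  is a function of the small-a variance). Limits: 0 as a → 0, 1/2 as
  a → ∞, decreasing in γ at fixed a. The annealed graph erases local
  structure, so this prediction is known to disagree with simulation
  at intermediate a; tests only assert the limits and monotonicity.
* Autocorrelation: the annealed first-moment equations close on
  (m_i, M); M relaxes at exactly 2a and each m_i at 2a + h, so by the
  regression theorem K_st[n](τ) is exactly a sum of two exponentials.
  The slow amplitude is N·Cov_st(n, M) and the fast amplitude is the
  remainder:

      A_f = −(N−2) (hγ/β) (1/4 − h²(1+γ)/(2Δ)),    A_s = Var_st[n] − A_f.

  A_f vanishes iff γ = 0 and is otherwise *negative*: the normalized
  ACF runs parallel to e^(−2aτ) at long lags with an *upward* log
  offset log(A_s/Var) that grows with γ. The `s1` field of
  `AcfComponents` is −A_f, the (positive) weight the fast mode
  transfers to the slow one. The two-exponential form was checked to
  13 digits against the spectrally-computed ACF of the annealed
  process at N = 12, so within the annealed model it is exact, not
  itself an expansion.

Accuracy against the true dynamics: on complete graphs the closed-form
variance is within 0.5/N of the exact birth–death value over
N ∈ [4, 64] (frozen test constant); on the N = 5 star — a maximally
heterogeneous toy far outside the cutoff — it underestimates the exact
variance by a recorded 11.2%.

## Simulation

Event-driven (Gillespie) sampling of the exact continuous-time chain:
exponential waiting times from the total rate, node choice by a binary
sum tree over per-node rates (O(log N) draw and update; only the
flipped node and its neighbours change rate), numba-compiled.
Observables are read on a fixed grid with last value carried forward,
which is unbiased for time averages of a piecewise-constant process.
Stationary averages discard a transient of N time units and pool over
time and realizations; "one time unit" is the natural CTMC time, about
N update events. Seeding: a single integer seed feeds a SeedSequence;
the realization index enters the stream so ensembles are reproducible
element by element.

Network generators (networkx-backed except the dichotomous one): ER
with p = ⟨k⟩/(N−1) and whole-graph regeneration while any node is
isolated (the rates divide by k_i); BA with m = round(⟨k⟩/2) from a
complete seed of m+1 nodes; dichotomous graphs by configuration-model
stub matching in which invalid pairs (self-loops, duplicates) are
broken together with an equal number of random valid pairs and
re-matched until the graph is simple — this preserves the two-valued
degree sequence exactly (equal halves at k1 and k2); random-regular;
complete; periodic 2D lattice. The study conditions fix ⟨k⟩ = 8
(BA m = 4, dichotomous k1 = 4, k2 = 12, matching the dichotomous
moments μ_k = 8, σ_k² = 16 used throughout the examples). Realized
heterogeneities at N = 2500 are then ≈ 0.125 (ER), 0.25 (dichotomous)
and ≈ 1.5 (BA). Note the equal-halves construction bounds γ below 1,
so at matched mean degree the dichotomous ensemble cannot exceed the
BA ensemble's heterogeneity, and the closed-form critical-point ratio
dichotomous/ER, (1+γ_d)/(1+γ_ER) ≈ 1.11, is necessarily below 2 for
any k1, k2; a substantially larger ratio would require unequal group
sizes or a wider degree split than the equal-halves ensemble allows.

## Estimation and inference

The empirical ACF is computed per realization by FFT after subtracting
the known symmetry mean N/2 (avoiding fitted-mean bias), then pooled.
ACF errors are strongly correlated across lags — slow realization-level
fluctuations move whole stretches of the curve coherently — so
`fit_acf` fits the *increments* of log K between consecutive lags,
which cancels the common mode; weights are the across-realization
standard errors of those increments when an ensemble is supplied.
Lags enter the fit while the ACF estimate exceeds 3× its standard
error (the fitting window is this package's convention; the source
analysis does not state one). The model is the closed-form normalized
two-exponential shape with parameters (a, h, γ) and N known;
optimization is deterministic trust-region least squares from a small
fixed multi-start grid, with the slow-rate initializer taken from the
tail slope. The un-truncated closed form is fitted directly — it
reduces to either asymptotic branch in its regime — and the
small-a/large-a branch label is assigned afterwards by self-consistency
(â against the crossover a* implied by the fitted moments) rather than
by running two separate truncated fits; this keeps the noiseless
round-trip exact to machine precision. At γ = 0 the fast component is
absent, h drops out of the model, and the fit flags h as
unidentifiable instead of reporting a spurious value.

Monte-Carlo characteristics at the study conditions (dichotomous
γ = 0.25, a = 0.01, h = 1, N = 2500): the fast component carries under
1% of the ACF weight, so `a` and γ are recovered tightly while ĥ is
the noise-limited quantity, with run-to-run spread of order ±15–25% at
the 2×10⁶-time-unit ensemble of the acceptance protocol and a few
percent of downward bias (the real dynamics' fast relaxation is a band
of rates around 2a+h, not a single exponential). The dedicated
consistency test (N = 400, dichotomous 2/14, 20 replicates) checks the
median recoveries: a within 10%, γ within 30%.

Classification of the stationary distribution of n compares the sample
variance to N(N+2)/12 with a band of 3 standard errors of the variance
estimate (ties → uniform); the empirical critical point interpolates
the variance linearly in log a across that level.

## Known limitations

* All closed forms inherit the annealed (uncorrelated, cutoff-
  respecting) assumptions; they degrade on graphs with strong
  structural correlations (the star-graph regression quantifies this).
* ⟨ρ⟩_st is quantitatively wrong at intermediate a by construction.
* The closed forms truncate degree information at the second moment;
  third-moment corrections are O(⟨k³⟩/(N²μ³)) and unmodelled.
* ĥ inference from aggregate data alone is information-limited when
  γ is small; its uncertainty should be judged from replicate scatter,
  which `acf_ensemble` exposes.
* Exact master-equation solves are limited to N ≤ 12.
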