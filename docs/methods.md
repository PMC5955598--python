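# Methods

## Model

`filaturing` implements a three-species activator–inhibitor model of
heterocyst patterning on a filament of Ω cells.  Each cell i carries counts
of the master regulator HetR (r_i) and its two inhibitors PatS (s_i) and
HetN (n_i).  The chemistry per cell, with V the cell volume (the
demographic-noise control parameter) and h(x) = x²/(K² + x²) the dimeric
Hill response:

| channel | rate | note |
| --- | --- | --- |
| ∅ → R, S, N | α_R V, α_S V, α_N V | constitutive production |
| ∅ → R | β_R V h(r/V) | HetR positive autoregulation |
| ∅ → S | β_S V h(r/V) | HetR activates PatS |
| R, S, N → ∅ | k_R r, k_S s, k_N n | linear turnover |
| 2R + S → ∅ | μ_S r(r−1)s/V² | complex formation and degradation |
| 2R + N → ∅ | μ_N r(r−1)n/V² | idem for HetN |
| S_i → S_j, N_i → N_j | D_S s, D_N n per neighbour | inhibitor hopping |

HetR does not diffuse.  The V-scaling of the propensities is fixed by
requiring that the ensemble-mean drift reproduce, term by term as V → ∞,
the mean-field rate equations

    φ̇_i = α_R − k_R φ_i + β_R h(φ_i) − 2μ_S φ_i²ψ_i − 2μ_N φ_i²η_i
    ψ̇_i = α_S − k_S ψ_i + β_S h(φ_i) − μ_S φ_i²ψ_i + D_S (Δψ)_i
    η̇_i = α_N − k_N η_i − μ_N φ_i²η_i + D_N (Δη)_i

where Δ = W − diag(k) is the graph Laplacian of the open chain (interior
degree 2, end cells degree 1 — zero-flux boundaries).  The exact pair
count r(r−1) is used in the trimolecular propensities; the factor 2 in the
activator equation reflects the two HetR molecules consumed per complex.
This convention is asserted in the test suite by comparing the summed
channel drift with the ODE right-hand side and by checking ensemble-mean
convergence of SSA runs to the integrated ODE as V grows.

All quantities are dimensionless.  The default kinetic constants are
k_R = 0.2, α_R = 0.2, K = 2, k_S = 0.1, α_S = 0.1, μ_S = 0.1, k_N = 0.7,
α_N = 0.3, μ_N = 3, with Ω = 40 and V = 5000; named presets pin the
feedback strengths and diffusivities just inside ("red", β_S = 3.7 at
β_R = 6.5, D_S/D_N = 3; β_R = 5.82 at β_S = 2.99, D_S = D_N = 4) and just
outside ("blue", β_S = 3.65; β_R = 5.69) the deterministic instability
region.

## Homogeneous equilibria and the reference state

Setting the inhibitor equations to zero gives closed forms
ψ*(φ) = (α_S + β_S h(φ))/(k_S + μ_S φ²) and η*(φ) = α_N/(k_N + μ_N φ²);
substituting into φ̇ = 0 leaves a scalar equation in φ.  Roots are
bracketed on a 2000-point grid over [0, (α_R + β_R)/k_R] (an upper bound
because h ≤ 1) and polished by bisection to 1e-13; every root is returned
with its residual and a homogeneous-stability flag.  The *reference*
equilibrium used for all linear analysis is the stable root; if several
are stable the one with largest φ* is taken (with a warning).  Turing
analysis is meaningless without a homogeneously stable base state, which
is why unstable roots are never silently promoted.

The Jacobian of the reaction terms is derived analytically by
differentiating the rate equations (row one carries −4μφψ-type diagonal
terms and −2μφ² off-diagonals) and is validated against central finite
differences in the tests.

## Dispersion relations and region scans

Mode α of the Laplacian eigenbasis evolves under
Q(Λ^(α)) = J0 + diag(0, D_S, D_N)Λ^(α); the leading real eigenvalue
λ_max(Λ) is the dispersion relation, and the continuum curve follows from
Λ → −k².  The discrete points lie exactly on the continuum curve, which
the suite asserts at 1e-10.  A parameter point is deterministically
Turing-unstable when the base state is homogeneously stable and
max λ over non-uniform modes is positive.  Threshold searches scan a
parameter grid (default step 0.005) and refine the boundary by bisection
to 1e-4.  Eigenvalues of the 3×3 blocks come from the dense LAPACK solver;
no closed forms are used.

## Linear-noise approximation

At next-to-leading order in V^(−1/2), fluctuations obey linear Langevin
equations with mode-wise drift M(Λ) = J0 + diag(0, D_S, D_N)Λ and noise
covariance B(Λ) = B_ns + Λ B_sp.  B_ns is assembled channel by channel as
Σ (stoichiometry outer product) × equilibrium rate; the symmetric hop
channels contribute, per diffusing species, a site-space covariance
−2Dc*Δ, i.e. a mode-space term −2Dc*Λ (encoded as
B_sp = diag(0, −2D_Sψ*, −2D_Nη*)).  The stationary spectrum is computed by
resolvent inversion, P_q(ω, Λ) = [F⁻¹B(Λ)F⁻†]_qq with F = −iωI − M(Λ).
Three independent checks pin this construction down: the decoupled limit
reproduces the Ornstein–Uhlenbeck Lorentzian 2α_R/(ω² + k_R²) to 1e-10;
∫P dω/2π matches the Lyapunov-equation variances to 1e-6 relative; and
mode-resolved SSA variances at V = 2000 agree within 3 standard errors.

Empirical spectra project fluctuations ξ = √V(x/V − equilibrium) onto the
Laplacian eigenvectors and apply a plain rectangular-window discrete
Fourier transform over the analysis interval; the periodogram |ξ̃|²/T is
reported without tapering (a taper is available behind a flag but is not
the default, matching the plain-transform convention used throughout).
The ω = 0 slice P_1(0, Λ) is the spatial fingerprint used to locate the
noise-selected wavelength from a single realization.

**Localized-maximum rule.**  For the stochastic-region map, a grid point
counts as noise-patterning when the maximum of P_1(0, Λ) over non-uniform
modes (i) does not sit at the most-negative-Λ band edge and (ii) exceeds
1.2× the uniform-mode power (ratio configurable).  Referencing the Λ = 0
mode, rather than the neighbouring non-uniform mode, keeps every
deterministically unstable point inside the stochastic region — as it must
be, since there the resolvent peak can sit arbitrarily close to the modes
that go unstable.

## Stochastic simulation

The SSA is the Gillespie direct method with per-cell propensity caching:
only cells touched by an event are recomputed, and cell selection is a
linear scan (Ω ≤ a few hundred here, so a tree brings nothing).  The core
is compiled with numba; a single stream seeded per run drives every
random choice, making trajectories bit-reproducible.  State is held
piecewise-constant between events and read out on a fixed τ grid (default
dτ = 1).  Zero total propensity terminates cleanly in the absorbing state.
Tau-leaping is deliberately absent: all reported stochastic results are
statistically exact, with problem sizes scaled instead (see below).

## Growing filaments

Each cell duplicates with propensity ρV, so the cell count is a Yule
process with E[Ω(τ)] = Ω₀e^{ρVτ} (asserted against 200 chemistry-off
runs).  On division the mother's slot is replaced by two adjacent
daughters (local insertion preserves all other neighbour relations) and
molecules are split equally (odd molecule to the left daughter, a
deterministic rule for reproducibility) or binomially.  The two rules give
statistically indistinguishable pattern spacings (two-sample test at
α = 0.01 in the suite).

The deterministic continuum companion maps the growing domain onto the
fixed unit interval: reaction terms unchanged, a uniform dilution −ρ̃c,
and diffusion coefficients divided by Ω(τ)² with Ω(τ) = Ω₀e^{ρ̃τ}
(method of lines, zero-flux ends).  This is the standard uniform-growth
form implied by the duplication dynamics; defaults are ρ = 1e-8 at
V = 5000 for the stochastic runs and ρ̃ = 5e-5 for the continuum runs.
The mode-band analysis (`unstable_band`) shows the number of unstable
modes growing with Ω and the leading mode index growing linearly
(R² > 0.99 over Ω ∈ [20, 80]) — in cell units the pattern wavelength is
invariant, so growth inserts new peaks at fixed spacing.

## Calibration

The partitioning estimator ν̂ = ⟨(f_a − f_b)²/f_mother⟩ follows from
Var(binomial difference) = n and y = νn.  A constant background is
subtracted first (clipped negatives are counted and reported); an optional
multiplicative bleach correction rescales daughter pairs to sum to the
mother in expectation.  Bootstrap resampling of the per-triplet ratios
gives the standard error.  On synthetic binomial data the bias is below
10% for ≥300 triplets across n ∈ [20, 200]; at ~50 triplets the relative
spread is of order tens of percent, which is the regime of published
copy-number estimates of ~40 ± 15 GFP molecules per cell.

Trace alignment estimates each cell's autofluorescence plateau and floor
from the first and last 10% of samples (after a 3-sample moving average),
interpolates the first downward crossing of their midpoint, and shifts
both channels so that crossing defines t = 0.  Traces with no crossing
(e.g. non-decaying cells) are excluded with a reason rather than guessed.

## Synthetic data

The generators emulate exactly the statistical structure the estimators
assume: binomial partitioning with optional Gaussian measurement noise and
constant background; logistic autofluorescence decays with uniformly
jittered onsets and a switch-like reporter rising a fixed lag (default
5 time units) after onset; and equilibrium fields with independent
uniform ±a relative perturbations (the distribution is a package choice —
any small zero-mean perturbation seeds the same linear modes).  They do
not emulate segmentation errors, cell-size variation, bleaching drift
within a trace, or correlated illumination noise, so passing tests
demonstrate estimator correctness under the stated noise model, not
robustness to real-microscopy artifacts.

## Numerical choices and problem sizes

- ODE integration: LSODA with rtol 1e-8 / atol 1e-10 (1e-7/1e-9 for the
  growing-domain method of lines); the trimolecular terms make patterned
  states stiff.  Concentrations are clipped at zero only on output.
- Eigenvector sign convention: first component of nonvanishing modulus
  positive; eigenpairs sorted by descending Λ, uniform mode first.
- Degenerate Laplacian eigenvalues cannot occur on an open path, but the
  orthonormalisation from the symmetric eigensolver is kept deterministic
  regardless.
- Stochastic tests run at reduced scale chosen once: the single-realization
  spectrum check uses Ω = 30, V = 500, τ ∈ [100, 300]; the SSA/LNA
  covariance comparison uses Ω = 3, V = 2000, 24 runs; the V^(−1/2)
  scaling uses a well-damped stable parameter set (β_R = 3, β_S = 2)
  because near-threshold parameter sets have a relaxation time (~1/0.007)
  that biases variance estimates over any reasonable window.
- The threshold scans report the smallest grid value (step 0.005) at which
  the dispersion maximum turns positive; `threshold_search` additionally
  refines by bisection to 1e-4 when a continuous boundary estimate is
  wanted.

## Known limitations

- The linear-noise spectrum assumes a homogeneously stable base state;
  inside the deterministic region the stationary formula is used only to
  classify localization, not to predict amplitudes.
- Single-realization spectra are periodogram estimates with O(1) relative
  variance per bin; only peak *locations* are meaningful from one run.
- The growing-filament SSA caps Ω (default 512) and drops division events
  beyond it, flagging truncation in the event log.
- No distinction between vegetative cells and heterocysts is enforced:
  the model describes pre-commitment pattern formation, and division
  applies to every cell.
- Hop rates are per neighbour and uniform; heterogeneous or
  direction-biased transport is out of scope.
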