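# Methods

## Models

All four population models share one generation update on a periodic lattice
of N = L^d habitat patches (d = 1 or 2): local growth under multiplicative
environmental noise, then dispersal. Growth acts patch-wise,

* Ricker / Ricker–Moore: X′_j = X_j · exp(r(1 − X_j) + λ ξ_j),
* logistic: X′_j = r X_j (1 − X_j) · e^{λ ξ_j},
* host–parasitoid (noisy Nicholson–Bailey):
  H′_j = r H_j e^{−a P_j + λ ξ_j}, P′_j = H_j (1 − e^{−a P_j}) e^{λ ξ′_j},

with ξ standard normal, independent across patches, generations and
species; λ is the standard deviation of the environmental noise and the
control parameter of the synchronization transition. Dispersal then moves a
fraction ε of every local population, split evenly among the z neighbours:
X_{j,t+1} = (1−ε) X′_j + (ε/z) Σ_{k∈∂j} X′_k. The kernels are
nearest-neighbour (z = 2d) and Moore (nearest plus next-nearest, z = 4 in
1D, 8 in 2D). Dispersal conserves the lattice total exactly and the update
is synchronous. The `deterministic_ricker` variant is the λ = 0 limit and
provides the single-patch orbit oracle used in tests.

The noisy logistic map can carry X > 1 to negative densities; densities are
defined nonnegative, so such outputs are clipped to the absorbing floor 0.
If every patch hits 0 the run raises an extinction signal naming the
generation: statistics are only meaningful on the long-lived metastable
state, and that state no longer exists.

Initial densities are drawn i.i.d. from Normal(μ0, σ0) with negative draws
rejected and redrawn (defaults μ0 = 0.5, σ0 = 0.1; quench experiments use
μ0 = 1.0, the Ricker fixed point, so that incoherent two-cycle phases
develop from the noise itself). One master seed governs everything; derived
streams are keyed by (cell index, replicate index) through `SeedSequence`,
so replicate ensembles do not depend on execution order, and every run is
bit-reproducible. The inner generation loop is a numba kernel fed with
noise pre-drawn in chunks from numpy's PCG64 stream; chunking does not
alter the stream.

## Order parameter and asymptotic statistics

The local spin analogue is the two-cycle amplitude
m_{j,t} = (−1)^t (X_{j,t} − X_{j,t−1})/2 (host field for the two-species
model). The parity factor keeps the sign of a phase-locked two-cycle
constant in time, so patches oscillating in opposite temporal phase carry
amplitudes of opposite sign and a deterministic global two-cycle gives
m = ±(x₊ − x₋)/2. The instantaneous synchronization m_t is the spatial
mean of m_{j,t}.

From a series of M samples of m_t on N patches:

* m_L = ⟨|m_t|⟩ — the standard finite-size estimator; the absolute value
  (not the mean of per-patch |m_{j,t}|) is required for m_L to vanish in
  the incoherent phase.
* χ_L = N(⟨m_t²⟩ − ⟨|m_t|⟩²) — the susceptibility paired with the |m|
  estimator.
* U = ⟨m_t⁴⟩/⟨m_t²⟩² − 3 — the excess-kurtosis Binder cumulant. This
  convention is fixed by its universal 2D Ising critical value between
  −1.830 and −1.835 (−2 deep in order, 0 deep in disorder); crossings of
  U_L curves for sizes (L, 2L), located on piecewise-linear interpolants,
  estimate the critical control value, with errors from resampling the U
  values within their stated uncertainties.

Error bars: m_L carries √(2 τ_int Var(|m_t|)/M), with τ_int the integrated
autocorrelation time of the |m_t| series computed with the self-consistent
truncation window W = min{k : k ≥ 6 τ_int(k)} and the Madras–Sokal error
formula. Variance-type statistics (χ_L, U) use a block bootstrap over 100
contiguous blocks with 1000 resamples (the resample count is our choice;
only the block count is prescribed). Both estimators are seeded.

Spatial correlations are measured along the lattice axes with periodic
wrap. The connected correlation function subtracts the square of the
*ensemble grand mean* (over all supplied fields and sites):
G(r) = ⟨m_j m_{j+r}⟩ − ⟨m⟩². The correlation length uses the second-moment
structure-factor estimator,
ξ_L = [2 sin(π/L)]^{−1} √(S(0)/S(k_min) − 1), k_min = 2π/L, with S(k)
connected in the same grand-mean sense and averaged over both axes. This
estimator is robust at finite L but needs the k = 0 variance of the
ensemble, which converges only as √(2/n) in the number of fields n; it is
therefore reported with a bootstrap error over fields and raises an
undefined-length signal when S(0) ≤ S(k_min) (disordered small-sample
noise). For ensembles whose samples hop between the two symmetry-broken
sectors (Wolff runs in the ordered phase), `align_signs=True` multiplies
each field by the sign of its spatial mean first, mirroring the
single-sector character of a metastable ecological trajectory. A uniform
field has G ≡ 0; an i.i.d. field has G(0) = Var and G(r ≥ 1) ≈ 0.

## Transient detection indices

All three are computed from two consecutive generations of an L×L
landscape (defined from t = 2):

* S_t = |(m_t + m_{t−1})/2| — the non-spatial two-generation index.
* V_t = N′(mean(m_k²) − mean(|m_k|)²) over the 2N means m_k of the
  (L/2)×(L/2) window in its N periodic placements in each of the two
  generations, N′ = (L/2)²; the window means are computed with a wrapped
  uniform filter in O(N) per generation.
* CL_t = 4 ℓ with ℓ = 1/ln[G_t(0)/G_t(1)], where
  G_{k,t}(r) = (1/N′) Σ_{i∈window k} m_i m_{i+r} − m_{k,t}² is averaged
  over all N placements and both generations. The short-distance decay
  length is taken from the single ratio G_t(0)/G_t(1) rather than a
  multi-point fit: at realistic noise levels G_t(r) for r ≥ 2 sits at or
  below the single-generation noise floor, and a fit across that floor
  destroys both the early-time behaviour of the index and its coarsening
  law, whereas the two-point form yields the documented phenomenology —
  ensemble-mean growth CL_t ∝ t^{1/2} after a quench into the synchronous
  phase (nonconserved-dynamics coarsening), a flat baseline in the
  incoherent phase, and 4ℓ₀ on fields with a known exponential correlation
  length ℓ₀. The ×4 prefactor makes CL_t roughly a synchronized-cluster
  diameter. The index is undefined (exception; ensemble code records NaN)
  when G_t(1) ≤ 0 or G_t does not decay — including the degenerate
  near-uniform field, where the windowed subtraction makes
  G_t(r ≥ 1) ≈ −σ²/N′ by construction.

## Finite-size scaling and the cross-model collapse

The reduced control parameter is τ = (λ − λ_c)/λ for the population models
and τ = (T − T_c)/T for Ising — the denominator is the running value, not
the critical one. With the 2D Ising exponents (ν = 1, β = 1/8, γ = 7/4)
fixed, measurements are rescaled as

    x = a · τ · L^{1/ν},
    y_m = b · m_L · L^{β/ν},  y_χ = b² · χ_L · L^{−γ/ν},  y_ξ = ξ_L / L,

so that sizes and models share master curves. The model statistics are
*multiplied* by the scale factors (a_Ising = b_Ising = 1 by convention):
b_model is the reciprocal of the model's local-amplitude scale, which is
why b is about 2 for the Ricker map (near-critical amplitude ≈ 0.49) and
larger for the logistic map (amplitude ≈ 0.17). Collapse quality is a
Houdayer–Hartmann-style statistic: each point is compared with a weighted
local-linear master-curve estimate built from the bracketing points of the
other sets, in units of the combined errors (≈ 1 for a perfect collapse
with honest error bars). Scale factors (a, b) are fitted by coarse
log-grid search plus Nelder–Mead on this quality summed over m, χ and ξ.

The coarsening exponent is the least-squares slope of ln(ensemble-mean
CL_t) against ln t over a pre-saturation window (fits are truncated, with
a warning, where the mean exceeds a saturation level such as L/4), with a
replicate bootstrap for its error. Phase boundaries are read off as the
per-row vertex of a quadratic through the interior maximum of ξ_L(λ);
rows whose maximum touches the grid edge are marked boundary-absent.

## Synthetic fixtures

The generator supplies fields with known ground truth for the statistics
layer: homogeneous two-cycle fields (constant ±c), i.i.d. sign fields, and
Gaussian fields with isotropic correlation e^{−r/ℓ₀} built by spectral
synthesis (the target spectrum is the FFT of the periodic-metric
correlation, clipped at zero; the synthesis therefore knows its own
structure factor exactly, which the tests use as an analytic oracle), plus
scaling datasets generated on closed-form master curves with known (a, b).
These fixtures emulate amplitude configurations, not dynamics: they have
no temporal autocorrelation, no noise floor riding on a coherent
background, and no cluster-shape structure, so tests passing on them
validate the estimators, not the ecological realism of any particular
parameter set — that is what the model-based tests are for.

## Problem sizes and numerical choices

The package targets desk scale: the bundled analyses use L ≤ 64,
2×10⁴-generation burn-ins, 2×10⁵-generation measurement runs, 2×10⁴–10⁵
Monte Carlo samples per point and ensembles of 200 replicates — roughly
three orders of magnitude below the runs behind the published
high-precision estimates, a deliberate trade chosen so the whole analysis
reruns in minutes. Consequences worth knowing:

* The Binder-crossing value U* for the small pair (16, 32) carries a
  finite-size correction of about −0.005 relative to the universal range;
  crossing estimates quote bootstrap errors that cover grid noise, not
  this correction.
* With the package's default dispersal fraction ε = 0.1 the Ricker
  crossing sits at λ_c ≈ 0.148, a few per cent above the published
  0.14131. λ_c(ε) is steep (≈ 0.123 at ε = 0.05), and the size pairs
  (16, 32) and (32, 64) agree with no start-configuration hysteresis, so
  we attribute the offset to the dispersal-fraction convention of the
  original runs rather than to finite size or equilibration; ε = 0.1 is
  kept as the package default throughout.
* In 1D at low noise (λ ≲ 0.1) chains up to L = 1024 remain metastably
  ordered far beyond these run lengths (domain-wall nucleation is
  exponentially suppressed), so the no-long-range-order property is
  demonstrated at λ = 0.15, inside the 1D scan window, where mixing is
  fast.
* Wolff updates are the default at criticality; Metropolis is retained for
  cross-validation (both are checked against exact enumeration on a 4×4
  lattice) and for single-sector ordered-phase runs, where cluster updates
  would flip the global sign at every step.
* Degenerate inputs fail loudly and specifically: zero-variance series make
  the Binder cumulant undefined, flat structure factors make ξ_L
  undefined, non-decaying windowed correlations make CL_t undefined, odd L
  is rejected by the L/2 windowing, and τ_int of a constant series is 1/2
  by convention.

## Limitations

The host–parasitoid model is the plain noisy Nicholson–Bailey map; the
two-cohort host structure of the original lattice study is not
implemented, so quantitative comparisons for that model are out of scope.
Landscape connectivity is homogeneous (no random or long-range kernels),
noise is purely environmental (no demographic noise), and corrections to
scaling and independent exponent estimation are not attempted — the
exponents are held at their 2D Ising values and only slope self-checks are
performed.
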