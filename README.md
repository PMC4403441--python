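# synclattice

Coupled-map-lattice simulations of oscillating spatial populations, and the
statistics that diagnose the emergence of long-range synchrony among them.

## The scientific problem

Many ecological populations oscillate with period two (boom–bust dynamics in
insects, small mammals, childhood diseases). On a landscape of habitat
patches coupled only by short-range dispersal and buffeted by environmental
noise that is *uncorrelated* in space and time, can those local two-cycles
synchronize over distances far beyond the dispersal scale — without any
Moran effect (spatially correlated forcing)?

On two-dimensional landscapes the answer is yes: as the noise level λ drops
below a critical value λ_c, the lattice of local two-cycle oscillators
undergoes a continuous phase transition from incoherence to long-range
synchrony, and this transition is in the 2D Ising universality class. The
local "spin" is the two-cycle amplitude of patch *j* at generation *t*,

    m_{j,t} = (−1)^t (X_{j,t} − X_{j,t−1}) / 2,

whose spatial average m_t (the instantaneous synchronization) plays the
role of the magnetization per site. The package provides:

* **Population models** (`synclattice.models`) — noisy Ricker
  (X′ = X·exp(r(1−X) + λξ)), noisy logistic (X′ = rX(1−X)·e^{λξ}),
  Ricker with a Moore dispersal kernel, and a noisy Nicholson–Bailey
  host–parasitoid map, all with growth followed by even dispersal of a
  fraction ε among the z periodic lattice neighbours.
* **Ising reference** (`synclattice.ising`) — Wolff-cluster and Metropolis
  samplers of the 2D Ising model, the universality-class anchor, with the
  exact Onsager critical temperature T_c = 2/ln(1+√2).
* **Asymptotic statistics** (`synclattice.stats`) — finite-size order
  parameter m_L = ⟨|m_t|⟩, susceptibility χ_L = N(⟨m_t²⟩ − ⟨|m_t|⟩²),
  excess-kurtosis Binder cumulant U = ⟨m_t⁴⟩/⟨m_t²⟩² − 3, spatial connected
  correlation function G(r), second-moment correlation length ξ_L,
  integrated autocorrelation times and block-bootstrap errors — applied
  identically to ecological amplitude fields and Ising spins.
* **Transient detection indices** (`synclattice.transient`) — S_t, V_t and
  CL_t, computable from just two consecutive generations, for rapid
  detection of sudden synchrony changes; CL_t grows as the nonconserved
  coarsening law t^{1/2} after a quench into the synchronous phase.
* **Scaling analysis** (`synclattice.scaling`) — Binder-crossing estimation
  of λ_c (or T_c), finite-size scaling collapse with the 2D Ising exponents
  (ν = 1, β = 1/8, γ = 7/4), cross-model scale-factor fitting against the
  Ising reference, coarsening-exponent fits and phase-boundary scans.
* **Orchestration** (`synclattice.io_cli`) — flat-text experiment configs,
  seeded resumable scan grids with CSV/JSON outputs, a synthetic fixture
  generator, and a `synclattice` command line (`simulate`, `scan`,
  `analyze`, `detect`, `fixture`).

## Worked example

Across the synchronization transition of the spatial Ricker model
(r = 2.3, ε = 0.1, 32×32 lattice):

```python
from synclattice import (ModelParams, SimulationConfig, SyncSeries,
                         build_landscape, simulate, order_parameter,
                         susceptibility, binder_cumulant,
                         integrated_autocorr_time)

land = build_landscape(L=32, d=2, kernel="nearest")
for lam in (0.12, 0.18):
    params = ModelParams("ricker", r=2.3, epsilon=0.1, lam=lam)
    config = SimulationConfig(land, params, T_burnin=5000, T_steps=20000,
                              M=20000, seed=42)
    series = SyncSeries.from_trajectory(simulate(config))
    m = order_parameter(series)
    chi = susceptibility(series, seed=42)
    U = binder_cumulant(series, seed=42)
    tau = integrated_autocorr_time(series.values)
    print(f"lambda = {lam:.2f}:  m_L = {m.value:.4f} +/- {m.stderr:.4f}   "
          f"chi_L = {chi.value:.3f} +/- {chi.stderr:.3f}   "
          f"U = {U.value:.3f}   tau_int = {tau.value:.1f}")
```

prints

```
lambda = 0.12:  m_L = 0.5322 +/- 0.0001   chi_L = 0.032 +/- 0.001   U = -2.000   tau_int = 3.8
lambda = 0.18:  m_L = 0.0265 +/- 0.0012   chi_L = 0.446 +/- 0.037   U = 0.237   tau_int = 89.6
```

Below the transition (λ = 0.12) the landscape is phase-locked: m_L sits
near the deterministic two-cycle half-amplitude (≈ 0.59, reduced by noise),
and U = −2 is the two-point-distribution limit of an ordered phase. Above
it (λ = 0.18) the order parameter is consistent with the ~N^{−1/2}
incoherent residual, U ≈ 0 signals Gaussian fluctuations, and both the
susceptibility and the autocorrelation time have grown on approach to the
critical region in between.

The same run from the shell:

```bash
printf 'model = ricker\nL = 32\nr = 2.3\nlambda = 0.12\nT_steps = 20000\nT_burnin = 5000\nseed = 42\n' > ricker.cfg
synclattice simulate --config ricker.cfg --out traj.npz
synclattice analyze traj.npz --out stats.csv
```

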