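# Methods

This note documents the models implemented in `tetherlytics`, the
numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Geometry and units

All trajectory analyses assume a slab: periodic in x/y with box lengths
`L_x, L_y`, bounded in z by reflecting (no-flux) walls at `z_b` (the
gold bioelectronic interface) and `z_t`. Internal units are nm, ns,
kJ/mol and K with `k_B = 0.0083145 kJ/mol/K`; lateral diffusion is
*reported* in nm²/μs (the customary scale for lipids — a lipid at
~100 nm²/μs moves a molecular diameter per microsecond), converted only
at the I/O boundary. Electrical quantities are SI throughout. Default
temperatures: 320 K for the molecular analyses (the liquid-phase
simulation temperature for phytanyl-chain membranes), 293 K for
electrical data (room-temperature electrochemistry).

## Brownian-dynamics generator

The synthetic trajectory source integrates the overdamped Langevin
equation whose law is the Fokker–Planck equation
`∂Ψ/∂t = ∇·D·[∇ + β∇F]Ψ`:

    z ← z + [−β D(z) F′(z) + D′(z)] dt + sqrt(2 D(z) dt) ξ,  ξ ~ N(0,1)

- **Itô convention with explicit spurious drift `D′(z)`.** Without this
  term a position-dependent diffusivity biases the stationary density;
  with it, the stationary law is exactly `∝ e^{−βF(z)}`, which is the
  property every downstream estimator is tested against.
- **Reflecting walls by coordinate mirroring** within the step, which
  preserves the equilibrium density to O(dt). In-range coordinates pass
  through bit-exactly, so zero-noise trajectories are frozen exactly and
  fixed seeds give bit-identical output.
- **Tabulated `F`/`D` are cubic splines**, drifts from the spline
  derivative; callables are differentiated by central differences with
  `h = 10⁻⁵ × slab width`. Non-finite or negative `D`, and any proposed
  step exceeding half the slab width, abort with a diagnostic rather
  than produce silently wrong physics.
- **Lateral motion** is free diffusion at constant `diffusion_xy`,
  stored *unwrapped* so MSDs can be taken directly; z and x/y noise are
  independent (verified by an increment-correlation test).
- Initial positions are uniform by default; `init="boltzmann"` draws
  from `e^{−βF}` by inverse-CDF on a 4096-point grid, which removes the
  equilibration transient when sampling stationary observables.
- The frame-saving interval (`save_every`) is a free choice; defaults
  save every step. Statistical tests that rely on effectively
  independent samples save sparsely (a few relaxation times apart), as
  one would with MD frames.

What the generator does **not** emulate: molecular structure and
force-field interactions, hydrodynamic coupling between particles,
collective lipid motion, membrane undulations, or anomalous diffusion.
Passing tests therefore demonstrate estimator correctness on the ideal
overdamped process, not fidelity of any particular MD system.

## Density, free energy, thickness

Densities are histograms over z with a default **0.05 nm bin width**,
chosen to resolve headgroup features (~0.5 nm) with ≥10 bins. The bulk
density `ρ₀` is the mean over a configurable bulk window, defaulting to
the upper quarter of the slab (the bulk-electrolyte side). Boltzmann
inversion `F = −k_B T ln(ρ/ρ₀)` masks empty bins rather than imputing
+∞, so no infinities propagate into the `e^{βF}` integrand of the
perpendicular-diffusion estimator; the gauge is fixed by `min F = 0`.

Membrane thickness `h_m` is the separation of the two dominant
headgroup-density peaks; the reservoir height `h_r` is the distance from
`z_b` to the proximal peak. Peaks are refined by a **3-point parabola**
around the binned maximum — sub-bin accuracy without assuming a peak
shape. Boundary maxima count as peaks (a membrane-less electrode still
has a proximal water-structure maximum).

## Lateral diffusion (MSD)

Time-and-ensemble averaged MSD per axis via the standard FFT
autocorrelation decomposition; `D` per axis is half the least-squares
slope over a lag window, `D_par` the mean of x and y. The default
window of **1–10 ns** sits past inertial/caging artifacts and before
lag statistics degrade; it is configurable. The reported uncertainty
combines half the x/y split with a bootstrap (200 resamples over
particles) standard error. Wrapped coordinates (a jump exceeding half a
box length) are rejected, not silently unwrapped.

## Perpendicular diffusion (round-trip times)

For each bin centre `z` the z series is scanned for non-overlapping
completed excursions `z → z* → z` detected by level crossings; their
mean duration estimates `τ_rt(z)`, and

    D_zz(z) = e^{βF(z)} · ∫ e^{−βF} dz′ / (∂τ_rt/∂z).

For flat `F` this identity is exact with slope `(z_t − z_b)/D`, which is
the package's closed-form oracle; for tilted landscapes the quadrature
oracle `τ_rt(z) = ∫_{z*}^{z} e^{βF(y)}/D(y) dy · ∫ e^{−βF}` follows from
splicing the two mean-first-passage legs.

Numerical choices:

- `z*` defaults to the bin adjacent to the lower wall, maximizing the
  number of completed excursions for membrane-spanning profiles;
  configurable.
- The slope is a **local quadratic (Savitzky–Golay) derivative over a
  7-bin window** (configurable): the derivative of noisy bin means needs
  regularization. Within half a window of `z*` the `τ_rt` profile has a
  kink and the smoothed slope (hence `D_zz`) is unreliable; estimates
  there are excluded from self-consistency comparisons.
- Bins with no completed round trip are masked, never zeroed. Estimates
  are censored for excursions longer than the trajectory, so analyses
  use trajectories ≥ ~25× the longest expected round-trip time.

## Umbrella sampling and WHAM

Windows carry a centre, a harmonic force constant (500 kJ/mol/nm² is
the standard stiff-spring choice for lipid pulling) and the sampled
reaction coordinate. WHAM iterates the window offsets

    p_j ∝ n_j / Σ_i N_i e^{β(f_i − w_i(z_j))},   f_i = −k_B T ln Σ_j c_ij p_j

with Jacobi-style simultaneous updates, 0.05 nm histogram bins, a
relative tolerance of 10⁻⁴ on the offsets and a 10⁵-iteration cap;
`G = −k_B T ln p`, min-shifted to 0. Unbiased input (`k = 0`)
reproduces plain Boltzmann inversion exactly, and the reconstruction is
translation-equivariant. Non-overlapping window chains converge but
emit a connectivity warning, since inter-segment offsets are then
unconstrained by data.

Derived quantities: the **desorption energy** is the mean PMF over the
solvated plateau (default `|z| > 3.5 nm` from the bilayer centre,
configurable — the plateau onset depends on the system) minus the
global minimum; the **flip-flop barrier** is the PMF maximum on the
closed interval between the global minimum and the bilayer centre
(z = 0 by the centring convention; a minimum at the centre is degenerate
and returns 0 with a warning); the **defect density** is the exact
evaluation `ρ₀ = e^{−βΔG_p}/A_L`. No leaflet symmetrization is applied.
Window-centre grids are generated inclusively (`round(range/spacing)+1`
points), e.g. 37 windows at 0.15 nm spacing over 5.4 nm, 48 at 0.1 nm
over 4.7 nm.

## Fractional-order circuit model

Topology: `R_e` in series with the membrane (`G_m ∥ C_m`) in series
with a constant-phase element `Z = 1/(q (jω)^p)`, `0 < p ≤ 1`. This is
the standard tBLM equivalent circuit; the CPE models diffusion-limited
charge transfer and ionic adsorption at the gold interface. It
reproduces the ideal-capacitor limit (`p = 1`, low-frequency phase
magnitude → 90°), the pure-CPE phase `p·90°`, the spacer-only electrode
(membrane branch removed via `C_m → ∞`), and identifiability of the
baseline parameters from a single frequency sweep. A double-layer
capacitance in parallel with the CPE is *not* modelled; a `C_dl` entry
in parameter files is accepted and ignored with a warning.

The time-domain solver treats the CPE as a Caputo-type fractional
derivative with zero initial state, discretized by the
**Grünwald–Letnikov binomial weights** `w_k = w_{k−1}(1 − (1+p)/k)`,
which reduce exactly to first differences at `p = 1`. Each step solves
the Kirchhoff loop implicitly (linear in the unknown current), with the
membrane branch advanced by backward Euler. The scheme is first-order;
oracle comparisons at `p = 1` against a stiff ODE solver reach 0.1% RMS
at `dt = 0.5 μs` on millisecond drives. An optional short-memory
truncation of the GL convolution is provided; note that for a genuine
power-law kernel the truncation error decays only like `(window)^{−p}`,
so unlike exponential-memory systems there is no short window that
guarantees sub-percent accuracy — the option is for exploratory speedups
only, and tests assert monotone convergence and exactness at full
memory rather than a fixed error at a fixed window.

**Electroporation.** The reduced pore-density ODE

    dN/dt = α e^{(V_m/V_ep)²} [1 − (N/N_o) e^{−q_pore (V_m/V_ep)²}]

has fixed point `N_o e^{q_pore (V_m/V_ep)²}` and couples to the circuit
through `G_m(t) = G_o + N(t) A_m G_p`. `α` carries absolute
density-rate units, so its magnitude must be scaled to `N_o` for a
given relaxation time. Pore geometry/energy constants (`r_m`, `W_es`,
`C`, `D`) are carried as opaque metadata; the full continuum
electroporation asymptotics are out of scope.

**Fitting** minimizes the joint residual of `log₁₀|Z|` and the phase in
degrees with equal weights (spectrum mode) or the current trace (trace
mode, with the simulator inside the objective), by bounded least
squares with log-parameterized positive parameters and deterministic
seeded multi-starts. Directions in which the Jacobian is numerically
null are reported as unidentifiable (e.g. `C_m` from spacer-only data).
The permittivity inversion `ε_m = C_m h_m/(ε₀ A_m)` flags values
outside [2, 80] — below pure hydrocarbon or above electrolyte — as
implausible.

## Pipeline and formats

All outputs are delimited text with commented headers, written at
`repr` precision so write→read round trips are bit-exact. The pipeline
runner executes simulate → profiles → diffusion → wham → energetics →
circuit as configured in TOML, propagates one global seed to every
stochastic stage, and writes a manifest with SHA-256 checksums; reruns
with identical configuration reproduce identical checksums for the
deterministic stages. GRO+XTC input is supported through MDAnalysis as
an optional dependency behind the same trajectory contract.

## Problem sizes in the test suite

The suite validates estimators at desk scale: 10⁶–10⁸ particle-steps
per fixture (seconds each), 48 umbrella windows × 4×10⁴ samples for the
WHAM recovery, 10⁷ particle-steps for the Boltzmann round trip (frames
saved every ~2 relaxation times so saved samples are effectively
independent), and 100 noise realizations for the fit study. Slab
geometries for round-trip tests are chosen narrow (2 nm) so trajectories
are long relative to the slowest excursions; the estimator physics is
scale-free.

## Known limitations

- The Euler–Maruyama integrator is weak order 1; stationary-law biases
  are O(dt) and the defaults keep `β D F″ dt ≪ 1`.
- Round-trip `D_zz` estimates degrade near the walls, near `z*`, and
  wherever excursions are censored by finite trajectory length.
- WHAM reports no statistical uncertainty by default; offset errors
  between distant windows accumulate diffusively along the chain.
- The circuit fit's equal weighting of phase (degrees) and `log₁₀|Z|`
  is a convention, not a maximum-likelihood weighting.
- Leaflet assignment uses time-mean z, which is appropriate while
  flip-flop is rare (barriers ≫ k_B T); it would misclassify particles
  that translocate mid-trajectory.
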