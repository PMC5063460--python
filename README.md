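# tetherlytics

Analysis toolkit for **tethered bilayer lipid membranes (tBLMs)** —
planar lipid bilayers anchored to a gold electrode through
polyethylene-glycol tethers, the workhorse platform for studying how
cytoskeleton-like supports shape membrane order, dynamics and electrical
response. The package is aimed at membrane biophysicists and
bioelectronics researchers who need to turn slab-confined particle
trajectories (typically from coarse-grained MD), umbrella-sampling
windows and swept-frequency impedance data into the standard derived
quantities of the field.

## What it computes

**Spatially resolved diffusion.** In a slab bounded by no-flux walls the
water diffusion tensor is diagonal with `D_xx = D_yy ≠ D_zz(z)`. The
lateral coefficient follows from the time-and-ensemble averaged mean
squared displacement, `⟨(x − x₀)²⟩ = 2 D_xx (t − t₀)`, per species and
leaflet/region. The perpendicular coefficient is position dependent and
is recovered from the mean round-trip time `τ_rt(z)` (time to go from
`z` to a reference `z*` and back):

    D_zz(z) = e^{βF(z)} / (∂τ_rt/∂z) · ∫_{z_b}^{z_t} e^{−βF(z′)} dz′

**Profiles.** Number-density profiles `ρ(z)/ρ₀`, Boltzmann inversion
`F(z) = −k_B T ln(ρ/ρ₀)`, membrane thickness `h_m` (headgroup peak
separation) and tethering-reservoir height `h_r`.

**Lipid energetics.** WHAM reconstruction of the potential of mean
force `G(z)` for moving a single lipid along the membrane normal from
harmonically biased umbrella windows; desorption free energy, lipid
flip-flop barrier `ΔG_p`, and the equilibrium defect density
`ρ₀ = e^{−βΔG_p}/A_L` with `A_L` the area per lipid.

**Electrical response.** A fractional-order equivalent circuit —
electrolyte resistance `R_e`, membrane `G_m ∥ C_m`, and a constant-phase
element `Z_CPE = 1/(q (jω)^p)` for the diffusion-limited gold interface.
Closed-form impedance, time-domain currents under piecewise-linear
drives via Grünwald–Letnikov discretization of the fractional
derivative, optional voltage-dependent pore (defect) dynamics, bounded
least-squares parameter fitting, and the parallel-plate permittivity
inversion `ε_m = C_m h_m/(ε₀ A_m)`.

**Synthetic data.** An overdamped Langevin (Brownian dynamics)
integrator with position-dependent `D(z)` and `F(z)` between reflecting
walls — Itô convention with the explicit spurious drift `D′(z)` so the
stationary density is exactly `∝ e^{−βF}` — plus generators for umbrella
windows, bimodal headgroup profiles and noisy circuit measurements.
Every estimator in the package is validated against this generator's
known ground truth.

Units: nm, ns, kJ/mol, K (with `k_B = 0.0083145 kJ/mol/K`); lateral
diffusion reported in nm²/μs; electrical quantities in SI.

## Worked example

```python
import tetherlytics as tl

dom = tl.SlabDomain(z_b=0.0, z_t=5.0, L_x=10.8, L_y=10.8)
spec = tl.LangevinSpec(domain=dom, diffusion_xy=0.29, diffusion_z=2.1,
                       n_particles=200, dt=1e-3, n_steps=50_000,
                       save_every=10, seed=1)
traj = tl.simulate_overdamped(spec)
res = tl.lateral_diffusion_msd(traj, "W", fit_window=(1.0, 10.0))
print(f"D_par = {res.D_par:.0f} +/- {res.uncertainty:.0f} nm^2/us")

heads = tl.make_membrane_density(peak_separation=3.53, proximal_peak=3.30)
print(f"h_m = {tl.membrane_thickness(heads):.2f} nm")

model = tl.defect_density(89.0, 0.69, 320.0)
print(f"rho0 = {model.rho0:.2e} nm^-2")
```

prints

```
D_par = 298 +/- 20 nm^2/us
h_m = 3.53 nm
rho0 = 4.30e-15 nm^-2
```

The lateral estimate recovers the generative 0.29 nm²/ns (290 nm²/μs,
the scale of proximal-leaflet lipid diffusion in an untethered
archaebacterial membrane) within its bootstrap uncertainty; the
thickness estimator reads the headgroup peak separation back off the
profile fixture; and a flip-flop barrier of 89 kJ/mol with a 0.69 nm²
area per lipid gives an equilibrium defect density of ~4×10⁻¹⁵ nm⁻² —
effectively defect-free at rest, which is why tBLMs are such quiet
electrical seals.

A command-line interface mirrors the library
(`tetherlytics simulate | profiles | diffusion | wham | energetics |
circuit | pipeline`), e.g.

```sh
$ tetherlytics circuit permittivity --c-m 12.5e-9 --h-m 3.5e-9
eps_m = 2.353
```

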