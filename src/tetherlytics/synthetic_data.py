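"""Synthetic-data generators for every pipeline stage.

The central piece is an overdamped Langevin (Brownian dynamics)
integrator for particles in a slab with a position-dependent normal
diffusivity D(z) and free-energy landscape F(z) between two reflecting
walls — the stochastic process whose law is the overdamped Fokker-Planck
equation used to analyse membrane water.  The integrator uses the Ito
convention with the explicit spurious-drift term D'(z) so that the
stationary density is proportional to exp(-beta F(z)) even when D varies
with position.  Lateral motion is free diffusion with a constant
coefficient, stored unwrapped.

On top of the integrator sit generators for harmonically biased umbrella
windows, bimodal headgroup-density fixtures, and noisy equivalent-circuit
current measurements, so the full analysis pipeline can be exercised
without coarse-grained MD runs or electrochemical hardware.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .constants import DEFAULT_TEMPERATURE_MD, beta as _beta
from .core import SlabDomain, Trajectory
from .electrical import CircuitParams, CurrentTrace, DriveWaveform, simulate_current
from .energetics import UmbrellaWindow
from .profiles import DensityProfile


class SimulationError(ValueError):
    pass


ProfileLike = Callable[[np.ndarray], np.ndarray] | tuple[np.ndarray, np.ndarray] | float | None


def _as_spline(profile, domain: SlabDomain):
    """Normalize a profile spec to (value_fn, derivative_fn, is_constant)."""
    if profile is None:
        return (lambda z: np.zeros_like(z)), (lambda z: np.zeros_like(z)), True
    if np.isscalar(profile):
        c = float(profile)
        return (lambda z: np.full_like(z, c)), (lambda z: np.zeros_like(z)), True
    if callable(profile):
        f = profile
        h = 1e-5 * domain.width

        def fp(z, f=f, h=h):
            return (f(z + h) - f(z - h)) / (2 * h)

        return f, fp, False
    z_grid, vals = profile
    spl = CubicSpline(np.asarray(z_grid, float), np.asarray(vals, float))
    return spl, spl.derivative(), False


@dataclass
class LangevinSpec:
    """Specification of one Brownian-dynamics run.

    ``free_energy`` and ``diffusion_z`` accept ``None`` (flat / zero), a
    scalar, a callable of z, or a ``(z_grid, values)`` table interpolated
    with a cubic spline (derivatives come from the spline).  Units:
    kJ/mol for F, nm^2/ns for D, nm for lengths, ns for times.

    ``init`` chooses initial z positions: "uniform" (default),
    "boltzmann" (drawn from exp(-beta F) on a fine grid), or an explicit
    array of shape (n_particles,).  ``save_every`` thins the saved
    frames; the integration step is always ``dt``.
    """

    domain: SlabDomain
    free_energy: ProfileLike = None
    diffusion_z: ProfileLike = 1.0
    diffusion_xy: float = 1.0
    temperature: float = DEFAULT_TEMPERATURE_MD
    n_particles: int = 100
    dt: float = 1e-3
    n_steps: int = 1000
    seed: int = 0
    save_every: int = 1
    species: str = "W"
    init: str | np.ndarray = "uniform"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise SimulationError("dt must be positive")
        if self.n_particles < 1 or self.n_steps < 1:
            raise SimulationError("n_particles and n_steps must be >= 1")
        if self.save_every < 1:
            raise SimulationError("save_every must be >= 1")
        if self.diffusion_xy < 0:
            raise SimulationError("diffusion_xy must be non-negative")


def _initial_z(spec: LangevinSpec, F, rng: np.random.Generator) -> np.ndarray:
    dom = spec.domain
    if isinstance(spec.init, np.ndarray):
        z0 = np.asarray(spec.init, dtype=float)
        if z0.shape != (spec.n_particles,):
            raise SimulationError("init array must have shape (n_particles,)")
        if not dom.contains_z(z0):
            raise SimulationError("init positions outside the slab")
        return z0.copy()
    if spec.init == "uniform":
        return rng.uniform(dom.z_b, dom.z_t, size=spec.n_particles)
    if spec.init == "boltzmann":
        grid = np.linspace(dom.z_b, dom.z_t, 4096)
        w = np.exp(-_beta(spec.temperature) * (F(grid) - F(grid).min()))
        cdf = np.cumsum(w)
        cdf /= cdf[-1]
        return np.interp(rng.random(spec.n_particles), cdf, grid)
    raise SimulationError(f"unknown init mode {spec.init!r}")


def _reflect(z: np.ndarray, z_b: float, z_t: float) -> np.ndarray:
    """Mirror coordinates into [z_b, z_t] (triangle-wave fold).

    In-range coordinates pass through bit-exactly.
    """
    out = (z < z_b) | (z > z_t)
    if not out.any():
        return z
    W = z_t - z_b
    y = np.mod(z[out] - z_b, 2 * W)
    folded = z_b + W - np.abs(W - y)
    z = z.copy()
    z[out] = folded
    return z


def simulate_overdamped(spec: LangevinSpec) -> Trajectory:
    """Euler-Maruyama integration of the overdamped Langevin equation.

    Per step (Ito convention):

        z <- z + [-beta D(z) F'(z) + D'(z)] dt + sqrt(2 D(z) dt) xi

    with xi ~ N(0, 1), followed by mirror reflection at the walls; the
    D'(z) spurious-drift term makes the stationary law exp(-beta F(z))
    exact for position-dependent D.  Lateral coordinates diffuse with the
    constant ``diffusion_xy`` and are stored unwrapped.  Identical specs
    (including the seed) give bit-identical trajectories.

    Raises :class:`SimulationError` when any proposed z displacement
    exceeds half the slab width in one step (the step size is then too
    large for the landscape), or when F or D evaluate non-finite.
    """
    dom = spec.domain
    F, Fp, F_const = _as_spline(spec.free_energy, dom)
    D, Dp, D_const = _as_spline(spec.diffusion_z, dom)
    b = _beta(spec.temperature)

    check = np.linspace(dom.z_b, dom.z_t, 257)
    with np.errstate(all="ignore"):
        Fv, Dv = F(check), D(check)
    if not (np.all(np.isfinite(Fv)) and np.all(np.isfinite(Dv))):
        raise SimulationError("free energy or diffusivity non-finite on the slab")
    if np.any(Dv < 0):
        raise SimulationError("diffusion_z must be non-negative on the slab")

    rng = np.random.Generator(np.random.PCG64(spec.seed))
    z = _initial_z(spec, F, rng)
    xy = np.zeros((spec.n_particles, 2))

    n_saved = spec.n_steps // spec.save_every + 1
    pos = np.empty((n_saved, spec.n_particles, 3))
    pos[0, :, :2] = xy
    pos[0, :, 2] = z

    half_width = 0.5 * dom.width
    sqrt_2dt = np.sqrt(2.0 * spec.dt)
    sig_xy = np.sqrt(2.0 * spec.diffusion_xy * spec.dt)
    const_D = float(D(np.array([dom.midpoint]))[0]) if D_const else None

    frame = 1
    for step in range(1, spec.n_steps + 1):
        noise = rng.standard_normal((spec.n_particles, 3))
        if D_const and F_const:
            dz = sqrt_2dt * np.sqrt(const_D) * noise[:, 2]
        else:
            Dz = D(z)
            drift = (-b * Dz * Fp(z) + Dp(z)) * spec.dt
            dz = drift + sqrt_2dt * np.sqrt(Dz) * noise[:, 2]
        if np.any(np.abs(dz) > half_width):
            i = int(np.argmax(np.abs(dz)))
            raise SimulationError(
                f"step size too large: |dz| = {abs(dz[i]):.3g} nm exceeds half "
                f"the slab width ({half_width:.3g} nm) at step {step}, particle "
                f"{i}; reduce dt"
            )
        z = _reflect(z + dz, dom.z_b, dom.z_t)
        xy = xy + sig_xy * noise[:, :2]
        if step % spec.save_every == 0:
            pos[frame, :, :2] = xy
            pos[frame, :, 2] = z
            frame += 1

    times = spec.dt * spec.save_every * np.arange(n_saved)
    return Trajectory(
        times=times,
        positions=pos[:frame],
        species=np.full(spec.n_particles, spec.species),
        domain=dom,
        meta={"dt": spec.dt, "save_every": spec.save_every, "seed": spec.seed},
    )


def simulate_umbrella_windows(
    spec: LangevinSpec,
    centers: Sequence[float],
    force_const: float,
    n_samples: int,
    equilibration_steps: int = 0,
    seed: int | None = None,
) -> list[UmbrellaWindow]:
    """Harmonically biased sampling for WHAM.

    For each centre c the base landscape is augmented with the umbrella
    potential 0.5 k (z - c)^2 and :func:`simulate_overdamped` is run;
    the first ``equilibration_steps`` saved frames are discarded and the
    remaining z series (all particles pooled) become the window samples.
    Per-window seeds are spawned deterministically from ``seed``.
    """
    centers = np.asarray(list(centers), dtype=float)
    if centers.size == 0:
        raise SimulationError("centers list is empty")
    if force_const < 0:
        raise SimulationError("force constant must be non-negative")
    dom = spec.domain
    if np.any(centers < dom.z_b) or np.any(centers > dom.z_t):
        raise SimulationError("umbrella centers must lie within the slab")
    base_F, _, _ = _as_spline(spec.free_energy, dom)
    seed = spec.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(seed).generate_state(centers.size) % (2**31)

    steps_per_particle = int(np.ceil(n_samples / spec.n_particles))
    windows = []
    for c, s in zip(centers, child_seeds):
        def biased(z, c=c):
            return base_F(np.asarray(z)) + 0.5 * force_const * (np.asarray(z) - c) ** 2

        wspec = LangevinSpec(
            domain=dom,
            free_energy=biased,
            diffusion_z=spec.diffusion_z,
            diffusion_xy=spec.diffusion_xy,
            temperature=spec.temperature,
            n_particles=spec.n_particles,
            dt=spec.dt,
            n_steps=equilibration_steps + steps_per_particle,
            seed=int(s),
            save_every=1,
            species=spec.species,
            init=np.full(spec.n_particles, np.clip(c, dom.z_b, dom.z_t)),
        )
        traj = simulate_overdamped(wspec)
        samples = traj.positions[equilibration_steps + 1:, :, 2].ravel()[:n_samples]
        windows.append(
            UmbrellaWindow(center=float(c), k=force_const, samples=samples)
        )
    return windows


def make_membrane_density(
    peak_separation: float,
    peak_width: float = 0.15,
    bins: int = 160,
    z_range: tuple[float, float] = (0.0, 8.0),
    proximal_peak: float | None = None,
    species: str = "headgroup",
) -> DensityProfile:
    """Symmetric bimodal headgroup-density fixture.

    Two equal Gaussian peaks separated by exactly ``peak_separation``
    (nm); ``proximal_peak`` places the lower peak (default: centred in
    ``z_range``).  The bin grid is aligned so that both peaks fall on
    bin centres, which makes the thickness estimator exact in the
    narrow-peak limit.
    """
    if peak_separation <= 0:
        raise ValueError("peak_separation must be positive")
    z0, z1 = z_range
    span = z1 - z0
    if peak_separation >= span:
        raise ValueError("peak_separation must fit inside z_range")
    dz = span / bins
    # snap dz so the separation is an integer number of bins
    n_sep = max(1, int(round(peak_separation / dz)))
    dz = peak_separation / n_sep
    if proximal_peak is None:
        proximal_peak = z0 + 0.5 * (span - peak_separation)
    distal_peak = proximal_peak + peak_separation
    # grid aligned so proximal_peak is a bin centre
    n_lo = int(np.floor((proximal_peak - z0) / dz + 0.5))
    start = proximal_peak - (n_lo + 0.5) * dz
    n_bins = int(np.floor((z1 - start) / dz))
    edges = start + dz * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    if peak_width < 0.5 * dz:
        y = np.zeros(n_bins)
        y[np.argmin(np.abs(centers - proximal_peak))] = 1.0
        y[np.argmin(np.abs(centers - distal_peak))] = 1.0
    else:
        y = (np.exp(-0.5 * ((centers - proximal_peak) / peak_width) ** 2)
             + np.exp(-0.5 * ((centers - distal_peak) / peak_width) ** 2))
    return DensityProfile(
        bin_edges=edges,
        counts=y,
        rho_norm=y / y.max(),
        rho_bulk=1.0,
        species=species,
    )


def simulate_measurement(
    params: CircuitParams,
    waveform: DriveWaveform,
    noise_sd: float,
    seed: int,
    dt: float = 1e-5,
    pore=None,
) -> CurrentTrace:
    """Noisy current measurement: :func:`simulate_current` plus i.i.d.
    Gaussian current noise of standard deviation ``noise_sd`` (A)."""
    trace = simulate_current(params, waveform, dt=dt, pore=pore)
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0:
        rng = np.random.Generator(np.random.PCG64(seed))
        trace = CurrentTrace(
            times=trace.times,
            current=trace.current + rng.normal(0, noise_sd, size=trace.current.size),
            drive=trace.drive,
        )
    return trace


def noisy_spectrum(params: CircuitParams, frequencies, rel_noise: float, seed: int):
    """Impedance sweep with multiplicative Gaussian noise on Re/Im parts."""
    from .electrical import ImpedanceSpectrum, impedance

    clean = impedance(params, frequencies)
    if rel_noise == 0:
        return clean
    rng = np.random.Generator(np.random.PCG64(seed))
    factor = (1 + rng.normal(0, rel_noise, clean.Z.size)) * np.exp(
        1j * rng.normal(0, rel_noise, clean.Z.size)
    )
    return ImpedanceSpectrum(frequencies=clean.frequencies, Z=clean.Z * factor)
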