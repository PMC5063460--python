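"""Fractional-order equivalent-circuit model of the tethered-membrane
electrical response.

Topology
--------
The electrode/membrane stack is modelled as the standard tBLM equivalent
circuit: the electrolyte resistance R_e in series with the membrane (a
parallel RC: conductance G_m, capacitance C_m) in series with the
gold-interface double layer, represented by a constant-phase element
(CPE) with impedance 1/(q (j w)^p).  The fractional order p in (0, 1]
captures diffusion-limited charge transfer and ionic adsorption at the
bioelectronic interface: p = 1 is an ideal capacitor (low-frequency phase
magnitude 90 degrees), p < 1 tilts the phase to p*90 degrees.

Time-domain currents are computed by discretizing the CPE's fractional
derivative (Caputo-type, zero initial state) with the Gruenwald-Letnikov
binomial weights, which reduce exactly to first differences at p = 1.
An optional electroporation stage makes the membrane conductance
voltage-dependent through a reduced pore-density ODE.

Units are SI throughout this module: seconds, volts, amperes, ohms,
farads, siemens; the CPE coefficient q is in S s^p.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .constants import EPSILON_0


class CircuitError(ValueError):
    pass


@dataclass(frozen=True)
class CircuitParams:
    """Equivalent-circuit parameters.

    ``C_m = inf`` (or ``G_m = inf``) removes the membrane branch — the
    spacer-only electrode where just R_e and the CPE remain.
    """

    R_e: float  # electrolyte resistance, Ohm
    C_m: float  # membrane capacitance, F
    G_m: float  # membrane conductance (baseline G_o), S
    q: float    # CPE coefficient, S s^p
    p: float    # fractional order, 0 < p <= 1
    A_m: float = 2.1e-6  # electrode area, m^2

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise CircuitError(f"fractional order p must be in (0, 1], got {self.p}")
        for name in ("R_e", "C_m", "q", "A_m"):
            if getattr(self, name) <= 0:
                raise CircuitError(f"{name} must be positive")
        if self.G_m < 0:
            raise CircuitError("G_m must be non-negative")

    @property
    def membrane_absent(self) -> bool:
        return math.isinf(self.C_m) or math.isinf(self.G_m)


@dataclass(frozen=True)
class PoreParams:
    """Reduced electroporation model parameters.

    dN/dt = alpha exp((V_m/V_ep)^2) [1 - (N/N_o) exp(-q_pore (V_m/V_ep)^2)]

    N is the areal pore density; each pore conducts G_p so the membrane
    conductance becomes G_m(t) = G_o + N(t) A_m G_p.  The geometry/energy
    constants r_m, W_es, C, D of the full continuum treatment are carried
    as metadata only.
    """

    alpha: float      # pore creation rate coefficient, s^-1
    q_pore: float     # pore model exponent, dimensionless
    V_ep: float       # characteristic electroporation voltage, V
    N_o: float        # equilibrium pore density, m^-2
    G_p: float        # per-pore conductance, S
    extra: dict = field(default_factory=dict, compare=False)  # r_m, W_es, C, D...

    def __post_init__(self) -> None:
        for name in ("alpha", "V_ep", "N_o", "G_p"):
            if getattr(self, name) <= 0:
                raise CircuitError(f"{name} must be positive")


@dataclass
class DriveWaveform:
    """Piecewise-linear drive potential V_s(t)."""

    times: np.ndarray
    voltages: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise CircuitError("breakpoint times must be strictly increasing")
        if self.times.shape != self.voltages.shape:
            raise CircuitError("times and voltages must have equal length")

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        return np.interp(t, self.times, self.voltages,
                         left=self.voltages[0], right=self.voltages[-1])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    @classmethod
    def ramp(cls, slope: float, rise_time: float, fall_slope: float | None = None,
             fall_time: float | None = None, t0: float = 0.0) -> "DriveWaveform":
        """Linear rise then linear fall, e.g. 100 V/s up for 5 ms then
        -100 V/s down for 5 ms."""
        fall_slope = -slope if fall_slope is None else fall_slope
        fall_time = rise_time if fall_time is None else fall_time
        peak = slope * rise_time
        return cls(
            times=np.array([t0, t0 + rise_time, t0 + rise_time + fall_time]),
            voltages=np.array([0.0, peak, peak + fall_slope * fall_time]),
        )

    @classmethod
    def step(cls, amplitude: float, t_on: float, t_end: float,
             rise: float = 1e-6) -> "DriveWaveform":
        """Voltage step approximated by a ``rise``-second linear edge."""
        return cls(
            times=np.array([0.0, t_on, t_on + rise, t_end]),
            voltages=np.array([0.0, 0.0, amplitude, amplitude]),
        )


@dataclass
class ImpedanceSpectrum:
    """Swept-frequency impedance: complex Z(f)."""

    frequencies: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.Z = np.asarray(self.Z, dtype=complex)
        if np.any(self.frequencies <= 0):
            raise CircuitError("frequencies must be positive")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.Z)

    @property
    def phase_deg(self) -> np.ndarray:
        """Signed phase angle of Z in degrees (capacitive = negative)."""
        return np.degrees(np.angle(self.Z))

    @property
    def phase_magnitude_deg(self) -> np.ndarray:
        """|angle(Z)| in degrees, the customary reporting convention."""
        return np.abs(self.phase_deg)


@dataclass
class CurrentTrace:
    """Time-domain current response to a drive potential."""

    times: np.ndarray
    current: np.ndarray
    drive: DriveWaveform | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.current = np.asarray(self.current, dtype=float)


#: The swept-frequency preset of the impedance reader used for tBLM QC (Hz).
TETHAPOD_FREQUENCIES = np.array(
    [1000.0, 500.0, 200.0, 100.0, 40.0, 20.0, 10.0, 5.0, 2.0, 1.0, 0.5, 0.1]
)

#: Default excitation amplitude for impedance sweeps (V).
DEFAULT_EXCITATION = 0.025


def impedance(params: CircuitParams, frequencies: np.ndarray) -> ImpedanceSpectrum:
    """Closed-form impedance of the series R_e + membrane + CPE circuit.

    Z(w) = R_e + 1/(G_m + j w C_m) + 1/(q (j w)^p).  With the membrane
    absent (C_m or G_m infinite) the membrane branch vanishes.
    """
    f = np.asarray(frequencies, dtype=float)
    if np.any(f <= 0):
        raise CircuitError("frequencies must be positive")
    w = 2 * np.pi * f
    jw = 1j * w
    Z = params.R_e + 1.0 / (params.q * jw ** params.p)
    if not params.membrane_absent:
        Z = Z + 1.0 / (params.G_m + jw * params.C_m)
    return ImpedanceSpectrum(frequencies=f, Z=Z)


def gl_weights(p: float, n: int) -> np.ndarray:
    """Gruenwald-Letnikov binomial weights w_0..w_n for order p.

    w_0 = 1, w_k = w_{k-1} (1 - (1+p)/k).  At p = 1 they reduce to the
    first-difference stencil [1, -1, 0, ...].
    """
    if n < 0:
        raise CircuitError("n must be >= 0")
    w = np.empty(n + 1)
    w[0] = 1.0
    for k in range(1, n + 1):
        w[k] = w[k - 1] * (1.0 - (1.0 + p) / k)
    return w


def pore_dynamics(
    times: np.ndarray, V_m: np.ndarray, pore: PoreParams
) -> np.ndarray:
    """Integrate the reduced pore-density ODE along a given V_m(t) trace.

    Explicit trapezoidal stepping on the trace grid; N(0) = N_o.  At
    constant V_m the density relaxes to N_o exp(q_pore (V_m/V_ep)^2).
    """
    times = np.asarray(times, dtype=float)
    V_m = np.asarray(V_m, dtype=float)
    N = np.empty_like(times)
    N[0] = pore.N_o
    for i in range(1, times.size):
        dt = times[i] - times[i - 1]
        k1 = _pore_rate(N[i - 1], V_m[i - 1], pore)
        k2 = _pore_rate(N[i - 1] + dt * k1, V_m[i], pore)
        N[i] = N[i - 1] + 0.5 * dt * (k1 + k2)
    return N


def _pore_rate(N: float, V: float, pore: PoreParams) -> float:
    x = (V / pore.V_ep) ** 2
    return pore.alpha * math.exp(x) * (1.0 - (N / pore.N_o) * math.exp(-pore.q_pore * x))


def simulate_current(
    params: CircuitParams,
    drive: DriveWaveform,
    dt: float,
    pore: PoreParams | None = None,
    t_end: float | None = None,
    memory: int | None = None,
) -> CurrentTrace:
    """Time-step the series circuit under a piecewise-linear drive.

    Per step the Kirchhoff loop V_s = I R_e + V_m + V_dl is solved
    implicitly for the current I: the membrane branch advances by
    backward Euler (C_m dV_m/dt + G_m V_m = I) and the CPE by the
    full-memory Gruenwald-Letnikov form I = q d^p V_dl / dt^p.  With
    pore parameters the membrane conductance G_m(t) = G_o + N(t) A_m G_p
    evolves alongside via :func:`pore_dynamics` stepping.

    ``memory`` truncates the GL convolution to the most recent ``memory``
    steps (the short-memory principle); ``None`` keeps full memory.
    """
    if dt <= 0:
        raise CircuitError("dt must be positive")
    t_end = drive.t_end if t_end is None else t_end
    n = int(round(t_end / dt))
    if n < 1:
        raise CircuitError("drive does not span a single time step")
    times = dt * np.arange(n + 1)
    Vs = drive(times)

    w = gl_weights(params.p, n)
    dt_p = dt ** params.p
    V_dl = np.zeros(n + 1)
    I = np.zeros(n + 1)
    V_m = 0.0
    G_o = params.G_m
    N = pore.N_o if pore is not None else 0.0
    pore_N = np.full(n + 1, N)

    no_membrane = params.membrane_absent
    for i in range(1, n + 1):
        if pore is not None and not no_membrane:
            # advance the pore density with the previous membrane voltage
            k1 = _pore_rate(N, V_m, pore)
            N = N + dt * k1
            pore_N[i] = N
            G_m = G_o + N * params.A_m * pore.G_p
        else:
            G_m = G_o
        # history part of the GL derivative: sum_{k>=1} w_k V_dl[i-k]
        kmax = i if memory is None else min(i, memory)
        recent = V_dl[i - kmax:i][::-1]
        hist = float(np.dot(w[1:kmax + 1], recent))
        # unknown I_i; V_dl_i = I_i dt^p / q - hist  (w_0 = 1)
        # membrane: V_m_i = (C_m V_m / dt + I_i) / (C_m/dt + G_m)
        if no_membrane:
            a_m, b_m = 0.0, 0.0
        else:
            denom = params.C_m / dt + G_m
            a_m = (params.C_m / dt) * V_m / denom   # constant part of V_m_i
            b_m = 1.0 / denom                       # dV_m_i/dI_i
        # V_s = I R_e + (a_m + b_m I) + (I dt^p/q - hist)
        coeff = params.R_e + b_m + dt_p / params.q
        I_i = (Vs[i] - a_m + hist) / coeff
        if not math.isfinite(I_i):
            raise CircuitError(f"per-step solve diverged at t = {times[i]:.6g} s")
        V_dl[i] = I_i * dt_p / params.q - hist
        if not no_membrane:
            V_m = a_m + b_m * I_i
        I[i] = I_i

    trace = CurrentTrace(times=times, current=I, drive=drive)
    trace.pore_density = pore_N if pore is not None else None
    return trace


@dataclass
class FitResult:
    """Outcome of a circuit fit."""

    params: CircuitParams
    cost: float
    free: tuple[str, ...]
    unidentifiable: tuple[str, ...] = ()
    n_data: int = 0


_POSITIVE = ("R_e", "C_m", "G_m", "q")


def fit_circuit(
    spectrum: ImpedanceSpectrum | None = None,
    trace: CurrentTrace | None = None,
    which: tuple[str, ...] = ("R_e", "C_m", "G_m", "q", "p"),
    initial: CircuitParams | None = None,
    seed: int = 0,
    n_starts: int = 4,
    dt: float | None = None,
) -> FitResult:
    """Estimate circuit parameters from an impedance spectrum or a
    current trace by bounded least squares.

    Spectrum mode minimizes the joint residual of log10|Z| and the phase
    in degrees with equal weights; trace mode minimizes the current
    residual with :func:`simulate_current` inside the objective.
    Positive parameters are searched in log space; p within (0, 1].
    Multi-start initial perturbations are drawn from ``seed`` so the fit
    is deterministic.  Parameters not in ``which`` stay fixed at their
    ``initial`` values.
    """
    if (spectrum is None) == (trace is None):
        raise CircuitError("provide exactly one of spectrum or trace")
    for name in which:
        if name not in _POSITIVE + ("p",):
            raise CircuitError(f"unknown parameter {name!r}")
    if initial is None:
        initial = CircuitParams(R_e=1e3, C_m=1e-8, G_m=1e-6, q=1e-7, p=0.9)

    if spectrum is not None:
        n_data = 2 * spectrum.frequencies.size
        target = np.concatenate(
            [np.log10(spectrum.magnitude), spectrum.phase_deg]
        )
        if spectrum.frequencies.size < 2 and {"q", "p"} <= set(which):
            raise CircuitError(
                "q and p are not jointly identifiable from a single frequency"
            )
    else:
        n_data = trace.times.size
        target = trace.current
        if trace.drive is None:
            raise CircuitError("trace mode requires the drive waveform on the trace")
        if dt is None:
            dt = float(trace.times[1] - trace.times[0])
    if n_data < 2 * len(which):
        raise CircuitError(
            f"{n_data} data points cannot constrain {len(which)} free parameters"
        )

    def pack(cp: CircuitParams) -> np.ndarray:
        vals = []
        for name in which:
            v = getattr(cp, name)
            vals.append(math.log(v) if name in _POSITIVE else v)
        return np.array(vals)

    def unpack(x: np.ndarray) -> CircuitParams:
        kw = {}
        for name, v in zip(which, x):
            kw[name] = math.exp(v) if name in _POSITIVE else float(v)
        return replace(initial, **kw)

    def residual(x: np.ndarray) -> np.ndarray:
        cp = unpack(x)
        if spectrum is not None:
            model = impedance(cp, spectrum.frequencies)
            pred = np.concatenate([np.log10(model.magnitude), model.phase_deg])
        else:
            pred = simulate_current(cp, trace.drive, dt=dt,
                                    t_end=float(trace.times[-1])).current
            pred = np.interp(trace.times, dt * np.arange(pred.size), pred)
        return pred - target

    lo = np.array([-np.inf if n in _POSITIVE else 1e-6 for n in which])
    hi = np.array([np.inf if n in _POSITIVE else 1.0 for n in which])
    rng = np.random.default_rng(seed)
    x0 = pack(initial)
    best = None
    for s in range(max(1, n_starts)):
        xs = x0 if s == 0 else x0 + rng.normal(0, 0.3, size=x0.size)
        xs = np.clip(xs, lo, hi)
        try:
            sol = least_squares(residual, xs, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise CircuitError("all fit starts failed")

    fitted = unpack(best.x)
    # flag parameters the data cannot constrain (flat objective directions)
    unident = []
    J = best.jac
    col_norm = np.linalg.norm(J, axis=0)
    scale = max(col_norm.max(), 1e-300)
    for name, cn in zip(which, col_norm):
        if cn < 1e-8 * scale:
            unident.append(name)
    if unident:
        warnings.warn(
            f"parameters not identifiable from these data: {unident}", stacklevel=2
        )
    return FitResult(
        params=fitted,
        cost=float(best.cost),
        free=tuple(which),
        unidentifiable=tuple(unident),
        n_data=n_data,
    )


@dataclass
class PermittivityInputs:
    """Parallel-plate inversion inputs: C_m (F), h_m (m), A_m (m^2)."""

    C_m: float
    h_m: float
    A_m: float
    eps_0: float = EPSILON_0


def relative_permittivity(inputs: PermittivityInputs) -> float:
    """Relative membrane permittivity eps_m = C_m h_m / (eps_0 A_m).

    Warns when eps_m falls outside [2, 80] — below pure hydrocarbon or
    above electrolyte, both physically implausible for a membrane.
    """
    eps = inputs.C_m * inputs.h_m / (inputs.eps_0 * inputs.A_m)
    if not (2.0 <= eps <= 80.0):
        warnings.warn(
            f"eps_m = {eps:.3g} outside the plausible membrane range [2, 80]",
            stacklevel=2,
        )
    return float(eps)


def membrane_capacitance(eps_m: float, h_m: float, A_m: float,
                         eps_0: float = EPSILON_0) -> float:
    """Inverse of :func:`relative_permittivity`: C_m = eps_m eps_0 A_m / h_m."""
    return eps_m * eps_0 * A_m / h_m
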