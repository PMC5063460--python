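"""Lipid energetics: umbrella-sampling PMF reconstruction and derived
defect/flip-flop quantities.

The potential of mean force G(z) for moving a single lipid along the
membrane normal is assembled from harmonically biased windows with the
weighted histogram analysis method (WHAM).  From the PMF we extract

* the free energy of desorption — plateau value in the solvated region
  relative to the equilibrium minimum;
* the flip-flop barrier — highest point of G between the equilibrium
  position and the bilayer centre, which we identify with the defect
  formation energy DG_p;
* the equilibrium areal defect density rho_0 = exp(-beta DG_p) / A_L,
  with A_L the area per lipid.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE_MD, K_B, beta as _beta


class WhamError(ValueError):
    pass


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic bias 0.5*k*(z-center)^2.

    ``center`` in nm, ``k`` in kJ/mol/nm^2, ``samples`` are reaction
    coordinate values (nm) recorded after equilibration.
    """

    center: float
    k: float
    samples: np.ndarray
    equilibrated: bool = True

    def __post_init__(self) -> None:
        self.samples = np.atleast_1d(np.asarray(self.samples, dtype=float))
        if self.k < 0:
            raise ValueError(f"force constant must be >= 0, got {self.k}")
        if self.samples.size < 1:
            raise ValueError("window must contain at least one sample")

    def bias(self, z: np.ndarray) -> np.ndarray:
        """Bias energy at z (kJ/mol)."""
        return 0.5 * self.k * (np.asarray(z) - self.center) ** 2


@dataclass
class PMF:
    """Reconstructed potential of mean force along z."""

    bin_centers: np.ndarray
    G: np.ndarray
    support: np.ndarray  # per-bin sample counts
    iterations: int = 0
    final_change: float = np.nan
    temperature: float = DEFAULT_TEMPERATURE_MD

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.support = np.asarray(self.support)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.G)


@dataclass
class DefectModel:
    """Areal defect density from the defect-formation energy.

    rho_0 = exp(-beta * dG_p) / A_L  (nm^-2), with dG_p in kJ/mol and the
    area per lipid A_L in nm^2.
    """

    dG_p: float
    A_L: float
    temperature: float
    rho0: float = field(init=False)

    def __post_init__(self) -> None:
        if self.A_L <= 0:
            raise ValueError("area per lipid must be positive")
        self.rho0 = float(np.exp(-_beta(self.temperature) * self.dG_p) / self.A_L)


def umbrella_centers(z_max: float, spacing: float, z_min: float = 0.0) -> np.ndarray:
    """Evenly spaced window centres from z_min to z_max inclusive (nm).

    The count is ``round((z_max - z_min)/spacing) + 1``; e.g. a 5.4 nm
    half-range at 0.15 nm spacing gives 37 windows, a 4.7 nm half-range
    at 0.1 nm gives 48.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    n = int(round((z_max - z_min) / spacing)) + 1
    return z_min + spacing * np.arange(n)


def wham(
    windows: list[UmbrellaWindow],
    bins: int | np.ndarray | None = None,
    temperature: float = DEFAULT_TEMPERATURE_MD,
    rel_tol: float = 1e-4,
    max_iter: int = 100_000,
    bin_width: float = 0.05,
) -> PMF:
    """Weighted histogram analysis of harmonically biased windows.

    Self-consistently iterates the window free-energy offsets f_i

        p_j  propto  n_j / sum_i N_i exp(beta (f_i - w_i(z_j)))
        f_i  =  -kT ln sum_j c_ij p_j

    (Jacobi-style simultaneous updates) until the maximum relative change
    of the offsets drops below ``rel_tol``; the unbiased PMF is
    G = -kT ln p, gauge-shifted so its minimum over supported bins is 0.

    ``bins`` may be an explicit edge array or a count; by default bins of
    ``bin_width`` nm cover the pooled sample range.  Windows whose sample
    ranges do not chain with overlap trigger a connectivity warning — the
    iteration still converges but the relative offsets between
    disconnected segments are not determined by the data.
    """
    if not windows:
        raise WhamError("no umbrella windows given")
    if rel_tol <= 0:
        raise WhamError("rel_tol must be positive")
    kT = K_B * temperature
    beta = 1.0 / kT

    allz = np.concatenate([w.samples for w in windows])
    if isinstance(bins, np.ndarray):
        edges = np.asarray(bins, dtype=float)
    else:
        lo, hi = allz.min(), allz.max()
        if bins is None:
            n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
        else:
            n_bins = int(bins)
        # widen by half a bin so edge samples fall strictly inside
        pad = 0.5 * (hi - lo) / max(n_bins, 1) if hi > lo else 0.5 * bin_width
        edges = np.linspace(lo - pad, hi + pad, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    _check_overlap(windows)

    n_win = len(windows)
    N = np.array([w.samples.size for w in windows], dtype=float)
    hist = np.zeros((n_win, centers.size))
    for i, w in enumerate(windows):
        hist[i], _ = np.histogram(w.samples, bins=edges)
    n_j = hist.sum(axis=0)

    # bias factors c_ij = exp(-beta w_i(z_j))
    log_c = -beta * np.stack([w.bias(centers) for w in windows])

    f = np.zeros(n_win)
    it = 0
    change = np.inf
    for it in range(1, max_iter + 1):
        # denominator_j = sum_i N_i exp(beta f_i) c_ij
        log_terms = np.log(N)[:, None] + beta * f[:, None] + log_c
        log_denom = _logsumexp(log_terms, axis=0)
        with np.errstate(divide="ignore"):
            log_p = np.where(n_j > 0, np.log(np.maximum(n_j, 1e-300)) - log_denom, -np.inf)
        # f_i = -kT ln sum_j c_ij p_j
        new_f = -kT * _logsumexp(log_c + log_p[None, :], axis=1)
        new_f -= new_f[0]  # gauge: first window offset pinned at 0
        change = float(np.max(np.abs(new_f - f)) / max(1.0, np.max(np.abs(new_f))))
        f = new_f
        if change < rel_tol:
            break

    log_terms = np.log(N)[:, None] + beta * f[:, None] + log_c
    log_denom = _logsumexp(log_terms, axis=0)
    with np.errstate(divide="ignore"):
        log_p = np.where(n_j > 0, np.log(np.maximum(n_j, 1e-300)) - log_denom, -np.inf)
    G = np.where(n_j > 0, -kT * log_p, np.nan)
    G = G - np.nanmin(G)
    return PMF(
        bin_centers=centers,
        G=G,
        support=n_j,
        iterations=it,
        final_change=change,
        temperature=temperature,
    )


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    out = np.log(np.sum(np.exp(a - m), axis=axis)) + np.squeeze(m, axis=axis)
    return out


def _check_overlap(windows: list[UmbrellaWindow]) -> None:
    order = np.argsort([w.center for w in windows])
    prev_hi = None
    for i in order:
        w = windows[i]
        lo, hi = w.samples.min(), w.samples.max()
        if prev_hi is not None and lo > prev_hi:
            warnings.warn(
                f"umbrella windows do not overlap near z = {lo:.3g} nm; "
                "relative offsets across the gap are unconstrained",
                stacklevel=3,
            )
        prev_hi = hi if prev_hi is None else max(prev_hi, hi)


def desorption_energy(pmf: PMF, solvated_region: tuple[float, float]) -> float:
    """Free energy of lipid desorption (kJ/mol).

    Mean of G over the fully solvated plateau (``solvated_region``, nm)
    minus G at the global minimum (0 by gauge).
    """
    lo, hi = solvated_region
    sel = (pmf.bin_centers >= lo) & (pmf.bin_centers <= hi) & pmf.defined
    if not sel.any():
        raise WhamError(
            f"no supported PMF bins inside the solvated region [{lo}, {hi}] nm"
        )
    return float(np.mean(pmf.G[sel]) - np.nanmin(pmf.G))


def flipflop_barrier(pmf: PMF, center: float = 0.0) -> float:
    """Flip-flop free-energy barrier (kJ/mol).

    Maximum of G on the closed interval between the global-minimum
    position and the bilayer centre, relative to the minimum.  If the
    global minimum sits at the centre the barrier is degenerate; returns
    0 with a warning.
    """
    ok = pmf.defined
    if not ok.any():
        raise WhamError("PMF has no supported bins")
    z = pmf.bin_centers[ok]
    G = pmf.G[ok]
    i_min = int(np.argmin(G))
    z_min = z[i_min]
    lo, hi = sorted((z_min, center))
    sel = (z >= lo - 1e-12) & (z <= hi + 1e-12)
    if abs(z_min - center) < (z[1] - z[0] if z.size > 1 else 1e-9):
        warnings.warn("PMF minimum coincides with the bilayer centre", stacklevel=2)
        return 0.0
    return float(np.max(G[sel]) - G[i_min])


def defect_density(
    dG_p: float, A_L: float, temperature: float = DEFAULT_TEMPERATURE_MD
) -> DefectModel:
    """Equilibrium defect density rho_0 = exp(-beta dG_p)/A_L (nm^-2)."""
    return DefectModel(dG_p=dG_p, A_L=A_L, temperature=temperature)
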