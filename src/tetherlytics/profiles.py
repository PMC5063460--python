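"""Density and free-energy profiles along the membrane normal.

A trajectory is binned along z into a number-density profile; Boltzmann
inversion, F(z) = -k_B T ln(rho(z)/rho_o), turns the normalized density
into a free-energy profile; the headgroup density locates the two leaflet
planes, whose separation is the membrane thickness h_m and whose distance
from the electrode gives the tethering-reservoir height h_r.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .constants import DEFAULT_TEMPERATURE_MD, K_B, beta
from .core import SlabDomain, Trajectory


class ProfileError(ValueError):
    """Raised for profiles that cannot support the requested analysis."""


@dataclass
class AnalysisConfig:
    """Shared binning/thermodynamics settings.

    Parameters
    ----------
    temperature
        Analysis temperature (K); sets beta = 1/(k_B T).
    bin_width
        z-bin width (nm).  The default 0.05 nm resolves headgroup peaks
        (~0.5 nm apart) with ~10 bins per feature.
    bulk_bounds
        (z_lo, z_hi) range (nm) used to estimate the bulk density rho_o.
        ``None`` defaults to the upper quarter of the slab, i.e. the bulk
        electrolyte side.
    seed
        Seed for any stochastic post-processing (bootstraps).
    """

    temperature: float = DEFAULT_TEMPERATURE_MD
    bin_width: float = 0.05
    bulk_bounds: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        beta(self.temperature)  # validates temperature > 0

    @property
    def beta(self) -> float:
        """1/(k_B T) in mol/kJ."""
        return beta(self.temperature)


@dataclass
class DensityProfile:
    """Binned number density of one species along z."""

    bin_edges: np.ndarray
    counts: np.ndarray
    rho_norm: np.ndarray
    rho_bulk: float
    species: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.rho_norm = np.asarray(self.rho_norm, dtype=float)
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0], rtol=1e-8):
            raise ProfileError("bin widths must be uniform")
        if np.any(self.counts < 0):
            raise ProfileError("counts must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def empty(self) -> np.ndarray:
        """Mask of bins with no samples."""
        return self.counts == 0


@dataclass
class FreeEnergyProfile:
    """F(z) from Boltzmann inversion, gauge-fixed so min F = 0."""

    bin_centers: np.ndarray
    F: np.ndarray
    temperature: float
    mask: np.ndarray = field(default=None)  # True where F undefined

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.mask is None:
            self.mask = ~np.isfinite(self.F)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def defined(self) -> np.ndarray:
        return ~self.mask


def compute_density(
    traj: Trajectory, species: str, config: AnalysisConfig
) -> DensityProfile:
    """Bin a trajectory's z coordinates into a normalized density profile.

    The bulk density rho_o is estimated as the mean number density over
    ``config.bulk_bounds`` (default: the upper quarter of the slab, the
    bulk-electrolyte side).  Raises :class:`ProfileError` if the bulk
    region holds no samples, since the profile cannot then be normalized.
    """
    dom = traj.domain
    z = traj.z(species).ravel()
    n_bins = max(1, int(round(dom.width / config.bin_width)))
    edges = np.linspace(dom.z_b, dom.z_t, n_bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    bin_vol = (edges[1] - edges[0]) * dom.L_x * dom.L_y
    rho = counts / (traj.n_frames * bin_vol)

    if config.bulk_bounds is None:
        lo, hi = dom.z_t - 0.25 * dom.width, dom.z_t
    else:
        lo, hi = config.bulk_bounds
    centers = 0.5 * (edges[:-1] + edges[1:])
    bulk = (centers >= lo) & (centers <= hi)
    if not bulk.any() or counts[bulk].sum() == 0:
        raise ProfileError(
            f"bulk region [{lo:.3g}, {hi:.3g}] nm contains no samples; "
            "cannot estimate rho_o"
        )
    rho_bulk = float(rho[bulk].mean())
    return DensityProfile(
        bin_edges=edges,
        counts=counts,
        rho_norm=rho / rho_bulk,
        rho_bulk=rho_bulk,
        species=species,
    )


def free_energy_from_density(
    density: DensityProfile, config: AnalysisConfig
) -> FreeEnergyProfile:
    """Boltzmann-invert a normalized density: F = -k_B T ln(rho/rho_o).

    Empty bins are masked, never imputed; the profile is shifted so the
    minimum over defined bins is zero (gauge convention).
    """
    if density.empty.all():
        raise ProfileError("all bins empty; no free energy defined")
    kT = K_B * config.temperature
    with np.errstate(divide="ignore"):
        F = -kT * np.log(np.where(density.rho_norm > 0, density.rho_norm, np.nan))
    mask = density.empty | ~np.isfinite(F)
    F = F - np.nanmin(F[~mask])
    F[mask] = np.nan
    return FreeEnergyProfile(
        bin_centers=density.bin_centers,
        F=F,
        temperature=config.temperature,
        mask=mask,
    )


def _parabolic_refine(centers: np.ndarray, values: np.ndarray, i: int) -> float:
    """Sub-bin peak position from a parabola through the 3 bins around i."""
    if i == 0 or i == len(values) - 1:
        return float(centers[i])
    y0, y1, y2 = values[i - 1], values[i], values[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(centers[i])
    delta = 0.5 * (y0 - y2) / denom
    dz = centers[1] - centers[0]
    return float(centers[i] + np.clip(delta, -0.5, 0.5) * dz)


def headgroup_peaks(density: DensityProfile) -> tuple[float, float]:
    """Locate the two dominant headgroup peaks (nm), proximal first.

    Each peak is refined by 3-point parabolic interpolation around the
    binned maximum.  Raises :class:`ProfileError` with a diagnostic when
    fewer than two local maxima exist (e.g. a monomodal profile).
    """
    y = density.rho_norm
    # pad so maxima sitting on the first/last bin still count as peaks
    idx, _ = find_peaks(np.concatenate(([-np.inf], y, [-np.inf])))
    idx -= 1
    if len(idx) < 2:
        raise ProfileError(
            f"need >= 2 local maxima in the headgroup density, found {len(idx)}; "
            "is this a bilayer headgroup profile?"
        )
    # two dominant peaks, returned in z order
    top = idx[np.argsort(y[idx])[-2:]]
    centers = density.bin_centers
    z1, z2 = sorted(_parabolic_refine(centers, y, i) for i in top)
    return z1, z2


def membrane_thickness(headgroup_density: DensityProfile) -> float:
    """Membrane thickness h_m (nm): separation of the two headgroup peaks."""
    z1, z2 = headgroup_peaks(headgroup_density)
    return z2 - z1


def reservoir_thickness(
    headgroup_density: DensityProfile, domain: SlabDomain
) -> float:
    """Tethering-reservoir height h_r (nm): electrode to proximal peak.

    Falls back to the single available maximum if the profile is
    monomodal (a membrane-less electrode still has a proximal water
    structure peak); warns in that case.
    """
    try:
        z1, _ = headgroup_peaks(headgroup_density)
    except ProfileError:
        y = headgroup_density.rho_norm
        i = int(np.argmax(y))
        z1 = _parabolic_refine(headgroup_density.bin_centers, y, i)
        warnings.warn(
            "monomodal profile: using its single maximum as the proximal peak",
            stacklevel=2,
        )
    return z1 - domain.z_b
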