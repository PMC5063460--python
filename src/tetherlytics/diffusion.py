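"""Spatially resolved diffusion estimators.

Two complementary estimators:

* **Lateral** — the diffusion tensor is diagonal with D_xx = D_yy, so
  the lateral coefficient follows from the time-and-ensemble averaged
  mean-squared displacement, <(x - x_o)^2> = 2 D_xx (t - t_o), fitted
  over a lag window per species and leaflet/region.

* **Perpendicular** — no-flux walls make D_zz position dependent; it is
  recovered from the mean round-trip time tau_rt(z) (time to go from z
  to a reference z_*, and back to z):

      D_zz(z) = e^{beta F(z)} / (d tau_rt / dz) * int_zb^zt e^{-beta F} dz'

  The round-trip times are harvested directly from the z time series by
  first-passage detection, and the slope is regularized with a local
  polynomial (Savitzky-Golay) derivative.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .constants import NM2_NS_TO_NM2_US
from .core import SlabDomain, Trajectory
from .profiles import AnalysisConfig, DensityProfile, FreeEnergyProfile, headgroup_peaks


class DiffusionError(ValueError):
    pass


@dataclass
class RoundTripProfile:
    """Mean round-trip times tau_rt(z) against a reference position z_*."""

    bin_centers: np.ndarray
    tau_rt: np.ndarray          # ns, NaN where masked
    counts: np.ndarray          # completed excursions per bin
    z_star: float
    slope: np.ndarray = None    # d tau_rt / dz, ns/nm

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.tau_rt = np.asarray(self.tau_rt, dtype=float)
        self.counts = np.asarray(self.counts)

    @property
    def defined(self) -> np.ndarray:
        return self.counts > 0


@dataclass
class DiffusionProfile:
    """Perpendicular diffusion D_zz(z), nm^2/ns."""

    bin_centers: np.ndarray
    D_zz: np.ndarray
    valid: np.ndarray


@dataclass
class LateralDiffusionResult:
    """Lateral diffusion for one species within one region.

    ``D_par`` and ``uncertainty`` are reported in nm^2/us, the customary
    scale for lipid lateral diffusion.
    """

    species: str
    region: str
    D_par: float
    uncertainty: float
    fit_window: tuple[float, float]
    n_particles: int = 0

    def __post_init__(self) -> None:
        if self.D_par < 0 or self.uncertainty < 0:
            raise DiffusionError("diffusion and uncertainty must be non-negative")


def assign_regions(
    traj: Trajectory,
    headgroups: DensityProfile,
    domain: SlabDomain,
    water_species: tuple[str, ...] = ("W", "water"),
) -> np.ndarray:
    """Label every particle by leaflet or water region.

    Lipids are proximal/distal according to their time-mean z relative to
    the bilayer midplane (midpoint of the two headgroup peaks); water is
    ``reservoir_water`` below the proximal peak, ``bulk_water`` above the
    distal peak, and ``interfacial_water`` in between.  Time-mean rather
    than per-frame assignment avoids fragmenting trajectories at the rare
    flip-flop events.
    """
    z1, z2 = headgroup_peaks(headgroups)  # raises if peaks missing
    midplane = 0.5 * (z1 + z2)
    mean_z = traj.positions[:, :, 2].mean(axis=0)
    labels = np.empty(traj.n_particles, dtype=object)
    is_water = np.isin(traj.species, water_species)
    labels[~is_water & (mean_z <= midplane)] = "proximal"
    labels[~is_water & (mean_z > midplane)] = "distal"
    labels[is_water & (mean_z < z1)] = "reservoir_water"
    labels[is_water & (mean_z > z2)] = "bulk_water"
    labels[is_water & (mean_z >= z1) & (mean_z <= z2)] = "interfacial_water"
    return labels.astype(str)


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """Time-averaged MSD for every lag, per column, via FFT autocorrelation."""
    n = x.shape[0]
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft(fx * np.conj(fx), n=nfft, axis=0)[:n].real
    sq = x ** 2
    css = np.cumsum(sq, axis=0)
    total = css[-1]
    lags = np.arange(n)
    # S1(m) = sum_{k=0}^{n-1-m} x_k^2 + sum_{k=m}^{n-1} x_k^2
    zero = np.zeros((1,) + x.shape[1:])
    s1 = css[::-1] + (total - np.concatenate([zero, css[:-1]]))
    norm = (n - lags)[:, None] if x.ndim > 1 else (n - lags)
    return (s1 - 2 * acf) / norm


def lateral_diffusion_msd(
    traj: Trajectory,
    selection: str | np.ndarray,
    fit_window: tuple[float, float] = (1.0, 10.0),
    region: str = "",
    n_bootstrap: int = 200,
    seed: int = 0,
) -> LateralDiffusionResult:
    """Lateral diffusion from the time-and-ensemble averaged MSD.

    ``selection`` is a species label or a boolean particle mask.  The MSD
    is computed per axis (x and y separately); D per axis is half the
    least-squares slope over the lag window (ns), and D_par their mean.
    The uncertainty combines half the |x - y| split with a bootstrap
    standard error over particles.  Raises on wrapped lateral
    coordinates (any single-frame jump beyond half a box length).
    """
    if isinstance(selection, str):
        mask = traj.select(selection)
        species = selection
    else:
        mask = np.asarray(selection, dtype=bool)
        species = "selection"
    xy = traj.positions[:, mask, :2]
    if xy.shape[1] == 0:
        raise DiffusionError("empty selection")
    jumps = np.abs(np.diff(xy, axis=0))
    if jumps.size and (
        np.any(jumps[:, :, 0] > 0.5 * traj.domain.L_x)
        or np.any(jumps[:, :, 1] > 0.5 * traj.domain.L_y)
    ):
        raise DiffusionError(
            "lateral jump exceeding half a box length detected: coordinates "
            "appear periodically wrapped; unwrap before MSD analysis"
        )

    dt = traj.frame_interval
    t_min, t_max = fit_window
    n = xy.shape[0]
    lags = np.arange(n)
    in_window = (lags * dt >= t_min) & (lags * dt <= t_max) & (lags > 0)
    if in_window.sum() < 2:
        raise DiffusionError(
            f"fewer than 2 lag points inside the fit window {fit_window} ns "
            f"(trajectory spans {(n - 1) * dt:.4g} ns at {dt:.4g} ns/frame)"
        )

    # per-particle, per-axis MSD; average over particles afterwards
    msd_x = _msd_fft(xy[:, :, 0])
    msd_y = _msd_fft(xy[:, :, 1])
    tau = lags[in_window] * dt

    def slope(msd_mean: np.ndarray) -> float:
        A = np.vstack([tau, np.ones_like(tau)]).T
        coef, *_ = np.linalg.lstsq(A, msd_mean[in_window], rcond=None)
        return float(coef[0])

    Dx = slope(msd_x.mean(axis=1)) / 2.0
    Dy = slope(msd_y.mean(axis=1)) / 2.0
    D_par = 0.5 * (Dx + Dy)

    rng = np.random.default_rng(seed)
    n_p = xy.shape[1]
    boots = np.empty(n_bootstrap)
    for bidx in range(n_bootstrap):
        pick = rng.integers(0, n_p, size=n_p)
        bx = slope(msd_x[:, pick].mean(axis=1)) / 2.0
        by = slope(msd_y[:, pick].mean(axis=1)) / 2.0
        boots[bidx] = 0.5 * (bx + by)
    se = float(boots.std(ddof=1)) if n_bootstrap > 1 else 0.0
    axis_split = 0.5 * abs(Dx - Dy)
    err = float(np.hypot(axis_split, se))

    return LateralDiffusionResult(
        species=species,
        region=region,
        D_par=max(D_par, 0.0) * NM2_NS_TO_NM2_US,
        uncertainty=err * NM2_NS_TO_NM2_US,
        fit_window=fit_window,
        n_particles=int(n_p),
    )


def _crossings(z: np.ndarray, level: float) -> np.ndarray:
    """Frame indices just after z crosses (or touches) a level."""
    s = z - level
    hit = (s[:-1] * s[1:] <= 0) & ~((s[:-1] == 0) & (s[1:] == 0))
    idx = np.nonzero(hit)[0] + 1
    return idx


def round_trip_times(
    traj: Trajectory,
    bins: int | np.ndarray = 50,
    z_star: float | None = None,
    slope_window: int = 7,
    species: str | None = None,
) -> RoundTripProfile:
    """Harvest mean round-trip times tau_rt(z) from z time series.

    For every bin centre z the trajectory is scanned for non-overlapping
    completed excursions z -> z_* -> z, detected by level crossings of
    the z series; their mean duration estimates tau_rt(z) (the sum of the
    two mean first-passage legs).  The default reference z_* is half a
    bin above the lower wall, which maximizes completed excursions for
    membrane-spanning profiles.  Bins with no completed round trip are
    masked (NaN), never zero.  The slope d tau_rt/dz is a local quadratic
    (Savitzky-Golay) derivative over ``slope_window`` bins.
    """
    dom = traj.domain
    if isinstance(bins, np.ndarray):
        edges = np.asarray(bins, dtype=float)
    else:
        edges = np.linspace(dom.z_b, dom.z_t, int(bins) + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if z_star is None:
        z_star = float(centers[0])
    if not (dom.z_b <= z_star <= dom.z_t):
        raise DiffusionError(f"z_star = {z_star} outside the slab")

    zs = traj.z(species) if species else traj.positions[:, :, 2]
    times = traj.times
    total = np.zeros(centers.size)
    counts = np.zeros(centers.size, dtype=int)

    for pidx in range(zs.shape[1]):
        z = zs[:, pidx]
        cross_star = _crossings(z, z_star)
        if cross_star.size == 0:
            continue
        for k, zk in enumerate(centers):
            if abs(zk - z_star) < 1e-12:
                continue
            cross_k = _crossings(z, zk)
            if cross_k.size == 0:
                continue
            pos = 0
            while True:
                # start of an excursion at level zk
                i = cross_k[pos] if pos < cross_k.size else None
                if i is None:
                    break
                # first passage to z_*
                j_idx = np.searchsorted(cross_star, i, side="right")
                if j_idx >= cross_star.size:
                    break
                j = cross_star[j_idx]
                # return to zk
                e_idx = np.searchsorted(cross_k, j, side="right")
                if e_idx >= cross_k.size:
                    break
                e = cross_k[e_idx]
                total[k] += times[e] - times[i]
                counts[k] += 1
                pos = int(np.searchsorted(cross_k, e, side="right"))

    tau = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    slope = _sg_slope(centers, tau, counts > 0, slope_window)
    return RoundTripProfile(
        bin_centers=centers, tau_rt=tau, counts=counts, z_star=z_star, slope=slope
    )


def _sg_slope(z: np.ndarray, tau: np.ndarray, ok: np.ndarray, window: int) -> np.ndarray:
    """Savitzky-Golay first derivative on the defined bins; NaN elsewhere."""
    slope = np.full_like(tau, np.nan)
    if ok.sum() < 3:
        return slope
    idx = np.nonzero(ok)[0]
    # interpolate over interior gaps so the filter sees a contiguous series
    zz = z[idx[0]: idx[-1] + 1]
    tt = tau[idx[0]: idx[-1] + 1]
    bad = ~np.isfinite(tt)
    if bad.any():
        tt = tt.copy()
        tt[bad] = np.interp(zz[bad], zz[~bad], tt[~bad])
    win = min(window if window % 2 == 1 else window + 1, len(tt) - (1 - len(tt) % 2))
    if win < 3:
        return slope
    dz = z[1] - z[0]
    der = savgol_filter(tt, window_length=win, polyorder=min(2, win - 1),
                        deriv=1, delta=dz)
    slope[idx[0]: idx[-1] + 1] = der
    slope[~ok] = np.nan
    return slope


def perpendicular_diffusion(
    rt: RoundTripProfile,
    F: FreeEnergyProfile,
    config: AnalysisConfig,
) -> DiffusionProfile:
    """Position-dependent perpendicular diffusion from round-trip times.

    D_zz(z) = e^{beta F(z)} / (d tau_rt/dz) * int e^{-beta F(z')} dz'.
    F is interpolated onto the round-trip bins; the partition integral is
    a trapezoid over the defined free-energy bins.  Bins with
    non-positive slope, undefined F, or no round-trip support are masked.
    """
    b = config.beta
    okF = F.defined
    if not okF.any():
        raise DiffusionError("free-energy profile entirely undefined")
    Fi = np.interp(rt.bin_centers, F.bin_centers[okF], F.F[okF])
    partition = np.trapezoid(np.exp(-b * F.F[okF]), F.bin_centers[okF])

    slope = rt.slope if rt.slope is not None else np.full_like(rt.tau_rt, np.nan)
    valid = rt.defined & np.isfinite(slope) & (slope > 0)
    if not valid.any():
        raise DiffusionError(
            "round-trip slope has no valid (positive, defined) bins; "
            "cannot invert for D_zz"
        )
    D = np.full_like(Fi, np.nan)
    D[valid] = np.exp(b * Fi[valid]) * partition / slope[valid]
    return DiffusionProfile(bin_centers=rt.bin_centers, D_zz=D, valid=valid)


def diffusion_reduction_factors(table: pd.DataFrame) -> pd.DataFrame:
    """Tether-induced and cross-species diffusion ratios.

    ``table`` needs columns ``tether_density`` (e.g. "0%", "25%"),
    ``species``, ``region`` and ``D_par``; exactly two tether densities
    must be present.  Returns one row per ratio:

    * ``tether_reduction`` — D(low density)/D(high density) per
      species/region pair;
    * ``species_ratio`` — DphPC/GDPE within each density and region where
      both species occur;
    * ``water_ratio`` — bulk over reservoir water within each density.

    Raises :class:`DiffusionError` when a required pairing is missing.
    """
    req = {"tether_density", "species", "region", "D_par"}
    if not req <= set(table.columns):
        raise DiffusionError(f"table must have columns {sorted(req)}")
    densities = sorted(table["tether_density"].unique(),
                       key=lambda s: float(str(s).rstrip("%")))
    if len(densities) != 2:
        raise DiffusionError(
            f"need exactly two tether densities, got {densities}"
        )
    lo, hi = densities
    rows = []

    def lookup(density, species, region):
        sel = table[(table.tether_density == density)
                    & (table.species == species)
                    & (table.region == region)]
        if len(sel) != 1:
            raise DiffusionError(
                f"missing or ambiguous entry: density={density} "
                f"species={species} region={region}"
            )
        return float(sel["D_par"].iloc[0])

    pairs = table[["species", "region"]].drop_duplicates()
    for _, (sp, rg) in pairs.iterrows():
        try:
            ratio = lookup(lo, sp, rg) / lookup(hi, sp, rg)
        except DiffusionError:
            continue
        rows.append({"kind": "tether_reduction", "species": sp, "region": rg,
                     "densities": f"{lo}/{hi}", "ratio": ratio})

    for density in densities:
        sub = table[table.tether_density == density]
        for rg in sub["region"].unique():
            sps = set(sub[sub.region == rg]["species"])
            if {"DphPC", "GDPE"} <= sps:
                ratio = lookup(density, "DphPC", rg) / lookup(density, "GDPE", rg)
                rows.append({"kind": "species_ratio", "species": "DphPC/GDPE",
                             "region": rg, "densities": density, "ratio": ratio})
        regions = set(sub["region"])
        if {"bulk_water", "reservoir_water"} <= regions:
            sp = sub[sub.region == "bulk_water"]["species"].iloc[0]
            ratio = (lookup(density, sp, "bulk_water")
                     / lookup(density, sp, "reservoir_water"))
            rows.append({"kind": "water_ratio", "species": sp,
                         "region": "bulk/reservoir", "densities": density,
                         "ratio": ratio})
    if not rows:
        raise DiffusionError("no computable ratios: check the pairings")
    return pd.DataFrame(rows)
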