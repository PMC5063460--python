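"""Readers and writers for the package's plain-text formats.

Every format is delimited text with a commented header so outputs stay
diff-able; floats are written with ``repr`` precision so a write/read
round trip is lossless.

Trajectory format (versioned)::

    # tetherlytics-traj v1 z_b z_t L_x L_y dt
    frame time particle_id species x y z
    ...

An optional GRO+XTC reader (via MDAnalysis, if installed) exposes
standard MD trajectories behind the same :class:`~tetherlytics.core.Trajectory`
contract.
"""
from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SlabDomain, Trajectory, TrajectoryError
from .diffusion import DiffusionProfile, RoundTripProfile
from .electrical import CurrentTrace, DriveWaveform, ImpedanceSpectrum
from .energetics import PMF, UmbrellaWindow
from .profiles import DensityProfile, FreeEnergyProfile

TRAJ_MAGIC = "tetherlytics-traj"
TRAJ_VERSION = "v1"


class FormatError(ValueError):
    pass


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    dt = traj.frame_interval
    with path.open("w") as fh:
        fh.write(
            f"# {TRAJ_MAGIC} {TRAJ_VERSION} {traj.domain.z_b!r} {traj.domain.z_t!r} "
            f"{traj.domain.L_x!r} {traj.domain.L_y!r} {float(dt)!r}\n"
        )
        fh.write("# frame time particle_id species x y z\n")
        for f in range(traj.n_frames):
            t = float(traj.times[f])
            for pidx in range(traj.n_particles):
                x, y, z = (float(v) for v in traj.positions[f, pidx])
                fh.write(
                    f"{f} {t!r} {pidx} {traj.species[pidx]} {x!r} {y!r} {z!r}\n"
                )


def read_trajectory(path: str | Path, format: str = "native",
                    topology: str | Path | None = None) -> Trajectory:
    """Read a trajectory.

    ``format="native"`` parses the versioned text format written by
    :func:`write_trajectory`; ``format="gro+xtc"`` reads a GRO topology
    (``topology``) plus XTC trajectory (``path``) through MDAnalysis.
    Validation against the slab bounds happens in the
    :class:`~tetherlytics.core.Trajectory` constructor and names the
    offending frame and particle.
    """
    if format == "native":
        return _read_native(Path(path))
    if format == "gro+xtc":
        return _read_gro_xtc(Path(path), Path(topology))
    raise FormatError(f"unknown trajectory format {format!r}")


def _read_native(path: Path) -> Trajectory:
    with path.open() as fh:
        header = fh.readline()
        parts = header.split()
        if (len(parts) != 8 or parts[0] != "#" or parts[1] != TRAJ_MAGIC
                or parts[2] != TRAJ_VERSION):
            raise FormatError(
                f"{path}:1: malformed trajectory header: expected "
                f"'# {TRAJ_MAGIC} {TRAJ_VERSION} z_b z_t L_x L_y dt', got "
                f"{header.strip()!r}"
            )
        z_b, z_t, L_x, L_y, _dt = map(float, parts[3:8])
        domain = SlabDomain(z_b=z_b, z_t=z_t, L_x=L_x, L_y=L_y)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            bits = line.split()
            if len(bits) != 7:
                raise FormatError(
                    f"{path}:{lineno}: expected 7 fields, got {len(bits)}"
                )
            try:
                rows.append((int(bits[0]), float(bits[1]), int(bits[2]),
                             bits[3], float(bits[4]), float(bits[5]),
                             float(bits[6])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise FormatError(f"{path}: no trajectory rows")
    frames = sorted({r[0] for r in rows})
    pids = sorted({r[2] for r in rows})
    f_index = {f: i for i, f in enumerate(frames)}
    p_index = {p: i for i, p in enumerate(pids)}
    times = np.full(len(frames), np.nan)
    pos = np.full((len(frames), len(pids), 3), np.nan)
    species = np.empty(len(pids), dtype=object)
    for f, t, pidx, sp, x, y, z in rows:
        fi, pi = f_index[f], p_index[pidx]
        times[fi] = t
        pos[fi, pi] = (x, y, z)
        species[pi] = sp
    if np.isnan(pos).any():
        raise FormatError(f"{path}: missing particle rows in some frames")
    return Trajectory(times=times, positions=pos, species=species.astype(str),
                      domain=domain)


def _read_gro_xtc(xtc: Path, gro: Path) -> Trajectory:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise FormatError(
            "reading GRO+XTC requires the optional MDAnalysis dependency"
        ) from exc
    u = mda.Universe(str(gro), str(xtc))
    n_frames = len(u.trajectory)
    n_atoms = len(u.atoms)
    pos = np.empty((n_frames, n_atoms, 3))
    times = np.empty(n_frames)
    Lx = Ly = Lz = None
    for i, ts in enumerate(u.trajectory):
        pos[i] = ts.positions / 10.0  # Angstrom -> nm
        times[i] = ts.time / 1000.0   # ps -> ns
        Lx, Ly, Lz = ts.dimensions[:3] / 10.0
    domain = SlabDomain(z_b=float(pos[:, :, 2].min()),
                        z_t=float(pos[:, :, 2].max()),
                        L_x=float(Lx), L_y=float(Ly))
    return Trajectory(times=times, positions=pos,
                      species=np.array(u.atoms.names, dtype=str), domain=domain)


# ---------------------------------------------------------------------------
# profile / PMF / spectra tables

def write_profiles(density: DensityProfile, free_energy: FreeEnergyProfile | None,
                   path: str | Path) -> None:
    """TSV: z_center  rho_norm  F_kJ_per_mol  n_samples."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# tetherlytics-profiles v1\n")
        fh.write("# z_center\trho_norm\tF_kJ_per_mol\tn_samples\n")
        F = (free_energy.F if free_energy is not None
             else np.full(density.bin_centers.size, np.nan))
        for z, r, f, n in zip(density.bin_centers, density.rho_norm, F,
                              density.counts):
            fh.write(f"{float(z)!r}\t{float(r)!r}\t{float(f)!r}\t{float(n)!r}\n")


def read_profiles(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip",
                       names=["z_center", "rho_norm", "F_kJ_per_mol",
                              "n_samples"])


def write_pmf(pmf: PMF, path: str | Path) -> None:
    """TSV: z  G  n."""
    with Path(path).open("w") as fh:
        fh.write("# tetherlytics-pmf v1\n# z\tG\tn\n")
        for z, g, n in zip(pmf.bin_centers, pmf.G, pmf.support):
            fh.write(f"{float(z)!r}\t{float(g)!r}\t{float(n)!r}\n")


def read_pmf(path: str | Path) -> PMF:
    df = pd.read_csv(path, sep="\t", comment="#", names=["z", "G", "n"],
                     float_precision="round_trip")
    return PMF(bin_centers=df["z"].to_numpy(), G=df["G"].to_numpy(),
               support=df["n"].to_numpy())


def write_window(window: UmbrellaWindow, path: str | Path) -> None:
    """One window per file: header '# center k', one sample per line."""
    with Path(path).open("w") as fh:
        fh.write(f"# {float(window.center)!r} {float(window.k)!r}\n")
        for s in window.samples:
            fh.write(f"{float(s)!r}\n")


def read_window(path: str | Path) -> UmbrellaWindow:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        if len(header) != 3 or header[0] != "#":
            raise FormatError(f"{path}:1: malformed window header")
        center, k = float(header[1]), float(header[2])
        samples = np.array([float(line) for line in fh if line.strip()])
    return UmbrellaWindow(center=center, k=k, samples=samples)


def write_spectrum(spec: ImpedanceSpectrum, path: str | Path) -> None:
    """CSV: freq_hz, zmag_ohm, phase_deg (signed phase)."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["freq_hz", "zmag_ohm", "phase_deg"])
        for f, m, ph in zip(spec.frequencies, spec.magnitude, spec.phase_deg):
            w.writerow([repr(float(f)), repr(float(m)), repr(float(ph))])


def read_spectrum(path: str | Path) -> ImpedanceSpectrum:
    df = pd.read_csv(path, float_precision="round_trip")
    Z = df["zmag_ohm"].to_numpy() * np.exp(1j * np.radians(df["phase_deg"].to_numpy()))
    return ImpedanceSpectrum(frequencies=df["freq_hz"].to_numpy(), Z=Z)


def write_trace(trace: CurrentTrace, path: str | Path) -> None:
    """CSV: t_s, i_a, v_s."""
    vs = (trace.drive(trace.times) if trace.drive is not None
          else np.full(trace.times.size, np.nan))
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t_s", "i_a", "v_s"])
        for t, i, v in zip(trace.times, trace.current, vs):
            w.writerow([repr(float(t)), repr(float(i)), repr(float(v))])


def read_trace(path: str | Path) -> CurrentTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    return CurrentTrace(times=df["t_s"].to_numpy(), current=df["i_a"].to_numpy())


def write_rtt(rt: RoundTripProfile, D: DiffusionProfile | None,
              path: str | Path) -> None:
    """TSV: z  tau_rt  slope  D_zz."""
    Dz = (D.D_zz if D is not None else np.full(rt.bin_centers.size, np.nan))
    with Path(path).open("w") as fh:
        fh.write("# tetherlytics-rtt v1\n# z\ttau_rt\tslope\tD_zz\n")
        for z, tau, s, d in zip(rt.bin_centers, rt.tau_rt, rt.slope, Dz):
            fh.write(f"{float(z)!r}\t{float(tau)!r}\t{float(s)!r}\t{float(d)!r}\n")
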