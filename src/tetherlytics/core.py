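"""Core geometric and trajectory containers shared by all analysis stages.

The geometry is a slab: periodic in x and y, bounded by reflecting walls
in z (the gold electrode below, the far solvent boundary above).  All
particle trajectories analysed by this package live in such a slab.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TrajectoryError(ValueError):
    """Raised when a trajectory violates the slab/timing contract."""


@dataclass(frozen=True)
class SlabDomain:
    """Wall-bounded slab geometry.

    Parameters
    ----------
    z_b, z_t
        Lower and upper reflecting-wall positions (nm).  ``z_b`` is the
        bioelectronic interface, ``z_t`` the opposite boundary.
    L_x, L_y
        Lateral box lengths (nm); the box is periodic in x and y.
    """

    z_b: float
    z_t: float
    L_x: float
    L_y: float

    def __post_init__(self) -> None:
        if not self.z_t > self.z_b:
            raise ValueError(f"z_t ({self.z_t}) must exceed z_b ({self.z_b})")
        if self.L_x <= 0 or self.L_y <= 0:
            raise ValueError("lateral box lengths must be positive")

    @property
    def width(self) -> float:
        """Slab width z_t - z_b (nm)."""
        return self.z_t - self.z_b

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.z_b + self.z_t)

    def contains_z(self, z: np.ndarray, atol: float = 1e-9) -> bool:
        z = np.asarray(z)
        return bool(np.all(z >= self.z_b - atol) and np.all(z <= self.z_t + atol))


@dataclass
class Trajectory:
    """Particle trajectory in a slab.

    Attributes
    ----------
    times
        Frame times (ns), strictly increasing and uniformly spaced.
    positions
        Array of shape ``(n_frames, n_particles, 3)`` in nm.  Lateral
        coordinates (x, y) are stored *unwrapped* (no periodic jumps) so
        that mean-squared displacements can be taken directly; z always
        lies within ``[z_b, z_t]``.
    species
        Length-``n_particles`` array of species labels (e.g. ``"W"``,
        ``"DphPC"``, ``"headgroup"``).
    domain
        The slab the trajectory lives in.
    """

    times: np.ndarray
    positions: np.ndarray
    species: np.ndarray
    domain: SlabDomain
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.species = np.asarray(self.species)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise TrajectoryError(
                f"positions must have shape (n_frames, n_particles, 3), "
                f"got {self.positions.shape}"
            )
        if self.times.shape[0] != self.positions.shape[0]:
            raise TrajectoryError("times and positions disagree on frame count")
        if self.species.shape[0] != self.positions.shape[1]:
            raise TrajectoryError("species and positions disagree on particle count")
        if self.times.size > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise TrajectoryError("frame times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise TrajectoryError("frame times must be uniformly spaced")
        if not self.domain.contains_z(self.positions[:, :, 2]):
            bad = np.argwhere(
                (self.positions[:, :, 2] < self.domain.z_b - 1e-9)
                | (self.positions[:, :, 2] > self.domain.z_t + 1e-9)
            )
            frame, particle = bad[0]
            raise TrajectoryError(
                f"z out of slab bounds at frame {frame}, particle {particle}: "
                f"z={self.positions[frame, particle, 2]:.6g} not in "
                f"[{self.domain.z_b}, {self.domain.z_t}]"
            )

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def frame_interval(self) -> float:
        """Frame spacing (ns)."""
        if self.times.size < 2:
            return float("nan")
        return float(self.times[1] - self.times[0])

    def select(self, species: str) -> np.ndarray:
        """Boolean particle mask for one species label."""
        mask = self.species == species
        if not mask.any():
            raise TrajectoryError(
                f"species {species!r} not present; available: "
                f"{sorted(set(self.species.tolist()))}"
            )
        return mask

    def z(self, species: str | None = None) -> np.ndarray:
        """z coordinates, shape (n_frames, n_selected)."""
        if species is None:
            return self.positions[:, :, 2]
        return self.positions[:, self.select(species), 2]
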