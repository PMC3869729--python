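"""Brownian-dynamics generator for numerical single-molecule trajectories.

Trajectories are integrated with sub-stepping: each recorded frame interval
dt is divided into ``substeps`` (default 1000) Langevin substeps.  The random
part of every substep is drawn with the step-length convention of the
reference generator: a Gaussian *length* g ~ Normal(0, sqrt(4*D*dt_sub))
paired with an angle uniform on [0, 2*pi) -- not independent Gaussian
coordinates.  The per-substep second moment E|step|^2 = 4*D*dt_sub matches
2-D Brownian diffusion, and at 1000 substeps per frame the recorded steps
are Gaussian to high accuracy by the central limit theorem.

If a confining potential is active the deterministic drift
F(r) * D * dt_sub / kBT is added to every substep (F = -grad V; potentials
are stored in kBT units so the friction never appears explicitly).
Substeps are recorded, not averaged: only every ``substeps``-th position is
kept.  Finally, static positioning noise -- a displacement with Gaussian
magnitude of standard deviation sigma and uniform angle -- is added
independently to every *recorded* position, never to substeps.

A confining segment's potential is centered on the particle position at the
segment's first frame, so transient confinement zones trap the molecule
where it currently is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .models import KT_310, PolynomialPotential
from .trajectory import Trajectory

__all__ = [
    "SimConfig",
    "Segment",
    "ModeSchedule",
    "draw_step",
    "simulate",
    "estimate_D_msd",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    D: diffusion coefficient (um^2/s, > 0); dt: acquisition interval (s, > 0);
    n_frames: recorded frames (>= 2); sigma: static positioning noise (um);
    substeps: Langevin substeps per frame (default 1000); kT: thermal energy
    (pN*um, default 4.28e-3 i.e. 310 K) used only for unit conversion;
    seed: RNG seed.
    """

    D: float
    dt: float
    n_frames: int
    sigma: float = 0.0
    substeps: int = 1000
    kT: float = KT_310
    seed: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.D) and self.D >= 0.0):
            raise ValueError(f"D must be finite and >= 0, got {self.D}")
        if not (math.isfinite(self.dt) and self.dt > 0.0):
            raise ValueError(f"dt must be finite and > 0, got {self.dt}")
        if self.n_frames < 2:
            raise ValueError(f"n_frames must be >= 2, got {self.n_frames}")
        if not (math.isfinite(self.sigma) and self.sigma >= 0.0):
            raise ValueError(f"sigma must be finite and >= 0, got {self.sigma}")
        if self.substeps < 1:
            raise ValueError(f"substeps must be >= 1, got {self.substeps}")
        if not (math.isfinite(self.kT) and self.kT > 0.0):
            raise ValueError(f"kT must be finite and > 0, got {self.kT}")


@dataclass(frozen=True)
class Segment:
    """Frames [start, end] (0-based, inclusive) governed by one mode."""

    start: int
    end: int
    potential: PolynomialPotential | None = None

    @property
    def mode_name(self) -> str:
        if self.potential is None:
            return "free"
        return "spring2" if self.potential.order == 2 else "quartic4"


@dataclass(frozen=True)
class ModeSchedule:
    """Contiguous, non-overlapping segments covering every frame."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule must contain at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))
        prev_end = -1
        for seg in self.segments:
            if seg.start != prev_end + 1:
                raise ValueError(
                    f"segments must be contiguous: segment starting at {seg.start} "
                    f"does not follow previous end {prev_end}"
                )
            if seg.end < seg.start:
                raise ValueError(f"segment end {seg.end} < start {seg.start}")
            prev_end = seg.end

    @property
    def n_frames(self) -> int:
        return self.segments[-1].end + 1

    def validate(self, n_frames: int) -> None:
        if self.segments[0].start != 0 or self.n_frames != n_frames:
            raise ValueError(
                f"schedule covers frames 0..{self.n_frames - 1}, "
                f"but the trajectory has {n_frames} frames"
            )

    @classmethod
    def free(cls, n_frames: int) -> "ModeSchedule":
        return cls((Segment(0, n_frames - 1, None),))

    @classmethod
    def confined(cls, n_frames: int, potential: PolynomialPotential) -> "ModeSchedule":
        return cls((Segment(0, n_frames - 1, potential),))

    @classmethod
    def switch(
        cls, n_frames: int, potential: PolynomialPotential, switch_frame: int
    ) -> "ModeSchedule":
        """Confined for frames [0, switch_frame - 1], free afterwards."""
        return cls(
            (
                Segment(0, switch_frame - 1, potential),
                Segment(switch_frame, n_frames - 1, None),
            )
        )

    @classmethod
    def zones(
        cls,
        n_frames: int,
        potential: PolynomialPotential,
        zones: list[tuple[int, int]],
    ) -> "ModeSchedule":
        """Free motion interleaved with confined zones [(start, end), ...]."""
        segs: list[Segment] = []
        cursor = 0
        for a, b in sorted(zones):
            if a > cursor:
                segs.append(Segment(cursor, a - 1, None))
            segs.append(Segment(a, b, potential))
            cursor = b + 1
        if cursor <= n_frames - 1:
            segs.append(Segment(cursor, n_frames - 1, None))
        return cls(tuple(segs))


def draw_step(D: float, dt: float, rng: np.random.Generator, size: int | None = None):
    """Random Brownian displacement(s): Gaussian length, uniform angle.

    The length is |g| with g ~ Normal(0, sqrt(4*D*dt)); the angle is uniform
    on [0, 2*pi).  Returns a (2,) vector, or (size, 2) when ``size`` is given.
    """
    if D < 0.0:
        raise ValueError(f"D must be >= 0, got {D}")
    if dt < 0.0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    n = 1 if size is None else size
    g = np.abs(rng.normal(0.0, math.sqrt(4.0 * D * dt), size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    out = np.column_stack([g * np.cos(theta), g * np.sin(theta)])
    return out[0] if size is None else out


@njit(cache=True)
def _integrate_confined(x0, y0, dx, dy, n_rec, substeps, drift, pis, pjs, pcs, ox, oy):
    """Sequential Langevin substeps under a polynomial force; records every
    ``substeps``-th position."""
    out_x = np.empty(n_rec)
    out_y = np.empty(n_rec)
    x = x0
    y = y0
    idx = 0
    n_mono = pcs.size
    for f in range(n_rec):
        for _ in range(substeps):
            xl = x - ox
            yl = y - oy
            fx = 0.0
            fy = 0.0
            for m in range(n_mono):
                i = pis[m]
                j = pjs[m]
                c = pcs[m]
                if i > 0:
                    fx -= i * c * xl ** (i - 1) * yl**j
                if j > 0:
                    fy -= j * c * xl**i * yl ** (j - 1)
            x += dx[idx] + fx * drift
            y += dy[idx] + fy * drift
            idx += 1
        out_x[f] = x
        out_y[f] = y
    return out_x, out_y


def _potential_arrays(potential: PolynomialPotential):
    items = sorted(potential.coeffs.items())
    pis = np.array([i for (i, _), _ in items], dtype=np.int64)
    pjs = np.array([j for (_, j), _ in items], dtype=np.int64)
    pcs = np.array([c for _, c in items], dtype=np.float64)
    return pis, pjs, pcs


def simulate(config: SimConfig, schedule: ModeSchedule) -> Trajectory:
    """Generate one trajectory under ``schedule`` (see module docstring).

    The step from frame f to f+1 is governed by the segment containing frame
    f.  Ground-truth per-frame labels are attached to the returned trajectory.
    """
    schedule.validate(config.n_frames)
    n = config.n_frames
    sub = config.substeps
    dt_sub = config.dt / sub
    rng = np.random.default_rng(config.seed)

    x = np.empty(n)
    y = np.empty(n)
    labels = np.empty(n, dtype=object)
    x[0] = 0.0
    y[0] = 0.0
    for seg in schedule.segments:
        labels[seg.start : seg.end + 1] = seg.mode_name
        # steps whose origin frame lies in this segment
        first_step = seg.start
        last_step = min(seg.end, n - 2)
        n_rec = last_step - first_step + 1
        if n_rec <= 0:
            continue
        # random substep displacements (Gaussian length, uniform angle)
        g = np.abs(rng.normal(0.0, math.sqrt(4.0 * config.D * dt_sub), n_rec * sub))
        theta = rng.uniform(0.0, 2.0 * np.pi, n_rec * sub)
        dx = g * np.cos(theta)
        dy = g * np.sin(theta)
        x0 = x[first_step]
        y0 = y[first_step]
        if seg.potential is None:
            # pure diffusion: recorded positions are partial sums
            seg_x = x0 + np.cumsum(np.add.reduceat(dx, np.arange(0, n_rec * sub, sub)))
            seg_y = y0 + np.cumsum(np.add.reduceat(dy, np.arange(0, n_rec * sub, sub)))
        else:
            pis, pjs, pcs = _potential_arrays(seg.potential)
            seg_x, seg_y = _integrate_confined(
                x0, y0, dx, dy, n_rec, sub, config.D * dt_sub, pis, pjs, pcs, x0, y0
            )
        x[first_step + 1 : last_step + 2] = seg_x
        y[first_step + 1 : last_step + 2] = seg_y

    if config.sigma > 0.0:
        g = np.abs(rng.normal(0.0, config.sigma, n))
        theta = rng.uniform(0.0, 2.0 * np.pi, n)
        x = x + g * np.cos(theta)
        y = y + g * np.sin(theta)

    t = np.arange(n) * config.dt
    return Trajectory(t, x, y, labels)


def estimate_D_msd(traj: Trajectory, sigma: float = 0.0) -> float:
    """Method-of-moments diffusion estimate from one-frame displacements:
    sum |dr|^2 / (4 (N-1) dt) minus the noise contribution sigma^2/dt."""
    dr = traj.displacements
    raw = float(np.sum(dr * dr) / (4.0 * dr.shape[0] * traj.dt))
    return raw - sigma * sigma / traj.dt
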