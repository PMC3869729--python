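"""Residence-time confinement detector (Simson-style baseline).

The classical sliding-window detector scores how improbable it is that a
freely diffusing molecule with known diffusion coefficient D would stay
inside the region it actually occupied.  For a window of w frames the
occupied region is the disk of radius R -- the maximal displacement from
the window's center position (arithmetic mean of the window's positions) --
and the stay probability over the window duration t = w*dt is approximated
by the empirical formula

    psi = 10 ** (0.2048 - 2.5117 * D * t / R^2),   clamped to [0, 1].

Nonrandom behavior is accentuated by the probability level

    L = |log10 psi| - 1   if psi <= 0.1,   else 0,

and runs of central frames with L above a cutoff Lc lasting longer than a
critical time tc are reported as confinement zones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .temporal import ConfinementZone
from .trajectory import Trajectory

__all__ = [
    "ResidenceConfig",
    "residence_psi",
    "probability_level",
    "residence_profile",
    "residence_detect",
    "calibrate_thresholds",
]


@dataclass(frozen=True)
class ResidenceConfig:
    """Detector settings: assumed D (um^2/s), window w (frames, odd),
    probability-level cutoff Lc, and minimum super-threshold duration tc (s).

    The defaults Lc = 1.0 and tc = 2.0 s come from a grid search on the
    packaged three-zone simulation ensembles (:func:`calibrate_thresholds`):
    they maximize recovered true zones (30/30) subject to at most one false
    zone per 5-trajectory ensemble, with ties broken toward the mildest
    thresholds (see docs/methods.md and scripts/calibrate_residence.py)."""

    D: float
    w: int = 51
    Lc: float = 1.0
    tc: float = 2.0

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise ValueError(f"D must be > 0, got {self.D}")
        if self.w < 3 or self.w % 2 == 0:
            raise ValueError(f"w must be an odd integer >= 3, got {self.w}")
        if not self.Lc > 0 or not self.tc > 0:
            raise ValueError("Lc and tc must be > 0")


def residence_psi(D: float, t: float, R: float) -> float:
    """Probability that a free Brownian walker stays within radius R for
    time t (empirical approximation, clamped to [0, 1])."""
    if not (D > 0 and t > 0 and R > 0):
        raise ValueError(f"D, t, R must all be > 0, got D={D}, t={t}, R={R}")
    exponent = 0.2048 - 2.5117 * D * t / (R * R)
    return float(min(10.0**exponent, 1.0))


def probability_level(psi: float) -> float:
    """Accentuated improbability level L of a stay probability psi."""
    if not 0.0 <= psi <= 1.0:
        raise ValueError(f"psi must be in [0, 1], got {psi}")
    if psi <= 0.1:
        if psi == 0.0:
            return math.inf
        return abs(math.log10(psi)) - 1.0
    return 0.0


def residence_profile(traj: Trajectory, cfg: ResidenceConfig):
    """Per-central-frame probability level L along the trajectory.

    Returns (centers, L): 0-based central-frame indices (half-window
    trimmed at both ends) and the corresponding levels.
    """
    n = traj.n_frames
    if n < cfg.w:
        raise ValueError(f"trajectory has {n} frames, shorter than window {cfg.w}")
    h = cfg.w // 2
    t_win = cfg.w * traj.dt
    centers = np.arange(h, n - h)
    L = np.empty(centers.size)
    x = traj.x
    y = traj.y
    for out_i, c in enumerate(centers):
        wx = x[c - h : c + h + 1]
        wy = y[c - h : c + h + 1]
        mx = wx.mean()
        my = wy.mean()
        R = float(np.sqrt(np.max((wx - mx) ** 2 + (wy - my) ** 2)))
        if R == 0.0:
            L[out_i] = math.inf
            continue
        L[out_i] = probability_level(residence_psi(cfg.D, t_win, R))
    return centers, L


def residence_detect(traj: Trajectory, cfg: ResidenceConfig) -> list[ConfinementZone]:
    """Confinement zones: runs with L > Lc lasting longer than tc."""
    centers, L = residence_profile(traj, cfg)
    above = L > cfg.Lc
    zones: list[ConfinementZone] = []
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            if (j - i + 1) * traj.dt > cfg.tc:
                zones.append(ConfinementZone(int(centers[i]), int(centers[j])))
            i = j + 1
        else:
            i += 1
    return zones


def calibrate_thresholds(
    lc_grid=(0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 2.5, 3.0),
    tc_grid=(0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0),
    max_false_per_set: int = 1,
    D: float | None = None,
    w: int = 51,
):
    """Grid-search the (Lc, tc) defaults on the packaged three-zone fixtures.

    Maximizes the number of recovered true zones across both three-zone
    ensembles subject to at most ``max_false_per_set`` false zones per
    5-trajectory ensemble; ties break toward fewer false zones, then toward
    the mildest thresholds.  Returns (best_config, results_table) where the
    table holds (Lc, tc, matched, false) per grid point.
    """
    from . import defaults
    from .fixtures import make_fixture, truth_zones
    from .temporal import match_zones

    if D is None:
        D = defaults.D
    ensembles = [make_fixture(name) for name in ("fig8_zones_k03", "fig8_zones_k06")]
    truth = truth_zones()
    rows = []
    best = None
    for Lc in lc_grid:
        for tc in tc_grid:
            cfg = ResidenceConfig(D=D, w=w, Lc=Lc, tc=tc)
            matched = 0
            false_per_set = []
            for trajs in ensembles:
                fp = 0
                for traj in trajs:
                    m, f = match_zones(residence_detect(traj, cfg), truth)
                    matched += m
                    fp += f
                false_per_set.append(fp)
            feasible = max(false_per_set) <= max_false_per_set
            rows.append((Lc, tc, matched, sum(false_per_set), feasible))
            if feasible:
                key = (-matched, sum(false_per_set), tc, Lc)
                if best is None or key < best[0]:
                    best = (key, cfg)
    return (best[1] if best is not None else None), rows
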