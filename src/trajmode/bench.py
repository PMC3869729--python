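"""Decision-map sweeps and threshold scans over simulation parameters.

These reproduce, at configurable replicate counts, the validation
experiments behind the decision tree: for each cell of a parameter grid,
simulate an ensemble of trajectories under a known true model, classify
each one per criterion (or with the full tree), and record the fraction of
correct decisions.  A 0.5 threshold on that fraction defines the usable
parameter region; a 1-D scan locates the boundary value where the fraction
first crosses 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from . import defaults
from .criteria import classify, decision_histogram
from .models import ModelLabel, PolynomialPotential, quartic_strength_matching_spring
from .simulate import ModeSchedule, SimConfig, simulate
from .trajectory import Trajectory

__all__ = ["SweepSpec", "DecisionMap", "simulate_ensemble", "run_sweep", "threshold_scan"]

_CRITERIA = ("bic", "aic", "aicc")


def _make_potential(truth: ModelLabel, k_kT: float, u_kT: float):
    if truth is ModelLabel.FREE:
        return None
    if truth is ModelLabel.SPRING2:
        return PolynomialPotential.spring(k_kT)
    return PolynomialPotential.quartic(u_kT)


def simulate_ensemble(
    truth: ModelLabel,
    count: int,
    n_frames: int,
    D: float = defaults.D,
    dt: float = defaults.DT,
    sigma: float = defaults.SIGMA,
    k_kT: float = defaults.K_KT,
    u_kT: float = defaults.U_KT,
    substeps: int = 1000,
    seed: int = 0,
) -> list[Trajectory]:
    """Simulate ``count`` independent trajectories under one true model."""
    potential = _make_potential(truth, k_kT, u_kT)
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=count)
    out = []
    for s in child_seeds:
        cfg = SimConfig(
            D=D, dt=dt, n_frames=n_frames, sigma=sigma, substeps=substeps, seed=int(s)
        )
        schedule = (
            ModeSchedule.free(n_frames)
            if potential is None
            else ModeSchedule.confined(n_frames, potential)
        )
        out.append(simulate(cfg, schedule))
    return out


@dataclass(frozen=True)
class SweepSpec:
    """One grid sweep: the varied axes, the fixed conditions, the truth.

    ``grid`` maps axis names (any of n_frames, D, dt, k_kT, u_kT, sigma) to
    value lists; ``fixed`` overrides the module defaults for the remaining
    parameters.  When the truth is quartic and only ``k_kT`` is varied, the
    quartic strength tracks it (variance-matched) unless u_kT is given.
    """

    truth: ModelLabel
    grid: dict[str, list] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)
    replicates: int = 50
    criteria: tuple[str, ...] = _CRITERIA
    score_tree: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for axis, values in self.grid.items():
            if len(values) == 0:
                raise ValueError(f"empty grid for axis {axis!r}")
        for crit in self.criteria:
            if crit not in _CRITERIA:
                raise ValueError(f"unknown criterion {crit!r}")


@dataclass(frozen=True)
class DecisionMap:
    """Per-cell correct-decision fractions with a 0.5 threshold mask."""

    table: pd.DataFrame
    threshold: float = 0.5

    def fractions(self, criterion: str) -> np.ndarray:
        return self.table[f"frac_{criterion}"].to_numpy()

    def mask(self, criterion: str) -> np.ndarray:
        """True where the criterion is usable (fraction > threshold)."""
        return self.fractions(criterion) > self.threshold


def _cell_params(spec: SweepSpec, combo: dict) -> dict:
    params = {
        "n_frames": 500,
        "D": defaults.D,
        "dt": defaults.DT,
        "sigma": defaults.SIGMA,
        "k_kT": defaults.K_KT,
        "u_kT": None,
        "substeps": 1000,
    }
    params.update(spec.fixed)
    params.update(combo)
    if params["u_kT"] is None:
        params["u_kT"] = quartic_strength_matching_spring(params["k_kT"])
    return params


def run_sweep(spec: SweepSpec) -> DecisionMap:
    """Simulate and score every grid cell; deterministic given spec.seed."""
    axes = list(spec.grid.keys())
    grids = [spec.grid[a] for a in axes]
    mesh = np.meshgrid(*grids, indexing="ij") if axes else []
    combos = (
        [dict(zip(axes, vals)) for vals in zip(*(m.ravel() for m in mesh))]
        if axes
        else [{}]
    )
    rng = np.random.default_rng(spec.seed)
    rows = []
    for combo in combos:
        cell_seed = int(rng.integers(0, 2**31 - 1))
        params = _cell_params(spec, combo)
        n_frames = int(params["n_frames"])
        row = dict(combo)
        row["n_frames"] = n_frames
        infeasible = n_frames < 2
        if infeasible:
            for crit in spec.criteria:
                row[f"frac_{crit}"] = np.nan
            rows.append(row)
            continue
        trajs = simulate_ensemble(
            spec.truth,
            count=spec.replicates,
            n_frames=n_frames,
            D=params["D"],
            dt=params["dt"],
            sigma=params["sigma"],
            k_kT=params["k_kT"],
            u_kT=params["u_kT"],
            substeps=int(params["substeps"]),
            seed=cell_seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for crit in spec.criteria:
                hist = decision_histogram(trajs, criterion=crit, sigma=params["sigma"])
                row[f"frac_{crit}"] = hist[spec.truth]
            if spec.score_tree:
                correct = sum(
                    1
                    for t in trajs
                    if classify(t, sigma=params["sigma"]).label is spec.truth
                )
                row["frac_tree"] = correct / len(trajs)
        rows.append(row)
    return DecisionMap(table=pd.DataFrame(rows))


def threshold_scan(
    axis: str,
    grid: Iterable,
    truth: ModelLabel,
    criterion: str,
    replicates: int = 50,
    fixed: dict | None = None,
    seed: int = 0,
    side: str = "min",
):
    """Boundary value along a monotone 1-D grid where the correct-decision
    fraction crosses 0.5.

    side="min": smallest grid value with fraction > 0.5 (e.g. the minimum
    usable trajectory length); side="max": largest such value.  Returns
    None when no grid value crosses the threshold (out of range).
    """
    grid = list(grid)
    if sorted(grid) != grid:
        raise ValueError("grid must be sorted ascending")
    spec = SweepSpec(
        truth=truth,
        grid={axis: grid},
        fixed=fixed or {},
        replicates=replicates,
        criteria=(criterion,),
        seed=seed,
    )
    dmap = run_sweep(spec)
    ok = dmap.mask(criterion)
    values = dmap.table[axis].to_numpy()
    passing = values[ok]
    if passing.size == 0:
        return None
    return type(grid[0])(passing.min() if side == "min" else passing.max())
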