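"""Seeded fixture generators for the validation experiments.

Every validation experiment runs on trajectories produced here, so the
whole test suite regenerates its data deterministically at run time -- no
files ship with the package.  Each fixture has a fixed default seed and
regenerating with the same name and seed is bit-identical.

Fixtures
--------
fig2_free / fig3_spring / fig4_quartic
    Ensembles of 500-frame trajectories under one true mode, at the default
    study conditions (D = 0.1 um^2/s, dt = 50 ms, sigma = 30 nm,
    k = 0.3 pN/um, variance-matched quartic strength).
fig7_switch
    50 trajectories of 500 frames, spring-confined for frames 0..249 and
    free from frame 250 on (SWITCH_FRAME).
fig8_zones_k03 / fig8_zones_k06
    5 trajectories of 1200 frames (60 s at 50 ms/frame) with three
    200-frame confinement zones at frames 100-299, 500-699 and 900-1099
    (ZONES), spring constant 0.3 or 0.6 pN/um.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import defaults
from .models import PolynomialPotential, spring_constant_to_kT
from .simulate import ModeSchedule, SimConfig, simulate
from .temporal import ConfinementZone
from .trajectory import Trajectory

__all__ = [
    "SWITCH_FRAME",
    "ZONES",
    "FixtureSpec",
    "available_fixtures",
    "make_fixture",
    "truth_zones",
]

#: first free frame of the fig7-style switch trajectories (0-based)
SWITCH_FRAME = 250

#: ground-truth confinement zones of the three-zone trajectories (inclusive)
ZONES = ((100, 299), (500, 699), (900, 1099))


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    count: int
    n_frames: int
    seed: int
    builder: Callable[["FixtureSpec", int], Trajectory]


def _ensemble_builder(potential_factory):
    def build(spec: FixtureSpec, seed: int) -> Trajectory:
        pot = potential_factory()
        schedule = (
            ModeSchedule.free(spec.n_frames)
            if pot is None
            else ModeSchedule.confined(spec.n_frames, pot)
        )
        cfg = SimConfig(
            D=defaults.D,
            dt=defaults.DT,
            n_frames=spec.n_frames,
            sigma=defaults.SIGMA,
            seed=seed,
        )
        return simulate(cfg, schedule)

    return build


def _switch_builder(spec: FixtureSpec, seed: int) -> Trajectory:
    pot = PolynomialPotential.spring(defaults.K_KT)
    schedule = ModeSchedule.switch(spec.n_frames, pot, SWITCH_FRAME)
    cfg = SimConfig(
        D=defaults.D,
        dt=defaults.DT,
        n_frames=spec.n_frames,
        sigma=defaults.SIGMA,
        seed=seed,
    )
    return simulate(cfg, schedule)


def _zones_builder(k_pN: float):
    def build(spec: FixtureSpec, seed: int) -> Trajectory:
        pot = PolynomialPotential.spring(spring_constant_to_kT(k_pN))
        schedule = ModeSchedule.zones(spec.n_frames, pot, list(ZONES))
        cfg = SimConfig(
            D=defaults.D,
            dt=defaults.DT,
            n_frames=spec.n_frames,
            sigma=defaults.SIGMA,
            seed=seed,
        )
        return simulate(cfg, schedule)

    return build


_REGISTRY: dict[str, FixtureSpec] = {
    spec.name: spec
    for spec in (
        FixtureSpec("fig2_free", 300, 500, 20201, _ensemble_builder(lambda: None)),
        FixtureSpec(
            "fig3_spring",
            300,
            500,
            20302,
            _ensemble_builder(lambda: PolynomialPotential.spring(defaults.K_KT)),
        ),
        FixtureSpec(
            "fig4_quartic",
            300,
            500,
            20403,
            _ensemble_builder(lambda: PolynomialPotential.quartic(defaults.U_KT)),
        ),
        FixtureSpec("fig7_switch", 50, 500, 20704, _switch_builder),
        FixtureSpec("fig8_zones_k03", 5, 1200, 20805, _zones_builder(0.3)),
        FixtureSpec("fig8_zones_k06", 5, 1200, 20806, _zones_builder(0.6)),
    )
}


def available_fixtures() -> list[str]:
    return sorted(_REGISTRY)


def make_fixture(
    name: str, count: int | None = None, seed: int | None = None
) -> list[Trajectory]:
    """Generate a named fixture ensemble (with ground-truth frame labels).

    ``count`` reduces/extends the ensemble; ``seed`` overrides the fixture's
    versioned default.  Unknown names raise an error listing the registry.
    """
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(available_fixtures())}"
        )
    spec = _REGISTRY[name]
    n = spec.count if count is None else count
    base_seed = spec.seed if seed is None else seed
    # one deterministic sub-seed per trajectory
    rng = np.random.default_rng(base_seed)
    child = rng.integers(0, 2**31 - 1, size=n)
    return [spec.builder(spec, int(s)) for s in child]


def truth_zones() -> list[ConfinementZone]:
    """Ground-truth zones of the three-zone fixtures as zone objects."""
    return [ConfinementZone(a, b) for a, b in ZONES]
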