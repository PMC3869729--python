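"""TOML configuration for the simulator.

Layout::

    [sim]
    D = 0.1          # um^2/s
    dt = 0.05        # s
    n_frames = 500
    sigma = 0.03     # um
    substeps = 1000
    seed = 1

    [[segment]]      # optional; omit for a fully free trajectory
    start = 0
    end = 249
    mode = "spring2" # free | spring2 | quartic4
    k = 70.09        # kBT/um^2 (spring2)

    [[segment]]
    start = 250
    end = 499
    mode = "free"

Quartic segments take ``u`` (kBT/um^4) instead of ``k``.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .models import PolynomialPotential
from .simulate import ModeSchedule, Segment, SimConfig

__all__ = ["load_sim_config"]


def _segment_potential(entry: dict) -> PolynomialPotential | None:
    mode = entry.get("mode", "free")
    if mode == "free":
        return None
    if mode == "spring2":
        return PolynomialPotential.spring(float(entry["k"]))
    if mode == "quartic4":
        return PolynomialPotential.quartic(float(entry["u"]))
    raise ValueError(f"unknown segment mode {mode!r}")


def load_sim_config(path) -> tuple[SimConfig, ModeSchedule]:
    """Read a simulation config (settings + mode schedule) from TOML."""
    data = tomllib.loads(Path(path).read_text())
    if "sim" not in data:
        raise ValueError(f"{path}: missing [sim] table")
    cfg = SimConfig(**data["sim"])
    entries = data.get("segment")
    if not entries:
        schedule = ModeSchedule.free(cfg.n_frames)
    else:
        schedule = ModeSchedule(
            tuple(
                Segment(int(e["start"]), int(e["end"]), _segment_potential(e))
                for e in entries
            )
        )
        schedule.validate(cfg.n_frames)
    return cfg, schedule
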