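"""Mode classification with temporal resolution along a trajectory.

A window of w frames (default 51, odd) slides along the trajectory; for
each central frame the first stage of the decision tree -- BIC comparison
of free Brownian motion against spring confinement -- is evaluated on the
window's sub-trajectory.  Only FREE vs SPRING2 is distinguished here: 51
frames are far below the ~500 needed to resolve the potential order, and
transient confinement detection only needs the free/confined boundary.

Central frames within half a window of either trajectory end carry no
label.  The raw label series is then low-pass filtered (a mode switch must
persist for several consecutive window positions to be accepted) and
maximal confined runs above a minimum duration become confinement zones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .criteria import information_criteria
from .inference import (
    _fit_confined_arrays,
    _fit_free_arrays,
    _step_centers_arrays,
    _DEGENERATE_PAD,
)
from .models import ModelLabel, N_FREE_PARAMS
from .trajectory import Trajectory

__all__ = [
    "LabelSeries",
    "ConfinementZone",
    "window_classify",
    "lowpass",
    "extract_zones",
    "match_zones",
    "detect_switch",
]


@dataclass(frozen=True)
class LabelSeries:
    """Per-central-frame labels from the sliding-window classifier.

    ``centers`` are 0-based frame indices w//2 .. N-1-w//2; ``labels`` hold
    ModelLabel values (FREE or SPRING2) aligned with ``centers``.
    """

    centers: np.ndarray
    labels: np.ndarray
    w: int

    def __post_init__(self) -> None:
        if self.centers.size != self.labels.size:
            raise ValueError("centers and labels must have equal length")

    def __len__(self) -> int:
        return self.centers.size

    def with_labels(self, labels: np.ndarray) -> "LabelSeries":
        return LabelSeries(self.centers, np.asarray(labels), self.w)


@dataclass(frozen=True)
class ConfinementZone:
    """Inclusive central-frame range classified as confined."""

    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("zone end before start")

    @property
    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def overlaps(self, other: "ConfinementZone") -> bool:
        return self.start_frame <= other.end_frame and other.start_frame <= self.end_frame


def window_classify(
    traj: Trajectory, w: int = 51, sigma: float = 0.0, n_bins: int = 10
) -> LabelSeries:
    """Label every full-window central frame FREE or SPRING2 via the BIC.

    For each central frame c the window spans frames [c - w//2, c + w//2];
    FREE and SPRING2 are fitted on that portion and the lower BIC wins
    (ties go to FREE, consistent with the whole-trajectory tree).
    """
    if w % 2 == 0 or w < 3:
        raise ValueError(f"window size must be an odd integer >= 3, got {w}")
    n = traj.n_frames
    if n < w:
        raise ValueError(
            f"trajectory has {n} frames, shorter than the window ({w}); "
            "use a smaller window"
        )
    h = w // 2
    dt = traj.dt
    x = traj.x
    y = traj.y
    dr_all = traj.displacements
    pad = sigma if sigma > 0.0 else _DEGENERATE_PAD
    n_steps = w - 1
    k_free = N_FREE_PARAMS[ModelLabel.FREE]
    k_spring = N_FREE_PARAMS[ModelLabel.SPRING2]
    centers = np.arange(h, n - h)
    labels = np.empty(centers.size, dtype=object)
    for out_i, c in enumerate(centers):
        lo = c - h
        hi = c + h + 1  # frames [lo, hi)
        dr = dr_all[lo : hi - 1]
        _, _, lm_free, _ = _fit_free_arrays(dr, dt, sigma)
        step_centers = _step_centers_arrays(x[lo:hi], y[lo:hi], n_bins, pad)
        _, _, lm_spring, _, _, _ = _fit_confined_arrays(
            dr, step_centers, dt, sigma, order=2
        )
        bic_free = k_free * math.log(n_steps) - 2.0 * lm_free
        bic_spring = k_spring * math.log(n_steps) - 2.0 * lm_spring
        labels[out_i] = (
            ModelLabel.FREE if bic_free <= bic_spring else ModelLabel.SPRING2
        )
    return LabelSeries(centers=centers, labels=labels, w=w)


def lowpass(series: LabelSeries, persistence: int = 3) -> LabelSeries:
    """Suppress short-lived mode switches.

    The output starts in the first input label; it switches at position i
    only when the ``persistence`` input labels starting at i all carry the
    new mode, otherwise the previous output label persists.
    """
    if persistence < 1:
        raise ValueError(f"persistence must be >= 1, got {persistence}")
    labels = series.labels
    n = labels.size
    out = np.empty(n, dtype=object)
    current = labels[0]
    for i in range(n):
        if labels[i] != current:
            run = labels[i : i + persistence]
            if run.size == persistence and all(v == labels[i] for v in run):
                current = labels[i]
        out[i] = current
    return series.with_labels(out)


def extract_zones(series: LabelSeries, min_duration: int = 25) -> list[ConfinementZone]:
    """Maximal SPRING2 runs of at least ``min_duration`` central frames."""
    if min_duration < 1:
        raise ValueError(f"min_duration must be >= 1, got {min_duration}")
    zones: list[ConfinementZone] = []
    labels = series.labels
    centers = series.centers
    i = 0
    n = labels.size
    while i < n:
        if labels[i] == ModelLabel.SPRING2:
            j = i
            while j + 1 < n and labels[j + 1] == ModelLabel.SPRING2:
                j += 1
            if j - i + 1 >= min_duration:
                zones.append(
                    ConfinementZone(int(centers[i]), int(centers[j]))
                )
            i = j + 1
        else:
            i += 1
    return zones


def match_zones(
    detected: list[ConfinementZone], truth: list[ConfinementZone]
) -> tuple[int, int]:
    """Score detections against ground truth by frame-range overlap.

    A detection matches a ground-truth zone when their ranges overlap; each
    ground-truth zone can be matched at most once.  Returns
    (n_matched_truth, n_false_positives).
    """
    matched_truth: set[int] = set()
    false_pos = 0
    for det in sorted(detected, key=lambda z: z.start_frame):
        hit = None
        for idx, tz in enumerate(truth):
            if idx not in matched_truth and det.overlaps(tz):
                hit = idx
                break
        if hit is None:
            false_pos += 1
        else:
            matched_truth.add(hit)
    return len(matched_truth), false_pos


def estimate_switch_frame(series: LabelSeries) -> int:
    """Best-fit confined-to-free change point of a (possibly noisy) series.

    Fits a step profile (SPRING2 before, FREE from the change on) to the
    labels by minimizing the number of mismatched positions and returns the
    first central frame of the free side.  On a clean series with a single
    confined-to-free change this coincides with :func:`detect_switch`; on a
    series with residual label flips it is the maximum-agreement change
    point (earliest such point on ties).
    """
    labels = series.labels
    n = labels.size
    is_free = np.array([lab == ModelLabel.FREE for lab in labels], dtype=int)
    # mismatches when the switch occurs before position c: free labels on the
    # confined side plus confined labels on the free side
    free_prefix = np.concatenate([[0], np.cumsum(is_free)])
    total_free = free_prefix[-1]
    c = np.arange(n + 1)
    mismatch = free_prefix[c] + (n - c) - (total_free - free_prefix[c])
    best = int(np.argmin(mismatch))
    if best >= n:
        best = n - 1
    return int(series.centers[best])


def detect_switch(series: LabelSeries) -> int:
    """Central frame at which a single mode change takes effect.

    Requires a (filtered) series with exactly one change point; returns the
    first central frame carrying the new mode.  Zero or multiple switches
    raise an error listing all change points.
    """
    labels = series.labels
    change_idx = [
        i for i in range(1, labels.size) if labels[i] != labels[i - 1]
    ]
    if len(change_idx) != 1:
        frames = [int(series.centers[i]) for i in change_idx]
        raise ValueError(
            f"expected exactly one mode change, found {len(change_idx)} "
            f"(at central frames {frames})"
        )
    return int(series.centers[change_idx[0]])
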