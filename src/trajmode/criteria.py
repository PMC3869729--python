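"""Information criteria and the two-stage decision tree.

For each candidate model the penalized model-selection scores are computed
from the MAP likelihood L, the free-parameter count k and the sample size N
(here the number of recorded transitions, N_frames - 1, i.e. the number of
terms in the Markov likelihood product):

    AIC  = 2k - 2 ln L
    AICc = AIC + 2k(k+1) / (N - k - 1)
    BIC  = k ln N - 2 ln L

The preferred model minimizes the score.  A single criterion is not enough:
the BIC separates free motion from confinement very reliably but maps
quartic-confined data onto the spring model, while the AIC resolves the
potential order but over-fits free motion.  The decision tree therefore
works in two stages: BIC first decides FREE vs CONFINED (comparing FREE
against SPRING2 -- the model the BIC picks for either kind of confinement),
then, for confined trajectories only, the AIC picks between SPRING2 and
QUARTIC4 (ties broken toward the lower order).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

from .inference import FitResult, map_fit
from .models import ModelLabel
from .trajectory import Trajectory

__all__ = [
    "InfoCriteria",
    "CriteriaSet",
    "TreeDecision",
    "information_criteria",
    "criteria_for",
    "classify",
    "decision_histogram",
]


class InfoCriteria(NamedTuple):
    aic: float
    aicc: float
    bic: float


def information_criteria(log_L: float, k: int, N: int) -> InfoCriteria:
    """AIC, AICc and BIC from a maximized log-likelihood.

    For N <= k + 1 the finite-sample correction diverges; AICc is reported
    as +inf with a warning (the model is unusable at that sample size).
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    aic = 2.0 * k - 2.0 * log_L
    if N > k + 1:
        aicc = aic + 2.0 * k * (k + 1.0) / (N - k - 1.0)
    else:
        warnings.warn(
            f"AICc undefined for N={N} <= k+1={k + 1}; reporting +inf",
            stacklevel=2,
        )
        aicc = math.inf
    bic = k * math.log(N) - 2.0 * log_L
    return InfoCriteria(aic=aic, aicc=aicc, bic=bic)


@dataclass(frozen=True)
class CriteriaSet:
    """Scores per fitted model plus the sample size they used."""

    per_model: dict[ModelLabel, InfoCriteria]
    n_steps: int

    def __getitem__(self, label: ModelLabel) -> InfoCriteria:
        return self.per_model[label]


def criteria_for(fits: Iterable[FitResult]) -> CriteriaSet:
    fits = list(fits)
    n_steps = fits[0].n_steps
    per_model = {
        f.model: information_criteria(f.log_map, f.n_params, f.n_steps) for f in fits
    }
    return CriteriaSet(per_model=per_model, n_steps=n_steps)


@dataclass(frozen=True)
class TreeDecision:
    """Outcome of the two-stage decision tree for one trajectory."""

    label: ModelLabel
    stage1: str  # "free" or "confined"
    criteria: CriteriaSet
    fits: dict[ModelLabel, FitResult]
    reliable: bool


def classify(
    traj: Trajectory, sigma: float = 0.0, n_bins: int = 10
) -> TreeDecision:
    """Apply the two-stage decision tree to one trajectory.

    Stage 1 (BIC): FREE when BIC(FREE) <= BIC(SPRING2), else CONFINED.
    Stage 2 (AIC, confined only): argmin over {SPRING2, QUARTIC4}, ties
    toward SPRING2.  QUARTIC4 is only fitted when stage 1 says confined.
    """
    if traj.n_frames < 20:
        warnings.warn(
            f"trajectory has {traj.n_frames} frames; the tree is validated "
            "for >= 20 frames",
            stacklevel=2,
        )
    fits = {
        ModelLabel.FREE: map_fit(traj, ModelLabel.FREE, sigma=sigma, n_bins=n_bins),
        ModelLabel.SPRING2: map_fit(
            traj, ModelLabel.SPRING2, sigma=sigma, n_bins=n_bins
        ),
    }
    cs = criteria_for(fits.values())
    if cs[ModelLabel.FREE].bic <= cs[ModelLabel.SPRING2].bic:
        reliable = all(f.converged for f in fits.values())
        return TreeDecision(
            label=ModelLabel.FREE,
            stage1="free",
            criteria=cs,
            fits=fits,
            reliable=reliable,
        )
    fits[ModelLabel.QUARTIC4] = map_fit(
        traj, ModelLabel.QUARTIC4, sigma=sigma, n_bins=n_bins
    )
    cs = criteria_for(fits.values())
    if cs[ModelLabel.QUARTIC4].aic < cs[ModelLabel.SPRING2].aic:
        label = ModelLabel.QUARTIC4
    else:
        label = ModelLabel.SPRING2
    reliable = all(f.converged for f in fits.values())
    return TreeDecision(
        label=label, stage1="confined", criteria=cs, fits=fits, reliable=reliable
    )


def decision_histogram(
    trajs: Iterable[Trajectory],
    criterion: str = "bic",
    sigma: float = 0.0,
    n_bins: int = 10,
) -> dict[ModelLabel, float]:
    """Normalized per-trajectory decision fractions for a single criterion.

    Every trajectory is fitted under all three models and assigned to the
    model minimizing the named criterion (no decision tree); ties break
    toward the lower-order model.
    """
    if criterion not in ("aic", "aicc", "bic"):
        raise ValueError(f"criterion must be aic, aicc or bic, got {criterion!r}")
    counts = {label: 0 for label in ModelLabel}
    total = 0
    for traj in trajs:
        fits = [
            map_fit(traj, label, sigma=sigma, n_bins=n_bins) for label in ModelLabel
        ]
        cs = criteria_for(fits)
        values = {
            label: getattr(cs[label], criterion) for label in ModelLabel
        }
        best = min(ModelLabel, key=lambda lab: (values[lab], int(lab)))
        counts[best] += 1
        total += 1
    if total == 0:
        raise ValueError("decision_histogram needs at least one trajectory")
    return {label: counts[label] / total for label in ModelLabel}
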