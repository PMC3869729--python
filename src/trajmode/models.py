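"""Candidate motion models for 2-D single-molecule trajectories.

Three generative models are considered for a tracked molecule moving in the
membrane plane: free Brownian motion, Brownian motion confined by a harmonic
(2nd-order) potential, and Brownian motion confined by an anharmonic
(4th-order) potential.  Motion follows the overdamped Langevin equation with
the friction eliminated through fluctuation-dissipation (gamma = kBT / D), so
a force F expressed in units of kBT/um produces a mean drift F * D * dt over
an interval dt.

Static localization error sigma enters the one-step transition density only
through an effective diffusivity D + sigma^2/dt; it is treated as a known
instrument property, not a fitted parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy.special import gamma as _gamma_fn

__all__ = [
    "KT_310",
    "ModelLabel",
    "N_FREE_PARAMS",
    "monomials",
    "PolynomialPotential",
    "ModelParams",
    "step_log_density",
    "spring_constant_to_kT",
    "quartic_strength_matching_spring",
]

#: thermal energy kB*T at 310 K, in pN*um
KT_310 = 4.28e-3


class ModelLabel(IntEnum):
    """The three candidate modes of motion.

    The integer order (FREE < SPRING2 < QUARTIC4) is used only for
    deterministic tie-breaking toward the lower-order model.
    """

    FREE = 0
    SPRING2 = 1
    QUARTIC4 = 2


#: free parameters per model: D alone, or D plus all polynomial coefficients
#: with total degree 1..order (no constant term -- it does not affect forces).
N_FREE_PARAMS = {
    ModelLabel.FREE: 1,
    ModelLabel.SPRING2: 6,
    ModelLabel.QUARTIC4: 15,
}


def monomials(order: int) -> list[tuple[int, int]]:
    """Exponent pairs (i, j) with 1 <= i+j <= order, in deterministic order."""
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    out = []
    for total in range(1, order + 1):
        for i in range(total, -1, -1):
            out.append((i, total - i))
    return out


@dataclass(frozen=True)
class PolynomialPotential:
    """Confining energy surface V(x, y) = sum c_ij x^i y^j in kBT units.

    Coefficients carry units kBT / um^(i+j).  The constant term is excluded
    (it never affects the force) and no exponent pair may exceed ``order``.
    """

    order: int
    coeffs: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.order not in (2, 4):
            raise ValueError(f"potential order must be 2 or 4, got {self.order}")
        for (i, j), c in self.coeffs.items():
            if i < 0 or j < 0 or i + j == 0:
                raise ValueError(f"invalid monomial exponents ({i}, {j})")
            if i + j > self.order:
                raise ValueError(
                    f"monomial x^{i} y^{j} exceeds potential order {self.order}"
                )
            if not math.isfinite(c):
                raise ValueError(f"non-finite coefficient for ({i}, {j})")

    @classmethod
    def spring(cls, k: float) -> "PolynomialPotential":
        """Harmonic well V = k/2 (x^2 + y^2), k in kBT/um^2."""
        return cls(order=2, coeffs={(2, 0): k / 2.0, (0, 2): k / 2.0})

    @classmethod
    def quartic(cls, u: float) -> "PolynomialPotential":
        """Axis-symmetric quartic well V = u (x^4 + y^4), u in kBT/um^4."""
        return cls(order=4, coeffs={(4, 0): u, (0, 4): u})

    def value(self, x, y):
        """Evaluate V(x, y) in kBT; broadcasts over array input."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        v = np.zeros(np.broadcast(x, y).shape)
        for (i, j), c in self.coeffs.items():
            v += c * x**i * y**j
        return v if v.ndim else float(v)

    def force(self, x, y):
        """Force -grad V in kBT/um; returns (Fx, Fy) broadcast over input."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        shape = np.broadcast(x, y).shape
        fx = np.zeros(shape)
        fy = np.zeros(shape)
        for (i, j), c in self.coeffs.items():
            if i > 0:
                fx -= i * c * x ** (i - 1) * y**j
            if j > 0:
                fy -= j * c * x**i * y ** (j - 1)
        if fx.ndim:
            return fx, fy
        return float(fx), float(fy)

    @property
    def label(self) -> ModelLabel:
        return ModelLabel.SPRING2 if self.order == 2 else ModelLabel.QUARTIC4


@dataclass(frozen=True)
class ModelParams:
    """Parameters of one candidate model.

    D is the diffusion coefficient (um^2/s); ``potential`` is absent for free
    motion; ``sigma`` (um) is the known localization noise; ``center`` is the
    coordinate origin the polynomial is expressed about (the fitted potential
    is reported relative to the trajectory centroid -- leading-order
    coefficients are unaffected by this shift).
    """

    D: float
    potential: PolynomialPotential | None = None
    sigma: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.D > 0.0) or not math.isfinite(self.D):
            raise ValueError(f"D must be finite and > 0, got {self.D}")
        if self.sigma < 0.0 or not math.isfinite(self.sigma):
            raise ValueError(f"sigma must be finite and >= 0, got {self.sigma}")

    @property
    def label(self) -> ModelLabel:
        if self.potential is None:
            return ModelLabel.FREE
        return self.potential.label

    @property
    def n_free_params(self) -> int:
        return N_FREE_PARAMS[self.label]


def step_log_density(dr, dt: float, D: float, F=(0.0, 0.0), sigma: float = 0.0):
    """Log transition density of one recorded displacement.

    The one-step propagator with a locally constant force F (kBT/um) is a 2-D
    Gaussian in the displacement ``dr`` with mean F*D*dt and per-axis variance
    2*(D + sigma^2/dt)*dt; setting F = 0 recovers the free-motion kernel.

    Parameters
    ----------
    dr : array-like, shape (2,) or (n, 2)
        Observed displacement(s), um.
    dt : float
        Frame interval, s (> 0).
    D : float
        Diffusion coefficient, um^2/s (> 0).
    F : array-like, shape (2,) or (n, 2)
        Force at the step's start point, kBT/um.
    sigma : float
        Static localization noise amplitude, um (>= 0).

    Returns
    -------
    float or ndarray of shape (n,)
    """
    if not dt > 0.0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if not D > 0.0:
        raise ValueError(f"D must be > 0, got {D}")
    if sigma < 0.0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    dr = np.asarray(dr, dtype=float)
    F = np.asarray(F, dtype=float)
    d_eff = D + sigma * sigma / dt
    dev = dr - F * D * dt
    sq = np.sum(dev * dev, axis=-1)
    out = -np.log(4.0 * np.pi * d_eff * dt) - sq / (4.0 * d_eff * dt)
    return out if np.ndim(out) else float(out)


def spring_constant_to_kT(k_pN_per_um: float, kT: float = KT_310) -> float:
    """Convert a spring constant from pN/um to kBT/um^2."""
    return k_pN_per_um / kT


# <x^2> of a Boltzmann density ~ exp(-u x^4) is (Gamma(3/4)/Gamma(1/4)) / sqrt(u)
_QUARTIC_VAR_CONST = float(_gamma_fn(0.75) / _gamma_fn(0.25))


def quartic_strength_matching_spring(k: float) -> float:
    """Quartic strength u (kBT/um^4) whose stationary per-axis variance
    matches that of a spring with constant k (kBT/um^2), i.e. 1/k."""
    if not k > 0:
        raise ValueError(f"k must be > 0, got {k}")
    return (_QUARTIC_VAR_CONST * k) ** 2
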