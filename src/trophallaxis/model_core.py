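"""Core model quantities: crop-content response functions and shared parameters.

Every behavioural decision in the model is a Bernoulli draw per one-second
timestep whose success probability depends sigmoidally on the ant's current
crop load ``Q`` through a Hill term with half-saturation ``k`` (food units)
and steepness ``n``:

* donating:   theta(Q)  = theta0 * Q^n / (k^n + Q^n)   (increasing in Q)
* receiving:  gamma(Q)  = gamma0 * k^n / (k^n + Q^n)   (decreasing in Q)
* leaving:    alpha(Q)  = alpha_max * k^n / (k^n + Q^n) (decreasing in Q)

A donor/receiver pair forms with the product of the two individual
probabilities.  Defaults ``n = 2`` and ``k = 120`` food units; ``k``
corresponds to the mean quantity of food exchanged during one event.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "DEFAULT_N", "DEFAULT_K",
    "Location", "Caste", "PairRole",
    "AntTraits", "AntState", "GlobalParams",
    "donor_probability", "receiver_probability", "leaving_probability",
    "pair_formation_probability", "hill_increasing", "hill_decreasing",
]

DEFAULT_N: float = 2.0
DEFAULT_K: float = 120.0


class Location(enum.Enum):
    IN_NEST = "IN_NEST"
    AT_SOURCE = "AT_SOURCE"
    RETURNING = "RETURNING"


class Caste(enum.Enum):
    NF = "NF"  # non-forager: never visited the food source
    F = "F"    # forager: visited the source at least once (absorbing)


class PairRole(enum.Enum):
    DONOR = "DONOR"
    RECEIVER = "RECEIVER"


def _check_hill_args(Q, k, n) -> None:
    if np.any(np.asarray(Q) < 0):
        raise ValueError(f"crop content Q must be >= 0, got {Q}")
    if np.any(np.asarray(k) <= 0):  # k may be per-individual (an array)
        raise ValueError(f"half-saturation k must be > 0, got {k}")
    if n <= 0:
        raise ValueError(f"Hill steepness n must be > 0, got {n}")


def _check_probability(p, name: str) -> None:
    arr = np.asarray(p)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"{name} must lie in [0, 1], got {p}")


def hill_increasing(Q, k: float, n: float):
    """Q^n / (k^n + Q^n); saturating from 0 at Q=0 towards 1 as Q -> inf."""
    _check_hill_args(Q, k, n)
    Q = np.asarray(Q, dtype=float)
    qn = Q ** n
    return qn / (k ** n + qn)


def hill_decreasing(Q, k: float, n: float):
    """k^n / (k^n + Q^n); the complement of :func:`hill_increasing`."""
    _check_hill_args(Q, k, n)
    Q = np.asarray(Q, dtype=float)
    kn = k ** n
    return kn / (kn + Q ** n)


def donor_probability(theta0, Q, k: float = DEFAULT_K, n: float = DEFAULT_N):
    """Per-timestep probability of acting as a food donor.

    theta0 is the individual's maximal giving probability theta_i(0); the
    realized probability rises sigmoidally with crop content, reaching
    theta0/2 at Q = k.  An empty ant (Q = 0) can never donate.
    """
    _check_probability(theta0, "theta0")
    return theta0 * hill_increasing(Q, k, n)


def receiver_probability(gamma0, Q, k: float = DEFAULT_K, n: float = DEFAULT_N):
    """Per-timestep probability of acting as a food receiver.

    Maximal (= gamma0) for an empty crop and decreasing sigmoidally as the
    crop fills; gamma0/2 at Q = k.
    """
    _check_probability(gamma0, "gamma0")
    return gamma0 * hill_decreasing(Q, k, n)


def leaving_probability(alpha_max, Q, k: float = DEFAULT_K, n: float = DEFAULT_N):
    """Per-timestep probability of leaving the nest for the food source.

    alpha_max is alpha_i(0) for a non-forager and the (larger) alpha'_i(0)
    once the ant has foraged; the realized probability is maximal at Q = 0
    and decreases with crop content.
    """
    _check_probability(alpha_max, "alpha_max")
    return alpha_max * hill_decreasing(Q, k, n)


def pair_formation_probability(theta_i, gamma_j):
    """Probability that donor i and receiver j start an exchange: theta_i * gamma_j."""
    _check_probability(theta_i, "theta_i")
    _check_probability(gamma_j, "gamma_j")
    return theta_i * gamma_j


@dataclass
class AntTraits:
    """Per-individual behavioural maxima and Hill parameters.

    theta0 / gamma0 / alpha0 are the crop-empty (or crop-full, for theta)
    maxima of the giving / receiving / nest-leaving probabilities, per
    1-second timestep.  alpha0_forager is the post-first-visit leaving
    maximum alpha'_i(0) >= alpha0.
    """

    theta0: float
    gamma0: float
    alpha0: float
    alpha0_forager: float
    k: float = DEFAULT_K
    n: float = DEFAULT_N

    def __post_init__(self) -> None:
        for name in ("theta0", "gamma0", "alpha0", "alpha0_forager"):
            _check_probability(getattr(self, name), name)
        if self.alpha0_forager < self.alpha0:
            raise ValueError(
                f"alpha0_forager ({self.alpha0_forager}) must be >= alpha0 ({self.alpha0})"
            )
        if self.k <= 0 or self.n <= 0:
            raise ValueError("k and n must be positive")


@dataclass
class AntState:
    """Full state of one agent at one instant."""

    id: int
    traits: AntTraits
    location: Location = Location.IN_NEST
    caste: Caste = Caste.NF
    crop: float = 0.0
    pair_partner: Optional[int] = None
    pair_role: Optional[PairRole] = None

    def __post_init__(self) -> None:
        if self.crop < 0:
            raise ValueError("crop must be >= 0")
        if self.pair_partner is not None and self.location is not Location.IN_NEST:
            raise ValueError("paired ants must be in the nest")

    @property
    def alpha_max(self) -> float:
        return self.traits.alpha0_forager if self.caste is Caste.F else self.traits.alpha0


@dataclass
class GlobalParams:
    """Colony-wide rates and run dimensions.

    beta          per-timestep probability of leaving the food source,
                  i.e. 1/beta is the mean feeding-bout duration.
    phi           per-timestep probability that an engaged trophallactic
                  pair separates; 1/phi is the mean event duration.
    intake_rate   food units ingested per timestep at the source.
    transfer_rate food units moved donor->receiver per timestep of an event;
                  the mean amount exchanged per event is transfer_rate/phi.
    return_delay  timesteps spent in transit when returning (0 = instantaneous).

    Defaults (beta, phi, intake_rate, transfer_rate and the leaving-rate
    distribution in :mod:`trophallaxis.config`) were calibrated so that a
    53-ant, 3600-step colony reproduces the reference foraging activity:
    ~99 trophallactic events and ~12 foragers per run (see docs/methods.md).
    """

    beta: float = 0.02
    phi: float = 1.0 / 90.0
    intake_rate: float = 10.0
    transfer_rate: float = 6.0
    return_delay: int = 0
    n_ants: int = 53
    n_steps: int = 3600

    def __post_init__(self) -> None:
        if not (0 < self.beta <= 1):
            raise ValueError("beta must lie in (0, 1]")
        if not (0 < self.phi <= 1):
            raise ValueError("phi must lie in (0, 1]")
        if self.intake_rate <= 0 or self.transfer_rate <= 0:
            raise ValueError("intake_rate and transfer_rate must be > 0")
        if self.return_delay < 0:
            raise ValueError("return_delay must be >= 0")
        if self.n_ants <= 1:
            raise ValueError("n_ants must be > 1")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
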