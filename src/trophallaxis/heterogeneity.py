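"""Interindividual trait heterogeneity and the forager/non-forager caste rules.

Three trait distributions with a common mean ``epsilon`` but increasing
spread are supported for the giving (theta0) and receiving (gamma0) maxima:

* DELTA        every ant gets exactly epsilon (the homogeneous null case);
* UNIFORM      a draw from U[0, 2*epsilon] (the widest nonnegative uniform
               with mean epsilon);
* EXPONENTIAL  a draw from an exponential law with mean epsilon, resampled
               until it falls in (0, 1] so that it remains a probability.

Nest-leaving maxima alpha_i(0) follow a bounded power law (Pareto): a few
ants are very likely to visit the food source while most almost never do.
On an ant's first visit it becomes a forager, permanently: its leaving
maximum is scaled up to alpha'_i(0) = forager_multiplier * alpha_i(0), and
under the two-emergent-caste (TEC) regime its theta0/gamma0 are freshly
resampled from the forager distributions, uncorrelated with the pre-visit
values.  Under the one-caste (OC) regime traits never change.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, replace

import numpy as np

from trophallaxis.model_core import AntState, Caste

__all__ = [
    "DistributionKind", "RegimeKind", "AlphaKind",
    "TraitDistributionSpec", "CasteRegime", "AlphaDistributionSpec",
    "sample_trait", "sample_alpha0", "promote_to_forager",
    "bounded_powerlaw_cdf",
]


class DistributionKind(enum.Enum):
    DELTA = "delta"
    UNIFORM = "uniform"
    EXPONENTIAL = "exponential"


class RegimeKind(enum.Enum):
    OC = "OC"    # one caste: forager traits identical to non-forager traits
    TEC = "TEC"  # two emergent castes: traits resampled on first source visit


class AlphaKind(enum.Enum):
    POWER_LAW = "power_law"
    DELTA = "delta"


@dataclass(frozen=True)
class TraitDistributionSpec:
    """Distribution of one trophallactic trait (theta0 or gamma0)."""

    kind: DistributionKind
    mean: float

    def __post_init__(self) -> None:
        if self.kind is DistributionKind.DELTA:
            if not (0 <= self.mean <= 1):  # mean 0 allowed: degenerate "never acts"
                raise ValueError(f"trait mean must lie in [0, 1], got {self.mean}")
        elif not (0 < self.mean <= 1):
            raise ValueError(f"trait mean must lie in (0, 1], got {self.mean}")
        if self.kind is DistributionKind.UNIFORM and self.mean > 0.5:
            raise ValueError("uniform trait mean must be <= 0.5 so draws stay in [0, 1]")


@dataclass(frozen=True)
class CasteRegime:
    """Per-caste trait distributions under the OC or TEC assumption."""

    kind: RegimeKind
    theta_nf: TraitDistributionSpec
    gamma_nf: TraitDistributionSpec
    theta_f: TraitDistributionSpec
    gamma_f: TraitDistributionSpec

    def __post_init__(self) -> None:
        if self.kind is RegimeKind.OC:
            if self.theta_f != self.theta_nf or self.gamma_f != self.gamma_nf:
                raise ValueError("OC regime requires identical F and NF trait specs")
        else:
            # The defining division-of-labour direction: foragers give more.
            # The receiving direction is left free -- fitted reference values
            # place gamma_F above gamma_NF even though the qualitative model
            # narrative suggests the opposite.
            if not (self.theta_f.mean > self.theta_nf.mean):
                raise ValueError("TEC regime requires mean(theta_F) > mean(theta_NF)")

    @classmethod
    def one_caste(cls, kind: DistributionKind, theta: float, gamma: float) -> "CasteRegime":
        t = TraitDistributionSpec(kind, theta)
        g = TraitDistributionSpec(kind, gamma)
        return cls(RegimeKind.OC, t, g, t, g)

    @classmethod
    def two_castes(
        cls, kind: DistributionKind,
        theta_f: float, theta_nf: float, gamma_f: float, gamma_nf: float,
    ) -> "CasteRegime":
        mk = lambda m: TraitDistributionSpec(kind, m)
        return cls(RegimeKind.TEC, mk(theta_nf), mk(gamma_nf), mk(theta_f), mk(gamma_f))


@dataclass(frozen=True)
class AlphaDistributionSpec:
    """Distribution of the nest-leaving maximum alpha_i(0).

    POWER_LAW draws from a bounded Pareto with survival ~ x^(1-exponent) on
    [min_value, max_value]; DELTA returns min_value (== max_value) exactly.
    forager_multiplier maps alpha_i(0) to the post-first-visit maximum
    alpha'_i(0) (capped at 1).
    """

    kind: AlphaKind = AlphaKind.POWER_LAW
    exponent: float = 1.2
    min_value: float = 1.05e-6
    max_value: float = 0.02
    forager_multiplier: float = 10.0

    def __post_init__(self) -> None:
        if self.kind is AlphaKind.DELTA:
            if not (0 <= self.min_value <= self.max_value <= 1):
                raise ValueError("need 0 <= min_value <= max_value <= 1")
            if self.min_value != self.max_value:
                raise ValueError("delta alpha distribution needs min_value == max_value")
        else:
            if not (0 < self.min_value <= self.max_value <= 1):
                raise ValueError("need 0 < min_value <= max_value <= 1")
            if self.min_value >= self.max_value:
                raise ValueError("power law needs min_value < max_value")
            if self.exponent <= 1:
                raise ValueError("power-law exponent must exceed 1 for a normalizable tail")
        if self.forager_multiplier < 1:
            raise ValueError("forager_multiplier must be >= 1")


def sample_trait(spec: TraitDistributionSpec, rng: np.random.Generator, size=None):
    """Draw theta0/gamma0 values with population mean spec.mean, in [0, 1].

    Out-of-range draws are rejected and resampled (not clipped) so no
    probability mass accumulates at 1.
    """
    scalar = size is None
    n = 1 if scalar else int(size)
    if spec.kind is DistributionKind.DELTA:
        out = np.full(n, spec.mean)
    elif spec.kind is DistributionKind.UNIFORM:
        out = rng.uniform(0.0, 2.0 * spec.mean, size=n)
    else:
        out = rng.exponential(spec.mean, size=n)
        bad = (out > 1.0) | (out <= 0.0)
        while np.any(bad):
            out[bad] = rng.exponential(spec.mean, size=int(bad.sum()))
            bad = (out > 1.0) | (out <= 0.0)
    return float(out[0]) if scalar else out


def bounded_powerlaw_cdf(x, spec: AlphaDistributionSpec):
    """Closed-form CDF of the bounded Pareto used for alpha_i(0)."""
    a, m, M = spec.exponent, spec.min_value, spec.max_value
    x = np.clip(np.asarray(x, dtype=float), m, M)
    g = a - 1.0
    return (1.0 - (m / x) ** g) / (1.0 - (m / M) ** g)


def sample_alpha0(spec: AlphaDistributionSpec, rng: np.random.Generator, size=None):
    """Draw nest-leaving maxima alpha_i(0) per the configured distribution."""
    scalar = size is None
    n = 1 if scalar else int(size)
    if spec.kind is AlphaKind.DELTA or spec.min_value == spec.max_value:
        out = np.full(n, spec.min_value)
    else:
        # inverse-transform sampling of the bounded Pareto
        g = spec.exponent - 1.0
        u = rng.random(n)
        ratio = (spec.min_value / spec.max_value) ** g
        out = spec.min_value / (1.0 - u * (1.0 - ratio)) ** (1.0 / g)
    return float(out[0]) if scalar else out


def promote_to_forager(ant: AntState, regime: CasteRegime, rng: np.random.Generator) -> AntState:
    """Return the ant's state after its first visit to the food source.

    Caste flips permanently to forager and the leaving maximum switches to
    alpha'_i(0).  Under TEC the giving/receiving maxima are resampled from
    the forager distributions, independent of the pre-visit values; under OC
    they are unchanged.  Calling on an ant that is already a forager is a
    no-op, so promotion is idempotent.
    """
    if ant.caste is Caste.F:
        return ant
    traits = ant.traits
    if regime.kind is RegimeKind.TEC:
        traits = dataclasses.replace(
            traits,
            theta0=sample_trait(regime.theta_f, rng),
            gamma0=sample_trait(regime.gamma_f, rng),
        )
    return replace(ant, caste=Caste.F, traits=traits)
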