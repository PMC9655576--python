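"""Run configuration: presets, YAML/JSON (de)serialization and validation.

``TRAIT_MEANS`` holds the calibrated population means of the giving (theta0)
and receiving (gamma0) maxima for the six model variants -- {one-caste OC,
two-emergent-caste TEC} x {delta, uniform, exponential} -- expressed as the
per-caste means fitted against the reference experiments (53 workers, one
hour, ~99 events, ~12 foragers).  ``default_config`` assembles a ready-to-run
:class:`~trophallaxis.simulator.SimulationConfig` for any variant.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from fractions import Fraction
from pathlib import Path
from typing import Optional, Union

import yaml

from trophallaxis.heterogeneity import (
    AlphaDistributionSpec,
    AlphaKind,
    CasteRegime,
    DistributionKind,
    RegimeKind,
    TraitDistributionSpec,
)
from trophallaxis.model_core import GlobalParams
from trophallaxis.simulator import SimulationConfig

__all__ = [
    "TRAIT_MEANS", "default_config", "load_config", "dump_config",
    "config_to_dict", "config_from_dict", "config_hash", "ConfigError",
]


class ConfigError(ValueError):
    """Invalid or unreadable run configuration."""


#: Calibrated per-caste giving/receiving means for each (regime, distribution)
#: variant.  OC variants use a single pair applied to every ant.
TRAIT_MEANS: dict[tuple[str, str], dict[str, float]] = {
    ("OC", "delta"): {"theta": 1 / 11, "gamma": 1 / 60},
    ("OC", "uniform"): {"theta": 1 / 10, "gamma": 1 / 50},
    ("OC", "exponential"): {"theta": 1 / 6, "gamma": 1 / 56},
    ("TEC", "delta"): {"theta_f": 1 / 10, "theta_nf": 1 / 33,
                       "gamma_f": 1 / 11, "gamma_nf": 1 / 38},
    ("TEC", "uniform"): {"theta_f": 1 / 11, "theta_nf": 1 / 32,
                         "gamma_f": 1 / 9, "gamma_nf": 1 / 28},
    ("TEC", "exponential"): {"theta_f": 1 / 9, "theta_nf": 1 / 23,
                             "gamma_f": 1 / 9, "gamma_nf": 1 / 27},
}


def default_config(
    regime: str = "TEC",
    distribution: str = "exponential",
    *,
    params: Optional[GlobalParams] = None,
    alpha_spec: Optional[AlphaDistributionSpec] = None,
    **overrides,
) -> SimulationConfig:
    """Build the standard configuration of one of the six model variants.

    53 ants, 3600 one-second timesteps, Hill parameters n = 2 and k = 120
    food units, the calibrated rate parameters, and the fitted per-caste
    trait means of the requested (regime, distribution) variant.
    """
    regime = regime.upper()
    distribution = distribution.lower()
    key = (regime, distribution)
    if key not in TRAIT_MEANS:
        raise ConfigError(f"unknown model variant {key}; choose regime in OC/TEC and "
                          "distribution in delta/uniform/exponential")
    means = TRAIT_MEANS[key]
    kind = DistributionKind(distribution)
    if regime == "OC":
        caste_regime = CasteRegime.one_caste(kind, means["theta"], means["gamma"])
    else:
        caste_regime = CasteRegime.two_castes(
            kind, means["theta_f"], means["theta_nf"], means["gamma_f"], means["gamma_nf"])
    return SimulationConfig(
        params=params or GlobalParams(),
        regime=caste_regime,
        alpha_spec=alpha_spec or AlphaDistributionSpec(),
        **overrides,
    )


# ---------------------------------------------------------------------------
# (de)serialization


def config_to_dict(config: SimulationConfig) -> dict:
    def spec_dict(s: TraitDistributionSpec) -> dict:
        return {"kind": s.kind.value, "mean": s.mean}

    return {
        "params": dataclasses.asdict(config.params),
        "regime": {
            "kind": config.regime.kind.value,
            "theta_nf": spec_dict(config.regime.theta_nf),
            "gamma_nf": spec_dict(config.regime.gamma_nf),
            "theta_f": spec_dict(config.regime.theta_f),
            "gamma_f": spec_dict(config.regime.gamma_f),
        },
        "alpha_spec": {
            "kind": config.alpha_spec.kind.value,
            "exponent": config.alpha_spec.exponent,
            "min_value": config.alpha_spec.min_value,
            "max_value": config.alpha_spec.max_value,
            "forager_multiplier": config.alpha_spec.forager_multiplier,
        },
        "k": config.k,
        "n": config.n,
        "record_trajectory": config.record_trajectory,
        "trajectory_interval": config.trajectory_interval,
        "pairing_before_departures": config.pairing_before_departures,
    }


def _number(x) -> float:
    """Accept fractions like '1/9' in config files (trait means are printed so)."""
    if isinstance(x, str):
        return float(Fraction(x))
    return float(x)


def config_from_dict(d: dict) -> SimulationConfig:
    try:
        params = GlobalParams(**d.get("params", {}))
        r = d["regime"]

        def spec(s) -> TraitDistributionSpec:
            return TraitDistributionSpec(DistributionKind(s["kind"]), _number(s["mean"]))

        regime = CasteRegime(
            kind=RegimeKind(r["kind"]),
            theta_nf=spec(r["theta_nf"]), gamma_nf=spec(r["gamma_nf"]),
            theta_f=spec(r["theta_f"]), gamma_f=spec(r["gamma_f"]),
        )
        a = d.get("alpha_spec", {})
        alpha_spec = AlphaDistributionSpec(
            kind=AlphaKind(a.get("kind", "power_law")),
            exponent=_number(a.get("exponent", 2.0)),
            min_value=_number(a.get("min_value", AlphaDistributionSpec().min_value)),
            max_value=_number(a.get("max_value", AlphaDistributionSpec().max_value)),
            forager_multiplier=_number(a.get("forager_multiplier",
                                             AlphaDistributionSpec().forager_multiplier)),
        )
        return SimulationConfig(
            params=params, regime=regime, alpha_spec=alpha_spec,
            k=_number(d.get("k", 120)), n=_number(d.get("n", 2)),
            record_trajectory=bool(d.get("record_trajectory", False)),
            trajectory_interval=int(d.get("trajectory_interval", 60)),
            pairing_before_departures=bool(d.get("pairing_before_departures", False)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc


def load_config(path: Union[str, Path]) -> SimulationConfig:
    """Read a YAML (or JSON: YAML is a superset) configuration file.

    The file may either spell out the full configuration or name a preset:

    .. code-block:: yaml

        preset: {regime: TEC, distribution: exponential}
        params: {n_steps: 3600, n_ants: 53}
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read configuration {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"configuration {path} must be a mapping")
    if "preset" in raw:
        preset = raw.pop("preset") or {}
        cfg = default_config(preset.get("regime", "TEC"),
                             preset.get("distribution", "exponential"))
        base = config_to_dict(cfg)
        for section, value in raw.items():
            if isinstance(value, dict) and isinstance(base.get(section), dict):
                base[section].update(value)
            else:
                base[section] = value
        return config_from_dict(base)
    return config_from_dict(raw)


def dump_config(config: SimulationConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def config_hash(config: SimulationConfig) -> str:
    """Stable short hash of a configuration, for provenance headers."""
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
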