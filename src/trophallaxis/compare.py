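"""Summary statistics, calibration and ensemble-vs-experiment comparisons.

The calibration targets are the statistics used to fit the model to
behavioural experiments: the mean number of foragers, the mean number of
trophallactic events and the counts of the four donor->receiver pair types
(F->F, F->NF, NF->F, NF->NF).  The pair-type discrepancy ``D`` is the summed
absolute difference of the four counts.  Ensembles are compared with
experimental samples with a two-sample Kolmogorov-Smirnov test, a
Mann-Whitney U test, and a Z-test against 200 resampled means of 5
replicates (mirroring a 5-colony experiment).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from trophallaxis.metrics import (
    activity_distributions,
    build_network,
    global_efficiency,
    lorenz_gini,
    t50,
)
from trophallaxis.model_core import Caste
from trophallaxis.observation import PAIR_TYPES, classify_pair_types
from trophallaxis.simulator import SimulationConfig, SimulationResult, run_simulation

__all__ = [
    "SummaryStats", "EnsembleSummary", "CalibrationResult",
    "summarize", "summarize_ensemble", "pair_type_discrepancy",
    "calibrate", "ks_compare", "mw_compare", "z_compare",
]


@dataclass
class SummaryStats:
    """Calibration/comparison statistics of one simulation run."""

    n_events: int
    n_foragers: int
    pair_type_counts: dict[str, int]
    pair_type_proportions: dict[str, float]
    nf_donation_share: float  # fraction of donated volume with a non-forager donor
    gini: Optional[float]
    t50: Optional[int]
    efficiency: Optional[float]

    def as_dict(self) -> dict:
        d = {
            "n_events": self.n_events,
            "n_foragers": self.n_foragers,
            "nf_donation_share": self.nf_donation_share,
            "gini": self.gini,
            "t50": self.t50,
            "efficiency": self.efficiency,
        }
        for pt in PAIR_TYPES:
            d[f"count_{pt}"] = self.pair_type_counts[pt]
            d[f"prop_{pt}"] = self.pair_type_proportions[pt]
        return d


@dataclass
class EnsembleSummary:
    """Per-replicate summary table plus ensemble means and SDs."""

    per_rep: pd.DataFrame
    mean: pd.Series
    sd: pd.Series

    @property
    def n_reps(self) -> int:
        return len(self.per_rep)

    def sem(self) -> pd.Series:
        return self.sd / np.sqrt(self.n_reps)


def summarize(result: SimulationResult, network_metrics: bool = True) -> SummaryStats:
    """Compute the summary statistics of one simulation result.

    ``network_metrics=False`` skips the Gini/T50/efficiency block (used by
    the calibration loop, which only needs counts) for speed.
    """
    events = result.events
    counts = classify_pair_types(events, first_visit_times=result.first_visit_times)
    n_events = len(events)
    props = {pt: (counts[pt] / n_events if n_events else 0.0) for pt in PAIR_TYPES}
    volume = sum(e.amount for e in events)
    nf_volume = sum(e.amount for e in events if e.donor_caste_at_start is Caste.NF)
    share = nf_volume / volume if volume > 0 else 0.0
    gini = t = eff = None
    if network_metrics and n_events:
        roster = range(result.n_ants)
        castes = result.caste_labels()
        profile = activity_distributions(events, roster, castes)
        _, gini = lorenz_gini(profile.table["total"].to_numpy())
        t = t50(events)
        eff = global_efficiency(build_network(events, roster, castes))
    return SummaryStats(
        n_events=n_events,
        n_foragers=result.n_foragers,
        pair_type_counts=counts,
        pair_type_proportions=props,
        nf_donation_share=share,
        gini=gini,
        t50=t,
        efficiency=eff,
    )


def summarize_ensemble(results: Sequence[SimulationResult],
                       network_metrics: bool = True) -> EnsembleSummary:
    rows = [summarize(r, network_metrics=network_metrics).as_dict() for r in results]
    per_rep = pd.DataFrame(rows, index=pd.RangeIndex(len(rows), name="rep"))
    numeric = per_rep.astype(float)
    return EnsembleSummary(per_rep=per_rep, mean=numeric.mean(), sd=numeric.std(ddof=1))


def pair_type_discrepancy(counts: Mapping[str, float], targets: Mapping[str, float]) -> float:
    """D = sum over the four pair types of |counts - targets| (0 iff exact match)."""
    return float(sum(abs(counts[pt] - targets[pt]) for pt in PAIR_TYPES))


# ---------------------------------------------------------------------------
# calibration


@dataclass
class CalibrationResult:
    fitted_means: dict[str, float]
    achieved: pd.Series            # ensemble means at the optimum
    loss: float
    trace: pd.DataFrame            # every evaluated point of the loss surface
    status: str                    # "converged" | "budget_exhausted"


_SEARCH_KEYS = ("theta_f", "theta_nf", "gamma_f", "gamma_nf")


def _with_means(config: SimulationConfig, means: Mapping[str, float]) -> SimulationConfig:
    regime = config.regime
    regime = type(regime)(
        kind=regime.kind,
        theta_nf=replace(regime.theta_nf, mean=means["theta_nf"]),
        gamma_nf=replace(regime.gamma_nf, mean=means["gamma_nf"]),
        theta_f=replace(regime.theta_f, mean=means["theta_f"]),
        gamma_f=replace(regime.gamma_f, mean=means["gamma_f"]),
    )
    return replace(config, regime=regime)


def _loss(achieved: pd.Series, targets: SummaryStats,
          w_events: float, w_foragers: float, w_pairs: float) -> float:
    counts = {pt: achieved[f"count_{pt}"] for pt in PAIR_TYPES}
    return (
        w_events * abs(achieved["n_events"] - targets.n_events)
        + w_foragers * abs(achieved["n_foragers"] - targets.n_foragers)
        + w_pairs * pair_type_discrepancy(counts, targets.pair_type_counts)
    )


def calibrate(
    targets: SummaryStats,
    config: SimulationConfig,
    search_space: Mapping[str, tuple[float, float]],
    budget: int = 30,
    seed: int = 0,
    n_reps_eval: int = 50,
    grid_points: int = 3,
    n_refinements: int = 3,
    w_events: float = 1.0,
    w_foragers: float = 4.0,
    w_pairs: float = 1.0,
) -> CalibrationResult:
    """Fit giving/receiving means to target summary statistics.

    Performs an iteratively refined grid search (coordinate-wise, geometric
    grids) over the means named in ``search_space`` (subset of theta_f,
    theta_nf, gamma_f, gamma_nf; bounds as (lo, hi) tuples), minimizing the
    weighted L1 loss |dN_events| + |dN_foragers| + D over pair-type counts.
    Each evaluation is an ensemble of ``n_reps_eval`` replicates.  Stops when
    the budget of ensemble evaluations is exhausted, returning the best
    point seen so far.
    """
    for key in search_space:
        if key not in _SEARCH_KEYS:
            raise ValueError(f"unknown search dimension {key!r}")
    regime = config.regime
    current = {
        "theta_f": regime.theta_f.mean, "theta_nf": regime.theta_nf.mean,
        "gamma_f": regime.gamma_f.mean, "gamma_nf": regime.gamma_nf.mean,
    }
    bounds = dict(search_space)
    evaluations = 0
    cache: dict[tuple, pd.Series] = {}
    trace_rows = []

    def evaluate(means: dict[str, float]) -> Optional[pd.Series]:
        nonlocal evaluations
        key = tuple(round(means[k], 12) for k in _SEARCH_KEYS)
        if key in cache:
            return cache[key]
        if evaluations >= budget:
            return None
        evaluations += 1
        cfg = _with_means(config, means)
        # common random numbers: the same replicate seeds for every candidate,
        # so loss differences reflect the parameters rather than the noise
        results = [run_simulation(cfg, seed * 100_003 + r) for r in range(n_reps_eval)]
        achieved = summarize_ensemble(results, network_metrics=False).mean
        cache[key] = achieved
        trace_rows.append({**means, "loss": _loss(achieved, targets, w_events, w_foragers, w_pairs)})
        return achieved

    best_means = dict(current)
    achieved = evaluate(best_means)
    best_loss = _loss(achieved, targets, w_events, w_foragers, w_pairs)
    status = "converged"
    searched = sorted(bounds)
    spans = {k: (bounds[k][1] / bounds[k][0]) ** 0.5 for k in searched}

    for _ in range(n_refinements + 1):
        improved = False
        for key in searched:
            lo = max(bounds[key][0], best_means[key] / spans[key])
            hi = min(bounds[key][1], best_means[key] * spans[key])
            for val in np.geomspace(lo, hi, grid_points):
                cand = dict(best_means)
                cand[key] = float(val)
                ach = evaluate(cand)
                if ach is None:
                    status = "budget_exhausted"
                    break
                loss = _loss(ach, targets, w_events, w_foragers, w_pairs)
                if loss < best_loss:
                    best_loss, best_means, achieved, improved = loss, cand, ach, True
            if status == "budget_exhausted":
                break
        if status == "budget_exhausted":
            break
        if best_loss == 0:
            break
        for k in searched:  # shrink around the incumbent
            spans[k] = spans[k] ** 0.55
    trace = pd.DataFrame(trace_rows)
    return CalibrationResult(
        fitted_means=best_means, achieved=achieved, loss=best_loss,
        trace=trace, status=status,
    )


# ---------------------------------------------------------------------------
# statistical comparison protocols


def ks_compare(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test; returns (D, p)."""
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires nonempty samples")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def mw_compare(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Mann-Whitney U test (two-sided); returns (U of sample_a, p)."""
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("Mann-Whitney test requires nonempty samples")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def z_compare(
    experimental_values: Sequence[float],
    ensemble_values: Sequence[float],
    rng: np.random.Generator,
    n_draws: int = 200,
    draw_size: int = 5,
) -> tuple[float, float]:
    """Z-test of an experimental mean against resampled ensemble means.

    Builds ``n_draws`` means of ``draw_size`` replicates drawn without
    replacement within each draw (with replacement across draws), then

        Z = (mean(experiment) - mean(draw means)) / SD(draw means)

    with a two-sided normal p-value.  A degenerate ensemble (zero SD of the
    draw means) raises, since Z is undefined.
    """
    exp = np.asarray(experimental_values, float)
    ens = np.asarray(ensemble_values, float)
    if exp.size == 0:
        raise ValueError("experimental sample is empty")
    if ens.size < draw_size:
        raise ValueError(f"ensemble must contain at least {draw_size} replicates")
    means = np.empty(n_draws)
    for d in range(n_draws):
        means[d] = ens[rng.choice(ens.size, size=draw_size, replace=False)].mean()
    sd = means.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate ensemble: resampled means have zero variance")
    z = (exp.mean() - means.mean()) / sd
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
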