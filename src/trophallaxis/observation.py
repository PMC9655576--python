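"""Observation model and synthetic experimental-data generation.

Behavioural experiments record trophallaxis by scan sampling: once per
minute every ongoing mandible-to-mandible contact is noted with donor and
receiver identity, and only contacts lasting longer than 5 seconds count.
The same ordered pair seen on consecutive scans is one observed event whose
duration is the number of scans.  Foragers are the ants that spent at least
five consecutive seconds feeding at the food source.

This module applies that observation process to simulated event logs and
packages scan-sampled simulations as synthetic "experimental" datasets:
per-colony CSV tables of scan records (colony, minute, donor, receiver)
plus a worker metadata table (colony, ant_id, is_forager), the format used
for real tagged-colony recordings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from trophallaxis.model_core import Caste

__all__ = [
    "PAIR_TYPES", "ObservedEvent", "SyntheticExperimentConfig",
    "scan_sample", "classify_pair_types", "generate_synthetic_experiment",
    "observed_events_to_scans", "read_experiment_tables",
]

PAIR_TYPES = ("F->F", "F->NF", "NF->F", "NF->NF")

MIN_FEEDING_STREAK = 5  # consecutive seconds at the source to be scored a forager


@dataclass(frozen=True)
class ObservedEvent:
    """One scan-sampled trophallactic event."""

    colony_id: int
    donor_id: int
    receiver_id: int
    first_scan_minute: int
    duration_minutes: int


def scan_sample(events: Iterable, scan_interval: int = 60, min_duration: int = 5,
                colony_id: int = 0, strict: bool = True) -> list[ObservedEvent]:
    """Apply the minute-scan observation model to a raw event log.

    Scans occur at t = scan_interval, 2*scan_interval, ...; an event is seen
    at every scan instant falling within [t_start, t_end], provided its total
    duration exceeds ``min_duration`` timesteps (strictly, by default -- the
    "longer than 5 s" rule).  The consecutive scans of one raw event merge
    into a single :class:`ObservedEvent`; separate raw events are never
    merged, so observation is one-to-one onto a subset of the raw log.
    """
    if scan_interval < 1:
        raise ValueError("scan_interval must be >= 1")
    observed = []
    for ev in events:
        duration = ev.t_end - ev.t_start + 1
        long_enough = duration > min_duration if strict else duration >= min_duration
        if not long_enough:
            continue
        first_scan = -(-ev.t_start // scan_interval)  # ceil division
        last_scan = ev.t_end // scan_interval
        if first_scan < 1 or last_scan < first_scan:
            continue  # never intersects a scan instant
        observed.append(ObservedEvent(
            colony_id=colony_id,
            donor_id=int(ev.donor_id),
            receiver_id=int(ev.receiver_id),
            first_scan_minute=int(first_scan),
            duration_minutes=int(last_scan - first_scan + 1),
        ))
    return observed


def classify_pair_types(
    events: Iterable,
    forager_ids: Optional[set[int]] = None,
    first_visit_times: Optional[Mapping[int, int]] = None,
) -> dict[str, int]:
    """Count events per donor->receiver caste pair (F->F, F->NF, NF->F, NF->NF).

    Caste is resolved at the event's start: from the recorded
    ``*_caste_at_start`` fields when present, else from ``first_visit_times``
    (forager iff first visit <= t_start), else from a static ``forager_ids``
    set.  The four counts partition the log.
    """
    counts = dict.fromkeys(PAIR_TYPES, 0)
    for ev in events:
        dc = getattr(ev, "donor_caste_at_start", None)
        rc = getattr(ev, "receiver_caste_at_start", None)
        if dc is None or rc is None:
            if first_visit_times is not None:
                dc = Caste.F if first_visit_times.get(int(ev.donor_id), np.inf) <= ev.t_start else Caste.NF
                rc = Caste.F if first_visit_times.get(int(ev.receiver_id), np.inf) <= ev.t_start else Caste.NF
            elif forager_ids is not None:
                dc = Caste.F if int(ev.donor_id) in forager_ids else Caste.NF
                rc = Caste.F if int(ev.receiver_id) in forager_ids else Caste.NF
            else:
                raise ValueError("caste not resolvable: provide forager_ids or first_visit_times")
        counts[f"{dc.value}->{rc.value}"] += 1
    return counts


def observed_events_to_scans(observed: Sequence[ObservedEvent]) -> pd.DataFrame:
    """Expand observed events into one row per scan record (the raw CSV format)."""
    rows = [
        (ev.colony_id, ev.first_scan_minute + m, ev.donor_id, ev.receiver_id)
        for ev in observed
        for m in range(ev.duration_minutes)
    ]
    return pd.DataFrame(rows, columns=["colony", "minute", "donor", "receiver"])


def scans_to_observed_events(scans: pd.DataFrame) -> list[ObservedEvent]:
    """Reassemble observed events from scan records (consecutive-minute merge)."""
    observed = []
    df = scans.sort_values(["colony", "donor", "receiver", "minute"])
    for (colony, donor, receiver), grp in df.groupby(["colony", "donor", "receiver"]):
        minutes = grp["minute"].to_numpy()
        start = minutes[0]
        prev = minutes[0]
        for m in minutes[1:]:
            if m != prev + 1:
                observed.append(ObservedEvent(int(colony), int(donor), int(receiver),
                                              int(start), int(prev - start + 1)))
                start = m
            prev = m
        observed.append(ObservedEvent(int(colony), int(donor), int(receiver),
                                      int(start), int(prev - start + 1)))
    return sorted(observed, key=lambda e: (e.colony_id, e.first_scan_minute,
                                           e.donor_id, e.receiver_id))


@dataclass(frozen=True)
class SyntheticExperimentConfig:
    """Configuration of the synthetic experimental-data generator.

    The generating mechanism is the calibrated two-emergent-caste
    exponential simulation pipeline run through the scan-sampling
    observation model, one simulation per colony.  ``target_mean_events``
    is the expected raw event count per colony (used as a self-check on the
    generator, matching the reference foraging activity of ~99 events).
    """

    n_colonies: int = 5
    n_workers: int = 53
    target_mean_events: float = 99.0
    scan_interval: int = 60
    min_duration: int = 5
    sim_config: Optional[object] = None  # SimulationConfig; default TEC-exponential

    def __post_init__(self) -> None:
        if self.n_colonies < 1:
            raise ValueError("n_colonies must be >= 1")
        if self.n_workers < 2:
            raise ValueError("n_workers must be >= 2")
        if self.target_mean_events <= 0:
            raise ValueError("target_mean_events must be positive")


def generate_synthetic_experiment(cfg: SyntheticExperimentConfig, seed: int,
                                  out_dir: Optional[Path] = None):
    """Generate a synthetic multi-colony experiment in the tagged-colony format.

    Runs one seeded simulation per colony, scan-samples each event log, and
    (optionally) writes per-colony scan tables ``colony_<c>_events.csv``
    (columns colony, minute, donor, receiver) plus a pooled ``workers.csv``
    (colony, ant_id, is_forager) where the forager flag follows the
    >= 5 consecutive seconds feeding rule.  Returns
    ``(scan_tables, workers, raw_results)``.
    """
    import dataclasses as _dc

    from trophallaxis.config import default_config
    from trophallaxis.simulator import run_simulation

    sim_config = cfg.sim_config or default_config("TEC", "exponential")
    if sim_config.params.n_ants != cfg.n_workers:
        sim_config = _dc.replace(
            sim_config, params=_dc.replace(sim_config.params, n_ants=cfg.n_workers))

    scan_tables: list[pd.DataFrame] = []
    worker_rows = []
    raw_results = []
    for colony in range(cfg.n_colonies):
        result = run_simulation(sim_config, seed + colony)
        raw_results.append(result)
        observed = scan_sample(result.events, cfg.scan_interval, cfg.min_duration,
                               colony_id=colony)
        scan_tables.append(observed_events_to_scans(observed))
        fed_long_enough = result.max_source_streak >= MIN_FEEDING_STREAK
        for ant in range(cfg.n_workers):
            worker_rows.append((colony, ant, bool(fed_long_enough[ant])))
    workers = pd.DataFrame(worker_rows, columns=["colony", "ant_id", "is_forager"])

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for colony, table in enumerate(scan_tables):
            table.to_csv(out_dir / f"colony_{colony}_events.csv", index=False)
        workers.to_csv(out_dir / "workers.csv", index=False)
    return scan_tables, workers, raw_results


def read_experiment_tables(paths: Sequence[Path]) -> pd.DataFrame:
    """Read and pool experimental-format scan tables (extra columns ignored)."""
    frames = []
    for p in paths:
        df = pd.read_csv(p)
        missing = {"colony", "minute", "donor", "receiver"} - set(df.columns)
        if missing:
            raise ValueError(f"{p}: missing required column(s) {sorted(missing)}")
        frames.append(df[["colony", "minute", "donor", "receiver"]])
    return pd.concat(frames, ignore_index=True)
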