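"""Scan-sampling observation model, pair typing and synthetic experiments."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from trophallaxis.model_core import Caste
from trophallaxis.observation import (
    PAIR_TYPES,
    SyntheticExperimentConfig,
    classify_pair_types,
    generate_synthetic_experiment,
    observed_events_to_scans,
    read_experiment_tables,
    scan_sample,
    scans_to_observed_events,
)
from trophallaxis.simulator import TrophallaxisEvent

from conftest import small_config


def ev(donor, receiver, t_start, t_end, dc=Caste.NF, rc=Caste.NF, amount=10.0):
    return TrophallaxisEvent(donor_id=donor, receiver_id=receiver, t_start=t_start,
                             t_end=t_end, amount=amount,
                             donor_caste_at_start=dc, receiver_caste_at_start=rc)


class TestScanSampling:
    def test_short_contact_dropped(self):
        # 4 s of contact misses the "longer than 5 s" rule even across a scan
        observed = scan_sample([ev(1, 2, 58, 61)])
        assert observed == []

    def test_event_spanning_two_scans_merges(self):
        (obs,) = scan_sample([ev(1, 2, 115, 185)])
        assert obs.first_scan_minute == 2
        assert obs.duration_minutes == 2

    def test_event_between_scans_unseen(self):
        assert scan_sample([ev(1, 2, 61, 70)]) == []

    def test_event_at_scan_instant_seen(self):
        (obs,) = scan_sample([ev(1, 2, 55, 60)])
        assert obs.first_scan_minute == 1 and obs.duration_minutes == 1

    def test_strictness_flag(self):
        five_s = [ev(1, 2, 56, 60)]
        assert scan_sample(five_s) == []  # duration exactly 5 is excluded
        assert len(scan_sample(five_s, strict=False)) == 1

    def test_contractive_and_one_to_one(self):
        rng = np.random.default_rng(5)
        events = []
        t = 1
        for _ in range(300):
            start = t + int(rng.integers(1, 40))
            dur = int(rng.integers(1, 150))
            events.append(ev(int(rng.integers(10)), int(rng.integers(10, 20)),
                             start, start + dur - 1))
            t = start
        observed = scan_sample(events)
        assert len(observed) <= len(events)
        # every observation window sits inside some raw event of the same pair
        for o in observed:
            t0 = o.first_scan_minute * 60
            matches = [e for e in events
                       if e.donor_id == o.donor_id and e.receiver_id == o.receiver_id
                       and e.t_start <= t0 <= e.t_end]
            assert matches


class TestPairTypes:
    def test_all_nonforagers(self):
        counts = classify_pair_types([ev(1, 2, 5, 9) for _ in range(4)])
        assert counts == {"F->F": 0, "F->NF": 0, "NF->F": 0, "NF->NF": 4}

    def test_toy_log_hand_counts(self):
        events = [
            ev(1, 2, 5, 9, Caste.F, Caste.NF),
            ev(2, 1, 10, 19, Caste.NF, Caste.F),
            ev(1, 3, 20, 29, Caste.F, Caste.F),
            ev(4, 5, 30, 39, Caste.NF, Caste.NF),
        ]
        counts = classify_pair_types(events)
        assert counts == {"F->F": 1, "F->NF": 1, "NF->F": 1, "NF->NF": 1}

    def test_partition_property(self):
        rng = np.random.default_rng(6)
        castes = [Caste.F, Caste.NF]
        events = [ev(0, 1, 1, 2, castes[rng.integers(2)], castes[rng.integers(2)])
                  for _ in range(57)]
        assert sum(classify_pair_types(events).values()) == 57

    def test_first_visit_resolution(self):
        class Bare:  # an event record without caste annotations
            donor_id, receiver_id, t_start, t_end = 1, 2, 100, 110

        counts = classify_pair_types([Bare()], first_visit_times={1: 50})
        assert counts["F->NF"] == 1
        counts = classify_pair_types([Bare()], first_visit_times={1: 150})
        assert counts["NF->NF"] == 1
        with pytest.raises(ValueError):
            classify_pair_types([Bare()])


class TestSyntheticExperiment:
    def make_cfg(self, **kw):
        sim = small_config(alpha=0.01, n_steps=1200)
        defaults = dict(n_colonies=2, n_workers=20, sim_config=sim)
        defaults.update(kw)
        return SyntheticExperimentConfig(**defaults)

    def test_deterministic_output(self, tmp_path):
        cfg = self.make_cfg()
        t1, w1, _ = generate_synthetic_experiment(cfg, seed=3)
        t2, w2, _ = generate_synthetic_experiment(cfg, seed=3)
        for a, b in zip(t1, t2):
            assert a.equals(b)
        assert w1.equals(w2)

    def test_written_files_round_trip(self, tmp_path):
        cfg = self.make_cfg()
        tables, workers, _ = generate_synthetic_experiment(cfg, seed=3, out_dir=tmp_path)
        paths = sorted(tmp_path.glob("colony_*_events.csv"))
        assert len(paths) == 2
        pooled = read_experiment_tables(paths)
        assert pooled.equals(pd.concat(tables, ignore_index=True))
        assert set(workers.columns) == {"colony", "ant_id", "is_forager"}
        assert len(workers) == 2 * 20

    def test_inactive_colony_writes_header_only(self, tmp_path):
        sim = small_config(alpha=0.0, n_ants=2, n_steps=60)
        cfg = SyntheticExperimentConfig(n_colonies=1, n_workers=2, sim_config=sim)
        tables, workers, _ = generate_synthetic_experiment(cfg, seed=1, out_dir=tmp_path)
        assert tables[0].empty
        text = (tmp_path / "colony_0_events.csv").read_text().strip()
        assert text == "colony,minute,donor,receiver"
        assert not workers["is_forager"].any()

    def test_forager_flag_follows_feeding_streak_rule(self):
        cfg = self.make_cfg()
        _, workers, raw = generate_synthetic_experiment(cfg, seed=3)
        for colony, result in enumerate(raw):
            flags = workers[workers["colony"] == colony].set_index("ant_id")["is_forager"]
            for ant in range(cfg.n_workers):
                assert flags[ant] == (result.max_source_streak[ant] >= 5)


def test_scan_table_round_trip():
    observed_in = scan_sample(
        [ev(1, 2, 115, 185), ev(3, 4, 50, 70), ev(5, 6, 230, 470)], colony_id=7)
    df = observed_events_to_scans(observed_in)
    assert sorted(scans_to_observed_events(df), key=lambda o: o.donor_id) == sorted(
        observed_in, key=lambda o: o.donor_id)


def test_default_generator_hits_its_event_target():
    """At the calibrated defaults the synthetic colonies' raw event counts
    scatter around the configured target mean."""
    cfg = SyntheticExperimentConfig(n_colonies=5, n_workers=53)
    _, _, raw = generate_synthetic_experiment(cfg, seed=11)
    counts = np.array([r.n_events for r in raw])
    sem = counts.std(ddof=1) / np.sqrt(len(counts))
    assert abs(counts.mean() - cfg.target_mean_events) <= 2 * sem
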