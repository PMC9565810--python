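import math

import numpy as np
import pytest

from fenestra.events import detect_events_all, vestibule_occupancy
from fenestra.synth import (
    GeneratorConfig,
    PathwayRates,
    generate_tracks,
    occupancy_rates,
    recovery_report,
)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            GeneratorConfig(dt=0.0)
        with pytest.raises(ValueError):
            GeneratorConfig(duration=0.5, dt=0.1)
        with pytest.raises(ValueError):
            GeneratorConfig(n_render=3)
        with pytest.raises(ValueError):
            PathwayRates(tm_inward=-0.1)

    def test_voltage_modulation_of_tm_streams(self):
        cfg = GeneratorConfig(
            rates=PathwayRates(tm_inward=0.1, tm_outward=0.1, lat_inward=0.2),
            voltage=100.0,
            drift_gain=0.01,
        )
        eff = cfg.effective_rates()
        assert eff[("transmembrane", "inward")] == pytest.approx(0.1 * 2.0)
        assert eff[("transmembrane", "outward")] == pytest.approx(0.1 * math.exp(-1.0))
        assert eff[("lateral", "inward")] == pytest.approx(0.2)  # untouched
        # negative voltage swaps the modulation
        cfg2 = GeneratorConfig(
            rates=PathwayRates(tm_inward=0.1, tm_outward=0.1), voltage=-100.0, drift_gain=0.01
        )
        eff2 = cfg2.effective_rates()
        assert eff2[("transmembrane", "outward")] == pytest.approx(0.2)
        assert eff2[("transmembrane", "inward")] == pytest.approx(0.1 * math.exp(-1.0))


class TestDeterminismAndTrivialCases:
    def test_identical_seed_identical_output(self, balanced_ensemble):
        cfg, tracks, truth = balanced_ensemble
        tracks2, truth2 = generate_tracks(cfg)
        for a, b in zip(tracks, tracks2):
            assert np.array_equal(a.positions, b.positions)
        assert [(e.ion_id, e.time, e.pathway, e.direction) for e in truth.log.events] == [
            (e.ion_id, e.time, e.pathway, e.direction) for e in truth2.log.events
        ]

    def test_different_seed_different_output(self, balanced_ensemble):
        cfg, tracks, _ = balanced_ensemble
        from dataclasses import replace

        tracks3, _ = generate_tracks(replace(cfg, seed=cfg.seed + 1))
        assert not np.array_equal(tracks[0].positions, tracks3[0].positions)

    def test_zero_rates_yield_no_events(self, geometry):
        cfg = GeneratorConfig(rates=PathwayRates(), duration=20.0, seed=5)
        tracks, truth = generate_tracks(cfg)
        assert truth.log.events == []
        log = detect_events_all(tracks, geometry)
        assert log.events == []  # idle jitter alone never crosses

    def test_track_shapes(self, balanced_ensemble):
        cfg, tracks, _ = balanced_ensemble
        n_frames = int(round(cfg.duration / cfg.dt)) + 1
        assert len(tracks) == cfg.n_ions
        for t in tracks:
            assert len(t) == n_frames
            assert t.species == "chloride"


class TestGroundTruth:
    def test_truth_within_run_and_realized_rates_consistent(self, balanced_ensemble):
        cfg, _, truth = balanced_ensemble
        for e in truth.log.events:
            assert 0.0 < e.time < cfg.duration
        for stream, rate in truth.realized_rates.items():
            assert rate == pytest.approx(
                truth.log.count(stream[0], stream[1]) / truth.log.total_time
            )

    def test_scheduled_counts_are_poisson_consistent(self):
        """Over many seeds the realized lateral count sits inside the Poisson
        band of the scheduled intensity (entry streams are rarely starved)."""
        lam_in = 0.3
        duration = 60.0
        counts = []
        for seed in range(15):
            cfg = GeneratorConfig(
                rates=PathwayRates(lat_inward=lam_in, lat_outward=0.3),
                duration=duration,
                seed=100 + seed,
                n_ions=30,
                n_vest_init=5,
            )
            _, truth = generate_tracks(cfg)
            counts.append(truth.log.count("lateral", "inward"))
        total = sum(counts)
        expected = lam_in * duration * 15
        # scheduling happens on ~duration - n_render*dt of each run
        assert abs(total - expected) < 4 * math.sqrt(expected) + 15


class TestDetectorRecovery:
    @pytest.mark.parametrize("seed", [42, 1, 7, 123])
    def test_full_fidelity_on_clean_ensembles(self, geometry, seed):
        """Every rendered crossing is detected and classified correctly."""
        cfg = GeneratorConfig(
            rates=PathwayRates(
                tm_inward=0.08,
                tm_outward=0.08,
                lat_inward=0.25,
                lat_outward=0.25,
                api_inward=0.02,
                api_outward=0.02,
            ),
            duration=80.0,
            seed=seed,
            n_ions=30,
            n_vest_init=4,
        )
        tracks, truth = generate_tracks(cfg)
        log = detect_events_all(tracks, geometry)
        rep = recovery_report(log, truth)
        assert rep.n_truth > 20
        assert rep.missed == 0
        assert rep.spurious == 0
        assert rep.misclassified == 0
        for err in rep.rate_errors.values():
            assert err == pytest.approx(0.0, abs=1e-12)

    def test_rate_recovery_within_poisson_error(self, geometry):
        """Detected stream rates match the scheduled intensities within
        counting error, pooled over seeds."""
        rates = PathwayRates(
            tm_inward=0.06, tm_outward=0.06, lat_inward=0.2, lat_outward=0.2
        )
        duration, n_seeds = 80.0, 10
        counts = {s: 0 for s in [("transmembrane", "inward"), ("transmembrane", "outward"), ("lateral", "inward"), ("lateral", "outward")]}
        for seed in range(n_seeds):
            cfg = GeneratorConfig(
                rates=rates, duration=duration, seed=500 + seed, n_ions=30, n_vest_init=5
            )
            tracks, _ = generate_tracks(cfg)
            log = detect_events_all(tracks, geometry)
            for s in counts:
                counts[s] += log.count(s[0], s[1])
        sched = rates.as_dict()
        key = {("transmembrane", "inward"): "tm_inward", ("transmembrane", "outward"): "tm_outward", ("lateral", "inward"): "lat_inward", ("lateral", "outward"): "lat_outward"}
        for s, n in counts.items():
            expected = sched[key[s]] * duration * n_seeds
            # 4-sigma Poisson band plus slack for starvation/truncation drops
            assert abs(n - expected) < 4 * math.sqrt(expected) + 0.05 * expected

    def test_negative_control_misclassification_is_flagged(self, geometry, balanced_ensemble):
        """Corrupting detected labels must show up in the report — guards the
        report itself against trivially passing."""
        from fenestra.events import EventLog, PermeationEvent

        cfg, tracks, truth = balanced_ensemble
        log = detect_events_all(tracks, geometry)
        corrupted = []
        for e in log.events:
            p = "apical" if e.pathway == "lateral" else e.pathway
            corrupted.append(PermeationEvent(e.ion_id, e.time, p, e.direction))
        bad = EventLog(events=corrupted, total_time=log.total_time, n_ions=log.n_ions)
        rep = recovery_report(bad, truth)
        assert rep.misclassified == truth.log.count("lateral")
        assert rep.misclassified > 5

        # dropping events shows up as missed
        half = EventLog(events=log.events[::2], total_time=log.total_time)
        rep2 = recovery_report(half, truth)
        assert rep2.missed > 0


class TestOccupancy:
    def test_occupancy_rates_formula(self):
        r = occupancy_rates(4.0, churn=1.0)
        assert r.lat_inward == pytest.approx(0.8)
        assert r.lat_outward == pytest.approx(1.0)
        with pytest.raises(ValueError):
            occupancy_rates(0.0)
        with pytest.raises(ValueError):
            occupancy_rates(2.0, churn=0.0)

    def test_mean_occupancy_hits_target(self, geometry):
        """Long-run detected vestibule occupancy approaches the queueing
        target within batch error."""
        target = 4.0
        cfg = GeneratorConfig(
            rates=occupancy_rates(target, churn=1.0),
            duration=1500.0,
            dt=0.2,
            seed=3,
            n_ions=40,
            n_vest_init=4,
        )
        tracks, _ = generate_tracks(cfg)
        occ = vestibule_occupancy(tracks, geometry)
        # batch means over 20 batches give the error scale
        batches = np.array_split(occ.counts, 20)
        means = np.array([b.mean() for b in batches])
        sem = means.std(ddof=1) / math.sqrt(len(means))
        assert abs(occ.mean - target) < 4 * sem + 0.5
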