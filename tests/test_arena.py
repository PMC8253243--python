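"""Zone analytics: occupancy, visits, latency, distances, recognition."""

import math

import numpy as np
import pandas as pd
import pytest

from phenopipe import arena, synthgen
from phenopipe.evaluation import brute_force_occupancy, _brute_force_path_length


def _track_from_points(points, rate=10.0):
    t = np.arange(len(points)) / rate
    xy = np.asarray(points, dtype=float)
    return arena.Trajectory(
        pd.DataFrame({"t": t, "x": xy[:, 0], "y": xy[:, 1]}), rate
    )


class TestZoneGeometry:
    def test_quadrants_partition_the_pool(self):
        zones = arena.quadrant_zones(0.0, 0.0, 50.0)
        rng = np.random.default_rng(0)
        pts = rng.uniform(-49, 49, size=(500, 2))
        inside_pool = np.hypot(pts[:, 0], pts[:, 1]) < 50.0
        member = np.stack(
            [z.contains(pts[:, 0], pts[:, 1]) for z in zones.zones.values()]
        )
        assert (member.sum(axis=0)[inside_pool] == 1).all()

    def test_open_field_annuli_are_disjoint_thirds(self):
        zones = arena.open_field_zones(0.0, 0.0, 60.0)
        assert zones.zones["center"].contains(10.0, 0.0)
        assert zones.zones["mid"].contains(30.0, 0.0)
        assert zones.zones["periphery"].contains(50.0, 0.0)

    def test_degenerate_zones_rejected(self):
        with pytest.raises(ValueError):
            arena.CircleZone(0, 0, 0.0)
        with pytest.raises(ValueError):
            arena.AnnulusZone(0, 0, 5.0, 5.0)


class TestZoneOccupancy:
    def test_scripted_visit_reported_exactly(self):
        zones = arena.sociobox_zones(0.0, 0.0, 60.0, zone_depth=10.0)
        track = synthgen.gen_trajectory(
            zones, 30.0, 15.0, seed=1, scripted_visits=[("insert_2", 10.0, 20.0)]
        )
        occ = arena.zone_occupancy(track, zones, 0.0, 30.0)["insert_2"]
        assert occ.total_time == pytest.approx(10.0)
        assert occ.n_visits == 1
        assert occ.latency_first_entry == pytest.approx(10.0)
        assert not occ.latency_censored

    def test_never_entered_is_censored_at_window_length(self):
        zones = arena.sociobox_zones(0.0, 0.0, 60.0, zone_depth=10.0)
        track = synthgen.gen_trajectory(zones, 30.0, 0.0, seed=1)  # parked at centre
        occ = arena.zone_occupancy(track, zones, 0.0, 30.0)["insert_1"]
        assert occ.total_time == 0.0 and occ.n_visits == 0
        assert occ.latency_censored and occ.latency_first_entry == 30.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed):
        zones = arena.open_field_zones(0.0, 0.0, 60.0)
        track = synthgen.gen_trajectory(zones, 20.0, 25.0, seed=seed)
        occ = arena.zone_occupancy(track, zones, 0.0, 20.0)
        for name, zone in zones.zones.items():
            ref = brute_force_occupancy(track, zone, 0.0, 20.0)
            assert occ[name].total_time == ref["total_time"]
            assert occ[name].n_visits == ref["n_visits"]
            assert occ[name].latency_first_entry == ref["latency"]
            assert occ[name].latency_censored == ref["censored"]

    def test_exhaustive_zone_times_sum_to_duration(self):
        zones = arena.quadrant_zones(0.0, 0.0, 60.0)
        track = synthgen.gen_trajectory(zones, 45.0, 30.0, seed=9)
        occ = arena.zone_occupancy(track, zones, 0.0, 45.0)
        total = sum(r.total_time for r in occ.values())
        assert total == pytest.approx(45.0, abs=1.0 / track.sampling_rate)

    def test_visit_debouncing_merges_and_filters(self):
        zone = arena.CircleZone(0.0, 0.0, 1.0)
        zones = arena.ZoneSet({"z": zone}, arena_center=(0, 0), arena_radius=10)
        # in 0.0-0.5s, out 0.5-0.6s (gap 0.1 <= 0.2 merges), in 0.6-1.0s,
        # then a lone 0.1s blip at 2.0s that fails the minimum duration
        points = []
        for t10 in range(31):
            t = t10 / 10.0
            inside = t < 0.5 or 0.6 <= t < 1.0 or 2.0 <= t < 2.1
            points.append((0.0, 0.0) if inside else (5.0, 5.0))
        occ = arena.zone_occupancy(
            _track_from_points(points), zones, 0.0, 3.1,
            min_visit_duration=0.5, merge_gap=0.2,
        )["z"]
        assert occ.n_visits == 1
        assert occ.total_time == pytest.approx(1.0)  # all in-zone samples count

    def test_too_short_track_rejected(self):
        zones = arena.open_field_zones(0.0, 0.0, 60.0)
        with pytest.raises(ValueError):
            arena.zone_occupancy(_track_from_points([(0, 0)]), zones, 0.0, 1.0)


class TestPathLength:
    def test_stationary_track_has_zero_length(self):
        track = _track_from_points([(3.0, 4.0)] * 20)
        assert arena.path_length(track, 0.0, 2.0) == 0.0

    def test_straight_line(self):
        track = _track_from_points([(x, 0.0) for x in np.linspace(0, 100, 11)])
        assert arena.path_length(track, 0.0, 1.1) == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", [10, 11])
    def test_matches_segment_sum_oracle(self, seed):
        zones = arena.open_field_zones(0.0, 0.0, 60.0)
        track = synthgen.gen_trajectory(zones, 15.0, 30.0, seed=seed)
        assert arena.path_length(track, 0.0, 15.0) == pytest.approx(
            _brute_force_path_length(track, 0.0, 15.0), abs=1e-9
        )


class TestRecognitionMetrics:
    @staticmethod
    def _occ(times, visits=None, latencies=None):
        visits = visits or {z: 1 for z in times}
        latencies = latencies or {z: 5.0 for z in times}
        return {
            z: arena.OccupancyRecord(
                z, t, visits[z], latencies[z], False,
                t / visits[z] if visits[z] else float("nan"),
            )
            for z, t in times.items()
        }

    ROLES = {
        "insert_1": "stimulus_1",
        "insert_2": "stimulus_2",
        "insert_3": "stimulus_3",
        "insert_4": "stimulus_4",
        "insert_5": "stranger",
    }

    def test_stranger_share_of_interaction_time(self):
        occ = self._occ(
            {"insert_1": 15.0, "insert_2": 15.0, "insert_3": 15.0,
             "insert_4": 15.0, "insert_5": 40.0}
        )
        m = arena.recognition_metrics(occ, self.ROLES)
        assert m.stranger_pct_time == pytest.approx(40.0)
        assert m.mean_stimulus_pct_time == pytest.approx(15.0)
        assert m.total_interaction_time == pytest.approx(100.0)

    def test_equal_times_are_symmetric_at_20_percent(self):
        occ = self._occ({z: 12.0 for z in self.ROLES})
        m = arena.recognition_metrics(occ, self.ROLES)
        assert m.stranger_pct_time == pytest.approx(20.0)
        assert m.mean_stimulus_pct_time == pytest.approx(20.0)

    def test_zero_interaction_time_flagged_undefined(self):
        occ = self._occ({z: 0.0 for z in self.ROLES}, visits={z: 0 for z in self.ROLES})
        m = arena.recognition_metrics(occ, self.ROLES)
        assert m.undefined and math.isnan(m.stranger_pct_time)

    def test_role_cardinality_enforced(self):
        roles = dict(self.ROLES, insert_4="stranger")
        with pytest.raises(ValueError):
            arena.recognition_metrics(self._occ({z: 1.0 for z in roles}), roles)


class TestTrialScheduleAndLearning:
    def test_sociobox_schedule_structure(self):
        trials = arena.trial_schedule("sociobox")
        assert len(trials) == 6
        for trial in trials:
            assert trial.phases == (("initiation", 0.0, 300.0), ("interaction", 300.0, 600.0))
        assert all(t.insert_roles == {} for t in trials[:3])  # habituations empty
        assert set(trials[3].insert_roles.values()) == {f"stimulus_{i}" for i in range(1, 6)}
        memory = trials[-1]
        roles = list(memory.insert_roles.values())
        assert roles.count("stranger") == 1
        assert sum(r.startswith("stimulus") for r in roles) == 4

    def test_unknown_paradigm_rejected(self):
        with pytest.raises(ValueError):
            arena.trial_schedule("radial_maze")

    def test_learning_curve_day_means(self):
        lat = [90.0] * 4 + [80.0, 60.0, 40.0, 20.0]
        assert arena.learning_curve(lat).tolist() == [90.0, 50.0]

    def test_improving_learner_is_monotone(self):
        days = 8
        lat = np.concatenate(
            [np.full(4, 90.0 * 0.8**d) for d in range(days)]
        )
        curve = arena.learning_curve(lat)
        assert (np.diff(curve) <= 0).all()

    def test_partial_day_and_range_validation(self):
        with pytest.raises(ValueError):
            arena.learning_curve([10.0] * 6)
        with pytest.raises(ValueError):
            arena.learning_curve([95.0] * 4)
        assert arena.learning_curve([10.0] * 6, allow_partial=True).tolist() == [10.0, 10.0]


class TestProbeMetrics:
    def test_track_confined_to_target(self):
        zones = arena.quadrant_zones(0.0, 0.0, 60.0, target="NE")
        track = _track_from_points([(10.0, 10.0)] * 900)  # NE sector, 90 s at 10 Hz
        m = arena.probe_metrics(track, zones, "NE")
        assert m.time_in_target == pytest.approx(90.0)
        assert m.latency_target == 0.0 and not m.latency_censored
        assert m.distance == 0.0

    def test_track_never_in_target_censored(self):
        zones = arena.quadrant_zones(0.0, 0.0, 60.0, target="NE")
        track = _track_from_points([(-10.0, -10.0)] * 900)  # SW
        m = arena.probe_metrics(track, zones, "NE")
        assert m.time_in_target == 0.0
        assert m.latency_censored and m.latency_target == 90.0

    def test_matches_quadrant_oracle(self):
        zones = arena.quadrant_zones(0.0, 0.0, 60.0, target="SE")
        track = synthgen.gen_trajectory(zones, 90.0, 25.0, seed=4)
        m = arena.probe_metrics(track, zones, "SE")
        ref = brute_force_occupancy(track, zones.zones["SE"], track.t[0], track.t[0] + 90.0)
        assert m.time_in_target == ref["total_time"]
        assert m.visits_target == ref["n_visits"]
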