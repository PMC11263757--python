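"""Cluster formation, polygons, summaries, Point IDs, and the full run."""

import math

import numpy as np
import pytest

from gpscluster.cluster_core import (
    assign_point_ids,
    build_polygon,
    find_clusters,
    find_clusters_consecutive,
    run_analysis,
    summarize_cluster,
)
from gpscluster.io_formats import cluster_table, fix_table
from gpscluster.model import AnalysisResult
from gpscluster.synthetic import Bout, TrackSpec, generate

from conftest import brute_force_partition, make_config, make_fix, random_instance


class TestFindClusters:
    def test_pair_within_twice_buffer_clusters(self, config):
        part = find_clusters([make_fix(0, 0, 0), make_fix(50, 0, 60)], config)
        assert part.as_sets() == [frozenset({0, 1})]

    def test_pair_beyond_twice_buffer_stays_single(self, config):
        part = find_clusters([make_fix(0, 0, 0), make_fix(70, 0, 60)], config)
        assert part.clusters == [] and part.singles == {0, 1}

    def test_tangent_buffers_count_as_overlap(self, config):
        # maximum linking distance is exactly 2x (inclusive)
        part = find_clusters([make_fix(0, 0, 0), make_fix(60.0, 0, 60)], config)
        assert part.as_sets() == [frozenset({0, 1})]

    def test_transitive_chain(self):
        config = make_config(min_locations=3)
        fixes = [make_fix(0, 0, 0), make_fix(55, 0, 60), make_fix(110, 0, 120)]
        part = find_clusters(fixes, config)
        assert part.as_sets() == [frozenset({0, 1, 2})]
        assert brute_force_partition(fixes, 30, 3)[0] == {frozenset({0, 1, 2})}

    def test_zero_or_one_fix(self, config):
        assert find_clusters([], config).clusters == []
        part = find_clusters([make_fix(0, 0, 0)], config)
        assert part.clusters == [] and part.singles == {0}

    def test_mixed_animals_rejected(self, config):
        with pytest.raises(ValueError, match="per animal"):
            find_clusters([make_fix(0, 0, 0, animal="A"), make_fix(0, 0, 60, animal="B")], config)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        fixes = random_instance(rng, n)
        buffer_m = float(rng.uniform(5, 120))
        min_loc = int(rng.integers(2, 6))
        config = make_config(buffer_m=buffer_m, min_locations=min_loc)
        part = find_clusters(fixes, config)
        oracle_clusters, oracle_singles = brute_force_partition(fixes, buffer_m, min_loc)
        assert set(part.as_sets()) == oracle_clusters
        assert frozenset(part.singles) == oracle_singles


class TestConsecutiveMode:
    def test_nonsequential_overlap_does_not_cluster(self):
        # A and C overlap spatially but B lies between them in time, far away:
        # no cluster in consecutive mode, one cluster {A, C} in default mode.
        fixes = [make_fix(0, 0, 0), make_fix(500, 0, 60), make_fix(10, 0, 120)]
        config = make_config(consecutive_only=True)
        assert find_clusters_consecutive(fixes, config).clusters == []
        default = find_clusters(fixes, make_config())
        assert default.as_sets() == [frozenset({0, 2})]

    def test_consecutive_run_clusters(self):
        config = make_config(min_locations=4, consecutive_only=True)
        fixes = [make_fix(40 * i, 0, 60 * i) for i in range(4)]  # gaps 40 <= 60
        part = find_clusters_consecutive(fixes, config)
        assert part.as_sets() == [frozenset({0, 1, 2, 3})]

    def test_jump_splits_runs(self):
        config = make_config(min_locations=3, consecutive_only=True)
        xs = [0, 40, 80, 580, 620, 660]  # 500 m jump between index 2 and 3
        fixes = [make_fix(x, 0, 60 * i) for i, x in enumerate(xs)]
        part = find_clusters_consecutive(fixes, config)
        assert part.as_sets() == [frozenset({0, 1, 2}), frozenset({3, 4, 5})]

    @pytest.mark.parametrize("seed", range(8))
    def test_consecutive_clusters_contained_in_default_clusters(self, seed):
        rng = np.random.default_rng(100 + seed)
        fixes = random_instance(rng, int(rng.integers(20, 150)))
        config = make_config(buffer_m=float(rng.uniform(10, 80)))
        cons = find_clusters_consecutive(
            fixes, make_config(buffer_m=config.buffer_m, consecutive_only=True)
        )
        default = find_clusters(fixes, config)
        for run in cons.as_sets():
            assert any(run <= comp for comp in default.as_sets())


class TestMonotonicity:
    @pytest.mark.parametrize("seed", range(8))
    def test_clustered_set_non_decreasing_in_buffer(self, seed):
        rng = np.random.default_rng(200 + seed)
        fixes = random_instance(rng, int(rng.integers(30, 150)))
        buffers = sorted(rng.uniform(5, 150, size=3))
        clustered_sets = []
        for b in buffers:
            part = find_clusters(fixes, make_config(buffer_m=float(b)))
            clustered_sets.append(set().union(*part.as_sets()) if part.clusters else set())
        assert clustered_sets[0] <= clustered_sets[1] <= clustered_sets[2]

    @pytest.mark.parametrize("seed", range(8))
    def test_raising_min_locations_filters_exactly(self, seed):
        rng = np.random.default_rng(300 + seed)
        fixes = random_instance(rng, int(rng.integers(30, 150)))
        b = float(rng.uniform(10, 100))
        y1, y2 = 2, int(rng.integers(3, 7))
        low = find_clusters(fixes, make_config(buffer_m=b, min_locations=y1))
        high = find_clusters(fixes, make_config(buffer_m=b, min_locations=y2))
        assert set(high.as_sets()) == {c for c in low.as_sets() if len(c) >= y2}


class TestBuildPolygon:
    def test_single_fix_disc_area(self):
        poly = build_polygon([make_fix(0, 0, 0)], 30)
        assert poly.area == pytest.approx(math.pi * 900, rel=0.01)
        assert len(poly.exterior.coords) - 1 >= 32

    def test_union_idempotent_for_coincident_fixes(self):
        one = build_polygon([make_fix(5, 5, 0)], 30)
        two = build_polygon([make_fix(5, 5, 0), make_fix(5, 5, 60)], 30)
        assert two.symmetric_difference(one).area == pytest.approx(0.0, abs=1e-9)

    def test_tangent_discs_form_single_polygon(self):
        poly = build_polygon([make_fix(0, 0, 0), make_fix(60, 0, 60)], 30)
        assert poly.geom_type == "Polygon"

    def test_polygon_contains_every_member(self):
        rng = np.random.default_rng(7)
        fixes = [make_fix(x, y, 60 * i) for i, (x, y) in enumerate(rng.uniform(0, 50, (8, 2)))]
        poly = build_polygon(fixes, 30)
        from shapely.geometry import Point

        assert all(poly.contains(Point(f.x, f.y)) for f in fixes)


class TestSummaries:
    def test_inside_outside_and_percent(self, config):
        members = [make_fix(0, 0, 60 * i) for i in range(4)]
        bystander = make_fix(5000, 5000, 90)  # inside the time window, not a member
        s = summarize_cluster(members, members + [bystander], config)
        assert (s["n_inside"], s["n_outside"]) == (4, 1)
        assert s["percent_time"] == pytest.approx(80.0)

    def test_percent_is_100_without_bystanders(self, config):
        members = [make_fix(0, 0, 60 * i) for i in range(3)]
        s = summarize_cluster(members, members, config)
        assert s["percent_time"] == pytest.approx(100.0)

    def test_mean_center(self, config):
        members = [make_fix(0, 0, 0), make_fix(10, 0, 60)]
        s = summarize_cluster(members, members, config)
        assert (s["mean_x"], s["mean_y"]) == (5.0, 0.0)


class TestPointIds:
    def _result(self, fixes, config):
        return AnalysisResult(config=config, clusters=[], fixes=fixes)

    def test_cluster_member_grammar(self, config):
        f = make_fix(0, 0, 0, animal="W1")
        f.timestamp = f.timestamp.replace(day=1, hour=14)
        f.cluster_seq = 2
        assign_point_ids(self._result([f], config))
        assert f.point_id == "W1_C2_050114"

    def test_single_point_grammar(self, config):
        f = make_fix(0, 0, 0, animal="W1")
        f.timestamp = f.timestamp.replace(day=1, hour=14)
        assign_point_ids(self._result([f], config))
        assert f.point_id == "W1_SP_050114"

    def test_same_hour_collision_gets_minutes(self, config):
        a = make_fix(0, 0, 0, animal="W1")
        b = make_fix(1, 0, 0, animal="W1")
        a.timestamp = a.timestamp.replace(hour=14, minute=5)
        b.timestamp = b.timestamp.replace(hour=14, minute=40)
        assign_point_ids(self._result([a, b], config))
        assert a.point_id == "W1_SP_05011405"
        assert b.point_id == "W1_SP_05011440"

    def test_all_point_ids_unique_even_within_one_minute(self, config):
        fixes = []
        for sec in (0, 20, 40):
            f = make_fix(sec, 0, 0, animal="W1")
            f.timestamp = f.timestamp.replace(hour=9, minute=30, second=sec)
            fixes.append(f)
        assign_point_ids(self._result(fixes, config))
        ids = [f.point_id for f in fixes]
        assert len(set(ids)) == 3
        assert all(i.startswith("W1_SP_05010930") for i in ids)


class TestRunAnalysis:
    def _two_animal_spec(self):
        return TrackSpec(
            animal_ids=["A", "B"],
            period_start="2014-05-01 00:00:00",
            period_end="2014-05-08 00:00:00",
            seed=42,
            start_positions={"A": (400000.0, 6700000.0), "B": (400000.0, 6780000.0)},
            base_headings_deg={"A": 0.0, "B": 0.0},
            bouts=[
                Bout("A", 430000.0, 6700000.0, "2014-05-02 00:00:00", "2014-05-02 12:00:00"),
                Bout("A", 530000.0, 6701000.0, "2014-05-05 00:00:00", "2014-05-05 18:00:00"),
                Bout("B", 440000.0, 6780500.0, "2014-05-03 00:00:00", "2014-05-03 10:00:00"),
            ],
        )

    def test_recovers_planted_bouts_per_animal(self, config):
        fixes, truth = generate(self._two_animal_spec())
        result = run_analysis(fixes, config)
        counts = {a: len(result.clusters_for(a)) for a in ("A", "B")}
        planted = {a: sum(1 for t in truth if t.animal_id == a) for a in ("A", "B")}
        assert counts == planted
        assert [c.cluster_id for c in result.clusters_for("A")] == ["A_1", "A_2"]
        assert [c.cluster_id for c in result.clusters_for("B")] == ["B_1"]

    def test_cluster_invariants_hold(self, config):
        from shapely.geometry import Point

        fixes, _ = generate(self._two_animal_spec())
        result = run_analysis(fixes, config)
        by_key = {(f.animal_id, f.timestamp): f for f in result.fixes}
        for c in result.clusters:
            assert c.n_inside >= config.min_locations
            assert 0 < c.percent_time <= 100
            assert c.polygon.area > 0
            assert c.first_time <= c.last_time
            for t in c.member_times:
                f = by_key[(c.animal_id, t)]
                assert c.polygon.contains(Point(f.x, f.y))
                assert f.cluster_seq == c.seq_number

    def test_percent_time_recomputable_from_fix_table(self, config):
        fixes, _ = generate(self._two_animal_spec())
        result = run_analysis(fixes, config)
        for c in result.clusters:
            window = [
                f
                for f in result.fixes
                if f.animal_id == c.animal_id and c.first_time <= f.timestamp <= c.last_time
            ]
            inside = sum(1 for f in window if f.cluster_seq == c.seq_number)
            assert c.percent_time == pytest.approx(100.0 * inside / len(window))

    def test_empty_in_period_data(self):
        config = make_config(period_start="2015-01-01", period_end="2015-02-01")
        fixes = [make_fix(0, 0, 60 * i) for i in range(5)]  # all in May 2014
        result = run_analysis(fixes, config)
        assert result.clusters == [] and result.fixes == []

    def test_deterministic_tables(self, config):
        fixes, _ = generate(self._two_animal_spec())
        r1 = run_analysis(fixes, config, analysis_time="2014-06-01 00:00:00")
        r2 = run_analysis(fixes, config, analysis_time="2014-06-01 00:00:00")
        assert cluster_table(r1).to_csv() == cluster_table(r2).to_csv()
        assert fix_table(r1).to_csv() == fix_table(r2).to_csv()

    def test_input_fixes_not_mutated(self, config):
        fixes = [make_fix(0, 0, 0), make_fix(10, 0, 60)]
        run_analysis(fixes, config)
        assert all(f.point_id is None and f.cluster_seq is None for f in fixes)
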