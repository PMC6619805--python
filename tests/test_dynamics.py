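"""Closed-loop simulation: stepping, refits, evaluation, paired comparison."""

import datetime

import numpy as np
import pandas as pd
import pytest

from bsevalue import (
    PolicyConfig,
    SiteGrid,
    WorldConfig,
    compare_policies,
    evaluate,
    make_world,
    paired_wins,
    run_simulation,
    step,
    write_bse_csv,
)
from bsevalue.covariates import SiteHistoryTracker
from bsevalue.dynamics import StaleSurfaceError
from bsevalue.value import MarginalValueSurface, normalize_and_rank, uniform_surface


def tiny_world(seed=5, n=6, n_observers=2):
    grid = SiteGrid(origin_x=0, origin_y=0, cell_size=100.0, n_x=n, n_y=n)
    return make_world(
        WorldConfig(
            grid=grid,
            n_observers=n_observers,
            distance_decay_lambda=100.0,
            seed=seed,
            home_points=np.full((n_observers, 2), n * 50.0),
        )
    )


EPOCH_ORD = datetime.date(2024, 1, 1).toordinal()


def surface_peaked_at(world, best_site):
    ids = world.grid.all_site_ids()
    raw = np.array([1.0 if sid == best_site else 0.0 for sid in ids])
    return MarginalValueSurface(
        as_of_date=EPOCH_ORD, frame=normalize_and_rank(ids, raw)
    )


class TestStep:
    def test_temperature_limit_picks_top_site(self):
        world = tiny_world()
        surface = surface_peaked_at(world, "4_2")
        policy = PolicyConfig(kind="guided", softmax_temperature=1e-9, agent_radius=1e6)
        tracker = SiteHistoryTracker(world.grid)
        rng = np.random.default_rng(0)
        new = step(world, tracker, surface, policy, day=0, rng=rng)
        assert {r.site_id for r in new} == {"4_2"}

    def test_one_bse_per_agent_per_day(self):
        world = tiny_world(n_observers=3)
        surface = uniform_surface(world.grid.all_site_ids(), as_of_date=EPOCH_ORD)
        policy = PolicyConfig(kind="guided")
        new = step(
            world, SiteHistoryTracker(world.grid), surface, policy, 0,
            np.random.default_rng(0),
        )
        assert len(new) == 3
        assert len({r.observer_id for r in new}) == 3

    def test_stale_surface_rejected(self):
        world = tiny_world()
        surface = uniform_surface(world.grid.all_site_ids(), as_of_date=EPOCH_ORD)
        policy = PolicyConfig(kind="guided", recompute_cadence=7)
        with pytest.raises(StaleSurfaceError):
            step(world, SiteHistoryTracker(world.grid), surface, policy, 30,
                 np.random.default_rng(0))

    def test_greedy_agent_avoids_just_sampled_site(self, record_factory):
        """With a positive days-since coefficient the surface refit demotes the
        site sampled in the previous period, so a near-greedy agent moves on."""
        from bsevalue import (
            ExpectedLeverageModel,
            compute_site_covariates,
            predict_marginal_value,
        )

        world = tiny_world(n_observers=1)
        # intercept + (sampled, dist, median, neighbor, days_since): only
        # days-since matters
        model = ExpectedLeverageModel(
            coefficients=np.array([0.0, 0.0, 0.0, 0.0, 0.0, 1.0])
        )
        grid = world.grid
        history = [
            record_factory(sid, day=0, grid=grid)
            for sid in ("0_0", "3_3", "5_1")
        ]
        policy = PolicyConfig(kind="guided", softmax_temperature=1e-9, agent_radius=1e6)
        chosen = []
        for period in (1, 8):  # two recompute periods, cadence 7
            as_of = datetime.date(2024, 1, 1) + datetime.timedelta(days=period)
            cov = compute_site_covariates(history, grid, as_of)
            surface = predict_marginal_value(model, cov, as_of_date=as_of.toordinal())
            tracker = SiteHistoryTracker(grid)
            new = step(world, tracker, surface, policy, period, np.random.default_rng(1))
            chosen.append(new[0].site_id)
            history.extend(
                record_factory(r.site_id, day=period, grid=grid) for r in new
            )
        assert chosen[0] != chosen[1]


class TestRunSimulation:
    def test_zero_days_is_noop(self, record_factory):
        world = tiny_world()
        initial = [record_factory("0_0", day=0, grid=world.grid)]
        result = run_simulation(
            world, PolicyConfig(kind="guided"), t_days=0, seed=1, initial_history=initial
        )
        assert result.history == initial

    def test_identical_seeds_bitwise_identical_runs(self, tmp_path):
        world = tiny_world()
        policy = PolicyConfig(kind="guided", recompute_cadence=5)
        a = run_simulation(world, policy, 15, seed=42)
        b = run_simulation(world, policy, 15, seed=42)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_bse_csv(a.history, pa)
        write_bse_csv(b.history, pb)
        assert pa.read_bytes() == pb.read_bytes()
        for sa, sb in zip(a.surfaces, b.surfaces):
            pd.testing.assert_frame_equal(sa.frame, sb.frame)

    def test_recompute_count_matches_cadence(self):
        world = tiny_world()
        policy = PolicyConfig(kind="haphazard", recompute_cadence=7)
        for t in (14, 20, 21):
            result = run_simulation(world, policy, t, seed=3)
            # surfaces = 1 cold start + floor(T / cadence) refits
            assert len(result.surfaces) == 1 + t // 7, t

    def test_event_covariates_row_per_event(self):
        world = tiny_world()
        result = run_simulation(world, PolicyConfig(kind="haphazard"), 10, seed=3)
        assert len(result.event_covariates) == len(result.history)


class TestEvaluate:
    def test_full_coverage_zeroes_nn_distance(self, record_factory):
        world = tiny_world()
        grid = world.grid
        history = [
            record_factory(sid, day=i % 5, grid=grid)
            for i, sid in enumerate(grid.all_site_ids())
        ]
        result = run_simulation(
            world, PolicyConfig(kind="guided"), 0, seed=1, initial_history=history
        )
        metrics = evaluate(result, world, span_days=10)
        assert metrics.mean_nn_distance == 0.0

    def test_median_interval_of_regular_revisits(self, record_factory):
        world = tiny_world()
        history = [record_factory("2_2", day=d, grid=world.grid) for d in (0, 14, 28)]
        result = run_simulation(
            world, PolicyConfig(kind="guided"), 0, seed=1, initial_history=history
        )
        intervals = result.tracker.per_site_median_intervals(censor_at=30.0)
        assert intervals[world.grid.site_index("2_2")] == 14.0

    def test_empty_history_rejected(self):
        world = tiny_world()
        result = run_simulation(world, PolicyConfig(kind="guided"), 0, seed=1)
        with pytest.raises(ValueError):
            evaluate(result, world, span_days=1)

    def test_occupancy_rmse_small_with_abundant_data(self):
        world = tiny_world(n=10, n_observers=6)
        result = run_simulation(world, PolicyConfig(kind="guided"), 60, seed=2)
        metrics = evaluate(result, world, span_days=60)
        assert 0.0 <= metrics.occupancy_rmse < 0.25


class TestComparePolicies:
    @staticmethod
    def _factory(seed):
        grid = SiteGrid(origin_x=0, origin_y=0, cell_size=100.0, n_x=8, n_y=8)
        return WorldConfig(grid=grid, n_observers=3, seed=seed)

    def test_self_comparison_is_exactly_tied(self):
        policies = {
            "a": PolicyConfig(kind="haphazard"),
            "b": PolicyConfig(kind="haphazard"),
        }
        report = compare_policies(self._factory, policies, t_days=10, n_replicates=2)
        wide = report.pivot(index="replicate", columns="policy")
        for metric in ("mean_nn_distance", "median_interval_median"):
            np.testing.assert_array_equal(
                wide[(metric, "a")], wide[(metric, "b")]
            )
        assert paired_wins(report, "mean_nn_distance", "a", "b") == 0.0

    def test_report_shape(self):
        policies = {
            "guided": PolicyConfig(kind="guided"),
            "haphazard": PolicyConfig(kind="haphazard"),
        }
        report = compare_policies(self._factory, policies, t_days=8, n_replicates=3)
        assert len(report) == 3 * 2
        assert set(report["policy"]) == {"guided", "haphazard"}
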