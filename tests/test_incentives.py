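"""Candidate selection, points, and the density-normalized leaderboard."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from bsevalue import (
    ExclusionMask,
    Leaderboard,
    ParticipantSpec,
    PointsScheme,
    assign_points,
    select_candidates,
    update_leaderboard,
)
from bsevalue.incentives import OptedOutError, StaleSurfaceError
from bsevalue.value import MarginalValueSurface, normalize_and_rank


@pytest.fixture
def surface(small_grid):
    ids = small_grid.all_site_ids()
    rng = np.random.default_rng(1)
    raw = rng.uniform(size=len(ids))
    return MarginalValueSurface(as_of_date=739000, frame=normalize_and_rank(ids, raw))


def participant(radius=160.0, center=(250.0, 250.0), opted_in=True):
    return ParticipantSpec(
        observer_id="p1", opted_in=opted_in, center=center, radius=radius
    )


class TestSelectCandidates:
    def test_radius_and_mask_set_arithmetic(self, small_grid, surface):
        # radius 120 m around the grid center covers the 5-cell plus shape
        mask = ExclusionMask(polygons=[box(200, 300, 300, 400)], labels=["reserve"])
        plist = select_candidates(
            surface, small_grid, participant(radius=120.0), mask=mask
        )
        assert len(plist.frame) == 4  # 5 candidates, 1 masked ("2_3")
        assert "2_3" not in plist.site_ids

    def test_opted_out_participant_refused(self, small_grid, surface):
        with pytest.raises(OptedOutError):
            select_candidates(surface, small_grid, participant(opted_in=False))

    def test_all_candidates_masked_flagged(self, small_grid, surface):
        mask = ExclusionMask(polygons=[box(0, 0, 500, 500)], labels=["all"])
        plist = select_candidates(surface, small_grid, participant(), mask=mask)
        assert plist.frame.empty
        assert plist.reason == "fully excluded"

    def test_ordering_matches_surface_ranks_restricted(self, small_grid, surface):
        plist = select_candidates(surface, small_grid, participant())
        by_site = surface.frame.set_index("site_id")
        surface_order = by_site.loc[plist.site_ids, "rank"]
        assert list(surface_order) == sorted(surface_order)

    def test_weekend_circle_extends_candidates(self, small_grid, surface):
        weekday_only = select_candidates(surface, small_grid, participant())
        both = select_candidates(
            surface,
            small_grid,
            ParticipantSpec(
                observer_id="p1",
                opted_in=True,
                center=(250.0, 250.0),
                radius=160.0,
                weekend_center=(50.0, 50.0),
                weekend_radius=60.0,
            ),
        )
        assert set(weekday_only.site_ids) < set(both.site_ids)
        assert "0_0" in both.site_ids

    @settings(max_examples=25, deadline=None)
    @given(
        x0=st.floats(0, 400),
        y0=st.floats(0, 400),
        w=st.floats(50, 300),
        h=st.floats(50, 300),
    )
    def test_masked_sites_never_listed(self, x0, y0, w, h):
        from bsevalue import SiteGrid

        grid = SiteGrid(origin_x=0, origin_y=0, cell_size=100.0, n_x=5, n_y=5)
        ids = grid.all_site_ids()
        surf = MarginalValueSurface(
            as_of_date=None,
            frame=normalize_and_rank(ids, np.arange(len(ids), dtype=float)),
        )
        mask = ExclusionMask(polygons=[box(x0, y0, x0 + w, y0 + h)], labels=["m"])
        plist = select_candidates(
            surf, grid, participant(radius=1000.0), mask=mask
        )
        assert not set(plist.site_ids) & mask.excluded_sites(grid)


class TestAssignPoints:
    def test_points_proportional_to_normalized_value(self, small_grid, surface, record_factory):
        by_site = surface.frame.set_index("site_id")
        top = by_site[by_site["rank"] == 1].index[0]
        bottom = by_site[by_site["rank"] == 25].index[0]
        assert assign_points(record_factory(top, day=0), surface) == pytest.approx(100.0)
        assert assign_points(record_factory(bottom, day=0), surface) == pytest.approx(0.0)

    def test_half_value_site_earns_half_points(self, small_grid, record_factory):
        ids = small_grid.all_site_ids()[:3]
        frame = normalize_and_rank(ids, np.array([0.0, 1.0, 2.0]))
        surf = MarginalValueSurface(as_of_date=None, frame=frame)
        assert assign_points(record_factory(ids[1], day=0), surf) == pytest.approx(50.0)

    def test_stale_surface_site_rejected(self, surface, record_factory):
        rec = record_factory("0_0", day=0)
        stale = MarginalValueSurface(
            as_of_date=None, frame=surface.frame[surface.frame["site_id"] != "0_0"]
        )
        with pytest.raises(StaleSurfaceError):
            assign_points(rec, stale)

    def test_points_never_depend_on_species(self, surface, record_factory, rng):
        """Looking, not finding: permuting species codes across records leaves
        every point award unchanged."""
        ids = [f"{i}_{j}" for i in range(5) for j in range(5)]
        records = [
            record_factory(ids[int(rng.integers(25))], day=d, species=sp)
            for d, sp in enumerate(["SP1", "NONE", "SP2"] * 10)
        ]
        before = [assign_points(r, surface) for r in records]
        perm = rng.permutation(len(records))
        from dataclasses import replace

        shuffled = [
            replace(r, species_code=records[perm[i]].species_code)
            for i, r in enumerate(records)
        ]
        after = [assign_points(r, surface) for r in shuffled]
        assert before == after

    def test_total_points_bounded_by_pmax_per_bse(self, surface, record_factory, rng):
        ids = [f"{i}_{j}" for i in range(5) for j in range(5)]
        records = [record_factory(ids[int(rng.integers(25))], day=d) for d in range(40)]
        total = sum(assign_points(r, surface) for r in records)
        assert total <= 100.0 * len(records) + 1e-9

    def test_rank_linear_scheme_decreasing_in_rank(self, surface, record_factory):
        scheme = PointsScheme(kind="rank_linear")
        by_site = surface.frame.set_index("site_id")
        pts = {
            sid: assign_points(record_factory(sid, day=0), surface, scheme)
            for sid in by_site.index
        }
        ordered = by_site.sort_values("rank").index
        values = [pts[sid] for sid in ordered]
        assert values == sorted(values, reverse=True)
        assert values[0] == pytest.approx(100.0)


class TestLeaderboard:
    def test_lone_participant_identity(self):
        p = participant()
        frame = update_leaderboard(Leaderboard(), {"p1": 100.0}, [p])
        assert frame.iloc[0]["density"] == 1
        assert frame.iloc[0]["score"] == pytest.approx(100.0)

    def test_colocated_participants_share_density(self):
        ps = [
            ParticipantSpec("a", True, (100.0, 100.0), 500.0),
            ParticipantSpec("b", True, (100.0, 100.0), 500.0),
        ]
        frame = update_leaderboard(Leaderboard(), {"a": 100.0, "b": 100.0}, ps)
        assert (frame["density"] == 2).all()
        np.testing.assert_allclose(frame["score"], 50.0)

    def test_empty_update_idempotent(self):
        board = Leaderboard()
        ps = [participant()]
        first = update_leaderboard(board, {"p1": 10.0}, ps)
        second = update_leaderboard(board, {}, ps)
        pd.testing.assert_frame_equal(first, second)

    def test_opted_out_neighbors_do_not_count_toward_density(self):
        ps = [
            ParticipantSpec("a", True, (100.0, 100.0), 500.0),
            ParticipantSpec("b", False, (100.0, 100.0), 500.0),
        ]
        frame = update_leaderboard(Leaderboard(), {"a": 80.0}, ps)
        assert frame.iloc[0]["density"] == 1
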