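"""Participant-facing workflow: candidate selection, points, leaderboard.

The incentive design rewards *looking*, not *finding*: a BSE's points depend
only on where and when it was made — never on the species recorded — which
removes the temptation to game the system by chasing rarities.  Opportunistic
BSEs outside the recommended list still earn points proportional to their
site's potential value.  Leaderboard scores are normalized by local
participant density so scores stay comparable between crowded and sparse
regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import ExclusionMask, SiteGrid
from .io import BSERecord
from .value import MarginalValueSurface, normalize_and_rank


class OptedOutError(PermissionError):
    """Participant has not opted into the challenge."""


class StaleSurfaceError(KeyError):
    """A scored BSE's site is absent from the value surface."""


@dataclass(frozen=True)
class ParticipantSpec:
    """Opt-in participant with a preferred sampling circle.

    An optional second circle models intraweek variation (e.g. a small
    weekday circle near home and a larger weekend one)."""

    observer_id: str
    opted_in: bool
    center: tuple[float, float]  # grid meters
    radius: float
    weekend_center: tuple[float, float] | None = None
    weekend_radius: float | None = None

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if (self.weekend_center is None) != (self.weekend_radius is None):
            raise ValueError("weekend center and radius must be given together")
        if self.weekend_radius is not None and self.weekend_radius <= 0:
            raise ValueError("weekend radius must be > 0")

    def circles(self):
        out = [(np.asarray(self.center, dtype=float), self.radius)]
        if self.weekend_center is not None:
            out.append((np.asarray(self.weekend_center, dtype=float), self.weekend_radius))
        return out


@dataclass
class PointsScheme:
    """How normalized site values map to points.

    ``proportional`` (default): points = p_max x normalized value — any
    opportunistic BSE earns in proportion to its site's potential value.
    ``rank_linear``: points decline linearly with rank from p_max to
    p_max / n — an alternative closer to a classic K..1 prize ladder.
    """

    p_max: float = 100.0
    kind: str = "proportional"

    def __post_init__(self):
        if self.kind not in ("proportional", "rank_linear"):
            raise ValueError(f"unknown points scheme {self.kind!r}")
        if self.p_max <= 0:
            raise ValueError("p_max must be > 0")


@dataclass
class PriorityList:
    """Ranked, masked, re-normalized candidates for one participant."""

    observer_id: str
    as_of_date: object
    frame: pd.DataFrame  # site_id, raw_value, normalized_value, rank, points
    reason: str | None = None  # set when the list is empty

    @property
    def site_ids(self) -> list[str]:
        return list(self.frame["site_id"])


def select_candidates(
    surface: MarginalValueSurface,
    grid: SiteGrid,
    participant: ParticipantSpec,
    mask: ExclusionMask | None = None,
    scheme: PointsScheme | None = None,
) -> PriorityList:
    """Steps 2–3: sites within the participant's circle(s), minus exclusions,
    re-normalized and ranked within the candidate set."""
    if not participant.opted_in:
        raise OptedOutError(
            f"participant {participant.observer_id!r} has not opted in"
        )
    scheme = scheme or PointsScheme()
    centers = grid.centers()
    ids = grid.all_site_ids()
    in_radius = np.zeros(len(ids), dtype=bool)
    for center, radius in participant.circles():
        d = np.sqrt(((centers - center) ** 2).sum(axis=1))
        in_radius |= d <= radius
    surface_ids = set(surface.frame["site_id"])
    candidates = [sid for sid, ok in zip(ids, in_radius) if ok and sid in surface_ids]
    if not candidates:
        return PriorityList(
            observer_id=participant.observer_id,
            as_of_date=surface.as_of_date,
            frame=_empty_priority_frame(),
            reason="no sites within radius",
        )
    if mask is not None:
        excluded = mask.excluded_sites(grid)
        kept = [sid for sid in candidates if sid not in excluded]
        if not kept:
            return PriorityList(
                observer_id=participant.observer_id,
                as_of_date=surface.as_of_date,
                frame=_empty_priority_frame(),
                reason="fully excluded",
            )
        candidates = kept
    sub = surface.frame.set_index("site_id").loc[candidates]
    frame = normalize_and_rank(candidates, sub["raw_value"].to_numpy())
    frame["points"] = _points_for_frame(frame, scheme)
    frame = frame.sort_values("rank").reset_index(drop=True)
    return PriorityList(
        observer_id=participant.observer_id,
        as_of_date=surface.as_of_date,
        frame=frame,
    )


def _empty_priority_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["site_id", "raw_value", "normalized_value", "rank", "points"]
    )


def _points_for_frame(frame: pd.DataFrame, scheme: PointsScheme) -> np.ndarray:
    if scheme.kind == "proportional":
        return scheme.p_max * frame["normalized_value"].to_numpy(dtype=float)
    n = len(frame)
    return scheme.p_max * (n - frame["rank"].to_numpy(dtype=float) + 1) / n


def assign_points(
    bse: BSERecord,
    surface: MarginalValueSurface,
    scheme: PointsScheme | None = None,
) -> float:
    """Step 4: points for one BSE — a pure function of site and surface.

    The species recorded never enters; looking is rewarded, finding is not.
    """
    scheme = scheme or PointsScheme()
    if bse.site_id is None:
        raise ValueError("BSE has no site_id; call attach_sites first")
    try:
        row = surface.frame.set_index("site_id").loc[bse.site_id]
    except KeyError:
        raise StaleSurfaceError(
            f"site {bse.site_id!r} missing from surface dated {surface.as_of_date}"
        )
    if scheme.kind == "proportional":
        return float(scheme.p_max * row["normalized_value"])
    n = len(surface.frame)
    return float(scheme.p_max * (n - row["rank"] + 1) / n)


@dataclass
class Leaderboard:
    """Cumulative raw points per observer plus density-normalized scores."""

    raw_points: dict[str, float] = field(default_factory=dict)

    def frame(self, participants: list[ParticipantSpec]) -> pd.DataFrame:
        specs = {p.observer_id: p for p in participants}
        rows = []
        for observer_id, raw in self.raw_points.items():
            if observer_id not in specs:
                raise KeyError(f"scored observer {observer_id!r} has no ParticipantSpec")
            density = participant_density(specs[observer_id], participants)
            rows.append(
                {
                    "observer_id": observer_id,
                    "raw_points": raw,
                    "density": density,
                    "score": raw / density,
                }
            )
        frame = pd.DataFrame(rows, columns=["observer_id", "raw_points", "density", "score"])
        return frame.sort_values(
            ["score", "observer_id"], ascending=[False, True]
        ).reset_index(drop=True)


def participant_density(
    participant: ParticipantSpec, participants: list[ParticipantSpec]
) -> int:
    """Opted-in participants whose centers lie within this participant's
    radius, including the participant (density >= 1)."""
    c = np.asarray(participant.center, dtype=float)
    n = 0
    for other in participants:
        if not other.opted_in:
            continue
        d = float(np.hypot(*(np.asarray(other.center, dtype=float) - c)))
        if d <= participant.radius:
            n += 1
    return max(n, 1)


def update_leaderboard(
    board: Leaderboard,
    new_points: dict[str, float],
    participants: list[ParticipantSpec],
) -> pd.DataFrame:
    """Accumulate points and return the sorted, density-normalized board.

    Idempotent on an empty update.
    """
    specs = {p.observer_id: p for p in participants}
    for observer_id, pts in new_points.items():
        if observer_id not in specs:
            raise KeyError(f"scored observer {observer_id!r} has no ParticipantSpec")
        board.raw_points[observer_id] = board.raw_points.get(observer_id, 0.0) + pts
    return board.frame(participants)
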