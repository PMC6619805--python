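"""Forward-looking spatio-temporal site covariates.

Five per-site covariates summarize a sampling history as of a given date,
computed only from events *strictly before* that date:

1. ``sampled`` — whether the site has ever been sampled (0/1);
2. ``dist_nearest_sampled`` — meters from the site center to the nearest
   sampled site's center (0 for a sampled site);
3. ``median_interval`` — median of the day gaps between the site's
   consecutive BSEs;
4. ``neighbor_median_interval`` — the median interval of the nearest sampled
   *other* site;
5. ``days_since_last`` — days since the site's most recent BSE.

Sites with fewer than two BSEs have no interval and never-sampled sites have
no "last BSE"; those fields are censored at a horizon ``H`` (default twice
the project's desired sampling interval) and flagged, which keeps unsampled
sites attractive to the value model without introducing infinities.
Distances are censored at the grid diagonal when nothing is sampled yet.

Timestamps are truncated to whole UTC days for all interval arithmetic.
"""

from __future__ import annotations

import datetime

import numpy as np
import pandas as pd

from .grid import SiteGrid
from .io import BSERecord

#: covariate column order used throughout the value model
COVARIATE_COLUMNS = [
    "sampled",
    "dist_nearest_sampled",
    "median_interval",
    "neighbor_median_interval",
    "days_since_last",
]

CENSOR_FLAGS = [
    "dist_censored",
    "median_interval_censored",
    "neighbor_censored",
    "days_since_censored",
]

DEFAULT_DESIRED_INTERVAL_DAYS = 14


def horizon_days(desired_interval_days: float = DEFAULT_DESIRED_INTERVAL_DAYS) -> float:
    """Censoring horizon H = 2 x the desired sampling interval."""
    return 2.0 * desired_interval_days


def _to_day(date) -> int:
    if isinstance(date, BSERecord):
        return date.day
    if isinstance(date, pd.Timestamp):
        return date.tz_convert("UTC").date().toordinal() if date.tzinfo else date.date().toordinal()
    if isinstance(date, datetime.date):
        return date.toordinal()
    if isinstance(date, (int, np.integer)):
        return int(date)
    raise TypeError(f"cannot interpret {date!r} as a day")


class SiteHistoryTracker:
    """Incremental per-site sampling state over a grid.

    Events are appended in chronological order; covariates for any site can
    be read off at any moment, reflecting only the events added so far.  This
    is what makes time-matched training rows and the closed-loop simulation
    cheap: covariates are maintained, not recomputed from scratch.
    """

    def __init__(self, grid: SiteGrid, horizon: float = horizon_days()):
        self.grid = grid
        self.horizon = float(horizon)
        self.centers = grid.centers()
        n = grid.n_sites
        self._event_days: list[list[int]] = [[] for _ in range(n)]
        self._median: np.ndarray = np.full(n, self.horizon)  # censored default
        self._median_censored = np.ones(n, dtype=bool)
        self._last_day = np.full(n, -1, dtype=np.int64)
        self._count = np.zeros(n, dtype=np.int64)
        # distance from every site center to the nearest sampled site center
        self._dist = np.full(n, grid.diagonal)
        self._sampled_indices: list[int] = []
        self._last_event_day: int | None = None

    # -- mutation -----------------------------------------------------------

    def add_record(self, record: BSERecord) -> None:
        if record.site_id is None:
            raise ValueError("record has no site_id; call attach_sites first")
        self.add_event(self.grid.site_index(record.site_id), record.day)

    def add_event(self, site_index: int, day: int) -> None:
        if self._last_event_day is not None and day < self._last_event_day:
            raise ValueError("events must be added in chronological order")
        self._last_event_day = day
        days = self._event_days[site_index]
        days.append(day)
        self._count[site_index] += 1
        self._last_day[site_index] = day
        if len(days) >= 2:
            self._median[site_index] = float(np.median(np.diff(days)))
            self._median_censored[site_index] = False
        if self._count[site_index] == 1:  # newly sampled site: update coverage field
            self._sampled_indices.append(site_index)
            d = np.sqrt(((self.centers - self.centers[site_index]) ** 2).sum(axis=1))
            np.minimum(self._dist, d, out=self._dist)

    # -- queries ------------------------------------------------------------

    @property
    def n_sampled(self) -> int:
        return len(self._sampled_indices)

    def sampled_mask(self) -> np.ndarray:
        return self._count > 0

    def _nearest_other_sampled(self, site_index: int) -> int | None:
        """Index of the nearest sampled site excluding the site itself."""
        cand = sorted(s for s in self._sampled_indices if s != site_index)
        if not cand:
            return None
        cand = np.asarray(cand)
        d = np.sqrt(((self.centers[cand] - self.centers[site_index]) ** 2).sum(axis=1))
        # argmin takes the first minimum; cand ascending => ties break by site index
        return int(cand[np.argmin(d)])

    def covariates_for_site(self, site_index: int, as_of_day) -> dict:
        """The five covariates (+ censor flags) for one site."""
        day = _to_day(as_of_day)
        sampled = self._count[site_index] > 0
        dist_censored = not sampled and self.n_sampled == 0
        dist = 0.0 if sampled else float(self._dist[site_index])
        days_since_censored = not sampled
        days_since = (
            float(day - self._last_day[site_index]) if sampled else self.horizon
        )
        neighbor = self._nearest_other_sampled(site_index)
        if neighbor is None:
            neighbor_interval, neighbor_censored = self.horizon, True
        else:
            neighbor_interval = float(self._median[neighbor])
            neighbor_censored = bool(self._median_censored[neighbor])
        return {
            "sampled": float(sampled),
            "dist_nearest_sampled": dist,
            "median_interval": float(self._median[site_index]),
            "neighbor_median_interval": neighbor_interval,
            "days_since_last": days_since,
            "dist_censored": dist_censored,
            "median_interval_censored": bool(self._median_censored[site_index]),
            "neighbor_censored": neighbor_censored,
            "days_since_censored": days_since_censored,
        }

    def site_covariates_table(self, as_of_day) -> pd.DataFrame:
        """Covariates for every grid site, canonical order, vectorized."""
        day = _to_day(as_of_day)
        n = self.grid.n_sites
        sampled = self._count > 0
        dist = np.where(sampled, 0.0, self._dist)
        days_since = np.where(sampled, day - self._last_day, self.horizon).astype(float)
        neighbor_interval = np.full(n, self.horizon)
        neighbor_censored = np.ones(n, dtype=bool)
        if self._sampled_indices:
            s_idx = np.sort(np.asarray(self._sampled_indices))
            # pairwise distances all sites x sampled sites; mask self-matches
            d = np.sqrt(
                ((self.centers[:, None, :] - self.centers[s_idx][None, :, :]) ** 2).sum(axis=2)
            )
            for col, s in enumerate(s_idx):
                d[s, col] = np.inf
            # argmin takes the first minimum; s_idx ascending => ties break by site index
            nearest = s_idx[np.argmin(d, axis=1)]
            valid = np.isfinite(np.min(d, axis=1))
            neighbor_interval[valid] = self._median[nearest[valid]]
            neighbor_censored[valid] = self._median_censored[nearest[valid]]
        return pd.DataFrame(
            {
                "site_id": self.grid.all_site_ids(),
                "as_of_day": day,
                "sampled": sampled.astype(float),
                "dist_nearest_sampled": dist,
                "median_interval": self._median.astype(float),
                "neighbor_median_interval": neighbor_interval,
                "days_since_last": days_since,
                "dist_censored": (~sampled) & (self.n_sampled == 0),
                "median_interval_censored": self._median_censored,
                "neighbor_censored": neighbor_censored,
                "days_since_censored": ~sampled,
            }
        )

    def per_site_median_intervals(self, censor_at: float) -> np.ndarray:
        """Per-site median intervals with <2-sample sites censored at ``censor_at``.

        Evaluation helper: the censor here is the observation span, not H, so
        that never-revisited sites register as worst-case, not as attractive.
        """
        out = np.full(self.grid.n_sites, float(censor_at))
        mask = ~self._median_censored
        out[mask] = self._median[mask]
        return out

    def nearest_sampled_distances(self) -> np.ndarray:
        if self.n_sampled == 0:
            raise ValueError("no site has been sampled; nearest distances undefined")
        return np.where(self._count > 0, 0.0, self._dist)


def compute_site_covariates(
    history: list[BSERecord],
    grid: SiteGrid,
    as_of_date,
    horizon: float = horizon_days(),
) -> pd.DataFrame:
    """Covariate table for all grid sites from events strictly before a date.

    An empty history is not an error: every site comes back unsampled with
    censored temporal fields.
    """
    day = _to_day(as_of_date)
    tracker = SiteHistoryTracker(grid, horizon=horizon)
    for r in sorted(history, key=lambda r: (r.day, r.observation_id)):
        if r.day < day:
            tracker.add_record(r)
    return tracker.site_covariates_table(day)


def event_covariates(
    history: list[BSERecord],
    grid: SiteGrid,
    horizon: float = horizon_days(),
) -> pd.DataFrame:
    """Time-matched covariates: one row per event, computed from the history
    strictly before that event's own day (the event itself and same-day
    events are excluded).  These are the training rows for the
    expected-leverage regression."""
    ordered = sorted(history, key=lambda r: (r.day, r.observation_id))
    tracker = SiteHistoryTracker(grid, horizon=horizon)
    rows = []
    pending: list[BSERecord] = []  # same-day events not yet visible
    pending_day: int | None = None
    for r in ordered:
        if pending_day is not None and r.day > pending_day:
            for q in pending:
                tracker.add_record(q)
            pending = []
        pending_day = r.day
        cov = tracker.covariates_for_site(grid.site_index(r.site_id), r.day)
        cov["observation_id"] = r.observation_id
        cov["site_id"] = r.site_id
        cov["event_day"] = r.day
        rows.append(cov)
        pending.append(r)
    cols = ["observation_id", "site_id", "event_day"] + COVARIATE_COLUMNS + CENSOR_FLAGS
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
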