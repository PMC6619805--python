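"""Closed-loop simulation: guided vs haphazard sampling at equal effort.

Agents sample one site per day each.  Under the *haphazard* policy each agent
chooses sites with the same exponential distance-decay kernel as the
synthetic history generator (convenience sampling).  Under the *guided*
policy each agent softmax-samples from the current marginal-value surface
restricted to sites within their radius — stochastic compliance with the
priority map rather than perfect obedience.

On a fixed cadence the loop refits the whole pipeline from the accumulated
data: target detection GLM -> per-BSE leverage -> expected-leverage
regression on time-matched covariates -> new surface.  Until the first
refit (and whenever a refit is impossible, e.g. a single-class response
early on) the surface is uniform — the cold-start rule.

Evaluation compares spatial coverage (mean distance from every site to the
nearest sampled site), temporal regularity (median over sites of the
per-site median sampling interval, censored at the observation span for
sites with fewer than two visits), and the quality of the refitted
occupancy model (RMSE against the true occupancy surface).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import SiteHistoryTracker, horizon_days
from .grid import SiteGrid
from .io import NO_DETECTION, BSERecord
from .leverage import (
    CollinearityError,
    NotConvergedError,
    SeparationError,
    build_design,
    fit_glm,
    hat_values,
)
from .value import (
    MarginalValueSurface,
    fit_expected_leverage,
    predict_marginal_value,
    uniform_surface,
)
from .world import (
    FOCAL_SPECIES,
    TrueState,
    WorldConfig,
    default_homes,
    generate_landscape,
    generate_occupancy,
    observer_site_probs,
    site_env_frame,
)

RECOVERABLE_FIT_ERRORS = (
    SeparationError,
    CollinearityError,
    NotConvergedError,
    ValueError,
    np.linalg.LinAlgError,
)


class StaleSurfaceError(RuntimeError):
    """Surface older than the recompute cadence allows."""


@dataclass
class PolicyConfig:
    """One agent population's behavior."""

    kind: str  # "guided" | "haphazard"
    softmax_temperature: float = 0.1
    distance_decay_lambda: float | None = None  # meters; default: world's value
    agent_radius: float = 2000.0  # meters; guided candidate circle
    recompute_cadence: int = 14  # days between surface refits

    def __post_init__(self):
        if self.kind not in ("guided", "haphazard"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.softmax_temperature <= 0:
            raise ValueError("softmax_temperature must be > 0")
        if self.recompute_cadence < 1:
            raise ValueError("recompute_cadence must be >= 1 day")


@dataclass
class World:
    """Config plus realized truth: landscape, occupancy, observer homes."""

    config: WorldConfig
    true_state: TrueState
    homes: np.ndarray

    @property
    def grid(self) -> SiteGrid:
        return self.config.grid


def make_world(config: WorldConfig) -> World:
    env = generate_landscape(config)
    streams = config.seed_streams()
    true_state = generate_occupancy(env, config.beta, seed_stream=streams[1])
    homes = (
        np.asarray(config.home_points, dtype=float)
        if config.home_points is not None
        else default_homes(config, np.random.default_rng(streams[3]))
    )
    return World(config=config, true_state=true_state, homes=homes)


@dataclass
class EvaluationMetrics:
    mean_nn_distance: float  # meters
    median_interval_median: float  # days
    occupancy_rmse: float

    def as_dict(self) -> dict:
        return {
            "mean_nn_distance": self.mean_nn_distance,
            "median_interval_median": self.median_interval_median,
            "occupancy_rmse": self.occupancy_rmse,
        }


@dataclass
class SimulationResult:
    history: list[BSERecord]
    surfaces: list[MarginalValueSurface]  # one per recompute, cold start included
    tracker: SiteHistoryTracker
    event_covariates: pd.DataFrame  # time-matched rows for every simulated event


def step(
    world: World,
    tracker: SiteHistoryTracker,
    surface: MarginalValueSurface,
    policy: PolicyConfig,
    day: int,
    rng: np.random.Generator,
    start_obs_index: int = 0,
) -> list[BSERecord]:
    """One simulated day: every agent makes one BSE.

    ``day`` is the day offset from the world's start date.  The surface must
    be no staler than the recompute cadence.
    """
    cfg = world.config
    grid = world.grid
    epoch = cfg.start_date.toordinal()
    if surface is not None and surface.as_of_date is not None:
        age = (epoch + day) - int(surface.as_of_date)
        if age > policy.recompute_cadence:
            raise StaleSurfaceError(
                f"surface dated ordinal day {surface.as_of_date} is {age} days old "
                f"(cadence {policy.recompute_cadence})"
            )
    centers = grid.centers()
    site_ids = grid.all_site_ids()
    date = cfg.start_date + datetime.timedelta(days=day)
    ts = pd.Timestamp(f"{date.isoformat()}T12:00:00Z")

    if policy.kind == "haphazard":
        lam = policy.distance_decay_lambda or cfg.distance_decay_lambda
        probs = observer_site_probs(grid, world.homes, lam)
    else:
        values = surface.normalized_for(site_ids)

    records = []
    for agent in range(cfg.n_observers):
        if policy.kind == "haphazard":
            site = int(rng.choice(grid.n_sites, p=probs[agent]))
        else:
            d = np.sqrt(((centers - world.homes[agent]) ** 2).sum(axis=1))
            cand = np.flatnonzero(d <= policy.agent_radius)
            if cand.size == 0:
                cand = np.array([int(np.argmin(d))])  # radius misses all centers
            v = values[cand] / policy.softmax_temperature
            w = np.exp(v - v.max())
            site = int(rng.choice(cand, p=w / w.sum()))
        jitter = rng.uniform(-0.5, 0.5, size=2) * grid.cell_size * 0.999
        x, y = centers[site] + jitter
        detected = bool(world.true_state.occupied[site]) and (
            rng.random() < cfg.detection_prob
        )
        lon, lat = grid.projection.to_lonlat(x, y)
        records.append(
            BSERecord(
                observation_id=f"sim{start_obs_index + len(records):07d}",
                lon=float(lon),
                lat=float(lat),
                timestamp=ts,
                species_code=FOCAL_SPECIES if detected else NO_DETECTION,
                observer_id=f"agent_{agent:02d}",
                site_id=site_ids[site],
            )
        )
    return records


def _refit_surface(
    world: World,
    history: list[BSERecord],
    event_cov: pd.DataFrame,
    day: int,
    tracker: SiteHistoryTracker,
) -> MarginalValueSurface:
    """Full pipeline refit; falls back to a uniform surface when the data
    cannot yet support a fit (cold start, single-class response, collinearity)."""
    site_ids = world.grid.all_site_ids()
    env = site_env_frame(world.true_state, world.grid)
    p = env.shape[1] + 1
    if len(history) < max(p + 2, 10):
        return uniform_surface(site_ids, as_of_date=day)
    try:
        design = build_design(history, env)
        model = fit_glm(design, family="binomial")
        lev = hat_values(model, design)
        value_model = fit_expected_leverage(lev, event_cov)
        site_cov = tracker.site_covariates_table(day)
        return predict_marginal_value(value_model, site_cov, as_of_date=day)
    except RECOVERABLE_FIT_ERRORS:
        return uniform_surface(site_ids, as_of_date=day)


def run_simulation(
    world: World,
    policy: PolicyConfig,
    t_days: int,
    seed: int,
    initial_history: list[BSERecord] = (),
    desired_interval: float = 14.0,
) -> SimulationResult:
    """Alternate stepping and cadence refits for ``t_days`` days.

    Deterministic given (world, policy, seed).  Every recomputed surface is
    retained for provenance.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, world.config.seed]))
    grid = world.grid
    epoch = world.config.start_date.toordinal()
    tracker = SiteHistoryTracker(grid, horizon=horizon_days(desired_interval))
    history: list[BSERecord] = []
    cov_rows: list[dict] = []
    for r in sorted(initial_history, key=lambda r: (r.day, r.observation_id)):
        _append_event(r, grid, tracker, cov_rows, epoch)
        history.append(r)

    surfaces: list[MarginalValueSurface] = []
    surface = uniform_surface(grid.all_site_ids(), as_of_date=epoch)
    surfaces.append(surface)
    for day in range(t_days):
        if day > 0 and day % policy.recompute_cadence == 0:
            surface = _refit_surface(
                world, history, pd.DataFrame(cov_rows), epoch + day, tracker
            )
            surfaces.append(surface)
        new = step(
            world, tracker, surface, policy, day, rng, start_obs_index=len(history)
        )
        # same-day events see identical (start-of-day) covariates, then post
        for r in new:
            cov = tracker.covariates_for_site(grid.site_index(r.site_id), r.day)
            cov["observation_id"] = r.observation_id
            cov["site_id"] = r.site_id
            cov["event_day"] = r.day
            cov_rows.append(cov)
        for r in new:
            tracker.add_record(r)
        history.extend(new)
    if t_days > 0 and t_days % policy.recompute_cadence == 0:
        # close the final cadence window so recomputes = floor(T / cadence)
        surfaces.append(
            _refit_surface(world, history, pd.DataFrame(cov_rows), epoch + t_days, tracker)
        )
    return SimulationResult(
        history=history,
        surfaces=surfaces,
        tracker=tracker,
        event_covariates=pd.DataFrame(cov_rows),
    )


def _append_event(record, grid, tracker, cov_rows, epoch):
    cov = tracker.covariates_for_site(grid.site_index(record.site_id), record.day)
    cov["observation_id"] = record.observation_id
    cov["site_id"] = record.site_id
    cov["event_day"] = record.day
    cov_rows.append(cov)
    tracker.add_record(record)


def evaluate(
    result: SimulationResult,
    world: World,
    span_days: int,
) -> EvaluationMetrics:
    """Coverage, regularity, and occupancy-recovery metrics for one run."""
    if not result.history:
        raise ValueError("cannot evaluate an empty history")
    tracker = result.tracker
    nn = tracker.nearest_sampled_distances()
    intervals = tracker.per_site_median_intervals(censor_at=float(span_days))
    rmse = occupancy_rmse(result.history, world)
    return EvaluationMetrics(
        mean_nn_distance=float(nn.mean()),
        median_interval_median=float(np.median(intervals)),
        occupancy_rmse=rmse,
    )


def occupancy_rmse(history: list[BSERecord], world: World) -> float:
    """RMSE of refitted vs true occupancy probabilities over all sites.

    A fresh binomial GLM is fit to the final history; its fitted recording
    probability is divided by the (known) detection probability to land on
    the occupancy scale before comparison.  NaN when the fit is impossible.
    """
    env = site_env_frame(world.true_state, world.grid)
    try:
        design = build_design(history, env)
        model = fit_glm(design, family="binomial")
    except RECOVERABLE_FIT_ERRORS:
        return float("nan")
    p_hat = model.predict_prob(env.reset_index())
    d = world.config.detection_prob
    psi_hat = np.clip(p_hat / d, 0.0, 1.0) if d > 0 else p_hat
    return float(np.sqrt(np.mean((psi_hat - world.true_state.occupancy_prob) ** 2)))


def compare_policies(
    world_config_factory,
    policies: dict[str, PolicyConfig],
    t_days: int,
    n_replicates: int,
    base_seed: int = 1,
) -> pd.DataFrame:
    """Paired policy comparison at equal effort.

    ``world_config_factory(seed)`` builds the per-replicate world config; each
    replicate draws a fresh world, and every policy runs on that same world
    with the same run seed (pairing).  Raises on any effort mismatch.

    Returns one row per (replicate, policy) with the evaluation metrics.
    """
    rows = []
    for rep in range(n_replicates):
        world_seed = (base_seed * 1_000_003 + rep) % (2**31 - 1)
        world = make_world(world_config_factory(world_seed))
        run_seed = (base_seed * 7_777_777 + rep) % (2**31 - 1)
        counts = {}
        for name, policy in policies.items():
            result = run_simulation(world, policy, t_days, seed=run_seed)
            counts[name] = len(result.history)
            metrics = evaluate(result, world, span_days=t_days)
            rows.append({"replicate": rep, "policy": name, **metrics.as_dict()})
        if len(set(counts.values())) > 1:
            raise ValueError(f"unequal effort across arms in replicate {rep}: {counts}")
    return pd.DataFrame(rows)


def paired_wins(report: pd.DataFrame, metric: str, a: str, b: str) -> float:
    """Fraction of replicates in which policy ``a`` beats ``b`` (strictly
    lower metric — all metrics are lower-is-better)."""
    pa = report[report["policy"] == a].set_index("replicate")[metric]
    pb = report[report["policy"] == b].set_index("replicate")[metric]
    return float((pa < pb.loc[pa.index]).mean())


def default_world_config(seed: int, grid: SiteGrid | None = None) -> WorldConfig:
    """The package's reference study conditions: a 30x30 grid of 100 m cells,
    two smooth environmental covariates with logit effects (0, 1, -0.75),
    detection probability 0.6, and 12 home-biased observers (lambda = 100 m,
    one cell — strong convenience bias)."""
    grid = grid or SiteGrid(origin_x=0.0, origin_y=0.0, cell_size=100.0, n_x=30, n_y=30)
    return WorldConfig(grid=grid, seed=seed)
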