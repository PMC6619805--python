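"""Synthetic citizen-science world: landscape, occupancy, and haphazard effort.

Emulates the statistical structure of semistructured citizen-science data
streams: smooth environmental covariates over a grid, logistic occupancy of a
focal species, imperfect detection, and observers whose site choice decays
exponentially with distance from home — the "convenience sampling" bias that
makes raw effort spatially patchy.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
stream splitting: child 0 drives the landscape, child 1 the occupancy draw,
child 2 the BSE history, so each stage is reproducible in isolation.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from scipy.special import expit

from .grid import SiteGrid
from .io import NO_DETECTION, BSERecord

FOCAL_SPECIES = "SP1"


@dataclass
class WorldConfig:
    """Study conditions for one synthetic world.

    ``beta`` is on the logit scale: intercept followed by one coefficient per
    environmental covariate.  ``distance_decay_lambda`` (meters) is the scale
    of the exponential site-choice kernel exp(-d/lambda): small lambda means
    strongly home-biased, convenience-style sampling.
    """

    grid: SiteGrid
    n_env_covariates: int = 2
    beta: tuple[float, ...] = (0.0, 1.0, -0.75)
    detection_prob: float = 0.6
    n_observers: int = 12
    home_points: np.ndarray | None = None  # (n_observers, 2) in grid meters
    distance_decay_lambda: float = 100.0
    n_days: int = 200
    events_per_day: int = 12
    seed: int = 0
    start_date: datetime.date = field(default_factory=lambda: datetime.date(2024, 1, 1))

    def __post_init__(self):
        if self.n_env_covariates < 1:
            raise ValueError("need at least one environmental covariate")
        if len(self.beta) != self.n_env_covariates + 1:
            raise ValueError(
                f"beta has {len(self.beta)} entries; expected "
                f"{self.n_env_covariates + 1} (intercept + one per covariate)"
            )
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be a probability")
        if self.n_observers < 1 or self.n_days < 1 or self.events_per_day < 0:
            raise ValueError("n_observers >= 1, n_days >= 1, events_per_day >= 0 required")
        if self.distance_decay_lambda <= 0:
            raise ValueError("distance_decay_lambda must be > 0 meters")

    def seed_streams(self) -> list[np.random.SeedSequence]:
        return np.random.SeedSequence(self.seed).spawn(4)


@dataclass
class TrueState:
    """Ground truth against which parameter recovery is scored."""

    env: np.ndarray  # (n_sites, k) standardized covariates, canonical site order
    occupancy_prob: np.ndarray  # (n_sites,)
    occupied: np.ndarray  # (n_sites,) bool


def generate_landscape(config: WorldConfig) -> np.ndarray:
    """Per-site environmental covariates: linear gradient + smoothed noise.

    Each covariate is the standardized (mean 0, sd 1 across sites) sum of a
    fixed linear gradient (direction deterministic per covariate index) and a
    3x3 moving-average of i.i.d. Gaussian noise — cheap spatial
    autocorrelation.  Deterministic given the config seed.
    """
    grid = config.grid
    if grid.n_sites < 2:
        raise ValueError("landscape generation needs a grid with more than one cell")
    rng = np.random.default_rng(config.seed_streams()[0])
    ys, xs = np.mgrid[0 : grid.n_y, 0 : grid.n_x]
    xs = xs / max(grid.n_x - 1, 1)
    ys = ys / max(grid.n_y - 1, 1)
    fields = []
    for j in range(config.n_env_covariates):
        theta = j * np.deg2rad(137.5)  # deterministic spread of gradient directions
        gradient = np.cos(theta) * xs + np.sin(theta) * ys
        noise = uniform_filter(rng.standard_normal((grid.n_y, grid.n_x)), size=3, mode="nearest")
        combined = _standardize(gradient) + _standardize(noise)
        fields.append(_standardize(combined).ravel())
    return np.column_stack(fields)


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    if sd == 0:
        return a - a.mean()
    return (a - a.mean()) / sd


def generate_occupancy(
    env: np.ndarray, beta: tuple[float, ...], seed_stream=None
) -> TrueState:
    """Logistic occupancy: psi = expit([1, env] @ beta); occupied ~ Bernoulli(psi)."""
    env = np.asarray(env, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if env.shape[1] + 1 != beta.size:
        raise ValueError(
            f"dimension mismatch: {env.shape[1]} covariates but {beta.size} coefficients"
        )
    design = np.column_stack([np.ones(env.shape[0]), env])
    psi = expit(design @ beta)
    rng = np.random.default_rng(seed_stream)
    occupied = rng.random(env.shape[0]) < psi
    return TrueState(env=env, occupancy_prob=psi, occupied=occupied)


def observer_site_probs(grid: SiteGrid, homes: np.ndarray, decay_lambda: float) -> np.ndarray:
    """(n_observers, n_sites) site-choice probabilities, exp(-d/lambda) kernel."""
    centers = grid.centers()
    d = np.sqrt(((homes[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
    w = np.exp(-d / decay_lambda)
    return w / w.sum(axis=1, keepdims=True)


def default_homes(config: WorldConfig, rng: np.random.Generator) -> np.ndarray:
    xmin, ymin, xmax, ymax = config.grid.extent
    return np.column_stack(
        [
            rng.uniform(xmin, xmax, config.n_observers),
            rng.uniform(ymin, ymax, config.n_observers),
        ]
    )


def simulate_bse_history(config: WorldConfig, true_state: TrueState) -> list[BSERecord]:
    """Haphazard BSE history: ``n_days * events_per_day`` events.

    Each event: an observer chosen uniformly, a site chosen with probability
    proportional to exp(-d(home, site)/lambda), a point jittered uniformly
    within the cell, and the focal species recorded iff the site is occupied
    and a Bernoulli(detection_prob) draw succeeds; otherwise the event is an
    all-zero checklist row (species ``NONE``).
    """
    grid = config.grid
    streams = config.seed_streams()
    rng = np.random.default_rng(streams[2])
    homes = (
        np.asarray(config.home_points, dtype=float)
        if config.home_points is not None
        else default_homes(config, np.random.default_rng(streams[3]))
    )
    if homes.shape != (config.n_observers, 2):
        raise ValueError("home_points must be (n_observers, 2)")
    probs = observer_site_probs(grid, homes, config.distance_decay_lambda)
    centers = grid.centers()
    site_ids = grid.all_site_ids()

    records: list[BSERecord] = []
    counter = 0
    for day in range(config.n_days):
        date = config.start_date + datetime.timedelta(days=day)
        ts = pd.Timestamp(f"{date.isoformat()}T12:00:00Z")
        for _ in range(config.events_per_day):
            obs = int(rng.integers(config.n_observers))
            site = int(rng.choice(grid.n_sites, p=probs[obs]))
            jitter = rng.uniform(-0.5, 0.5, size=2) * grid.cell_size * 0.999
            x, y = centers[site] + jitter
            detected = bool(true_state.occupied[site]) and (
                rng.random() < config.detection_prob
            )
            lon, lat = grid.projection.to_lonlat(x, y)
            records.append(
                BSERecord(
                    observation_id=f"obs{counter:07d}",
                    lon=float(lon),
                    lat=float(lat),
                    timestamp=ts,
                    species_code=FOCAL_SPECIES if detected else NO_DETECTION,
                    observer_id=f"observer_{obs:02d}",
                    site_id=site_ids[site],
                )
            )
            counter += 1
    return records


def truth_frame(true_state: TrueState, grid: SiteGrid) -> pd.DataFrame:
    """Truth surface as a tidy frame (site_id, env_*, occupancy_prob, occupied)."""
    data = {"site_id": grid.all_site_ids()}
    for j in range(true_state.env.shape[1]):
        data[f"env_{j}"] = true_state.env[:, j]
    data["occupancy_prob"] = true_state.occupancy_prob
    data["occupied"] = true_state.occupied.astype(int)
    return pd.DataFrame(data)


def site_env_frame(true_state: TrueState, grid: SiteGrid) -> pd.DataFrame:
    """Environmental covariates indexed by site_id (the SDM design inputs)."""
    frame = pd.DataFrame(
        true_state.env,
        index=pd.Index(grid.all_site_ids(), name="site_id"),
        columns=[f"env_{j}" for j in range(true_state.env.shape[1])],
    )
    return frame
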