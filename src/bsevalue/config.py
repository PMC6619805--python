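"""Run configuration: a single YAML document validated on load.

Unknown keys are rejected (typos should fail loudly, not silently fall back
to defaults).  The full schema:

.. code-block:: yaml

    seed: 1
    grid:
      n_x: 30           # cells
      n_y: 30
      cell_size: 100.0  # meters
      origin_x: 0.0
      origin_y: 0.0
      lon0: 151.0       # projection anchor (degrees)
      lat0: -33.8
    world:
      n_env_covariates: 2
      beta: [0.0, 1.0, -0.75]   # logit occupancy: intercept + per covariate
      detection_prob: 0.6
      n_observers: 12
      distance_decay_lambda: 100.0   # meters
      n_days: 200
      events_per_day: 12
    model:
      family: binomial       # target detection model
    value:
      desired_interval: 14   # days; censoring horizon H = 2x this
      transforms: {}         # per-covariate overrides: log1p | identity
    points:
      p_max: 100.0
      kind: proportional     # or rank_linear
    policy:
      kind: guided           # or haphazard
      softmax_temperature: 0.1
      agent_radius: 2000.0   # meters
      recompute_cadence: 14  # days
    t_days: 200
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .grid import EquirectangularProjection, SiteGrid
from .incentives import PointsScheme
from .dynamics import PolicyConfig
from .world import WorldConfig


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


_SECTIONS = {"seed", "grid", "world", "model", "value", "points", "policy", "t_days"}
_GRID_KEYS = {"n_x", "n_y", "cell_size", "origin_x", "origin_y", "lon0", "lat0"}
_WORLD_KEYS = {
    "n_env_covariates",
    "beta",
    "detection_prob",
    "n_observers",
    "distance_decay_lambda",
    "n_days",
    "events_per_day",
}
_MODEL_KEYS = {"family"}
_VALUE_KEYS = {"desired_interval", "transforms"}
_POINTS_KEYS = {"p_max", "kind"}
_POLICY_KEYS = {"kind", "softmax_temperature", "agent_radius", "recompute_cadence", "distance_decay_lambda"}


@dataclass
class RunConfig:
    seed: int
    grid: SiteGrid
    world: WorldConfig
    family: str
    desired_interval: float
    transforms: dict
    points: PointsScheme
    policy: PolicyConfig
    t_days: int
    raw: dict = field(default_factory=dict, repr=False)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:8]


def _check_keys(section: str, mapping: dict, allowed: set[str]) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in '{section}': {sorted(unknown)} (allowed: {sorted(allowed)})"
        )


def load_config(path: str | Path) -> RunConfig:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("config must be a mapping")
    _check_keys("top level", doc, _SECTIONS)

    g = dict(doc.get("grid", {}))
    _check_keys("grid", g, _GRID_KEYS)
    try:
        grid = SiteGrid(
            origin_x=float(g.get("origin_x", 0.0)),
            origin_y=float(g.get("origin_y", 0.0)),
            cell_size=float(g.get("cell_size", 100.0)),
            n_x=int(g.get("n_x", 30)),
            n_y=int(g.get("n_y", 30)),
            projection=EquirectangularProjection(
                lon0=float(g.get("lon0", 151.0)), lat0=float(g.get("lat0", -33.8))
            ),
        )
    except ValueError as exc:
        raise ConfigError(f"grid: {exc}") from exc

    seed = int(doc.get("seed", 0))
    w = dict(doc.get("world", {}))
    _check_keys("world", w, _WORLD_KEYS)
    try:
        world = WorldConfig(
            grid=grid,
            n_env_covariates=int(w.get("n_env_covariates", 2)),
            beta=tuple(float(b) for b in w.get("beta", (0.0, 1.0, -0.75))),
            detection_prob=float(w.get("detection_prob", 0.6)),
            n_observers=int(w.get("n_observers", 12)),
            distance_decay_lambda=float(w.get("distance_decay_lambda", 100.0)),
            n_days=int(w.get("n_days", 200)),
            events_per_day=int(w.get("events_per_day", 12)),
            seed=seed,
        )
    except ValueError as exc:
        raise ConfigError(f"world: {exc}") from exc

    m = dict(doc.get("model", {}))
    _check_keys("model", m, _MODEL_KEYS)
    family = str(m.get("family", "binomial"))
    if family not in ("binomial", "gaussian"):
        raise ConfigError(f"model.family: unknown family {family!r}")

    v = dict(doc.get("value", {}))
    _check_keys("value", v, _VALUE_KEYS)
    transforms = dict(v.get("transforms", {}) or {})
    for key, name in transforms.items():
        if name not in ("log1p", "identity"):
            raise ConfigError(f"value.transforms.{key}: unknown transform {name!r}")

    p = dict(doc.get("points", {}))
    _check_keys("points", p, _POINTS_KEYS)
    try:
        points = PointsScheme(
            p_max=float(p.get("p_max", 100.0)), kind=str(p.get("kind", "proportional"))
        )
    except ValueError as exc:
        raise ConfigError(f"points: {exc}") from exc

    pol = dict(doc.get("policy", {}))
    _check_keys("policy", pol, _POLICY_KEYS)
    try:
        policy = PolicyConfig(
            kind=str(pol.get("kind", "guided")),
            softmax_temperature=float(pol.get("softmax_temperature", 0.1)),
            distance_decay_lambda=(
                float(pol["distance_decay_lambda"])
                if pol.get("distance_decay_lambda") is not None
                else None
            ),
            agent_radius=float(pol.get("agent_radius", 2000.0)),
            recompute_cadence=int(pol.get("recompute_cadence", 14)),
        )
    except ValueError as exc:
        raise ConfigError(f"policy: {exc}") from exc

    return RunConfig(
        seed=seed,
        grid=grid,
        world=world,
        family=family,
        desired_interval=float(v.get("desired_interval", 14)),
        transforms=transforms,
        points=points,
        policy=policy,
        t_days=int(doc.get("t_days", 200)),
        raw=doc,
    )
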