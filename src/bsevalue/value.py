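"""Expected leverage: regress historical hat values on site covariates and
forecast the marginal value of a future BSE at every candidate site.

The marginal value of one more BSE cannot be known before the observation is
made, but its *expected leverage* can be forecast: regress the leverages of
past events on the forward-looking covariates their sites had at the time
(time-matched rows), then evaluate that regression at each candidate site's
current covariates.  Raw predictions are min–max normalized over the
candidate set and ranked descending (ties broken by ascending site id).

Distance and the three day-scale covariates enter through a log1p transform —
leverage–distance relationships saturate — while the 0/1 ``sampled`` flag
enters raw.  The transform specification is stored on the model and is
swappable per covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .covariates import COVARIATE_COLUMNS
from .leverage import LeverageTable

TRANSFORMS = {
    "log1p": np.log1p,
    "identity": lambda a: a,
}

DEFAULT_TRANSFORM_SPEC = {
    "sampled": "identity",
    "dist_nearest_sampled": "log1p",
    "median_interval": "log1p",
    "neighbor_median_interval": "log1p",
    "days_since_last": "log1p",
}


class UnderdeterminedError(ValueError):
    """Fewer regression rows than coefficients."""


def transform_covariates(
    covariates: pd.DataFrame, transform_spec: dict[str, str]
) -> np.ndarray:
    """Apply the per-covariate transforms, canonical column order."""
    cols = []
    for name in COVARIATE_COLUMNS:
        fn = TRANSFORMS[transform_spec.get(name, "identity")]
        cols.append(fn(covariates[name].to_numpy(dtype=float)))
    return np.column_stack(cols)


@dataclass
class ExpectedLeverageModel:
    """OLS of leverage on transformed site covariates."""

    coefficients: np.ndarray  # intercept + one per covariate, canonical order
    transform_spec: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TRANSFORM_SPEC)
    )
    r_squared: float = float("nan")
    n_obs: int = 0

    def linear_predictor(
        self, covariates: pd.DataFrame, weights: np.ndarray | None = None
    ) -> np.ndarray:
        """Evaluate the regression; optional per-covariate multipliers let a
        project re-weight the formula toward its own goals (default 1)."""
        Z = transform_covariates(covariates, self.transform_spec)
        coef = np.asarray(self.coefficients, dtype=float)
        slopes = coef[1:]
        if weights is not None:
            slopes = slopes * np.asarray(weights, dtype=float)
        return coef[0] + Z @ slopes


@dataclass
class MarginalValueSurface:
    """Per-site expected-leverage forecast at one date."""

    as_of_date: object
    frame: pd.DataFrame  # columns: site_id, raw_value, normalized_value, rank

    def __post_init__(self):
        self._by_site = self.frame.set_index("site_id")

    def normalized_value(self, site_id: str) -> float:
        try:
            return float(self._by_site.at[site_id, "normalized_value"])
        except KeyError:
            raise KeyError(f"site {site_id!r} absent from surface (surface stale?)")

    def normalized_for(self, site_ids) -> np.ndarray:
        return self._by_site.loc[list(site_ids), "normalized_value"].to_numpy(dtype=float)


def fit_expected_leverage(
    leverage: LeverageTable,
    covariates: pd.DataFrame,
    transform_spec: dict[str, str] | None = None,
) -> ExpectedLeverageModel:
    """OLS of hat values on transformed, time-matched event covariates.

    ``covariates`` must carry one row per leverage row (joined on
    observation_id) holding each site's covariates as of its own event date.
    """
    spec = dict(transform_spec or DEFAULT_TRANSFORM_SPEC)
    merged = leverage.frame.merge(covariates, on="observation_id", how="inner")
    if len(merged) != len(leverage.frame):
        raise ValueError("leverage rows without matching covariate rows")
    Z = transform_covariates(merged, spec)
    X = np.column_stack([np.ones(len(merged)), Z])
    if X.shape[0] < X.shape[1]:
        raise UnderdeterminedError(
            f"{X.shape[0]} rows cannot identify {X.shape[1]} coefficients"
        )
    res = sm.OLS(merged["h"].to_numpy(dtype=float), X).fit()
    return ExpectedLeverageModel(
        coefficients=np.asarray(res.params),
        transform_spec=spec,
        r_squared=float(res.rsquared),
        n_obs=int(res.nobs),
    )


def normalize_and_rank(site_ids, raw: np.ndarray) -> pd.DataFrame:
    """Min–max normalize and rank descending; ties by ascending site id.

    Degenerate case (all raw values equal): there is no information to rank
    on, so every site gets normalized value 0.5 — the midpoint avoids
    manufacturing fake extremes.
    """
    site_ids = list(site_ids)
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi - lo < 1e-12:
        normalized = np.full(raw.shape, 0.5)
    else:
        normalized = (raw - lo) / (hi - lo)
    order = sorted(range(len(site_ids)), key=lambda i: (-raw[i], site_ids[i]))
    rank = np.empty(len(site_ids), dtype=int)
    for pos, i in enumerate(order, start=1):
        rank[i] = pos
    return pd.DataFrame(
        {
            "site_id": site_ids,
            "raw_value": raw,
            "normalized_value": normalized,
            "rank": rank,
        }
    )


def predict_marginal_value(
    model: ExpectedLeverageModel,
    covariates: pd.DataFrame,
    as_of_date=None,
    weights: np.ndarray | None = None,
) -> MarginalValueSurface:
    """Forecast the marginal-value surface over a candidate covariate table."""
    if covariates.empty:
        raise ValueError("empty candidate set")
    raw = model.linear_predictor(covariates, weights=weights)
    frame = normalize_and_rank(covariates["site_id"], raw)
    if as_of_date is None and "as_of_day" in covariates.columns:
        as_of_date = covariates["as_of_day"].iloc[0]
    return MarginalValueSurface(as_of_date=as_of_date, frame=frame)


def uniform_surface(site_ids, as_of_date=None) -> MarginalValueSurface:
    """Cold-start surface: no model yet, every site equally valuable (0.5)."""
    site_ids = list(site_ids)
    if not site_ids:
        raise ValueError("empty candidate set")
    frame = normalize_and_rank(site_ids, np.zeros(len(site_ids)))
    return MarginalValueSurface(as_of_date=as_of_date, frame=frame)
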