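"""Target-model fitting and per-BSE leverage (hat values).

The statistical goal of a monitoring project defines a target model; given
that model fitted to the accumulated BSEs, each event's contribution is
measured by its *leverage* — the diagonal of the hat (projection) matrix.
For a Gaussian fit this is diag(X (X'X)^-1 X'); for a binomial-logit GLM it
is the standard weighted form diag(W^1/2 X (X'WX)^-1 X' W^1/2) with W the
IRLS weights at convergence.  Hat values are computed here from the reduced
QR of the (weighted) design, which gives the diagonal without forming the
full n x n hat matrix.

Leverage identities (0 <= h_i <= 1, sum h_i = p) hold exactly only for
unpenalized fits, so no regularization is offered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import BSERecord


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


class SeparationError(RuntimeError):
    """Binomial response is degenerate or (quasi-)separated."""


class NotConvergedError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


@dataclass
class DesignMatrix:
    """Fitting-ready design: intercept first, then standardized covariates."""

    X: np.ndarray  # (n, p)
    y: np.ndarray  # (n,) response (0/1 detection, or continuous)
    row_ids: list[str]  # observation ids, aligned with rows
    columns: list[str]  # column names, columns[0] == "intercept"
    center: np.ndarray  # training means of raw covariates (len p-1)
    scale: np.ndarray  # training sds of raw covariates (len p-1)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class FittedModel:
    family: str  # "gaussian" | "binomial"
    coefficients: np.ndarray
    irls_weights: np.ndarray  # per-row final weights; ones for gaussian
    converged: bool
    n_iter: int
    columns: list[str]
    center: np.ndarray
    scale: np.ndarray

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        """Evaluate eta on new rows using the training standardization."""
        raw = covariates[self.columns[1:]].to_numpy(dtype=float)
        Z = (raw - self.center) / self.scale
        X = np.column_stack([np.ones(len(Z)), Z])
        return X @ self.coefficients

    def predict_prob(self, covariates: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit

        eta = self.linear_predictor(covariates)
        return expit(eta) if self.family == "binomial" else eta


@dataclass
class LeverageTable:
    """Per-BSE hat values plus a fingerprint of the generating fit."""

    frame: pd.DataFrame  # columns: observation_id, h
    family: str
    p: int
    n: int

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def h(self) -> np.ndarray:
        return self.frame["h"].to_numpy()


def build_design(
    records: list[BSERecord],
    site_covariates: pd.DataFrame,
    covariate_names: list[str] | None = None,
) -> DesignMatrix:
    """Assemble the detection design from records and per-site covariates.

    ``site_covariates`` is indexed by site_id.  The response is the 0/1
    detection flag of each record.  Covariates are standardized with
    training-set statistics that are stored on the design (and carried onto
    the fitted model) so candidate-site prediction reuses identical scaling.
    """
    if not records:
        raise ValueError("cannot build a design from zero records")
    names = covariate_names or list(site_covariates.columns)
    missing = [r.site_id for r in records if r.site_id not in site_covariates.index]
    if missing:
        raise KeyError(f"records reference sites without covariates, e.g. {missing[0]!r}")
    raw = site_covariates.loc[[r.site_id for r in records], names].to_numpy(dtype=float)
    center = raw.mean(axis=0)
    scale = raw.std(axis=0)
    degenerate = scale == 0
    if degenerate.any():
        bad = [n for n, d in zip(names, degenerate) if d]
        raise CollinearityError(f"constant covariate column(s): {bad}")
    Z = (raw - center) / scale
    X = np.column_stack([np.ones(len(records)), Z])
    if X.shape[0] <= X.shape[1]:
        raise ValueError(f"need more rows ({X.shape[0]}) than columns ({X.shape[1]})")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns from the QR diagonal
        _, R = np.linalg.qr(X)
        small = np.abs(np.diag(R)) < 1e-10 * np.abs(np.diag(R)).max()
        bad = [(["intercept"] + names)[i] for i in np.flatnonzero(small)]
        raise CollinearityError(f"design is rank deficient; collinear column(s): {bad}")
    y = np.array([1.0 if r.detected() else 0.0 for r in records])
    return DesignMatrix(
        X=X,
        y=y,
        row_ids=[r.observation_id for r in records],
        columns=["intercept"] + names,
        center=center,
        scale=scale,
    )


def fit_glm(design: DesignMatrix, family: str = "binomial") -> FittedModel:
    """Fit the target model.

    Gaussian: closed-form least squares.  Binomial: logistic IRLS (relative
    coefficient change < 1e-8, max 50 iterations) via statsmodels; degenerate
    or separated responses raise :class:`SeparationError`, non-convergence
    raises :class:`NotConvergedError`.
    """
    if family == "gaussian":
        coef, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
        return FittedModel(
            family="gaussian",
            coefficients=coef,
            irls_weights=np.ones(design.n),
            converged=True,
            n_iter=1,
            columns=design.columns,
            center=design.center,
            scale=design.scale,
        )
    if family != "binomial":
        raise ValueError(f"unknown family {family!r}")
    y = design.y
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("binomial response must be 0/1")
    if y.min() == y.max():
        raise SeparationError(
            f"degenerate binomial response: all rows are {int(y[0])}"
        )
    model = sm.GLM(y, design.X, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            # separation surfaces as a hard error below, not a warning
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=50, tol=1e-8)
    except Exception as exc:  # statsmodels raises PerfectSeparationError and friends
        raise SeparationError(f"binomial fit failed: {exc}") from exc
    if not res.converged:
        raise NotConvergedError("IRLS did not converge in 50 iterations")
    eta = design.X @ res.params
    if np.abs(eta).max() > 30 or not np.all(np.isfinite(res.params)):
        raise SeparationError(
            "fitted probabilities numerically 0/1: response is (quasi-)separated"
        )
    mu = res.fittedvalues
    return FittedModel(
        family="binomial",
        coefficients=np.asarray(res.params),
        irls_weights=mu * (1.0 - mu),
        converged=True,
        n_iter=int(res.fit_history.get("iteration", len(res.fit_history.get("deviance", [])))),
        columns=design.columns,
        center=design.center,
        scale=design.scale,
    )


def hat_values(model: FittedModel, design: DesignMatrix) -> LeverageTable:
    """Per-row hat values from the reduced QR of the weighted design."""
    if not model.converged:
        raise ValueError("leverage requires a converged model")
    w = model.irls_weights
    Xw = np.sqrt(w)[:, None] * design.X
    Q, R = np.linalg.qr(Xw)
    if np.abs(np.diag(R)).min() < 1e-12 * np.abs(np.diag(R)).max():
        raise np.linalg.LinAlgError("singular weighted cross-product in hat computation")
    h = np.einsum("ij,ij->i", Q, Q)
    total = h.sum()
    if abs(total - design.p) > 1e-8:
        raise AssertionError(
            f"hat-value trace {total} deviates from column count {design.p}"
        )
    frame = pd.DataFrame({"observation_id": design.row_ids, "h": h})
    return LeverageTable(frame=frame, family=model.family, p=design.p, n=design.n)


def hat_diagonal_bruteforce(X: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Explicit full hat matrix diagonal — the slow oracle for testing."""
    if w is None:
        w = np.ones(X.shape[0])
    Xw = np.sqrt(w)[:, None] * X
    H = Xw @ np.linalg.inv(Xw.T @ Xw) @ Xw.T
    return np.diag(H).copy()
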