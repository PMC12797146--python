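"""Two-stage polynomial baseline normative model.

A covariate-only reference model in the spirit of regression-based normative
modelling: stage one fits an ordinary least-squares polynomial mean per
feature on the standardised scale (polynomial in standardised age, linear in
the remaining covariates); stage two takes the RMSE of the stage-one
residuals as a constant per-feature residual SD. Together these give a
Gaussian predictive distribution from covariates alone, so the full
evaluation battery (metrics, calibration, deviations) runs unchanged on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import (
    CohortTable,
    StandardisationState,
    fit_standardisation,
    standardise,
)
from .inference import PredictiveDistribution

__all__ = ["TwoStageBaseline", "fit_baseline", "predict_baseline"]


def _design(Xstd: np.ndarray, age_degree: int) -> np.ndarray:
    age = Xstd[:, 0]
    cols = [np.ones(len(Xstd))]
    cols += [age**d for d in range(1, age_degree + 1)]
    cols += [Xstd[:, j] for j in range(1, Xstd.shape[1])]
    return np.column_stack(cols)


def _design_names(age_degree: int, covariate_names) -> list[str]:
    names = ["intercept"] + [f"age^{d}" for d in range(1, age_degree + 1)]
    names += list(covariate_names[1:])
    return names


@dataclass
class TwoStageBaseline:
    """Fitted per-feature polynomial mean + constant residual SD."""

    coefficients: np.ndarray  # design columns x F
    residual_sd: np.ndarray  # F
    age_degree: int
    standardisation: StandardisationState
    feature_names: list[str]

    @property
    def label(self) -> str:
        return f"two_stage_poly(deg={self.age_degree})"


def fit_baseline(
    train: CohortTable, age_degree: int = 2, wmh_offset: float = 1.0
) -> TwoStageBaseline:
    """Least-squares mean fit per feature; residual RMSE as the SD estimate."""
    state = fit_standardisation(train, wmh_offset=wmh_offset)
    Ystd, Xstd = standardise(state, train)
    D = _design(Xstd, age_degree)
    if train.n_subjects <= D.shape[1]:
        raise ValueError(
            f"need more subjects ({train.n_subjects}) than design columns "
            f"({D.shape[1]})"
        )
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        names = _design_names(age_degree, state_cov_names())
        # identify columns whose removal restores full column rank
        collinear = [
            names[j]
            for j in range(D.shape[1])
            if np.linalg.matrix_rank(np.delete(D, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear column(s): {collinear}")
    coef, *_ = np.linalg.lstsq(D, Ystd, rcond=None)
    resid = Ystd - D @ coef
    sd = np.sqrt(np.mean(np.square(resid), axis=0))
    if np.any(sd <= 0):
        bad = [train.feature_names[j] for j in np.flatnonzero(sd <= 0)]
        raise ValueError(f"zero residual SD for feature(s) {bad}")
    return TwoStageBaseline(
        coefficients=coef,
        residual_sd=sd,
        age_degree=age_degree,
        standardisation=state,
        feature_names=train.feature_names,
    )


def state_cov_names():
    from .cohort import COVARIATE_COLUMNS

    return list(COVARIATE_COLUMNS)


def predict_baseline(
    model: TwoStageBaseline, Xstd: np.ndarray
) -> PredictiveDistribution:
    """Gaussian predictive distribution from standardised covariates only."""
    Xstd = np.atleast_2d(np.asarray(Xstd, dtype=float))
    if Xstd.shape[1] != len(state_cov_names()):
        raise ValueError("covariate matrix has wrong width")
    D = _design(Xstd, model.age_degree)
    if D.shape[1] != model.coefficients.shape[0]:
        raise ValueError("design width does not match fitted coefficients")
    mu = D @ model.coefficients
    sd = np.broadcast_to(model.residual_sd, mu.shape).copy()
    return PredictiveDistribution(
        mu=mu,
        sd=sd,
        within_var=np.square(sd),
        between_var=np.zeros_like(sd),
        n_draws=0,
        mode="baseline",
    )
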