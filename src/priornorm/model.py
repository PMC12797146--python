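"""Model/Results facade over the cVAE and baseline normative models.

Follows the familiar two-object pattern of statistical modelling libraries:
a model object is constructed from a cohort, ``fit()`` returns a results
object that carries the fitted state and exposes prediction, deviation
scoring, evaluation and a text ``summary()``.

    >>> spec = GeneratorSpec(n_subjects=2000, seed=1)
    >>> train, _ = simulate_cohort(spec, normotensive_only=True)
    >>> res = CVAENormative(train, CVAEConfig(latent_dim=8, hidden_dim=64)).fit()
    >>> dist = res.predict(holdout, mode="prior", K=1000, seed=3)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .baseline import TwoStageBaseline, fit_baseline, predict_baseline
from .cohort import CohortTable, StandardisationState, standardise, standardise_covariates
from .cvae import CVAEConfig, TrainedCVAE, train_cvae
from .inference import (
    EXTREME_Z_THRESHOLD,
    DeviationMatrix,
    PredictiveDistribution,
    deviation_scores,
    posterior_predict,
    prior_predict,
)
from .metrics import metric_table

__all__ = [
    "NormativeResults",
    "CVAENormative",
    "CVAENormativeResults",
    "TwoStageBaselineModel",
    "BaselineResults",
]


class NormativeResults:
    """Shared results behaviour: predict from covariates, score deviations.

    Subclasses implement ``_predict_dist`` and ``label``; every conforming
    results object predicts from covariates only in its default mode, which
    is what makes it a normative model.
    """

    standardisation: StandardisationState
    feature_names: list[str]

    @property
    def label(self) -> str:  # pragma: no cover - overridden
        raise NotImplementedError

    def _predict_dist(self, Ystd, Xstd, mode, K, seed) -> PredictiveDistribution:
        raise NotImplementedError

    def _standardised(self, cohort: CohortTable):
        return standardise(self.standardisation, cohort)

    def predict(
        self,
        cohort: CohortTable | None = None,
        X: np.ndarray | None = None,
        mode: str = "prior",
        K: int = 1000,
        seed: int = 0,
    ) -> PredictiveDistribution:
        """Predictive distribution for a cohort (or raw covariate matrix)."""
        if cohort is not None:
            Ystd, Xstd = self._standardised(cohort)
        elif X is not None:
            if mode == "posterior":
                raise ValueError("posterior mode needs observed features (a cohort)")
            Ystd, Xstd = None, standardise_covariates(self.standardisation, X)
        else:
            raise ValueError("provide a cohort or a covariate matrix")
        return self._predict_dist(Ystd, Xstd, mode, K, seed)

    def deviations(
        self,
        cohort: CohortTable,
        mode: str = "prior",
        K: int = 1000,
        seed: int = 0,
        threshold: float = EXTREME_Z_THRESHOLD,
    ) -> DeviationMatrix:
        """Deviation z-scores of a cohort against this normative model."""
        Ystd, _ = self._standardised(cohort)
        dist = self.predict(cohort, mode=mode, K=K, seed=seed)
        return deviation_scores(dist, Ystd, threshold=threshold)

    def evaluate(
        self,
        cohort: CohortTable,
        mode: str = "prior",
        K: int = 1000,
        seed: int = 0,
    ) -> pd.DataFrame:
        """Per-feature accuracy metrics on the standardised scale."""
        Ystd, _ = self._standardised(cohort)
        dist = self.predict(cohort, mode=mode, K=K, seed=seed)
        return metric_table(Ystd, dist.mu, self.feature_names, model=self.label)


@dataclass
class CVAENormative:
    """Prior-sampling cVAE normative model of a training cohort."""

    cohort: CohortTable
    config: CVAEConfig | None = None
    wmh_offset: float = 1.0

    def fit(self, seed: int | None = None, verbose: bool = False
            ) -> "CVAENormativeResults":
        cfg = self.config or CVAEConfig(n_features=self.cohort.n_features)
        if seed is not None:
            cfg = CVAEConfig(**{**cfg.to_dict(), "seed": seed})
        trained = train_cvae(
            self.cohort, cfg, wmh_offset=self.wmh_offset, verbose=verbose
        )
        return CVAENormativeResults(trained, self.cohort.feature_names)


class CVAENormativeResults(NormativeResults):
    """Fitted cVAE with prior- and posterior-sampling prediction."""

    def __init__(self, trained: TrainedCVAE, feature_names: list[str]):
        self.trained = trained
        self.standardisation = trained.standardisation
        self.feature_names = feature_names

    @property
    def label(self) -> str:
        return "prior_cvae"

    def _predict_dist(self, Ystd, Xstd, mode, K, seed):
        if mode == "prior":
            return prior_predict(self.trained, Xstd, K=K, seed=seed)
        if mode == "posterior":
            if Ystd is None:
                raise ValueError("posterior mode needs observed features")
            return posterior_predict(self.trained, Ystd, Xstd, K=K, seed=seed)
        raise ValueError(f"unknown mode {mode!r}")

    def save(self, path) -> None:
        self.trained.save(path)

    @classmethod
    def load(cls, path) -> "CVAENormativeResults":
        trained = TrainedCVAE.load(path)
        return cls(trained, trained.standardisation.feature_names)

    def summary(self) -> str:
        t = self.trained
        h = t.history
        lines = [
            "Prior-sampling cVAE normative model",
            "=" * 42,
            f"features:           {t.config.n_features}",
            f"covariates:         {t.config.n_covariates}",
            f"latent dim:         {t.config.latent_dim}",
            f"hidden:             {t.config.n_hidden_layers} x {t.config.hidden_dim} (ReLU)",
            f"learning rate:      {t.config.learning_rate:g} (Adam)",
            f"batch size:         {t.config.batch_size}",
            f"epochs run:         {len(h)} (max {t.config.max_epochs}, "
            f"patience {t.config.patience})",
            f"best epoch:         {t.best_epoch}",
            f"best val loss:      {t.best_val_loss:.4f}",
            f"final train loss:   {h['train_loss'].iloc[-1]:.4f}",
            f"WMH log offset:     {t.standardisation.wmh_offset:g}",
            f"seed:               {t.config.seed}",
        ]
        return "\n".join(lines)


@dataclass
class TwoStageBaselineModel:
    """Polynomial-mean + residual-RMSE baseline over the same cohort API."""

    cohort: CohortTable
    age_degree: int = 2
    wmh_offset: float = 1.0

    def fit(self) -> "BaselineResults":
        fitted = fit_baseline(
            self.cohort, age_degree=self.age_degree, wmh_offset=self.wmh_offset
        )
        return BaselineResults(fitted)


class BaselineResults(NormativeResults):
    """Fitted two-stage baseline; covariate-only by construction."""

    def __init__(self, fitted: TwoStageBaseline):
        self.fitted = fitted
        self.standardisation = fitted.standardisation
        self.feature_names = fitted.feature_names

    @property
    def label(self) -> str:
        return self.fitted.label

    def _predict_dist(self, Ystd, Xstd, mode, K, seed):
        if mode not in ("prior", "baseline"):
            raise ValueError(
                f"baseline model only predicts from covariates (mode {mode!r})"
            )
        return predict_baseline(self.fitted, Xstd)

    def summary(self) -> str:
        f = self.fitted
        lines = [
            "Two-stage polynomial baseline normative model",
            "=" * 46,
            f"features:        {len(f.feature_names)}",
            f"age degree:      {f.age_degree}",
            f"design columns:  {f.coefficients.shape[0]}",
            f"residual SD:     median {np.median(f.residual_sd):.4f} "
            f"(range {f.residual_sd.min():.4f}-{f.residual_sd.max():.4f})",
            f"WMH log offset:  {f.standardisation.wmh_offset:g}",
        ]
        return "\n".join(lines)
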