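"""Seeded synthetic cohort generator with known ground truth.

The generator emulates the statistical structure of a large population
imaging cohort of middle-aged/older adults: truncated-normal age, Bernoulli
sex and vascular risk factors, normal intracranial volume, a correlated
bivariate-normal blood-pressure model from which a four-level hypertension
grade is derived, and features produced by a linear model on standardised
covariates plus Gaussian noise on a *transformed* scale — identity for
morphometric measures, log for WMH volumes (exponentiated back to mm^3, so
the raw WMH distribution is zero-inflated and heavily right-skewed).

Hypertension pathology enters as additive per-level shifts on the transformed
scale, expressed in multiples of each feature's noise SD. Because every
subject's true conditional mean and SD are recorded in :class:`GroundTruth`,
the generator doubles as an oracle for parameter-recovery and calibration
tests of any normative model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import COVARIATE_COLUMNS, CohortTable, FeatureMeta

__all__ = [
    "EffectSpec",
    "GeneratorSpec",
    "GroundTruth",
    "classify_hypertension",
    "sample_covariates",
    "sample_features",
    "simulate_cohort",
]

#: Hypertension-grade boundaries (mmHg): level 0 requires SBP<130 and DBP<85;
#: level 1: SBP 130-139 or DBP 85-89; level 2: SBP 140-159 or DBP 90-99;
#: level 3: SBP>=160 or DBP>=100. Higher grade wins.
_SBP_CUTS = (130.0, 140.0, 160.0)
_DBP_CUTS = (85.0, 90.0, 100.0)


def classify_hypertension(sbp, dbp):
    """Grade blood pressure into levels 0-3 (normotensive to severe).

    Accepts scalars or arrays; vectorised, total on positive pressures.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    level = np.zeros(np.broadcast(sbp, dbp).shape, dtype=int)
    level = np.maximum(
        np.searchsorted(_SBP_CUTS, sbp, side="right"),
        np.searchsorted(_DBP_CUTS, dbp, side="right"),
    )
    if level.ndim == 0:
        return int(level)
    return level


@dataclass(frozen=True)
class EffectSpec:
    """Per-category feature model on the transformed scale.

    ``effects`` are coefficients on the standardised covariate vector
    (age z-score, sex 0/1, ICV z-score, diabetes, hyperchol, obesity,
    smoking), expressed in multiples of the noise SD ``sd``.
    ``level_shift`` gives the additive hypertension-pathology shift per level
    0..3, also in SD multiples (level 0 must be 0).
    """

    intercept: float
    sd: float
    effects: tuple[float, ...]  # length 7, SD multiples
    level_shift: tuple[float, float, float, float]

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("noise SD must be positive")
        if len(self.effects) != len(COVARIATE_COLUMNS):
            raise ValueError("effects must have 7 entries")
        if self.level_shift[0] != 0.0:
            raise ValueError("level-0 pathology shift must be 0")


# Default per-category models. Signs follow well-replicated epidemiology:
# ageing thins cortex and shrinks grey matter, grows WMH load; male sex and
# larger heads mean larger volumes; vascular risk factors add small
# detriments. Magnitudes are chosen so total covariate effects reach ~0.5 SD.
_DEFAULT_EFFECTS = {
    "cortical_thickness": EffectSpec(
        intercept=2.5,
        sd=0.12,
        effects=(-0.35, 0.05, 0.10, -0.06, -0.05, -0.04, -0.05),
        level_shift=(0.0, -0.05, -0.12, -0.25),
    ),
    "cortical_volume": EffectSpec(
        intercept=5200.0,
        sd=650.0,
        effects=(-0.30, 0.25, 0.50, -0.05, -0.04, -0.03, -0.04),
        level_shift=(0.0, -0.04, -0.10, -0.22),
    ),
    "subcortical_volume": EffectSpec(
        intercept=3900.0,
        sd=420.0,
        effects=(-0.28, 0.20, 0.45, -0.04, -0.03, -0.03, -0.03),
        level_shift=(0.0, -0.03, -0.08, -0.18),
    ),
    "wmh": EffectSpec(
        intercept=1.0,
        sd=1.2,
        effects=(0.40, 0.08, 0.08, 0.08, 0.10, 0.05, 0.06),
        level_shift=(0.0, 0.15, 0.35, 0.80),
    ),
}


@dataclass
class GeneratorSpec:
    """Full description of a synthetic cohort.

    Covariate marginals default to the demographics of a large UK population
    imaging cohort of 45-84-year-olds (age 60.76 +/- 7.20 years, 30.8% male)
    with prevalences of diabetes 1.8%, hypercholesterolaemia 7.4%, obesity
    8.5% and smoking history 33.8%. Blood pressure is bivariate normal
    (SBP 135 +/- 18, DBP 82 +/- 10, r = 0.7), which yields all four
    hypertension grades in realistic proportions.
    """

    n_subjects: int = 1000
    n_features: dict = field(
        default_factory=lambda: {
            "cortical_thickness": 5,
            "cortical_volume": 5,
            "subcortical_volume": 5,
            "wmh": 5,
        }
    )
    seed: int = 0
    age_mean: float = 60.76
    age_sd: float = 7.20
    age_range: tuple[float, float] = (45.0, 84.0)
    sex_prevalence: float = 0.308  # male = 1
    diabetes_prevalence: float = 0.018
    hyperchol_prevalence: float = 0.074
    obesity_prevalence: float = 0.085
    smoking_prevalence: float = 0.338
    icv_mean: float = 1.55e6
    icv_sd: float = 1.4e5
    sbp_mean: float = 135.0
    sbp_sd: float = 18.0
    dbp_mean: float = 82.0
    dbp_sd: float = 10.0
    bp_correlation: float = 0.7
    effects: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECTS))
    effect_jitter: float = 0.3  # per-feature multiplicative spread of effects
    hetero_age_slope: float = 0.0  # optional per-age-SD multiplicative SD slope
    wmh_offset: float = 1.0
    apply_pathology: bool = True

    def __post_init__(self):
        for p in (
            self.sex_prevalence,
            self.diabetes_prevalence,
            self.hyperchol_prevalence,
            self.obesity_prevalence,
            self.smoking_prevalence,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("prevalences must lie in [0, 1]")

    @property
    def total_features(self) -> int:
        return sum(self.n_features.values())

    def feature_meta(self) -> list[FeatureMeta]:
        meta = []
        for cat in ("cortical_thickness", "cortical_volume", "subcortical_volume", "wmh"):
            for i in range(self.n_features.get(cat, 0)):
                meta.append(FeatureMeta(name=f"{cat}_{i:03d}", category=cat))
        return meta

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effects"] = {k: asdict(v) for k, v in self.effects.items()}
        return d


@dataclass
class GroundTruth:
    """True per-subject conditional moments on the transformed scale."""

    mean: np.ndarray  # subjects x F
    sd: np.ndarray  # subjects x F
    hypertension_level: np.ndarray  # subjects
    effect_matrix: np.ndarray  # 8 x F (intercept + 7 covariates), transformed scale
    noise_sd: np.ndarray  # F, base noise SD per feature


def sample_covariates(spec: GeneratorSpec, rng: np.random.Generator | None = None):
    """Draw the covariate matrix and blood pressures for a spec.

    Returns ``(X, sbp, dbp)`` with ``X`` in `COVARIATE_COLUMNS` order.
    """
    if spec.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    lo, hi = spec.age_range
    # solve for the pre-truncation location so the *realised* mean matches
    # spec.age_mean despite the asymmetric [lo, hi] truncation
    loc = spec.age_mean
    for _ in range(4):
        a, b = (lo - loc) / spec.age_sd, (hi - loc) / spec.age_sd
        bias = stats.truncnorm.mean(a, b, loc=loc, scale=spec.age_sd) - spec.age_mean
        loc = loc - bias
    a, b = (lo - loc) / spec.age_sd, (hi - loc) / spec.age_sd
    age = stats.truncnorm.ppf(rng.random(n), a, b, loc=loc, scale=spec.age_sd)
    sex = (rng.random(n) < spec.sex_prevalence).astype(float)
    icv = rng.normal(spec.icv_mean, spec.icv_sd, size=n)
    diabetes = (rng.random(n) < spec.diabetes_prevalence).astype(float)
    chol = (rng.random(n) < spec.hyperchol_prevalence).astype(float)
    obesity = (rng.random(n) < spec.obesity_prevalence).astype(float)
    smoking = (rng.random(n) < spec.smoking_prevalence).astype(float)
    # correlated blood pressures
    z = rng.standard_normal((n, 2))
    r = spec.bp_correlation
    sbp = spec.sbp_mean + spec.sbp_sd * z[:, 0]
    dbp = spec.dbp_mean + spec.dbp_sd * (r * z[:, 0] + np.sqrt(1 - r**2) * z[:, 1])
    sbp = np.maximum(sbp, 70.0)
    dbp = np.maximum(dbp, 40.0)
    X = np.column_stack([age, sex, icv, diabetes, chol, obesity, smoking])
    return X, sbp, dbp


def _effect_matrix(spec: GeneratorSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature (8 x F) coefficient matrix, noise SDs, level shifts (4 x F).

    Coefficients are on the transformed scale (SD multiples scaled by each
    feature's noise SD); per-feature jitter makes features within a category
    distinct while keeping everything deterministic in ``spec.seed``.
    """
    meta = spec.feature_meta()
    F = len(meta)
    jitter_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7**5]))
    B = np.zeros((8, F))
    s = np.zeros(F)
    delta = np.zeros((4, F))
    for j, m in enumerate(meta):
        eff = spec.effects[m.category]
        mult = 1.0 + spec.effect_jitter * (2.0 * jitter_rng.random(7) - 1.0)
        s[j] = eff.sd
        B[0, j] = eff.intercept
        B[1:, j] = np.asarray(eff.effects) * mult * eff.sd
        delta[:, j] = np.asarray(eff.level_shift) * eff.sd
    return B, s, delta


def _standardised_covariates(spec: GeneratorSpec, X: np.ndarray) -> np.ndarray:
    Xs = X.copy()
    Xs[:, 0] = (Xs[:, 0] - spec.age_mean) / spec.age_sd
    Xs[:, 2] = (Xs[:, 2] - spec.icv_mean) / spec.icv_sd
    return Xs


def sample_features(
    spec: GeneratorSpec,
    X: np.ndarray,
    sbp: np.ndarray,
    dbp: np.ndarray,
    rng: np.random.Generator | None = None,
    subject_prefix: str = "S",
) -> tuple[CohortTable, GroundTruth]:
    """Generate features for given covariates; returns cohort plus oracle.

    Transformed-scale model per feature j:
    ``mean = B0_j + B_j . x_std + delta[level, j]``, observation =
    mean + noise, with noise SD ``s_j`` (optionally scaled by age). WMH
    features are mapped to raw mm^3 via ``exp(.) - offset`` clipped at 0.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if X.shape[1] != len(COVARIATE_COLUMNS):
        raise ValueError("covariate matrix must have 7 columns")
    meta = spec.feature_meta()
    B, s, delta = _effect_matrix(spec)
    level = classify_hypertension(sbp, dbp)
    Xs = _standardised_covariates(spec, X)
    design = np.column_stack([np.ones(n), Xs])
    mean = design @ B
    if spec.apply_pathology:
        mean = mean + delta[level, :]
    sd = np.broadcast_to(s, (n, len(meta))).copy()
    if spec.hetero_age_slope:
        sd = sd * (1.0 + spec.hetero_age_slope * Xs[:, [0]])
        sd = np.maximum(sd, 1e-6)
    T = mean + sd * rng.standard_normal((n, len(meta)))
    log_mask = np.array([m.log_transform for m in meta])
    Y = T.copy()
    Y[:, log_mask] = np.maximum(np.exp(T[:, log_mask]) - spec.wmh_offset, 0.0)
    ids = [f"{subject_prefix}{i:06d}" for i in range(n)]
    cohort = CohortTable(
        subject_ids=ids,
        covariates=pd.DataFrame(X, columns=list(COVARIATE_COLUMNS)),
        features=pd.DataFrame(Y, columns=[m.name for m in meta]),
        feature_meta=meta,
        sbp_mmHg=sbp,
        dbp_mmHg=dbp,
        hypertension_level=level,
    )
    truth = GroundTruth(
        mean=mean,
        sd=sd,
        hypertension_level=level,
        effect_matrix=B,
        noise_sd=s,
    )
    return cohort, truth


def simulate_cohort(
    spec: GeneratorSpec,
    normotensive_only: bool = False,
    subject_prefix: str = "S",
) -> tuple[CohortTable, GroundTruth]:
    """End-to-end simulation: covariates, hypertension grading, features.

    With ``normotensive_only`` the covariate draw is repeated (rejection
    sampling on the blood-pressure model) until ``n_subjects`` level-0
    subjects are collected — mirroring training on normotensive data only.
    Bitwise reproducible for a given spec.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    feat_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    X, sbp, dbp = sample_covariates(spec, rng=rng)
    if normotensive_only:
        keep = classify_hypertension(sbp, dbp) == 0
        X, sbp, dbp = X[keep], sbp[keep], dbp[keep]
        while X.shape[0] < spec.n_subjects:
            X2, sbp2, dbp2 = sample_covariates(spec, rng=rng)
            keep = classify_hypertension(sbp2, dbp2) == 0
            X = np.vstack([X, X2[keep]])
            sbp = np.concatenate([sbp, sbp2[keep]])
            dbp = np.concatenate([dbp, dbp2[keep]])
        X, sbp, dbp = (
            X[: spec.n_subjects],
            sbp[: spec.n_subjects],
            dbp[: spec.n_subjects],
        )
    return sample_features(
        spec, X, sbp, dbp, rng=feat_rng, subject_prefix=subject_prefix
    )
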