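"""Cohort containers, delimited-text IO and the standardisation transform.

A cohort couples a covariate table (age, sex, intracranial volume and four
binary vascular risk factors) with a feature table of continuous
imaging-derived phenotypes (IDPs): regional cortical thickness, cortical and
subcortical volumes, and white-matter-hyperintensity (WMH) lesion volumes.
WMH volumes are heavily right-skewed with many exact zeros, so they are
log-transformed (with a configurable positive offset) before z-scoring;
all other features are z-scored on their raw scale.

Standardisation statistics are always fitted on the training cohort only and
frozen into a :class:`StandardisationState`, which also carries the mean/SD
used to normalise the two continuous covariates (age, ICV). Binary covariates
pass through unchanged as 0/1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_CATEGORIES",
    "COVARIATE_COLUMNS",
    "AlignmentError",
    "ValidationError",
    "FeatureMeta",
    "CohortTable",
    "StandardisationState",
    "load_cohort",
    "write_cohort",
    "fit_standardisation",
    "standardise",
    "destandardise",
]

FEATURE_CATEGORIES = (
    "cortical_thickness",
    "cortical_volume",
    "subcortical_volume",
    "wmh",
)

#: Fixed covariate order: two continuous, sex, then the vascular risk factors.
#: Sex is encoded male=1, female=0; risk factors are 0/1 indicators.
COVARIATE_COLUMNS = (
    "age_years",
    "sex",
    "icv_mm3",
    "diabetes",
    "hyperchol",
    "obesity",
    "smoking",
)

_BINARY_COVARIATES = ("sex", "diabetes", "hyperchol", "obesity", "smoking")


class AlignmentError(ValueError):
    """Subject ids of the covariate and feature tables do not match."""


class ValidationError(ValueError):
    """A table violates the cohort contract (missing/invalid cells)."""


@dataclass(frozen=True)
class FeatureMeta:
    """Metadata for one imaging-derived phenotype.

    ``log_transform`` defaults to ``True`` exactly for WMH volumes but can be
    overridden per feature.
    """

    name: str
    category: str
    log_transform: bool | None = None

    def __post_init__(self) -> None:
        if self.category not in FEATURE_CATEGORIES:
            raise ValidationError(
                f"unknown feature category {self.category!r} for {self.name!r};"
                f" expected one of {FEATURE_CATEGORIES}"
            )
        if self.log_transform is None:
            object.__setattr__(self, "log_transform", self.category == "wmh")


@dataclass
class CohortTable:
    """Row-aligned covariates and features for a set of subjects."""

    subject_ids: list[str]
    covariates: pd.DataFrame
    features: pd.DataFrame
    feature_meta: list[FeatureMeta]
    sbp_mmHg: np.ndarray | None = None
    dbp_mmHg: np.ndarray | None = None
    hypertension_level: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            raise ValidationError("duplicate subject ids")
        if list(self.covariates.columns) != list(COVARIATE_COLUMNS):
            raise ValidationError(
                f"covariate columns must be {list(COVARIATE_COLUMNS)},"
                f" got {list(self.covariates.columns)}"
            )
        if len(self.covariates) != n or len(self.features) != n:
            raise AlignmentError("covariate/feature tables not aligned with subject ids")
        names = [m.name for m in self.feature_meta]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate feature names")
        if list(self.features.columns) != names:
            raise AlignmentError("feature columns do not match feature metadata")
        for df, label in ((self.covariates, "covariate"), (self.features, "feature")):
            if df.isna().any().any():
                r, c = np.argwhere(df.isna().to_numpy())[0]
                raise ValidationError(
                    f"missing value in {label} table at subject "
                    f"{self.subject_ids[r]!r}, column {df.columns[c]!r}"
                )
        wmh_cols = [m.name for m in self.feature_meta if m.category == "wmh"]
        if wmh_cols and (self.features[wmh_cols].to_numpy() < 0).any():
            bad = [
                c for c in wmh_cols if (self.features[c].to_numpy() < 0).any()
            ]
            raise ValidationError(f"negative WMH volumes in column(s) {bad}")
        for extra in ("sbp_mmHg", "dbp_mmHg", "hypertension_level"):
            arr = getattr(self, extra)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != (n,):
                    raise AlignmentError(f"{extra} not aligned with subject ids")
                setattr(self, extra, arr)

    # -- convenience accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_meta)

    @property
    def X(self) -> np.ndarray:
        """Raw covariate matrix, subjects x 7, in `COVARIATE_COLUMNS` order."""
        return self.covariates.to_numpy(dtype=float)

    @property
    def Y(self) -> np.ndarray:
        """Raw feature matrix, subjects x F."""
        return self.features.to_numpy(dtype=float)

    @property
    def feature_names(self) -> list[str]:
        return [m.name for m in self.feature_meta]

    def subset(self, index: Sequence[int] | np.ndarray) -> "CohortTable":
        """Row subset (positional), preserving all optional columns."""
        index = np.asarray(index)
        return CohortTable(
            subject_ids=[self.subject_ids[i] for i in index],
            covariates=self.covariates.iloc[index].reset_index(drop=True),
            features=self.features.iloc[index].reset_index(drop=True),
            feature_meta=list(self.feature_meta),
            sbp_mmHg=None if self.sbp_mmHg is None else self.sbp_mmHg[index],
            dbp_mmHg=None if self.dbp_mmHg is None else self.dbp_mmHg[index],
            hypertension_level=(
                None
                if self.hypertension_level is None
                else self.hypertension_level[index]
            ),
        )


def _read_table(path, id_required: bool = True) -> pd.DataFrame:
    # comma default, tab accepted: csv sniffing via the python engine
    df = pd.read_csv(path, sep=None, engine="python")
    if id_required and "subject_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'subject_id'")
    if id_required:
        df["subject_id"] = df["subject_id"].astype(str)
    return df


def load_cohort(covariate_path, feature_path, meta_path) -> CohortTable:
    """Load a cohort from three delimited text files.

    ``covariate_path`` and ``feature_path`` each need a ``subject_id`` column;
    rows of the feature file are re-aligned to the covariate file's row order.
    ``meta_path`` has columns ``name,category`` (optional ``log_transform``).
    Optional covariate-file columns ``sbp_mmHg``/``dbp_mmHg``/
    ``hypertension_level`` are carried through.
    """
    cov = _read_table(covariate_path)
    feat = _read_table(feature_path)
    meta_df = _read_table(meta_path, id_required=False)
    if "name" not in meta_df.columns or "category" not in meta_df.columns:
        raise ValidationError(f"{meta_path}: expected columns 'name','category'")

    ids = cov["subject_id"].tolist()
    if set(ids) != set(feat["subject_id"]):
        raise AlignmentError(
            "subject ids differ between covariate and feature files"
        )
    feat = feat.set_index("subject_id").loc[ids].reset_index()

    meta = [
        FeatureMeta(
            name=str(r["name"]),
            category=str(r["category"]),
            log_transform=(
                bool(r["log_transform"]) if "log_transform" in meta_df.columns else None
            ),
        )
        for r in meta_df.to_dict("records")
    ]
    names = [m.name for m in meta]
    missing = [n for n in names if n not in feat.columns]
    if missing:
        raise AlignmentError(f"feature file lacks column(s) {missing}")

    extras = {}
    for col, key in (
        ("sbp_mmHg", "sbp_mmHg"),
        ("dbp_mmHg", "dbp_mmHg"),
        ("hypertension_level", "hypertension_level"),
    ):
        if col in cov.columns:
            extras[key] = cov[col].to_numpy()
    return CohortTable(
        subject_ids=ids,
        covariates=cov[list(COVARIATE_COLUMNS)].astype(float).reset_index(drop=True),
        features=feat[names].astype(float).reset_index(drop=True),
        feature_meta=meta,
        **extras,
    )


def write_cohort(cohort: CohortTable, covariate_path, feature_path, meta_path) -> None:
    """Write the three delimited files `load_cohort` reads (6 sig. digits)."""
    cov = cohort.covariates.copy()
    cov.insert(0, "subject_id", cohort.subject_ids)
    for extra in ("sbp_mmHg", "dbp_mmHg", "hypertension_level"):
        arr = getattr(cohort, extra)
        if arr is not None:
            cov[extra] = arr
    cov.to_csv(covariate_path, index=False, float_format="%.6g")
    feat = cohort.features.copy()
    feat.insert(0, "subject_id", cohort.subject_ids)
    feat.to_csv(feature_path, index=False, float_format="%.6g")
    pd.DataFrame(
        {
            "name": [m.name for m in cohort.feature_meta],
            "category": [m.category for m in cohort.feature_meta],
            "log_transform": [m.log_transform for m in cohort.feature_meta],
        }
    ).to_csv(meta_path, index=False)


# ---------------------------------------------------------------------------
# Standardisation
# ---------------------------------------------------------------------------


@dataclass
class StandardisationState:
    """Frozen training-time transform: log (WMH) then z-score.

    All SDs use the n-1 (sample) convention. ``feature_mean``/``feature_sd``
    are on the transformed scale (log(raw + offset) for WMH features).
    """

    feature_names: list[str]
    log_mask: np.ndarray  # boolean, per feature
    wmh_offset: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    age_mean: float
    age_sd: float
    icv_mean: float
    icv_sd: float

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("log_mask", "feature_mean", "feature_sd"):
            d[k] = np.asarray(d[k]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StandardisationState":
        d = dict(d)
        d["log_mask"] = np.asarray(d["log_mask"], dtype=bool)
        d["feature_mean"] = np.asarray(d["feature_mean"], dtype=float)
        d["feature_sd"] = np.asarray(d["feature_sd"], dtype=float)
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "StandardisationState":
        return cls.from_dict(json.loads(s))

    # transformed (possibly log) scale helpers
    def transform_features(self, Y: np.ndarray) -> np.ndarray:
        Y = np.asarray(Y, dtype=float)
        out = Y.copy()
        out[:, self.log_mask] = np.log(out[:, self.log_mask] + self.wmh_offset)
        return out

    def untransform_features(self, T: np.ndarray) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        out = T.copy()
        out[:, self.log_mask] = np.exp(out[:, self.log_mask]) - self.wmh_offset
        return out


def fit_standardisation(train: CohortTable, wmh_offset: float = 1.0) -> StandardisationState:
    """Fit per-feature and age/ICV moments on a training cohort.

    WMH features are log(raw + ``wmh_offset``)-transformed first; the default
    offset of 1 mm^3 maps a zero lesion load to zero. Raises
    :class:`ValidationError` for any zero-variance transformed feature.
    """
    if wmh_offset <= 0:
        raise ValidationError("wmh_offset must be positive")
    if train.n_subjects < 2:
        raise ValidationError("need at least 2 training subjects")
    log_mask = np.array([m.log_transform for m in train.feature_meta], dtype=bool)
    state = StandardisationState(
        feature_names=train.feature_names,
        log_mask=log_mask,
        wmh_offset=float(wmh_offset),
        feature_mean=np.zeros(train.n_features),
        feature_sd=np.ones(train.n_features),
        age_mean=float(train.covariates["age_years"].mean()),
        age_sd=float(train.covariates["age_years"].std(ddof=1)),
        icv_mean=float(train.covariates["icv_mm3"].mean()),
        icv_sd=float(train.covariates["icv_mm3"].std(ddof=1)),
    )
    T = state.transform_features(train.Y)
    state.feature_mean = T.mean(axis=0)
    state.feature_sd = T.std(axis=0, ddof=1)
    zero = np.flatnonzero(state.feature_sd <= 0)
    if zero.size:
        raise ValidationError(
            "zero-variance feature(s) after transform: "
            f"{[train.feature_names[i] for i in zero]}"
        )
    if state.age_sd <= 0 or state.icv_sd <= 0:
        raise ValidationError("zero-variance age or ICV in training cohort")
    return state


def standardise(
    state: StandardisationState, cohort: CohortTable
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(Ystd, Xstd)`` for a cohort under a fitted state.

    ``Ystd`` is the z-scored (after any log transform) feature matrix;
    ``Xstd`` standardises age and ICV only, binaries stay 0/1.
    """
    if cohort.feature_names != state.feature_names:
        raise ValidationError("cohort features do not match standardisation state")
    Ystd = (state.transform_features(cohort.Y) - state.feature_mean) / state.feature_sd
    Xstd = cohort.X.copy()
    Xstd[:, 0] = (Xstd[:, 0] - state.age_mean) / state.age_sd
    Xstd[:, 2] = (Xstd[:, 2] - state.icv_mean) / state.icv_sd
    return Ystd, Xstd


def standardise_covariates(state: StandardisationState, X: np.ndarray) -> np.ndarray:
    """Standardise a raw covariate matrix (age, ICV columns only)."""
    Xstd = np.asarray(X, dtype=float).copy()
    Xstd[:, 0] = (Xstd[:, 0] - state.age_mean) / state.age_sd
    Xstd[:, 2] = (Xstd[:, 2] - state.icv_mean) / state.icv_sd
    return Xstd


def destandardise(state: StandardisationState, Ystd: np.ndarray) -> np.ndarray:
    """Exact inverse of the feature part of :func:`standardise`."""
    T = np.asarray(Ystd, dtype=float) * state.feature_sd + state.feature_mean
    return state.untransform_features(T)
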