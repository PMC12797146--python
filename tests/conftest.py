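"""Shared fixtures: the scaled study conditions used across the suite.

A 20-feature synthetic cohort (5 per category) stands in for the full
195-feature problem; the cVAE is scaled to latent 32 / hidden 256
accordingly. Training fixtures are session-scoped so the (~30 s) fit runs
once.
"""

from __future__ import annotations

import numpy as np
import pytest

from priornorm import (
    CVAEConfig,
    GeneratorSpec,
    simulate_cohort,
    train_cvae,
)
from priornorm.cohort import standardise

TRAIN_SEED = 11
HOLDOUT_SEED = 12
EVAL_SEED = 13


def study_config(**overrides) -> CVAEConfig:
    base = dict(
        n_features=20,
        latent_dim=32,
        hidden_dim=256,
        max_epochs=600,
        patience=30,
        seed=0,
    )
    base.update(overrides)
    return CVAEConfig(**base)


@pytest.fixture(scope="session")
def train_cohort():
    spec = GeneratorSpec(n_subjects=2000, seed=TRAIN_SEED)
    cohort, truth = simulate_cohort(spec, normotensive_only=True)
    return cohort, truth


@pytest.fixture(scope="session")
def holdout():
    """Normotensive hold-out cohort with its generator ground truth."""
    spec = GeneratorSpec(n_subjects=1000, seed=HOLDOUT_SEED)
    return simulate_cohort(spec, normotensive_only=True)


@pytest.fixture(scope="session")
def eval_cohort():
    """Mixed-hypertension evaluation cohort (all four levels present)."""
    spec = GeneratorSpec(n_subjects=6000, seed=EVAL_SEED)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def trained(train_cohort):
    cohort, _ = train_cohort
    return train_cvae(cohort, study_config())


@pytest.fixture(scope="session")
def holdout_std(trained, holdout):
    cohort, _ = holdout
    Ystd, Xstd = standardise(trained.standardisation, cohort)
    return Ystd, Xstd


@pytest.fixture(scope="session")
def eval_std(trained, eval_cohort):
    cohort, _ = eval_cohort
    Ystd, Xstd = standardise(trained.standardisation, cohort)
    return Ystd, Xstd


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
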