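"""Conditional variational autoencoder: architecture, loss, training, tuning.

The generative model is a cVAE over standardised feature vectors ``Y``
conditioned on covariates ``X``. The encoder maps ``[Y, X]`` through a ReLU
hidden layer to a Gaussian posterior ``q(z | Y, X) = N(mu_z, diag(sigma_z^2))``
over a low-dimensional latent space; the decoder maps ``[z, X]`` through a
ReLU hidden layer to a Gaussian observation model
``Y ~ N(mu_Y, diag(sigma_Y^2))`` with a learned per-feature log-variance.
Training minimises the negative evidence lower bound

    loss = mean_batch[ KL(q(z|Y,X) || N(0,I)) - log p(Y | z, X) ]

with the KL summed over latent dimensions and the Gaussian log-likelihood
summed over features, using the reparameterisation ``z = mu + sigma * eps``.
Early stopping monitors a held-out validation split; the parameters with the
lowest validation loss are retained.

All computation is plain NumPy; gradients are derived analytically and
verified against finite differences in the test suite.
"""

from __future__ import annotations

import dataclasses
import io
import json
import zipfile
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .cohort import (
    CohortTable,
    StandardisationState,
    fit_standardisation,
    standardise,
)
from .nn import Adam, init_two_head_mlp, two_head_backward, two_head_forward

__all__ = [
    "CVAEConfig",
    "TrainedCVAE",
    "TrainingDivergedError",
    "init_params",
    "encode",
    "reparameterise",
    "decode",
    "elbo_loss",
    "train_cvae",
    "tune_hyperparameters",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass
class CVAEConfig:
    """Architecture and optimisation settings.

    Defaults follow the reference architecture for ~200 features: a
    64-dimensional latent space and a single 512-unit ReLU hidden layer,
    Adam with learning rate 1e-3 and batch size 256, 10% validation split
    and early stopping with patience 20.
    """

    n_features: int = 195
    n_covariates: int = 7
    latent_dim: int = 64
    hidden_dim: int = 512
    n_hidden_layers: int = 1
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 300
    patience: int = 20
    validation_fraction: float = 0.10
    seed: int = 0
    logvar_clamp: tuple[float, float] = (-10.0, 10.0)

    def __post_init__(self):
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        self.logvar_clamp = tuple(self.logvar_clamp)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CVAEConfig":
        return cls(**d)


def init_params(config: CVAEConfig, rng: np.random.Generator) -> dict:
    """Fresh encoder/decoder weights for a config."""
    F, C, L, H = (
        config.n_features,
        config.n_covariates,
        config.latent_dim,
        config.hidden_dim,
    )
    return {
        "encoder": init_two_head_mlp(F + C, H, L, config.n_hidden_layers, rng),
        "decoder": init_two_head_mlp(L + C, H, F, config.n_hidden_layers, rng),
        "logvar_clamp": tuple(config.logvar_clamp),
    }


def _clamp(logvar: np.ndarray, clamp: tuple[float, float]) -> np.ndarray:
    return np.clip(logvar, clamp[0], clamp[1])


def encode(params: dict, Ystd: np.ndarray, Xstd: np.ndarray):
    """Deterministic encoder pass: ``(mu_z, logvar_z)``, log-variance clamped."""
    Ystd = np.atleast_2d(np.asarray(Ystd, dtype=float))
    Xstd = np.atleast_2d(np.asarray(Xstd, dtype=float))
    mu, logvar = two_head_forward(params["encoder"], np.hstack([Ystd, Xstd]))
    return mu, _clamp(logvar, params["logvar_clamp"])


def reparameterise(mu_z, logvar_z, seed=None, rng: np.random.Generator | None = None):
    """``z = mu + sigma * eps`` with ``eps ~ N(0, I)`` from a seeded stream."""
    if rng is None:
        rng = np.random.default_rng(seed)
    mu_z = np.asarray(mu_z, dtype=float)
    eps = rng.standard_normal(mu_z.shape)
    return mu_z + np.exp(np.asarray(logvar_z) / 2.0) * eps


def decode(params: dict, z: np.ndarray, Xstd: np.ndarray):
    """Deterministic decoder pass: ``(mu_Y, logvar_Y)``, log-variance clamped."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    Xstd = np.atleast_2d(np.asarray(Xstd, dtype=float))
    mu, logvar = two_head_forward(params["decoder"], np.hstack([z, Xstd]))
    return mu, _clamp(logvar, params["logvar_clamp"])


def elbo_loss(Ystd, mu_y, logvar_y, mu_z, logvar_z):
    """Negative ELBO and its components, averaged over the batch.

    Returns ``(loss, kl, recon)`` where ``kl`` is the closed-form Gaussian KL
    to the standard-normal prior summed over latent dimensions and ``recon``
    the Gaussian negative log-likelihood summed over features.
    """
    for arr in (Ystd, mu_y, logvar_y, mu_z, logvar_z):
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite input to elbo_loss")
    Ystd = np.atleast_2d(Ystd)
    kl = 0.5 * np.sum(
        np.square(mu_z) + np.exp(logvar_z) - 1.0 - logvar_z, axis=-1
    )
    nll = 0.5 * np.sum(
        _LOG_2PI + logvar_y + np.square(Ystd - mu_y) * np.exp(-logvar_y), axis=-1
    )
    return float(np.mean(kl + nll)), float(np.mean(kl)), float(np.mean(nll))


def _loss_and_grads(params: dict, Ystd: np.ndarray, Xstd: np.ndarray,
                    eps: np.ndarray):
    """One training step's loss, components and exact parameter gradients."""
    lo, hi = params["logvar_clamp"]
    B = Ystd.shape[0]
    enc_in = np.hstack([Ystd, Xstd])
    (mu_z, raw_lv_z), enc_acts = two_head_forward(params["encoder"], enc_in, cache=True)
    lv_z = np.clip(raw_lv_z, lo, hi)
    sigma_z = np.exp(lv_z / 2.0)
    z = mu_z + sigma_z * eps
    dec_in = np.hstack([z, Xstd])
    (mu_y, raw_lv_y), dec_acts = two_head_forward(params["decoder"], dec_in, cache=True)
    lv_y = np.clip(raw_lv_y, lo, hi)

    loss, kl, nll = elbo_loss(Ystd, mu_y, lv_y, mu_z, lv_z)

    inv_var_y = np.exp(-lv_y)
    resid = mu_y - Ystd
    d_mu_y = resid * inv_var_y / B
    d_lv_y = 0.5 * (1.0 - np.square(resid) * inv_var_y) / B
    d_lv_y = d_lv_y * ((raw_lv_y > lo) & (raw_lv_y < hi))
    dec_grads, d_dec_in = two_head_backward(params["decoder"], dec_acts, d_mu_y, d_lv_y)

    d_z = d_dec_in[:, : mu_z.shape[1]]
    d_mu_z = d_z + mu_z / B
    d_lv_z = d_z * eps * 0.5 * sigma_z + 0.5 * (np.exp(lv_z) - 1.0) / B
    d_lv_z = d_lv_z * ((raw_lv_z > lo) & (raw_lv_z < hi))
    enc_grads, _ = two_head_backward(params["encoder"], enc_acts, d_mu_z, d_lv_z)
    return loss, kl, nll, {"encoder": enc_grads, "decoder": dec_grads}


@dataclass
class TrainedCVAE:
    """A fitted cVAE: weights, config, frozen standardisation and history."""

    config: CVAEConfig
    params: dict
    standardisation: StandardisationState
    history: pd.DataFrame  # per-epoch train/val loss and components
    best_epoch: int

    @property
    def best_val_loss(self) -> float:
        return float(self.history["val_loss"].iloc[self.best_epoch])

    def save(self, path) -> None:
        """Single-archive checkpoint: JSON config/state + raw tensors."""
        arrays = {}
        for net in ("encoder", "decoder"):
            for k, v in self.params[net].items():
                if isinstance(v, np.ndarray):
                    arrays[f"{net}.{k}"] = v
        meta = {
            "format_version": 1,
            "config": self.config.to_dict(),
            "standardisation": self.standardisation.to_dict(),
            "best_epoch": self.best_epoch,
            "n_hidden_layers": self.config.n_hidden_layers,
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            zf.writestr("history.csv", self.history.to_csv(index=False))
            buf = io.BytesIO()
            np.savez(buf, **arrays)
            zf.writestr("params.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "TrainedCVAE":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            history = pd.read_csv(io.StringIO(zf.read("history.csv").decode()))
            npz = np.load(io.BytesIO(zf.read("params.npz")))
            config = CVAEConfig.from_dict(meta["config"])
            params = init_params(config, np.random.default_rng(0))
            for key in npz.files:
                net, name = key.split(".", 1)
                params[net][name] = npz[key]
        return cls(
            config=config,
            params=params,
            standardisation=StandardisationState.from_dict(meta["standardisation"]),
            history=history,
            best_epoch=int(meta["best_epoch"]),
        )


def train_cvae(
    train: CohortTable,
    config: CVAEConfig,
    wmh_offset: float = 1.0,
    verbose: bool = False,
) -> TrainedCVAE:
    """Fit the cVAE on a training cohort with early stopping.

    A seeded ``validation_fraction`` of subjects is held out to monitor the
    loss; standardisation is fitted on the remaining training split only.
    Stops once the validation loss has not improved for ``config.patience``
    epochs and restores the best parameters.
    """
    if train.n_subjects < 20:
        raise ValueError("need at least 20 subjects to train")
    if config.n_features != train.n_features:
        config = dataclasses.replace(config, n_features=train.n_features)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = train.n_subjects
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.validation_fraction * n)))
    val_idx, fit_idx = perm[:n_val], perm[n_val:]
    fit_cohort = train.subset(fit_idx)
    val_cohort = train.subset(val_idx)

    state = fit_standardisation(fit_cohort, wmh_offset=wmh_offset)
    Y_fit, X_fit = standardise(state, fit_cohort)
    Y_val, X_val = standardise(state, val_cohort)

    params = init_params(config, rng)
    opt = Adam(params["encoder"], lr=config.learning_rate)
    opt_dec = Adam(params["decoder"], lr=config.learning_rate)

    history = {"epoch": [], "train_loss": [], "train_kl": [], "train_recon": [],
               "val_loss": []}
    best_loss = np.inf
    best_epoch = -1
    best_params = None
    since_improve = 0
    n_fit = len(fit_idx)

    for epoch in range(config.max_epochs):
        order = rng.permutation(n_fit)
        tot, tot_kl, tot_nll, nb = 0.0, 0.0, 0.0, 0
        for start in range(0, n_fit, config.batch_size):
            idx = order[start : start + config.batch_size]
            eps = rng.standard_normal((len(idx), config.latent_dim))
            try:
                loss, kl, nll, grads = _loss_and_grads(
                    params, Y_fit[idx], X_fit[idx], eps
                )
            except ValueError as exc:  # non-finite activations mid-pass
                raise TrainingDivergedError(epoch) from exc
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            opt.step(params["encoder"], grads["encoder"])
            opt_dec.step(params["decoder"], grads["decoder"])
            tot += loss
            tot_kl += kl
            tot_nll += nll
            nb += 1

        eps_val = rng.standard_normal((len(val_idx), config.latent_dim))
        try:
            mu_z, lv_z = encode(params, Y_val, X_val)
            z = mu_z + np.exp(lv_z / 2.0) * eps_val
            mu_y, lv_y = decode(params, z, X_val)
            val_loss, _, _ = elbo_loss(Y_val, mu_y, lv_y, mu_z, lv_z)
        except ValueError as exc:
            raise TrainingDivergedError(epoch) from exc
        if not np.isfinite(val_loss):
            raise TrainingDivergedError(epoch)

        history["epoch"].append(epoch)
        history["train_loss"].append(tot / nb)
        history["train_kl"].append(tot_kl / nb)
        history["train_recon"].append(tot_nll / nb)
        history["val_loss"].append(val_loss)
        if verbose:
            print(f"epoch {epoch:4d}  train {tot / nb:.4f}  val {val_loss:.4f}")

        if val_loss < best_loss:
            best_loss = val_loss
            best_epoch = epoch
            best_params = {
                "encoder": {k: (v.copy() if isinstance(v, np.ndarray) else v)
                            for k, v in params["encoder"].items()},
                "decoder": {k: (v.copy() if isinstance(v, np.ndarray) else v)
                            for k, v in params["decoder"].items()},
                "logvar_clamp": params["logvar_clamp"],
            }
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                break

    return TrainedCVAE(
        config=config,
        params=best_params,
        standardisation=state,
        history=pd.DataFrame(history),
        best_epoch=best_epoch,
    )


def tune_hyperparameters(
    train: CohortTable,
    search_space: dict,
    n_trials: int = 20,
    n_folds: int = 5,
    seed: int = 0,
    base_config: CVAEConfig | None = None,
    wmh_offset: float = 1.0,
) -> tuple[CVAEConfig, pd.DataFrame]:
    """Seeded random search over a discrete hyperparameter space with k-fold CV.

    ``search_space`` maps :class:`CVAEConfig` field names to candidate lists.
    Each trial draws one combination, trains on each of ``n_folds`` folds and
    scores the negative ELBO on the held-out fold; the config with the lowest
    mean CV loss is returned together with the full trial table
    (``n_trials * n_folds`` rows).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if not search_space or any(len(v) == 0 for v in search_space.values()):
        raise ValueError("search space must be non-empty")
    rng = np.random.default_rng(seed)
    base = base_config or CVAEConfig(n_features=train.n_features)
    n = train.n_subjects
    fold_of = np.random.default_rng(seed + 1).integers(0, n_folds, size=n)

    rows = []
    best = (np.inf, None)
    for trial in range(n_trials):
        choice = {k: v[rng.integers(len(v))] for k, v in search_space.items()}
        cfg = CVAEConfig(**{**base.to_dict(), **choice, "seed": seed + trial})
        fold_losses = []
        for fold in range(n_folds):
            fit_part = train.subset(np.flatnonzero(fold_of != fold))
            held = train.subset(np.flatnonzero(fold_of == fold))
            try:
                model = train_cvae(fit_part, cfg, wmh_offset=wmh_offset)
                Yh, Xh = standardise(model.standardisation, held)
                mu_z, lv_z = encode(model.params, Yh, Xh)
                z = reparameterise(mu_z, lv_z, seed=seed + 10_000 + fold)
                mu_y, lv_y = decode(model.params, z, Xh)
                loss, _, _ = elbo_loss(Yh, mu_y, lv_y, mu_z, lv_z)
            except TrainingDivergedError:
                loss = np.inf
            fold_losses.append(loss)
            rows.append({"trial": trial, "fold": fold, "val_loss": loss, **choice})
        mean_loss = float(np.mean(fold_losses))
        if mean_loss < best[0]:
            best = (mean_loss, cfg)
    if best[1] is None:
        raise RuntimeError("all trials diverged")
    return best[1], pd.DataFrame(rows)
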