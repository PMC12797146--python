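"""Prior/posterior sampling inference and deviation scoring."""

import numpy as np
import pytest

from priornorm import (
    CVAEConfig,
    DeviationMatrix,
    deviation_scores,
    extreme_rates,
    posterior_predict,
    prior_predict,
)
from priornorm.cvae import TrainedCVAE, init_params
from priornorm.cohort import StandardisationState
from priornorm.inference import PredictiveDistribution

import pandas as pd


def _random_model(F=4, C=7, L=3, H=8, seed=0) -> TrainedCVAE:
    """Untrained (random-weight) model: inference properties are structural."""
    cfg = CVAEConfig(n_features=F, n_covariates=C, latent_dim=L, hidden_dim=H,
                     seed=seed)
    params = init_params(cfg, np.random.default_rng(seed))
    state = StandardisationState(
        feature_names=[f"f{j}" for j in range(F)],
        log_mask=np.zeros(F, dtype=bool),
        wmh_offset=1.0,
        feature_mean=np.zeros(F),
        feature_sd=np.ones(F),
        age_mean=60.0, age_sd=7.0, icv_mean=1.5e6, icv_sd=1.4e5,
    )
    return TrainedCVAE(cfg, params, state, pd.DataFrame({"val_loss": [0.0]}), 0)


def test_total_variance_identity_is_exact():
    model = _random_model()
    X = np.random.default_rng(1).standard_normal((20, 7))
    dist = prior_predict(model, X, K=50, seed=2)
    np.testing.assert_allclose(
        np.square(dist.sd), dist.within_var + dist.between_var, rtol=0,
        atol=1e-12,
    )


def test_decoder_ignoring_z_has_zero_between_variance():
    model = _random_model()
    L = model.config.latent_dim
    model.params["decoder"]["W0"][:L, :] = 0.0  # sever the z pathway
    X = np.random.default_rng(1).standard_normal((10, 7))
    dist = prior_predict(model, X, K=50, seed=2)
    np.testing.assert_allclose(dist.between_var, 0.0, atol=1e-20)
    np.testing.assert_allclose(np.square(dist.sd), dist.within_var)


def test_prior_predict_variance_matches_mixture_sampling_oracle():
    """sigma*^2 agrees with the empirical variance of draws from the
    K-component Gaussian mixture the decoder defines."""
    from priornorm.cvae import decode
    from priornorm.inference import _subject_rngs

    model = _random_model(seed=3)
    rng = np.random.default_rng(4)
    X = rng.standard_normal((1, 7))
    K = 400
    dist = prior_predict(model, X, K=K, seed=5)
    # brute force: regenerate the subject's own K mixture components, then
    # sample y ~ mixture_k N(mu_k, sigma_k^2), 10^5 draws
    z = _subject_rngs(5, 1)[0].standard_normal((K, model.config.latent_dim))
    mu_k, lv_k = decode(model.params, z, np.repeat(X, K, axis=0))
    n_mc = 100_000
    pick = rng.integers(0, K, n_mc)
    y = mu_k[pick] + np.exp(lv_k[pick] / 2.0) * rng.standard_normal(
        (n_mc, model.config.n_features)
    )
    emp_var = y.var(axis=0)
    # MC SE of a variance estimate ~ var * sqrt(2 + kurtosis / n)
    m4 = np.mean((y - y.mean(axis=0)) ** 4, axis=0)
    se = np.sqrt((m4 - emp_var**2) / n_mc)
    assert (np.abs(np.square(dist.sd[0]) - emp_var) < 3 * se + 0.02).all()


def test_prior_predict_never_consults_observations():
    model = _random_model()
    X = np.random.default_rng(1).standard_normal((10, 7))
    a = prior_predict(model, X, K=20, seed=3)
    b = prior_predict(model, X, K=20, seed=3)
    np.testing.assert_array_equal(a.mu, b.mu)
    np.testing.assert_array_equal(a.sd, b.sd)


def test_identical_covariates_and_seed_keys_give_identical_rows():
    model = _random_model()
    X = np.zeros((2, 7))
    dist = prior_predict(model, X, K=30, seed=7, subject_keys=[5, 5])
    np.testing.assert_array_equal(dist.mu[0], dist.mu[1])
    np.testing.assert_array_equal(dist.sd[0], dist.sd[1])


def test_subject_order_does_not_change_results():
    model = _random_model()
    X = np.random.default_rng(1).standard_normal((6, 7))
    full = prior_predict(model, X, K=30, seed=7, subject_keys=[0, 1, 2, 3, 4, 5])
    rev = prior_predict(model, X[::-1], K=30, seed=7,
                        subject_keys=[5, 4, 3, 2, 1, 0])
    np.testing.assert_array_equal(full.mu, rev.mu[::-1])


def test_mu_converges_with_more_draws():
    model = _random_model(seed=9)
    X = np.random.default_rng(2).standard_normal((5, 7))
    ref = prior_predict(model, X, K=20_000, seed=11).mu
    err = [
        np.linalg.norm(prior_predict(model, X, K=K, seed=12).mu - ref)
        for K in (100, 10_000)
    ]
    assert err[1] < err[0]


def test_posterior_collapsed_to_prior_matches_prior_predict():
    model = _random_model()
    # zero encoder weights -> q(z|Y,X) = N(0, I) = prior
    for k, v in model.params["encoder"].items():
        if isinstance(v, np.ndarray):
            model.params["encoder"][k] = np.zeros_like(v)
    rng = np.random.default_rng(3)
    Y = rng.standard_normal((8, 4))
    X = rng.standard_normal((8, 7))
    prior = prior_predict(model, X, K=40, seed=5)
    post = posterior_predict(model, Y, X, K=40, seed=5)
    np.testing.assert_allclose(post.mu, prior.mu, atol=1e-12)
    np.testing.assert_allclose(post.sd, prior.sd, atol=1e-12)


def test_posterior_beats_prior_on_reconstruction(trained, eval_std):
    Ystd, Xstd = eval_std
    sub = slice(0, 1500)
    prior = prior_predict(trained, Xstd[sub], K=200, seed=5)
    post = posterior_predict(trained, Ystd[sub], Xstd[sub], K=200, seed=5)
    assert np.mean(np.abs(Ystd[sub] - post.mu)) < np.mean(
        np.abs(Ystd[sub] - prior.mu)
    )


def test_k_below_two_rejected():
    model = _random_model()
    with pytest.raises(ValueError):
        prior_predict(model, np.zeros((2, 7)), K=1, seed=0)


def test_deviation_scores_anchors():
    mu = np.zeros((100, 3))
    sd = np.ones((100, 3))
    dist = PredictiveDistribution(mu, sd, np.ones((100, 3)),
                                  np.zeros((100, 3)), 10, "prior")
    dev = deviation_scores(dist, mu)  # Y == mu* -> z == 0
    assert (dev.z == 0).all()
    assert not dev.extreme_pos.any() and not dev.extreme_neg.any()
    dev = deviation_scores(dist, mu + 2.6 * sd)
    assert dev.extreme_pos.all() and not dev.extreme_neg.any()
    dev = deviation_scores(dist, mu - 2.6 * sd)
    assert dev.extreme_neg.all()


def test_extreme_fraction_near_one_percent_for_calibrated_scores():
    n = 100_000
    y = np.random.default_rng(0).standard_normal((n, 1))
    dist = PredictiveDistribution(
        np.zeros((n, 1)), np.ones((n, 1)), np.ones((n, 1)),
        np.zeros((n, 1)), 10, "prior",
    )
    dev = deviation_scores(dist, y)
    frac = (dev.extreme_pos | dev.extreme_neg).mean()
    assert frac == pytest.approx(0.0099, abs=0.0015)


def test_extreme_rates_counting_and_oracle():
    z = np.zeros((100, 2))
    z[:3, 0] = 3.0  # 3 extreme-positive subjects in group 0, feature 0
    dev = DeviationMatrix(z=z, extreme_pos=z > 2.58, extreme_neg=z < -2.58)
    groups = np.zeros(100, dtype=int)
    rates = extreme_rates(dev, groups, ["a", "b"])
    row = rates[(rates.level == 0) & (rates.feature == "a")].iloc[0]
    assert row.pct_pos == pytest.approx(3.0)
    assert row.pct_neg == 0.0
    # independent boolean-sum oracle across random matrices
    rng = np.random.default_rng(5)
    z = rng.standard_normal((200, 3)) * 1.5
    g = rng.integers(0, 3, 200)
    dev = DeviationMatrix(z=z, extreme_pos=z > 2.58, extreme_neg=z < -2.58)
    rates = extreme_rates(dev, g, ["a", "b", "c"])
    for lv in range(3):
        for j, name in enumerate(["a", "b", "c"]):
            want = 100.0 * np.sum((z[g == lv, j] > 2.58)) / np.sum(g == lv)
            got = rates[(rates.level == lv) & (rates.feature == name)].pct_pos
            assert float(got.iloc[0]) == pytest.approx(want)


def test_extreme_rates_empty_group_warns_and_reports_missing():
    z = np.zeros((10, 1))
    dev = DeviationMatrix(z=z, extreme_pos=z > 2.58, extreme_neg=z < -2.58)
    with pytest.warns(UserWarning, match="level 1"):
        rates = extreme_rates(dev, np.zeros(10, dtype=int), ["a"],
                              levels=[0, 1])
    assert np.isnan(rates[rates.level == 1].pct_pos.iloc[0])


def test_sd_must_be_positive():
    with pytest.raises(ValueError):
        PredictiveDistribution(
            np.zeros((2, 1)), np.zeros((2, 1)), np.zeros((2, 1)),
            np.zeros((2, 1)), 5, "prior",
        )
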