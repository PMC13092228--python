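import numpy as np
import pandas as pd
import pytest

from rockyshore import inference as inf
from rockyshore import synthetic_data as sd
from rockyshore.inference import McmcConfig, PosteriorFit, PriorConfig

FAST = sd.REDUCED_MCMC
NEFF = sd.REDUCED_NEFF_MIN


def test_draw_count_matches_protocol(rng):
    data = sd.simulate_trend_data(rng)
    fit = inf.fit_trend_era_model(data, mcmc=FAST, neff_min=NEFF)
    assert fit.chains.shape[:2] == (FAST.n_chains, FAST.n_iter - FAST.n_warmup)
    assert fit.n_draws_total == 1000
    assert set(fit.diagnostics["param"]) == set(fit.param_names)


def test_trend_model_no_signal_case(rng):
    data = sd.simulate_trend_data(rng, beta_year=0.0, sigma=1e-6, alpha=5.0)
    data.y[:] = 5.0
    fit = inf.fit_trend_era_model(data, mcmc=FAST, neff_min=NEFF)
    beta = fit.draws("beta_year")
    assert abs(np.median(beta)) < 0.05
    alphas = [np.median(fit.draws(f"alpha[{e}]")) for e in fit.extras["era_labels"]]
    assert np.ptp(alphas) < 0.05


def test_trend_model_determinism(rng):
    data = sd.simulate_trend_data(rng)
    f1 = inf.fit_trend_era_model(data, mcmc=FAST, neff_min=NEFF)
    f2 = inf.fit_trend_era_model(data, mcmc=FAST, neff_min=NEFF)
    assert np.array_equal(f1.chains, f2.chains)


def test_trend_model_preconditions(rng):
    data = sd.simulate_trend_data(rng)
    one_era = inf.TrendData(year=data.year, era=np.repeat("1993-1996", data.year.size), y=data.y)
    with pytest.raises(ValueError, match="two eras"):
        inf.fit_trend_era_model(one_era, mcmc=FAST)


def test_samplers_agree_on_trend_posterior(rng):
    """Independence-MH and emcee are independent routes to the same posterior."""
    data = sd.simulate_trend_data(rng, beta_year=-0.6)
    fi = inf.fit_trend_era_model(data, mcmc=FAST, neff_min=NEFF)
    fe = inf.fit_trend_era_model(
        data,
        mcmc=McmcConfig(n_chains=2, n_iter=1500, n_warmup=750, n_walkers=60,
                        seed=3, sampler="emcee"),
        neff_min=50,
    )
    bi, be = fi.draws("beta_year"), fe.draws("beta_year")
    assert np.median(bi) == pytest.approx(np.median(be), abs=0.08)
    assert np.std(bi) == pytest.approx(np.std(be), rel=0.25)


def test_temp_model_constant_covariate_prior_dominated(rng):
    data = sd.simulate_confounded_trend(rng, beta_temp=0.0)
    data.t[:] = 14.0
    priors = PriorConfig(beta_temp_scale=1.0)
    fit = inf.fit_temp_linear_model(data, priors=priors, mcmc=FAST, neff_min=NEFF)
    bt = fit.draws("beta_temp")
    # unidentified coefficient: posterior matches its prior
    assert np.std(bt) == pytest.approx(1.0, rel=0.2)
    assert np.median(bt) == pytest.approx(0.0, abs=0.15)


def test_naive_vs_adjusted_on_confounded_data(rng):
    data = sd.simulate_confounded_trend(rng, beta_temp=0.0, confound_per_decade=-0.8,
                                        t_noise_sd=0.1)
    naive = inf.fit_temp_linear_model(data, mcmc=FAST, naive=True, neff_min=NEFF)
    adj = inf.fit_temp_linear_model(data, mcmc=FAST, neff_min=NEFF)
    assert abs(np.median(naive.draws("beta_temp"))) > abs(np.median(adj.draws("beta_temp")))
    assert 0.0 <= naive.extras["p_beta_temp_negative"] <= 1.0


def test_temp_model_agrees_with_trend_model_without_temperature(rng):
    """On temperature-free data the year slopes of Models 1 and 2 coincide."""
    data = sd.simulate_trend_data(rng, beta_year=-0.6)
    # temperature orthogonal to year and era, so conditioning on it cannot
    # shift the year slope
    t_raw = rng.normal(0, 0.3, data.year.size)
    design = np.column_stack(
        [np.ones(data.year.size), data.year_c]
        + [(data.era_idx == k).astype(float) for k in range(len(data.era_labels))]
    )
    resid = t_raw - design @ np.linalg.lstsq(design, t_raw, rcond=None)[0]
    with_t = inf.TrendData(year=data.year, era=data.era, y=data.y, t=14.0 + resid)
    f1 = inf.fit_trend_era_model(data, mcmc=FAST, neff_min=NEFF)
    f2 = inf.fit_temp_linear_model(with_t, mcmc=FAST, neff_min=NEFF)
    assert np.median(f1.draws("beta_year")) == pytest.approx(
        np.median(f2.draws("beta_year")), abs=0.15
    )


def test_gp_nested_limit_matches_linear_model(rng):
    data = sd.simulate_confounded_trend(rng, beta_temp=-0.4, confound_per_decade=0.0,
                                        t_noise_sd=0.3)
    pinned = PriorConfig(eta_scale=1e-8)
    gp = inf.fit_temp_gp_model(data, priors=pinned, mcmc=FAST, neff_min=NEFF,
                               latent_draws=False)
    naive = inf.fit_temp_linear_model(data, mcmc=FAST, naive=True, neff_min=NEFF)
    assert np.median(gp.draws("beta_temp")) == pytest.approx(
        np.median(naive.draws("beta_temp")), abs=0.1
    )


def test_gp_handles_duplicate_years(rng):
    data = sd.simulate_confounded_trend(rng)
    dup = inf.TrendData(
        year=np.concatenate([data.year, data.year[:3]]),
        era=np.concatenate([data.era, data.era[:3]]),
        y=np.concatenate([data.y, data.y[:3] + 0.05]),
        t=np.concatenate([data.t, data.t[:3]]),
    )
    fit = inf.fit_temp_gp_model(dup, mcmc=FAST, neff_min=NEFF, latent_draws=False)
    assert np.isfinite(fit.chains).all()


def test_gp_latent_draws_shape(rng):
    data = sd.simulate_confounded_trend(rng, confound_per_decade=0.8)
    fit = inf.fit_temp_gp_model(data, mcmc=FAST, neff_min=NEFF, latent_draws=True)
    f = fit.extras["f_year"]
    assert f.shape[1] == data.y.size and np.isfinite(f).all()


def test_lrr_model_recovers_contrast(rng):
    data = sd.simulate_lrr_data(rng, mu_coastwide=-1.0, mu_southern=1.0, se=0.1)
    fit = inf.fit_lrr_range_model(data, mcmc=FAST, neff_min=NEFF)
    assert np.median(fit.extras["delta_draws"]) == pytest.approx(2.0, abs=0.3)


def test_lrr_model_null_and_prior_limit(rng):
    data = sd.simulate_lrr_data(rng, mu_coastwide=0.0, mu_southern=0.0, sigma_theta=0.1)
    fit = inf.fit_lrr_range_model(data, mcmc=FAST, neff_min=NEFF)
    assert np.median(fit.extras["delta_draws"]) == pytest.approx(0.0, abs=0.2)
    # when every observation is nearly uninformative the contrast widens
    vague = sd.simulate_lrr_data(rng, se=50.0, sigma_theta=0.01)
    wide = inf.fit_lrr_range_model(vague, mcmc=FAST, neff_min=NEFF)
    assert np.std(wide.extras["delta_draws"]) > 5 * np.std(fit.extras["delta_draws"])


def test_lrr_model_requires_two_taxa_per_class(rng):
    data = sd.simulate_lrr_data(rng, n_per_class=20)
    data.range_class[:19] = "uncertain"
    with pytest.raises(ValueError, match="coastwide"):
        inf.fit_lrr_range_model(data, mcmc=FAST)


def _fit_from_chains(chains, names=("theta",)):
    return PosteriorFit("toy", list(names), chains, McmcConfig())


def test_diagnostics_ideal_and_broken_chains(rng):
    good = rng.standard_normal((4, 800, 1))
    rep = inf.mcmc_diagnostics(_fit_from_chains(good), neff_min=100)
    assert rep["rhat"].iloc[0] == pytest.approx(1.0, abs=0.02)
    assert bool(rep["passed"].iloc[0])
    broken = good.copy()
    broken[0] += 10.0
    rep2 = inf.mcmc_diagnostics(_fit_from_chains(broken), neff_min=100)
    assert rep2["rhat"].iloc[0] > 1.05
    assert not rep2["passed"].iloc[0]


def test_diagnostics_threshold_is_strict(rng):
    chains = rng.standard_normal((4, 800, 1))
    r = inf.mcmc_diagnostics(_fit_from_chains(chains))["rhat"].iloc[0]
    at = inf.mcmc_diagnostics(_fit_from_chains(chains), rhat_max=r, neff_min=10)
    above = inf.mcmc_diagnostics(_fit_from_chains(chains), rhat_max=r + 1e-6, neff_min=10)
    assert not at["passed"].iloc[0]      # R-hat equal to the threshold fails
    assert above["passed"].iloc[0]       # strictly below passes


def test_diagnostics_single_chain_rhat_undefined(rng):
    rep = inf.mcmc_diagnostics(_fit_from_chains(rng.standard_normal((1, 500, 1))))
    assert np.isnan(rep["rhat"].iloc[0])
    assert not rep["passed"].iloc[0]


def test_posterior_predict_envelopes_mean_interval(rng):
    data = sd.simulate_trend_data(rng)
    fit = inf.fit_trend_era_model(data, mcmc=FAST, neff_min=NEFF)
    pred = inf.posterior_predict(fit, data.year, force=True)
    assert (pred["pi_low"] <= pred["mu_low"]).all()
    assert (pred["pi_high"] >= pred["mu_high"]).all()


def test_posterior_predict_noiseless_limit(rng):
    data = sd.simulate_trend_data(rng)
    fit = inf.fit_trend_era_model(data, mcmc=FAST, neff_min=NEFF)
    k = len(fit.extras["era_labels"])
    fit.chains[:, :, k + 1] = -30.0  # log sigma -> 0 noise
    pred = inf.posterior_predict(fit, data.year[:3], force=True)
    assert np.allclose(pred["pi_low"], pred["mu_low"], atol=1e-6)
    assert np.allclose(pred["pi_high"], pred["mu_high"], atol=1e-6)


def test_posterior_predict_coverage_of_new_observations(rng):
    """95% predictive intervals catch ~95% of fresh simulated observations."""
    hits, total = 0, 0
    for rep in range(12):
        data = sd.simulate_trend_data(rng, beta_year=-0.4, sigma=0.5)
        fit = inf.fit_trend_era_model(data, mcmc=FAST, neff_min=NEFF)
        pred = inf.posterior_predict(fit, data.year, force=True).set_index("year")
        fresh = sd.simulate_trend_data(rng, beta_year=-0.4, sigma=0.5)
        # same latent process, new noise: check the envelope at observed years
        for yr, y in zip(fresh.year, fresh.y):
            row = pred.loc[yr]
            hits += int(row["pi_low"] <= y <= row["pi_high"])
            total += 1
    assert 0.85 <= hits / total <= 1.0


def test_prior_predictive_spans_wide_trends(rng):
    data = sd.simulate_trend_data(rng)
    draws = inf.prior_predictive_trends(data, n_draws=500, seed=1)
    slopes = draws["slope_per_decade"]
    assert slopes.abs().max() > 1.0
    assert slopes.median() == pytest.approx(0.0, abs=0.2)
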