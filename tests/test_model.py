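import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cpue_ssm import covariates as cov
from cpue_ssm import model, synthetic
from cpue_ssm.io import FisheryPanel


class TestPreprocessCatch:
    def test_zero_floored(self):
        assert np.isclose(model.preprocess_catch([0.0])[0], np.log(50.0))

    def test_nonzero_unchanged(self):
        assert np.isclose(model.preprocess_catch([1000.0])[0], np.log(1000.0))
        assert abs(model.preprocess_catch([1000.0])[0] - 6.9078) < 1e-4

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            model.preprocess_catch([-5.0])

    def test_custom_floor(self):
        assert np.isclose(model.preprocess_catch([0.0], floor=10.0)[0], np.log(10.0))

    def test_small_positive_not_floored(self):
        # values below the floor but above zero are kept as-is
        assert np.isclose(model.preprocess_catch([1.0])[0], 0.0)

    def test_count_of_floored(self):
        arr = np.array([0.0, 5.0, 0.0, 0.0, 120.0])
        out = model.preprocess_catch(arr)
        assert (out == np.log(50.0)).sum() == 3


class TestGrowthMean:
    def test_baseline(self):
        assert model.growth_mean((0.1, -0.3, -0.2), (0, 0, 0)) == pytest.approx(0.1)

    def test_period2(self):
        assert model.growth_mean((0.1, -0.3, -0.2), (1, 0, 0)) == pytest.approx(-0.2)

    def test_period4(self):
        assert model.growth_mean((0.05, -0.3, -0.2, 0.2), (0, 0, 1)) == pytest.approx(0.25)

    def test_period4_without_beta4_errors(self):
        with pytest.raises(ValueError, match="beta4"):
            model.growth_mean((0.1, -0.3, -0.2), (0, 0, 1))

    def test_two_indicators_rejected(self):
        with pytest.raises(ValueError):
            model.growth_mean((0.1, -0.3, -0.2), (1, 1, 0))


class TestClimateTerm:
    def test_product(self):
        assert model.climate_term(-0.1, 2.0) == pytest.approx(-0.2)

    def test_zero_anomaly(self):
        assert model.climate_term(0.73, 0.0) == 0.0

    def test_zero_gamma(self):
        assert model.climate_term(0.0, 5.0) == 0.0

    def test_nonfinite_anomaly_rejected(self):
        with pytest.raises(ValueError):
            model.climate_term(0.1, np.nan)


def tiny_instance(missing=(1968,), n_taxa=2, seed=0):
    """2-taxa, 3-year panel with one missing effort year."""
    rng = np.random.default_rng(seed)
    years = np.arange(1966, 1969)
    taxa = [f"t{i}" for i in range(n_taxa)]
    catch = pd.DataFrame(
        rng.uniform(5e3, 5e4, size=(3, n_taxa)), index=years, columns=taxa
    )
    effort = pd.Series([40.0, 42.0, 39.0], index=years)
    for y in missing:
        effort.loc[y] = np.nan
    temp = pd.Series([14.0, 14.4, 14.2], index=years)
    panel = FisheryPanel(catch=catch, effort=effort, temperature=temp)
    return model.prepare(panel)


def random_params_states(data, seed=1):
    rng = np.random.default_rng(seed)
    n_i, n_t = data.n_taxa, data.n_years
    theta = rng.normal(0, 0.1, (n_i, 5))
    theta[~data.restoration, 4] = 0.0
    A = rng.normal(0, 0.2, (4, 4))
    Sigma = 0.05 * np.eye(4) + 0.1 * (A @ A.T)
    params = model.SSMParams(
        theta=theta,
        sigma_y=rng.uniform(0.1, 0.4, n_i),
        sigma_x=rng.uniform(0.1, 0.4, n_i),
        sigma_lambda=0.08,
        mu_beta=rng.normal(0, 0.1, 4),
        Sigma_beta=Sigma,
    )
    states = model.LatentStates(
        log_cpue=rng.normal(6.0, 1.0, (n_i, n_t)),
        log_lambda=rng.normal(np.log(40.0), 0.1, n_t),
        z_missing=np.array([41.0] * (~data.observed_mask).sum()),
    )
    return params, states


def oracle_log_joint(params, states, data, priors):
    """Sum of scipy scalar densities, written independently of the package."""
    total = 0.0
    n_i, n_t = data.n_taxa, data.n_years
    z = data.effort.copy()
    z[~data.observed_mask] = states.z_missing
    lam = np.exp(states.log_lambda)
    for i in range(n_i):
        for t in range(1, n_t):
            total += stats.norm.logpdf(
                data.log_catch[i, t],
                states.log_cpue[i, t] + np.log(z[t]),
                params.sigma_y[i],
            )
            ind = data.U[i, t]
            drift = (
                params.theta[i, 0]
                + params.theta[i, 1] * ind[1]
                + params.theta[i, 2] * ind[2]
                + params.theta[i, 3] * ind[3]
                + params.theta[i, 4] * ind[4]
            )
            total += stats.norm.logpdf(
                states.log_cpue[i, t],
                states.log_cpue[i, t - 1] + drift,
                params.sigma_x[i],
            )
    for t in range(n_t):
        total += stats.poisson.logpmf(np.round(z[t]), lam[t])
        if not data.observed_mask[t]:
            total -= np.log1p(-np.exp(-lam[t]))
    for t in range(1, n_t):
        total += stats.norm.logpdf(
            states.log_lambda[t], states.log_lambda[t - 1], params.sigma_lambda
        )
    z_fill = data.effort_filled()
    for i in range(n_i):
        total += stats.norm.logpdf(
            states.log_cpue[i, 0],
            data.log_catch[i, 0] - np.log(z_fill[0]),
            priors.init_sd,
        )
    total += stats.norm.logpdf(
        states.log_lambda[0],
        np.log(data.effort[data.observed_mask][0]),
        priors.init_sd,
    )
    for i in range(n_i):
        total += stats.multivariate_normal.logpdf(
            params.theta[i, :4], params.mu_beta, params.Sigma_beta
        )
    for i in np.flatnonzero(data.restoration):
        total += stats.norm.logpdf(params.theta[i, 4], 0.0, priors.beta4_sd)
    total += stats.norm.logpdf(params.mu_beta, priors.mu0, priors.tau0).sum()
    total += stats.invwishart.logpdf(params.Sigma_beta, priors.nu0, priors.Psi0)
    total += -(2 * n_i + 1) * np.log(priors.sd_max)
    return total


class TestLogJoint:
    def test_matches_scalar_density_oracle(self):
        data = tiny_instance()
        priors = model.Priors()
        params, states = random_params_states(data)
        got = model.log_joint(params, states, data, priors)
        want = oracle_log_joint(params, states, data, priors)
        assert abs(got - want) < 1e-10 * max(1.0, abs(want))

    def test_additivity_over_taxa(self):
        # two independent taxa = sum of single-taxon models, with the shared
        # effort and hyper layers counted once
        data2 = tiny_instance(n_taxa=2)
        priors = model.Priors()
        params, states = random_params_states(data2)
        full = model.log_joint(params, states, data2, priors)

        def taxon_only_terms(i):
            total = 0.0
            for t in range(1, data2.n_years):
                z = data2.effort.copy()
                z[~data2.observed_mask] = states.z_missing
                total += stats.norm.logpdf(
                    data2.log_catch[i, t],
                    states.log_cpue[i, t] + np.log(z[t]),
                    params.sigma_y[i],
                )
                drift = data2.U[i, t] @ params.theta[i]
                total += stats.norm.logpdf(
                    states.log_cpue[i, t],
                    states.log_cpue[i, t - 1] + drift,
                    params.sigma_x[i],
                )
            z_fill = data2.effort_filled()
            total += stats.norm.logpdf(
                states.log_cpue[i, 0],
                data2.log_catch[i, 0] - np.log(z_fill[0]),
                priors.init_sd,
            )
            total += stats.multivariate_normal.logpdf(
                params.theta[i, :4], params.mu_beta, params.Sigma_beta
            )
            return total

        # shared effort/hyper terms, computed explicitly and counted once
        z = data2.effort.copy()
        z[~data2.observed_mask] = states.z_missing
        lam = np.exp(states.log_lambda)
        shared = 0.0
        for t in range(data2.n_years):
            shared += stats.poisson.logpmf(np.round(z[t]), lam[t])
            if not data2.observed_mask[t]:
                shared -= np.log1p(-np.exp(-lam[t]))
        for t in range(1, data2.n_years):
            shared += stats.norm.logpdf(
                states.log_lambda[t], states.log_lambda[t - 1], params.sigma_lambda
            )
        shared += stats.norm.logpdf(
            states.log_lambda[0],
            np.log(data2.effort[data2.observed_mask][0]),
            priors.init_sd,
        )
        shared += stats.norm.logpdf(params.mu_beta, priors.mu0, priors.tau0).sum()
        shared += stats.invwishart.logpdf(params.Sigma_beta, priors.nu0, priors.Psi0)
        shared += -(2 * data2.n_taxa + 1) * np.log(priors.sd_max)
        assert abs(
            full - (taxon_only_terms(0) + taxon_only_terms(1) + shared)
        ) < 1e-9

    def test_taxon_permutation_invariance(self):
        data = tiny_instance(n_taxa=3)
        priors = model.Priors()
        params, states = random_params_states(data)
        base = model.log_joint(params, states, data, priors)
        perm = [2, 0, 1]
        params_p = model.SSMParams(
            theta=params.theta[perm],
            sigma_y=params.sigma_y[perm],
            sigma_x=params.sigma_x[perm],
            sigma_lambda=params.sigma_lambda,
            mu_beta=params.mu_beta,
            Sigma_beta=params.Sigma_beta,
        )
        states_p = model.LatentStates(
            log_cpue=states.log_cpue[perm],
            log_lambda=states.log_lambda,
            z_missing=states.z_missing,
        )
        data_p = model.PreparedData(
            taxa=tuple(data.taxa[i] for i in perm),
            years=data.years,
            log_catch=data.log_catch[perm],
            effort=data.effort,
            U=data.U[perm],
            restoration=data.restoration[perm],
            schemes=tuple(data.schemes[i] for i in perm),
            temperature=data.temperature,
        )
        assert np.isclose(
            base, model.log_joint(params_p, states_p, data_p, priors), atol=1e-10
        )

    def test_doubling_sigma_y_at_mean(self):
        # with data sitting exactly at the observation mean, doubling
        # sigma_y lowers each observation term by log 2
        data = tiny_instance()
        priors = model.Priors()
        params, states = random_params_states(data)
        z = data.effort.copy()
        z[~data.observed_mask] = states.z_missing
        data.log_catch[:, 1:] = states.log_cpue[:, 1:] + np.log(z)[None, 1:]
        base = model.log_joint(params, states, data, priors)
        params2 = model.SSMParams(
            theta=params.theta,
            sigma_y=2 * params.sigma_y,
            sigma_x=params.sigma_x,
            sigma_lambda=params.sigma_lambda,
            mu_beta=params.mu_beta,
            Sigma_beta=params.Sigma_beta,
        )
        n_obs = data.n_taxa * (data.n_years - 1)
        assert np.isclose(
            model.log_joint(params2, states, data, priors),
            base - n_obs * np.log(2.0),
            atol=1e-9,
        )

    def test_invalid_sigma_rejected(self):
        data = tiny_instance()
        params, states = random_params_states(data)
        params.sigma_y = np.zeros_like(params.sigma_y)
        with pytest.raises(ValueError):
            model.log_joint(params, states, data)

    def test_continuity_in_theta(self):
        data = tiny_instance()
        priors = model.Priors()
        params, states = random_params_states(data)
        base = model.log_joint(params, states, data, priors)
        params.theta = params.theta + 1e-8
        assert abs(model.log_joint(params, states, data, priors) - base) < 1e-4


class TestPrepare:
    def test_from_synthetic_panel(self):
        cfg = synthetic.group_structured_config()
        syn = synthetic.simulate_community(cfg, 2)
        prep = model.prepare(syn.panel, period4_starts=dict(cfg.period4_starts))
        assert prep.n_taxa == 8 and prep.n_years == 57
        assert prep.restoration.sum() == 2
        assert sorted(prep.missing_years) == [1969, 1970, 1994]

    def test_missing_scheme_errors(self):
        data = tiny_instance()
        cfg = synthetic.group_structured_config()
        syn = synthetic.simulate_community(cfg, 2)
        with pytest.raises(ValueError, match="scheme"):
            model.prepare(syn.panel, schemes=[cov.default_scheme("nope")])

    def test_floor_applied(self):
        cfg = synthetic.group_structured_config()
        cfg.zero_years = {"taxon_1": (1985,)}
        syn = synthetic.simulate_community(cfg, 2)
        prep = model.prepare(syn.panel, period4_starts=dict(cfg.period4_starts))
        i = prep.taxa.index("taxon_1")
        t = int(np.where(prep.years == 1985)[0][0])
        assert np.isclose(prep.log_catch[i, t], np.log(50.0))
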