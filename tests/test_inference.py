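"""Hierarchical fits: diagnostics, contrasts, predictive checks, calibration."""

import warnings

import numpy as np
import pandas as pd
import pytest

import arviz as az

from valsearch.cohort import (
    young_hyper, sample_population, simulate_learning_agent,
)
from valsearch.design import build_learning_schedule
from valsearch.inference import (
    MCMCConfig, Posterior, fit_rl_hierarchical, fit_ddm_hierarchical,
    rhat, group_contrast, posterior_predictive,
)

TINY = dict(iterations=150, burn_in=150, chains=2, thin=1)


@pytest.fixture(scope="module")
def rl_posterior(small_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_rl_hierarchical(
            small_cohort["learning"], MCMCConfig(seed=5, **TINY))


@pytest.fixture(scope="module")
def ddm_posterior(small_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_ddm_hierarchical(
            small_cohort["search"], MCMCConfig(seed=6, model="ddm", **TINY))


class TestRhat:
    def test_iid_chains_near_one(self, rng):
        draws = rng.standard_normal((4, 5000))
        assert rhat(draws) == pytest.approx(1.0, abs=0.01)

    def test_divergent_chains_flagged(self, rng):
        draws = rng.standard_normal((2, 2000))
        draws[1] += 10.0
        assert rhat(draws) > 1.1

    def test_single_chain_errors(self, rng):
        with pytest.raises(ValueError):
            rhat(rng.standard_normal((1, 100)))

    def test_matches_textbook_formula(self, rng):
        """Independent two-pass reimplementation oracle."""
        x = rng.standard_normal((3, 400)) + rng.standard_normal((3, 1)) * 0.3

        def textbook(chains):
            half = chains.shape[1] // 2
            splits = [c[:half] for c in chains] + [c[half:2 * half] for c in chains]
            m, n = len(splits), half
            means = [np.mean(s) for s in splits]
            variances = [np.var(s, ddof=1) for s in splits]
            W = np.mean(variances)
            B = n * np.var(means, ddof=1)
            var_hat = (n - 1) / n * W + B / n
            return np.sqrt(var_hat / W)

        assert rhat(x) == pytest.approx(textbook(x), rel=1e-12)

    def test_matches_arviz_split_rhat(self, rng):
        x = rng.standard_normal((4, 600)) + np.arange(4)[:, None] * 0.05
        ref = az.rhat(az.convert_to_dataset(x), method="split")["x"].values.item()
        assert rhat(x) == pytest.approx(ref, rel=1e-6)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(chains=1)
        with pytest.raises(ValueError):
            MCMCConfig(iterations=0)
        with pytest.raises(ValueError):
            MCMCConfig(model="lba")

    def test_full_scale_config(self):
        cfg = MCMCConfig.full_scale(seed=3)
        assert (cfg.iterations, cfg.burn_in, cfg.chains) == (5000, 5000, 4)


class TestFits:
    def test_rl_outputs(self, rl_posterior, small_cohort):
        summ = rl_posterior.summary()
        group = summ[summ["level"] == "group"]["parameter"].tolist()
        for name in ("eta_r", "eta_p", "tau_r", "tau_p",
                     "eta_r_minus_eta_p", "tau_r_minus_tau_p"):
            assert name in group
        table = rl_posterior.individual_table()
        assert len(table) == 6
        assert set(table.columns) == {"participant_id", "eta_r", "eta_p",
                                      "tau_r", "tau_p"}
        assert ((summ["ci_lo"] <= summ["ci_hi"]).all())

    def test_ddm_outputs(self, ddm_posterior):
        names = set(ddm_posterior.draws)
        assert "t0" in names and "alpha_reward" in names and "rho_zero" in names
        # start point is fixed, never sampled
        assert not any(n == "z" or n.startswith("z[") for n in names)
        table = ddm_posterior.individual_table()
        assert {"alpha_reward", "nu_punishment", "nu_zero"} <= set(table.columns)
        # t0 respects its bound
        assert ddm_posterior.flat("t0").max() < ddm_posterior.meta["rt_min"]

    def test_reproducible(self, small_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_rl_hierarchical(small_cohort["learning"], MCMCConfig(seed=9, **TINY))
            b = fit_rl_hierarchical(small_cohort["learning"], MCMCConfig(seed=9, **TINY))
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])

    def test_too_few_participants(self, small_cohort):
        one = small_cohort["learning"]
        one = one[one["participant_id"] == one["participant_id"].iloc[0]]
        with pytest.raises(ValueError, match="participants"):
            fit_rl_hierarchical(one, MCMCConfig(**TINY))

    def test_degenerate_learner_does_not_crash(self, small_cohort):
        """All-target choices push tau toward its prior upper mass but the
        fit must complete with finite draws."""
        trials = small_cohort["learning"].copy()
        trials["chose_target"] = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = fit_rl_hierarchical(trials, MCMCConfig(seed=2, **TINY))
        assert np.isfinite(post.flat("tau_r")).all()

    def test_save_load_roundtrip(self, rl_posterior, tmp_path):
        rl_posterior.save(tmp_path / "post")
        back = Posterior.load(tmp_path / "post")
        assert set(back.draws) == set(rl_posterior.draws)
        np.testing.assert_allclose(back.draws["eta_r"], rl_posterior.draws["eta_r"])
        assert back.level == rl_posterior.level


class TestContrasts:
    def test_identical_posteriors(self, rl_posterior):
        c = group_contrast(rl_posterior, rl_posterior, "eta_r")
        assert c.mean_diff == 0.0
        assert c.ci95[0] <= 0.0 <= c.ci95[1]

    def test_known_shift(self, rl_posterior):
        shifted = Posterior(
            draws={"eta_r": rl_posterior.draws["eta_r"] + 0.25},
            level={"eta_r": "group"}, config=rl_posterior.config)
        c = group_contrast(rl_posterior, shifted, "eta_r")
        assert c.mean_diff == pytest.approx(-0.25)
        assert c.ci95[0] <= c.ci95[1]

    def test_mismatched_lengths_warn(self, rl_posterior):
        trimmed = Posterior(
            draws={"eta_r": rl_posterior.draws["eta_r"][:, :50]},
            level={"eta_r": "group"}, config=rl_posterior.config)
        with pytest.warns(RuntimeWarning, match="truncating"):
            group_contrast(rl_posterior, trimmed, "eta_r")

    def test_missing_parameter(self, rl_posterior):
        with pytest.raises(KeyError):
            group_contrast(rl_posterior, rl_posterior, "gamma")


class TestPosteriorPredictive:
    def test_empty_posterior_errors(self, small_cohort):
        empty = Posterior(draws={}, level={}, config=MCMCConfig(**TINY))
        with pytest.raises(ValueError, match="empty"):
            posterior_predictive("rl", empty, small_cohort["learning"], seed=0)

    def test_rl_bands_cover_self_simulated_data(self, rl_posterior, small_cohort):
        ppc = posterior_predictive("rl", rl_posterior, small_cohort["learning"],
                                   seed=1, n_draws=30)
        assert ppc.fraction_within >= 0.9
        assert (ppc.table["band_lo"] <= ppc.table["band_hi"]).all()

    def test_ddm_quantiles_monotone(self, ddm_posterior, small_cohort):
        ppc = posterior_predictive("ddm", ddm_posterior, small_cohort["search"],
                                   seed=1, n_draws=15)
        for cond, sub in ppc.table.groupby("condition"):
            q = sub.sort_values("quantile")
            assert q["observed"].is_monotonic_increasing
            assert q["band_lo"].is_monotonic_increasing
        assert ppc.fraction_within >= 0.6


class TestCalibration:
    def test_group_location_coverage_and_ranks(self):
        """Small-scale simulation-based calibration: cohorts are drawn from
        the model's own prior (Normal(0,1) locations, HalfNormal(1) scales
        on the transformed scales), fitted, and the 95% CI for the group
        eta_p location must cover the truth in most replicates with the
        posterior rank of the truth not piling at the extremes."""
        from dataclasses import replace as drep
        expit = lambda v: 1 / (1 + np.exp(-v))
        reps = 20
        cover = 0
        ranks = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for r in range(reps):
                sr = np.random.SeedSequence(entropy=77, spawn_key=(r,))
                rng = np.random.default_rng(sr)
                mu = rng.normal(0.0, 1.0, 4)
                sd = np.abs(rng.normal(0.0, 1.0, 2))
                hyper = drep(
                    young_hyper(),
                    eta_r=float(expit(mu[0])), eta_p=float(expit(mu[1])),
                    tau_r=float(np.exp(mu[2])), tau_p=float(np.exp(mu[3])),
                    eta_sd=float(sd[0]), tau_sd=float(sd[1]))
                parts = sample_population(hyper, 8, rng)
                trials = pd.concat([
                    simulate_learning_agent(
                        p, build_learning_schedule(int(rng.integers(2**31))), seed=rng)
                    for p in parts], ignore_index=True)
                post = fit_rl_hierarchical(
                    trials, MCMCConfig(seed=r, iterations=250, burn_in=250,
                                       chains=2, thin=2))
                draws = post.flat("eta_p")
                lo, hi = np.percentile(draws, [2.5, 97.5])
                cover += int(lo <= hyper.eta_p <= hi)
                ranks.append(np.mean(draws < hyper.eta_p))
        assert cover / reps >= 0.8
        ranks = np.asarray(ranks)
        # ranks spread over (0, 1) rather than piling at the ends
        assert 0.2 < ranks.mean() < 0.8
        assert (ranks < 0.05).sum() + (ranks > 0.95).sum() <= reps // 3
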