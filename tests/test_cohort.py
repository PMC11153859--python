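"""Synthetic-cohort generator: populations, contingency, trial simulation."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats

from valsearch.cohort import (
    PopulationHyper, StudyConfig, young_hyper, old_hyper,
    sample_population, sample_coupled_population, draw_outcome,
    simulate_learning_agent, simulate_search_participant, generate_study,
)
from valsearch.design import build_learning_schedule, build_search_schedule
from valsearch.rw import RWParams, rl_loglik
from valsearch.wiener import boundary_prob, ddm_loglik, DDMParams


class TestPopulation:
    def test_study_group_sizes(self):
        young = sample_population(young_hyper(), 29, 0)
        old = sample_population(old_hyper(), 32, 1)
        assert len(young) + len(old) == 61
        assert {p.group for p in young} == {"young"}

    def test_degenerate_scales_collapse(self):
        hyper = replace(young_hyper(), eta_sd=0.0, tau_sd=0.0, alpha_sd=0.0,
                        nu_sd=0.0, t0_sd=0.0)
        parts = sample_population(hyper, 5, 0)
        assert all(p.rw.eta_r == pytest.approx(hyper.eta_r) for p in parts)
        assert all(p.ddm.t0 == pytest.approx(hyper.t0) for p in parts)

    def test_seeded_determinism(self):
        a = sample_population(young_hyper(), 4, 9)
        b = sample_population(young_hyper(), 4, 9)
        assert [p.rw for p in a] == [p.rw for p in b]

    def test_invalid_hyper(self):
        with pytest.raises(ValueError):
            PopulationHyper(group="x", eta_sd=-0.1)
        with pytest.raises(ValueError):
            sample_population(young_hyper(), 0, 0)

    def test_coupled_population_rank_correlation(self):
        parts = sample_coupled_population(young_hyper(), 2000, 3, rank_corr=0.6)
        r = stats.spearmanr([p.rw.eta_r for p in parts],
                            [p.ddm.nu["reward"] for p in parts])[0]
        assert abs(r - 0.6) < 0.05


class TestOutcomes:
    def test_zero_condition_always_zero(self, rng):
        assert all(draw_outcome("zero", bool(rng.random() < 0.5), rng) == 0
                   for _ in range(200))

    def test_contingency_calibration(self, rng):
        draws = [draw_outcome("reward", True, rng) for _ in range(10_000)]
        assert abs(np.mean([d == 1 for d in draws]) - 0.8) < 0.01
        pun = [draw_outcome("punishment", True, rng) for _ in range(10_000)]
        assert abs(np.mean([d == -1 for d in pun]) - 0.8) < 0.01
        non = [draw_outcome("reward", False, rng) for _ in range(10_000)]
        assert abs(np.mean([d == 1 for d in non]) - 0.2) < 0.01

    def test_contingency_validation(self, rng):
        with pytest.raises(ValueError):
            draw_outcome("reward", True, rng, contingency=1.2)

    def test_exact_block_balance(self):
        """With pre-randomised outcome schedules, each (block, pair) holds
        exactly 8 event trials: the target pays on event trials and the
        nontarget on the others, so the event indicator is recoverable as
        (chose_target == outcome_nonzero)."""
        p = sample_population(young_hyper(), 1, 0)[0]
        trials = simulate_learning_agent(
            p, build_learning_schedule(3), seed=4, exact_block_balance=True)
        nz = trials[trials["condition"] != "zero"].copy()
        nz["event"] = nz["chose_target"] == (nz["outcome"] != 0)
        events = nz.groupby(["block", "condition"])["event"].sum()
        assert (events == 8).all()


class TestLearningSimulation:
    def test_strong_learner_reaches_ceiling(self):
        """Long-run simulation oracle: high eta_r and tau_r drive the
        final-block reward choice proportion to ~1."""
        p = sample_population(young_hyper(), 1, 0)[0]
        strong = replace(p, rw=RWParams(0.5, 0.5, 15.0, 15.0))
        props = []
        for s in range(30):
            trials = simulate_learning_agent(
                strong, build_learning_schedule(s), seed=100 + s)
            rew = trials[trials["condition"] == "reward"]
            props.append(rew.tail(10)["chose_target"].mean())
        assert np.mean(props) > 0.95

    def test_reward_curve_nondecreasing_in_expectation(self):
        """Averaged over 200 agents the reward learning curve rises."""
        parts = sample_population(young_hyper(), 200, 11)
        sched = build_learning_schedule(0)
        mat = []
        for i, p in enumerate(parts):
            t = simulate_learning_agent(p, sched, seed=3000 + i)
            rew = t[t["condition"] == "reward"]["chose_target"].to_numpy(float)
            mat.append(rew.reshape(10, 10).mean(axis=1))
        curve = np.mean(mat, axis=0)
        assert curve[-1] > curve[0] + 0.1
        # no decade-to-decade drop beyond Monte-Carlo noise
        assert np.all(np.diff(curve) > -0.03)

    def test_likelihood_self_consistency(self, small_cohort):
        """Average log-likelihood at the generating parameters beats
        perturbed parameters on the same data (both RL and DDM)."""
        parts = {p.participant_id: p for p in small_cohort["participants"]}
        diffs = []
        for pid, p in parts.items():
            t = small_cohort["learning"]
            one = t[t["participant_id"] == pid]
            true_ll = rl_loglik(p.rw, one)
            pert = RWParams(min(0.9, p.rw.eta_r * 3 + 0.05), p.rw.eta_p,
                            p.rw.tau_r * 0.4, p.rw.tau_p)
            diffs.append(true_ll - rl_loglik(pert, one))
        assert np.mean(diffs) > 0

        ddm_diffs = []
        for pid, p in parts.items():
            s = small_cohort["search"]
            one = s[(s["participant_id"] == pid) & s["target_present"]]
            true_ll = ddm_loglik(p.ddm, one)
            pert = DDMParams(alpha=p.ddm.alpha,
                             nu={c: v * 0.4 for c, v in p.ddm.nu.items()},
                             t0=p.ddm.t0)
            ddm_diffs.append(true_ll - ddm_loglik(pert, one))
        assert np.mean(ddm_diffs) > 0


class TestSearchSimulation:
    def test_rts_above_t0(self, small_cohort):
        parts = {p.participant_id: p for p in small_cohort["participants"]}
        for pid, p in parts.items():
            s = small_cohort["search"]
            rts = s[s["participant_id"] == pid]["rt_sec"]
            assert (rts > p.ddm.t0).all()

    def test_large_drift_pins_response(self, rng):
        p = sample_population(young_hyper(), 1, 0)[0]
        pinned = replace(
            p, ddm=DDMParams(alpha=p.ddm.alpha,
                             nu={c: 30.0 for c in p.ddm.nu}, t0=p.ddm.t0))
        out = simulate_search_participant(
            pinned, build_search_schedule(1), seed=rng, dt=5e-4)
        present = out[out["target_present"]]
        assert (present["response"] == "present").all()

    def test_choice_proportions_match_density_oracle(self, rng):
        """20,000 simulated passages agree with the closed-form absorption
        probability and the density-implied RT quartiles."""
        from valsearch.wiener import simulate_fpt, wfpt_density
        alpha, nu, t0 = 1.8, 1.1, 0.36
        rt, up = simulate_fpt(alpha, nu, t0, 20_000, rng, dt=2e-4)
        assert abs(up.mean() - boundary_prob(alpha, nu)) < 3 * np.sqrt(0.25 / 20_000) + 0.005
        grid = np.linspace(t0 + 1e-3, t0 + 15, 4000)
        pdf = wfpt_density(grid, alpha, nu, t0, boundary="upper") \
            + wfpt_density(grid, alpha, nu, t0, boundary="lower")
        cdf = np.concatenate([[0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
        cdf /= cdf[-1]
        for q in (0.25, 0.5, 0.75):
            pred = np.interp(q, cdf, grid)
            assert np.quantile(rt, q) == pytest.approx(pred, abs=0.02)


class TestGenerateStudy:
    def test_full_study_shapes(self, tmp_path):
        cfg = StudyConfig(n_young=3, n_old=2)
        study = generate_study(cfg, 7, outdir=tmp_path)
        assert len(study["learning"]) == 5 * 300
        assert len(study["search"]) == 5 * 192
        assert len(study["truth"]) == 5
        assert (tmp_path / "learning_trials.csv").exists()

    def test_rerun_identical(self, tmp_path):
        cfg = StudyConfig(n_young=2, n_old=2)
        a = generate_study(cfg, 5, outdir=tmp_path / "a")
        b = generate_study(cfg, 5, outdir=tmp_path / "b")
        for name in ("learning_trials.csv", "search_trials.csv", "truth.csv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()
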