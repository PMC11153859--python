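"""Wiener first-passage density, absorption probabilities and likelihood."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from valsearch.wiener import (
    DDMParams, wfpt_density, boundary_prob, ddm_loglik, simulate_fpt,
    wfpt_logdensity_fast,
)

PARAM_GRID = [(1.0, 1.5, 0.3), (1.8, 0.8, 0.36), (2.2, -1.2, 0.5), (0.9, 0.0, 0.2)]


class TestDensity:
    def test_zero_below_t0(self):
        assert wfpt_density(0.25, 1.5, 2.0, t0=0.3) == 0.0
        assert wfpt_density(0.3, 1.5, 2.0, t0=0.3) == 0.0

    def test_drift_free_symmetry(self):
        t = np.linspace(0.31, 4.0, 50)
        up = wfpt_density(t, 1.4, 0.0, 0.3, boundary="upper")
        lo = wfpt_density(t, 1.4, 0.0, 0.3, boundary="lower")
        np.testing.assert_array_equal(up, lo)

    @pytest.mark.parametrize("alpha,nu,t0", PARAM_GRID)
    def test_normalisation(self, alpha, nu, t0):
        total = sum(
            quad(lambda t: wfpt_density(t, alpha, nu, t0, boundary=b),
                 t0, t0 + 80.0, limit=300)[0]
            for b in ("upper", "lower"))
        assert total == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("alpha,nu,t0", PARAM_GRID)
    def test_boundary_prob_matches_quadrature(self, alpha, nu, t0):
        upper = quad(lambda t: wfpt_density(t, alpha, nu, t0, boundary="upper"),
                     t0, t0 + 80.0, limit=300)[0]
        assert boundary_prob(alpha, nu) == pytest.approx(upper, abs=1e-3)

    def test_boundary_prob_limits(self):
        assert boundary_prob(1.5, 0.0) == pytest.approx(0.5)
        assert boundary_prob(1.5, 50.0) == pytest.approx(1.0)
        assert boundary_prob(1.5, -50.0, boundary="lower") == pytest.approx(1.0)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            wfpt_density(1.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            boundary_prob(0.0, 1.0)

    def test_fast_log_kernel_agrees(self, rng):
        """Compiled log-density path vs the series reference path."""
        t = rng.uniform(0.32, 5.0, 2000)
        a = rng.uniform(0.7, 2.8, 2000)
        v = rng.uniform(-3.5, 3.5, 2000)
        up = rng.random(2000) < 0.5
        fast = wfpt_logdensity_fast(t, a, v, 0.3, up)
        ref = np.empty_like(t)
        ref[up] = wfpt_density(t[up], a[up], v[up], 0.3, boundary="upper")
        ref[~up] = wfpt_density(t[~up], a[~up], v[~up], 0.3, boundary="lower")
        np.testing.assert_allclose(fast, np.log(np.maximum(ref, 1e-300)), atol=1e-8)

    def test_fast_log_kernel_finite_for_wild_parameters(self, rng):
        a = 10.0 ** rng.uniform(-150, 150, 5000)
        v = rng.uniform(-500, 500, 5000)
        t = rng.uniform(0.301, 8.0, 5000)
        out = wfpt_logdensity_fast(t, a, v, 0.3, rng.random(5000) < 0.5)
        assert np.isfinite(out).all()

    def test_matches_euler_maruyama(self, rng):
        """Simulation oracle at moderate scale (the large-scale version of
        this check runs in the acceptance suite)."""
        alpha, nu, t0 = 1.4, 1.2, 0.3
        rt, up = simulate_fpt(alpha, nu, t0, 30_000, rng, dt=2e-4)
        assert abs(up.mean() - boundary_prob(alpha, nu)) < 0.01
        grid = np.linspace(t0 + 1e-3, t0 + 12, 3000)
        pdf = wfpt_density(grid, alpha, nu, t0, boundary="upper") \
            + wfpt_density(grid, alpha, nu, t0, boundary="lower")
        cdf = np.concatenate([[0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
        srt = np.sort(rt)
        emp = np.arange(1, srt.size + 1) / srt.size
        ks = np.max(np.abs(np.interp(srt, grid, cdf) - emp))
        assert ks < 0.02

    def test_mean_decision_time_decreases_in_drift(self):
        """E[T] from the density matches the closed form (a/2v)tanh(va/2)
        and decreases in |nu| at fixed alpha."""
        alpha, t0 = 1.6, 0.0
        means = []
        for nu in (0.5, 1.0, 2.0, 3.0):
            m = sum(
                quad(lambda t: t * wfpt_density(t, alpha, nu, t0, boundary=b),
                     0, 80.0, limit=300)[0]
                for b in ("upper", "lower"))
            closed = (alpha / (2 * nu)) * np.tanh(nu * alpha / 2)
            assert m == pytest.approx(closed, rel=1e-3)
            means.append(m)
        assert all(x > y for x, y in zip(means, means[1:]))


class TestLoglik:
    def _trials(self, rt, resp, cond="reward"):
        return pd.DataFrame({
            "condition": cond, "target_present": True,
            "response": resp, "rt_sec": rt,
        })

    def _params(self, **kw):
        kw.setdefault("alpha", {c: 1.5 for c in ("reward", "punishment", "zero")})
        kw.setdefault("nu", {c: 1.0 for c in ("reward", "punishment", "zero")})
        kw.setdefault("t0", 0.3)
        return DDMParams(**kw)

    def test_symmetric_response_equality(self):
        p = self._params(nu={c: 0.0 for c in ("reward", "punishment", "zero")})
        a = ddm_loglik(p, self._trials([0.8], ["present"]))
        b = ddm_loglik(p, self._trials([0.8], ["absent"]))
        assert a == pytest.approx(b)

    def test_empty_is_zero(self):
        assert ddm_loglik(self._params(), self._trials([], [])) == 0.0

    def test_rt_below_t0_errors(self):
        with pytest.raises(ValueError, match="t0"):
            ddm_loglik(self._params(t0=0.5), self._trials([0.4], ["present"]))

    def test_z_fixed(self):
        with pytest.raises(ValueError, match="fixed"):
            self._params(z=0.4)

    def test_contaminant_mixture_and_trimming(self):
        p = self._params()
        t = self._trials([0.8, 12.0], ["present", "present"])
        # trimming drops the slow outlier entirely
        base = ddm_loglik(p, self._trials([0.8], ["present"]))
        assert ddm_loglik(p, t, trim_above=10.0) == pytest.approx(base)
        # a small uniform contaminant floor rescues outlier likelihoods
        with_mix = ddm_loglik(p, t, contaminant_weight=0.02,
                              contaminant_ceiling=15.0)
        assert with_mix > ddm_loglik(p, t)
        with pytest.raises(ValueError):
            ddm_loglik(p, t, contaminant_weight=1.5)

    def test_true_parameters_beat_perturbed(self, rng):
        """Self-consistency: on simulated data the likelihood at the
        generating drift exceeds the likelihood at nu +/- 50%."""
        alpha, nu, t0 = 1.5, 1.4, 0.3
        rt, up = simulate_fpt(alpha, nu, t0, 5000, rng, dt=2e-4)
        trials = self._trials(rt, np.where(up, "present", "absent"))
        base = {c: alpha for c in ("reward", "punishment", "zero")}
        ll = {f: ddm_loglik(DDMParams(
            alpha=base, nu={c: nu * f for c in base}, t0=t0), trials)
            for f in (0.5, 1.0, 1.5)}
        assert ll[1.0] > ll[0.5] and ll[1.0] > ll[1.5]
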