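"""Hierarchical Bayesian estimation for the learning and diffusion models.

Both models share one hierarchy: participant parameters live on
unconstrained scales (logit for learning rates, log for inverse
temperatures and boundary separations, raw for drift rates) and are drawn
from group-level Normal distributions with weakly-informative priors —
Normal(0, 1) locations, HalfNormal(1) scales, and for the diffusion model
an LKJ(2)-type prior on the within-condition correlation between
log-boundary and drift.  The non-decision time t0 is a single
population-level parameter bounded by the minimum observed RT; the start
point z is fixed at 0.5 and never sampled.

Sampling is adaptive random-walk Metropolis-within-Gibbs.  Because the
likelihood factorises over participants given the group level, all
participant blocks are proposed and accepted/rejected simultaneously in
vectorised form; group locations are updated by conjugate Gibbs steps and
group scales/correlations by small Metropolis moves.  Proposal scales
adapt toward a 30% acceptance rate during burn-in only, so the kept chain
is Markovian.  The contract is draws plus diagnostics: every stored
parameter gets a split-R-hat, and any value above 1.05 triggers a warning
and a flag in the summary rather than silent success.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import CONDITIONS
from .rw import rl_cond_loglik, trials_to_arrays
from .wiener import wfpt_density, wfpt_logdensity_fast

__all__ = [
    "MCMCConfig", "Posterior", "PosteriorSummary", "GroupContrast",
    "fit_rl_hierarchical", "fit_ddm_hierarchical", "rhat",
    "group_contrast", "posterior_predictive", "sample_rt_from_density",
]

_expit = lambda x: 1.0 / (1.0 + np.exp(-x))
_logit = lambda p: np.log(p / (1.0 - p))

RHAT_FLAG = 1.05


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration.

    The desk-scale default is 1,000 kept iterations after 1,000 burn-in
    across 4 chains; :meth:`full_scale` returns the 5,000/5,000/4 setting
    used for full-scale runs.
    """

    iterations: int = 1000
    burn_in: int = 1000
    chains: int = 4
    seed: int = 0
    model: str = "rl"
    thin: int = 5

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.burn_in < 1:
            raise ValueError("iterations and burn_in must be >= 1")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if self.model not in ("rl", "ddm"):
            raise ValueError(f"model must be 'rl' or 'ddm', got {self.model!r}")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def full_scale(cls, **kw) -> "MCMCConfig":
        kw.setdefault("iterations", 5000)
        kw.setdefault("burn_in", 5000)
        kw.setdefault("chains", 4)
        return cls(**kw)


@dataclass(frozen=True)
class PosteriorSummary:
    parameter: str
    level: str                  # "group" or "individual"
    mean: float
    mode: float
    ci95: tuple[float, float]
    rhat: float

    @property
    def converged(self) -> bool:
        return self.rhat <= RHAT_FLAG


@dataclass(frozen=True)
class GroupContrast:
    parameter: str
    mean_diff: float
    ci95: tuple[float, float]


def rhat(draws) -> float:
    """Split R-hat convergence diagnostic.

    ``draws`` is an (m, n) array of m >= 2 chains of equal length n.  Each
    chain is split in half (2m half-chains), and the statistic is
    sqrt(((n-1)/n + B/(n W))) with B/W the between/within half-chain
    variances.  Approximately 1 for well-mixed chains.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("rhat needs an (m >= 2, n) array of chain draws")
    m, n = x.shape
    half = n // 2
    splits = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    n = half
    means = splits.mean(axis=1)
    W = splits.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else np.inf
    return float(np.sqrt((n - 1) / n + B / (n * W)))


@dataclass
class Posterior:
    """Posterior draws keyed by parameter name.

    ``draws[name]`` has shape (chains, iterations).  ``level`` maps each
    name to "group" or "individual"; ``meta`` records participant ids,
    the model and the data bound (e.g. min RT for the diffusion model).
    """

    draws: dict[str, np.ndarray]
    level: dict[str, str]
    config: MCMCConfig
    meta: dict = field(default_factory=dict)

    def flat(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def rhats(self) -> dict[str, float]:
        return {name: rhat(d) for name, d in self.draws.items()}

    def summary(self) -> pd.DataFrame:
        from .linking import posterior_mode
        rows = []
        for name, d in self.draws.items():
            flatd = d.reshape(-1)
            lo, hi = np.percentile(flatd, [2.5, 97.5])
            rows.append(PosteriorSummary(
                parameter=name, level=self.level[name],
                mean=float(flatd.mean()), mode=float(posterior_mode(flatd)),
                ci95=(float(lo), float(hi)), rhat=rhat(d)))
        df = pd.DataFrame([{
            "parameter": s.parameter, "level": s.level, "mean": s.mean,
            "mode": s.mode, "ci_lo": s.ci95[0], "ci_hi": s.ci95[1],
            "rhat": s.rhat, "converged": s.converged} for s in rows])
        return df

    def individual_table(self, stat: str = "mean") -> pd.DataFrame:
        """Per-participant point estimates, wide (one row per participant)."""
        from .linking import posterior_mode
        cells: dict[str, dict[str, float]] = {}
        for name, lvl in self.level.items():
            if lvl != "individual" or "[" not in name:
                continue
            base, pid = name[:-1].split("[")
            flatd = self.flat(name)
            val = float(flatd.mean()) if stat == "mean" else float(posterior_mode(flatd))
            cells.setdefault(pid, {})[base] = val
        out = pd.DataFrame.from_dict(cells, orient="index").sort_index()
        out.index.name = "participant_id"
        return out.reset_index()

    def save(self, outdir) -> None:
        from pathlib import Path
        import json
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        chains, iters = next(iter(self.draws.values())).shape
        frames = []
        for name, d in self.draws.items():
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(chains), iters),
                "iteration": np.tile(np.arange(iters), chains),
                "parameter": name,
                "value": d.reshape(-1),
            }))
        pd.concat(frames, ignore_index=True).to_csv(outdir / "draws.csv", index=False)
        summ = self.summary()
        summ.to_csv(outdir / "summary.csv", index=False)
        with open(outdir / "posterior.json", "w") as fh:
            json.dump({
                "model": self.config.model,
                "config": {"iterations": self.config.iterations,
                           "burn_in": self.config.burn_in,
                           "chains": self.config.chains,
                           "seed": self.config.seed,
                           "thin": self.config.thin},
                "level": self.level, "meta": self.meta,
                "max_rhat": float(summ["rhat"].max()),
            }, fh, indent=2)

    @classmethod
    def load(cls, outdir) -> "Posterior":
        from pathlib import Path
        import json
        outdir = Path(outdir)
        with open(outdir / "posterior.json") as fh:
            info = json.load(fh)
        long = pd.read_csv(outdir / "draws.csv")
        chains = int(long["chain"].max()) + 1
        draws = {}
        for name, sub in long.groupby("parameter", sort=False):
            draws[name] = sub["value"].to_numpy().reshape(chains, -1)
        cfg = MCMCConfig(model=info["model"], **info["config"])
        return cls(draws=draws, level=info["level"], config=cfg, meta=info["meta"])


def _check_rhats(post: Posterior) -> None:
    worst = max(post.rhats().items(), key=lambda kv: kv[1])
    if worst[1] > RHAT_FLAG:
        warnings.warn(
            f"MCMC may not have converged: R-hat({worst[0]}) = {worst[1]:.3f} "
            f"> {RHAT_FLAG}; inspect the flagged rows of summary()",
            RuntimeWarning, stacklevel=3)


def _adapt(log_scale, accepted, it, target=0.3):
    """Robbins–Monro proposal-scale adaptation (burn-in only)."""
    gamma = (it + 1.0) ** -0.6
    return log_scale + gamma * (accepted - target)


# ---------------------------------------------------------------------------
# Reinforcement-learning model
# ---------------------------------------------------------------------------

_RL_NAMES = ("eta_r", "eta_p", "tau_r", "tau_p")
# participant parameters are updated in two 2-D blocks matching the
# likelihood factorisation: (logit eta_r, log tau_r) and (logit eta_p,
# log tau_p); columns of X are [logit eta_r, logit eta_p, log tau_r, log tau_p]
_RL_BLOCKS = {"r": (0, 2), "p": (1, 3)}
_RL_BASE_STEP = np.array([0.35, 0.20])


def _run_rl_chains(data, n, chains, iterations, burn_in, thin, rng):
    """All chains advance together (chains are a vectorised batch axis).

    Each kept iteration advances the chain ``thin`` sweeps; burn-in counts
    iterations on the same footing, so the total sweep budget is
    ``(burn_in + iterations) * thin`` with adaptation active during the
    first ``burn_in * thin`` sweeps only.
    """
    C = chains
    burn_sweeps = burn_in * thin
    total = (burn_in + iterations) * thin
    mu = np.array([_logit(0.08), _logit(0.08), np.log(4.0), np.log(4.0)]) \
        + 0.5 * rng.standard_normal((C, 4))          # dispersed chain starts
    sigma = 0.3 + 0.4 * np.abs(rng.standard_normal((C, 4)))
    X = mu[:, None, :] + sigma[:, None, :] * rng.standard_normal((C, n, 4))
    ll = {
        "r": rl_cond_loglik(_expit(X[..., 0]), np.exp(X[..., 2]),
                            data["chose_r"], data["out_r"]),
        "p": rl_cond_loglik(_expit(X[..., 1]), np.exp(X[..., 3]),
                            data["chose_p"], data["out_p"]),
    }
    log_scale = {k: np.zeros((C, n)) for k in _RL_BLOCKS}
    log_scale_nc = {k: np.zeros(C) for k in _RL_BLOCKS}
    # running mean/covariance of each participant block (Haario-style
    # adaptive proposals, frozen after burn-in)
    prop_mean = {k: X[..., list(v)].copy() for k, v in _RL_BLOCKS.items()}
    prop_cov = {k: np.tile(np.diag(_RL_BASE_STEP**2), (C, n, 1, 1))
                for k in _RL_BLOCKS}
    prop_chol = {k: np.linalg.cholesky(prop_cov[k]) for k in _RL_BLOCKS}

    kept_X = np.empty((iterations, C, n, 4))
    kept_mu = np.empty((iterations, C, 4))
    kept_sigma = np.empty((iterations, C, 4))

    burn_in = burn_sweeps          # adaptation horizon, in sweeps
    for it in range(total):
        # --- participant blocks, all chains and participants at once -------
        for key, (je, jt) in _RL_BLOCKS.items():
            # 20% of proposals are independence draws from the conditional
            # prior N(mu, sigma): participants with near-flat likelihood
            # (e.g. unidentified tau at tiny eta) accept these at rate ~1,
            # where a random walk would crawl
            indep = rng.random((C, n)) < 0.2
            jump = np.exp(0.6 * rng.standard_normal((C, n, 1)))
            step = np.exp(log_scale[key])[..., None] * jump
            noise = np.einsum("cnij,cnj->cni", prop_chol[key],
                              rng.standard_normal((C, n, 2)))
            rw_prop = X[..., [je, jt]] + step * noise
            pr_prop = (mu[:, None, [je, jt]]
                       + sigma[:, None, [je, jt]] * rng.standard_normal((C, n, 2)))
            prop = np.where(indep[..., None], pr_prop, rw_prop)
            llp = rl_cond_loglik(_expit(prop[..., 0]), np.exp(prop[..., 1]),
                                 data[f"chose_{key}"], data[f"out_{key}"])
            dpr = np.zeros((C, n))
            for d, j in enumerate((je, jt)):
                mu_j = mu[:, j, None]
                sg_j = sigma[:, j, None]
                dpr += (-0.5 * ((prop[..., d] - mu_j) / sg_j) ** 2
                        + 0.5 * ((X[..., j] - mu_j) / sg_j) ** 2)
            # prior-independence proposals cancel the prior ratio exactly
            logr = (llp - ll[key]) + np.where(indep, 0.0, dpr)
            accept = np.log(rng.random((C, n))) < logr
            for d, j in enumerate((je, jt)):
                X[..., j] = np.where(accept, prop[..., d], X[..., j])
            ll[key] = np.where(accept, llp, ll[key])
            if it < burn_in:
                # adapt the random-walk scale on random-walk proposals only
                log_scale[key] = _adapt(
                    log_scale[key],
                    np.where(indep, 0.3, accept.astype(float)), it)
                gam = (it + 2.0) ** -0.6
                blk = X[..., [je, jt]]
                prop_mean[key] += gam * (blk - prop_mean[key])
                dev = blk - prop_mean[key]
                prop_cov[key] += gam * (dev[..., :, None] * dev[..., None, :]
                                        - prop_cov[key])
                if it % 25 == 24:
                    prop_chol[key] = np.linalg.cholesky(
                        prop_cov[key] + 1e-5 * np.eye(2))

        # --- group location: conjugate Gibbs (prior N(0,1)) ----------------
        prec = 1.0 + n / sigma**2
        mean = (X.sum(axis=1) / sigma**2) / prec
        mu = mean + rng.standard_normal((C, 4)) / np.sqrt(prec)

        # --- group scale: Metropolised independence draw --------------------
        # proposal = the inverse-gamma conditional implied by the Normal
        # likelihood alone; the HalfNormal(1) prior enters via the (near-1)
        # acceptance ratio, so sigma draws are conditionally near-independent
        ssq = ((X - mu[:, None, :]) ** 2).sum(axis=1)
        sp2 = (ssq / 2.0) / rng.gamma((n - 1) / 2.0, 1.0, size=(C, 4))
        acc_s = np.log(rng.random((C, 4))) < -(sp2 - sigma**2) / 2.0
        sigma = np.where(acc_s, np.sqrt(sp2), sigma)

        # --- interweaved non-centered move ---------------------------------
        # Holding the standardised effects eps = (X - mu)/sigma fixed,
        # propose (mu, log sigma) jointly and translate/rescale all
        # participants with them.  This breaks the centred-hierarchy funnel
        # that slows mixing of the group scales.
        for key, dims in _RL_BLOCKS.items():
            dims = list(dims)
            eps = (X[..., dims] - mu[:, None, dims]) / sigma[:, None, dims]
            # heavy-tailed step mixture: occasional large jumps let chains
            # cross the low-scale funnel neck and flat-likelihood plateaus
            jump = np.exp(0.8 * rng.standard_normal((C, 1)))
            step = np.exp(log_scale_nc[key])[:, None] * jump
            # alternate sweeps between a pure rescale (group scale) and a
            # pure shift (group location); separate moves accept better
            # than a joint proposal in both directions
            if it % 2 == 0:
                mu_p = mu[:, dims].copy()
                lsig_p = np.log(sigma[:, dims]) + 0.3 * step * rng.standard_normal((C, 2))
            else:
                mu_p = mu[:, dims] + 0.2 * step * rng.standard_normal((C, 2))
                lsig_p = np.log(sigma[:, dims])
            sig_p = np.exp(lsig_p)
            Xp = mu_p[:, None, :] + sig_p[:, None, :] * eps
            llp = rl_cond_loglik(_expit(Xp[..., 0]), np.exp(Xp[..., 1]),
                                 data[f"chose_{key}"], data[f"out_{key}"])
            dpr = (-0.5 * mu_p**2 + 0.5 * mu[:, dims] ** 2
                   - 0.5 * sig_p**2 + np.log(sig_p)
                   + 0.5 * sigma[:, dims] ** 2 - np.log(sigma[:, dims])).sum(axis=1)
            accept = np.log(rng.random(C)) < (llp.sum(axis=1) - ll[key].sum(axis=1)) + dpr
            for d, j in enumerate(dims):
                X[..., j] = np.where(accept[:, None], Xp[..., d], X[..., j])
                mu[:, j] = np.where(accept, mu_p[:, d], mu[:, j])
                sigma[:, j] = np.where(accept, sig_p[:, d], sigma[:, j])
            ll[key] = np.where(accept[:, None], llp, ll[key])
            if it < burn_in:
                log_scale_nc[key] = _adapt(log_scale_nc[key], accept.astype(float), it,
                                           target=0.25)

        if it >= burn_sweeps and (it - burn_sweeps) % thin == thin - 1:
            k = (it - burn_sweeps) // thin
            kept_X[k] = X
            kept_mu[k] = mu
            kept_sigma[k] = sigma
    # reorder to (chains, iterations, ...)
    return (kept_X.transpose(1, 0, 2, 3), kept_mu.transpose(1, 0, 2),
            kept_sigma.transpose(1, 0, 2))


def fit_rl_hierarchical(trials: pd.DataFrame, config: MCMCConfig) -> Posterior:
    """Fit the dual-learning-rate model to one population of participants.

    ``trials`` holds learning records for >= 2 participants (zero-condition
    trials are excluded internally).  Returns a :class:`Posterior` with
    individual draws (natural scale), group-level locations mapped to the
    natural scale, their transformed-scale locations/scales, and the
    derived group contrasts eta_r - eta_p and tau_r - tau_p.
    """
    pids = list(pd.unique(trials["participant_id"]))
    if len(pids) < 2:
        raise ValueError("hierarchical fit needs >= 2 participants")
    data = trials_to_arrays(trials, pids)
    if data["chose_r"].shape[1] == 0 and data["chose_p"].shape[1] == 0:
        raise ValueError("no reward/punishment trials present")
    n = len(pids)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    X, mu, sig = _run_rl_chains(data, n, config.chains, config.iterations,
                                config.burn_in, config.thin, rng)

    draws: dict[str, np.ndarray] = {}
    level: dict[str, str] = {}
    nat_group = [_expit(mu[..., 0]), _expit(mu[..., 1]), np.exp(mu[..., 2]), np.exp(mu[..., 3])]
    for j, name in enumerate(_RL_NAMES):
        draws[name] = nat_group[j]
        level[name] = "group"
        draws[f"mu_{name}"] = mu[..., j]
        level[f"mu_{name}"] = "group"
        draws[f"sigma_{name}"] = sig[..., j]
        level[f"sigma_{name}"] = "group"
    draws["eta_r_minus_eta_p"] = nat_group[0] - nat_group[1]
    draws["tau_r_minus_tau_p"] = nat_group[2] - nat_group[3]
    level["eta_r_minus_eta_p"] = level["tau_r_minus_tau_p"] = "group"
    nat_ind = [_expit(X[..., 0]), _expit(X[..., 1]), np.exp(X[..., 2]), np.exp(X[..., 3])]
    for j, name in enumerate(_RL_NAMES):
        for i, pid in enumerate(pids):
            draws[f"{name}[{pid}]"] = nat_ind[j][..., i]
            level[f"{name}[{pid}]"] = "individual"

    post = Posterior(draws=draws, level=level, config=replace(config, model="rl"),
                     meta={"participants": pids, "model": "rl"})
    _check_rhats(post)
    return post


# ---------------------------------------------------------------------------
# Drift-diffusion model
# ---------------------------------------------------------------------------

_DDM_BASE_STEP = np.array([0.08, 0.15])   # (log alpha, nu)


def _ddm_pack(trials: pd.DataFrame, pids: list) -> dict:
    """Flatten target-present trials per condition with participant index."""
    present = trials[trials["target_present"].astype(bool)]
    pid_index = {p: i for i, p in enumerate(pids)}
    packed = {}
    for c, cond in enumerate(CONDITIONS):
        sub = present[present["condition"] == cond]
        packed[cond] = {
            "rt": sub["rt_sec"].to_numpy(float),
            "upper": (sub["response"].to_numpy() == "present"),
            "pidx": sub["participant_id"].map(pid_index).to_numpy(int),
        }
    packed["rt_min"] = float(present["rt_sec"].min())
    return packed


def _ddm_cond_loglik_chains(pack_c, alpha, nu, t0, n) -> np.ndarray:
    """Per-(chain, participant) log-likelihood for one condition.

    ``alpha``/``nu`` have shape (C, n); ``t0`` shape (C,).  Returns (C, n).
    """
    rt, upper, pidx = pack_c["rt"], pack_c["upper"], pack_c["pidx"]
    C = alpha.shape[0]
    out = np.empty((C, n))
    for c in range(C):
        logf = wfpt_logdensity_fast(rt, alpha[c, pidx], nu[c, pidx],
                                    float(t0[c]), upper)
        out[c] = np.bincount(pidx, weights=logf, minlength=n)
    return out


def _run_ddm_chains(pack, n, chains, iterations, burn_in, thin, rng):
    """All chains advance together; sweep bookkeeping as in the RL sampler."""
    C = chains
    ncond = len(CONDITIONS)
    rt_min = pack["rt_min"]
    burn_sweeps = burn_in * thin
    total = (burn_in + iterations) * thin

    mu = np.array([np.log(1.5), 1.0]) + 0.4 * rng.standard_normal((C, ncond, 2))
    sigma = 0.2 + 0.3 * np.abs(rng.standard_normal((C, ncond, 2)))
    rho = np.zeros((C, ncond))
    Y = mu[:, None, :, :] + sigma[:, None, :, :] * rng.standard_normal((C, n, ncond, 2))
    u = _logit(0.7) + 0.3 * rng.standard_normal(C)
    t0 = rt_min * _expit(u)

    L = np.stack([_ddm_cond_loglik_chains(pack[c], np.exp(Y[:, :, j, 0]),
                                          Y[:, :, j, 1], t0, n)
                  for j, c in enumerate(CONDITIONS)], axis=2)      # (C, n, ncond)
    log_scale = np.zeros((C, n, ncond))
    log_scale_t0 = np.full(C, np.log(0.1))
    log_scale_grp = np.zeros((C, ncond))
    log_scale_nc = np.zeros((C, ncond))
    prop_mean = Y.copy()                                            # (C, n, ncond, 2)
    prop_cov = np.tile(np.diag(_DDM_BASE_STEP**2), (C, n, ncond, 1, 1))
    prop_chol = np.linalg.cholesky(prop_cov)

    kept_Y = np.empty((iterations, C, n, ncond, 2))
    kept_mu = np.empty((iterations, C, ncond, 2))
    kept_sigma = np.empty((iterations, C, ncond, 2))
    kept_rho = np.empty((iterations, C, ncond))
    kept_t0 = np.empty((iterations, C))

    def bvn_lp(Yj, mu_j, sig_j, rho_j):
        """(C, n) bivariate normal logpdf with per-chain parameters."""
        z0 = (Yj[..., 0] - mu_j[:, None, 0]) / sig_j[:, None, 0]
        z1 = (Yj[..., 1] - mu_j[:, None, 1]) / sig_j[:, None, 1]
        r = rho_j[:, None]
        q = (z0**2 - 2 * r * z0 * z1 + z1**2) / (1 - r**2)
        return -0.5 * q - np.log(2 * np.pi * sig_j[:, None, 0] * sig_j[:, None, 1]
                                 * np.sqrt(1 - r**2))

    for it in range(total):
        # --- participant (log alpha, nu) blocks per condition --------------
        for j, cond in enumerate(CONDITIONS):
            indep = rng.random((C, n)) < 0.2
            jump = np.exp(0.6 * rng.standard_normal((C, n, 1)))
            step = np.exp(log_scale[:, :, j])[..., None] * jump
            noise = np.einsum("cnij,cnj->cni", prop_chol[:, :, j],
                              rng.standard_normal((C, n, 2)))
            rw_prop = Y[:, :, j, :] + step * noise
            zdraw = rng.standard_normal((C, n, 2))
            r = rho[:, j][:, None]
            corr_noise = np.stack([
                zdraw[..., 0],
                r * zdraw[..., 0] + np.sqrt(1 - r**2) * zdraw[..., 1]], axis=-1)
            pr_prop = mu[:, None, j, :] + sigma[:, None, j, :] * corr_noise
            prop = np.where(indep[..., None], pr_prop, rw_prop)
            Lp = _ddm_cond_loglik_chains(pack[cond], np.exp(prop[..., 0]),
                                         prop[..., 1], t0, n)
            dpr = bvn_lp(prop, mu[:, j], sigma[:, j], rho[:, j]) \
                - bvn_lp(Y[:, :, j, :], mu[:, j], sigma[:, j], rho[:, j])
            logr = (Lp - L[:, :, j]) + np.where(indep, 0.0, dpr)
            accept = np.log(rng.random((C, n))) < logr
            Y[:, :, j, :] = np.where(accept[..., None], prop, Y[:, :, j, :])
            L[:, :, j] = np.where(accept, Lp, L[:, :, j])
            if it < burn_sweeps:
                log_scale[:, :, j] = _adapt(
                    log_scale[:, :, j],
                    np.where(indep, 0.3, accept.astype(float)), it)
                gam = (it + 2.0) ** -0.6
                blk = Y[:, :, j, :]
                prop_mean[:, :, j] += gam * (blk - prop_mean[:, :, j])
                dev = blk - prop_mean[:, :, j]
                prop_cov[:, :, j] += gam * (dev[..., :, None] * dev[..., None, :]
                                            - prop_cov[:, :, j])
                if it % 25 == 24:
                    prop_chol[:, :, j] = np.linalg.cholesky(
                        prop_cov[:, :, j] + 1e-5 * np.eye(2))

        # --- population t0: per-chain MH on the bounded logit scale --------
        up = u + np.exp(log_scale_t0) * rng.standard_normal(C)
        t0p = rt_min * _expit(up)
        Lp_all = np.stack([
            _ddm_cond_loglik_chains(pack[c], np.exp(Y[:, :, j, 0]),
                                    Y[:, :, j, 1], t0p, n)
            for j, c in enumerate(CONDITIONS)], axis=2)
        s_new, s_cur = _expit(up), _expit(u)
        dpr = (np.log(s_new) + np.log1p(-s_new)) - (np.log(s_cur) + np.log1p(-s_cur))
        acc_t0 = np.log(rng.random(C)) < (
            Lp_all.sum(axis=(1, 2)) - L.sum(axis=(1, 2))) + dpr
        u = np.where(acc_t0, up, u)
        t0 = np.where(acc_t0, t0p, t0)
        L = np.where(acc_t0[:, None, None], Lp_all, L)
        if it < burn_sweeps:
            log_scale_t0 = _adapt(log_scale_t0, acc_t0.astype(float), it, target=0.4)

        # --- group level per condition (cheap; loop over chains) -----------
        for j in range(ncond):
            Yj = Y[:, :, j, :]                                      # (C, n, 2)
            for c in range(C):
                s1, s2 = sigma[c, j]
                r = rho[c, j]
                cov_j = np.array([[s1**2, r * s1 * s2], [r * s1 * s2, s2**2]])
                Sinv = np.linalg.inv(cov_j)
                prec = np.eye(2) + n * Sinv
                covp = np.linalg.inv(prec)
                mean = covp @ (Sinv @ Yj[c].sum(axis=0))
                mu[c, j] = mean + np.linalg.cholesky(covp) @ rng.standard_normal(2)

            raw = np.concatenate([np.log(sigma[:, j]), np.arctanh(rho[:, j])[:, None]],
                                 axis=1)                            # (C, 3)
            rawp = raw + np.exp(log_scale_grp[:, j])[:, None] * 0.15 \
                * rng.standard_normal((C, 3))
            sn = np.exp(rawp[:, :2])
            rn = np.tanh(rawp[:, 2])

            def grp_lp(sig_j, rho_j):
                lp = bvn_lp(Yj, mu[:, j], sig_j, rho_j).sum(axis=1)
                lp += (-0.5 * sig_j**2 + np.log(sig_j)).sum(axis=1)  # HalfNormal+Jac
                lp += np.log1p(-rho_j**2)                            # LKJ(2)
                lp += np.log1p(-rho_j**2)                            # tanh Jacobian
                return lp

            acc_g = np.log(rng.random(C)) < grp_lp(sn, rn) - grp_lp(sigma[:, j], rho[:, j])
            sigma[:, j] = np.where(acc_g[:, None], sn, sigma[:, j])
            rho[:, j] = np.where(acc_g, rn, rho[:, j])
            if it < burn_sweeps:
                log_scale_grp[:, j] = _adapt(log_scale_grp[:, j],
                                             acc_g.astype(float), it)

        # --- interweaved rescale of the group scales (every other sweep) ---
        # holding standardised residuals fixed, rescale (log alpha, nu)
        # around the group location; diagonal rescaling preserves the
        # within-condition correlation, so only the HalfNormal scale prior
        # and the likelihood enter the ratio
        if it % 2 == 0:
            for j, cond in enumerate(CONDITIONS):
                jumpg = np.exp(0.8 * rng.standard_normal((C, 1)))
                stepg = np.exp(log_scale_nc[:, j])[:, None] * jumpg
                sig_p = sigma[:, j] * np.exp(0.3 * stepg * rng.standard_normal((C, 2)))
                ratio = (sig_p / sigma[:, j])[:, None, :]
                Yp = mu[:, None, j, :] + (Y[:, :, j, :] - mu[:, None, j, :]) * ratio
                Lp = _ddm_cond_loglik_chains(pack[cond], np.exp(Yp[..., 0]),
                                             Yp[..., 1], t0, n)
                dpr = (-0.5 * sig_p**2 + np.log(sig_p)
                       + 0.5 * sigma[:, j] ** 2 - np.log(sigma[:, j])).sum(axis=1)
                acc = np.log(rng.random(C)) < (Lp.sum(axis=1)
                                               - L[:, :, j].sum(axis=1)) + dpr
                Y[:, :, j, :] = np.where(acc[:, None, None], Yp, Y[:, :, j, :])
                sigma[:, j] = np.where(acc[:, None], sig_p, sigma[:, j])
                L[:, :, j] = np.where(acc[:, None], Lp, L[:, :, j])
                if it < burn_sweeps:
                    log_scale_nc[:, j] = _adapt(log_scale_nc[:, j],
                                                acc.astype(float), it, target=0.25)

        if it >= burn_sweeps and (it - burn_sweeps) % thin == thin - 1:
            k = (it - burn_sweeps) // thin
            kept_Y[k] = Y
            kept_mu[k] = mu
            kept_sigma[k] = sigma
            kept_rho[k] = rho
            kept_t0[k] = t0
    return (kept_Y.transpose(1, 0, 2, 3, 4), kept_mu.transpose(1, 0, 2, 3),
            kept_sigma.transpose(1, 0, 2, 3), kept_rho.transpose(1, 0, 2),
            kept_t0.transpose(1, 0))


def fit_ddm_hierarchical(trials: pd.DataFrame, config: MCMCConfig) -> Posterior:
    """Fit the hierarchical diffusion model to target-present search trials.

    Individual (alpha, nu) pairs per condition share a correlated
    group-level bivariate prior; t0 is a single population parameter
    bounded by the minimum observed RT; z stays fixed at 0.5 and is never
    sampled.  Trials with rt at or below a feasible t0 would make the
    likelihood undefined; the bounded t0 parameterisation guarantees
    t0 < min(rt) instead of erroring per trial.
    """
    present = trials[trials["target_present"].astype(bool)]
    pids = list(pd.unique(present["participant_id"]))
    if len(pids) < 2:
        raise ValueError("hierarchical fit needs >= 2 participants with present trials")
    if (present["rt_sec"] <= 0).any():
        bad = present.index[present["rt_sec"] <= 0].tolist()
        raise ValueError(f"non-positive RTs at rows {bad[:10]}")
    pack = _ddm_pack(trials, pids)
    n = len(pids)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    Y, mu, sig, rho, t0 = _run_ddm_chains(
        pack, n, config.chains, config.iterations, config.burn_in, config.thin, rng)
    # shapes: Y (chains, iters, n, ncond, 2); mu/sig (chains, iters, ncond, 2)
    # rho (chains, iters, ncond); t0 (chains, iters)

    draws: dict[str, np.ndarray] = {"t0": t0}
    level: dict[str, str] = {"t0": "group"}
    for j, cond in enumerate(CONDITIONS):
        draws[f"alpha_{cond}"] = np.exp(mu[..., j, 0])
        draws[f"nu_{cond}"] = mu[..., j, 1]
        draws[f"rho_{cond}"] = rho[..., j]
        draws[f"sigma_log_alpha_{cond}"] = sig[..., j, 0]
        draws[f"sigma_nu_{cond}"] = sig[..., j, 1]
        for name in (f"alpha_{cond}", f"nu_{cond}", f"rho_{cond}",
                     f"sigma_log_alpha_{cond}", f"sigma_nu_{cond}"):
            level[name] = "group"
        for i, pid in enumerate(pids):
            draws[f"alpha_{cond}[{pid}]"] = np.exp(Y[..., i, j, 0])
            draws[f"nu_{cond}[{pid}]"] = Y[..., i, j, 1]
            level[f"alpha_{cond}[{pid}]"] = "individual"
            level[f"nu_{cond}[{pid}]"] = "individual"

    post = Posterior(draws=draws, level=level, config=replace(config, model="ddm"),
                     meta={"participants": pids, "model": "ddm",
                           "rt_min": pack["rt_min"], "z": 0.5})
    _check_rhats(post)
    return post


# ---------------------------------------------------------------------------
# Posterior contrasts and predictive checks
# ---------------------------------------------------------------------------

def group_contrast(posterior_a: Posterior, posterior_b: Posterior,
                   parameter: str) -> GroupContrast:
    """Draw-wise difference a - b of one group-level parameter."""
    for post in (posterior_a, posterior_b):
        if parameter not in post.draws:
            raise KeyError(f"parameter {parameter!r} not sampled in posterior")
    a = posterior_a.flat(parameter)
    b = posterior_b.flat(parameter)
    if a.size != b.size:
        warnings.warn(
            f"posteriors hold {a.size} vs {b.size} draws of {parameter!r}; "
            "truncating to the common length", RuntimeWarning)
        k = min(a.size, b.size)
        a, b = a[:k], b[:k]
    d = a - b
    lo, hi = np.percentile(d, [2.5, 97.5])
    return GroupContrast(parameter=parameter, mean_diff=float(d.mean()),
                         ci95=(float(lo), float(hi)))


def sample_rt_from_density(alpha: float, nu: float, t0: float, n: int,
                           rng: np.random.Generator, *, z: float = 0.5,
                           grid_points: int = 400, t_max: float = 12.0) -> np.ndarray:
    """Draw RTs (either boundary pooled) by inverting the FPT CDF on a grid."""
    t = np.linspace(t0 + 1e-4, t0 + t_max, grid_points)
    pdf = wfpt_density(t, alpha, nu, t0, z, "upper") \
        + wfpt_density(t, alpha, nu, t0, z, "lower")
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(t))])
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, t)


@dataclass
class PPCResult:
    """Posterior predictive check output.

    ``table`` holds observed statistics with 95% predictive bands;
    ``fraction_within`` is the share of cells whose observed value falls
    inside its band.
    """

    model: str
    table: pd.DataFrame
    fraction_within: float


def posterior_predictive(model: str, posterior: Posterior, trials: pd.DataFrame,
                         seed: int, *, n_draws: int = 50,
                         contingency: float = 0.8) -> PPCResult:
    """Simulate datasets from the fitted posterior and compare to the data.

    For the learning model the statistic is the cross-participant mean
    target-choice proportion per condition and 10-trial block; for the
    diffusion model it is the pooled RT quantile (0.1/0.3/0.5/0.7/0.9) per
    condition on target-present trials.
    """
    if model not in ("rl", "ddm"):
        raise ValueError(f"model must be 'rl' or 'ddm', got {model!r}")
    if not posterior.draws:
        raise ValueError("empty posterior")
    rng = np.random.default_rng(seed)
    chains, iters = next(iter(posterior.draws.values())).shape
    pick = rng.integers(0, chains * iters, size=n_draws)

    if model == "rl":
        from .rw import RWParams, ValueState, simulate_choice
        from .cohort import draw_outcome
        pids = posterior.meta["participants"]
        seqs = {p: trials[(trials["participant_id"] == p)].sort_values("trial")
                for p in pids}
        obs = _rl_block_props(seqs)
        sims = []
        for d in pick:
            props = {}
            for pid in pids:
                params = RWParams(*(posterior.flat(f"{nm}[{pid}]")[d] for nm in _RL_NAMES))
                sub = seqs[pid]
                state = ValueState()
                chose = np.empty(len(sub), dtype=bool)
                for k, cond in enumerate(sub["condition"].to_numpy()):
                    ch = simulate_choice(state, cond, params, rng)
                    chose[k] = ch
                    if cond != "zero":
                        out = draw_outcome(cond, ch, rng, contingency)
                        state.update(cond, ch, out, params.eta(cond))
                props[pid] = pd.DataFrame({
                    "condition": sub["condition"].to_numpy(), "chose_target": chose})
            sims.append(_rl_block_props_from_choices(props))
        sim = np.stack(sims)  # (n_draws, cells)
        lo, hi = np.percentile(sim, [2.5, 97.5], axis=0)
        tab = obs.copy()
        tab["band_lo"], tab["band_hi"] = lo, hi
        tab["within"] = (tab["observed"] >= lo) & (tab["observed"] <= hi)
    else:
        present = trials[trials["target_present"].astype(bool)]
        qs = [0.1, 0.3, 0.5, 0.7, 0.9]
        pids = posterior.meta["participants"]
        rows = []
        for cond in CONDITIONS:
            rts = present[present["condition"] == cond]["rt_sec"].to_numpy()
            for q, val in zip(qs, np.quantile(rts, qs)):
                rows.append({"condition": cond, "quantile": q, "observed": val})
        obs = pd.DataFrame(rows)
        counts = {cond: int((present["condition"] == cond).sum()) for cond in CONDITIONS}
        sims = []
        for d in pick:
            t0 = posterior.flat("t0")[d]
            vals = []
            for cond in CONDITIONS:
                per = max(1, counts[cond] // len(pids))
                pool = [sample_rt_from_density(
                    posterior.flat(f"alpha_{cond}[{pid}]")[d],
                    posterior.flat(f"nu_{cond}[{pid}]")[d], t0, per, rng)
                    for pid in pids]
                vals.extend(np.quantile(np.concatenate(pool), qs))
            sims.append(vals)
        sim = np.stack(sims)
        lo, hi = np.percentile(sim, [2.5, 97.5], axis=0)
        tab = obs.copy()
        tab["band_lo"], tab["band_hi"] = lo, hi
        tab["within"] = (tab["observed"] >= lo) & (tab["observed"] <= hi)
    return PPCResult(model=model, table=tab, fraction_within=float(tab["within"].mean()))


def _rl_block_props(seqs: dict[str, pd.DataFrame]) -> pd.DataFrame:
    props = {pid: sub[["condition", "chose_target"]] for pid, sub in seqs.items()}
    return _rl_block_props_frame(props)


def _rl_block_props_from_choices(props: dict[str, pd.DataFrame]) -> np.ndarray:
    return _rl_block_props_frame(props)["observed"].to_numpy()


def _rl_block_props_frame(props: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Mean target-choice proportion per condition x 10-trial block."""
    rows = []
    for cond in CONDITIONS:
        per = []
        for pid, sub in props.items():
            ch = sub[sub["condition"] == cond]["chose_target"].to_numpy(dtype=float)
            nblk = len(ch) // 10
            per.append(ch[: nblk * 10].reshape(nblk, 10).mean(axis=1))
        mat = np.stack(per)
        for b in range(mat.shape[1]):
            rows.append({"condition": cond, "block": b + 1,
                         "observed": float(mat[:, b].mean())})
    return pd.DataFrame(rows)
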