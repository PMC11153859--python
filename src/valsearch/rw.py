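"""Dual-learning-rate Rescorla–Wagner model with softmax choice.

The learner tracks four expected values — (target, nontarget) x (reward,
punishment condition).  On each reward/punishment trial the chosen option's
value moves toward the monetary outcome by the condition's learning rate:

    EV <- EV + eta * (outcome - EV)

and the probability of choosing the target is a softmax over the pair's two
values with a condition-specific inverse temperature tau.  Zero-outcome
trials carry no feedback, leave the values untouched and are excluded from
the likelihood (their parameters are not identified).

Conventions: values start at 0 (the midpoint of the outcome scale); only
the chosen option's value updates; the softmax is evaluated through a
numerically stable log-sum-exp form so large tau never overflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


__all__ = [
    "RWParams", "ValueState", "update_value", "choice_prob", "rl_loglik",
    "simulate_choice", "rl_loglik_matrix", "trials_to_arrays",
]

# EV slot layout: 0 = reward/target, 1 = reward/nontarget,
#                 2 = punishment/target, 3 = punishment/nontarget
_COND_INDEX = {"reward": 0, "punishment": 1}


@dataclass(frozen=True)
class RWParams:
    """Per-participant learning parameters.

    eta_r, eta_p : learning rates for reward / punishment, in (0, 1)
    tau_r, tau_p : softmax inverse temperatures, > 0
    """

    eta_r: float
    eta_p: float
    tau_r: float
    tau_p: float

    def __post_init__(self) -> None:
        for name in ("eta_r", "eta_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("tau_r", "tau_p"):
            v = getattr(self, name)
            if v < 0.0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    def eta(self, condition: str) -> float:
        return self.eta_r if condition == "reward" else self.eta_p

    def tau(self, condition: str) -> float:
        return self.tau_r if condition == "reward" else self.tau_p


@dataclass
class ValueState:
    """The four expected values plus the most recent prediction error."""

    ev: np.ndarray = field(default_factory=lambda: np.zeros(4))
    last_pe: float = 0.0

    def pair(self, condition: str) -> tuple[float, float]:
        """(EV_target, EV_nontarget) for a reward/punishment condition."""
        i = 2 * _COND_INDEX[condition]
        return float(self.ev[i]), float(self.ev[i + 1])

    def update(self, condition: str, chose_target: bool, outcome: int, eta: float) -> None:
        i = 2 * _COND_INDEX[condition] + (0 if chose_target else 1)
        pe = outcome - self.ev[i]
        self.ev[i] += eta * pe
        self.last_pe = float(pe)


def update_value(ev: float, outcome: int, eta: float) -> float:
    """One delta-rule step: ``ev + eta * (outcome - ev)``.

    ``eta`` must lie in [0, 1); 0 is tolerated as the degenerate no-learning
    limit.  With outcomes in {-1, 0, +1} and ev in [-1, 1] the result stays
    in [-1, 1].
    """
    if not 0.0 <= eta < 1.0:
        raise ValueError(f"eta must lie in [0, 1), got {eta}")
    if outcome not in (-1, 0, 1):
        raise ValueError(f"outcome must be -1, 0 or +1, got {outcome}")
    return ev + eta * (outcome - ev)


def choice_prob(ev_chosen: float, ev_other: float, tau: float) -> float:
    """Softmax probability of the chosen option.

    ``exp(tau*ev_chosen) / (exp(tau*ev_chosen) + exp(tau*ev_other))``,
    computed as ``1 / (1 + exp(-tau * (ev_chosen - ev_other)))`` which is
    stable for |tau * ev| up to the float range.  tau = 0 gives 0.5.
    """
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    x = tau * (ev_chosen - ev_other)
    # logistic via exp of the negative magnitude only
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return float(e / (1.0 + e))


def rl_loglik(params: RWParams, trials) -> float:
    """Sequential log-likelihood of a participant's learning trials.

    ``trials`` is a DataFrame with columns ``trial`` (time order),
    ``condition``, ``chose_target`` and ``outcome``.  Values are updated
    after each reward/punishment trial; zero-condition trials contribute
    nothing and do not touch the state.  Result is <= 0.
    """
    t = trials["trial"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError("trials must be strictly time-ordered within participant")
    state = ValueState()
    ll = 0.0
    for cond, chose, outcome in zip(
        trials["condition"], trials["chose_target"], trials["outcome"]
    ):
        if cond == "zero":
            continue
        ev_t, ev_n = state.pair(cond)
        tau = params.tau(cond)
        p = choice_prob(ev_t, ev_n, tau) if chose else choice_prob(ev_n, ev_t, tau)
        ll += np.log(p)
        state.update(cond, bool(chose), int(outcome), params.eta(cond))
    return float(ll)


def simulate_choice(
    state: ValueState, condition: str, params: RWParams, rng: np.random.Generator
) -> bool:
    """Draw chose_target ~ Bernoulli(softmax); zero condition is uniform."""
    if condition == "zero":
        return bool(rng.random() < 0.5)
    ev_t, ev_n = state.pair(condition)
    p = choice_prob(ev_t, ev_n, params.tau(condition))
    return bool(rng.random() < p)


# ---------------------------------------------------------------------------
# Vectorised likelihood used by the hierarchical sampler
# ---------------------------------------------------------------------------

def trials_to_arrays(trials, participant_ids) -> dict[str, np.ndarray]:
    """Pack per-participant trial sequences into per-condition (n, T) arrays.

    Because the two EV pairs never interact, the likelihood factorises
    into a reward part (depending only on eta_r, tau_r) and a punishment
    part (eta_p, tau_p); the sampler exploits this by evaluating each part
    separately.  All participants must have the same trial count per
    condition (true by design: 100 each).  Zero-condition trials carry no
    likelihood and are dropped here once.
    """
    out: dict[str, np.ndarray] = {}
    for key, cond in (("r", "reward"), ("p", "punishment")):
        choices, outcomes = [], []
        for pid in participant_ids:
            sub = trials[trials["participant_id"] == pid].sort_values("trial")
            sub = sub[sub["condition"] == cond]
            choices.append(sub["chose_target"].to_numpy(dtype=bool))
            outcomes.append(sub["outcome"].to_numpy(dtype=np.float64))
        shapes = {len(c) for c in choices}
        if len(shapes) != 1:
            raise ValueError(
                f"participants differ in {cond} trial counts: {sorted(shapes)}")
        out[f"chose_{key}"] = np.stack(choices)     # (n, T) True = target
        out[f"out_{key}"] = np.stack(outcomes)      # (n, T) in {-1, 0, +1}
    return out


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _njit = None


def _rl_cond_loglik_numpy(eta, tau, chose, outcome):
    T = chose.shape[-1]
    ev_t = np.zeros(np.broadcast_shapes(eta.shape, chose[:, 0].shape))
    ev_n = np.zeros_like(ev_t)
    ll = np.zeros_like(ev_t)
    for t in range(T):
        ch = chose[:, t]
        x = tau * np.where(ch, ev_t - ev_n, ev_n - ev_t)
        ll -= np.logaddexp(0.0, -x)
        pe_t = outcome[:, t] - ev_t
        pe_n = outcome[:, t] - ev_n
        ev_t = np.where(ch, ev_t + eta * pe_t, ev_t)
        ev_n = np.where(ch, ev_n, ev_n + eta * pe_n)
    return ll


if _njit is not None:

    @_njit(cache=True, error_model="numpy")
    def _rl_cond_loglik_jit(eta, tau, chose, outcome):  # pragma: no cover
        C, n = eta.shape
        T = chose.shape[1]
        ll = np.zeros((C, n))
        for c in range(C):
            for i in range(n):
                ev_t = 0.0
                ev_n = 0.0
                e = eta[c, i]
                tu = tau[c, i]
                acc = 0.0
                for t in range(T):
                    if chose[i, t]:
                        x = tu * (ev_t - ev_n)
                    else:
                        x = tu * (ev_n - ev_t)
                    if x > -30.0:
                        acc -= np.log1p(np.exp(-x))
                    else:
                        acc += x
                    if chose[i, t]:
                        ev_t += e * (outcome[i, t] - ev_t)
                    else:
                        ev_n += e * (outcome[i, t] - ev_n)
                ll[c, i] = acc
        return ll


def rl_cond_loglik(eta: np.ndarray, tau: np.ndarray,
                   chose: np.ndarray, outcome: np.ndarray) -> np.ndarray:
    """Sequential log-likelihood of one condition's trials, batched.

    ``eta`` and ``tau`` have shape (..., n); ``chose``/``outcome`` have
    shape (n, T) and broadcast across the leading batch axes (e.g. MCMC
    chains).  Returns log-likelihoods of shape (..., n).  The
    (chains, n) case runs through a compiled kernel when numba is
    available; the numpy path is the reference implementation.
    """
    eta = np.asarray(eta, float)
    tau = np.asarray(tau, float)
    if (_njit is not None and eta.ndim == 2 and eta.shape == tau.shape
            and eta.shape[1] == chose.shape[0]):
        return _rl_cond_loglik_jit(
            np.ascontiguousarray(eta), np.ascontiguousarray(tau),
            np.ascontiguousarray(chose), np.ascontiguousarray(outcome))
    return _rl_cond_loglik_numpy(eta, tau, chose, outcome)


def rl_loglik_matrix(
    eta_r: np.ndarray, eta_p: np.ndarray, tau_r: np.ndarray, tau_p: np.ndarray,
    data: dict[str, np.ndarray],
) -> np.ndarray:
    """Total log-likelihood for n participants at once.

    Parameters are length-n vectors (or batched (..., n)); ``data`` comes
    from :func:`trials_to_arrays`.  Agrees with :func:`rl_loglik`
    participant-by-participant.
    """
    return (rl_cond_loglik(eta_r, tau_r, data["chose_r"], data["out_r"])
            + rl_cond_loglik(eta_p, tau_p, data["chose_p"], data["out_p"]))
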