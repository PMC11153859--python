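"""Cross-model analysis: posterior modes, rank correlations, learning curves.

Individual parameters from the two fitted models are reduced to their
marginal posterior modes (KDE argmax, Silverman bandwidth) and related by
Spearman rank correlations.  Because no correlation-level power analysis
is possible at these sample sizes, a conservative flag marks cells with
|r| > 0.30; p-values are reported per cell without multiplicity
correction, so with 24 cells some flags are expected under the null —
treat the table as descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import CONDITIONS

__all__ = [
    "posterior_mode", "spearman", "correlation_table", "learning_curves",
    "CONSERVATIVE_R",
]

#: Conservative effect-size criterion for flagging a correlation.
CONSERVATIVE_R = 0.30

#: Row order of the correlation table: boundary then drift, per condition.
DDM_ROWS = [f"alpha_{c}" for c in CONDITIONS] + [f"nu_{c}" for c in CONDITIONS]
RL_COLS = ["eta_r", "eta_p", "tau_r", "tau_p"]


def posterior_mode(samples: np.ndarray, *, grid_points: int = 512) -> float:
    """Mode of a marginal posterior: argmax of a Gaussian KDE on a grid.

    The KDE uses Silverman's bandwidth and the grid spans the sample range
    with ``grid_points`` points (512 by default).  Constant samples return
    that constant.  Fewer than 100 draws would make the KDE unreliable and
    raise an error.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 100:
        raise ValueError(f"posterior_mode needs >= 100 draws, got {x.size}")
    lo, hi = x.min(), x.max()
    if lo == hi:
        return float(lo)
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(lo, hi, grid_points)
    return float(grid[np.argmax(kde(grid))])


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Average ranks resolve ties; the p-value uses the large-sample t
    approximation.  Zero variance in either vector leaves the coefficient
    undefined and raises an error (flagging, not silently returning NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("spearman needs at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined: zero variance in an input vector")
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def correlation_table(rl_modes: pd.DataFrame, ddm_modes: pd.DataFrame) -> pd.DataFrame:
    """6 x 4 Spearman table between diffusion and learning parameters.

    Both inputs need a ``participant_id`` column plus the parameter
    columns (``eta_r .. tau_p``; ``alpha_<cond>``/``nu_<cond>``).
    Participants must match exactly between the two tables.  Each cell of
    the result holds ``spearman_r``, ``p_value`` and ``flag_conservative``
    (|r| > 0.30); the output is a long DataFrame of 24 rows.
    """
    a = set(rl_modes["participant_id"])
    b = set(ddm_modes["participant_id"])
    if a != b:
        raise ValueError(
            f"participant mismatch between models: only-RL={sorted(a - b)}, "
            f"only-DDM={sorted(b - a)}")
    rl = rl_modes.set_index("participant_id").sort_index()
    ddm = ddm_modes.set_index("participant_id").sort_index()
    rows = []
    for drow in DDM_ROWS:
        for rcol in RL_COLS:
            r, p = spearman(ddm[drow].to_numpy(), rl[rcol].to_numpy())
            rows.append({
                "ddm_parameter": drow, "rl_parameter": rcol,
                "spearman_r": r, "p_value": p,
                "flag_conservative": abs(r) > CONSERVATIVE_R,
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LearningCurve:
    condition: str
    block: int
    proportion: float
    se: float


def learning_curves(trials: pd.DataFrame, block_size: int = 5) -> pd.DataFrame:
    """Cross-participant learning curves per condition.

    Each condition contributes 100 trials per participant, binned into
    blocks of ``block_size`` trials (5 gives the 20-point descriptive
    curve, 20 the five coarse bins); ``block_size`` must divide the
    per-condition trial count.  Returns condition, block, the mean
    proportion of target choices across participants, and its standard
    error.
    """
    rows = []
    for cond in CONDITIONS:
        per_participant = []
        for pid, sub in trials[trials["condition"] == cond].groupby(
                "participant_id", sort=False):
            ch = sub.sort_values("trial")["chose_target"].to_numpy(dtype=float)
            if len(ch) % block_size != 0:
                raise ValueError(
                    f"block_size {block_size} does not divide the "
                    f"{len(ch)} {cond} trials of participant {pid}")
            per_participant.append(
                ch.reshape(-1, block_size).mean(axis=1))
        mat = np.stack(per_participant)          # (participants, blocks)
        mean = mat.mean(axis=0)
        se = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 \
            else np.zeros(mat.shape[1])
        for b in range(mat.shape[1]):
            rows.append({"condition": cond, "block": b + 1,
                         "proportion": float(mean[b]), "se": float(se[b])})
    return pd.DataFrame(rows)
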