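"""Task designs for the value-learning and visual-search experiments.

Two deterministic, seedable schedule generators encode the study design:

* an associative learning task — three fixed face pairs, one per value
  condition (reward / punishment / zero outcome), each pair shown 10 times
  per block over 10 blocks (300 main trials), with the constraint that the
  same pair never appears in the same vertical arrangement on two
  consecutive trials;
* a visual search task — 4 blocks of 48 trials, each block holding 24
  target-present trials (8 per value condition) and 24 target-absent
  trials; over the experiment every target face appears exactly 8 times in
  each of the 4 display positions (32 presentations per target), and the
  same target never occupies the same position on two consecutive trials.

Schedules are plain :class:`pandas.DataFrame` objects so downstream code
(simulation, likelihoods, plotting) can use ordinary DataFrame operations.
Trial-level behavioural records use the CSV schemas documented in
:func:`write_learning_trials` / :func:`write_search_trials`.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd

#: The three value conditions of the learning task, in canonical order.
CONDITIONS: tuple[str, ...] = ("reward", "punishment", "zero")

#: Search trials additionally allow the target-absent condition.
SEARCH_CONDITIONS: tuple[str, ...] = CONDITIONS + ("absent",)

#: Valid monetary outcome codes (±20 yen coded as ±1).
OUTCOME_CODES: tuple[int, ...] = (-1, 0, 1)

N_LEARNING_BLOCKS = 10
PAIR_REPEATS_PER_BLOCK = 10          # 3 pairs x 10 = 30 trials per block
N_LEARNING_TRIALS = 300

N_SEARCH_BLOCKS = 4
PRESENT_PER_CONDITION_PER_BLOCK = 8  # 3 conditions x 8 = 24 present trials
ABSENT_PER_BLOCK = 24
N_SEARCH_TRIALS = 192
N_POSITIONS = 4

_MAX_RESAMPLE = 10_000

#: The six possible allocations of the three face pairs to conditions.
CONDITION_ALLOCATIONS: tuple[tuple[str, str, str], ...] = tuple(
    itertools.permutations(CONDITIONS)
)

# The source experiment counterbalanced "1 of 24 stimulus presentation
# combinations" across participants.  A full factorisation of 6 condition
# allocations x 8 target-status flips gives 48, not 24, so the intended
# factorisation is ambiguous; both readings are recorded here and a single
# default allocation (identity, no flips) is used throughout.  Allocation
# only relabels which physical pair carries which condition — it has no
# computational effect on the schedule structure.
COUNTERBALANCE_READINGS = {
    "allocations_x_joint_status_flip": 6 * 4,   # 24 — matches the printed count
    "allocations_x_independent_flips": 6 * 8,   # 48 — full factorial reading
}


class ScheduleError(RuntimeError):
    """Raised when constraint-satisfying resampling exceeds its attempt cap."""


def _order_block_with_no_repeat(
    items: list[tuple], rng: np.random.Generator, prev_last: tuple | None
) -> list[tuple]:
    """Shuffle ``items`` until no two adjacent entries are identical.

    ``prev_last`` is the final entry of the preceding block; the first entry
    of the new ordering must differ from it so the constraint also holds
    across block boundaries.  Entries compare on their full tuple identity
    (e.g. ``(pair, arrangement)``); ``None`` entries never clash.
    """
    items = list(items)
    for _ in range(_MAX_RESAMPLE):
        rng.shuffle(items)
        ok = prev_last is None or items[0] is None or items[0] != prev_last
        if ok and all(
            a is None or b is None or a != b for a, b in zip(items, items[1:])
        ):
            return items
    raise ScheduleError(
        f"could not order a block without adjacent repeats in {_MAX_RESAMPLE} attempts"
    )


def build_learning_schedule(
    seed: int,
    *,
    condition_allocation: Sequence[str] = CONDITIONS,
    include_practice: bool = False,
) -> pd.DataFrame:
    """Build the 300-trial learning schedule.

    Parameters
    ----------
    seed
        Non-negative integer seeding the ordering; equal seeds give
        byte-identical schedules.
    condition_allocation
        Permutation of the three conditions assigning a condition to each of
        the three physical face pairs (counterbalancing handle; the default
        is the identity allocation).
    include_practice
        If True, prepend a 30-trial practice block (``block = 0``,
        ``practice = True``) that analysis code must exclude.

    Returns
    -------
    DataFrame with columns ``block`` (1..10), ``trial`` (1..300, continuous
    over main trials), ``pair_id`` (1..3), ``condition``, ``target_on_top``
    (bool arrangement flag) and ``practice``.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    alloc = tuple(condition_allocation)
    if sorted(alloc) != sorted(CONDITIONS):
        raise ValueError(f"condition_allocation must permute {CONDITIONS}, got {alloc}")
    rng = np.random.default_rng(seed)

    blocks = range(0, N_LEARNING_BLOCKS + 1) if include_practice else range(1, N_LEARNING_BLOCKS + 1)
    rows: list[tuple] = []
    prev_last: tuple | None = None
    for block in blocks:
        # 10 presentations per pair; the arrangement flag is balanced 5/5
        # within each pair and block.
        items = [
            (pair, top)
            for pair in (1, 2, 3)
            for top in (True,) * 5 + (False,) * 5
        ]
        ordered = _order_block_with_no_repeat(items, rng, prev_last)
        prev_last = ordered[-1]
        for pair, top in ordered:
            rows.append((block, pair, alloc[pair - 1], top, block == 0))

    out = pd.DataFrame(
        rows, columns=["block", "pair_id", "condition", "target_on_top", "practice"]
    )
    trial = np.zeros(len(out), dtype=int)
    main = ~out["practice"].to_numpy()
    trial[main] = np.arange(1, main.sum() + 1)
    out.insert(1, "trial", trial)
    return out


def build_search_schedule(seed: int, *, include_practice: bool = False) -> pd.DataFrame:
    """Build the 192-trial visual-search schedule.

    Per block: 24 target-present trials (8 per condition, each target shown
    twice at each of the 4 positions) and 24 target-absent trials.  Over the
    4 blocks every target therefore appears 8 times at each position, 32
    times in total.  The same target never appears at the same position on
    two consecutive trials (absent trials carry no target and never clash).

    Returns a DataFrame with columns ``block``, ``trial``, ``condition``
    (including ``absent``), ``target_present``, ``target_position``
    (1..4, ``<NA>`` on absent trials) and ``practice``.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    rng = np.random.default_rng(seed)

    rows: list[tuple] = []
    prev_last: tuple | None = None

    def emit_block(block: int) -> None:
        nonlocal prev_last
        items: list[tuple | None] = [
            (cond, pos)
            for cond in CONDITIONS
            for pos in range(1, N_POSITIONS + 1)
            for _ in range(PRESENT_PER_CONDITION_PER_BLOCK // N_POSITIONS)
        ]
        items += [None] * ABSENT_PER_BLOCK
        ordered = _order_block_with_no_repeat(items, rng, prev_last)
        if ordered[-1] is not None:
            prev_last = ordered[-1]
        for entry in ordered:
            if entry is None:
                rows.append((block, "absent", False, pd.NA, block == 0))
            else:
                cond, pos = entry
                rows.append((block, cond, True, pos, block == 0))

    if include_practice:
        # The 24-trial practice block: half present (one target per
        # condition at random positions), half absent.
        practice: list[tuple | None] = [
            (cond, int(rng.integers(1, N_POSITIONS + 1)))
            for cond in CONDITIONS
            for _ in range(4)
        ] + [None] * 12
        ordered = _order_block_with_no_repeat(practice, rng, None)
        prev_last = next((e for e in reversed(ordered) if e is not None), None)
        for entry in ordered:
            if entry is None:
                rows.append((0, "absent", False, pd.NA, True))
            else:
                rows.append((0, entry[0], True, entry[1], True))

    for block in range(1, N_SEARCH_BLOCKS + 1):
        emit_block(block)

    out = pd.DataFrame(
        rows,
        columns=["block", "condition", "target_present", "target_position", "practice"],
    )
    out["target_position"] = out["target_position"].astype("Int64")
    trial = np.zeros(len(out), dtype=int)
    main = ~out["practice"].to_numpy()
    trial[main] = np.arange(1, main.sum() + 1)
    out.insert(1, "trial", trial)
    return out


# ---------------------------------------------------------------------------
# Trial-record validation and CSV I/O
# ---------------------------------------------------------------------------

LEARNING_COLUMNS = [
    "participant_id", "group", "block", "trial", "condition", "chose_target", "outcome",
]
SEARCH_COLUMNS = [
    "participant_id", "group", "block", "trial", "condition",
    "target_present", "response", "rt_sec",
]


def validate_trials(records: pd.DataFrame) -> list[str]:
    """Check trial records against the design invariants.

    Accepts either learning or search records (detected from the columns)
    and returns a list of human-readable violation strings; an empty list
    means the records are valid.  An unknown condition label is a hard
    error (``ValueError``) naming the offending row, since no downstream
    computation is meaningful for it.
    """
    cols = set(records.columns)
    if {"chose_target", "outcome"} <= cols:
        kind = "learning"
        allowed = set(CONDITIONS)
    elif {"response", "rt_sec"} <= cols:
        kind = "search"
        allowed = set(SEARCH_CONDITIONS)
    else:
        raise ValueError(
            "records match neither the learning nor the search schema; "
            f"columns = {sorted(cols)}"
        )

    bad_cond = ~records["condition"].isin(allowed)
    if bad_cond.any():
        row = int(np.flatnonzero(bad_cond.to_numpy())[0])
        raise ValueError(
            f"unknown condition {records['condition'].iloc[row]!r} at row {row}"
        )

    report: list[str] = []
    if kind == "learning":
        bad_outcome = ~records["outcome"].isin(OUTCOME_CODES)
        for row in np.flatnonzero(bad_outcome.to_numpy()):
            report.append(f"row {row}: outcome {records['outcome'].iloc[row]!r} not in {OUTCOME_CODES}")
        zero_bad = (records["condition"] == "zero") & (records["outcome"] != 0)
        for row in np.flatnonzero(zero_bad.to_numpy()):
            report.append(f"row {row}: zero-condition trial with nonzero outcome")
        # under the default contingency reward never pays -1, punishment never +1
        for cond, illegal in (("reward", -1), ("punishment", 1)):
            mask = (records["condition"] == cond) & (records["outcome"] == illegal)
            for row in np.flatnonzero(mask.to_numpy()):
                report.append(f"row {row}: {cond}-condition trial with outcome {illegal}")
        for pid, sub in records.groupby("participant_id", sort=False):
            n = len(sub[sub["block"] > 0]) if "block" in sub else len(sub)
            if n != N_LEARNING_TRIALS:
                report.append(
                    f"participant {pid}: {n} main learning trials, expected {N_LEARNING_TRIALS}"
                )
    else:
        nonpos = records["rt_sec"] <= 0
        for row in np.flatnonzero(nonpos.to_numpy()):
            report.append(f"row {row}: rt_sec = {records['rt_sec'].iloc[row]} is not > 0")
        bad_resp = ~records["response"].isin(("present", "absent"))
        for row in np.flatnonzero(bad_resp.to_numpy()):
            report.append(f"row {row}: response {records['response'].iloc[row]!r} invalid")
        mismatch = records["target_present"].astype(bool) != (records["condition"] != "absent")
        for row in np.flatnonzero(mismatch.to_numpy()):
            report.append(f"row {row}: target_present flag contradicts condition")
        for pid, sub in records.groupby("participant_id", sort=False):
            if len(sub) != N_SEARCH_TRIALS:
                report.append(
                    f"participant {pid}: {len(sub)} search trials, expected {N_SEARCH_TRIALS}"
                )
    return report


def write_learning_trials(df: pd.DataFrame, path) -> None:
    """Write learning-trial records as UTF-8 CSV with a header row."""
    df[LEARNING_COLUMNS].to_csv(path, index=False)


def write_search_trials(df: pd.DataFrame, path) -> None:
    df[SEARCH_COLUMNS].to_csv(path, index=False)


def read_learning_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(LEARNING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"learning CSV missing columns {sorted(missing)}")
    df["chose_target"] = df["chose_target"].astype(bool)
    return df


def read_search_trials(path) -> pd.DataFrame:
    # round_trip parsing: RTs are likelihood inputs, a 1-ulp parser error
    # would make CSV-mediated refits differ from in-memory fits
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(SEARCH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"search CSV missing columns {sorted(missing)}")
    df["target_present"] = df["target_present"].astype(bool)
    return df
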