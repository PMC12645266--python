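"""Trial-schedule generation and validation for the prosocial effort task.

A session interleaves two offer streams: on every trial the participant
chooses between a fixed "rest" offer (6 shocks, no effort) and a "work"
offer (1-5 shocks, grip effort at one of five levels mapping to 40-80% of
maximum voluntary contraction).  Half of the trials decide shocks for the
participant ("self"), half for another person ("other").

Schedules are pseudo-randomized under three constraints:

* every consecutive non-overlapping block of 5 trials contains each effort
  level exactly once (so the block-mean effort is always 3);
* the same recipient never occurs more than 4 times in a row;
* within each recipient, every (effort level, work shocks) cell occurs
  equally often.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recipient",
    "TrialSpec",
    "TrialSchedule",
    "generate_schedule",
    "validate_schedule",
    "schedule_to_frame",
    "schedule_from_frame",
    "write_schedule_csv",
    "read_schedule_csv",
]

REST_SHOCKS = 6
PENALTY_SHOCKS = 10
EFFORT_LEVELS = (1, 2, 3, 4, 5)
WORK_SHOCK_LEVELS = (1, 2, 3, 4, 5)
#: %MVC corresponding to each effort level 1..5
EFFORT_PCT = {1: 40, 2: 50, 3: 60, 4: 70, 5: 80}
MAX_RECIPIENT_RUN = 4
_MAX_ATTEMPTS = 10_000


class Recipient(str, enum.Enum):
    SELF = "self"
    OTHER = "other"


@dataclasses.dataclass(frozen=True)
class TrialSpec:
    """One offer pair: rest (6 shocks, no effort) vs. work (fewer shocks, effort)."""

    index: int
    recipient: Recipient
    effort_level: int
    work_shocks: int
    rest_shocks: int = REST_SHOCKS
    penalty_shocks: int = PENALTY_SHOCKS

    def __post_init__(self) -> None:
        if self.effort_level not in EFFORT_LEVELS:
            raise ValueError(f"effort_level must be in 1..5, got {self.effort_level}")
        if self.work_shocks not in WORK_SHOCK_LEVELS:
            raise ValueError(f"work_shocks must be in 1..5, got {self.work_shocks}")
        if self.work_shocks >= self.rest_shocks:
            raise ValueError("work offer must involve fewer shocks than the rest offer")

    @property
    def effort_pct(self) -> int:
        return EFFORT_PCT[self.effort_level]


@dataclasses.dataclass(frozen=True)
class TrialSchedule:
    trials: tuple[TrialSpec, ...]
    seed: int | None
    n_per_recipient: int

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def recipients(self) -> np.ndarray:
        return np.array([t.recipient.value for t in self.trials])

    @property
    def effort_levels(self) -> np.ndarray:
        return np.array([t.effort_level for t in self.trials])

    @property
    def work_shocks(self) -> np.ndarray:
        return np.array([t.work_shocks for t in self.trials])


def _recipient_runs_ok(codes: np.ndarray, max_run: int = MAX_RECIPIENT_RUN) -> bool:
    run = 1
    for i in range(1, len(codes)):
        run = run + 1 if codes[i] == codes[i - 1] else 1
        if run > max_run:
            return False
    return True


def generate_schedule(n_per_recipient: int = 75, seed: int | None = None) -> TrialSchedule:
    """Generate a pseudo-randomized schedule of ``2 * n_per_recipient`` trials.

    ``n_per_recipient`` must be a positive multiple of 25 so that the
    (effort x shock) design is balanced within each recipient.  The same
    seed always yields the identical schedule.

    Raises
    ------
    ValueError
        If ``n_per_recipient`` is not a positive multiple of 25.
    RuntimeError
        If the recipient run-length constraint cannot be satisfied within
        the bounded number of resampling attempts.
    """
    if n_per_recipient <= 0 or n_per_recipient % 25 != 0:
        raise ValueError(
            "n_per_recipient must be a positive multiple of 25 so that the "
            f"5x5 effort-by-shock design balances; got {n_per_recipient}"
        )
    rng = np.random.default_rng(seed)
    n_total = 2 * n_per_recipient
    n_blocks = n_total // 5

    # Effort stream: each block of 5 is a fresh permutation of levels 1..5.
    effort = np.concatenate(
        [rng.permutation(EFFORT_LEVELS) for _ in range(n_blocks)]
    )

    # Recipient stream: within every effort level, exactly half the
    # occurrences go to each recipient; resample until run lengths <= 4.
    per_effort = n_total // 5  # occurrences of each effort level
    for _ in range(_MAX_ATTEMPTS):
        codes = np.empty(n_total, dtype=np.int8)
        for lev in EFFORT_LEVELS:
            pos = np.flatnonzero(effort == lev)
            half = per_effort // 2
            assignment = np.array([0] * half + [1] * half, dtype=np.int8)
            rng.shuffle(assignment)
            codes[pos] = assignment
        if _recipient_runs_ok(codes):
            break
    else:
        raise RuntimeError(
            f"could not satisfy recipient run-length <= {MAX_RECIPIENT_RUN} "
            f"within {_MAX_ATTEMPTS} attempts"
        )
    recipient = np.where(codes == 0, Recipient.SELF.value, Recipient.OTHER.value)

    # Shock stream: within each (recipient, effort) cell, a shuffled
    # balanced multiset of the five shock levels.
    reps = n_per_recipient // 25
    shocks = np.empty(n_total, dtype=np.int64)
    for rec in (Recipient.SELF.value, Recipient.OTHER.value):
        for lev in EFFORT_LEVELS:
            pos = np.flatnonzero((recipient == rec) & (effort == lev))
            cell = np.repeat(WORK_SHOCK_LEVELS, reps)
            rng.shuffle(cell)
            shocks[pos] = cell

    trials = tuple(
        TrialSpec(
            index=i,
            recipient=Recipient(recipient[i]),
            effort_level=int(effort[i]),
            work_shocks=int(shocks[i]),
        )
        for i in range(n_total)
    )
    return TrialSchedule(trials=trials, seed=seed, n_per_recipient=n_per_recipient)


def validate_schedule(schedule: TrialSchedule) -> list[str]:
    """Return a list of violated design constraints (empty if the schedule is valid).

    Validation never raises on content; malformed (empty) input raises
    ``ValueError``.
    """
    if len(schedule) == 0:
        raise ValueError("cannot validate an empty schedule")
    report: list[str] = []
    rec = schedule.recipients
    eff = schedule.effort_levels
    shk = schedule.work_shocks
    n = len(schedule)

    if n != 2 * schedule.n_per_recipient:
        report.append(
            f"length: expected {2 * schedule.n_per_recipient} trials, found {n}"
        )
    counts = {r: int(np.sum(rec == r)) for r in ("self", "other")}
    if counts["self"] != counts["other"]:
        report.append(
            f"recipient balance: self={counts['self']} other={counts['other']}"
        )

    # mini-block rule: each non-overlapping block of 5 is a permutation of 1..5
    for b in range(n // 5):
        block = eff[5 * b : 5 * b + 5]
        if sorted(block) != list(EFFORT_LEVELS):
            report.append(
                f"mini-block rule: block {b} (trials {5 * b}..{5 * b + 4}) has "
                f"effort levels {tuple(block)}, not a permutation of 1..5"
            )

    # recipient run-length rule
    run_start, run = 0, 1
    for i in range(1, n):
        if rec[i] == rec[i - 1]:
            run += 1
        else:
            run_start, run = i, 1
        if run == MAX_RECIPIENT_RUN + 1:
            report.append(
                f"recipient-run rule: more than {MAX_RECIPIENT_RUN} consecutive "
                f"'{rec[i]}' trials starting at trial {run_start}"
            )

    # per-recipient marginal balance of effort and shock levels
    for r in ("self", "other"):
        mask = rec == r
        for name, values in (("effort_level", eff), ("work_shocks", shk)):
            cnt = np.bincount(values[mask], minlength=6)[1:6]
            if len(set(cnt.tolist())) > 1:
                report.append(
                    f"marginal balance: {name} counts for recipient '{r}' are "
                    f"{cnt.tolist()}, expected all equal"
                )
    return report


# ---------------------------------------------------------------------------
# CSV round-trip (1-based trial numbering in the exported file)

_SCHEDULE_COLUMNS = ["trial", "recipient", "effort_level", "effort_pct",
                     "work_shocks", "rest_shocks"]


def schedule_to_frame(schedule: TrialSchedule) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial": [t.index + 1 for t in schedule],
            "recipient": [t.recipient.value for t in schedule],
            "effort_level": [t.effort_level for t in schedule],
            "effort_pct": [t.effort_pct for t in schedule],
            "work_shocks": [t.work_shocks for t in schedule],
            "rest_shocks": [t.rest_shocks for t in schedule],
        }
    )


def schedule_from_frame(frame: pd.DataFrame, seed: int | None = None) -> TrialSchedule:
    missing = [c for c in _SCHEDULE_COLUMNS if c not in frame.columns and c != "effort_pct"]
    if missing:
        raise ValueError(f"schedule table is missing columns: {missing}")
    frame = frame.sort_values("trial")
    trials = tuple(
        TrialSpec(
            index=int(row.trial) - 1,
            recipient=Recipient(row.recipient),
            effort_level=int(row.effort_level),
            work_shocks=int(row.work_shocks),
        )
        for row in frame.itertuples()
    )
    n_self = sum(1 for t in trials if t.recipient is Recipient.SELF)
    return TrialSchedule(trials=trials, seed=seed, n_per_recipient=n_self)


def write_schedule_csv(schedule: TrialSchedule, path) -> None:
    schedule_to_frame(schedule).to_csv(path, index=False)


def read_schedule_csv(path) -> TrialSchedule:
    return schedule_from_frame(pd.read_csv(path))
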