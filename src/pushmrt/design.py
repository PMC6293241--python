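"""Decision-point engine for a push-notification micro-randomized trial (MRT).

In an MRT each user is repeatedly randomized, at prespecified decision
points, between receiving and not receiving an intervention option — here a
push notification prompting self-monitoring ("charting") in a well-being
app.  Six decision slots are scheduled per day (8:30, 12:30, 17:30, 18:30,
19:30, 20:30).  At each slot the user is first classified as *available* or
not; among a day's available slots exactly one is selected (uniformly at
random) as the *considered* time point, at which the push/no-push coin is
flipped with probability 0.5.  Once a slot has been considered the user is
unavailable for the remainder of that day.

Availability throttles notification burden as a function of disengagement:
the number of days a user must wait after a decision before becoming
available again is a step function of their current days of inactivity
(days since they last charted).  On weekends, morning slots (before noon)
are blocked.

This module owns the scheduling/randomization layer only; outcomes are
supplied by an oracle callback (see :func:`run_design`) or generated by the
vectorized simulator in :mod:`pushmrt.cohort`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SLOT_TIMES",
    "AvailabilityRuleTable",
    "TrialConfig",
    "UserDayState",
    "slot_schedule",
    "wait_days",
    "assess_availability",
    "select_considered_slot",
    "randomize_treatment",
    "run_design",
    "check_design_invariants",
    "availability_fraction",
]

#: Clock times (hours) of the six daily decision slots.
DEFAULT_SLOT_TIMES: tuple[float, ...] = (8.5, 12.5, 17.5, 18.5, 19.5, 20.5)

#: Weekday indices; day 0 is Monday, 5-6 are the weekend.
WEEKEND_DAYS = (5, 6)

#: Columns of a decision-record table, one row per user x day x slot.
RECORD_COLUMNS = [
    "user_id",
    "day",
    "slot",
    "available",
    "considered",
    "prob",
    "push",
    "outcome_24h",
]


@dataclass(frozen=True)
class AvailabilityRuleTable:
    """Step function mapping days of inactivity to the post-decision wait.

    ``buckets`` is an ordered tuple of ``(low, high, wait_days)`` half-open
    inactivity ranges ``[low, high)`` that must partition ``[0, inf)``.  The
    default reproduces the deployed throttling rule: recently active users
    (<2 days inactive) wait 3 days between decisions (about twice a week),
    users 2-9 days inactive wait 2 days, 10-29 days wait 6 (weekly), and
    30+ days wait 15 (fortnightly).
    """

    buckets: tuple[tuple[float, float, int], ...] = (
        (0, 2, 3),
        (2, 10, 2),
        (10, 30, 6),
        (30, math.inf, 15),
    )

    def __post_init__(self) -> None:
        if not self.buckets:
            raise ValueError("rule table needs at least one bucket")
        lo = 0.0
        for low, high, wait in self.buckets:
            if low != lo:
                raise ValueError(
                    f"buckets must partition [0, inf) without gaps/overlap; "
                    f"expected bucket starting at {lo}, got {low}"
                )
            if high <= low:
                raise ValueError(f"empty bucket [{low}, {high})")
            if wait < 1:
                raise ValueError(f"wait days must be >= 1, got {wait}")
            lo = high
        if not math.isinf(lo):
            raise ValueError("last bucket must extend to infinity")

    @property
    def min_wait(self) -> int:
        return min(w for _, _, w in self.buckets)

    def wait_days(self, days_inactive: float) -> int:
        """Wait (days) imposed by the bucket containing ``days_inactive``."""
        if days_inactive < 0:
            raise ValueError(f"days_inactive must be >= 0, got {days_inactive}")
        for low, high, wait in self.buckets:
            if low <= days_inactive < high:
                return wait
        raise AssertionError("unreachable: buckets partition [0, inf)")

    def wait_days_vec(self, days_inactive: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`wait_days` (used by the simulator)."""
        d = np.asarray(days_inactive)
        if np.any(d < 0):
            raise ValueError("days_inactive must be >= 0")
        lows = np.array([b[0] for b in self.buckets])
        waits = np.array([b[2] for b in self.buckets])
        idx = np.searchsorted(lows, d, side="right") - 1
        return waits[idx]


def wait_days(rule_table: AvailabilityRuleTable, days_inactive: float) -> int:
    """Functional alias for :meth:`AvailabilityRuleTable.wait_days`."""
    return rule_table.wait_days(days_inactive)


@dataclass(frozen=True)
class TrialConfig:
    """Static parameters of the trial design.

    Parameters
    ----------
    n_days:
        Study duration in days (default 89, ~13 weeks).
    slot_times:
        Strictly increasing clock times (hours) of the daily decision slots.
    randomization_prob:
        Probability of sending the push at a considered slot, in (0, 1).
    rule_table:
        Inactivity-bucket wait rule, see :class:`AvailabilityRuleTable`.
    weekend_morning_blocked:
        If true (default), slots before noon are closed on weekends.
    start_weekday:
        Day of week of study day 1 (0 = Monday ... 6 = Sunday).
    """

    n_days: int = 89
    slot_times: tuple[float, ...] = DEFAULT_SLOT_TIMES
    randomization_prob: float = 0.5
    rule_table: AvailabilityRuleTable = field(default_factory=AvailabilityRuleTable)
    weekend_morning_blocked: bool = True
    start_weekday: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError(f"n_days must be >= 1, got {self.n_days}")
        times = tuple(float(t) for t in self.slot_times)
        if len(times) < 1 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("slot_times must be strictly increasing")
        if any(t < 0 or t >= 24 for t in times):
            raise ValueError("slot_times must lie in [0, 24)")
        object.__setattr__(self, "slot_times", times)
        if not 0 < self.randomization_prob < 1:
            raise ValueError(
                f"randomization_prob must be in (0, 1), got {self.randomization_prob}"
            )
        if not 0 <= self.start_weekday <= 6:
            raise ValueError("start_weekday must be in 0..6 (0 = Monday)")

    @property
    def n_slots(self) -> int:
        return len(self.slot_times)

    def weekday(self, day_index: int) -> int:
        """Day of week (0 = Monday) of study day ``day_index`` (1-based)."""
        return (self.start_weekday + day_index - 1) % 7

    def is_weekend(self, day_index: int) -> bool:
        return self.weekday(day_index) in WEEKEND_DAYS

    def with_overrides(self, **kwargs) -> "TrialConfig":
        return replace(self, **kwargs)


@dataclass
class UserDayState:
    """Mutable per-user state evaluated at the start of a day.

    ``None`` for either counter means the event has never happened.
    ``days_since_last_chart`` is the current inactivity in days (a user who
    charted yesterday has value 1; 0 means a chart earlier today).
    """

    days_since_last_chart: Optional[int] = None
    days_since_last_decision: Optional[int] = None
    considered_today: bool = False
    notifications_enabled: bool = True


def slot_schedule(config: TrialConfig, day_index: int) -> list[int]:
    """Slot indices (1-based) open on a given study day.

    All slots are open on weekdays; on weekends, slots before noon are
    closed when ``weekend_morning_blocked`` is set (by default this removes
    only the 8:30 slot).
    """
    if not 1 <= day_index <= config.n_days:
        raise ValueError(
            f"day_index must be in 1..{config.n_days}, got {day_index}"
        )
    if config.weekend_morning_blocked and config.is_weekend(day_index):
        return [i for i, t in enumerate(config.slot_times, start=1) if t >= 12.0]
    return list(range(1, config.n_slots + 1))


def assess_availability(
    state: UserDayState, day_index: int, slot_index: int, config: TrialConfig
) -> int:
    """Availability indicator I_t for one user at one decision slot.

    A user is available iff notifications are enabled, the slot is open on
    that day, no slot has been considered yet today, and enough days have
    passed since the previous decision per the inactivity wait rule (users
    with no previous decision are immediately eligible).
    """
    if not state.notifications_enabled:
        return 0
    if state.considered_today:
        return 0
    if slot_index not in slot_schedule(config, day_index):
        return 0
    if state.days_since_last_decision is None:
        return 1
    inactivity = (
        state.days_since_last_chart
        if state.days_since_last_chart is not None
        else day_index - 1
    )
    return int(
        state.days_since_last_decision >= config.rule_table.wait_days(inactivity)
    )


def select_considered_slot(
    open_available_slots: Sequence[int], rng: np.random.Generator
) -> Optional[int]:
    """Pick the day's considered slot uniformly among available open slots.

    Returns ``None`` when no slot is available.  Realized sequentially this
    is equivalent to advancing past each slot with probability
    ``1 - 1/(remaining open slots)``, so exactly one slot is considered on
    any day with at least one available slot.
    """
    if len(open_available_slots) == 0:
        return None
    return int(open_available_slots[int(rng.integers(len(open_available_slots)))])


def randomize_treatment(prob: float, rng: np.random.Generator) -> int:
    """Bernoulli(prob) push/no-push draw at a considered slot."""
    if not 0 < prob < 1:
        raise ValueError(f"randomization probability must be in (0, 1), got {prob}")
    return int(rng.random() < prob)


# ---------------------------------------------------------------------------
# Reference trial engine (per-user loop, oracle-driven outcomes)
# ---------------------------------------------------------------------------

OutcomeOracle = Callable[[int, int, Optional[int], int, np.random.Generator], int]


def run_design(
    users: int | Sequence[UserDayState],
    config: TrialConfig,
    outcome_oracle: OutcomeOracle,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Run the decision-point process and emit one row per user x day x slot.

    ``outcome_oracle(user, day, considered_slot, treatment, rng)`` must
    return the binary chart-within-24h outcome for the day; a returned 1 is
    treated as a chart event on that day and feeds back into the next day's
    inactivity counter.  ``considered_slot`` is ``None`` on days without a
    decision (the oracle is still consulted, with treatment 0, so that
    spontaneous engagement can drive the availability dynamics).

    Outcomes here are day-resolution: every slot row of a day carries the
    day's outcome draw.  The vectorized simulator in :mod:`pushmrt.cohort`
    refines this to clock-resolution 24-hour windows.

    With the default configuration each user contributes
    ``n_slots * n_days = 534`` rows.
    """
    if isinstance(users, (int, np.integer)):
        states = [UserDayState() for _ in range(int(users))]
    else:
        states = [replace(s) for s in users]

    rows: list[tuple] = []
    p = config.randomization_prob
    for uid, init in enumerate(states):
        # internal day-stamped state; day 0 = the day before the study
        last_chart_day: Optional[int] = (
            None
            if init.days_since_last_chart is None
            else 1 - init.days_since_last_chart
        )
        last_dec_day: Optional[int] = (
            None
            if init.days_since_last_decision is None
            else 1 - init.days_since_last_decision
        )
        enabled = init.notifications_enabled
        for day in range(1, config.n_days + 1):
            sched = slot_schedule(config, day)
            state = UserDayState(
                days_since_last_chart=(
                    None if last_chart_day is None else day - last_chart_day
                ),
                days_since_last_decision=(
                    None if last_dec_day is None else day - last_dec_day
                ),
                considered_today=False,
                notifications_enabled=enabled,
            )
            open_slots = [
                s for s in sched if assess_availability(state, day, s, config)
            ]
            considered_slot = select_considered_slot(open_slots, rng)
            treatment = 0
            if considered_slot is not None:
                treatment = randomize_treatment(p, rng)
            try:
                outcome = int(outcome_oracle(uid, day, considered_slot, treatment, rng))
            except Exception as exc:  # pragma: no cover - context attachment
                raise RuntimeError(
                    f"outcome oracle failed for user {uid}, day {day}"
                ) from exc
            if outcome not in (0, 1):
                raise RuntimeError(
                    f"outcome oracle returned non-binary value {outcome!r} "
                    f"for user {uid}, day {day}"
                )
            for slot in range(1, config.n_slots + 1):
                available = int(
                    considered_slot is not None
                    and slot in sched
                    and slot <= considered_slot
                )
                considered = int(slot == considered_slot)
                rows.append(
                    (
                        uid,
                        day,
                        slot,
                        available,
                        considered,
                        p if considered else np.nan,
                        treatment if considered else 0,
                        outcome,
                    )
                )
            if considered_slot is not None:
                last_dec_day = day
            if outcome:
                last_chart_day = day
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    for col in ("user_id", "day", "slot", "available", "considered", "push", "outcome_24h"):
        df[col] = df[col].astype(np.int64)
    return df


# ---------------------------------------------------------------------------
# Invariant assertion suite
# ---------------------------------------------------------------------------

def check_design_invariants(records: pd.DataFrame, config: TrialConfig | None = None) -> None:
    """Assert the structural invariants of a decision-record table.

    Raises ``AssertionError`` listing every violated invariant.  Checked:

    - ``considered == 1`` implies ``available == 1``;
    - ``push == 1`` implies ``considered == 1``;
    - at most one considered slot per user-day;
    - consecutive considered decisions for a user are >= ``min_wait`` days
      apart (2 under the default rule table);
    - ``prob`` lies in (0, 1) exactly on considered rows;
    - under the default weekend rule no considered decision occurs at a
      before-noon slot on a weekend.
    """
    cfg = config or TrialConfig()
    problems: list[str] = []

    bad = records[(records.considered == 1) & (records.available != 1)]
    if len(bad):
        problems.append(f"{len(bad)} considered rows are not available")
    bad = records[(records.push == 1) & (records.considered != 1)]
    if len(bad):
        problems.append(f"{len(bad)} pushed rows are not considered")

    per_day = records.groupby(["user_id", "day"], sort=False)["considered"].sum()
    if (per_day > 1).any():
        problems.append(
            f"{int((per_day > 1).sum())} user-days have >1 considered slot"
        )

    cons = records[records.considered == 1]
    gaps = cons.sort_values(["user_id", "day"]).groupby("user_id")["day"].diff()
    if (gaps.dropna() < cfg.rule_table.min_wait).any():
        problems.append(
            f"considered decisions closer than {cfg.rule_table.min_wait} days"
        )

    if not cons.empty:
        if cons["prob"].isna().any() or not (
            (cons["prob"] > 0) & (cons["prob"] < 1)
        ).all():
            problems.append("prob outside (0,1) on considered rows")
    noncons = records[records.considered == 0]
    if not noncons["prob"].isna().all():
        problems.append("prob set on non-considered rows")

    if cfg.weekend_morning_blocked:
        weekend = cons["day"].map(cfg.is_weekend)
        morning = cons["slot"].map(lambda s: cfg.slot_times[s - 1] < 12.0)
        n_bad = int((weekend & morning).sum())
        if n_bad:
            problems.append(f"{n_bad} weekend before-noon considered decisions")

    if problems:
        raise AssertionError("design invariants violated: " + "; ".join(problems))


def availability_fraction(records: pd.DataFrame) -> float:
    """Fraction of person-slot records at which the user was available."""
    return float(records["available"].mean())
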