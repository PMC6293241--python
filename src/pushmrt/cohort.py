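"""Synthetic user cohorts and trial datasets with a known outcome model.

The study's real dataset is proprietary, so every downstream stage is
exercised on synthetic data drawn from a fully specified log-linear
data-generating process (DGP).  The probability that a user charts within
24 hours of decision point t is

    P(Y = 1 | H_t, A_t) = min( cap, exp( g_t' alpha* + b_u + A_t f_t' beta* ) ),

where g_t are the standard control covariates, b_u ~ N(0, user_sd^2) is a
per-user intercept inducing within-person correlation, and beta* is the
planted causal excursion effect on the log risk-ratio scale.  The cap
(default 0.95) truncates the log-linear mean away from 1; the default
alpha* keeps uncapped probabilities below the cap in essentially all
person-time so the planted risk ratio is preserved where it matters.

Chart process
-------------
At most one chart event is simulated per calendar day.  On a day with a
considered decision, the day's (single) chart is the decision's outcome
draw, placed uniformly inside the 24-hour window after the considered
slot; spontaneous (untreated-rate) charting occurs only on days with no
decision today or yesterday.  This construction makes the recorded 24-hour
outcome at every considered decision point *exactly* the model Bernoulli
draw, so the empirical risk ratio in generated data converges to
exp(f' beta*).  Chart events feed back into next-day availability (the
inactivity wait rule) and into the history covariates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .design import TrialConfig, slot_schedule
from .emee import (
    DAYS_SINCE_CHART_CAP,
    DEFAULT_CONTROL_TERMS,
    ModelMatrixSpec,
    moderator_matrix,
)

__all__ = [
    "DEFAULT_ALPHA_STAR",
    "CohortConfig",
    "OutcomeModelParams",
    "sample_cohort",
    "engagement_probability",
    "misspecified_variant",
    "simulate_trial_dataset",
    "make_fixture",
]

#: Default true control coefficients.  The intercept sets the untreated
#: daily chart probability to ~0.25 (a free simulation parameter; the study
#: never reports the real base rate); the remaining slopes give mild,
#: plausible history dependence while keeping probabilities under the cap.
DEFAULT_ALPHA_STAR: Mapping[str, float] = {
    "intercept": float(np.log(0.25)),
    "week_in_study": -0.005,
    "days_since_chart": -0.03,
    "pushed_indicator": -0.15,
    "push_success_ratio": 0.30,
    "has_charted_10": 0.15,
}

_NEVER = -(10**6)


@dataclass(frozen=True)
class CohortConfig:
    """Size and fixture-dressing demographics of the simulated cohort.

    The demographic shares mirror the study sample (63.97% female; age
    shares 28.86% / 42.44% / 28.70% for <30, 30-50, >50; 52.88% with
    BMI >= 25); they dress the fixtures and are not causal moderators.
    All users enroll on day 1.
    """

    n_users: int = 1255
    share_female: float = 0.6397
    age_shares: tuple[float, float, float] = (0.2886, 0.4244, 0.2870)
    share_bmi25: float = 0.5288

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise ValueError(f"n_users must be >= 1, got {self.n_users}")
        shares = (self.share_female, *self.age_shares, self.share_bmi25)
        if any(not 0 <= s <= 1 for s in shares):
            raise ValueError("demographic shares must lie in [0, 1]")
        if abs(sum(self.age_shares) - 1.0) > 1e-9:
            raise ValueError("age bucket shares must sum to 1")


@dataclass(frozen=True)
class OutcomeModelParams:
    """True parameters of the synthetic outcome model.

    ``alpha_star`` maps control-covariate names (plus ``intercept``) to the
    true nuisance coefficients; ``beta_star`` are the true excursion
    coefficients on the log risk-ratio scale, matching ``moderator_spec``.
    ``hidden_weekend_uplift`` adds a weekend shift to the *generating*
    control model only — it is never part of the analysis controls, which
    is what makes :func:`misspecified_variant` a robustness probe.
    """

    alpha_star: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ALPHA_STAR)
    )
    beta_star: tuple[float, ...] = (0.04,)
    moderator_spec: ModelMatrixSpec = field(default_factory=ModelMatrixSpec)
    user_sd: float = 0.25
    prob_cap: float = 0.95
    hidden_weekend_uplift: float = 0.0

    def __post_init__(self) -> None:
        if self.user_sd < 0:
            raise ValueError("user_sd must be >= 0")
        if not 0 < self.prob_cap < 1:
            raise ValueError("prob_cap must be in (0, 1)")
        nb = len(self.moderator_spec.moderator_names)
        if len(self.beta_star) != nb:
            raise ValueError(
                f"beta_star has {len(self.beta_star)} entries but the "
                f"moderator spec defines {nb} columns"
            )

    def alpha_vector(self, terms: Sequence[str] = DEFAULT_CONTROL_TERMS) -> np.ndarray:
        return np.array(
            [self.alpha_star.get("intercept", 0.0)]
            + [self.alpha_star.get(t, 0.0) for t in terms]
        )


def misspecified_variant(
    params: OutcomeModelParams, hidden_weekend_uplift: float = 0.3
) -> OutcomeModelParams:
    """Variant whose generating control model adds a hidden weekend uplift.

    The excursion coefficients are unchanged, so any bias in beta_hat on
    data from this variant is attributable to nuisance misspecification.
    """
    return dataclasses.replace(params, hidden_weekend_uplift=hidden_weekend_uplift)


def sample_cohort(
    config: CohortConfig, rng: np.random.Generator, *, user_sd: float = 0.25
) -> pd.DataFrame:
    """Draw user traits and per-user intercepts b_u ~ N(0, user_sd^2)."""
    n = config.n_users
    female = (rng.random(n) < config.share_female).astype(np.int64)
    age_group = rng.choice(3, size=n, p=np.asarray(config.age_shares))
    bmi25 = (rng.random(n) < config.share_bmi25).astype(np.int64)
    intercept = (
        rng.normal(0.0, user_sd, size=n) if user_sd > 0 else np.zeros(n)
    )
    return pd.DataFrame(
        {
            "user_id": np.arange(n, dtype=np.int64),
            "female": female,
            "age_group": age_group,
            "bmi_ge_25": bmi25,
            "user_intercept": intercept,
        }
    )


def engagement_probability(
    covariates: np.ndarray,
    moderators: np.ndarray,
    treatment: int | np.ndarray,
    user_intercept: float | np.ndarray,
    params: OutcomeModelParams,
) -> np.ndarray | float:
    """Outcome probability min(cap, exp(g'alpha + b_u + A f'beta)).

    ``covariates`` must include the leading 1 for the intercept and align
    with ``(intercept, *DEFAULT_CONTROL_TERMS)``; ``moderators`` aligns
    with ``params.beta_star``.  Accepts single vectors or row-stacked
    matrices.
    """
    g = np.atleast_2d(np.asarray(covariates, dtype=float))
    f = np.atleast_2d(np.asarray(moderators, dtype=float))
    alpha = params.alpha_vector()
    beta = np.asarray(params.beta_star)
    if g.shape[1] != len(alpha):
        raise ValueError(
            f"control vector has {g.shape[1]} entries, expected {len(alpha)}"
        )
    if f.shape[1] != len(beta):
        raise ValueError(
            f"moderator vector has {f.shape[1]} entries, expected {len(beta)}"
        )
    a = np.asarray(treatment, dtype=float)
    lp = g @ alpha + np.asarray(user_intercept, dtype=float) + a * (f @ beta)
    prob = np.minimum(params.prob_cap, np.exp(lp))
    return float(prob[0]) if prob.shape == (1,) else prob


# ---------------------------------------------------------------------------
# Vectorized trial simulation
# ---------------------------------------------------------------------------

def simulate_trial_dataset(
    trial_config: TrialConfig,
    cohort_config: CohortConfig,
    params: OutcomeModelParams,
    rng: np.random.Generator,
    *,
    keep: str = "all",
    disable_day: Optional[np.ndarray] = None,
    return_events: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a complete long-format decision-record dataset.

    One row is emitted per user x day x slot (534 rows per user at the
    default 6 slots x 89 days), carrying the design indicators, the
    24-hour outcome, and the history covariates.  ``keep`` may restrict
    the returned rows to ``"available"`` or ``"considered"`` person-time
    (all rows are still simulated; this only trims the output, which the
    replication experiments use for speed).  ``disable_day``, if given, is
    a per-user day index from which notifications are off (the user can
    still chart spontaneously).  With ``return_events`` the chart-event log
    (user_id, day, clock) is returned alongside, for covariate
    cross-checks.

    The simulation is deterministic given ``rng``'s seed.
    """
    if keep not in ("all", "available", "considered"):
        raise ValueError(f"keep must be all/available/considered, got {keep!r}")
    cfg = trial_config
    n = cohort_config.n_users
    D = cfg.n_days
    S = cfg.n_slots
    slot_times = np.asarray(cfg.slot_times)
    p = cfg.randomization_prob
    spec = params.moderator_spec
    alpha = params.alpha_vector()
    beta = np.asarray(params.beta_star)
    a0, a_wk, a_dsc, a_pu, a_psr, a_h10 = alpha
    cap = params.prob_cap
    hidden = params.hidden_weekend_uplift

    users = sample_cohort(cohort_config, rng, user_sd=params.user_sd)
    b_u = users["user_intercept"].to_numpy()
    off_day = (
        np.full(n, np.inf) if disable_day is None else np.asarray(disable_day, float)
    )

    # running state
    last_evt = np.full(n, _NEVER)
    prev_evt = np.full(n, _NEVER)
    n_events = np.zeros(n, dtype=np.int64)
    last_dec = np.full(n, _NEVER)
    dec_yesterday = np.zeros(n, dtype=bool)
    push_cum = np.zeros(n, dtype=np.int64)
    succ_cum = np.zeros(n, dtype=np.int64)

    # logs (day index 0 unused; D+1 holds the post-study spillover day)
    evt_clock = np.full((n, D + 2), np.nan)
    push_day = np.zeros((n, D + 2), dtype=bool)
    push_clock = np.full((n, D + 2), np.nan)
    push_succ = np.zeros((n, D + 2), dtype=bool)
    eligible_log = np.zeros((n, D + 1), dtype=bool)
    cons_slot = np.zeros((n, D + 1), dtype=np.int64)
    treat_log = np.zeros((n, D + 1), dtype=np.int64)

    def day_controls(d: int) -> tuple[np.ndarray, ...]:
        """Day-start covariates (events/pushes strictly before day d)."""
        before = np.where(last_evt <= d - 1, last_evt, prev_evt)
        never = before < _NEVER // 2
        inact = np.where(never, d - 1, d - before)
        dsc = np.minimum(inact, DAYS_SINCE_CHART_CAP).astype(float)
        pushed = (push_cum > 0).astype(float)
        psr = succ_cum / np.maximum(push_cum, 1)
        n_before = n_events - (last_evt == d)
        hc10 = (n_before >= 10).astype(float)
        return inact, dsc, pushed, psr, hc10

    def record_events(mask: np.ndarray, eday: np.ndarray, clock: np.ndarray) -> None:
        idx = np.flatnonzero(mask)
        evt_clock[idx, eday[idx]] = clock[idx]
        prev_evt[idx] = last_evt[idx]
        last_evt[idx] = eday[idx]
        n_events[idx] += 1

    for d in range(1, D + 1):
        weekend = cfg.is_weekend(d)
        which_day = 0 if weekend else 1
        week = (d - 1) // 7
        sched = np.asarray(slot_schedule(cfg, d))
        k = len(sched)

        inact, dsc, pushed, psr, hc10 = day_controls(d)
        wait = cfg.rule_table.wait_days_vec(inact)
        enabled = d < off_day
        eligible = enabled & ((last_dec < _NEVER // 2) | (d - last_dec >= wait))

        draw_slot = rng.integers(0, k, size=n)
        draw_a = rng.random(n) < p
        draw_u = rng.random(n)
        draw_y = rng.random(n)

        slot_of = sched[draw_slot]
        lp = (
            a0
            + a_wk * week
            + a_dsc * dsc
            + a_pu * pushed
            + a_psr * psr
            + a_h10 * hc10
            + hidden * (1 - which_day)
            + b_u
        )
        fbeta = np.zeros(n)
        elig_idx = np.flatnonzero(eligible)
        if len(beta) and not spec.moderator_terms:
            fbeta[:] = beta[0]  # intercept-only moderator: constant effect
        elif len(elig_idx) and len(beta):
            fdf = pd.DataFrame(
                {
                    "slot": slot_of[elig_idx],
                    "week_in_study": float(week),
                    "which_day": float(which_day),
                    "days_since_chart": dsc[elig_idx],
                    "pushed_indicator": pushed[elig_idx],
                    "push_success_ratio": psr[elig_idx],
                    "has_charted_10": hc10[elig_idx],
                }
            )
            fbeta[elig_idx] = moderator_matrix(fdf, spec) @ beta
        a_eff = eligible & draw_a
        prob = np.minimum(cap, np.exp(lp + np.where(a_eff, fbeta, 0.0)))
        chart = draw_y < prob

        # decision-attributed chart events, uniform in the 24 h window
        ce = eligible & chart
        t_raw = slot_times[slot_of - 1] + draw_u * 24.0
        eday = np.where(t_raw >= 24.0, d + 1, d)
        clock = np.where(t_raw >= 24.0, t_raw - 24.0, t_raw)
        record_events(ce, eday, clock)

        # spontaneous charting on decision-free days
        spont = (~eligible) & (~dec_yesterday) & chart
        record_events(spont, np.full(n, d), draw_u * 24.0)

        pushed_today = eligible & draw_a
        push_day[:, d] = pushed_today
        push_clock[pushed_today, d] = slot_times[slot_of[pushed_today] - 1]
        push_succ[:, d] = pushed_today & chart
        push_cum += pushed_today
        succ_cum += pushed_today & chart
        last_dec[eligible] = d
        eligible_log[:, d] = eligible
        cons_slot[:, d] = np.where(eligible, slot_of, 0)
        treat_log[:, d] = a_eff.astype(np.int64)
        dec_yesterday = eligible

    # one extra day of spontaneous charting so final-day outcomes are
    # never censored
    d = D + 1
    _, dsc, pushed, psr, hc10 = day_controls(d)
    week = (d - 1) // 7
    which_day = 0 if ((cfg.start_weekday + d - 1) % 7) in (5, 6) else 1
    lp = (
        a0 + a_wk * week + a_dsc * dsc + a_pu * pushed + a_psr * psr
        + a_h10 * hc10 + hidden * (1 - which_day) + b_u
    )
    chart = rng.random(n) < np.minimum(cap, np.exp(lp))
    spont = (~dec_yesterday) & chart
    record_events(spont, np.full(n, d), rng.random(n) * 24.0)

    df = _assemble_records(
        cfg, n, evt_clock, push_day, push_clock, push_succ,
        eligible_log, cons_slot, treat_log, keep,
    )
    if return_events:
        uu, dd = np.nonzero(~np.isnan(evt_clock))
        events = pd.DataFrame(
            {"user_id": uu.astype(np.int64), "day": dd.astype(np.int64),
             "clock": evt_clock[uu, dd]}
        )
        return df, events
    return df


def _assemble_records(
    cfg: TrialConfig,
    n: int,
    evt_clock: np.ndarray,
    push_day: np.ndarray,
    push_clock: np.ndarray,
    push_succ: np.ndarray,
    eligible_log: np.ndarray,
    cons_slot: np.ndarray,
    treat_log: np.ndarray,
    keep: str,
) -> pd.DataFrame:
    """Build the long-format table with exact slot-level covariates."""
    D, S = cfg.n_days, cfg.n_slots
    tau = np.asarray(cfg.slot_times)  # (S,)
    days = np.arange(1, D + 1)

    in_sched = np.zeros((D, S), dtype=bool)
    for i, d in enumerate(days):
        in_sched[i, np.asarray(slot_schedule(cfg, d)) - 1] = True

    has_evt = ~np.isnan(evt_clock)  # (n, D+2)
    day_idx = np.arange(evt_clock.shape[1])
    L = np.maximum.accumulate(np.where(has_evt, day_idx[None, :], _NEVER), axis=1)
    cum_evt = np.cumsum(has_evt, axis=1)
    cum_push = np.cumsum(push_day, axis=1)
    cum_succ = np.cumsum(push_succ, axis=1)

    # (n, D, S) broadcasts; day d occupies column d-1 of the middle axis
    e_d = evt_clock[:, 1 : D + 1, None]
    e_d1 = evt_clock[:, 2 : D + 2, None]
    outcome = (~np.isnan(e_d) & (e_d > tau)) | (~np.isnan(e_d1) & (e_d1 <= tau))

    same_day_before = has_evt[:, 1 : D + 1, None] & (e_d < tau)
    L_prev = L[:, 0:D, None].astype(float)
    d_b = days[None, :, None].astype(float)
    dsc = np.where(
        same_day_before,
        0.0,
        np.where(L_prev > _NEVER // 2, d_b - L_prev, d_b - 1),
    )
    dsc = np.minimum(dsc, DAYS_SINCE_CHART_CAP)

    sent_before = cum_push[:, 0:D, None] + (
        push_day[:, 1 : D + 1, None] & (push_clock[:, 1 : D + 1, None] < tau)
    )
    prev_idx = np.maximum(days - 2, 0)
    compl_prev = push_day[:, 0:D, None] & (push_clock[:, 0:D, None] <= tau)
    succ_prev = push_succ[:, 0:D, None] & (push_clock[:, 0:D, None] <= tau)
    completed = cum_push[:, prev_idx, None] + compl_prev
    successes = cum_succ[:, prev_idx, None] + succ_prev
    psr = successes / np.maximum(completed, 1)

    hc10 = (cum_evt[:, 0:D, None] + same_day_before) >= 10

    cs = cons_slot[:, 1 : D + 1, None]
    slots_b = np.arange(1, S + 1)[None, None, :]
    available = (
        eligible_log[:, 1 : D + 1, None] & in_sched[None, :, :] & (slots_b <= cs)
    )
    considered = cs == slots_b
    push = considered & (treat_log[:, 1 : D + 1, None] == 1)

    weekdays = np.array([(cfg.start_weekday + d - 1) % 7 for d in days])
    which_day = (weekdays < 5).astype(np.int64)
    week = (days - 1) // 7

    flat = {
        "user_id": np.repeat(np.arange(n, dtype=np.int64), D * S),
        "day": np.tile(np.repeat(days, S), n),
        "slot": np.tile(np.arange(1, S + 1), n * D),
        "available": available.astype(np.int64).ravel(),
        "considered": considered.astype(np.int64).ravel(),
        "prob": np.where(considered, cfg.randomization_prob, np.nan).ravel(),
        "push": push.astype(np.int64).ravel(),
        "outcome_24h": outcome.astype(np.int64).ravel(),
        "week_in_study": np.tile(np.repeat(week, S), n),
        "which_day": np.tile(np.repeat(which_day, S), n),
        "days_since_chart": dsc.ravel(),
        "pushed_indicator": (sent_before > 0).astype(np.int64).ravel(),
        "push_success_ratio": psr.astype(float).ravel(),
        "has_charted_10": hc10.astype(np.int64).ravel(),
    }
    if keep == "available":
        mask = flat["available"] == 1
    elif keep == "considered":
        mask = flat["considered"] == 1
    else:
        mask = None
    if mask is not None:
        flat = {k: v[mask] for k, v in flat.items()}
    return pd.DataFrame(flat)


def make_fixture(seed: int = 20170301) -> pd.DataFrame:
    """Deterministic regression fixture: 5 users x 14 days x 6 slots."""
    rng = np.random.default_rng(seed)
    return simulate_trial_dataset(
        TrialConfig(n_days=14),
        CohortConfig(n_users=5),
        OutcomeModelParams(),
        rng,
    )
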