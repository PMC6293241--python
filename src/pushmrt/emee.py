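"""Causal excursion-effect estimation for a binary proximal outcome.

Estimates the marginal (or moderated) effect of sending versus not sending
a push notification on the probability of engaging with the app within
24 hours, on the log risk-ratio scale.  The effect at decision point t,
given moderators f(S_t), is modeled as

    log RR(t) = f_t' beta,

while a working log-linear nuisance model g_t' alpha absorbs the control
covariates.  Estimation solves the centered, weighted estimating equation

    0 = sum_users sum_t I_t W_t [ exp(-A_t f_t'beta) Y_{t+1} - exp(g_t'alpha) ]
                    * ( g_t ; (A_t - ptilde_t) f_t ),

with W_t = (ptilde_t/p_t)^{A_t} ((1-ptilde_t)/(1-p_t))^{1-A_t}.  The
exponential tilt exp(-A f'beta) "blips down" the treated outcomes, and the
centering factor (A - ptilde) f makes the beta estimate consistent even
when the control model g'alpha is misspecified — the defining robustness
property of this estimator.  Variance is the user-clustered sandwich
B^{-1} M B^{-T}, so standard errors are valid under arbitrary
within-person correlation of the binary outcomes.

The solver is Newton-Raphson with the analytic Jacobian and step-halving;
it is deterministic given the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_CONTROL_TERMS",
    "ModelMatrixSpec",
    "FitResult",
    "EffectEstimate",
    "WaldResult",
    "EstimationError",
    "ConvergenceError",
    "SeparationError",
    "derive_covariates",
    "moderator_matrix",
    "control_matrix",
    "estimating_function",
    "fit_emee",
    "sandwich_variance",
    "wald_test",
    "effect_estimate",
    "summary_table",
]

#: The five standard control covariates of the preplanned analyses.
DEFAULT_CONTROL_TERMS: tuple[str, ...] = (
    "week_in_study",
    "days_since_chart",
    "pushed_indicator",
    "push_success_ratio",
    "has_charted_10",
)

#: Cap on the days-since-chart covariate, to bound leverage.
DAYS_SINCE_CHART_CAP = 30


class EstimationError(RuntimeError):
    """Base class for estimation failures."""


class ConvergenceError(EstimationError):
    """Newton-Raphson failed to drive the estimating function to zero."""


class SeparationError(EstimationError):
    """A treatment arm has no positive outcomes; log-scale fit undefined."""


# ---------------------------------------------------------------------------
# Model matrix specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelMatrixSpec:
    """Which covariates enter the moderator vector f and the controls g.

    ``moderator_terms`` are added on top of an intercept unless
    ``moderator_intercept`` is false (used for one-hot slot coding, whose
    indicators span the constant).  ``p_tilde`` is the reference
    randomization probability used for centering and weighting; ``None``
    (default) uses each row's recorded randomization probability, which
    makes all weights 1.
    """

    moderator_terms: tuple[str, ...] = ()
    control_terms: tuple[str, ...] = DEFAULT_CONTROL_TERMS
    moderator_intercept: bool = True
    p_tilde: Optional[float] = None

    def __post_init__(self) -> None:
        if self.p_tilde is not None and not 0 < self.p_tilde < 1:
            raise ValueError(f"p_tilde must be in (0, 1), got {self.p_tilde}")
        if not self.moderator_intercept and not self.moderator_terms:
            raise ValueError("moderator must contain at least one column")

    @property
    def moderator_names(self) -> list[str]:
        names = ["push"] if self.moderator_intercept else []
        names += [f"push:{t}" for t in self.moderator_terms]
        return names

    @property
    def control_names(self) -> list[str]:
        return ["intercept"] + list(self.control_terms)


def _term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    """Resolve one model term to a numeric column.

    Supports plain covariate names, slot indicators ``slot_k``, and slot-by-
    day-type indicators ``slot_k:weekday`` / ``slot_k:weekend``.
    """
    if term in df.columns:
        return df[term].to_numpy(dtype=float)
    base, _, qual = term.partition(":")
    if base.startswith("slot_"):
        k = int(base.split("_")[1])
        col = (df["slot"].to_numpy() == k).astype(float)
        if qual == "weekday":
            col = col * (df["which_day"].to_numpy() == 1)
        elif qual == "weekend":
            col = col * (df["which_day"].to_numpy() == 0)
        elif qual:
            raise ValueError(f"unknown slot qualifier in term {term!r}")
        return col
    raise ValueError(f"unknown model term {term!r}")


def moderator_matrix(df: pd.DataFrame, spec: ModelMatrixSpec) -> np.ndarray:
    """Build the moderator design matrix f(S_t), one row per record."""
    cols = []
    if spec.moderator_intercept:
        cols.append(np.ones(len(df)))
    cols += [_term_column(df, t) for t in spec.moderator_terms]
    return np.column_stack(cols)


def control_matrix(df: pd.DataFrame, spec: ModelMatrixSpec) -> np.ndarray:
    """Build the control design matrix g(S_t) with a leading intercept."""
    cols = [np.ones(len(df))]
    cols += [_term_column(df, t) for t in spec.control_terms]
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Covariate derivation (reference, per-user implementation)
# ---------------------------------------------------------------------------

def derive_covariates(
    decisions: pd.DataFrame,
    charts: pd.DataFrame,
    *,
    slot_times: Sequence[float] = (8.5, 12.5, 17.5, 18.5, 19.5, 20.5),
    start_weekday: int = 0,
) -> pd.DataFrame:
    """Compute history covariates for each decision record, past-only.

    Parameters
    ----------
    decisions:
        One row per user x day x slot with columns ``user_id``, ``day``,
        ``slot`` and ``push`` (1 where a notification was sent), ordered
        chronologically within user.
    charts:
        Chart events with columns ``user_id``, ``day``, ``clock`` (hour of
        day in [0, 24)).

    Returns the decision table with columns ``week_in_study``,
    ``which_day``, ``days_since_chart``, ``pushed_indicator``,
    ``push_success_ratio`` and ``has_charted_10`` appended.  Every value is
    a function of strictly prior history: a past push counts toward the
    success ratio only once its full 24-hour window has elapsed, and its
    "success" is whether any chart event fell inside that window.
    """
    slot_times = tuple(slot_times)

    def abs_time(day: int, clock: float) -> float:
        return (day - 1) * 24.0 + clock

    out_rows = []
    for uid, grp in decisions.groupby("user_id", sort=False):
        days = grp["day"].to_numpy()
        slots = grp["slot"].to_numpy()
        if np.any(np.diff(abs_time(days, np.take(slot_times, slots - 1))) <= 0):
            raise ValueError(
                f"decision history for user {uid!r} is not chronologically ordered"
            )
        ev = charts[charts["user_id"] == uid]
        ev_times = np.sort(abs_time(ev["day"].to_numpy(), ev["clock"].to_numpy()))
        push_rows = grp[grp["push"] == 1]
        push_times = abs_time(
            push_rows["day"].to_numpy(),
            np.take(slot_times, push_rows["slot"].to_numpy() - 1),
        )
        push_success = np.array(
            [
                bool(np.any((ev_times > t) & (ev_times <= t + 24.0)))
                for t in push_times
            ]
        )
        for day, slot in zip(days, slots):
            t = abs_time(day, slot_times[slot - 1])
            week = (day - 1) // 7
            which_day = 0 if ((start_weekday + day - 1) % 7) in (5, 6) else 1
            past_ev = ev_times[ev_times < t]
            if len(past_ev):
                last_day = int(past_ev[-1] // 24) + 1
                dsc = min(day - last_day, DAYS_SINCE_CHART_CAP)
            else:
                dsc = min(day - 1, DAYS_SINCE_CHART_CAP)
            sent = push_times < t
            completed = push_times + 24.0 <= t
            n_completed = int(completed.sum())
            psr = (
                float(push_success[completed].sum()) / n_completed
                if n_completed
                else 0.0
            )
            out_rows.append(
                (
                    int(sent.sum() > 0),
                    psr,
                    int(week),
                    int(which_day),
                    float(dsc),
                    int(len(past_ev) >= 10),
                )
            )
    cov = pd.DataFrame(
        out_rows,
        columns=[
            "pushed_indicator",
            "push_success_ratio",
            "week_in_study",
            "which_day",
            "days_since_chart",
            "has_charted_10",
        ],
        index=decisions.index,
    )
    order = [
        "week_in_study",
        "which_day",
        "days_since_chart",
        "pushed_indicator",
        "push_success_ratio",
        "has_charted_10",
    ]
    return pd.concat([decisions, cov[order]], axis=1)


# ---------------------------------------------------------------------------
# Estimating equation
# ---------------------------------------------------------------------------

@dataclass
class _EmeeData:
    """Prepared row-level arrays for the estimating equation."""

    Y: np.ndarray
    A: np.ndarray
    p: np.ndarray
    p_tilde: np.ndarray
    G: np.ndarray
    F: np.ndarray
    user_codes: np.ndarray  # 0..n_users-1 per row
    n_users: int

    @property
    def weights(self) -> np.ndarray:
        return np.where(
            self.A == 1, self.p_tilde / self.p, (1 - self.p_tilde) / (1 - self.p)
        )

    @property
    def stack(self) -> np.ndarray:
        """Row-wise stacked vector ( g ; (A - ptilde) f )."""
        return np.hstack([self.G, (self.A - self.p_tilde)[:, None] * self.F])


def _prepare(
    data: pd.DataFrame,
    spec: ModelMatrixSpec,
    mode: str,
    trial_config=None,
) -> _EmeeData:
    from .design import TrialConfig, slot_schedule  # local: avoid cycle at import

    if mode not in ("considered", "available"):
        raise ValueError(f"mode must be 'considered' or 'available', got {mode!r}")
    if mode == "considered":
        rows = data[data["considered"] == 1].copy()
        p = rows["prob"].to_numpy(dtype=float)
    else:
        cfg = trial_config or TrialConfig()
        rows = data[data["available"] == 1].copy()
        # P(push at this slot | still available here) = p / (remaining open
        # slots including this one), by the sequential uniform selection law.
        remaining = np.empty(len(rows))
        sched_cache = {
            d: slot_schedule(cfg, d) for d in rows["day"].unique()
        }
        for i, (d, s) in enumerate(zip(rows["day"].to_numpy(), rows["slot"].to_numpy())):
            sched = sched_cache[d]
            remaining[i] = len(sched) - sched.index(s)
        p = cfg.randomization_prob / remaining
    if rows.empty:
        raise EstimationError("no analysis rows (empty risk set)")

    Y = rows["outcome_24h"].to_numpy(dtype=float)
    A = rows["push"].to_numpy(dtype=float)
    if not np.isfinite(p).all() or np.any((p <= 0) | (p >= 1)):
        raise EstimationError("randomization probabilities must lie in (0, 1)")
    pt = np.full(len(rows), spec.p_tilde) if spec.p_tilde is not None else p.copy()
    G = control_matrix(rows, spec)
    F = moderator_matrix(rows, spec)
    for names, mat, what in (
        (spec.control_names, G, "control"),
        (spec.moderator_names, F, "moderator"),
    ):
        sd = mat.std(axis=0)
        start = 1 if names and names[0] in ("intercept", "push") else 0
        for j in range(start, mat.shape[1]):
            if sd[j] == 0:
                raise EstimationError(
                    f"{what} column {names[j]!r} is constant in the analysis "
                    f"rows; drop it or use richer data"
                )
    codes, uniques = pd.factorize(rows["user_id"], sort=True)
    n_users = len(uniques)
    if n_users < 2:
        raise EstimationError("need at least 2 users for clustered inference")
    if (A == 1).sum() == 0 or (A == 0).sum() == 0:
        raise EstimationError("need considered records in both treatment arms")
    if Y[A == 1].sum() == 0 or Y[A == 0].sum() == 0:
        raise SeparationError(
            "a treatment arm has all-zero outcomes; the log-linear fit is "
            "not identified"
        )
    return _EmeeData(Y, A, p, pt, G, F, codes.astype(np.int64), n_users)


def _split(theta: np.ndarray, d: _EmeeData) -> tuple[np.ndarray, np.ndarray]:
    qa = d.G.shape[1]
    return theta[:qa], theta[qa:]


def _residual(theta: np.ndarray, d: _EmeeData) -> np.ndarray:
    alpha, beta = _split(theta, d)
    lin_a = d.G @ alpha
    lin_b = d.F @ beta
    with np.errstate(over="ignore"):
        ea = np.exp(lin_a)
        eb = np.exp(-d.A * lin_b)
    for name, arr in (("exp(g'alpha)", ea), ("exp(-A f'beta)", eb)):
        if not np.isfinite(arr).all():
            row = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise OverflowError(
                f"nonfinite {name} at analysis row {row} "
                f"(user code {d.user_codes[row]})"
            )
    return d.weights * (eb * d.Y - ea)


def estimating_function(
    theta: np.ndarray, d: _EmeeData
) -> tuple[np.ndarray, np.ndarray]:
    """Mean estimating function U(theta) and per-user contributions.

    Returns ``(U, per_user)`` where ``per_user`` has one row per user and
    ``U = per_user.mean(axis=0)``.
    """
    r = _residual(theta, d)
    rows = d.stack * r[:, None]
    per_user = np.zeros((d.n_users, rows.shape[1]))
    np.add.at(per_user, d.user_codes, rows)
    return per_user.mean(axis=0), per_user


def _jacobian(theta: np.ndarray, d: _EmeeData) -> np.ndarray:
    """Analytic Jacobian of the mean estimating function."""
    alpha, beta = _split(theta, d)
    ea = np.exp(d.G @ alpha)
    eb = np.exp(-d.A * (d.F @ beta))
    C = d.stack
    W = d.weights
    da = -(C * (W * ea)[:, None]).T @ d.G / d.n_users
    db = -(C * (W * d.A * eb * d.Y)[:, None]).T @ d.F / d.n_users
    return np.hstack([da, db])


def _per_user_jacobians(theta: np.ndarray, d: _EmeeData) -> np.ndarray:
    """Per-user Jacobian contributions (sum over the user's rows)."""
    alpha, beta = _split(theta, d)
    ea = np.exp(d.G @ alpha)
    eb = np.exp(-d.A * (d.F @ beta))
    C = d.stack
    W = d.weights
    q = C.shape[1]
    rows = np.empty((len(d.Y), q, q))
    left_a = C * (W * ea)[:, None]
    left_b = C * (W * d.A * eb * d.Y)[:, None]
    qa = d.G.shape[1]
    rows[:, :, :qa] = -left_a[:, :, None] * d.G[:, None, :]
    rows[:, :, qa:] = -left_b[:, :, None] * d.F[:, None, :]
    out = np.zeros((d.n_users, q, q))
    np.add.at(out, d.user_codes, rows)
    return out


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Solution of the excursion-effect estimating equation.

    ``vcov`` is the sandwich covariance of the stacked estimate
    (alpha_hat, beta_hat), already scaled to the estimates (divided by the
    number of users).  ``per_user_scores`` holds each user's summed
    estimating-function contribution at the solution.
    """

    alpha_hat: np.ndarray
    beta_hat: np.ndarray
    vcov: np.ndarray
    per_user_scores: np.ndarray
    n_users: int
    iterations: int
    converged: bool
    spec: ModelMatrixSpec
    alpha_names: list[str] = field(default_factory=list)
    beta_names: list[str] = field(default_factory=list)
    n_rows: int = 0

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.alpha_hat, self.beta_hat])

    @property
    def vcov_beta(self) -> np.ndarray:
        qa = len(self.alpha_hat)
        return self.vcov[qa:, qa:]

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))


def fit_emee(
    data: pd.DataFrame,
    spec: ModelMatrixSpec,
    *,
    mode: str = "considered",
    trial_config=None,
    small_sample: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FitResult:
    """Fit the log-linear causal excursion-effect model.

    Parameters
    ----------
    data:
        Long-format decision-record table carrying the covariate columns.
    spec:
        Moderator/control specification.
    mode:
        ``"considered"`` (default) restricts the risk set to considered
        decision points, where the recorded randomization probability
        applies; ``"available"`` uses all available person-time, treating
        not-yet-considered slots as untreated with the slot-selection
        probability folded into p_t (requires the trial configuration for
        the slot schedule; defaults apply when omitted).
    small_sample:
        Apply a Mancl-DeRouen-type bias correction to the sandwich
        meat (default off).

    Raises
    ------
    ConvergenceError
        If Newton-Raphson does not reach ``max(|U|) < tol``.
    SeparationError
        If a treatment arm has no positive outcomes.
    """
    d = _prepare(data, spec, mode, trial_config)
    qa, qb = d.G.shape[1], d.F.shape[1]

    # moment start: log rate among untreated rows for the intercept, 0 else
    base = max(float(d.Y[d.A == 0].mean()), 1e-6)
    theta = np.zeros(qa + qb)
    theta[0] = np.log(base)

    U, _ = estimating_function(theta, d)
    norm = np.max(np.abs(U))
    it = 0
    while norm >= tol and it < max_iter:
        J = _jacobian(theta, d)
        try:
            step = np.linalg.solve(J, -U)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular Jacobian at iteration {it} "
                f"(cond={np.linalg.cond(J):.3g})"
            ) from exc
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            U_new, _ = estimating_function(cand, d)
            if np.max(np.abs(U_new)) < norm:
                break
            scale *= 0.5
        else:
            raise ConvergenceError(
                f"step-halving stalled at iteration {it}, |U|_inf={norm:.3e}"
            )
        theta, U = cand, U_new
        norm = np.max(np.abs(U))
        it += 1
    if norm >= tol:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations, |U|_inf={norm:.3e}"
        )

    _, per_user = estimating_function(theta, d)
    vcov = _sandwich(theta, d, per_user, small_sample=small_sample)
    alpha, beta = _split(theta, d)
    return FitResult(
        alpha_hat=alpha,
        beta_hat=beta,
        vcov=vcov,
        per_user_scores=per_user,
        n_users=d.n_users,
        iterations=it,
        converged=True,
        spec=spec,
        alpha_names=spec.control_names,
        beta_names=spec.moderator_names,
        n_rows=len(d.Y),
    )


def _sandwich(
    theta: np.ndarray,
    d: _EmeeData,
    per_user: np.ndarray,
    *,
    small_sample: bool = False,
) -> np.ndarray:
    n = d.n_users
    B = _jacobian(theta, d)
    if small_sample:
        Ju = _per_user_jacobians(theta, d)
        B_tot = Ju.sum(axis=0)
        q = B_tot.shape[0]
        adj = np.empty_like(per_user)
        Binv_tot = np.linalg.inv(B_tot)
        for i in range(n):
            H = Ju[i] @ Binv_tot
            adj[i] = np.linalg.solve(np.eye(q) - H, per_user[i])
        M = adj.T @ adj / n
    else:
        M = per_user.T @ per_user / n
    try:
        Binv = np.linalg.inv(B)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(
            f"singular bread matrix (cond={np.linalg.cond(B):.3g})"
        ) from exc
    V = Binv @ M @ Binv.T
    V = (V + V.T) / 2
    return V / n


def sandwich_variance(
    fit: FitResult,
    data: pd.DataFrame,
    *,
    mode: str = "considered",
    trial_config=None,
    small_sample: bool = False,
) -> np.ndarray:
    """Recompute the user-clustered sandwich covariance of a converged fit.

    ``V = B^{-1} M B^{-T} / n_users`` with B the Jacobian of the mean
    estimating function and M the empirical second moment of per-user
    contributions; with ``small_sample`` the Mancl-DeRouen-type leverage
    correction inflates each user's contribution.
    """
    if not fit.converged:
        raise EstimationError("sandwich variance requires a converged fit")
    d = _prepare(data, fit.spec, mode, trial_config)
    _, per_user = estimating_function(fit.theta, d)
    return _sandwich(fit.theta, d, per_user, small_sample=small_sample)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaldResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class EffectEstimate:
    """A risk-ratio effect at one moderator value, with log-symmetric CI."""

    log_rr: float
    se: float
    ci_low: float
    ci_high: float
    level: float

    @property
    def rr(self) -> float:
        return float(np.exp(self.log_rr))


def wald_test(fit: FitResult, L: np.ndarray) -> WaldResult:
    """Wald chi-square test of H0: L beta = 0 using the sandwich covariance."""
    L = np.atleast_2d(np.asarray(L, dtype=float))
    qb = len(fit.beta_hat)
    if L.shape[1] != qb:
        raise ValueError(f"contrast has {L.shape[1]} columns, beta has {qb}")
    if np.linalg.matrix_rank(L) < L.shape[0]:
        raise ValueError("contrast matrix is rank deficient")
    est = L @ fit.beta_hat
    cov = L @ fit.vcov_beta @ L.T
    stat = float(est @ np.linalg.solve(cov, est))
    df = L.shape[0]
    return WaldResult(statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)))


def effect_estimate(
    fit: FitResult, x: Sequence[float], level: float = 0.95
) -> EffectEstimate:
    """Risk-ratio estimate exp(x' beta) with a normal-theory log-scale CI."""
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    x = np.asarray(x, dtype=float)
    if x.shape != (len(fit.beta_hat),):
        raise ValueError(
            f"moderator vector has shape {x.shape}, expected ({len(fit.beta_hat)},)"
        )
    log_rr = float(x @ fit.beta_hat)
    se = float(np.sqrt(x @ fit.vcov_beta @ x))
    z = stats.norm.ppf(0.5 + level / 2)
    return EffectEstimate(
        log_rr=log_rr,
        se=se,
        ci_low=float(np.exp(log_rr - z * se)),
        ci_high=float(np.exp(log_rr + z * se)),
        level=level,
    )


def summary_table(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Coefficient table mirroring the published layout.

    Causal (excursion) rows first, then control rows; p-values (normal
    reference) are reported for the causal coefficients only.
    """
    z = stats.norm.ppf(0.5 + level / 2)
    se = fit.se()
    qa = len(fit.alpha_hat)
    rows = []
    for j, name in enumerate(fit.beta_names):
        est, s = fit.beta_hat[j], se[qa + j]
        pz = 2 * stats.norm.sf(abs(est / s)) if s > 0 else np.nan
        rows.append(("causal", name, est, s, est - z * s, est + z * s, pz))
    for j, name in enumerate(fit.alpha_names):
        est, s = fit.alpha_hat[j], se[j]
        rows.append(("control", name, est, s, est - z * s, est + z * s, np.nan))
    return pd.DataFrame(
        rows,
        columns=["block", "term", "coefficient", "se", "ci_low", "ci_high", "p"],
    )
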