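"""Synthetic EMA study generation.

Emulates the design the engine was built for — 6 prompts/day for 21 days,
randomized within 2-hour windows between 9 AM and 9 PM — and the two
statistics reported for the latent constructs: intraclass correlations in
the 0.39-0.63 range and the calibrated interfactor correlations.

Latent model.  Person i's trajectory on domain g at occasion t is

    theta_{itg} = b_{ig} + e_{itg},

with person means b_i ~ MVN(0, diag(sqrt(icc)) R diag(sqrt(icc))) and
occasion deviations following a stationary lag-1 autoregression with
stationary covariance diag(sqrt(1-icc)) R diag(sqrt(1-icc)).  The total
stationary variance is therefore 1 per domain (preserving the calibration
metric) and the between-person share equals the configured ICC.  The AR(1)
deviation process is a modeling stand-in: no dynamic model is identified by
the reported statistics, and lag-1 autocorrelation (default phi = 0.4) is
the simplest way to make within-person change smooth rather than white.

Responses are sampled forward from the graded response model at the true
occasion theta.  Compliance is a Bernoulli process on a logistic scale with
a weekly decline and a normal person intercept; static risk-monitoring
items (intent / plan / attempt) are generated from the true active-SI
severity by logistic links, outside the adaptive test, and feed the alert
rule (intent above 8 of 10, any plan, or any attempt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .adaptive import SessionRecord, StoppingConfig, run_study
from .bank import ItemBank, ItemParameters
from .mgrm import category_probabilities
from .scoring import map_estimate

#: Published per-domain intraclass correlations, in default domain order.
DEFAULT_DOMAIN_ICCS: tuple[float, ...] = (
    0.49,  # humiliation
    0.57,  # loneliness
    0.39,  # anger
    0.58,  # pain
    0.49,  # negative urgency
    0.55,  # defeat
    0.54,  # entrapment
    0.53,  # distress tolerance
    0.63,  # perceived burdensomeness
    0.54,  # thwarted belongingness
    0.56,  # hope
    0.61,  # aggression
    0.55,  # passive SI
    0.47,  # active SI
)

DAY_START_MINUTE = 9 * 60  # windows span 9 AM .. 9 PM
WINDOW_MINUTES = 120
MIN_GAP_MINUTES = 15


@dataclass
class TrajectoryConfig:
    """Latent trajectory generator settings (defaults mirror the study design)."""

    n_persons: int = 29
    days: int = 21
    prompts_per_day: int = 6
    icc: Sequence[float] = DEFAULT_DOMAIN_ICCS
    ar_phi: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        icc = np.asarray(self.icc, dtype=float)
        if np.any(icc <= 0) or np.any(icc >= 1):
            raise ValueError("every domain ICC must lie strictly inside (0, 1)")
        if not 0 <= self.ar_phi < 1:
            raise ValueError("ar_phi must lie in [0, 1)")

    @property
    def n_occasions(self) -> int:
        return self.days * self.prompts_per_day


@dataclass
class TrueTrajectory:
    """One person's true latent path: (n_occasions, m) array plus the mean."""

    person_id: str
    theta: np.ndarray
    person_mean: np.ndarray


@dataclass
class ComplianceConfig:
    """Bernoulli-logistic compliance process.

    Defaults put mean completion near 0.56 with a latent-scale person-level
    ICC near 0.53 (person_sd^2 / (person_sd^2 + pi^2/3)) and a weekly
    decline of -0.10 logits, the anchors reported for the live study.
    """

    base_logit: float = 0.45
    week_slope: float = -0.10
    person_sd: float = 1.9


@dataclass
class RiskResponses:
    """Static risk-monitoring answers at one prompt."""

    intent: int  # 1..10
    plan: bool
    attempt: bool

    def __post_init__(self) -> None:
        if not 1 <= int(self.intent) <= 10:
            raise ValueError("intent must be in 1..10")


# ---------------------------------------------------------------------------
# Prompt schedule
# ---------------------------------------------------------------------------

def generate_prompt_schedule(days: int, seed: int = 0) -> np.ndarray:
    """Prompt times in minutes from midnight of day 0 (6 per day).

    One prompt is drawn uniformly inside each of six 2-hour windows between
    9 AM and 9 PM; a day is redrawn until all adjacent prompts are at least
    15 minutes apart.  Overnight gaps always exceed the minimum.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(days * 6)
    offsets = DAY_START_MINUTE + WINDOW_MINUTES * np.arange(6)
    for day in range(days):
        while True:
            t = offsets + rng.uniform(0, WINDOW_MINUTES, size=6)
            if np.all(np.diff(t) >= MIN_GAP_MINUTES):
                break
        out[day * 6 : (day + 1) * 6] = day * 1440 + t
    return out


# ---------------------------------------------------------------------------
# Latent trajectories
# ---------------------------------------------------------------------------

def sample_trajectories(
    config: TrajectoryConfig, prior_correlation: np.ndarray
) -> list[TrueTrajectory]:
    """Draw correlated person-level latent trajectories.

    Person means carry the between-person share of variance (the ICC) and
    deviations the rest, both with cross-domain correlation matrix R, so
    the stationary per-domain variance is 1.
    """
    R = np.asarray(prior_correlation, dtype=float)
    m = R.shape[0]
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as e:
        raise ValueError("prior correlation must be positive definite") from e

    icc = np.broadcast_to(np.asarray(config.icc, float), (m,)).copy()
    sd_between = np.sqrt(icc)
    sd_within = np.sqrt(1.0 - icc)
    phi = config.ar_phi
    T = config.n_occasions
    rng = np.random.default_rng(config.seed)

    trajectories = []
    for i in range(config.n_persons):
        b = sd_between * (L @ rng.standard_normal(m))
        e = np.empty((T, m))
        e[0] = sd_within * (L @ rng.standard_normal(m))
        innov_scale = np.sqrt(1.0 - phi**2)
        for t in range(1, T):
            eta = sd_within * (L @ rng.standard_normal(m))
            e[t] = phi * e[t - 1] + innov_scale * eta
        trajectories.append(
            TrueTrajectory(person_id=f"p{i:03d}", theta=b + e, person_mean=b)
        )
    return trajectories


# ---------------------------------------------------------------------------
# Response and compliance sampling
# ---------------------------------------------------------------------------

def sample_response(
    item: ItemParameters, theta: np.ndarray, rng: np.random.Generator
) -> int:
    """One category draw (1..K) from the graded response model at theta."""
    p = category_probabilities(item, theta)
    u = rng.random() * p.sum()
    return int(np.searchsorted(np.cumsum(p), u, side="right")) + 1


def grm_responder(true_theta: np.ndarray):
    """Responder closure for the adaptive engine at a fixed true theta."""
    theta = np.asarray(true_theta, dtype=float)

    def respond(item: ItemParameters, rng: np.random.Generator) -> int:
        return sample_response(item, theta, rng)

    return respond


def simulate_compliance(
    n_persons: int,
    occasions: int,
    base_logit: float = ComplianceConfig.base_logit,
    week_slope: float = ComplianceConfig.week_slope,
    person_sd: float = ComplianceConfig.person_sd,
    seed: int = 0,
    occasions_per_week: int = 42,
) -> np.ndarray:
    """Boolean completion matrix (n_persons, occasions).

    Completion ~ Bernoulli(logistic(base_logit + week_slope * week + b_i)),
    b_i ~ N(0, person_sd^2), week = occasion // occasions_per_week.
    """
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, person_sd, size=n_persons) if person_sd > 0 else np.zeros(n_persons)
    week = np.arange(occasions) // occasions_per_week
    logit = base_logit + week_slope * week[None, :] + b[:, None]
    return rng.random((n_persons, occasions)) < expit(logit)


def sample_risk_responses(
    active_si_theta: float, rng: np.random.Generator
) -> RiskResponses:
    """Static risk items from true active-SI severity via logistic links."""
    th = float(active_si_theta)
    intent = 1 + int(rng.binomial(9, expit(1.5 * (th - 2.0))))
    plan = bool(rng.random() < expit(2.0 * (th - 3.0)))
    attempt = bool(rng.random() < expit(2.0 * (th - 4.0)))
    return RiskResponses(intent=intent, plan=plan, attempt=attempt)


def flag_risk(responses: RiskResponses) -> bool:
    """Alert rule: intent above 8 of 10, a same-day plan, or an attempt."""
    return responses.intent > 8 or responses.plan or responses.attempt


# ---------------------------------------------------------------------------
# Whole-study orchestration
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    """Everything a simulated study produces, truth included."""

    sessions: list[SessionRecord]
    records: pd.DataFrame  # participant, occasion, prompt_time, step, item_id, response
    truth: pd.DataFrame  # participant, occasion, domain, true_theta (completed occasions)
    trajectories: list[TrueTrajectory]
    completed: np.ndarray  # (n_persons, n_occasions) bool
    schedule: np.ndarray  # minutes from midnight of day 0
    risk: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_study(
    bank: ItemBank,
    trajectory_config: TrajectoryConfig | None = None,
    stopping_config: StoppingConfig | None = None,
    compliance_config: ComplianceConfig | None = None,
    seed: int = 0,
    baseline: bool = True,
    active_si_domain: str = "active_si",
) -> StudyResult:
    """Simulate a full EMA study: truth, compliance, adaptive sessions, risk.

    Each person's baseline responses (full bank at their mean severity)
    initialize the first adaptive session; later sessions chain through
    carry-over.  All randomness derives from the single study seed.
    """
    tcfg = trajectory_config or TrajectoryConfig()
    ccfg = compliance_config or ComplianceConfig()
    root = np.random.SeedSequence(seed)
    traj_seed, comp_seed, sched_seed, resp_seed = root.spawn(4)

    tcfg_seeded = TrajectoryConfig(
        n_persons=tcfg.n_persons,
        days=tcfg.days,
        prompts_per_day=tcfg.prompts_per_day,
        icc=tcfg.icc,
        ar_phi=tcfg.ar_phi,
        seed=int(traj_seed.generate_state(1)[0] % (2**31)),
    )
    trajectories = sample_trajectories(tcfg_seeded, bank.prior_correlation)
    T = tcfg.n_occasions
    completed = simulate_compliance(
        tcfg.n_persons,
        T,
        ccfg.base_logit,
        ccfg.week_slope,
        ccfg.person_sd,
        seed=int(comp_seed.generate_state(1)[0] % (2**31)),
        occasions_per_week=7 * tcfg.prompts_per_day,
    )
    schedule = generate_prompt_schedule(
        tcfg.days, seed=int(sched_seed.generate_state(1)[0] % (2**31))
    )

    try:
        si_idx = [d.name for d in bank.domains].index(active_si_domain)
    except ValueError:
        si_idx = bank.n_domains - 1

    person_seeds = resp_seed.spawn(tcfg.n_persons)
    sessions: list[SessionRecord] = []
    truth_rows = []
    risk_rows = []
    for i, traj in enumerate(trajectories):
        base_rng = np.random.default_rng(person_seeds[i].spawn(1)[0])
        baseline_responses = (
            {
                it.item_id: sample_response(it, traj.person_mean, base_rng)
                for it in bank.items
            }
            if baseline
            else None
        )
        responders = [grm_responder(traj.theta[t]) for t in range(T)]
        recs = run_study(
            bank,
            responders,
            completed[i].tolist(),
            stopping_config,
            baseline_responses,
            participant_id=traj.person_id,
            seed=person_seeds[i],
        )
        sessions.extend(recs)
        risk_rng = np.random.default_rng(person_seeds[i].spawn(1)[0])
        for rec in recs:
            t = rec.occasion
            for d in bank.domains:
                truth_rows.append(
                    {
                        "participant": traj.person_id,
                        "occasion": t,
                        "domain": d.name,
                        "true_theta": traj.theta[t, d.domain_id],
                    }
                )
            rr = sample_risk_responses(traj.theta[t, si_idx], risk_rng)
            risk_rows.append(
                {
                    "participant": traj.person_id,
                    "occasion": t,
                    "intent": rr.intent,
                    "plan": rr.plan,
                    "attempt": rr.attempt,
                    "alert": flag_risk(rr),
                }
            )

    rec_rows = []
    for rec in sessions:
        for step, (iid, y) in enumerate(zip(rec.items, rec.responses)):
            rec_rows.append(
                {
                    "participant": rec.participant_id,
                    "occasion": rec.occasion,
                    "prompt_time": schedule[rec.occasion % len(schedule)],
                    "step": step,
                    "item_id": iid,
                    "response": y,
                }
            )
    return StudyResult(
        sessions=sessions,
        records=pd.DataFrame(rec_rows),
        truth=pd.DataFrame(truth_rows),
        trajectories=trajectories,
        completed=completed,
        schedule=schedule,
        risk=pd.DataFrame(risk_rows),
    )


# ---------------------------------------------------------------------------
# Evaluation aids
# ---------------------------------------------------------------------------

def aligned_truth_and_estimates(
    result: StudyResult,
) -> tuple[list[tuple[str, int]], np.ndarray, np.ndarray]:
    """Session-aligned (keys, true theta, adaptive estimate) arrays."""
    trajs = {t.person_id: t for t in result.trajectories}
    keys = [(s.participant_id, s.occasion) for s in result.sessions]
    truth = np.array([trajs[p].theta[o] for p, o in keys])
    est = np.array([s.final_state.theta_hat for s in result.sessions])
    return keys, truth, est


def fixed_form_estimates(
    bank: ItemBank,
    result: StudyResult,
    n_items: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, list[str]]:
    """Benchmark: MAP estimates from one random fixed form at the same truths.

    A single random `n_items`-item form (default: one test-length's worth,
    m items) is administered at every completed occasion of ``result``, with
    responses sampled from the same true latent states the adaptive sessions
    saw, scored with the same prior and carry-over starts.  Returns estimates
    aligned with ``aligned_truth_and_estimates`` plus the form's item ids.
    """
    n_items = n_items or bank.n_domains
    rng = np.random.default_rng(seed)
    form = [bank.items[i] for i in rng.choice(bank.n_items, n_items, replace=False)]
    trajs = {t.person_id: t for t in result.trajectories}
    prev: dict[str, np.ndarray] = {}
    rows = []
    for rec in result.sessions:
        theta_true = trajs[rec.participant_id].theta[rec.occasion]
        responses = {it.item_id: sample_response(it, theta_true, rng) for it in form}
        st = map_estimate(bank, responses, start=prev.get(rec.participant_id))
        rows.append(st.theta_hat)
        prev[rec.participant_id] = st.theta_hat
    return np.array(rows), [it.item_id for it in form]
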