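"""The adaptive administration engine: warm-up, D-optimal selection, stopping.

One session (one EMA survey) proceeds as follows.

1. Warm-up.  The most informative item from each of the m domains is
   administered, so every domain is assessed directly on every occasion and
   the minimum survey length is m (14 by default).  Selection is greedy: at
   each warm-up step the D-criterion best item among all still-uncovered
   domains is administered.
2. Adaptive phase.  Items are selected sequentially to maximize the
   determinant of the accumulated Fisher information matrix (D-optimal
   selection), which favors items informative about several latent domains
   at once.  The running matrix A includes the prior precision by default
   (Bayesian D-optimality), so determinants are nonsingular from the first
   item; a rank-1 identity det(A + g a a^T) = det(A)(1 + g a^T A^-1 a)
   reduces each candidate evaluation to a quadratic form.
3. Re-scoring.  After every response the latent state is re-estimated by
   MAP, giving the per-administration estimate history the CT-rule needs.
4. Stopping (dual rule, checked once the warm-up is complete):
   - D-rule: stop when det of the accumulated item information reaches
     (v/c)^2, where v is the volume constant of the m-dimensional
     confidence ellipsoid at level alpha and c the maximum allowable
     ellipsoid volume (default: the m-dimensional unit-ball volume).
   - CT-rule: stop when every domain estimate changed by less than epsilon
     (default 0.01) for `consecutive` (default 2) successive administrations.
   - A maximum test length (default 50) is enforced when neither rule fires.
   Precedence when several fire at the same step: D > CT > MAX.

Sessions are chained across EMA occasions by carry-over initialization:
occasion 1 starts from the full-bank baseline MAP estimate and every later
occasion from the final estimates of the most recent completed occasion.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln
from scipy.stats import chi2

from .bank import ItemBank, ItemParameters
from .mgrm import information_scalar, item_information
from .scoring import LatentState, map_estimate

logger = logging.getLogger(__name__)

#: A responder maps (item, rng) to a category in 1..K.
Responder = Callable[[ItemParameters, np.random.Generator], int]

D_RULE = "D_RULE"
CT_RULE = "CT_RULE"
MAX_LENGTH = "MAX_LENGTH"


def volume_constant(m: int, alpha: float) -> float:
    """Volume constant v of the level-(1-alpha) confidence ellipsoid.

        v = 2 pi^{m/2} [chi2_m(1-alpha)]^{m/2} / (m Gamma(m/2))

    For information matrix I the ellipsoid {theta : theta^T I theta <=
    chi2_m(1-alpha)} has volume v / sqrt(det I); at m=1 this reduces to
    twice the 0.975 normal quantile, at m=2 to pi * chi2_2(0.95).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    q = chi2.ppf(1 - alpha, df=m)
    log_v = (
        math.log(2.0)
        + (m / 2) * math.log(math.pi)
        + (m / 2) * math.log(q)
        - math.log(m)
        - gammaln(m / 2)
    )
    return float(math.exp(log_v))


def unit_ball_volume(m: int) -> float:
    """Volume of the m-dimensional unit ball, the default ellipsoid bound c."""
    return float(math.exp((m / 2) * math.log(math.pi) - gammaln(m / 2 + 1)))


@dataclass
class StoppingConfig:
    """Parameters of the dual variable-length stopping rule.

    ``c`` defaults to the unit-ball volume in the bank's dimension at run
    time (set ``c`` explicitly to override).  ``threshold_form`` selects the
    D-rule determinant threshold: "ratio" uses (v/c)^2, the form implied by
    the ellipsoid-volume derivation (volume v/sqrt(det) <= c); "product"
    uses (v*c)^2.  ``selection_includes_prior`` applies the prior precision
    inside the selection determinant (Bayesian D-optimality);
    ``stopping_includes_prior`` would do the same for the stopping
    determinant, which by default uses item information only.
    """

    alpha: float = 0.05
    c: float | None = None
    epsilon: float = 0.01
    consecutive: int = 2
    max_items: int = 50
    threshold_form: str = "ratio"
    selection_includes_prior: bool = True
    stopping_includes_prior: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.c is not None and not self.c > 0:
            raise ValueError("c must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        if self.consecutive < 1:
            raise ValueError("consecutive must be >= 1")
        if self.threshold_form not in ("ratio", "product"):
            raise ValueError("threshold_form must be 'ratio' or 'product'")

    def ellipsoid_bound(self, m: int) -> float:
        return self.c if self.c is not None else unit_ball_volume(m)

    def log_det_threshold(self, m: int) -> float:
        """log of the D-rule determinant threshold in dimension m."""
        v = volume_constant(m, self.alpha)
        c = self.ellipsoid_bound(m)
        if self.threshold_form == "ratio":
            return 2.0 * (math.log(v) - math.log(c))
        return 2.0 * (math.log(v) + math.log(c))

    def validate_for_bank(self, m: int) -> None:
        if self.max_items < m:
            raise ValueError(
                f"max_items={self.max_items} below the warm-up floor m={m}"
            )


@dataclass
class SessionRecord:
    """One administered EMA survey: items, responses, estimates, stop reason."""

    participant_id: str
    occasion: int
    items: list[str]
    responses: list[int]
    theta_history: list[np.ndarray]
    stop_reason: str | None
    final_state: LatentState
    complete: bool = True
    log_det_history: list[float] = field(default_factory=list)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def item_set(self) -> frozenset[str]:
        return frozenset(self.items)


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def _candidate_scores(bank: ItemBank, A: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """D-criterion gain g_j a_j^T A^-1 a_j for every bank item.

    det(A + g a a^T) = det(A) (1 + g a^T A^-1 a), so maximizing the gain
    maximizes the updated determinant.  Gains are nonnegative (PSD rank-1
    updates), hence the determinant never decreases within a step.
    """
    A_mat, D, _ = bank.arrays()
    g = information_scalar(A_mat @ theta, D)
    chol = cho_factor(A)
    S = cho_solve(chol, A_mat.T)  # (m, J)
    qf = np.einsum("jm,mj->j", A_mat, S)
    scores = g * qf
    if scores.min() < -1e-9:
        raise AssertionError("negative D-criterion gain: information update not PSD")
    return np.maximum(scores, 0.0)


def _argmax_lexicographic(bank: ItemBank, scores: np.ndarray, mask: np.ndarray) -> int:
    """Index of the best-scoring eligible item; ties go to the smallest item_id."""
    masked = np.where(mask, scores, -np.inf)
    best = masked.max()
    if not np.isfinite(best):
        raise ValueError("no eligible candidate items")
    tol = 1e-12 * max(1.0, abs(best))
    tied = np.flatnonzero(masked >= best - tol)
    ids = bank.item_ids
    return int(min(tied, key=lambda i: ids[i]))


def select_next_item(
    bank: ItemBank, state: LatentState, administered: set[str] | frozenset[str]
) -> str:
    """D-optimal next item: argmax_j det(A + I_j(theta_hat)) over the pool.

    A is taken from ``state.info`` (prior precision plus administered item
    information at the current estimate).  Ties break lexicographically.
    """
    ids = bank.item_ids
    mask = np.array([iid not in administered for iid in ids])
    if not mask.any():
        raise ValueError("all items have been administered")
    scores = _candidate_scores(bank, state.info, state.theta_hat)
    return ids[_argmax_lexicographic(bank, scores, mask)]


def warmup_sequence(bank: ItemBank, state: LatentState) -> list[str]:
    """Greedy warm-up: one D-optimal item per domain, best-uncovered first.

    At each step the best item of every still-uncovered domain is evaluated
    against the running information matrix and the globally best one is
    taken.  Evaluated at the fixed provisional estimate in ``state``.
    """
    ids = bank.item_ids
    _, _, primary = bank.arrays()
    A = state.info.copy()
    theta = state.theta_hat
    uncovered = {d.domain_id for d in bank.domains}
    chosen: list[str] = []
    chosen_idx: set[int] = set()
    while uncovered:
        scores = _candidate_scores(bank, A, theta)
        mask = np.array(
            [
                (primary[i] in uncovered) and (i not in chosen_idx)
                for i in range(bank.n_items)
            ]
        )
        if not mask.any():
            missing = sorted(uncovered)
            raise ValueError(f"no unadministered items left for domains {missing}")
        i = _argmax_lexicographic(bank, scores, mask)
        chosen.append(ids[i])
        chosen_idx.add(i)
        uncovered.discard(int(primary[i]))
        A = A + item_information(bank.items[i], theta)
    return chosen


# ---------------------------------------------------------------------------
# Stopping
# ---------------------------------------------------------------------------

def evaluate_stopping(
    state: LatentState, config: StoppingConfig, n_administered: int
) -> tuple[bool, str | None]:
    """Dual stopping rule, evaluated only once the warm-up is complete.

    Returns (stop, reason) with precedence D_RULE > CT_RULE > MAX_LENGTH.
    """
    m = state.theta_hat.shape[0]
    if n_administered < m:
        return False, None

    M = state.info if config.stopping_includes_prior else state.item_info
    sign, logdet = np.linalg.slogdet(M)
    if sign > 0 and logdet >= config.log_det_threshold(m):
        return True, D_RULE

    hist = state.history
    need = config.consecutive + 1
    if len(hist) >= need:
        recent = hist[-need:]
        changes = [
            float(np.max(np.abs(recent[i + 1] - recent[i])))
            for i in range(config.consecutive)
        ]
        if all(ch < config.epsilon for ch in changes):
            return True, CT_RULE

    if n_administered >= config.max_items:
        return True, MAX_LENGTH
    return False, None


# ---------------------------------------------------------------------------
# Session and study orchestration
# ---------------------------------------------------------------------------

def run_session(
    bank: ItemBank,
    responder: Responder,
    config: StoppingConfig | None = None,
    init: np.ndarray | None = None,
    seed: int | np.random.SeedSequence | None = None,
    prior_mean: np.ndarray | None = None,
    prior_cov: np.ndarray | None = None,
    participant_id: str = "p0",
    occasion: int = 0,
    carryover: str = "start",
) -> SessionRecord:
    """Administer one adaptive session against a responder.

    ``init`` carries over the preceding occasion's final estimates: with
    ``carryover="start"`` (default) it sets the provisional estimate used to
    select the first items and the MAP optimizer start, leaving the prior at
    the calibration N(0, R); with ``carryover="prior_mean"`` it shifts the
    prior mean itself.  Deterministic given (seed, responder).
    """
    config = config or StoppingConfig()
    m = bank.n_domains
    config.validate_for_bank(m)
    if carryover not in ("start", "prior_mean"):
        raise ValueError("carryover must be 'start' or 'prior_mean'")

    mu = np.zeros(m) if prior_mean is None else np.asarray(prior_mean, float)
    if init is not None and carryover == "prior_mean":
        mu = np.asarray(init, float)
    Sigma = bank.prior_correlation if prior_cov is None else prior_cov
    rng = np.random.default_rng(seed)

    state = map_estimate(bank, {}, prior_mean=mu, prior_cov=Sigma)
    if init is not None and carryover == "start":
        state.theta_hat = np.asarray(init, float).copy()

    items: list[str] = []
    responses: dict[str, int] = {}
    theta_hist: list[np.ndarray] = []
    logdet_hist: list[float] = []
    uncovered = {d.domain_id for d in bank.domains}
    administered: set[str] = set()
    stop_reason: str | None = None

    def _record() -> SessionRecord:
        state.history = theta_hist
        return SessionRecord(
            participant_id=participant_id,
            occasion=occasion,
            items=items,
            responses=[responses[i] for i in items],
            theta_history=theta_hist,
            stop_reason=stop_reason,
            final_state=state,
            complete=stop_reason is not None,
            log_det_history=logdet_hist,
        )

    while len(items) < config.max_items:
        ids = bank.item_ids
        if uncovered:
            _, _, primary = bank.arrays()
            mask = np.array(
                [
                    iid not in administered and primary[i] in uncovered
                    for i, iid in enumerate(ids)
                ]
            )
        else:
            mask = np.array([iid not in administered for iid in ids])
        if not mask.any():
            raise ValueError("item pool exhausted before a stopping rule fired")
        scores = _candidate_scores(bank, state.info, state.theta_hat)
        idx = _argmax_lexicographic(bank, scores, mask)
        item = bank.items[idx]

        try:
            y = int(responder(item, rng))
        except Exception:
            logger.exception(
                "responder failed at item %s; aborting session", item.item_id
            )
            return _record()
        if not 1 <= y <= 5:
            logger.error(
                "responder returned invalid category %r for item %s; aborting",
                y,
                item.item_id,
            )
            return _record()

        items.append(item.item_id)
        administered.add(item.item_id)
        responses[item.item_id] = y
        uncovered.discard(item.primary_domain)

        state = map_estimate(
            bank, responses, prior_mean=mu, prior_cov=Sigma, start=state.theta_hat
        )
        theta_hist.append(state.theta_hat.copy())
        state.history = theta_hist
        sign, logdet = np.linalg.slogdet(state.item_info)
        logdet_hist.append(float(logdet) if sign > 0 else -np.inf)

        stop, reason = evaluate_stopping(state, config, len(items))
        if stop:
            stop_reason = reason
            break

    if stop_reason is None:
        # loop guard exhausted without a rule firing (max_items reached)
        stop_reason = MAX_LENGTH
    return _record()


def run_study(
    bank: ItemBank,
    responders: Sequence[Responder],
    completed: Sequence[bool] | None,
    config: StoppingConfig | None,
    baseline_responses: Mapping[str, int] | None,
    participant_id: str = "p0",
    seed: int | np.random.SeedSequence = 0,
    prior_mean: np.ndarray | None = None,
    prior_cov: np.ndarray | None = None,
    carryover: str = "start",
) -> list[SessionRecord]:
    """Run all EMA occasions for one participant with carry-over initialization.

    Occasion 1 is initialized from a full-bank MAP fit to the baseline
    responses; each later occasion from the final estimates of the most
    recent completed occasion.  Missed occasions (``completed[t]`` false)
    are skipped, carrying the last estimates forward.  With no baseline the
    first occasion starts from the prior mean (logged).
    """
    m = bank.n_domains
    mu = np.zeros(m) if prior_mean is None else np.asarray(prior_mean, float)
    Sigma = bank.prior_correlation if prior_cov is None else prior_cov
    if baseline_responses:
        baseline_state = map_estimate(
            bank, baseline_responses, prior_mean=mu, prior_cov=Sigma
        )
        init = baseline_state.theta_hat
    else:
        logger.warning(
            "participant %s: no baseline responses; initializing from prior mean",
            participant_id,
        )
        init = mu.copy()

    if completed is None:
        completed = [True] * len(responders)
    if len(completed) != len(responders):
        raise ValueError("completed flags must match the number of occasions")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(len(responders))

    records: list[SessionRecord] = []
    for t, responder in enumerate(responders):
        if not completed[t]:
            continue
        rec = run_session(
            bank,
            responder,
            config=config,
            init=init,
            seed=children[t],
            prior_mean=prior_mean,
            prior_cov=prior_cov,
            participant_id=participant_id,
            occasion=t,
            carryover=carryover,
        )
        records.append(rec)
        if rec.complete:
            init = rec.final_state.theta_hat
    return records


# ---------------------------------------------------------------------------
# Logs
# ---------------------------------------------------------------------------

def write_sessions_jsonl(records: Sequence[SessionRecord], path: str | Path) -> None:
    """One administration per line: who/when/what plus the running estimate."""
    with Path(path).open("w") as fh:
        for rec in records:
            for step, (iid, y) in enumerate(zip(rec.items, rec.responses)):
                fh.write(
                    json.dumps(
                        {
                            "participant": rec.participant_id,
                            "occasion": rec.occasion,
                            "step": step,
                            "item_id": iid,
                            "response": y,
                            "theta_hat": rec.theta_history[step].tolist(),
                            "log_det": rec.log_det_history[step],
                            "stop_reason": (
                                rec.stop_reason if step == rec.n_items - 1 else None
                            ),
                        }
                    )
                    + "\n"
                )


def sessions_to_frame(records: Sequence[SessionRecord]):
    """Long study table: one row per administered item."""
    import pandas as pd

    rows = []
    for rec in records:
        for step, (iid, y) in enumerate(zip(rec.items, rec.responses)):
            rows.append(
                {
                    "participant": rec.participant_id,
                    "occasion": rec.occasion,
                    "step": step,
                    "item_id": iid,
                    "response": y,
                    "stop_reason": rec.stop_reason,
                    "session_length": rec.n_items,
                }
            )
    return pd.DataFrame(rows)
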