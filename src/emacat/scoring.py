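"""Maximum a posteriori (MAP) scoring of the multidimensional latent state.

Latent severity theta (one coordinate per domain, standard-normal metric) is
estimated as the posterior mode under a multivariate normal prior
N(mu, Sigma), where Sigma defaults to the bank's calibrated interfactor
correlation matrix.  The correlated prior is what lets a 14-dimensional
instrument work with short adaptive tests: items answered on one domain
shift the estimates of correlated domains through the prior ("borrowing
strength"), and domains with no administered items shrink to the prior mean.

The optimizer is a damped Newton ascent on the log posterior

    l(theta) = sum_j log p_{j, y_j}(theta) - (theta - mu)^T Sigma^{-1} (theta - mu) / 2

using the analytic gradient and the expected-information Hessian
approximation  H = Sigma^{-1} + sum_j I_j(theta),  which is positive
definite by construction, so every Newton direction is an ascent direction.
Step halving guards the rare non-concave far field.  Convergence is declared
at gradient norm < 1e-6 (max 200 iterations); the run is deterministic given
(responses, start), so repeated calls are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from .bank import ItemBank, N_CATEGORIES
from .mgrm import PROB_FLOOR

GRAD_TOL = 1e-6
MAX_ITER = 200


class ConvergenceError(RuntimeError):
    """MAP optimizer failed to converge; carries the best iterate found."""

    def __init__(self, message: str, best_state: "LatentState"):
        super().__init__(message)
        self.best_state = best_state


@dataclass
class LatentState:
    """Point estimate, accumulated information, and within-session history.

    ``info`` is prior precision plus the Fisher information of every scored
    item, evaluated at ``theta_hat`` (symmetric PD).  ``item_info`` is the
    same sum without the prior precision — the quantity the D-rule stopping
    determinant is defined on.  ``history`` holds theta_hat after each
    administration within a session.
    """

    theta_hat: np.ndarray
    info: np.ndarray
    item_info: np.ndarray
    history: list[np.ndarray] = field(default_factory=list)


def _response_arrays(bank: ItemBank, responses: Mapping[str, int]):
    A_rows, D_rows, ys = [], [], []
    for item_id, y in responses.items():
        if not 1 <= int(y) <= N_CATEGORIES:
            raise ValueError(
                f"response {y} for item {item_id!r} outside 1..{N_CATEGORIES}"
            )
        it = bank.item(item_id)
        A_rows.append(it.a)
        D_rows.append(it.d)
        ys.append(int(y))
    m = bank.n_domains
    if not A_rows:
        return np.zeros((0, m)), np.zeros((0, N_CATEGORIES - 1)), np.zeros(0, int)
    return np.stack(A_rows), np.stack(D_rows), np.array(ys, int)


def _posterior_pieces(A, D, y, theta, mu, prior_prec):
    """Log posterior, its gradient, scalar informations g_j, and p_{y_j}."""
    n = A.shape[0]
    if n:
        x = A @ theta
        cum = expit(x[:, None] + D)
        cum = np.concatenate([np.ones((n, 1)), cum, np.zeros((n, 1))], axis=1)
        p = np.maximum(-np.diff(cum, axis=1), PROB_FLOOR)  # (n, K)
        w = cum * (1.0 - cum)
        dw = w[:, :-1] - w[:, 1:]  # (n, K)
        idx = np.arange(n)
        p_y = p[idx, y - 1]
        s = dw[idx, y - 1] / p_y  # d log p_y / dx
        g = np.sum(dw * dw / p, axis=1)
        ll = float(np.sum(np.log(p_y)))
        grad_ll = A.T @ s
    else:
        ll, grad_ll, g = 0.0, np.zeros_like(theta), np.zeros(0)
    resid = theta - mu
    prior_term = prior_prec @ resid
    obj = ll - 0.5 * float(resid @ prior_term)
    grad = grad_ll - prior_term
    return obj, grad, g


def map_estimate(
    bank: ItemBank,
    responses: Mapping[str, int],
    prior_mean: np.ndarray | None = None,
    prior_cov: np.ndarray | None = None,
    start: np.ndarray | None = None,
) -> LatentState:
    """Posterior-mode estimate of theta given a response map.

    With no responses the mode is the prior mean exactly.  ``start`` sets
    the optimizer's initial point (used for occasion-to-occasion carry-over);
    it does not change the optimum, only the path to it.
    """
    m = bank.n_domains
    mu = np.zeros(m) if prior_mean is None else np.asarray(prior_mean, float).copy()
    Sigma = (
        bank.prior_correlation if prior_cov is None else np.asarray(prior_cov, float)
    )
    if Sigma.shape != (m, m) or not np.allclose(Sigma, Sigma.T, atol=1e-10):
        raise ValueError("prior covariance must be symmetric m x m")
    try:
        chol = cho_factor(Sigma)
    except np.linalg.LinAlgError as e:
        raise ValueError("prior covariance must be positive definite") from e
    prior_prec = cho_solve(chol, np.eye(m))
    prior_prec = (prior_prec + prior_prec.T) / 2

    A, D, y = _response_arrays(bank, responses)

    theta = mu.copy() if start is None else np.asarray(start, float).copy()
    obj, grad, g = _posterior_pieces(A, D, y, theta, mu, prior_prec)

    converged = not len(responses) and start is None
    if converged:
        theta = mu.copy()
    for _ in range(MAX_ITER):
        if float(np.linalg.norm(grad)) < GRAD_TOL:
            converged = True
            break
        H = prior_prec + (A.T * g) @ A if len(y) else prior_prec
        step = np.linalg.solve(H, grad)
        # damped Newton: halve until the log posterior does not decrease
        t = 1.0
        for _ in range(40):
            cand = theta + t * step
            cand_obj, cand_grad, cand_g = _posterior_pieces(
                A, D, y, cand, mu, prior_prec
            )
            if cand_obj >= obj - 1e-12:
                break
            t /= 2
        theta, obj, grad, g = cand, cand_obj, cand_grad, cand_g

    if len(y):
        x = A @ theta
        from .mgrm import information_scalar

        g_final = information_scalar(x, D)
        item_info = (A.T * g_final) @ A
    else:
        item_info = np.zeros((m, m))
    item_info = (item_info + item_info.T) / 2
    state = LatentState(
        theta_hat=theta,
        info=prior_prec + item_info,
        item_info=item_info,
        history=[theta.copy()],
    )
    if not converged and float(np.linalg.norm(grad)) >= GRAD_TOL:
        raise ConvergenceError(
            f"MAP did not converge in {MAX_ITER} iterations "
            f"(gradient norm {np.linalg.norm(grad):.3e})",
            state,
        )
    return state


def posterior_covariance(state: LatentState) -> np.ndarray:
    """Inverse of the accumulated information (symmetric PD)."""
    try:
        chol = cho_factor(state.info)
    except np.linalg.LinAlgError as e:
        raise ValueError("state.info is not positive definite") from e
    cov = cho_solve(chol, np.eye(state.info.shape[0]))
    return (cov + cov.T) / 2


def scores_to_frame(states, bank: ItemBank, participant_ids, occasions):
    """Long-format score table: participant, occasion, domain, theta_hat, sd."""
    import pandas as pd

    rows = []
    for pid, occ, st in zip(participant_ids, occasions, states):
        sd = np.sqrt(np.diag(posterior_covariance(st)))
        for d in bank.domains:
            rows.append(
                {
                    "participant": pid,
                    "occasion": occ,
                    "domain": d.name,
                    "theta_hat": st.theta_hat[d.domain_id],
                    "posterior_sd": sd[d.domain_id],
                }
            )
    return pd.DataFrame(rows)
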