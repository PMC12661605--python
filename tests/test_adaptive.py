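"""Adaptive engine: volume constant, warm-up, selection, stopping, sessions."""

import math

import numpy as np
import pytest
from scipy.stats import chi2, norm

from emacat.adaptive import (
    CT_RULE,
    D_RULE,
    MAX_LENGTH,
    SessionRecord,
    StoppingConfig,
    evaluate_stopping,
    run_session,
    run_study,
    select_next_item,
    unit_ball_volume,
    volume_constant,
    warmup_sequence,
)
from emacat.bank import BankConfig, DomainSpec, ItemBank, ItemParameters, make_synthetic_bank
from emacat.mgrm import item_information
from emacat.scoring import LatentState, map_estimate
from emacat.simulate import grm_responder

from conftest import make_toy_bank


class TestVolumeConstant:
    def test_one_dimension_reduces_to_normal_quantile(self):
        assert volume_constant(1, 0.05) == pytest.approx(2 * norm.ppf(0.975), rel=1e-12)

    def test_two_dimensions_reduces_to_ellipse_area(self):
        assert volume_constant(2, 0.05) == pytest.approx(
            math.pi * chi2.ppf(0.95, 2), rel=1e-12
        )

    def test_monte_carlo_ellipsoid_coverage(self, rng):
        """{theta: theta' I theta <= chi2_m(.95)} covers 95% of N(0, I^-1)."""
        for m in (2, 5):
            A = rng.normal(size=(m, m))
            I_mat = A @ A.T + m * np.eye(m)
            cov = np.linalg.inv(I_mat)
            L = np.linalg.cholesky(cov)
            n = 20000
            z = (L @ rng.standard_normal((m, n))).T
            inside = np.einsum("ni,ij,nj->n", z, I_mat, z) <= chi2.ppf(0.95, m)
            se = math.sqrt(0.95 * 0.05 / n)
            assert abs(inside.mean() - 0.95) < 3 * se

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            volume_constant(0, 0.05)
        with pytest.raises(ValueError):
            volume_constant(3, 1.5)


def fresh_state(bank, theta=None):
    st = map_estimate(bank, {})
    if theta is not None:
        st.theta_hat = np.asarray(theta, float)
    return st


class TestWarmup:
    def test_default_bank_covers_all_fourteen_domains(self, default_bank):
        seq = warmup_sequence(default_bank, fresh_state(default_bank))
        assert len(seq) == 14
        domains = {default_bank.item(i).primary_domain for i in seq}
        assert domains == set(range(14))
        assert len(set(seq)) == 14

    def test_dominant_items_selected(self):
        """With shared thresholds, the largest-discrimination item per domain
        dominates the D-criterion and must be the one selected."""
        d = np.array([1.2, 0.4, -0.4, -1.2])
        items = []
        for g in range(2):
            for j, a in enumerate((0.9, 1.4, 2.2)):
                vec = np.zeros(2)
                vec[g] = a
                items.append(ItemParameters(f"g{g}i{j}", "", vec, d, g))
        bank = ItemBank(
            items,
            [DomainSpec(0, "a", "risk"), DomainSpec(1, "b", "risk")],
            np.array([[1.0, 0.3], [0.3, 1.0]]),
        )
        seq = warmup_sequence(bank, fresh_state(bank))
        assert set(seq) == {"g0i2", "g1i2"}

    def test_greedy_matches_brute_force_determinants(self, toy_bank):
        """Replay the greedy warm-up with direct det evaluation per step."""
        state = fresh_state(toy_bank, theta=np.array([0.5, -0.3, 0.2]))
        seq = warmup_sequence(toy_bank, state)
        A = state.info.copy()
        uncovered = {0, 1, 2}
        chosen = set()
        for picked in seq:
            best_id, best_det = None, -np.inf
            for it in toy_bank.items:
                if it.item_id in chosen or it.primary_domain not in uncovered:
                    continue
                det = np.linalg.det(A + item_information(it, state.theta_hat))
                if det > best_det * (1 + 1e-12) or (
                    np.isclose(det, best_det, rtol=1e-10) and it.item_id < best_id
                ):
                    best_id, best_det = it.item_id, det
            assert picked == best_id
            chosen.add(picked)
            uncovered.discard(toy_bank.item(picked).primary_domain)
            A += item_information(toy_bank.item(picked), state.theta_hat)

    def test_empty_domain_raises(self, toy_bank):
        bank = ItemBank(
            [it for it in toy_bank.items if it.primary_domain != 2],
            toy_bank.domains,
            toy_bank.prior_correlation,
        )
        with pytest.raises(ValueError, match="domains"):
            warmup_sequence(bank, fresh_state(bank))


class TestSelection:
    def test_matches_brute_force_determinant_maximization(self, toy_bank, rng):
        responses = {}
        state = fresh_state(toy_bank)
        administered = set()
        for _ in range(12):
            picked = select_next_item(toy_bank, state, administered)
            best_id, best_det = None, -np.inf
            for it in toy_bank.items:
                if it.item_id in administered:
                    continue
                det = np.linalg.det(
                    state.info + item_information(it, state.theta_hat)
                )
                if det > best_det:
                    best_id, best_det = it.item_id, det
            assert picked == best_id
            administered.add(picked)
            responses[picked] = int(rng.integers(1, 6))
            state = map_estimate(toy_bank, responses, start=state.theta_hat)

    def test_unidimensional_candidates_ordered_by_discrimination(self):
        d = np.array([1.0, 0.3, -0.3, -1.0])  # common location at theta = 0
        items = [
            ItemParameters(f"i{j}", "", np.array([a]), d, 0)
            for j, a in enumerate((0.8, 1.1, 1.9, 1.5))
        ]
        bank = ItemBank(items, [DomainSpec(0, "only", "risk")], np.eye(1))
        state = fresh_state(bank, theta=np.zeros(1))
        assert select_next_item(bank, state, set()) == "i2"

    def test_never_returns_administered_item(self, toy_bank):
        state = fresh_state(toy_bank)
        administered = set()
        for _ in range(toy_bank.n_items):
            nxt = select_next_item(toy_bank, state, administered)
            assert nxt not in administered
            administered.add(nxt)
        with pytest.raises(ValueError, match="administered"):
            select_next_item(toy_bank, state, administered)

    def test_rank_one_determinant_identity(self, toy_bank, rng):
        """det(A + g aa') = det(A)(1 + g a'A^-1 a) to 1e-8 relative."""
        for _ in range(25):
            B = rng.normal(size=(3, 3))
            A = B @ B.T + 3 * np.eye(3)
            a = rng.normal(size=3)
            g = float(rng.uniform(0, 2))
            direct = np.linalg.det(A + g * np.outer(a, a))
            shortcut = np.linalg.det(A) * (1 + g * a @ np.linalg.solve(A, a))
            assert direct == pytest.approx(shortcut, rel=1e-8)

    def test_determinant_monotone_under_item_updates(self, toy_bank):
        theta = np.array([0.2, -0.4, 0.7])
        A = np.linalg.inv(toy_bank.prior_correlation)
        prev = np.linalg.det(A)
        for it in toy_bank.items:
            A = A + item_information(it, theta)
            cur = np.linalg.det(A)
            assert cur >= prev * (1 - 1e-12)
            prev = cur


class TestStopping:
    def _state(self, m=3, history=None, item_info=None):
        info = np.eye(m) * 5
        ii = item_info if item_info is not None else np.eye(m)
        st = LatentState(np.zeros(m), info, ii)
        st.history = history or []
        return st

    def test_not_evaluated_before_warmup_completes(self):
        st = self._state(history=[np.zeros(3)] * 5, item_info=np.eye(3) * 100)
        assert evaluate_stopping(st, StoppingConfig(max_items=50), 2) == (False, None)

    def test_ct_threshold_boundary(self):
        cfg = StoppingConfig(epsilon=0.01, consecutive=2, max_items=50)
        base = np.zeros(3)
        near = [base, base + 0.009, base + 0.018]
        st = self._state(history=near, item_info=np.eye(3) * 1e-6)
        assert evaluate_stopping(st, cfg, 10) == (True, CT_RULE)
        far = [base, base + 0.011, base + 0.022]
        st = self._state(history=far, item_info=np.eye(3) * 1e-6)
        assert evaluate_stopping(st, cfg, 10) == (False, None)

    def test_max_length_fires_at_cap(self):
        cfg = StoppingConfig(c=1e-200, epsilon=0.0, max_items=50)
        st = self._state(history=[np.zeros(3), np.ones(3)], item_info=np.eye(3))
        assert evaluate_stopping(st, cfg, 49) == (False, None)
        assert evaluate_stopping(st, cfg, 50) == (True, MAX_LENGTH)

    def test_d_rule_precedence_over_ct(self):
        cfg = StoppingConfig(c=1e200, epsilon=10.0, max_items=50)
        st = self._state(history=[np.zeros(3)] * 3, item_info=np.eye(3))
        assert evaluate_stopping(st, cfg, 10) == (True, D_RULE)

    def test_max_items_below_warmup_floor_rejected(self, toy_bank):
        cfg = StoppingConfig(max_items=2)
        with pytest.raises(ValueError, match="warm-up floor"):
            run_session(toy_bank, lambda item, rng: 3, cfg, seed=0)


class TestRunSession:
    def test_length_bounds_and_no_repeats(self, default_bank, rng):
        theta = np.linalg.cholesky(default_bank.prior_correlation) @ rng.standard_normal(14)
        rec = run_session(default_bank, grm_responder(theta), seed=5)
        assert 14 <= rec.n_items <= 50
        assert len(set(rec.items)) == rec.n_items
        assert len(rec.theta_history) == rec.n_items
        assert rec.stop_reason in (D_RULE, CT_RULE, MAX_LENGTH)
        assert rec.complete

    def test_trivial_d_rule_stops_at_warmup_floor(self, default_bank, rng):
        theta = rng.standard_normal(14) * 0.5
        cfg = StoppingConfig(c=1e250)
        rec = run_session(default_bank, grm_responder(theta), cfg, seed=6)
        assert rec.n_items == 14
        assert rec.stop_reason == D_RULE

    def test_unreachable_rules_stop_at_cap(self, default_bank, rng):
        theta = rng.standard_normal(14) * 0.5
        cfg = StoppingConfig(c=1e-250, epsilon=0.0)
        rec = run_session(default_bank, grm_responder(theta), cfg, seed=6)
        assert rec.n_items == 50
        assert rec.stop_reason == MAX_LENGTH

    def test_same_seed_gives_identical_record(self, toy_bank):
        theta = np.array([0.8, -0.5, 0.1])
        cfg = StoppingConfig(max_items=12)
        r1 = run_session(toy_bank, grm_responder(theta), cfg, seed=77)
        r2 = run_session(toy_bank, grm_responder(theta), cfg, seed=77)
        assert r1.items == r2.items
        assert r1.responses == r2.responses
        assert r1.stop_reason == r2.stop_reason
        for a, b in zip(r1.theta_history, r2.theta_history):
            assert np.array_equal(a, b)

    def test_ct_stop_fires_at_recorded_step_not_before(self, default_bank, rng):
        theta = rng.standard_normal(14) * 0.3
        cfg = StoppingConfig(epsilon=0.08)  # generous so CT fires mid-session
        rec = run_session(default_bank, grm_responder(theta), cfg, seed=8)
        if rec.stop_reason == CT_RULE and rec.n_items > 15:
            h = rec.theta_history
            last = [np.max(np.abs(h[-1] - h[-2])), np.max(np.abs(h[-2] - h[-3]))]
            assert all(ch < cfg.epsilon for ch in last)
            prior_step = [np.max(np.abs(h[-2] - h[-3])), np.max(np.abs(h[-3] - h[-4]))]
            assert not all(ch < cfg.epsilon for ch in prior_step)

    def test_responder_failure_flags_incomplete_partial_record(self, toy_bank):
        calls = {"n": 0}

        def flaky(item, rng):
            calls["n"] += 1
            if calls["n"] > 2:
                raise RuntimeError("respondent walked away")
            return 3

        rec = run_session(toy_bank, flaky, StoppingConfig(max_items=10), seed=1)
        assert not rec.complete
        assert rec.n_items == 2
        assert rec.stop_reason is None


class TestRunStudy:
    def _setup(self, rng):
        bank = make_toy_bank(n_domains=3, items_per_domain=8, seed=21)
        theta = rng.normal(size=3) * 0.5
        baseline = {
            it.item_id: int(rng.integers(1, 6)) for it in bank.items
        }
        responders = [grm_responder(theta + 0.1 * t) for t in range(4)]
        cfg = StoppingConfig(max_items=10)
        return bank, baseline, responders, cfg

    def test_first_occasion_initialized_from_baseline_map(self, rng):
        bank, baseline, responders, cfg = self._setup(rng)
        recs = run_study(bank, responders, [True, False, False, False], cfg, baseline, seed=3)
        init = map_estimate(bank, baseline).theta_hat
        children = np.random.SeedSequence(3).spawn(4)
        manual = run_session(bank, responders[0], cfg, init=init, seed=children[0], occasion=0)
        assert recs[0].items == manual.items
        assert recs[0].responses == manual.responses

    def test_carry_over_and_missed_occasion_carry_forward(self, rng):
        bank, baseline, responders, cfg = self._setup(rng)
        completed = [True, False, False, True]
        recs = run_study(bank, responders, completed, cfg, baseline, seed=3)
        assert [r.occasion for r in recs] == [0, 3]
        children = np.random.SeedSequence(3).spawn(4)
        manual = run_session(
            bank,
            responders[3],
            cfg,
            init=recs[0].final_state.theta_hat,
            seed=children[3],
            occasion=3,
        )
        assert recs[1].items == manual.items
        assert recs[1].responses == manual.responses

    def test_empty_baseline_falls_back_to_prior_mean_with_warning(self, rng, caplog):
        bank, _, responders, cfg = self._setup(rng)
        with caplog.at_level("WARNING"):
            recs = run_study(bank, responders[:1], [True], cfg, None, seed=4)
        assert "prior mean" in caplog.text
        assert len(recs) == 1
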