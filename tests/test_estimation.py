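"""MML-EM fitting: degenerate inputs, EM ascent, oracle equivalence, Wald tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import ehrlit as el
from ehrlit.estimation import DegenerateItemError, FitConfig, FitResult

from conftest import simulate_complete


def _grid_search_mml(matrix, nodes, weights, points=21, sweeps=80):
    """Independent oracle: grid maximization of the marginal likelihood of a
    small c = 0 item set, written directly from the model definition.

    The surface couples the slopes through the latent trait, so a single
    shrinking grid stalls off-peak; instead each item's (a, b) pair is
    maximized on a dense 2-D grid in turn, recentring on the best node and
    shrinking that item's window only when its maximum is interior.

    Note the 2-item case is not identified (4 parameters against 3 free
    pattern probabilities) -- use >= 3 items for parameter comparisons.
    """
    X = matrix.data
    n_items = X.shape[1]
    pats, counts = np.unique(X.astype(int), axis=0, return_counts=True)

    def loglik(params):
        a = params[0::2][:, None]
        b = params[1::2][:, None]
        P = expit(a * (nodes[None, :] - b))  # (items, nodes)
        L = np.ones((len(pats), len(nodes)))
        for j in range(n_items):
            L *= np.where(pats[:, j:j + 1] == 1, P[j][None, :], 1 - P[j][None, :])
        return float(counts @ np.log(np.clip(L @ weights, 1e-300, None)))

    center = np.array([1.0, 0.0] * n_items)
    half = np.array([1.4, 2.0] * n_items)
    for _ in range(sweeps):
        for item in range(n_items):
            ai, bi = 2 * item, 2 * item + 1
            a_axis = np.maximum(
                np.linspace(center[ai] - half[ai], center[ai] + half[ai], points), 0.05
            )
            b_axis = np.linspace(center[bi] - half[bi], center[bi] + half[bi], points)
            best, best_ll = None, -np.inf
            trial = center.copy()
            for ia, av in enumerate(a_axis):
                for ib, bv in enumerate(b_axis):
                    trial[ai], trial[bi] = av, bv
                    ll = loglik(trial)
                    if ll > best_ll:
                        best_ll, best = ll, (ia, ib)
            ia, ib = best
            center[ai], center[bi] = a_axis[ia], b_axis[ib]
            if 0 < ia < points - 1:
                half[ai] *= 0.5
            if 0 < ib < points - 1:
                half[bi] *= 0.5
        if np.all(half < 0.005):
            break
    return center, loglik(center)


class TestFitBasics:
    def test_all_correct_item_rejected_by_name(self):
        data = np.array([[1.0, 1.0], [0.0, 1.0], [1.0, 1.0]])
        m = el.ResponseMatrix(["p1", "p2", "p3"], ["ok", "easy"], data)
        with pytest.raises(DegenerateItemError, match="easy"):
            el.fit_3pl(m, FitConfig(fix_c_to_zero=True))

    def test_all_incorrect_item_rejected(self):
        data = np.array([[1.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        m = el.ResponseMatrix(["p1", "p2", "p3"], ["ok", "hard"], data)
        with pytest.raises(DegenerateItemError, match="hard"):
            el.fit_3pl(m)

    def test_em_loglik_nondecreasing(self):
        _, _, _, m = simulate_complete(8, 300, seed=21, guessing_fixed_zero=True)
        fit = el.fit_3pl(m, FitConfig(fix_c_to_zero=True, compute_se=False))
        hist = np.array(fit.loglik_history)
        assert np.all(np.diff(hist) > -1e-8)

    def test_convergence_flag_and_counts(self):
        _, _, _, m = simulate_complete(6, 250, seed=22, guessing_fixed_zero=True)
        fit = el.fit_3pl(m, FitConfig(fix_c_to_zero=True, compute_se=False))
        assert fit.converged
        assert fit.n_persons == 250 and fit.n_items == 6
        assert np.isfinite(fit.loglik)

    def test_standard_errors_positive_where_free(self):
        _, _, _, m = simulate_complete(6, 400, seed=23, guessing_fixed_zero=True)
        fit = el.fit_3pl(m, FitConfig(fix_c_to_zero=True))
        se = fit.standard_errors
        assert (se["a_se"] > 0).all() and (se["b_se"] > 0).all()
        assert se["c_se"].isna().all()  # fixed parameters carry no SE


class TestParameterRecovery:
    def test_difficulty_recovery_c_fixed_zero(self):
        """500 persons x 10 items with known 2PL truth: corr(b, b_hat) >= 0.9."""
        rng = np.random.default_rng(101)
        items = [
            el.ItemParameters(f"i{j:02d}", a=rng.uniform(0.8, 2.0), b=rng.uniform(-2, 1))
            for j in range(10)
        ]
        bank = el.ItemBank(items)
        theta = rng.standard_normal(500)
        m = el.simulate_responses(bank, theta, seed=101)
        fit = el.fit_3pl(m, FitConfig(fix_c_to_zero=True, compute_se=False))
        assert np.corrcoef(bank.b, fit.bank.b)[0, 1] >= 0.9

    def test_small_instance_fit_matches_grid_search_oracle(self):
        """EM estimates on a 3-item instance agree with direct grid
        maximization of the marginal likelihood within 0.05 per parameter."""
        bank = el.ItemBank(
            [
                el.ItemParameters("i1", 1.2, -0.5),
                el.ItemParameters("i2", 0.9, 0.4),
                el.ItemParameters("i3", 1.6, -1.0),
            ]
        )
        rng = np.random.default_rng(55)
        theta = rng.standard_normal(400)
        m = el.simulate_responses(bank, theta, seed=55)
        cfg = FitConfig(fix_c_to_zero=True, compute_se=False, convergence_tol=1e-7)
        fit = el.fit_3pl(m, cfg)
        grid = cfg.grid()
        oracle, _ = _grid_search_mml(m, grid.nodes, grid.weights)
        est = np.column_stack([fit.bank.a, fit.bank.b]).ravel()
        np.testing.assert_allclose(est, oracle, atol=0.05)


def _fake_fit(params, ses, fixed=False):
    bank = el.ItemBank(params)
    se = pd.DataFrame(
        ses, index=pd.Index(bank.item_ids, name="item_id"),
        columns=["a_se", "b_se", "c_se"],
    )
    cfg = FitConfig(fix_c_to_zero=fixed)
    return FitResult(
        bank=bank, standard_errors=se, loglik=-100.0, converged=True,
        n_iterations=10, n_persons=500, n_items=len(bank), config=cfg,
    )


class TestWaldTests:
    def test_small_guessing_not_significant(self):
        # |z| = 0.02 / 0.05 = 0.4 < 1.96
        fit = _fake_fit(
            [el.ItemParameters("i1", 1.0, 0.0, 0.02)], [[0.1, 0.1, 0.05]]
        )
        table = el.wald_tests(fit, alpha=0.05)
        assert table.loc["i1", "c_verdict"] == "not_significant"

    def test_strong_slope_significantly_positive(self):
        # z = 1.0 / 0.1 = 10 > 1.645
        fit = _fake_fit(
            [el.ItemParameters("i1", 1.0, 0.0, 0.2)], [[0.1, 0.1, 0.04]]
        )
        table = el.wald_tests(fit, alpha=0.05)
        assert bool(table.loc["i1", "a_significantly_positive"])
        assert table.loc["i1", "c_verdict"] == "significant"  # 0.2/0.04 = 5

    def test_fixed_guessing_skipped(self):
        fit = _fake_fit(
            [el.ItemParameters("i1", 1.0, 0.0, 0.0)],
            [[0.1, 0.1, np.nan]],
            fixed=True,
        )
        table = el.wald_tests(fit)
        assert table.loc["i1", "c_verdict"] == "fixed"

    def test_missing_slope_se_errors(self):
        fit = _fake_fit([el.ItemParameters("i1", 1.0, 0.0, 0.0)], [[np.nan, 0.1, 0.1]])
        with pytest.raises(ValueError, match="standard error"):
            el.wald_tests(fit)


@pytest.fixture(scope="module")
def fitted():
    bank, theta, _, m = simulate_complete(10, 500, seed=31, guessing_fixed_zero=True)
    fit = el.fit_3pl(m, FitConfig(compute_se=False))
    return bank, m, fit


class TestRefits:

    def test_identity_refit_keeps_loglik(self, fitted):
        _, m, fit = fitted
        refit = el.refit_with_constraints(m, fit)
        assert refit.loglik == pytest.approx(fit.loglik, abs=0.5)
        assert refit.item_ids == fit.item_ids

    def test_removing_one_item_shrinks_bank(self, fitted):
        _, m, fit = fitted
        refit = el.refit_with_constraints(m, fit, remove_items=[fit.item_ids[0]])
        assert len(refit.bank) == 9
        assert fit.item_ids[0] not in refit.item_ids

    def test_fixing_true_zero_guessing_costs_little(self, fitted):
        """Data generated with c=0: pinning one small c-hat at 0 moves the
        marginal log-likelihood by < 2 units (nested models, true value 0)."""
        _, m, fit = fitted
        smallest = fit.bank.item_ids[int(np.argmin(fit.bank.c))]
        refit = el.refit_with_constraints(m, fit, fix_c_items=[smallest])
        assert abs(refit.loglik - fit.loglik) < 2.0

    def test_exhausting_bank_rejected(self, fitted):
        _, m, fit = fitted
        with pytest.raises(ValueError, match="fewer than 2"):
            el.refit_with_constraints(m, fit, remove_items=fit.item_ids[:-1])


class TestResponseMatrix:
    def test_long_round_trip(self):
        _, _, _, m = simulate_complete(6, 40, seed=41)
        again = el.ResponseMatrix.from_long(m.to_long())
        assert again.person_ids == m.person_ids
        assert again.item_ids == m.item_ids
        np.testing.assert_array_equal(
            np.nan_to_num(again.data, nan=-1), np.nan_to_num(m.data, nan=-1)
        )

    def test_invalid_entries_rejected(self):
        with pytest.raises(ValueError):
            el.ResponseMatrix(["p1"], ["i1"], np.array([[2.0]]))

    def test_validate_catches_empty_person(self):
        m = el.ResponseMatrix(["p1", "p2"], ["i1"], np.array([[1.0], [np.nan]]))
        with pytest.raises(ValueError, match="p2"):
            m.validate()
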