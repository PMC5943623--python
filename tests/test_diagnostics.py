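"""Local-independence diagnostics: residual calibration, duplicates, covering."""

import numpy as np
import pytest
from scipy.stats import kstest

import ehrlit as el
from ehrlit.diagnostics import MarginalResidual
from ehrlit.estimation import FitConfig

from conftest import simulate_complete


@pytest.fixture(scope="module")
def fitted_null():
    """A fit, plus fresh data simulated from that fitted model (null case)."""
    bank, theta, _, m = simulate_complete(12, 1000, seed=61, guessing_fixed_zero=True)
    fit = el.fit_3pl(m, FitConfig(fix_c_to_zero=True, compute_se=False))
    rng = np.random.default_rng(62)
    fresh_theta = rng.standard_normal(1000)
    fresh = el.simulate_responses(fit.bank, fresh_theta, seed=62)
    return fit, fresh


class TestResidualStructure:
    def test_pairs_symmetric_in_item_order(self, fitted_null):
        fit, data = fitted_null
        res = el.pair_residuals(fit, data)
        # swap the response-matrix column order; residuals must be unchanged
        reversed_items = list(reversed(data.item_ids))
        swapped = data.subset_items(reversed_items)
        res_swapped = el.pair_residuals(fit, swapped)
        lut = {frozenset(r.item_set): r for r in res_swapped}
        for r in res:
            other = lut[frozenset(r.item_set)]
            assert r.z == pytest.approx(other.z, abs=1e-10)
            assert r.expected == pytest.approx(other.expected, abs=1e-12)

    def test_single_item_bank_empty(self):
        _, _, _, m = simulate_complete(2, 100, seed=63, guessing_fixed_zero=True)
        fit = el.fit_3pl(m, FitConfig(fix_c_to_zero=True, compute_se=False))
        one = m.subset_items([m.item_ids[0]])
        assert el.pair_residuals(fit, one) == []
        two = m  # 2 items: pairs exist but triplets cannot
        assert el.triplet_residuals(fit, two) == []

    def test_small_joint_sample_flagged_insufficient(self, fitted_null):
        fit, data = fitted_null
        res = el.pair_residuals(fit, data, min_joint_n=10**6)
        assert all(np.isnan(r.z) for r in res)
        assert all(r.insufficient for r in res)


class TestNullCalibration:
    def test_pair_residuals_rarely_exceed_three(self, fitted_null):
        """Data simulated from the fitted model: <= 1% of pairs with |z| > 3."""
        fit, fresh = fitted_null
        res = el.pair_residuals(fit, fresh)
        z = np.array([r.z for r in res])
        assert np.mean(np.abs(z) > 3) <= 0.01

    def test_triplet_residuals_rarely_exceed_three(self, fitted_null):
        fit, fresh = fitted_null
        res = el.triplet_residuals(fit, fresh)
        z = np.array([r.z for r in res])
        assert np.mean(np.abs(z) > 3) <= 0.01

    def test_residuals_approximately_standard_normal(self, fitted_null):
        """Marginal z-values are approximately N(0,1) under the null.

        Residuals within one administration are correlated through the
        shared respondents, so the aggregation takes one residual per
        independently simulated replicate (rotating through the pairs),
        giving independent draws for the KS test.
        """
        fit, _ = fitted_null
        zs = []
        for rep in range(60):
            rng = np.random.default_rng(700 + rep)
            fresh = el.simulate_responses(
                fit.bank, rng.standard_normal(1000), seed=700 + rep
            )
            res = el.pair_residuals(fit, fresh)
            zs.append(res[rep % len(res)].z)
        assert kstest(np.array(zs), "norm").pvalue > 0.01


@pytest.fixture(scope="module")
def duplicated_item_fit():
    """Calibrated-bank scenario: the model is fit honestly on clean data and
    a literal duplicate of one item appears at administration time.  (When
    the duplicate is present during fitting, MML can absorb the doublet into
    near-Guttman items, which masks the dependence -- so the calibrated-bank
    construction is the sharp test of the diagnostic itself.)"""
    from dataclasses import replace as _replace

    from ehrlit.estimation import FitResult

    bank, theta, _, m = simulate_complete(8, 1200, seed=65, guessing_fixed_zero=True)
    fit = el.fit_3pl(m, FitConfig(fix_c_to_zero=True, compute_se=False))
    dup_item = _replace(fit.bank.items[3], item_id="dup")
    ext_bank = el.ItemBank(fit.bank.items + [dup_item])
    ext_fit = FitResult(
        bank=ext_bank, standard_errors=None, loglik=fit.loglik,
        converged=fit.converged, n_iterations=fit.n_iterations,
        n_persons=fit.n_persons, n_items=len(ext_bank), config=fit.config,
    )
    data = np.column_stack([m.data, m.data[:, 3]])
    dup = el.ResponseMatrix(m.person_ids, m.item_ids + ["dup"], data)
    return dup, ext_fit


class TestDuplicatedItems:
    def test_duplicate_pair_flagged(self, duplicated_item_fit):
        dup, fit = duplicated_item_fit
        res = el.pair_residuals(fit, dup)
        target = next(r for r in res if set(r.item_set) == {dup.item_ids[3], "dup"})
        assert abs(target.z) > 3

    def test_triplets_containing_duplicates_flagged(self, duplicated_item_fit):
        dup, fit = duplicated_item_fit
        res = el.triplet_residuals(fit, dup)
        hits = [r for r in res if {dup.item_ids[3], "dup"} <= set(r.item_set)]
        assert hits and any(abs(r.z) > 3 for r in hits)

    def test_flagging_nominates_lower_slope_duplicate(self, duplicated_item_fit):
        dup, fit = duplicated_item_fit
        res = el.pair_residuals(fit, dup) + el.triplet_residuals(fit, dup)
        slopes = {it.item_id: it.a for it in fit.bank}
        slopes["dup"] -= 0.01  # make the tie-break deterministic
        removed = el.flag_local_dependence(res, 3.0, slopes)
        assert "dup" in removed

    def test_partial_duplicate_detected_within_fit(self):
        """A partially dependent extra item (15% of entries re-randomized) in
        a well-anchored 18-item bank is flagged from the within-sample fit."""
        bank, theta, _, m = simulate_complete(18, 1500, seed=301, guessing_fixed_zero=True)
        rng = np.random.default_rng(1235)
        dupcol = m.data[:, 3].copy()
        mask = rng.random(len(dupcol)) < 0.15
        dupcol[mask] = (rng.random(mask.sum()) < 0.7).astype(float)
        dup = el.ResponseMatrix(
            m.person_ids, m.item_ids + ["dup"], np.column_stack([m.data, dupcol])
        )
        fit = el.fit_3pl(dup, FitConfig(fix_c_to_zero=True, compute_se=False))
        res = el.pair_residuals(fit, dup) + el.triplet_residuals(fit, dup)
        slopes = {it.item_id: it.a for it in fit.bank}
        removed = el.flag_local_dependence(res, 3.0, slopes)
        assert {m.item_ids[3], "dup"} & set(removed)


class TestFlagCovering:
    def test_no_flags_empty_removal(self):
        res = [MarginalResidual(("a", "b"), 0.5, 0.5, 100, 0.2)]
        assert el.flag_local_dependence(res) == []

    def test_single_flagged_pair_removes_one_member(self):
        res = [MarginalResidual(("a", "b"), 0.9, 0.5, 100, 8.0)]
        removed = el.flag_local_dependence(res, slopes={"a": 1.0, "b": 0.5})
        assert removed == ["b"]  # lower slope nominated

    def test_cover_is_minimal_on_overlapping_flags(self):
        # item "hub" participates in every flagged set: one removal suffices
        res = [
            MarginalResidual(("hub", "x"), 0.9, 0.5, 100, 5.0),
            MarginalResidual(("hub", "y"), 0.9, 0.5, 100, 5.0),
            MarginalResidual(("hub", "z", "w"), 0.9, 0.5, 100, 5.0),
        ]
        assert el.flag_local_dependence(res) == ["hub"]

    def test_insufficient_pairs_never_flagged(self):
        res = [MarginalResidual(("a", "b"), 0.9, 0.5, 10, np.nan)]
        assert el.flag_local_dependence(res) == []
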