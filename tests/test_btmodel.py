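"""Bradley-Terry fitting and inference against independent oracles."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from pairpref import (
    ComparisonRecord,
    CountMatrices,
    ItemSet,
    SimulationScenario,
    aggregate,
    fit,
    fit_with_order,
    lrt_vs_null,
    pairwise_table,
    rereference,
    simulate_study,
    win_probability,
)
from pairpref.btmodel import BTFit, SeparationError, _loglik_counts, _pair_arrays

from conftest import grid_mle_3item


def _counts(labels, wins):
    wins = np.asarray(wins)
    items = ItemSet(labels)
    totals = wins + wins.T
    comparisons = np.triu(totals)  # any order split; wins drive the fit
    return CountMatrices(items, comparisons, wins)


TOY3 = _counts("abc", [[0, 8, 6], [2, 0, 7], [4, 3, 0]])


class TestWinProbability:
    def test_equal_worths_are_a_fair_coin(self):
        assert win_probability(0.0, 0.0, 0.0) == pytest.approx(0.5)

    @settings(max_examples=50, derandomize=True)
    @given(b1=st.floats(-5, 5), b2=st.floats(-5, 5))
    def test_complement_identity(self, b1, b2):
        assert win_probability(b1, b2) + win_probability(b2, b1) == pytest.approx(1.0)

    def test_closed_form_at_published_worths(self):
        # contrast 1.49 - 1.19 = 0.30 between the two best-liked products
        assert win_probability(1.49, 1.19, 0.0) == pytest.approx(
            1.0 / (1.0 + np.exp(-0.30)))

    def test_order_advantage_shifts_the_logit(self):
        assert win_probability(0.0, 0.0, 0.5) == pytest.approx(expit(0.5))


class TestFit:
    def test_perfectly_symmetric_pair_gives_zero_contrast(self):
        counts = _counts("ab", [[0, 5], [5, 0]])
        f = fit(counts, reference="a")
        assert f.beta[1] == pytest.approx(0.0, abs=1e-8)
        assert pairwise_table(f).p_value("a", "b") == pytest.approx(1.0)

    def test_three_item_toy_matches_grid_oracle(self):
        f = fit(TOY3, reference="a")
        oracle = grid_mle_3item(TOY3.wins)
        np.testing.assert_allclose(f.beta, oracle, atol=1e-3)

    def test_mm_and_newton_agree_on_the_toy(self):
        a = fit(TOY3, algorithm="newton")
        b = fit(TOY3, algorithm="mm")
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-6)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-9)

    def test_reference_coefficient_is_exactly_zero(self, fixture_fit):
        assert fixture_fit.beta[0] == 0.0

    def test_score_equations_hold_at_the_mle(self, fixture_counts, fixture_fit):
        # observed wins == sum of fitted win probabilities per item
        p = expit(fixture_fit.beta[:, None] - fixture_fit.beta[None, :])
        expected = (fixture_counts.pair_totals * p).sum(axis=1)
        observed = fixture_counts.wins.sum(axis=1)
        np.testing.assert_allclose(expected, observed, atol=1e-6)

    def test_likelihood_is_translation_invariant(self, fixture_counts, fixture_fit):
        iu, w_ij, n_ij = _pair_arrays(fixture_counts)
        ll0 = _loglik_counts(fixture_fit.beta, iu, w_ij, n_ij)
        ll1 = _loglik_counts(fixture_fit.beta + 3.7, iu, w_ij, n_ij)
        assert ll0 == pytest.approx(ll1, abs=1e-9)

    def test_covariance_is_symmetric_psd(self, fixture_fit):
        cov = fixture_fit.covariance
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_fit_json_roundtrip(self, fixture_fit, tmp_path):
        path = tmp_path / "fit.json"
        fixture_fit.to_json(path)
        back = BTFit.from_json(path)
        np.testing.assert_allclose(back.beta, fixture_fit.beta)
        np.testing.assert_allclose(back.covariance, fixture_fit.covariance)
        assert back.reference == fixture_fit.reference


class TestSeparation:
    def test_item_without_wins_is_named(self):
        counts = _counts("abc", [[0, 3, 2], [1, 0, 4], [0, 0, 0]])
        with pytest.raises(SeparationError) as exc:
            fit(counts)
        assert "c" in exc.value.items

    def test_disconnected_win_digraph_detected(self):
        # {a,b} and {c,d} trade wins internally; a,b always beat c,d
        wins = [[0, 2, 3, 3], [2, 0, 3, 3], [0, 0, 0, 2], [0, 0, 2, 0]]
        with pytest.raises(SeparationError, match="strongly connected"):
            fit(_counts("abcd", wins))

    def test_pseudocount_regularization_yields_finite_fit(self):
        counts = _counts("abc", [[0, 3, 2], [1, 0, 4], [0, 0, 0]])
        f = fit(counts, pseudocount=0.5)
        assert np.all(np.isfinite(f.beta))
        assert f.beta[2] < 0  # the all-losing item stays worst


class TestFitWithOrder:
    def test_null_order_effect_estimated_near_zero(self):
        sc = SimulationScenario.study_like(seed=21, true_delta=0.0,
                                           n_subjects=3000)
        f = fit_with_order(simulate_study(sc))
        assert abs(f.order_coef) < 3 * f.order_se

    def test_first_always_wins_between_equal_worths_separates(self):
        recs = [ComparisonRecord(f"s{k}", a, b, a)
                for k, (a, b) in enumerate(
                    [("x", "y"), ("y", "x"), ("x", "z"), ("z", "x"),
                     ("y", "z"), ("z", "y")] * 10)]
        with pytest.raises(SeparationError):
            fit_with_order(recs)

    def test_matches_statsmodels_logit(self):
        sm = pytest.importorskip("statsmodels.api")
        sc = SimulationScenario.study_like(seed=8, true_delta=0.2,
                                           n_subjects=150)
        records = simulate_study(sc)
        f = fit_with_order(records, reference="A1")
        items = sc.items
        labels = [x for x in items if x != "A1"]
        X, y = [], []
        for r in records:
            row = [(1.0 if lab == r.first else 0.0)
                   - (1.0 if lab == r.second else 0.0) for lab in labels]
            X.append(row + [1.0])
            y.append(1.0 if r.preferred == r.first else 0.0)
        res = sm.Logit(np.array(y), np.array(X)).fit(disp=0)
        ours = np.array([f.beta_dict[lab] for lab in labels] + [f.order_coef])
        np.testing.assert_allclose(ours, res.params, atol=1e-6)
        ses = np.array([f.se(lab) for lab in labels] + [f.order_se])
        np.testing.assert_allclose(ses, res.bse, atol=1e-5)


class TestRereference:
    def test_identity_rereference(self, fixture_fit):
        same = rereference(fixture_fit, "A1")
        np.testing.assert_allclose(same.beta, fixture_fit.beta)
        np.testing.assert_allclose(same.covariance, fixture_fit.covariance)

    def test_antisymmetry_of_reference_swap(self, fixture_fit):
        f4 = rereference(fixture_fit, "A4")
        assert f4.beta_dict["A1"] == pytest.approx(-fixture_fit.beta_dict["A4"])

    @pytest.mark.parametrize("ref", [f"A{k}" for k in range(1, 9)])
    def test_transform_agrees_with_refit(self, fixture_counts, fixture_fit, ref):
        transformed = rereference(fixture_fit, ref)
        refit = fit(fixture_counts, reference=ref)
        np.testing.assert_allclose(transformed.beta, refit.beta, atol=1e-6)
        np.testing.assert_allclose(transformed.covariance, refit.covariance,
                                   atol=1e-6)
        assert transformed.loglik == pytest.approx(fixture_fit.loglik, abs=0)

    def test_order_coefficient_survives_rereferencing(self):
        sc = SimulationScenario.study_like(seed=4, true_delta=0.3,
                                           n_subjects=200)
        f = fit_with_order(simulate_study(sc))
        g = rereference(f, "A5")
        assert g.order_coef == pytest.approx(f.order_coef)
        assert g.order_se == pytest.approx(f.order_se, rel=1e-9)


class TestPairwiseTable:
    def test_symmetry_and_antisymmetry(self, fixture_fit):
        tab = pairwise_table(fixture_fit)
        off = ~np.eye(8, dtype=bool)
        np.testing.assert_allclose(tab.p_values[off], tab.p_values.T[off])
        np.testing.assert_allclose(tab.estimates, -tab.estimates.T, atol=1e-12)
        assert np.isnan(np.diag(tab.p_values)).all()

    def test_every_cell_matches_refit_with_that_reference(self, fixture_counts,
                                                          fixture_fit):
        tab = pairwise_table(fixture_fit)
        labels = list(fixture_counts.items)
        for ref in labels:
            refit = fit(fixture_counts, reference=ref)
            for other in labels:
                if other == ref:
                    continue
                assert tab.p_value(other, ref) == pytest.approx(
                    refit.wald_p(other), abs=1e-6)


class TestGlobalTest:
    def test_null_loglik_is_closed_form(self, fixture_counts):
        res = lrt_vs_null(fixture_counts)
        assert res.loglik_null == pytest.approx(-224 * np.log(2))

    def test_balanced_wins_give_zero_statistic(self):
        wins = np.full((4, 4), 3)
        np.fill_diagonal(wins, 0)
        res = lrt_vs_null(_counts("abcd", wins))
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_statistic_nonnegative_and_df_m_minus_1(self, fixture_counts):
        res = lrt_vs_null(fixture_counts)
        assert res.statistic >= 0
        assert res.df == 7


@settings(max_examples=30, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_mm_and_newton_reach_the_same_optimum(seed):
    """Property: both fitters agree on random connected instances."""
    rng = np.random.default_rng(seed)
    m = 5
    beta = rng.uniform(-1.5, 1.5, m)
    wins = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i + 1, m):
            n_ij = rng.integers(4, 9)
            p = expit(beta[i] - beta[j])
            w = rng.binomial(n_ij, p)
            wins[i, j], wins[j, i] = w, n_ij - w
    counts = _counts([f"i{k}" for k in range(m)], wins)
    try:
        a = fit(counts, algorithm="newton")
    except SeparationError:
        return
    b = fit(counts, algorithm="mm")
    np.testing.assert_allclose(a.beta, b.beta, atol=1e-6)
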