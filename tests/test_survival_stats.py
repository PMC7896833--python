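"""Survival battery against hand computations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wsdlprog import (
    classification_metrics,
    cox_fit,
    fisher_exact,
    km_estimate,
    logrank_test,
    time_dependent_auc,
    univariate_screen,
)
from wsdlprog.survival_stats import SurvivalRecord


def _df(times, events):
    return pd.DataFrame({"time": times, "event": events})


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = km_estimate(_df([1, 2, 3, 4], [0, 1, 0, 1]))
        # at t=2: 3 at risk, 1 event -> S = 2/3; at t=4: 1 at risk -> S = 0
        np.testing.assert_allclose(curve.times, [2, 4])
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])
        np.testing.assert_allclose(curve.at_risk, [3, 1])
        assert curve.survival_at(1.5) == 1.0
        assert curve.survival_at(3.0) == pytest.approx(2 / 3)

    def test_all_censored_flat_curve(self):
        curve = km_estimate(_df([3, 5, 8], [0, 0, 0]))
        assert len(curve.times) == 0
        assert curve.survival_at(100) == 1.0

    def test_single_event(self):
        curve = km_estimate(_df([5.0], [1]))
        assert curve.survival_at(5.0) == 0.0
        assert curve.survival_at(4.9) == 1.0

    def test_nonincreasing_with_unit_start(self, rng):
        t = rng.exponential(10, 50) + 0.1
        e = rng.integers(0, 2, 50)
        if e.sum() == 0:
            e[0] = 1
        curve = km_estimate(_df(t, e))
        assert curve.survival_at(0) == 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(_df([0.0, 1.0], [1, 1]))
        with pytest.raises(ValueError):
            SurvivalRecord("x", -1.0, 1)


class TestLogRank:
    def test_identical_groups_null(self):
        g = _df([1, 2, 3, 4], [1, 0, 1, 1])
        chi2, p = logrank_test(g, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_symmetric_under_group_swap(self):
        a = _df([1, 2, 5, 7], [1, 1, 0, 1])
        b = _df([3, 4, 8], [1, 0, 1])
        chi2_ab, _ = logrank_test(a, b)
        chi2_ba, _ = logrank_test(b, a)
        assert chi2_ab == pytest.approx(chi2_ba, abs=1e-12)
        assert chi2_ab >= 0

    def test_hand_hypergeometric_table(self):
        """No censoring, A events at 1,2,3 and B at 4,5,6: the O-E and V
        accumulations have a closed hand-computed form."""
        a = _df([1, 2, 3], [1, 1, 1])
        b = _df([4, 5, 6], [1, 1, 1])
        chi2, p = logrank_test(a, b)
        # per event time: n1, n (at risk in A, total), one event each
        o_minus_e, v = 0.0, 0.0
        n1, n2 = 3, 3
        for in_a in (True, True, True, False, False, False):
            n = n1 + n2
            e_a = n1 / n
            o_minus_e += (1.0 if in_a else 0.0) - e_a
            v += n1 * n2 * (n - 1) / (n ** 2 * (n - 1)) if n > 1 else 0.0
            if in_a:
                n1 -= 1
            else:
                n2 -= 1
        expect_chi2 = o_minus_e ** 2 / v
        assert chi2 == pytest.approx(expect_chi2, abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(expect_chi2, 1), abs=1e-10)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(_df([1, 2], [0, 0]), _df([3], [0]))


class TestTimeDependentAuc:
    def test_perfect_marker(self):
        t = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        auc, _ = time_dependent_auc(-t, _df(t, np.ones(6, int)), t_eval=3.5)
        assert auc == pytest.approx(1.0)

    def test_constant_marker_half(self):
        t = np.arange(1, 9, dtype=float)
        auc, _ = time_dependent_auc(np.zeros(8), _df(t, np.ones(8, int)), t_eval=4.5)
        assert auc == pytest.approx(0.5)

    def test_equals_pair_counting_without_censoring(self, rng):
        t = rng.exponential(10, 40) + 0.5
        e = np.ones(40, int)
        m = rng.standard_normal(40)
        t_eval = float(np.median(t))
        auc, roc = time_dependent_auc(m, _df(t, e), t_eval)
        cases = m[t <= t_eval]
        ctrls = m[t > t_eval]
        wins = sum((c > k) + 0.5 * (c == k) for c in cases for k in ctrls)
        assert auc == pytest.approx(wins / (len(cases) * len(ctrls)), abs=1e-12)
        assert roc["sensitivity"].iloc[-1] == pytest.approx(1.0)
        assert 0 <= auc <= 1

    def test_matches_ipcw_reference_with_censoring(self, rng):
        """Cross-check against scikit-survival's cumulative/dynamic AUC."""
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        n = 60
        t = rng.exponential(20, n) + 0.5
        c = rng.exponential(30, n) + 0.5
        obs = np.minimum(t, c)
        e = (t <= c).astype(int)
        m = -t + rng.standard_normal(n)
        t_eval = float(np.quantile(obs, 0.5))
        if not ((obs <= t_eval) & (e == 1)).any():
            pytest.skip("no cases at the evaluation time")
        auc, _ = time_dependent_auc(m, _df(obs, e), t_eval)
        y = np.array(
            [(bool(ev), tt) for ev, tt in zip(e, obs)],
            dtype=[("event", "?"), ("time", "<f8")],
        )
        ref, _ = sksurv_metrics.cumulative_dynamic_auc(y, y, m, [t_eval])
        assert auc == pytest.approx(float(ref[0]), abs=5e-3)

    def test_out_of_range_t_eval_rejected(self):
        with pytest.raises(ValueError):
            time_dependent_auc([1, 2], _df([1, 2], [1, 1]), t_eval=10.0)


class TestCox:
    def test_grid_search_partial_likelihood_oracle(self):
        """12 patients, binary covariate, no ties: the fitted log-HR matches
        a dense grid search of the partial likelihood to 1e-4."""
        times = np.array([1.1, 2.3, 3.1, 4.7, 5.2, 6.9, 7.4, 8.8, 9.5, 10.1, 11.6, 12.2])
        events = np.ones(12, int)
        x = np.array([1, 1, 0, 1, 0, 1, 0, 0, 1, 0, 0, 0], dtype=float)
        fit = cox_fit(pd.DataFrame({"x": x}), _df(times, events))
        beta_hat = float(np.log(fit.hazard_ratio("x")))

        order = np.argsort(times)
        xs = x[order]
        betas = np.linspace(-5, 5, 200_001)

        def neg_pl(b):
            # all events, no ties: sum over events of b*x_i - log(sum_riskset e^{b x_j})
            val = np.zeros_like(b)
            for i in range(12):
                risk = xs[i:]
                val += b * xs[i] - np.log(np.exp(b[:, None] * risk).sum(axis=1))
            return -val

        beta_grid = betas[np.argmin(neg_pl(betas))]
        assert beta_hat == pytest.approx(beta_grid, abs=1e-4)

    def test_collinear_covariates_rejected(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        cov = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValueError, match="collinear|constant"):
            cox_fit(cov, _df(np.arange(1, 7, dtype=float), np.ones(6, int)))

    def test_ci_coverage_of_true_hazard_ratio(self):
        """Exponential data with true HR 3 at n=300: the 95% Wald CI covers
        the truth in at least 17 of 20 replicates."""
        covered = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            x = rng.integers(0, 2, 300).astype(float)
            t = rng.exponential(1.0 / (0.05 * 3.0 ** x))
            fit = cox_fit(pd.DataFrame({"x": x}), _df(t, np.ones(300, int)))
            row = fit.summary.loc["x"]
            covered += row["ci_lower"] <= 3.0 <= row["ci_upper"]
        assert covered >= 17


class TestClassificationMetrics:
    def test_confusion_matrix_inversion_of_test_set(self):
        # TP=7 FN=1 TN=10 FP=2 -> 87.50 / 83.33 / 85.00
        truth = [1] * 8 + [0] * 12
        pred = [1] * 7 + [0] + [0] * 10 + [1] * 2
        sens, spec, acc = classification_metrics(pred, truth)
        assert sens == pytest.approx(87.50)
        assert spec == pytest.approx(83.33, abs=0.005)
        assert acc == pytest.approx(85.00)

    def test_perfect_prediction(self):
        sens, spec, acc = classification_metrics([1, 0, 1], [1, 0, 1])
        assert (sens, spec, acc) == (100.0, 100.0, 100.0)

    def test_all_predicted_positive(self):
        sens, spec, acc = classification_metrics([1, 1, 1, 1], [1, 1, 0, 0])
        assert (sens, spec, acc) == (100.0, 0.0, 50.0)

    def test_degenerate_margin_named(self):
        with pytest.raises(ValueError, match="no true positives"):
            classification_metrics([1, 0], [0, 0])


class TestFisherExact:
    def test_balanced_table_null(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [
            [[3, 7], [6, 2]],
            [[1, 9], [8, 2]],
            [[4, 0], [3, 5]],
            [[10, 0], [0, 10]],
        ],
    )
    def test_matches_hypergeometric_enumeration(self, table):
        (a, b), (c, d) = table
        n = a + b + c + d
        row1, col1 = a + b, a + c
        kmin, kmax = max(0, col1 - (n - row1)), min(row1, col1)
        pmf = {
            k: stats.hypergeom.pmf(k, n, row1, col1) for k in range(kmin, kmax + 1)
        }
        p_obs = pmf[a]
        expect = sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))
        assert fisher_exact(table) == pytest.approx(min(expect, 1.0), abs=1e-12)

    def test_extreme_table_significant(self):
        assert fisher_exact([[10, 0], [0, 10]]) < 1e-4

    def test_empty_margin_convention(self):
        with pytest.warns(UserWarning):
            assert fisher_exact([[0, 0], [3, 4]]) == 1.0


class TestUnivariateScreen:
    def test_consistent_with_direct_logrank(self, rng):
        n = 40
        t = rng.exponential(12, n) + 0.5
        e = rng.integers(0, 2, n)
        e[:5] = 1
        group = rng.integers(0, 2, n)
        table = pd.DataFrame({"psi_high": group})
        res = univariate_screen(table, _df(t, e))
        hi, lo = _df(t[group == 1], e[group == 1]), _df(t[group == 0], e[group == 0])
        _, p_direct = logrank_test(hi, lo)
        assert res.loc[res.variable == "psi_high", "p"].iloc[0] == pytest.approx(p_direct)

    def test_median_cutoff_splits_evenly(self, rng):
        vals = np.arange(1, 11, dtype=float)
        rng.shuffle(vals)
        t = np.arange(1, 11, dtype=float)
        e = np.ones(10, int)
        res = univariate_screen(pd.DataFrame({"v": vals}), _df(t, e))
        assert res["cutoff"].iloc[0] == pytest.approx(5.5)

    def test_constant_variable_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            res = univariate_screen(
                pd.DataFrame({"c": np.ones(6)}),
                _df(np.arange(1, 7, dtype=float), np.ones(6, int)),
            )
        assert len(res) == 0

    def test_null_covariate_type_one_error(self):
        """Independent marker: the 5% level test rejects in ~5% of 200
        replicates of n = 500 (binomial band 5% +/- 2.5%)."""
        n, reps = 500, 200
        rejections = 0
        for rep in range(reps):
            rng = np.random.default_rng(5000 + rep)
            t = rng.exponential(30, n) + 0.01
            c = rng.uniform(5, 60, n)
            obs = np.minimum(t, c)
            e = (t <= c).astype(int)
            marker = rng.standard_normal(n)
            res = univariate_screen(pd.DataFrame({"m": marker}), _df(obs, e))
            rejections += res["p"].iloc[0] < 0.05
        rate = rejections / reps
        assert 0.025 <= rate <= 0.075
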