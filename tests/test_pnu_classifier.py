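"""PNU risk algebra, Monte-Carlo unbiasedness, and fitting oracles."""

import numpy as np
import pytest
from scipy import integrate, stats

from wsdlprog import (
    PnuConfig,
    assign_implicit_labels,
    fit_pnu,
    nu_risk,
    pn_risk,
    pnu_risk,
    pu_risk,
)

LN2 = np.log(2.0)


def _logistic(z):
    return np.logaddexp(0.0, -z)


class TestRiskAlgebra:
    def test_constant_zero_scorer_gives_ln2_everywhere(self):
        z = np.zeros(5)
        for prior in (0.2, 0.5, 0.9):
            assert pn_risk(z, z, prior) == pytest.approx(LN2, abs=1e-12)
            assert pu_risk(z, z, prior) == pytest.approx(LN2, abs=1e-12)
            assert nu_risk(z, z, prior) == pytest.approx(LN2, abs=1e-12)
            cfg = PnuConfig(gamma=0.5, prior_pos=prior)
            assert pnu_risk(z, z, z, cfg) == pytest.approx(LN2, abs=1e-12)

    def test_perfect_separation_limit(self):
        assert pn_risk([50.0], [-50.0], 0.5) < 1e-9

    def test_pn_risk_matches_hand_formula(self):
        sp, sn, prior = np.array([1.0, -1.0]), np.array([-2.0]), 0.5
        expect = prior * _logistic(sp).mean() + (1 - prior) * _logistic(-sn).mean()
        assert pn_risk(sp, sn, prior) == pytest.approx(expect, abs=1e-12)

    def test_clamp_zeroes_negative_term(self):
        # unlabeled scores far below the positives' drive the PU negative
        # term below zero; with the correction it contributes exactly 0
        sp = np.array([2.0, 3.0])
        su = np.array([-5.0, -6.0])
        prior = 0.9
        uncorrected = pu_risk(sp, su, prior, nonneg_correction=False)
        corrected = pu_risk(sp, su, prior, nonneg_correction=True)
        neg_term = _logistic(-su).mean() - prior * _logistic(-sp).mean()
        assert neg_term < 0
        assert corrected == pytest.approx(prior * _logistic(sp).mean(), abs=1e-12)
        assert uncorrected < corrected

    def test_gamma_endpoints_bitwise(self, rng):
        sp = rng.standard_normal(7)
        sn = rng.standard_normal(5)
        su = rng.standard_normal(11)
        for prior in (0.3, 0.6):
            base = dict(prior_pos=prior)
            assert pnu_risk(sp, sn, su, PnuConfig(gamma=0.0, **base)) == pn_risk(sp, sn, prior)
            assert pnu_risk(sp, sn, su, PnuConfig(gamma=1.0, **base)) == pu_risk(sp, su, prior)
            assert pnu_risk(sp, sn, su, PnuConfig(gamma=-1.0, **base)) == nu_risk(sn, su, prior)

    def test_empty_unlabeled_requires_gamma_zero(self):
        sp, sn = np.ones(3), -np.ones(3)
        assert pnu_risk(sp, sn, [], PnuConfig(gamma=0.0)) == pn_risk(sp, sn, 0.5)
        with pytest.raises(ValueError):
            pnu_risk(sp, sn, [], PnuConfig(gamma=0.5))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            pn_risk([], [1.0], 0.5)

    def test_permutation_and_duplication_invariance(self, rng):
        sp = rng.standard_normal(6)
        sn = rng.standard_normal(4)
        su = rng.standard_normal(9)
        cfg = PnuConfig(gamma=0.25, prior_pos=0.4)
        base = pnu_risk(sp, sn, su, cfg)
        assert pnu_risk(sp[::-1], rng.permutation(sn), su, cfg) == pytest.approx(base, abs=1e-12)
        assert pnu_risk(np.tile(sp, 3), sn, np.tile(su, 2), cfg) == pytest.approx(
            base, abs=1e-12
        )

    def test_corrected_risks_nonnegative(self, rng):
        for _ in range(20):
            sp = rng.standard_normal(5) * 3
            sn = rng.standard_normal(5) * 3
            su = rng.standard_normal(8) * 3
            assert pu_risk(sp, su, 0.7) >= 0
            assert nu_risk(sn, su, 0.7) >= 0


class TestUnbiasedness:
    def test_uncorrected_pu_risk_is_unbiased_monte_carlo(self):
        """Mean of the uncorrected PU risk over repeated draws from a known
        positive/negative score mixture matches the population PN risk."""
        prior = 0.4
        mu_p, mu_n, sd = 1.0, -1.0, 1.0

        def pop_term(mu, sign):
            f = lambda s: _logistic(sign * s) * stats.norm.pdf(s, mu, sd)
            return integrate.quad(f, -12, 12)[0]

        pop_risk = prior * pop_term(mu_p, +1) + (1 - prior) * pop_term(mu_n, -1)

        rng = np.random.default_rng(2024)
        n_rep, n_p, n_u = 10_000, 40, 60
        sp = rng.normal(mu_p, sd, size=(n_rep, n_p))
        comp = rng.random((n_rep, n_u)) < prior
        su = np.where(
            comp,
            rng.normal(mu_p, sd, size=(n_rep, n_u)),
            rng.normal(mu_n, sd, size=(n_rep, n_u)),
        )
        vals = np.array(
            [
                pu_risk(sp[i], su[i], prior, nonneg_correction=False)
                for i in range(n_rep)
            ]
        )
        se = vals.std(ddof=1) / np.sqrt(n_rep)
        assert abs(vals.mean() - pop_risk) < 3 * se


class TestFitPnu:
    def _toy_1d(self, rng, n=30):
        xp = 1.0 + 0.1 * rng.standard_normal((n, 1))
        xn = -1.0 - 0.1 * rng.standard_normal((n, 1))
        comp = rng.random(2 * n) < 0.5
        xu = np.where(comp, 1.0, -1.0)[:, None] + 0.1 * rng.standard_normal((2 * n, 1))
        return xp, xn, xu

    def test_matches_dense_grid_search_oracle(self, rng):
        """Penalized PNU objective at the fitted point agrees with a dense
        (weight, bias) grid search over [-5, 5]^2 to 1e-4."""
        xp, xn, xu = self._toy_1d(rng)
        l2 = 0.05
        cfg = PnuConfig(gamma=0.5, prior_pos=0.5, l2_penalty=l2)
        model = fit_pnu(xp, xn, xu, cfg)
        assert model.weights[0] > 0

        def objective(W, B):
            def mean_loss(x, sign):
                s = sign * (W[..., None] * x.ravel() + B[..., None])
                return _logistic(s).mean(axis=-1)

            pn = 0.5 * mean_loss(xp, 1) + 0.5 * mean_loss(xn, -1)
            neg = np.maximum(0.0, mean_loss(xu, -1) - 0.5 * mean_loss(xp, -1))
            pu = 0.5 * mean_loss(xp, 1) + neg
            return 0.5 * pn + 0.5 * pu + l2 * W ** 2

        # coarse pass over the full box, then a fine pass around the optimum
        W, B = np.meshgrid(np.linspace(-5, 5, 101), np.linspace(-5, 5, 101), indexing="ij")
        obj = objective(W, B)
        i, j = np.unravel_index(obj.argmin(), obj.shape)
        w0, b0 = W[i, j], B[i, j]
        Wf, Bf = np.meshgrid(
            np.linspace(w0 - 0.15, w0 + 0.15, 301),
            np.linspace(b0 - 0.15, b0 + 0.15, 301),
            indexing="ij",
        )
        grid_best = objective(Wf, Bf).min()

        fitted = (
            pnu_risk(model.score(xp), model.score(xn), model.score(xu), cfg)
            + l2 * float(model.weights @ model.weights)
        )
        assert fitted == pytest.approx(grid_best, abs=1e-4)

    def test_reduces_to_pn_classification_without_unlabeled(self, rng):
        from sklearn.linear_model import LogisticRegression

        xp = rng.normal(1.2, 0.4, (10, 1))
        xn = rng.normal(-1.2, 0.4, (10, 1))
        cfg = PnuConfig(gamma=0.0, prior_pos=0.5, l2_penalty=1e-3)
        model = fit_pnu(xp, xn, None, cfg)
        skl = LogisticRegression(C=1e3).fit(
            np.vstack([xp, xn]), np.r_[np.ones(10), np.zeros(10)]
        )
        test_x = np.linspace(-2, 2, 21)[:, None]
        ours = np.sign(model.score(test_x))
        theirs = np.sign(skl.decision_function(test_x))
        agree = (ours == theirs) | (ours == 0)
        assert agree.mean() >= 0.95

    def test_duplication_leaves_fit_unchanged(self, rng):
        xp, xn, xu = self._toy_1d(rng, n=10)
        cfg = PnuConfig(gamma=0.3, prior_pos=0.5)
        m1 = fit_pnu(xp, xn, xu, cfg)
        m2 = fit_pnu(np.vstack([xp, xp]), np.vstack([xn, xn]), np.vstack([xu, xu]), cfg)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-10)
        assert m1.bias == pytest.approx(m2.bias, abs=1e-10)

    def test_final_risk_beats_zero_scorer(self, rng):
        xp, xn, xu = self._toy_1d(rng)
        cfg = PnuConfig(prior_pos=0.5, l2_penalty=1e-3)
        model = fit_pnu(xp, xn, xu, cfg)
        assert model.risk_trace[-1] <= LN2

    def test_degenerate_features_rejected(self):
        x = np.zeros((5, 3))
        with pytest.raises(ValueError, match="degenerate"):
            fit_pnu(x, x, x, PnuConfig(gamma=0.0))

    def test_model_json_round_trip(self, rng, tmp_path):
        from wsdlprog import PnuModel

        xp, xn, xu = self._toy_1d(rng, n=8)
        model = fit_pnu(xp, xn, xu, PnuConfig(gamma=0.25))
        model.to_json(tmp_path / "m.json")
        back = PnuModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.weights, model.weights)
        assert back.fitted_gamma == model.fitted_gamma


class TestImplicitLabels:
    def test_sign_rule_and_tie_break(self):
        from wsdlprog.pnu_classifier import PnuModel

        model = PnuModel(weights=np.array([1.0]), bias=0.0, config=PnuConfig(), fitted_gamma=0.0)
        labels = assign_implicit_labels(model, np.array([[2.0], [-3.0], [0.0]]))
        assert [l.label for l in labels] == ["positive", "negative", "negative"]
        assert labels[0].confidence > 0.5
        assert labels[2].confidence == pytest.approx(0.5)

    def test_implicit_label_accuracy_in_separable_regime(self):
        """Gaussian feature blobs far apart: implicit labels recover the
        hidden classes at >= 0.8 accuracy across 5 seeds."""
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            d = 16
            mu = np.zeros(d)
            mu[0] = 2.0
            xp = rng.standard_normal((25, d)) + mu
            xn = rng.standard_normal((25, d)) - mu
            hidden = rng.random(60) < 0.4
            xu = np.where(
                hidden[:, None], rng.standard_normal((60, d)) + mu, rng.standard_normal((60, d)) - mu
            )
            model = fit_pnu(xp, xn, xu, PnuConfig(prior_pos=0.4, seed=seed))
            labels = assign_implicit_labels(model, xu)
            pred = np.array([l.label == "positive" for l in labels])
            accs.append((pred == hidden).mean())
        assert np.mean(accs) >= 0.8
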