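"""Positive-negative-unlabeled (PNU) classification over deep features.

Semi-supervised linear classification that combines three unbiased risk
estimators: the ordinary positive-negative (PN) risk, and the PU / NU risks
that replace one labeled class with the unlabeled marginal using the class
prior pi_p.  A weight gamma in [-1, 1] interpolates:

    gamma in [0, 1]:   (1 - gamma) * R_pn + gamma * R_pu
    gamma in [-1, 0):  (1 + gamma) * R_pn + (-gamma) * R_nu

The unlabeled pool thereby regularizes the decision boundary without any
cluster or smoothness assumption.  Risks are minimized by deterministic
full-batch gradient descent; gamma is chosen by cross-validated PN risk on
the labeled data.  Fitted models assign hard "implicit labels" to unlabeled
patients by the sign of the linear score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "PnuConfig",
    "PnuModel",
    "ImplicitLabel",
    "pn_risk",
    "pu_risk",
    "nu_risk",
    "pnu_risk",
    "fit_pnu",
    "assign_implicit_labels",
]


# losses: value and derivative as functions of the margin z
def _logistic(z):
    return np.logaddexp(0.0, -z)


def _logistic_d(z):
    return -1.0 / (1.0 + np.exp(z))


def _squared(z):
    return 0.25 * (1.0 - z) ** 2


def _squared_d(z):
    return -0.5 * (1.0 - z)


_LOSSES = {"logistic": (_logistic, _logistic_d), "squared": (_squared, _squared_d)}


@dataclass
class PnuConfig:
    gamma: float | None = None          # fixed gamma; None = select from gamma_grid
    prior_pos: float = 0.5              # class prior pi_p of the positive class
    loss_name: str = "logistic"
    l2_penalty: float = 1e-3
    nonneg_correction: bool = True
    cv_folds: int = 5
    gamma_grid: tuple = (-0.5, -0.25, 0.0, 0.25, 0.5, 0.75, 1.0)
    max_iter: int = 2000
    step: float = 0.1
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma is not None and not -1 <= self.gamma <= 1:
            raise ValueError("gamma must lie in [-1, 1]")
        if not 0 < self.prior_pos < 1:
            raise ValueError("prior_pos must lie in (0, 1)")
        if self.loss_name not in _LOSSES:
            raise ValueError(f"unknown loss {self.loss_name!r}")


@dataclass
class PnuModel:
    weights: np.ndarray
    bias: float
    config: PnuConfig
    fitted_gamma: float
    risk_trace: list = field(default_factory=list)

    def score(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def to_json(self, path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "fitted_gamma": self.fitted_gamma,
            "config": asdict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "PnuModel":
        payload = json.loads(Path(path).read_text())
        cfg = PnuConfig(**payload["config"])
        return cls(
            weights=np.asarray(payload["weights"], dtype=float),
            bias=float(payload["bias"]),
            config=cfg,
            fitted_gamma=float(payload["fitted_gamma"]),
        )


@dataclass
class ImplicitLabel:
    patient_id: str
    label: str            # "positive" / "negative"
    score: float
    confidence: float     # |score| through the logistic link


# --------------------------------------------------------------------------
# risk estimators
# --------------------------------------------------------------------------

def _check(scores, name):
    s = np.asarray(scores, dtype=float).ravel()
    if s.size == 0:
        raise ValueError(f"empty {name} score list")
    return s


def pn_risk(scores_pos, scores_neg, prior_pos: float, loss: str = "logistic") -> float:
    """pi_p * E_p[l(s)] + (1 - pi_p) * E_n[l(-s)] on empirical means."""
    sp = _check(scores_pos, "positive")
    sn = _check(scores_neg, "negative")
    l, _ = _LOSSES[loss]
    return float(prior_pos * l(sp).mean() + (1.0 - prior_pos) * l(-sn).mean())


def pu_risk(
    scores_pos,
    scores_unl,
    prior_pos: float,
    loss: str = "logistic",
    nonneg_correction: bool = True,
) -> float:
    """Positive-unlabeled risk; the negative-class term is estimated from the
    unlabeled mean minus the positive contribution, optionally clamped at 0
    (the uncorrected form is the unbiased estimator)."""
    sp = _check(scores_pos, "positive")
    su = _check(scores_unl, "unlabeled")
    l, _ = _LOSSES[loss]
    neg_term = l(-su).mean() - prior_pos * l(-sp).mean()
    if nonneg_correction:
        neg_term = max(0.0, neg_term)
    return float(prior_pos * l(sp).mean() + neg_term)


def nu_risk(
    scores_neg,
    scores_unl,
    prior_pos: float,
    loss: str = "logistic",
    nonneg_correction: bool = True,
) -> float:
    """Mirror image of :func:`pu_risk` with the positive class estimated from
    the unlabeled pool."""
    sn = _check(scores_neg, "negative")
    su = _check(scores_unl, "unlabeled")
    l, _ = _LOSSES[loss]
    pos_term = l(su).mean() - (1.0 - prior_pos) * l(sn).mean()
    if nonneg_correction:
        pos_term = max(0.0, pos_term)
    return float((1.0 - prior_pos) * l(-sn).mean() + pos_term)


def pnu_risk(scores_pos, scores_neg, scores_unl, config: PnuConfig, gamma=None) -> float:
    """Convex gamma-combination of the PN risk with the PU or NU risk."""
    g = config.gamma if gamma is None else gamma
    if g is None:
        raise ValueError("gamma not set; pass gamma= or set config.gamma")
    su = np.asarray(scores_unl, dtype=float).ravel() if scores_unl is not None else np.array([])
    if su.size == 0 and g != 0:
        raise ValueError("unlabeled scores required when gamma != 0")
    pn = pn_risk(scores_pos, scores_neg, config.prior_pos, config.loss_name)
    if g == 0:
        return pn
    if g > 0:
        pu = pu_risk(scores_pos, su, config.prior_pos, config.loss_name, config.nonneg_correction)
        return (1.0 - g) * pn + g * pu if g < 1 else pu
    nu = nu_risk(scores_neg, su, config.prior_pos, config.loss_name, config.nonneg_correction)
    return (1.0 + g) * pn + (-g) * nu if g > -1 else nu


# --------------------------------------------------------------------------
# gradient of the combined objective
# --------------------------------------------------------------------------

def _risk_and_grad(w, b, Xp, Xn, Xu, gamma, config: PnuConfig):
    """Objective pnu_risk + l2 ||w||^2 with analytic gradients.

    The clamp in the corrected PU/NU risks has gradient 0 on its flat side
    (subgradient choice).
    """
    l, ld = _LOSSES[config.loss_name]
    pi = config.prior_pos

    def terms(X, sign):
        if X is None or len(X) == 0:
            return 0.0, 0.0, 0.0
        s = sign * (X @ w + b)
        val = l(s).mean()
        g = sign * ld(s) / len(X)
        return val, g @ X, g.sum()

    # PN components
    vp, gwp, gbp = terms(Xp, +1)       # E_p l(s)
    vn, gwn, gbn = terms(Xn, -1)       # E_n l(-s)
    risk = 0.0
    gw = np.zeros_like(w)
    gb = 0.0

    c_pn = (1.0 - abs(gamma)) if -1 < gamma < 1 else 0.0
    if gamma == 0:
        c_pn = 1.0
    if c_pn > 0:
        risk += c_pn * (pi * vp + (1 - pi) * vn)
        gw += c_pn * (pi * gwp + (1 - pi) * gwn)
        gb += c_pn * (pi * gbp + (1 - pi) * gbn)

    if gamma > 0:
        vpm, gwpm, gbpm = terms(Xp, -1)    # E_p l(-s)
        vum, gwum, gbum = terms(Xu, -1)    # E_u l(-s)
        neg = vum - pi * vpm
        risk += gamma * pi * vp
        gw += gamma * pi * gwp
        gb += gamma * pi * gbp
        if not (config.nonneg_correction and neg < 0):
            risk += gamma * neg
            gw += gamma * (gwum - pi * gwpm)
            gb += gamma * (gbum - pi * gbpm)
    elif gamma < 0:
        g = -gamma
        vnp, gwnp, gbnp = terms(Xn, +1)    # E_n l(s)
        vup, gwup, gbup = terms(Xu, +1)    # E_u l(s)
        pos = vup - (1 - pi) * vnp
        risk += g * (1 - pi) * vn
        gw += g * (1 - pi) * gwn
        gb += g * (1 - pi) * gbn
        if not (config.nonneg_correction and pos < 0):
            risk += g * pos
            gw += g * (gwup - (1 - pi) * gwnp)
            gb += g * (gbup - (1 - pi) * gbnp)

    risk += config.l2_penalty * float(w @ w)
    gw += 2.0 * config.l2_penalty * w
    return risk, gw, gb


def _minimize(Xp, Xn, Xu, gamma, config: PnuConfig):
    """Full-batch gradient descent with step halving on risk increase."""
    d = Xp.shape[1]
    w = np.zeros(d)
    b = 0.0
    step = config.step
    risk, gw, gb = _risk_and_grad(w, b, Xp, Xn, Xu, gamma, config)
    trace = [risk]
    for _ in range(config.max_iter):
        w_new = w - step * gw
        b_new = b - step * gb
        risk_new, gw_new, gb_new = _risk_and_grad(w_new, b_new, Xp, Xn, Xu, gamma, config)
        if risk_new > risk:
            step *= 0.5
            if step < 1e-12:
                break
            continue
        done = abs(risk - risk_new) < config.tol * max(abs(risk), 1.0)
        w, b, risk, gw, gb = w_new, b_new, risk_new, gw_new, gb_new
        trace.append(risk)
        if done:
            break
    return w, b, trace


def fit_pnu(features_pos, features_neg, features_unl, config: PnuConfig) -> PnuModel:
    """Fit the linear PNU scorer.

    When ``config.gamma`` is None, gamma is selected from ``gamma_grid`` by
    ``cv_folds``-fold cross-validated PN risk on the labeled data (the
    unlabeled pool participates in every fold's training); the final model is
    refit on all data with the chosen gamma.
    """
    Xp = np.atleast_2d(np.asarray(features_pos, dtype=float))
    Xn = np.atleast_2d(np.asarray(features_neg, dtype=float))
    Xu = (
        np.atleast_2d(np.asarray(features_unl, dtype=float))
        if features_unl is not None and len(features_unl) > 0
        else np.empty((0, Xp.shape[1]))
    )
    if len(Xp) == 0 or len(Xn) == 0:
        raise ValueError("both labeled classes must be non-empty")
    allX = np.vstack([Xp, Xn, Xu])
    if np.all(allX.var(axis=0) < 1e-24):
        raise ValueError("degenerate features: zero variance in every coordinate")

    grid = [config.gamma] if config.gamma is not None else list(config.gamma_grid)
    if Xu.shape[0] == 0:
        bad = [g for g in grid if g != 0]
        if config.gamma is not None and bad:
            raise ValueError("unlabeled features required when gamma != 0")
        grid = [g for g in grid if g == 0] or [0.0]

    if len(grid) == 1:
        best_gamma = grid[0]
    else:
        rng = np.random.default_rng(config.seed)
        folds_p = _fold_indices(len(Xp), config.cv_folds, rng)
        folds_n = _fold_indices(len(Xn), config.cv_folds, rng)
        cv_risk = []
        for g in grid:
            vals = []
            for k in range(config.cv_folds):
                trp, vap = folds_p != k, folds_p == k
                trn, van = folds_n != k, folds_n == k
                if vap.sum() == 0 or van.sum() == 0 or trp.sum() == 0 or trn.sum() == 0:
                    continue
                w, b, _ = _minimize(Xp[trp], Xn[trn], Xu, g, config)
                vals.append(
                    pn_risk(Xp[vap] @ w + b, Xn[van] @ w + b, config.prior_pos, config.loss_name)
                )
            cv_risk.append(np.mean(vals) if vals else np.inf)
        best_gamma = grid[int(np.argmin(cv_risk))]

    w, b, trace = _minimize(Xp, Xn, Xu, best_gamma, config)
    return PnuModel(weights=w, bias=float(b), config=config, fitted_gamma=float(best_gamma),
                    risk_trace=trace)


def _fold_indices(n, k, rng):
    idx = np.repeat(np.arange(k), int(np.ceil(n / k)))[:n]
    rng.shuffle(idx)
    return idx


def assign_implicit_labels(model: PnuModel, features_unl, patient_ids=None) -> list[ImplicitLabel]:
    """Hard labels for unlabeled patients by the sign of the linear score.

    A score of exactly 0 is labeled negative.  Confidence maps |score|
    through the logistic link to [0.5, 1).
    """
    X = np.atleast_2d(np.asarray(features_unl, dtype=float))
    scores = model.score(X)
    if patient_ids is None:
        patient_ids = [f"case{i:03d}" for i in range(len(scores))]
    out = []
    for pid, s in zip(patient_ids, scores):
        label = "positive" if s > 0 else "negative"
        conf = float(1.0 / (1.0 + np.exp(-abs(s))))
        out.append(ImplicitLabel(patient_id=pid, label=label, score=float(s), confidence=conf))
    return out
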