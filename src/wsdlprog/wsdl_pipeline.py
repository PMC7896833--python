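"""Orchestration of the weakly supervised (WSDL) and conventional (CDL)
training procedures, and the PSI prognostic score.

The WSDL procedure has four steps:

1. train the baseline network on the labeled training patients;
2. extract 128-dimensional deep features for labeled and unlabeled patients
   with the baseline network;
3. fit the PNU classifier on those features and assign implicit labels to
   the unlabeled pool;
4. retrain the network from fresh initialization on the union of labeled
   patients (true labels, weight 1) and unlabeled patients (implicit labels,
   weight ``unlabeled_weight``).

CDL trains on the labeled training patients only.  Both report the
prediction similarity index PSI = p_pos / p_neg per patient, dichotomized at
PSI = 1 (PSI exactly 1 falls in the low group: with normalized
probabilities, high <=> p_pos > 0.5).

CDL and WSDL step 4 share the same training seed, and zero-weight samples
are dropped before training, so setting ``unlabeled_weight = 0`` makes the
step-4 network identical to the CDL network.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pet_io
from .dcnn import (
    NetworkConfig,
    PredictedProbability,
    build_network,
    extract_features,
    predict_probabilities,
    train_supervised,
)
from .pnu_classifier import PnuConfig, assign_implicit_labels, fit_pnu
from .synthetic_cohort import Cohort, RELAPSE

__all__ = [
    "PsiResult",
    "PipelineConfig",
    "RunManifest",
    "compute_psi",
    "psi_table",
    "run_cdl",
    "run_wsdl",
    "evaluate_psi",
    "survival_frame",
]

PSI_EPS = 1e-12


@dataclass
class PsiResult:
    patient_id: str
    p_pos: float
    p_neg: float
    psi: float
    group: str  # "high" (PSI > 1) / "low" (PSI <= 1)


@dataclass
class PipelineConfig:
    """All knobs of one run, serializable into the manifest."""

    side_mm: float = 96.0
    out_voxels: int = 32
    channels: str = "petct"
    network: NetworkConfig = field(default_factory=NetworkConfig)
    pnu: PnuConfig = field(default_factory=PnuConfig)
    #: take the PNU class prior from the labeled-train relapse prevalence
    prior_from_train: bool = True
    unlabeled_weight: float = 1.0
    confidence_weighting: bool = False
    fine_tune: bool = False
    mtv_threshold_fraction: float = 0.41

    def __post_init__(self) -> None:
        if self.network.input_voxels != self.out_voxels:
            raise ValueError("network.input_voxels must equal out_voxels")
        want = 2 if self.channels == "petct" else 1
        if self.network.input_channels != want:
            raise ValueError(
                f"network.input_channels={self.network.input_channels} inconsistent "
                f"with channels={self.channels!r}"
            )


@dataclass
class RunManifest:
    mode: str  # "WSDL" / "CDL"
    cohort_config: dict
    pipeline_config: dict
    seed: int
    checksum: str = ""

    def __post_init__(self) -> None:
        if not self.checksum:
            payload = json.dumps(
                {
                    "mode": self.mode,
                    "cohort": self.cohort_config,
                    "pipeline": self.pipeline_config,
                    "seed": self.seed,
                },
                sort_keys=True,
                default=str,
            )
            self.checksum = hashlib.sha256(payload.encode()).hexdigest()


def _manifest(mode: str, cohort: Cohort, config: PipelineConfig) -> RunManifest:
    return RunManifest(
        mode=mode,
        cohort_config=dataclasses.asdict(cohort.config),
        pipeline_config=dataclasses.asdict(config),
        seed=config.network.seed,
    )


# --------------------------------------------------------------------------
# PSI
# --------------------------------------------------------------------------

def compute_psi(p: PredictedProbability) -> PsiResult:
    """PSI = p_pos / p_neg with an epsilon guard against p_neg = 0.

    The high/low split is strict: PSI exactly 1 (equal probabilities) is
    grouped low.
    """
    psi = p.p_pos / max(p.p_neg, PSI_EPS)
    return PsiResult(
        patient_id=p.patient_id,
        p_pos=p.p_pos,
        p_neg=p.p_neg,
        psi=psi,
        group="high" if psi > 1.0 else "low",
    )


def psi_table(probs: list[PredictedProbability], split: str = "") -> pd.DataFrame:
    rows = []
    for p in probs:
        r = compute_psi(p)
        rows.append(
            {
                "patient_id": r.patient_id,
                "split": split,
                "p_pos": r.p_pos,
                "p_neg": r.p_neg,
                "psi": r.psi,
                "group": r.group,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def _preprocess(cohort: Cohort, config: PipelineConfig):
    """ROI tensors for every patient; PET normalization statistics are taken
    from the labeled training volumes and frozen for test/unlabeled use."""
    norm = pet_io.cohort_pet_norm([p.volume for p in cohort.train])
    tensors = {}
    for p in cohort.all_patients:
        tensors[p.patient_id] = pet_io.crop_resample(
            p.volume,
            side_mm=config.side_mm,
            out_voxels=config.out_voxels,
            pet_norm=norm,
            channels=config.channels,
        )
    return tensors, norm


def _stack(tensors, patients):
    return [tensors[p.patient_id] for p in patients]


# --------------------------------------------------------------------------
# runs
# --------------------------------------------------------------------------

@dataclass
class RunResult:
    mode: str
    network: object
    psi: pd.DataFrame                      # train + test rows
    manifest: RunManifest
    implicit_labels: pd.DataFrame | None = None
    pnu_model: object = None
    baseline_network: object = None
    training_log: list = field(default_factory=list)


def run_cdl(cohort: Cohort, config: PipelineConfig | None = None) -> RunResult:
    """Conventional deep learning: train on the labeled training set only.

    Any unlabeled pool in the cohort is ignored.
    """
    config = config or PipelineConfig()
    tensors, _ = _preprocess(cohort, config)
    labels = cohort.labels(cohort.train)
    net = build_network(config.network)
    net, log = train_supervised(net, _stack(tensors, cohort.train), labels, config=config.network)
    psi = pd.concat(
        [
            psi_table(predict_probabilities(net, _stack(tensors, cohort.train)), "train"),
            psi_table(predict_probabilities(net, _stack(tensors, cohort.test)), "test"),
        ],
        ignore_index=True,
    )
    return RunResult(
        mode="CDL",
        network=net,
        psi=psi,
        manifest=_manifest("CDL", cohort, config),
        training_log=log,
    )


def run_wsdl(
    cohort: Cohort,
    config: PipelineConfig | None = None,
    *,
    implicit_label_override: dict | str | None = None,
) -> RunResult:
    """The four-step weakly supervised procedure.

    ``implicit_label_override`` replaces step 3's labels: a dict of
    patient_id -> "positive"/"negative", or the string ``"truth"`` to inject
    the generator's latent classes (oracle upper-bound experiments).
    """
    config = config or PipelineConfig()
    if len(cohort.unlabeled) == 0:
        raise ValueError("empty unlabeled pool: use run_cdl for labeled-only training")
    tensors, _ = _preprocess(cohort, config)
    labels = cohort.labels(cohort.train)

    # step 1: baseline model on labeled training patients
    base_cfg = dataclasses.replace(config.network, seed=config.network.seed + 1)
    baseline = build_network(base_cfg)
    baseline, _ = train_supervised(
        baseline, _stack(tensors, cohort.train), labels, config=base_cfg
    )

    # step 2: deep features for labeled and unlabeled patients
    feats_train = extract_features(baseline, _stack(tensors, cohort.train))
    feats_unl = extract_features(baseline, _stack(tensors, cohort.unlabeled))
    F_train = np.stack([f.values for f in feats_train])
    F_unl = np.stack([f.values for f in feats_unl])

    # step 3: PNU classifier -> implicit labels
    pnu_cfg = config.pnu
    if config.prior_from_train:
        pnu_cfg = dataclasses.replace(pnu_cfg, prior_pos=float(labels.mean()))
    model = fit_pnu(F_train[labels == 1], F_train[labels == 0], F_unl, pnu_cfg)
    implicit = assign_implicit_labels(
        model, F_unl, patient_ids=[p.patient_id for p in cohort.unlabeled]
    )
    if implicit_label_override == "truth":
        override = {
            p.patient_id: ("positive" if cohort.truth[p.patient_id] == RELAPSE else "negative")
            for p in cohort.unlabeled
        }
    else:
        override = implicit_label_override
    if override:
        for lab in implicit:
            if lab.patient_id in override:
                lab.label = override[lab.patient_id]
    implicit_df = pd.DataFrame(
        [
            {
                "patient_id": lab.patient_id,
                "label": lab.label,
                "score": lab.score,
                "confidence": lab.confidence,
            }
            for lab in implicit
        ]
    )

    # step 4: retrain on labeled + implicitly labeled unlabeled patients
    all_tensors = _stack(tensors, cohort.train) + _stack(tensors, cohort.unlabeled)
    all_labels = np.concatenate(
        [labels, np.array([1 if lab.label == "positive" else 0 for lab in implicit])]
    )
    w_unl = np.full(len(implicit), config.unlabeled_weight)
    if config.confidence_weighting:
        w_unl = w_unl * implicit_df["confidence"].to_numpy()
    weights = np.concatenate([np.ones(len(labels)), w_unl])
    keep = weights > 0  # zero-weight samples are dropped (w_u = 0 degenerates to CDL)
    all_tensors = [t for t, k in zip(all_tensors, keep) if k]
    all_labels = all_labels[keep]
    weights = weights[keep]

    if config.fine_tune:
        net = baseline
    else:
        net = build_network(config.network)  # fresh init, same seed family as CDL
    net, log = train_supervised(net, all_tensors, all_labels, weights, config=config.network)

    psi = pd.concat(
        [
            psi_table(predict_probabilities(net, _stack(tensors, cohort.train)), "train"),
            psi_table(predict_probabilities(net, _stack(tensors, cohort.test)), "test"),
        ],
        ignore_index=True,
    )
    return RunResult(
        mode="WSDL",
        network=net,
        psi=psi,
        manifest=_manifest("WSDL", cohort, config),
        implicit_labels=implicit_df,
        pnu_model=model,
        baseline_network=baseline,
        training_log=log,
    )


# --------------------------------------------------------------------------
# cohort-level experiment
# --------------------------------------------------------------------------

def desk_scale_config(seed: int = 0) -> PipelineConfig:
    """Training configuration for cohort-level experiments on one CPU.

    A narrow residual network (stage widths 8/16/32/128, one block per
    stage) on 32^3 two-channel inputs, trained for up to 12 epochs with
    early stopping — small enough that a full weakly-supervised run over a
    167-patient cohort takes well under a minute, while still separating the
    simulated phenotype classes.
    """
    net = NetworkConfig(
        stage_widths=(8, 16, 32, 128),
        blocks_per_stage=1,
        max_epochs=12,
        early_stop_patience=4,
        batch_size=16,
        learning_rate=3e-3,
        seed=seed,
    )
    return PipelineConfig(network=net, pnu=PnuConfig(seed=seed))


def wsdl_cdl_experiment(
    n_seeds: int = 10,
    base_seed: int = 0,
    cohort_config=None,
    oracle_arm: bool = False,
    t_eval: float = 24.0,
) -> pd.DataFrame:
    """Head-to-head WSDL vs CDL comparison over repeated simulated studies.

    For each seed a fresh default cohort (84 labeled / 83 unlabeled) is
    simulated and both procedures are trained and scored; the table reports
    the test-set time-dependent AUC of PSI at ``t_eval`` months per arm.
    ``oracle_arm`` adds a WSDL run whose implicit labels are replaced by the
    generator's latent classes (an upper-bound reference).
    """
    import dataclasses as _dc

    from .synthetic_cohort import CohortConfig, simulate_cohort

    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        cc = cohort_config or CohortConfig()
        cohort = simulate_cohort(_dc.replace(cc, seed=seed))
        config = desk_scale_config(seed)
        records = survival_frame(cohort, cohort.test)
        row = {"seed": seed}
        cdl = run_cdl(cohort, config)
        row["auc_cdl"] = evaluate_psi(
            cdl.psi[cdl.psi.split == "test"], records, t_eval=t_eval
        )["auc"]
        wsdl = run_wsdl(cohort, config)
        row["auc_wsdl"] = evaluate_psi(
            wsdl.psi[wsdl.psi.split == "test"], records, t_eval=t_eval
        )["auc"]
        truth = np.array(
            [cohort.truth[p] == RELAPSE for p in wsdl.implicit_labels.patient_id]
        )
        row["implicit_accuracy"] = float(
            ((wsdl.implicit_labels.label == "positive").to_numpy() == truth).mean()
        )
        if oracle_arm:
            oracle = run_wsdl(cohort, config, implicit_label_override="truth")
            row["auc_wsdl_oracle"] = evaluate_psi(
                oracle.psi[oracle.psi.split == "test"], records, t_eval=t_eval
            )["auc"]
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# evaluation glue
# --------------------------------------------------------------------------

def survival_frame(cohort: Cohort, patients) -> pd.DataFrame:
    """Observed (time, event) records for labeled patients."""
    rows = []
    for p in patients:
        c = p.clinical
        if c.event is None:
            raise ValueError(f"patient {p.patient_id} has no outcome")
        rows.append({"patient_id": p.patient_id, "time": c.observed_time, "event": c.event})
    return pd.DataFrame(rows)


def evaluate_psi(
    psi: pd.DataFrame, records: pd.DataFrame, t_eval: float = 24.0
) -> dict:
    """Survival evaluation of a PSI table against observed outcomes.

    Returns the time-dependent AUC of PSI at ``t_eval``, the log-rank test
    between the high and low PSI groups, and sensitivity/specificity/accuracy
    against the ``t_eval`` outcome (event observed by ``t_eval``).
    """
    from . import survival_stats as ss

    merged = psi.merge(records, on="patient_id")
    out: dict = {}
    out["auc"], out["roc"] = ss.time_dependent_auc(
        merged["psi"].to_numpy(), merged[["time", "event"]], t_eval
    )
    hi = merged[merged["group"] == "high"][["time", "event"]]
    lo = merged[merged["group"] == "low"][["time", "event"]]
    if len(hi) and len(lo):
        out["logrank_chi2"], out["logrank_p"] = ss.logrank_test(hi, lo)
    truth = ((merged["time"] <= t_eval) & (merged["event"] == 1)).astype(int)
    pred = (merged["group"] == "high").astype(int)
    try:
        out["sensitivity"], out["specificity"], out["accuracy"] = ss.classification_metrics(
            pred, truth
        )
    except ValueError:
        pass
    return out
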