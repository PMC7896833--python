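"""Synthetic PET/CT lymphoma cohorts with class-linked phenotypes and survival.

Emulates the study design the pipeline assumes: a labeled cohort followed for
at least two years (split into stratified train/test sets), plus an unlabeled
pool with short or missing follow-up imaged on three scanner profiles with
different voxel geometries, reconstruction resolution, and noise.

Relapse-prone patients receive lesions with higher mean SUV, larger volume,
and stronger multiplicative texture heterogeneity; the separation between the
class-conditional lesion-parameter distributions is controlled by a single
``effect_size`` (roughly a Cohen's d in log-parameter space).  Progression-free
survival (PFS) is exponential with a class-dependent hazard.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ScannerProfile",
    "CohortConfig",
    "ClinicalRecord",
    "SimulatedPatient",
    "Cohort",
    "SCANNER_PRESETS",
    "scanner_preset",
    "sample_lesion_params",
    "simulate_patient",
    "simulate_survival",
    "simulate_cohort",
    "write_cohort",
]


# --------------------------------------------------------------------------
# scanner profiles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScannerProfile:
    """Acquisition/reconstruction profile emulated as blur + noise.

    Parameters
    ----------
    voxel_size : (mm, mm, mm) grid spacing per axis.
    psf_fwhm : effective reconstruction resolution, applied as an isotropic
        Gaussian point-spread function (mm full width at half maximum).
    noise_sd : additive Gaussian noise scale in SUV units.
    """

    name: str
    voxel_size: tuple[float, float, float]
    psf_fwhm: float
    noise_sd: float

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if self.psf_fwhm < 0 or self.noise_sd < 0:
            raise ValueError("psf_fwhm and noise_sd must be non-negative")


#: Three built-in profiles mirroring the voxel geometries of the study's
#: scanners: an older OSEM system with a 6-mm Gaussian filter and coarse
#: isotropic grid, a regularized-reconstruction system at intermediate
#: resolution, and a fine-grid TOF system reconstructed without filtering.
SCANNER_PRESETS: dict[str, ScannerProfile] = {
    "scanner1": ScannerProfile("scanner1", (5.47, 5.47, 5.47), psf_fwhm=6.0, noise_sd=0.50),
    "scanner2": ScannerProfile("scanner2", (2.7, 2.7, 2.79), psf_fwhm=4.0, noise_sd=0.35),
    "scanner3": ScannerProfile("scanner3", (1.6, 1.6, 1.5), psf_fwhm=3.0, noise_sd=0.45),
}


def scanner_preset(name_or_index) -> ScannerProfile:
    """Return a built-in profile by name or 1-based index."""
    if isinstance(name_or_index, ScannerProfile):
        return name_or_index
    if isinstance(name_or_index, int):
        names = list(SCANNER_PRESETS)
        if not 1 <= name_or_index <= len(names):
            raise KeyError(f"scanner preset index out of range: {name_or_index}")
        return SCANNER_PRESETS[names[name_or_index - 1]]
    return SCANNER_PRESETS[name_or_index]


# --------------------------------------------------------------------------
# configuration and record types
# --------------------------------------------------------------------------

RELAPSE = "relapse"
NON_RELAPSE = "non-relapse"


@dataclass
class CohortConfig:
    """Cohort-level generator settings.

    Defaults mirror the study structure: 84 labeled patients followed at
    least 24 months (64 train / 20 test, relapse ratio preserved), and an
    unlabeled pool of 83 patients across the three scanner profiles with
    counts 39/29/15.
    """

    n_labeled: int = 84
    n_unlabeled: int = 83
    train_fraction: float = 64 / 84
    relapse_prevalence: float = 23 / 84
    #: events per month for exponential PFS; defaults correspond to ~30% and
    #: ~90% 2-year PFS for the relapse-prone and non-relapse classes.
    hazard_relapse: float = 0.050
    hazard_nonrelapse: float = 0.0044
    censor_horizon_labeled: float = 24.0
    unlabeled_followup_max: float = 24.0
    effect_size: float = 1.0
    scanner_mix: tuple[float, float, float] = (39 / 83, 29 / 83, 15 / 83)
    labeled_scanner: str = "scanner1"
    #: latent relapse prevalence in the unlabeled pool; None = same as labeled
    #: (the class-prior assumption of PNU learning).  Set differently to test
    #: prior misspecification.
    unlabeled_prevalence: float | None = None
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    covariate_assoc: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.relapse_prevalence < 1:
            raise ValueError("relapse_prevalence must lie in (0, 1)")
        if not self.hazard_relapse > self.hazard_nonrelapse > 0:
            raise ValueError("require hazard_relapse > hazard_nonrelapse > 0")
        if abs(sum(self.scanner_mix) - 1.0) > 1e-9:
            raise ValueError("scanner_mix must sum to 1")
        if self.censor_horizon_labeled < 24.0:
            raise ValueError("labeled follow-up horizon must be >= 24 months")
        if self.unlabeled_followup_max > 24.0:
            raise ValueError("unlabeled follow-up must stay below 24 months")


@dataclass
class ClinicalRecord:
    """Covariates and follow-up for one patient.

    For unlabeled patients ``pfs_months``/``event`` are ``None``: their
    outcome is never exposed downstream.  ``followup_months`` is the
    administrative follow-up; for labeled patients the observed PFS time is
    ``min(pfs_months, followup_months)``.
    """

    patient_id: str
    age: float
    gender: str                      # "M"/"F"
    ldh: float                       # serum lactate dehydrogenase, U/L
    ecog: int                        # ECOG performance score 0..4
    ebv_dna: int                     # Epstein-Barr virus DNA positive (1) / negative (0)
    b2_microglobulin: float          # mg/L
    ann_arbor: int                   # stage I..IV
    b_symptoms: int
    followup_months: float
    labeled: bool
    pfs_months: float | None = None
    event: int | None = None

    @property
    def observed_time(self) -> float | None:
        if not self.labeled:
            return None
        return min(self.pfs_months, self.followup_months)


@dataclass
class SimulatedPatient:
    patient_id: str
    volume: "PatientVolume"
    clinical: ClinicalRecord
    scanner: ScannerProfile
    #: ground-truth lesion parameters (oracle use only; not written to the
    #: clinical table)
    lesion_params: dict = field(default_factory=dict)


@dataclass
class Cohort:
    """A simulated study: labeled train/test splits plus an unlabeled pool.

    ``truth`` maps patient_id -> latent class for every patient, including
    unlabeled ones; it exists only for oracle experiments and evaluation and
    is never written into the clinical table of the unlabeled pool.
    """

    train: list[SimulatedPatient]
    test: list[SimulatedPatient]
    unlabeled: list[SimulatedPatient]
    config: CohortConfig
    truth: dict[str, str]

    @property
    def all_patients(self) -> list[SimulatedPatient]:
        return self.train + self.test + self.unlabeled

    def labels(self, patients: list[SimulatedPatient]) -> np.ndarray:
        """Binary relapse labels (1 = event observed) for labeled patients."""
        out = []
        for p in patients:
            if p.clinical.event is None:
                raise ValueError(f"patient {p.patient_id} is unlabeled")
            out.append(int(p.clinical.event))
        return np.asarray(out, dtype=int)


# --------------------------------------------------------------------------
# lesion phenotype sampling
# --------------------------------------------------------------------------

# class-conditional log-space baselines; relapse-prone lesions shift upward
# by effect_size * sigma in each log-parameter
_BASE_LOG_SUV = np.log(6.0)
_SIGMA_LOG_SUV = 0.30
_BASE_LOG_RADIUS = np.log(11.0)   # mm
_SIGMA_LOG_RADIUS = 0.22
_BASE_TEXTURE = 0.15              # multiplicative field sd (log scale)
_TEXTURE_SHIFT = 0.10


def sample_lesion_params(latent_class: str, effect_size: float, rng: np.random.Generator) -> dict:
    """Draw class-conditional lesion parameters (mean SUV, radii, texture).

    The relapse-prone class is shifted by ``effect_size`` standard deviations
    in log mean-SUV and log radius, and gets texture-field variance larger by
    ``effect_size * 0.10``.  At ``effect_size == 0`` both classes share one
    distribution.
    """
    if latent_class not in (RELAPSE, NON_RELAPSE):
        raise ValueError(f"unknown latent class: {latent_class!r}")
    shift = effect_size if latent_class == RELAPSE else 0.0
    mean_suv = float(np.exp(_BASE_LOG_SUV + _SIGMA_LOG_SUV * (rng.standard_normal() + shift)))
    radii = np.exp(
        _BASE_LOG_RADIUS
        + _SIGMA_LOG_RADIUS * (rng.standard_normal(3) * 0.5 + shift)
    )
    texture_sd = _BASE_TEXTURE + _TEXTURE_SHIFT * shift + 0.03 * rng.standard_normal()
    return {
        "mean_suv": mean_suv,
        "radii_mm": tuple(float(r) for r in radii),
        "texture_sd": float(max(texture_sd, 0.0)),
    }


def _smooth_field(shape, rng: np.random.Generator, corr_vox: float) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=corr_vox)
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def simulate_patient(
    latent_class: str,
    scanner,
    rng_seed: int,
    *,
    effect_size: float = 1.0,
    grid_shape: tuple[int, int, int] = (48, 48, 48),
    patient_id: str = "sim",
) -> SimulatedPatient:
    """Simulate one patient's PET/CT volume with a single ellipsoidal lesion.

    The PET channel is a low-uptake background plus an ellipsoidal lesion
    whose voxel values are ``mean_suv`` modulated by a multiplicative
    log-Gaussian texture field; the whole grid is blurred by the scanner PSF
    and corrupted by additive Gaussian noise (clipped at 0 — SUV is
    non-negative).  The CT channel is a smooth soft-tissue background with
    added contrast at the lesion.  The mask is the pre-blur ellipsoid.

    Identical (arguments, seed) give bit-identical output.
    """
    from .pet_io import PatientVolume  # local import to avoid cycle

    scanner = scanner_preset(scanner)
    rng = np.random.default_rng(rng_seed)
    params = sample_lesion_params(latent_class, effect_size, rng)
    spacing = np.asarray(scanner.voxel_size, dtype=float)
    shape = tuple(int(s) for s in grid_shape)

    radii_vox = np.asarray(params["radii_mm"]) / spacing
    # jitter the lesion center by up to ~2 voxels per axis
    center = np.asarray(shape) / 2.0 + rng.uniform(-2, 2, size=3)
    lo = center - radii_vox
    hi = center + radii_vox
    bad = [i for i in range(3) if lo[i] < 0 or hi[i] > shape[i] - 1]
    if bad:
        names = "xyz"
        raise ValueError(
            "lesion does not fit grid along axis(es) "
            + ", ".join(names[i] for i in bad)
            + f": radii {params['radii_mm']} mm on shape {shape} at spacing {tuple(spacing)}"
        )

    idx = np.indices(shape, dtype=float)
    dist2 = sum(((idx[i] - center[i]) / radii_vox[i]) ** 2 for i in range(3))
    mask = (dist2 <= 1.0).astype(np.uint8)

    # texture correlation length ~6 mm
    corr_vox = 6.0 / spacing.mean()
    texture = np.exp(params["texture_sd"] * _smooth_field(shape, rng, corr_vox))

    pet = np.full(shape, 0.8, dtype=float)
    pet += 0.15 * _smooth_field(shape, rng, corr_vox * 2)
    pet = np.where(mask > 0, params["mean_suv"] * texture, pet)

    ct = 0.30 + 0.05 * _smooth_field(shape, rng, corr_vox * 3)
    ct = np.where(mask > 0, ct + 0.20, ct)

    sigma_vox = scanner.psf_fwhm / 2.3548 / spacing
    pet = ndimage.gaussian_filter(pet, sigma=sigma_vox)
    pet = pet + scanner.noise_sd * rng.standard_normal(shape)
    pet = np.clip(pet, 0.0, None)
    ct = ndimage.gaussian_filter(ct, sigma=sigma_vox) + 0.01 * rng.standard_normal(shape)

    volume = PatientVolume(
        patient_id=patient_id,
        pet=pet.astype(np.float32),
        ct=ct.astype(np.float32),
        mask=mask,
        spacing=tuple(float(s) for s in spacing),
    )
    clinical = _sample_covariates(patient_id, latent_class, 1.0, rng)
    return SimulatedPatient(
        patient_id=patient_id,
        volume=volume,
        clinical=clinical,
        scanner=scanner,
        lesion_params=params,
    )


# --------------------------------------------------------------------------
# survival and covariates
# --------------------------------------------------------------------------

def simulate_survival(
    latent_class: str,
    config: CohortConfig,
    rng_seed,
    *,
    labeled: bool = True,
) -> tuple[float, int, float]:
    """Draw (pfs_months, event_flag, followup_months) for one patient.

    PFS is exponential with the class hazard.  Labeled patients' follow-up is
    at least ``censor_horizon_labeled`` months; unlabeled patients' follow-up
    is uniform on (3, ``unlabeled_followup_max``).  The event is observed iff
    PFS falls within follow-up.
    """
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    hazard = config.hazard_relapse if latent_class == RELAPSE else config.hazard_nonrelapse
    pfs = float(rng.exponential(1.0 / hazard))
    if labeled:
        followup = float(config.censor_horizon_labeled + rng.exponential(18.0))
    else:
        followup = float(rng.uniform(3.0, config.unlabeled_followup_max))
    event = int(pfs <= followup)
    return pfs, event, followup


_ECOG_PROBS = {NON_RELAPSE: (0.60, 0.28, 0.12), RELAPSE: (0.35, 0.35, 0.30)}


def _sample_covariates(
    patient_id: str, latent_class: str, assoc: float, rng: np.random.Generator
) -> ClinicalRecord:
    """Class-correlated clinical covariates; ``assoc`` scales every shift."""
    rel = float(latent_class == RELAPSE) * assoc
    age = float(np.clip(rng.normal(52 + 3 * rel, 12), 18, 85))
    gender = "M" if rng.random() < 0.70 else "F"
    ldh = float(np.exp(np.log(180) + 0.25 * rng.standard_normal() + 0.30 * rel))
    p0, p1, p2 = np.asarray(_ECOG_PROBS[RELAPSE]) * rel + np.asarray(_ECOG_PROBS[NON_RELAPSE]) * (1 - rel)
    ecog = int(rng.choice([0, 1, 2], p=np.array([p0, p1, p2]) / (p0 + p1 + p2)))
    ebv = int(rng.random() < 0.35 + 0.30 * rel)
    b2m = float(np.exp(np.log(2.0) + 0.35 * rng.standard_normal() + 0.35 * rel))
    stage34 = rng.random() < 0.20 + 0.25 * rel
    ann_arbor = int(rng.choice([3, 4]) if stage34 else rng.choice([1, 2]))
    b_sym = int(rng.random() < 0.38 + 0.12 * rel)
    return ClinicalRecord(
        patient_id=patient_id,
        age=age,
        gender=gender,
        ldh=ldh,
        ecog=ecog,
        ebv_dna=ebv,
        b2_microglobulin=b2m,
        ann_arbor=ann_arbor,
        b_symptoms=b_sym,
        followup_months=np.nan,
        labeled=False,
    )


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------

def _largest_remainder_counts(n: int, proportions) -> list[int]:
    raw = np.asarray(proportions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def _stratified_split(n_rel: int, n_non: int, train_fraction: float, n_labeled: int):
    """Per-class train counts so the overall train size is exact and the
    relapse ratio is preserved to within integer rounding."""
    n_train = int(round(train_fraction * n_labeled))
    rel_train = int(round(train_fraction * n_rel))
    non_train = n_train - rel_train
    if not (0 < rel_train <= n_rel) or not (0 < non_train <= n_non):
        raise ValueError(
            f"impossible stratification: {n_rel} relapse / {n_non} non-relapse "
            f"cannot fill a train set of {n_train}"
        )
    if rel_train == n_rel or non_train == n_non:
        raise ValueError("stratification leaves an empty class in the test set")
    return rel_train, non_train, n_train


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Simulate a full study cohort.

    Labeled patients' relapse label is their latent class: survival draws are
    repeated until the observed-event status agrees with the class, so the
    configured prevalence is exact and every labeled patient either has an
    event or >= 24 months of event-free follow-up.  The unlabeled pool keeps
    unconditional draws, never exposes its outcome, and is spread over the
    scanner presets by ``scanner_mix`` (largest-remainder rounding).
    """
    rng = np.random.default_rng(config.seed)
    n_rel = int(round(config.relapse_prevalence * config.n_labeled))
    n_non = config.n_labeled - n_rel
    if n_rel == 0 or n_non == 0:
        raise ValueError("relapse_prevalence leaves one class empty in the labeled cohort")
    rel_train, non_train, _ = _stratified_split(
        n_rel, n_non, config.train_fraction, config.n_labeled
    )

    labeled_scanner = scanner_preset(config.labeled_scanner)
    truth: dict[str, str] = {}

    def make_labeled(latent: str, pid: str) -> SimulatedPatient:
        pat = simulate_patient(
            latent,
            labeled_scanner,
            int(rng.integers(2**31)),
            effect_size=config.effect_size,
            grid_shape=config.grid_shape,
            patient_id=pid,
        )
        # rejection: observed-event status must match the latent class
        for _ in range(10_000):
            pfs, event, fu = simulate_survival(latent, config, rng, labeled=True)
            if bool(event) == (latent == RELAPSE):
                break
        else:  # pragma: no cover - hazards make this astronomically unlikely
            raise RuntimeError("survival rejection sampling failed")
        c = pat.clinical
        c.followup_months, c.pfs_months, c.event, c.labeled = fu, pfs, event, True
        pat.clinical = _recompute_assoc(c, latent, config, rng)
        truth[pid] = latent
        return pat

    def _recompute_assoc(c, latent, config, rng):
        if config.covariate_assoc == 1.0:
            return c
        fresh = _sample_covariates(c.patient_id, latent, config.covariate_assoc, rng)
        fresh.followup_months, fresh.pfs_months, fresh.event, fresh.labeled = (
            c.followup_months, c.pfs_months, c.event, c.labeled,
        )
        return fresh

    train, test = [], []
    counter = 0
    for latent, n_train_cls, n_total_cls in (
        (RELAPSE, rel_train, n_rel),
        (NON_RELAPSE, non_train, n_non),
    ):
        for k in range(n_total_cls):
            pid = f"L{counter:03d}"
            counter += 1
            pat = make_labeled(latent, pid)
            (train if k < n_train_cls else test).append(pat)

    # unlabeled pool: scanner counts per mix, latent classes at the pool prior
    prev_u = (
        config.relapse_prevalence
        if config.unlabeled_prevalence is None
        else config.unlabeled_prevalence
    )
    scanner_counts = _largest_remainder_counts(config.n_unlabeled, config.scanner_mix)
    scanners = [
        s for s, cnt in zip(SCANNER_PRESETS.values(), scanner_counts) for _ in range(cnt)
    ]
    n_rel_u = int(round(prev_u * config.n_unlabeled))
    latents_u = [RELAPSE] * n_rel_u + [NON_RELAPSE] * (config.n_unlabeled - n_rel_u)
    rng.shuffle(latents_u)

    unlabeled = []
    for k, (sc, latent) in enumerate(zip(scanners, latents_u)):
        pid = f"U{k:03d}"
        pat = simulate_patient(
            latent,
            sc,
            int(rng.integers(2**31)),
            effect_size=config.effect_size,
            grid_shape=config.grid_shape,
            patient_id=pid,
        )
        _, _, fu = simulate_survival(latent, config, rng, labeled=False)
        c = pat.clinical
        c.followup_months, c.labeled = fu, False
        c.pfs_months = None
        c.event = None
        pat.clinical = _recompute_assoc(c, latent, config, rng)
        truth[pid] = latent
        unlabeled.append(pat)

    # deterministic shuffles so class blocks are not ordered
    for lst in (train, test):
        order = rng.permutation(len(lst))
        lst[:] = [lst[i] for i in order]
    return Cohort(train=train, test=test, unlabeled=unlabeled, config=config, truth=truth)


# --------------------------------------------------------------------------
# on-disk form
# --------------------------------------------------------------------------

def clinical_table(cohort: Cohort) -> pd.DataFrame:
    """Clinical CSV: one row per patient.  Unlabeled rows carry no outcome."""
    rows = []
    for split, patients in (
        ("train", cohort.train),
        ("test", cohort.test),
        ("unlabeled", cohort.unlabeled),
    ):
        for p in patients:
            c = p.clinical
            rows.append(
                {
                    "patient_id": c.patient_id,
                    "split": split,
                    "scanner": p.scanner.name,
                    "age": c.age,
                    "gender": c.gender,
                    "ldh": c.ldh,
                    "ecog": c.ecog,
                    "ebv_dna": c.ebv_dna,
                    "b2_microglobulin": c.b2_microglobulin,
                    "ann_arbor": c.ann_arbor,
                    "b_symptoms": c.b_symptoms,
                    "followup_months": c.followup_months,
                    "pfs_months": c.observed_time if c.labeled else np.nan,
                    "event": c.event if c.labeled else np.nan,
                }
            )
    return pd.DataFrame(rows)


def write_cohort(cohort: Cohort, outdir) -> Path:
    """Write volumes (NIfTI), the clinical table (CSV), and a manifest (JSON)."""
    from .pet_io import write_patient

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": dataclasses.asdict(cohort.config), "patients": {}}
    for split, patients in (
        ("train", cohort.train),
        ("test", cohort.test),
        ("unlabeled", cohort.unlabeled),
    ):
        for p in patients:
            paths = write_patient(p.volume, outdir / "volumes")
            manifest["patients"][p.patient_id] = {
                "split": split,
                "scanner": p.scanner.name,
                "paths": {k: str(v) for k, v in paths.items()},
            }
    clinical_table(cohort).to_csv(outdir / "clinical.csv", index=False)
    manifest["clinical_csv"] = str(outdir / "clinical.csv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return outdir / "manifest.json"
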