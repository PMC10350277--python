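"""Synthetic cohorts with known ground truth.

Two levels are provided.  ``generate_feature_cohort`` draws a patients x
features table from an equicorrelated Gaussian plus exponential
proportional-hazards survival, for testing the selection and survival
machinery directly.  ``generate_phantom_patient`` / ``generate_phantom_cohort``
build image-level phantoms — ellipsoidal tumors filled with a correlated
Gaussian random texture whose correlation length is driven by a latent
per-patient risk — so the whole pipeline (preprocessing, extraction,
stability, selection, training, evaluation) can be exercised end-to-end.

The default phantom geometry mirrors a typical 1.5 T head-and-neck
acquisition: ~0.6 x 0.6 mm in-plane pixels with 3 mm slices, tumors of a
few cm.  Survival defaults give a median follow-up near 37 months with
roughly 55-60% censoring, matching the kind of retrospective cohort the
pipeline is designed for.  Censoring is independent uniform
administrative censoring on (0, censor_horizon); the mechanism is a
parameter, not a fact about any particular cohort.

All randomness flows from explicit seeds; per-patient substreams are
spawned from the cohort seed so a cohort can be extended without
reshuffling existing patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .survival_eval import SurvivalData
from .volume import ImageVolume, RoiMask

__all__ = [
    "FeatureCohortSpec", "PhantomSpec", "PhantomPatient", "PhantomCohort",
    "generate_feature_cohort", "generate_phantom_patient",
    "generate_phantom_cohort", "write_phantom_cohort",
]


# ---------------------------------------------------------------- feature level

@dataclass
class FeatureCohortSpec:
    """Feature-level synthetic cohort parameters.

    ``true_features`` index the informative columns; ``beta_true`` are
    their Cox log-hazard coefficients.  ``baseline_scale`` is the mean of
    the exponential baseline survival time (months); censoring is uniform
    on (0, censor_horizon).  The defaults yield ~57% censoring and a
    median follow-up in the mid-30s of months.
    """

    n_patients: int = 123
    n_features: int = 50
    true_features: tuple[int, ...] = ()
    beta_true: tuple[float, ...] = ()
    correlation: float = 0.2
    baseline_scale: float = 60.0
    censor_horizon: float = 75.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if len(self.true_features) != len(self.beta_true):
            raise ValueError("true_features and beta_true lengths differ")
        if len(self.true_features) > self.n_features:
            raise ValueError("more true features than features")
        if any(i >= self.n_features or i < 0 for i in self.true_features):
            raise ValueError("true feature index out of range")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must be in [0, 1)")
        if self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be positive")


def generate_feature_cohort(spec: FeatureCohortSpec
                            ) -> tuple[pd.DataFrame, SurvivalData, dict]:
    """Draw a feature table + survival with known informative features.

    Features follow an equicorrelated multivariate normal (pairwise
    correlation ``spec.correlation``); survival times are exponential
    with hazard h0 * exp(sum beta_true * x_true), censored at an
    independent Uniform(0, censor_horizon) administrative time.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_patients, spec.n_features
    rho = spec.correlation
    shared = rng.standard_normal(n)
    x = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * rng.standard_normal((n, p))

    lp = np.zeros(n)
    for idx, beta in zip(spec.true_features, spec.beta_true):
        lp += beta * x[:, idx]

    t_event = rng.exponential(spec.baseline_scale, size=n) * np.exp(-lp)
    t_cens = rng.uniform(0.0, spec.censor_horizon, size=n)
    time = np.minimum(t_event, t_cens)
    time = np.maximum(time, 1e-6)
    event = (t_event <= t_cens).astype(int)

    cols = [f"feat_{i:03d}" for i in range(p)]
    features = pd.DataFrame(x, columns=cols)
    truth = {
        "true_features": [cols[i] for i in spec.true_features],
        "true_indices": list(spec.true_features),
        "beta_true": list(spec.beta_true),
        "linear_predictor": lp,
        "event_time": t_event,
        "censor_time": t_cens,
    }
    return features, SurvivalData(time, event), truth


# ----------------------------------------------------------------- image level

@dataclass
class PhantomSpec:
    """Image-level phantom parameters.

    Geometry defaults emulate an anisotropic 1.5 T acquisition
    (0.625 x 0.625 mm in-plane, 3 mm slices).  ``texture_correlation_length``
    (mm) sets the width of the Gaussian kernel smoothing the white-noise
    texture inside the tumor, which directly controls run-length
    statistics; ``risk_link`` scales how strongly the latent per-patient
    risk modulates that correlation length
    (length_eff = length * exp(risk_link * latent)).
    """

    grid_shape: tuple[int, int, int] = (80, 80, 28)
    voxel_spacing: tuple[float, float, float] = (0.625, 0.625, 3.0)
    tumor_radii: tuple[float, float, float] = (12.0, 10.0, 9.0)  # mm
    texture_correlation_length: float = 4.0  # mm
    noise_sd: float = 30.0  # intensity units
    risk_link: float = 0.35
    seed: int = 0
    t1_background: float = 300.0
    t1_tumor_mean: float = 200.0
    t2_background: float = 150.0
    t2_tumor_mean: float = 320.0

    def __post_init__(self) -> None:
        if self.texture_correlation_length <= 0:
            raise ValueError("texture_correlation_length must be positive")
        for r, n, s in zip(self.tumor_radii, self.grid_shape,
                           self.voxel_spacing):
            if 2 * r >= (n - 2) * s:
                raise ValueError(
                    f"tumor (diameter {2 * r} mm) does not fit inside the "
                    f"grid ({n} voxels at {s} mm)")


@dataclass
class PhantomPatient:
    """One synthetic patient: co-registered T1w/T2w volumes, tumor mask,
    and the latent risk that generated the texture."""

    patient_id: str
    t1: ImageVolume
    t2: ImageVolume
    mask: RoiMask
    latent_risk: float


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    shape = spec.grid_shape
    center = [(n - 1) / 2.0 for n in shape]
    axes = [np.arange(n) for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    q = np.zeros(shape)
    for g, c, s, r in zip(grids, center, spec.voxel_spacing, spec.tumor_radii):
        q += ((g - c) * s / r) ** 2
    return q <= 1.0


def _correlated_field(shape, spacing, corr_length_mm, rng) -> np.ndarray:
    """Gaussian-filtered white noise, rescaled to unit variance."""
    noise = rng.standard_normal(shape)
    sigma_vox = [corr_length_mm / s for s in spacing]
    fld = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
    sd = fld.std()
    return fld / sd if sd > 0 else fld


def generate_phantom_patient(spec: PhantomSpec,
                             latent_risk: float | None = None,
                             patient_id: str = "P0000") -> PhantomPatient:
    """Build one ellipsoidal-tumor phantom.

    The tumor interior is a constant modality-specific mean plus
    ``noise_sd`` times a unit-variance correlated Gaussian field whose
    correlation length grows with the latent risk; the background is a
    smooth low-frequency ramp.  T1w and T2w share geometry and texture
    field but differ in contrast.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _ellipsoid_mask(spec)
    if latent_risk is None:
        latent_risk = float(np.clip(rng.standard_normal(), -2.5, 2.5))

    corr_len = spec.texture_correlation_length * float(
        np.exp(spec.risk_link * latent_risk))
    field = _correlated_field(spec.grid_shape, spec.voxel_spacing,
                              corr_len, rng)

    # smooth background ramp (outside the tumor only)
    axes = [np.linspace(-1, 1, n) for n in spec.grid_shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    ramp = 0.10 * gx + 0.06 * gy + 0.15 * gz

    vols = {}
    for mod, bg, tumor_mean, amp in (
            ("T1w", spec.t1_background, spec.t1_tumor_mean, 0.8),
            ("T2w", spec.t2_background, spec.t2_tumor_mean, 1.0)):
        data = bg * (1.0 + ramp)
        data[mask] = tumor_mean + amp * spec.noise_sd * field[mask]
        vols[mod] = ImageVolume(data, spec.voxel_spacing, mod)

    return PhantomPatient(patient_id, vols["T1w"], vols["T2w"],
                          RoiMask(mask, spec.voxel_spacing),
                          float(latent_risk))


@dataclass
class PhantomCohort:
    patients: list[PhantomPatient]
    survival: SurvivalData
    stages: pd.DataFrame  # columns: patient_id, cTNM, pTNM
    latent_risk: np.ndarray


def generate_phantom_cohort(n: int, spec: PhantomSpec,
                            survival_beta: float = 1.0,
                            baseline_scale: float = 60.0,
                            censor_horizon: float = 75.0,
                            seed: int = 0,
                            radius_jitter: float = 0.15) -> PhantomCohort:
    """A cohort of phantoms with proportional-hazards survival on the
    latent risk.

    Each patient's tumor radii are jittered (lognormally, fractional SD
    ``radius_jitter``) so shape features vary across subjects; the latent
    risk drives both the texture correlation length and the hazard
    (log-hazard = survival_beta * latent).  TNM stage labels are drawn
    with advanced-stage probability increasing in the latent risk.
    Per-patient substreams come from SeedSequence((seed, i)), so the
    cohort is extendable without reshuffling.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2 patients")
    patients = []
    latents = np.empty(n)
    cohort_rng = np.random.default_rng(np.random.SeedSequence((seed, 10_000)))
    for i in range(n):
        sub = np.random.SeedSequence((seed, i))
        prng = np.random.default_rng(sub)
        latent = float(np.clip(prng.standard_normal(), -2.5, 2.5))
        radii = tuple(float(r * np.exp(radius_jitter * prng.standard_normal()))
                      for r in spec.tumor_radii)
        pat_spec = PhantomSpec(
            grid_shape=spec.grid_shape, voxel_spacing=spec.voxel_spacing,
            tumor_radii=radii,
            texture_correlation_length=spec.texture_correlation_length,
            noise_sd=spec.noise_sd, risk_link=spec.risk_link,
            seed=int(sub.generate_state(1)[0] % (2 ** 31)),
            t1_background=spec.t1_background,
            t1_tumor_mean=spec.t1_tumor_mean,
            t2_background=spec.t2_background,
            t2_tumor_mean=spec.t2_tumor_mean)
        patients.append(generate_phantom_patient(
            pat_spec, latent_risk=latent, patient_id=f"P{i:04d}"))
        latents[i] = latent

    lp = survival_beta * latents
    t_event = cohort_rng.exponential(baseline_scale, size=n) * np.exp(-lp)
    t_cens = cohort_rng.uniform(0.0, censor_horizon, size=n)
    time = np.maximum(np.minimum(t_event, t_cens), 1e-6)
    event = (t_event <= t_cens).astype(int)
    survival = SurvivalData(time, event,
                            np.array([p.patient_id for p in patients]))

    # stage labels: advanced pathologic stage more likely at high risk
    logit = 0.8 * latents + 0.5
    p_adv = 1.0 / (1.0 + np.exp(-logit))
    adv = cohort_rng.uniform(size=n) < p_adv
    iva = cohort_rng.uniform(size=n) < 0.55
    ptnm = np.where(adv, np.where(iva, "IVa", "IVb"), "III")
    cagree = cohort_rng.uniform(size=n) < 0.8
    ctnm = np.where(cagree, np.where(adv, "IVa", "III"),
                    np.where(adv, "III", "IVa"))
    stages = pd.DataFrame({"patient_id": survival.patient_id,
                           "cTNM": ctnm, "pTNM": ptnm})
    return PhantomCohort(patients, survival, stages, latents)


def write_phantom_cohort(cohort: PhantomCohort, out_dir: str | Path) -> Path:
    """Write NIfTI volumes/masks and the survival/stage CSV to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in cohort.patients:
        p.t1.to_nifti(str(out / f"{p.patient_id}_T1w.nii.gz"))
        p.t2.to_nifti(str(out / f"{p.patient_id}_T2w.nii.gz"))
        p.mask.to_nifti(str(out / f"{p.patient_id}_mask.nii.gz"))
    df = cohort.survival.to_frame().merge(cohort.stages, on="patient_id")
    df.to_csv(out / "survival.csv", index=False)
    return out
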