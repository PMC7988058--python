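"""Synthetic lesion phantoms and survival outcomes.

The generator stands in for a contrast-enhanced-CT lung-lesion cohort: each
patient gets an ellipsoidal soft-tissue lesion with a spatially correlated
texture field (Gaussian-smoothed white noise of controllable correlation
length and amplitude) on a soft-tissue background, plus white acquisition
noise. Survival times are exponential with a per-patient hazard that
depends log-linearly on the lesion's true MPP at a reference spatial scale,
so the full pipeline (filtration -> features -> ROC -> KM -> Cox) can be
exercised end to end with a known direction and magnitude of effect.

Censoring is administrative: an independent exponential censoring time whose
rate is calibrated by bisection so that the expected censored fraction
matches ``censor_rate_target`` given the realised per-patient hazards.
Progression-free survival is a fixed fraction of overall survival —
the pipeline only needs ordered, correlated endpoints with pfs <= os —
and the binary progression label is "progression event observed within
``landmark_days``".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import imaging_io
from .errors import ValidationError
from .filtration import (
    DEFAULT_CONFIG,
    FiltrationConfig,
    build_log_kernel,
    compute_features,
    extract_voi_values,
)
from .imaging_io import CTVolume, LesionMask


@dataclass(frozen=True)
class PhantomSpec:
    """One synthetic lesion-on-background CT volume.

    Defaults emulate a ~14 mm solid lesion on a venous-phase CECT: lesion
    mean about 60 HU on a 40 HU soft-tissue surround, texture correlation
    length of a few mm, and mild acquisition noise. Spacing defaults to
    2.5 x 1.0 x 1.0 mm (slice, row, column).
    """

    grid_shape: tuple[int, int, int] = (12, 40, 40)
    spacing_mm: tuple[float, float, float] = (2.5, 1.0, 1.0)
    lesion_diameter_mm: float = 14.0
    background_hu: float = 40.0
    lesion_mean_hu: float = 60.0
    texture_amplitude_hu: float = 20.0
    texture_scale_mm: float = 3.0
    noise_sd_hu: float = 5.0

    def validate(self, max_ssf_mm: float = 6.0) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError("spacings must be > 0")
        if self.lesion_diameter_mm <= 0 or self.texture_scale_mm <= 0:
            raise ValidationError("lengths must be > 0")
        if self.texture_amplitude_hu < 0 or self.noise_sd_hu < 0:
            raise ValidationError("noise amplitudes must be >= 0")
        # the grid must hold the lesion plus the coarsest kernel support in-plane
        kernel = build_log_kernel(max_ssf_mm, self.spacing_mm[1:])
        half = kernel.coefficients.shape[0] // 2
        for axis in (1, 2):
            need = self.lesion_diameter_mm / self.spacing_mm[axis] + 2 * half
            if need > self.grid_shape[axis]:
                raise ValidationError(
                    f"grid axis {axis} too small: lesion + SSF {max_ssf_mm} kernel "
                    f"support needs {need:.1f} px, grid has {self.grid_shape[axis]}"
                )
        if self.lesion_diameter_mm / self.spacing_mm[0] > self.grid_shape[0]:
            raise ValidationError("lesion exceeds the grid along the slice axis")


def generate_phantom(spec: PhantomSpec, seed, patient_id: str = "phantom") -> tuple[CTVolume, LesionMask]:
    """Build one textured lesion phantom, deterministically for a fixed seed.

    The mask is a sphere (in mm) centred in the grid. Lesion voxels are
    ``lesion_mean_hu`` + a correlated field (white Gaussian noise smoothed to
    ``texture_scale_mm`` and rescaled to ``texture_amplitude_hu`` SD) + white
    noise; background voxels are ``background_hu`` + white noise.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm)

    center = (np.asarray(shape) - 1) / 2.0
    coords = np.stack(
        np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    )
    dist2 = sum(((coords[a] - center[a]) * spacing[a]) ** 2 for a in range(3))
    mask_arr = dist2 <= (spec.lesion_diameter_mm / 2.0) ** 2
    if not mask_arr.any():
        raise ValidationError("lesion diameter too small for the voxel grid")

    # draw order is fixed so identical specs give identical volumes
    texture = np.zeros(shape)
    if spec.texture_amplitude_hu > 0:
        white = rng.standard_normal(shape)
        sigma_vox = spec.texture_scale_mm / spacing
        smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            texture = smooth * (spec.texture_amplitude_hu / sd)
    noise = np.zeros(shape)
    if spec.noise_sd_hu > 0:
        noise = rng.normal(0.0, spec.noise_sd_hu, size=shape)

    voxels = np.full(shape, spec.background_hu, dtype=np.float64) + noise
    voxels[mask_arr] = spec.lesion_mean_hu + texture[mask_arr] + noise[mask_arr]

    volume = CTVolume(voxels=voxels, spacing_mm=tuple(spec.spacing_mm), patient_id=patient_id)
    mask = LesionMask(voxels=mask_arr, reference=patient_id)
    return volume, mask


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic cohort whose hazard depends on true lesion MPP.

    ``beta_mpp`` is the log hazard per unit of true MPP at
    ``reference_ssf_mm`` (HR 0.89 per unit corresponds to -0.117); the
    default baseline hazard puts the median overall survival of a
    median-texture patient near 270 days. Default censoring (0.57) and the
    PFS fraction (0.44) follow a cohort where roughly 4 of 10 patients die
    during follow-up and median PFS is just under half the median OS.
    Per-patient texture parameters are drawn uniformly from the given
    ranges; substreams are derived from (seed, patient index) so cohorts
    are reproducible patient by patient.
    """

    n_patients: int = 100
    beta_mpp: float = -0.117
    baseline_hazard_per_day: float = 1.6
    censor_rate_target: float = 0.57
    pfs_fraction_of_os: float = 0.44
    landmark_days: float = 180.0
    reference_ssf_mm: float = 3.0
    seed: int = 0
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    lesion_mean_hu_range: tuple[float, float] = (50.0, 80.0)
    texture_amplitude_hu_range: tuple[float, float] = (25.0, 60.0)
    texture_scale_mm_range: tuple[float, float] = (2.0, 4.0)
    lesion_diameter_mm_range: tuple[float, float] = (10.0, 16.0)

    def validate(self) -> None:
        if self.n_patients < 4:
            raise ValidationError("a cohort needs at least 4 patients")
        if self.baseline_hazard_per_day <= 0:
            raise ValidationError("baseline hazard must be > 0")
        if not 0.0 <= self.censor_rate_target < 1.0:
            raise ValidationError("censor_rate_target must be in [0, 1)")
        if not 0.0 < self.pfs_fraction_of_os <= 1.0:
            raise ValidationError("pfs_fraction_of_os must be in (0, 1]")
        for lo, hi in (
            self.lesion_mean_hu_range,
            self.texture_amplitude_hu_range,
            self.texture_scale_mm_range,
            self.lesion_diameter_mm_range,
        ):
            if hi < lo:
                raise ValidationError("parameter ranges must have low <= high")


@dataclass(frozen=True)
class Cohort:
    """Generated phantoms plus the survival and truth tables."""

    volumes: list[CTVolume]
    masks: list[LesionMask]
    survival: pd.DataFrame
    truth: pd.DataFrame
    spec: CohortSpec


def _calibrate_censor_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate mu with mean_i mu/(mu+lambda_i) = target."""
    if target <= 0:
        return 0.0

    def censored_fraction(mu: float) -> float:
        return float(np.mean(mu / (mu + hazards)))

    lo, hi = 1e-12, float(hazards.max())
    while censored_fraction(hi) < target:
        hi *= 2.0
        if hi > 1e12:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if censored_fraction(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _patient_rng(seed: int, index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(index), int(stream)])


def generate_cohort(spec: CohortSpec, config: FiltrationConfig = DEFAULT_CONFIG) -> Cohort:
    """Generate phantoms, survival outcomes and the generating-truth table."""
    spec.validate()
    volumes: list[CTVolume] = []
    masks: list[LesionMask] = []
    truth_rows = []
    for i in range(spec.n_patients):
        rng = _patient_rng(spec.seed, i, 0)
        pid = f"P{i:04d}"
        pspec = replace(
            spec.phantom,
            lesion_mean_hu=float(rng.uniform(*spec.lesion_mean_hu_range)),
            texture_amplitude_hu=float(rng.uniform(*spec.texture_amplitude_hu_range)),
            texture_scale_mm=float(rng.uniform(*spec.texture_scale_mm_range)),
            lesion_diameter_mm=float(rng.uniform(*spec.lesion_diameter_mm_range)),
        )
        volume, mask = generate_phantom(pspec, seed=rng, patient_id=pid)
        sample = extract_voi_values(volume, mask, spec.reference_ssf_mm, config)
        true_mpp = compute_features(sample, config).mpp
        if not np.isfinite(true_mpp):
            true_mpp = 0.0  # no positive filtered voxels: flat lesion
        volumes.append(volume)
        masks.append(mask)
        truth_rows.append(
            {
                "patient_id": pid,
                "lesion_mean_hu": pspec.lesion_mean_hu,
                "texture_amplitude_hu": pspec.texture_amplitude_hu,
                "texture_scale_mm": pspec.texture_scale_mm,
                "lesion_diameter_mm": pspec.lesion_diameter_mm,
                "true_mpp": float(true_mpp),
                "reference_ssf_mm": spec.reference_ssf_mm,
            }
        )
    truth = pd.DataFrame(truth_rows)

    hazards = spec.baseline_hazard_per_day * np.exp(spec.beta_mpp * truth["true_mpp"].to_numpy())
    truth["hazard_per_day"] = hazards
    censor_rate = _calibrate_censor_rate(hazards, spec.censor_rate_target)

    surv_rows = []
    os_true_col, censor_col = [], []
    for i, pid in enumerate(truth["patient_id"]):
        rng = _patient_rng(spec.seed, i, 1)
        t_os = rng.exponential(1.0 / hazards[i])
        c = rng.exponential(1.0 / censor_rate) if censor_rate > 0 else np.inf
        t_pfs = spec.pfs_fraction_of_os * t_os
        os_days = min(t_os, c)
        os_event = int(t_os <= c)
        pfs_days = min(t_pfs, c)
        pfs_event = int(t_pfs <= c)
        progressor = int(pfs_event == 1 and pfs_days <= spec.landmark_days)
        surv_rows.append(
            {
                "patient_id": pid,
                "os_days": float(os_days),
                "os_event": os_event,
                "pfs_days": float(pfs_days),
                "pfs_event": pfs_event,
                "progressor": progressor,
            }
        )
        os_true_col.append(float(t_os))
        censor_col.append(float(c))
    truth["os_days_true"] = os_true_col
    truth["censor_days"] = censor_col
    survival = pd.DataFrame(surv_rows, columns=imaging_io.SURVIVAL_COLUMNS)
    return Cohort(volumes=volumes, masks=masks, survival=survival, truth=truth, spec=spec)


def write_cohort(cohort: Cohort, out_dir) -> dict[str, list[str] | str]:
    """Write phantoms as NIfTI pairs and the survival/truth tables as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    volume_paths, mask_paths = [], []
    for volume, mask in zip(cohort.volumes, cohort.masks):
        vpath = out / f"{volume.patient_id}_ct.nii.gz"
        mpath = out / f"{volume.patient_id}_mask.nii.gz"
        imaging_io.write_volume_nifti(volume, vpath)
        imaging_io.write_mask_nifti(mask, volume.spacing_mm, mpath)
        volume_paths.append(str(vpath))
        mask_paths.append(str(mpath))
    surv_path = out / "survival.csv"
    truth_path = out / "truth.csv"
    imaging_io.write_survival_table(cohort.survival, surv_path)
    cohort.truth.to_csv(truth_path, index=False)
    return {
        "volumes": volume_paths,
        "masks": mask_paths,
        "survival": str(surv_path),
        "truth": str(truth_path),
    }
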