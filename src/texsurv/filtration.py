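"""Filtration-histogram texture analysis.

The method derives, from one CT volume and lesion mask, a family of
band-pass filtered images: each axial slice is convolved with a
Laplacian-of-Gaussian (LoG) kernel whose spatial scale filter (SSF) value,
in mm, selects the approximate size of the image structures it highlights
(2 mm = fine, 3-4 mm = medium, 5-6 mm = coarse; SSF 0 means no filtration).
Voxel values inside the volume of interest (VOI) are then pooled across
slices and summarised by six first-order histogram statistics: mean,
standard deviation, entropy, kurtosis, skewness and the mean of positive
pixels (MPP).

The SSF value is mapped to the Gaussian scale via sigma_mm = SSF / (2*sqrt(2)),
the scale at which an LoG filter's blob response peaks for a blob of radius
sigma*sqrt(2), i.e. diameter ~= SSF. The constant is configurable because
filtration-histogram implementations differ in this convention; absolute
feature values (and hence published cut-offs) do not transfer between
conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import ValidationError
from .imaging_io import FEATURE_TABLE_COLUMNS, CTVolume, LesionMask

DEFAULT_SSF_LIST = (0.0, 2.0, 3.0, 4.0, 5.0, 6.0)

#: sigma_mm per SSF mm: blob-diameter convention, sigma = SSF / (2*sqrt(2))
SIGMA_PER_SSF_MM = 1.0 / (2.0 * math.sqrt(2.0))


@dataclass(frozen=True)
class FiltrationConfig:
    """Tunable conventions of the filtration-histogram method."""

    ssf_list: tuple[float, ...] = DEFAULT_SSF_LIST
    sigma_convention: float = SIGMA_PER_SSF_MM  # sigma_mm = convention * ssf_mm
    entropy_bins: int = 256
    boundary_mode: str = "reflect"  # scipy.ndimage name; 'reflect' = mirror pad
    sd_denominator: int = 1  # ddof for the standard deviation


DEFAULT_CONFIG = FiltrationConfig()


@dataclass(frozen=True)
class LoGKernel:
    """A discrete 2D Laplacian-of-Gaussian kernel at one SSF.

    ``coefficients`` is None for SSF 0 (identity / no filtration). The sign
    is chosen so that structures brighter than their surround produce
    positive responses, making MPP the mean brightness of highlighted
    features.
    """

    ssf_mm: float
    sigma_px: tuple[float, float] | None
    coefficients: np.ndarray | None

    @property
    def is_identity(self) -> bool:
        return self.coefficients is None


@dataclass(frozen=True)
class VOISample:
    """All VOI voxel values at one SSF (raw HU at SSF 0)."""

    values: np.ndarray
    ssf_mm: float

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=np.float64).ravel()
        if vals.size == 0:
            raise ValidationError("VOI sample is empty")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("VOI sample contains non-finite values")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class FeatureVector:
    """Six first-order statistics at one SSF; NaN marks an undefined feature."""

    mean: float
    sd: float
    entropy_bits: float
    kurtosis_excess: float
    skewness: float
    mpp: float
    ssf_mm: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "entropy": self.entropy_bits,
            "kurtosis": self.kurtosis_excess,
            "skewness": self.skewness,
            "mpp": self.mpp,
        }


def build_log_kernel(
    ssf_mm: float,
    in_plane_spacing_mm: tuple[float, float],
    sigma_convention: float = SIGMA_PER_SSF_MM,
) -> LoGKernel:
    """Construct the LoG kernel for one SSF at a given pixel spacing.

    The kernel is sampled on a square support of half-width
    ``ceil(4 * max(sigma_px))`` and mean-subtracted so its coefficients sum
    to zero: a zero-sum kernel removes the DC component, which is what makes
    the filtration a band-pass.  SSF 0 returns the identity marker.
    """
    sr, sc = (float(s) for s in in_plane_spacing_mm)
    if sr <= 0 or sc <= 0:
        raise ValidationError(f"in-plane spacings must be > 0, got {(sr, sc)}")
    if ssf_mm < 0:
        raise ValidationError(f"ssf_mm must be >= 0, got {ssf_mm}")
    if ssf_mm == 0:
        return LoGKernel(ssf_mm=0.0, sigma_px=None, coefficients=None)

    sigma_mm = sigma_convention * ssf_mm
    sig_r, sig_c = sigma_mm / sr, sigma_mm / sc
    half = int(math.ceil(4.0 * max(sig_r, sig_c)))
    r = np.arange(-half, half + 1, dtype=np.float64)[:, None]
    c = np.arange(-half, half + 1, dtype=np.float64)[None, :]
    gauss = np.exp(-(r**2 / (2 * sig_r**2) + c**2 / (2 * sig_c**2)))
    laplacian = gauss * (
        (r**2 / sig_r**4 - 1.0 / sig_r**2) + (c**2 / sig_c**4 - 1.0 / sig_c**2)
    )
    coeff = -laplacian  # bright-blob response positive
    coeff -= coeff.mean()
    return LoGKernel(ssf_mm=float(ssf_mm), sigma_px=(sig_r, sig_c), coefficients=coeff)


def filter_slice(slice_2d: np.ndarray, kernel: LoGKernel, boundary_mode: str = "reflect") -> np.ndarray:
    """Correlate one axial slice with the kernel (mirror boundary padding).

    Output shape equals input shape; the identity kernel returns a copy.
    """
    arr = np.asarray(slice_2d, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError("filter_slice expects a 2D slice")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("slice contains non-finite values")
    if kernel.is_identity:
        return arr.copy()
    return ndimage.correlate(arr, kernel.coefficients, mode=boundary_mode)


def _filter_stack(stack: np.ndarray, kernel: LoGKernel, boundary_mode: str) -> np.ndarray:
    """Filter a (k, rows, cols) stack of slices in one call.

    The kernel extends only in-plane, so boundary handling along the slice
    axis never enters; results are identical to per-slice filtering.
    """
    if kernel.is_identity:
        return stack.astype(np.float64, copy=True)
    return ndimage.correlate(
        stack.astype(np.float64, copy=False),
        kernel.coefficients[None, :, :],
        mode=boundary_mode,
    )


def extract_voi_values(
    volume: CTVolume,
    mask: LesionMask,
    ssf_mm: float,
    config: FiltrationConfig = DEFAULT_CONFIG,
) -> VOISample:
    """Pool VOI voxel values at one SSF into a single volumetric sample.

    Every axial slice intersecting the mask is filtered whole (never
    mask-cropped, so the filter support sees true surrounding tissue) and
    sampled at the mask's foreground positions; per-slice samples are
    concatenated in slice order. SSF 0 pools the raw HU values.
    """
    if mask.shape != volume.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match volume shape {volume.shape}"
        )
    slice_has_mask = mask.voxels.any(axis=(1, 2))
    idx = np.flatnonzero(slice_has_mask)
    kernel = build_log_kernel(ssf_mm, volume.in_plane_spacing_mm, config.sigma_convention)
    filtered = _filter_stack(volume.voxels[idx], kernel, config.boundary_mode)
    values = filtered[mask.voxels[idx]]
    return VOISample(values=values, ssf_mm=float(ssf_mm))


def compute_features(sample: VOISample, config: FiltrationConfig = DEFAULT_CONFIG) -> FeatureVector:
    """First-order histogram statistics of one VOI sample.

    mean: arithmetic mean. sd: sample standard deviation (ddof per config;
    0 when n = 1). skewness: biased third standardized moment m3/m2^1.5.
    kurtosis: excess kurtosis m4/m2^2 - 3 (normal -> 0). entropy: Shannon
    entropy in bits of the normalised histogram with ``entropy_bins``
    equal-width bins spanning the sample's own [min, max] (0 for a constant
    sample). mpp: mean of strictly positive values, NaN when there are none.
    Shape moments are NaN for zero-variance samples rather than infinite.
    """
    x = sample.values
    n = x.size
    mean = float(np.mean(x))
    if n == 1:
        sd = 0.0
    else:
        sd = float(np.std(x, ddof=config.sd_denominator))

    m2 = float(np.mean((x - mean) ** 2))
    if m2 == 0.0:
        skewness = float("nan")
        kurtosis = float("nan")
    else:
        skewness = float(stats.skew(x, bias=True))
        kurtosis = float(stats.kurtosis(x, fisher=True, bias=True))

    xmin, xmax = float(np.min(x)), float(np.max(x))
    if xmin == xmax:
        entropy = 0.0
    else:
        counts, _ = np.histogram(x, bins=config.entropy_bins, range=(xmin, xmax))
        p = counts[counts > 0] / n
        entropy = float(-(p * np.log2(p)).sum())

    positives = x[x > 0]
    mpp = float(np.mean(positives)) if positives.size else float("nan")

    return FeatureVector(
        mean=mean,
        sd=sd,
        entropy_bits=entropy,
        kurtosis_excess=kurtosis,
        skewness=skewness,
        mpp=mpp,
        ssf_mm=sample.ssf_mm,
        n=n,
    )


def extract_feature_table(
    volume: CTVolume,
    mask: LesionMask,
    ssf_list: tuple[float, ...] | None = None,
    config: FiltrationConfig = DEFAULT_CONFIG,
    per_slice: bool = False,
) -> pd.DataFrame:
    """Feature table for one lesion: one row per SSF (six features each).

    With the default SSF list (0, 2, 3, 4, 5, 6) this yields the standard
    36 features per lesion. ``per_slice=True`` instead emits one row per
    (SSF, slice) with features computed on each slice's own mask sample —
    a finer observation unit some implementations use; it adds a
    ``slice_index`` column.
    """
    if ssf_list is None:
        ssf_list = config.ssf_list
    rows = []
    for ssf in ssf_list:
        if not per_slice:
            sample = extract_voi_values(volume, mask, ssf, config)
            fv = compute_features(sample, config)
            rows.append({"patient_id": volume.patient_id, "ssf": float(ssf), **fv.as_dict()})
        else:
            idx = np.flatnonzero(mask.voxels.any(axis=(1, 2)))
            kernel = build_log_kernel(ssf, volume.in_plane_spacing_mm, config.sigma_convention)
            filtered = _filter_stack(volume.voxels[idx], kernel, config.boundary_mode)
            for j, k in enumerate(idx):
                vals = filtered[j][mask.voxels[k]]
                fv = compute_features(VOISample(values=vals, ssf_mm=float(ssf)), config)
                rows.append(
                    {
                        "patient_id": volume.patient_id,
                        "ssf": float(ssf),
                        "slice_index": int(k),
                        **fv.as_dict(),
                    }
                )
    columns = FEATURE_TABLE_COLUMNS if not per_slice else (
        ["patient_id", "ssf", "slice_index"] + FEATURE_TABLE_COLUMNS[2:]
    )
    return pd.DataFrame(rows, columns=columns)
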