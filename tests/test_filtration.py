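import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from texsurv.errors import ValidationError
from texsurv.filtration import (
    DEFAULT_SSF_LIST,
    FiltrationConfig,
    VOISample,
    build_log_kernel,
    compute_features,
    extract_feature_table,
    extract_voi_values,
    filter_slice,
)
from texsurv.imaging_io import CTVolume, LesionMask

from conftest import blob_slice_and_voi


def brute_force_correlate(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Nested-loop correlation with mirror (symmetric) padding — the oracle."""
    half = kernel.shape[0] // 2
    padded = np.pad(image, half, mode="symmetric")
    out = np.empty_like(image, dtype=np.float64)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            window = padded[i : i + kernel.shape[0], j : j + kernel.shape[1]]
            out[i, j] = float((window * kernel).sum())
    return out


def feature_oracle(x: np.ndarray) -> dict:
    """Direct-formula first-order features, independent of the implementation."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    mean = x.sum() / n
    d = x - mean
    m2 = (d**2).sum() / n
    m3 = (d**3).sum() / n
    m4 = (d**4).sum() / n
    sd = math.sqrt((d**2).sum() / (n - 1)) if n > 1 else 0.0
    skew = m3 / m2**1.5 if m2 > 0 else float("nan")
    kurt = m4 / m2**2 - 3.0 if m2 > 0 else float("nan")
    if x.min() == x.max():
        ent = 0.0
    else:
        edges = np.linspace(x.min(), x.max(), 257)
        counts = np.zeros(256)
        for v in x:
            b = int((v - x.min()) / (x.max() - x.min()) * 256)
            counts[min(b, 255)] += 1
        p = counts[counts > 0] / n
        ent = float(-(p * np.log2(p)).sum())
    pos = x[x > 0]
    mpp = pos.mean() if pos.size else float("nan")
    return {"mean": mean, "sd": sd, "entropy": ent, "kurtosis": kurt, "skewness": skew, "mpp": mpp}


class TestKernel:
    def test_ssf_zero_is_identity(self):
        k = build_log_kernel(0.0, (0.7, 0.7))
        assert k.is_identity
        img = np.random.default_rng(0).normal(size=(10, 12))
        np.testing.assert_array_equal(filter_slice(img, k), img)

    def test_sigma_mapping_at_unit_spacing(self):
        k = build_log_kernel(2.0, (1.0, 1.0))
        assert k.sigma_px == pytest.approx((0.7071067811865475, 0.7071067811865475))

    def test_anisotropic_spacing_gives_anisotropic_sigma(self):
        k = build_log_kernel(4.0, (0.7, 1.0))
        sig_mm = 4.0 / (2 * math.sqrt(2))
        assert k.sigma_px == pytest.approx((sig_mm / 0.7, sig_mm / 1.0))

    @pytest.mark.parametrize("ssf", [2.0, 3.0, 4.0, 5.0, 6.0])
    def test_zero_sum_and_point_symmetry(self, ssf):
        k = build_log_kernel(ssf, (0.7, 0.7))
        w = k.coefficients
        assert abs(w.sum()) <= 1e-10 * np.abs(w).max()
        np.testing.assert_allclose(w, np.rot90(w, 2), rtol=0, atol=1e-15)

    def test_support_halfwidth(self):
        k = build_log_kernel(6.0, (1.0, 1.0))
        half = math.ceil(4 * max(k.sigma_px))
        assert k.coefficients.shape == (2 * half + 1, 2 * half + 1)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValidationError):
            build_log_kernel(2.0, (0.0, 1.0))


class TestFilterSlice:
    def test_constant_slice_maps_to_zero(self):
        img = np.full((24, 24), 50.0)
        for ssf in (2.0, 4.0, 6.0):
            out = filter_slice(img, build_log_kernel(ssf, (1.0, 1.0)))
            assert np.abs(out).max() <= 1e-8 * 50.0

    def test_impulse_reproduces_kernel(self):
        k = build_log_kernel(3.0, (1.0, 1.0))
        half = k.coefficients.shape[0] // 2
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = filter_slice(img, k)
        # symmetric kernel: correlation with an impulse recenters the kernel
        np.testing.assert_allclose(
            out[20 - half : 20 + half + 1, 20 - half : 20 + half + 1],
            k.coefficients,
            atol=1e-12,
        )

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(7)
        img = rng.normal(0, 100, size=(32, 32))
        k = build_log_kernel(4.0, (1.0, 1.0))
        out = filter_slice(img, k)
        oracle = brute_force_correlate(img, k.coefficients)
        assert np.abs(out - oracle).max() <= 1e-10 * np.abs(oracle).max()

    def test_linearity_kills_dc_offset(self):
        rng = np.random.default_rng(3)
        img = rng.normal(0, 30, size=(28, 28))
        k = build_log_kernel(3.0, (0.7, 0.7))
        lhs = filter_slice(3.5 * img + 120.0, k)
        rhs = 3.5 * filter_slice(img, k)
        assert np.abs(lhs - rhs).max() <= 1e-8 * np.abs(rhs).max()

    def test_nonfinite_input_rejected(self):
        img = np.zeros((8, 8))
        img[0, 0] = np.inf
        with pytest.raises(ValidationError):
            filter_slice(img, build_log_kernel(2.0, (1.0, 1.0)))


class TestExtractVOI:
    def test_ssf_zero_pools_raw_hu(self):
        vox = np.zeros((1, 2, 2))
        vox[0] = [[-10.0, 0.0], [10.0, 20.0]]
        volume = CTVolume(vox, (1.0, 1.0, 1.0), "p")
        mask = LesionMask(np.ones((1, 2, 2), dtype=bool), "p")
        sample = extract_voi_values(volume, mask, 0.0)
        assert sorted(sample.values.tolist()) == [-10.0, 0.0, 10.0, 20.0]

    def test_constant_volume_filters_to_zero(self):
        volume = CTVolume(np.full((3, 30, 30), 75.0), (1.0, 1.0, 1.0), "p")
        mask_arr = np.zeros((3, 30, 30), dtype=bool)
        mask_arr[1, 10:20, 10:20] = True
        sample = extract_voi_values(volume, LesionMask(mask_arr, "p"), 4.0)
        assert np.abs(sample.values).max() <= 1e-8 * 75.0

    def test_two_slice_sample_is_concatenation(self, tiny_volume_mask):
        volume, mask = tiny_volume_mask
        pooled = extract_voi_values(volume, mask, 3.0)
        parts = []
        for k in (1, 2):
            sub = np.zeros_like(mask.voxels)
            sub[k] = mask.voxels[k]
            parts.append(extract_voi_values(volume, LesionMask(sub, "tiny"), 3.0).values)
        np.testing.assert_allclose(pooled.values, np.concatenate(parts), atol=1e-12)
        assert pooled.n == sum(p.size for p in parts)

    def test_whole_slice_filtering_sees_outside_context(self):
        # cropping to the mask bounding box before filtering would change values
        rng = np.random.default_rng(11)
        vox = rng.normal(0, 50, size=(1, 40, 40))
        volume = CTVolume(vox, (1.0, 1.0, 1.0), "p")
        mask_arr = np.zeros((1, 40, 40), dtype=bool)
        mask_arr[0, 15:25, 15:25] = True
        sample = extract_voi_values(volume, LesionMask(mask_arr, "p"), 4.0)
        cropped = CTVolume(vox[:, 15:25, 15:25], (1.0, 1.0, 1.0), "p")
        cropped_sample = extract_voi_values(
            cropped, LesionMask(np.ones((1, 10, 10), dtype=bool), "p"), 4.0
        )
        assert not np.allclose(sample.values, cropped_sample.values)


class TestFeatures:
    def test_worked_example_mean_sd_mpp(self):
        sample = VOISample(np.array([1.0, 2.0, 3.0, -2.0]), ssf_mm=0.0)
        fv = compute_features(sample)
        assert fv.mean == pytest.approx(1.0)
        assert fv.mpp == pytest.approx(2.0)  # mean of {1, 2, 3}
        assert fv.sd == pytest.approx(math.sqrt(14.0 / 3.0))
        oracle = feature_oracle(sample.values)
        assert fv.skewness == pytest.approx(oracle["skewness"], rel=1e-12)
        assert fv.kurtosis_excess == pytest.approx(oracle["kurtosis"], rel=1e-12)

    def test_symmetric_sample(self):
        fv = compute_features(VOISample(np.array([-3.0, -1.0, 1.0, 3.0]), 0.0))
        assert fv.skewness == pytest.approx(0.0, abs=1e-12)
        assert fv.mpp == pytest.approx(2.0)

    def test_all_negative_sample_has_missing_mpp(self):
        fv = compute_features(VOISample(np.array([-5.0, -1.0]), 0.0))
        assert math.isnan(fv.mpp)

    def test_zero_variance_gives_missing_shape_moments(self):
        fv = compute_features(VOISample(np.full(10, 7.0), 0.0))
        assert math.isnan(fv.skewness) and math.isnan(fv.kurtosis_excess)
        assert fv.sd == 0.0
        assert fv.entropy_bits == 0.0

    def test_single_voxel_sample(self):
        fv = compute_features(VOISample(np.array([4.0]), 0.0))
        assert fv.sd == 0.0 and fv.mean == 4.0 and fv.entropy_bits == 0.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            VOISample(np.array([]), 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_random_samples(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 2000))
        x = rng.normal(rng.uniform(-50, 50), rng.uniform(0.1, 80), size=n)
        fv = compute_features(VOISample(x, 0.0))
        oracle = feature_oracle(x)
        got = fv.as_dict()
        for key, want in oracle.items():
            if math.isnan(want):
                assert math.isnan(got[key])
            else:
                assert got[key] == pytest.approx(want, rel=1e-10, abs=1e-12), key

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-500, max_value=500, allow_nan=False),
            min_size=1,
            max_size=64,
        )
    )
    def test_entropy_bounds_and_sd_nonneg(self, values):
        fv = compute_features(VOISample(np.array(values), 0.0))
        assert fv.sd >= 0.0
        assert 0.0 <= fv.entropy_bits <= 8.0  # at most log2(256) bits
        if not any(v > 0 for v in values):
            assert math.isnan(fv.mpp)
        else:
            assert fv.mpp > 0


class TestFeatureTable:
    def test_default_run_yields_36_features(self, small_phantom):
        volume, mask = small_phantom
        table = extract_feature_table(volume, mask)
        assert len(table) == 6
        assert table[["mean", "sd", "entropy", "kurtosis", "skewness", "mpp"]].size == 36
        assert list(table["ssf"]) == list(DEFAULT_SSF_LIST)

    def test_constant_lesion_features(self):
        from texsurv.cohort import PhantomSpec, generate_phantom

        # lesion equal to its background: no texture, no edge, nothing to filter
        spec = PhantomSpec(
            texture_amplitude_hu=0.0, noise_sd_hu=0.0, lesion_mean_hu=64.0, background_hu=64.0
        )
        volume, mask = generate_phantom(spec, seed=0)
        table = extract_feature_table(volume, mask).set_index("ssf")
        assert table.loc[0.0, "mean"] == pytest.approx(64.0)
        assert table.loc[0.0, "sd"] == 0.0
        for ssf in (2.0, 3.0, 4.0, 5.0, 6.0):
            assert abs(table.loc[ssf, "mean"]) <= 1e-8 * 64.0
            # mpp is missing (no positive responses) or rounding dust of the
            # exactly-zero response field
            mpp = table.loc[ssf, "mpp"]
            assert math.isnan(mpp) or abs(mpp) <= 1e-8 * 64.0

    def test_single_ssf_subset_matches_full_run(self, small_phantom):
        volume, mask = small_phantom
        full = extract_feature_table(volume, mask).set_index("ssf")
        sub = extract_feature_table(volume, mask, ssf_list=(3.0,)).set_index("ssf")
        pd_row = sub.loc[3.0]
        for col in ("mean", "sd", "entropy", "kurtosis", "skewness", "mpp"):
            assert pd_row[col] == pytest.approx(full.loc[3.0, col], rel=1e-12)

    def test_per_slice_mode_rows_and_pooling(self, tiny_volume_mask):
        volume, mask = tiny_volume_mask
        per_slice = extract_feature_table(volume, mask, ssf_list=(0.0, 3.0), per_slice=True)
        assert set(per_slice["slice_index"]) == {1, 2}
        assert len(per_slice) == 4  # 2 SSFs x 2 mask slices
        # per-slice means pool back to the volumetric mean at SSF 0
        pooled = extract_feature_table(volume, mask, ssf_list=(0.0,))["mean"].iloc[0]
        sizes = mask.voxels.sum(axis=(1, 2))[[1, 2]]
        sl = per_slice[per_slice.ssf == 0.0].sort_values("slice_index")["mean"].to_numpy()
        assert np.average(sl, weights=sizes) == pytest.approx(pooled, rel=1e-12)


class TestScaleProperties:
    def test_scale_selectivity_nondecreasing(self):
        argmaxes = []
        for d in (2.0, 4.0, 6.0):
            img, voi = blob_slice_and_voi(d, spacing=1.0)
            responses = {}
            for ssf in (2.0, 3.0, 4.0, 5.0, 6.0):
                out = filter_slice(img, build_log_kernel(ssf, (1.0, 1.0)))
                responses[ssf] = np.abs(out[voi]).mean()
            argmaxes.append(max(responses, key=responses.get))
        assert argmaxes == sorted(argmaxes)
        assert argmaxes[0] < argmaxes[-1]

    def test_spacing_invariance_of_filtered_sd(self):
        # the same smooth mm-defined field sampled at 0.7 and 1.0 mm pixels
        rng = np.random.default_rng(5)
        centers = rng.uniform(10, 38, size=(25, 2))
        amps = rng.uniform(-60, 60, size=25)
        widths = rng.uniform(2.5, 5.0, size=25)

        def sample(spacing):
            n = int(round(48.0 / spacing))
            ax = (np.arange(n) + 0.5) * spacing
            yy, xx = np.meshgrid(ax, ax, indexing="ij")
            sl = np.full((n, n), 50.0)
            for (cy, cx), a, w in zip(centers, amps, widths):
                sl += a * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * w**2)))
            vol = CTVolume(sl[None], (2.5, spacing, spacing), "p")
            voi = ((yy - 24.0) ** 2 + (xx - 24.0) ** 2) <= 15.0**2
            return vol, LesionMask(voi[None], "p")

        for ssf in (2.0, 3.0, 4.0, 5.0, 6.0):
            sds = {}
            for spacing in (0.7, 1.0):
                vol, mask = sample(spacing)
                fv = compute_features(extract_voi_values(vol, mask, ssf))
                sds[spacing] = fv.sd
            assert abs(sds[0.7] - sds[1.0]) / sds[1.0] < 0.10

    def test_entropy_binning_is_configurable(self, small_phantom):
        volume, mask = small_phantom
        sample = extract_voi_values(volume, mask, 3.0)
        e256 = compute_features(sample).entropy_bits
        e16 = compute_features(sample, FiltrationConfig(entropy_bins=16)).entropy_bits
        assert e16 < e256
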