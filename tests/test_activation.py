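"""Reference building, CC mapping and region extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fmrisr.activation import (
    CCMap,
    build_reference,
    cc_map,
    extract_region,
    normalized_pixel_count,
    range_threshold,
    run_arm,
    upsample_mask_nearest,
)
from fmrisr.hrf import canonical_hrf
from fmrisr.io import FunctionalSeries, TaskDesign


def _series(data, tr=0.5):
    return FunctionalSeries(np.asarray(data, dtype=float), tr=tr)


class TestReference:
    def test_canonical_hrf_peaks_at_5_to_6_seconds(self):
        tr = 0.1
        h = canonical_hrf(tr)
        assert 5.0 <= np.argmax(h) * tr <= 6.0
        assert h.sum() == pytest.approx(1.0)

    def test_impulse_kernel_returns_boxcar(self):
        design = TaskDesign(blocks=[("a", 10.0, 10.0)], tr=0.5, n_volumes=100)
        ref = build_reference(design, "a", hrf="impulse")
        np.testing.assert_array_equal(ref.values, design.boxcar("a"))

    def test_unknown_label_errors(self):
        design = TaskDesign(blocks=[("a", 10.0, 10.0)], tr=0.5, n_volumes=100)
        with pytest.raises(KeyError):
            build_reference(design, "nope")

    def test_empty_after_discard_errors(self):
        # single early block entirely inside the discard window
        design = TaskDesign(blocks=[("a", 0.0, 5.0)], tr=0.5, n_volumes=100)
        with pytest.raises(ValueError, match="no activity"):
            build_reference(design, "a", n_discarded=80, hrf="impulse")

    def test_discard_aligns_reference(self):
        design = TaskDesign(blocks=[("a", 30.0, 10.0)], tr=0.5, n_volumes=200)
        full = build_reference(design, "a")
        cut = build_reference(design, "a", n_discarded=40)
        np.testing.assert_array_equal(cut.values, full.values[40:])


class TestCCMap:
    def _ref(self, values):
        from fmrisr.activation import ReferenceTimecourse

        return ReferenceTimecourse(values=np.asarray(values, float), task_label="a")

    def test_identical_opposite_orthogonal(self):
        t = np.arange(64)
        rx = np.sin(2 * np.pi * t / 16)
        ortho = np.cos(2 * np.pi * t / 16)
        data = np.stack([rx, -rx, ortho]).reshape(3, 1, 1, 64)
        out = cc_map(_series(data), self._ref(rx))
        np.testing.assert_allclose(
            out.values[:, 0], [1.0, -1.0, 0.0], atol=1e-10
        )

    def test_matches_bruteforce_oracle(self, rng):
        nt = 20
        data = rng.normal(size=(10, 10, 1, nt))
        ref_vals = rng.normal(size=nt)
        out = cc_map(_series(data), self._ref(ref_vals), center=True)
        rx = ref_vals - ref_vals.mean()
        for i in range(10):
            for j in range(10):
                ry = data[i, j, 0] - data[i, j, 0].mean()
                expected = (rx @ ry) / (np.linalg.norm(rx) * np.linalg.norm(ry))
                assert out.values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_uncentered_is_cosine_similarity(self, rng):
        nt = 30
        data = rng.uniform(1, 2, size=(4, 4, 1, nt))
        ref_vals = rng.uniform(0, 1, size=nt)
        out = cc_map(_series(data), self._ref(ref_vals), center=False)
        rx = ref_vals
        ry = data[2, 3, 0]
        expected = (rx @ ry) / (np.linalg.norm(rx) * np.linalg.norm(ry))
        assert out.values[2, 3] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_pixel_flagged_zero(self):
        data = np.ones((2, 2, 1, 16))
        data[0, 0, 0] = np.sin(np.arange(16))
        out = cc_map(_series(data), self._ref(np.sin(np.arange(16))))
        assert out.values[1, 1] == 0.0
        assert out.zero_variance[1, 1] and not out.zero_variance[0, 0]

    def test_bounded_and_nan_outside_mask(self, rng):
        data = rng.normal(size=(8, 8, 1, 25)) * 1e6
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        out = cc_map(_series(data), self._ref(rng.normal(size=25)), mask=mask)
        assert np.all(np.isnan(out.values[~mask]))
        assert np.nanmax(np.abs(out.values)) <= 1 + 1e-12

    def test_length_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="length"):
            cc_map(_series(rng.normal(size=(2, 2, 1, 10))), self._ref(np.ones(9)))


class TestExtractRegion:
    @pytest.mark.parametrize(
        "mx, mn, expected", [(1.0, 0.0, 0.75), (0.8, 0.4, 0.7)]
    )
    def test_threshold_arithmetic(self, mx, mn, expected):
        assert range_threshold(mx, mn) == pytest.approx(expected)

    def _map(self, values, mask=None):
        values = np.asarray(values, float)
        if mask is None:
            mask = np.ones(values.shape, bool)
        return CCMap(values=np.where(mask, values, np.nan), mask=mask, task_label="a")

    def test_constant_map_returns_whole_mask(self):
        mask = np.zeros((5, 5), bool)
        mask[1:4, 1:4] = True
        region = extract_region(self._map(np.full((5, 5), 0.3), mask))
        assert region.threshold_used == pytest.approx(0.3)
        np.testing.assert_array_equal(region.mask, mask)

    def test_region_is_inclusive_superlevel_set(self, rng):
        values = rng.uniform(-1, 1, size=(12, 12))
        mask = rng.uniform(size=(12, 12)) > 0.3
        region = extract_region(self._map(values, mask))
        thr = region.threshold_used
        for i in range(12):
            for j in range(12):
                expected = mask[i, j] and values[i, j] >= thr
                assert region.mask[i, j] == expected
        # always contains the in-mask argmax
        inside = np.where(mask, values, -np.inf)
        assert region.mask[np.unravel_index(np.argmax(inside), inside.shape)]

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            extract_region(self._map(np.zeros((3, 3)), np.zeros((3, 3), bool)))

    @given(shift=st.floats(-0.5, 0.5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_translation_equivariance(self, shift):
        rng = np.random.default_rng(5)
        values = rng.uniform(-0.4, 0.4, size=(9, 9))
        base = extract_region(self._map(values))
        moved = extract_region(self._map(values + shift))
        np.testing.assert_array_equal(base.mask, moved.mask)
        assert moved.threshold_used == pytest.approx(
            base.threshold_used + shift, abs=1e-12
        )


class TestRunArm:
    def test_identity_generator_equals_lanczos_preupscaled_arm(
        self, small_spec, small_design, small_phantom
    ):
        """Running the SR arm with a frozen (identity-residual) generator is
        the same as running the native arm on Lanczos-upscaled frames."""
        import dataclasses

        from fmrisr.io import FunctionalSeries
        from fmrisr.phantom import make_structural_pair
        from fmrisr.preprocess import PreprocessConfig, discard_initial
        from fmrisr.sr import GanConfig, train_subject_model, upscale_lanczos

        series, gt = small_phantom
        hi, lo = make_structural_pair(small_spec)
        frozen = GanConfig(
            n_resblocks=1, n_features=4, disc_base_channels=4,
            patch_size=16, iterations=1, lr=0.0, seed=1,
        )
        model = train_subject_model(hi, lo, frozen)
        pre = PreprocessConfig(n_discard=20)
        mask = gt.analysis_mask_lr

        via_generator = run_arm(
            series, small_design, mask, pre, generator=model
        )

        # per-frame upscaling commutes with the discard step, so upscale
        # the whole series and run the native arm with the same config
        up = np.stack(
            [upscale_lanczos(series.data[:, :, 0, t], 2) for t in range(series.n_volumes)],
            axis=-1,
        )[:, :, None, :]
        up_series = FunctionalSeries(up, tr=series.tr, pixel_size=series.pixel_size / 2)
        manual = run_arm(up_series, small_design, upsample_mask_nearest(mask, 2), pre)
        for label in via_generator:
            np.testing.assert_allclose(
                via_generator[label]["cc_map"].values,
                manual[label]["cc_map"].values,
                atol=1e-4,
            )


class TestPixelCount:
    def test_division_contract(self):
        assert normalized_pixel_count(40, 4) == 10.0
        assert normalized_pixel_count(37, 1) == 37.0

    def test_upsampled_mask_count_matches_original(self, rng):
        for _ in range(100):
            mask = rng.uniform(size=(9, 7)) > 0.6
            up = upsample_mask_nearest(mask, 2)
            assert up.shape == (18, 14)
            assert normalized_pixel_count(up.sum(), 4) == float(mask.sum())

    def test_factor_below_one_errors(self):
        with pytest.raises(ValueError):
            normalized_pixel_count(10, 0.5)
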