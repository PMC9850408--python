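"""MSI data model, imzML round-trips, and preprocessing."""

import numpy as np
import pytest

from picamsi import (
    IonImage,
    MSIDataset,
    PreprocessConfig,
    align_features,
    extract_ion_image,
    pick_peaks,
    read_imzml,
    recalibrate,
    render_ion_image,
    tic_normalize,
    write_imzml,
)

from conftest import make_dataset


class TestDatasetInvariants:
    def test_shape_mismatches_rejected(self):
        with pytest.raises(ValueError):
            make_dataset(np.ones((3, 2)), mz_axis=[100.0])
        with pytest.raises(ValueError):
            MSIDataset(coords=[[1, 1]], intensities=np.ones((2, 2)), mz_axis=[100.0, 200.0])

    def test_descending_axis_rejected(self):
        with pytest.raises(ValueError):
            make_dataset(np.ones((2, 2)), mz_axis=[200.0, 100.0])

    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError):
            make_dataset([[1.0, -1.0]])

    def test_duplicate_coords_rejected(self):
        with pytest.raises(ValueError):
            MSIDataset(coords=[[1, 1], [1, 1]], intensities=np.ones((2, 1)), mz_axis=[100.0])


class TestImzmlRoundTrip:
    def test_round_trip_preserves_data(self, tmp_path):
        rng = np.random.default_rng(7)
        ds = make_dataset(rng.gamma(2.0, 10.0, size=(20, 50)),
                          mz_axis=np.sort(rng.uniform(100, 1000, 50)))
        path = tmp_path / "roundtrip.imzML"
        write_imzml(ds, path)
        back = read_imzml(path)
        assert np.array_equal(back.coords, ds.coords)
        assert np.allclose(back.mz_axis, ds.mz_axis, rtol=0, atol=1e-9)
        rel = np.abs(back.intensities - ds.intensities) / np.maximum(ds.intensities, 1e-30)
        assert rel.max() <= 1e-4

    def test_tiny_continuous_file(self, tmp_path):
        ds = make_dataset([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]], mz_axis=[100.0, 200.0])
        path = tmp_path / "tiny.imzML"
        write_imzml(ds, path)
        back = read_imzml(path)
        assert back.n_pixels == 3 and back.n_features == 2
        assert back.metadata["mode"] == "continuous"

    def test_empty_feature_dataset_refused(self, tmp_path):
        ds = MSIDataset(coords=[[1, 1]], intensities=np.zeros((1, 0)), mz_axis=[])
        with pytest.raises(ValueError):
            write_imzml(ds, tmp_path / "empty.imzML")

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(ValueError):
            read_imzml(tmp_path / "nope.imzML")


class TestAlignment:
    def test_close_centroids_merge_into_one_feature(self):
        # two pixels whose centroids differ by 1.8 mDa: one aligned feature
        spectra = [([300.0501], [10.0]), ([300.0519], [30.0])]
        mz_axis, intensities = align_features(spectra, bin_tol=0.003)
        assert len(mz_axis) == 1
        # representative = intensity-weighted mean
        assert mz_axis[0] == pytest.approx((300.0501 * 10 + 300.0519 * 30) / 40)
        assert intensities.shape == (2, 1)

    def test_gap_beyond_tol_splits(self):
        spectra = [([300.0501, 300.0601], [10.0, 5.0]), ([300.0519], [30.0])]
        mz_axis, _ = align_features(spectra, bin_tol=0.003)
        assert len(mz_axis) == 2

    def test_matches_single_linkage_oracle(self):
        """Cluster count equals single-linkage clustering at the gap cutoff."""
        from scipy.cluster.hierarchy import fcluster, linkage

        rng = np.random.default_rng(11)
        mzs = np.sort(rng.uniform(100, 110, 40))
        spectra = [(mzs[i::4], np.ones(len(mzs[i::4]))) for i in range(4)]
        mz_axis, _ = align_features(spectra, bin_tol=0.05)
        z = linkage(mzs[:, None], method="single")
        # fcluster cuts at distance <= t; the gap rule splits strictly above tol
        n_oracle = len(np.unique(fcluster(z, t=0.05, criterion="distance")))
        assert len(mz_axis) == n_oracle

    def test_processed_mode_file_is_aligned(self, tmp_path):
        from pyimzml.ImzMLWriter import ImzMLWriter

        path = tmp_path / "processed.imzML"
        with ImzMLWriter(str(path), mode="processed") as w:
            w.addSpectrum([300.0501, 400.0], [10.0, 1.0], (1, 1, 1))
            w.addSpectrum([300.0519], [30.0], (2, 1, 1))
        ds = read_imzml(path, bin_tol=0.003)
        assert ds.metadata["mode"] == "processed"
        assert ds.n_features == 2  # 300.05x merged, 400.0 separate
        assert ds.n_pixels == 2


class TestTicNormalize:
    def test_hand_computed_example(self):
        # TICs 2 and 4, mean 3: both rows scaled to sum 3
        ds = make_dataset([[1.0, 1.0], [2.0, 2.0]])
        out = tic_normalize(ds)
        assert np.allclose(out.intensities, [[1.5, 1.5], [1.5, 1.5]])

    def test_explicit_target(self):
        ds = make_dataset([[5.0, 0.0], [1.0, 1.0]])
        out = tic_normalize(ds, target=10.0)
        assert np.allclose(out.intensities[0], [10.0, 0.0])

    def test_idempotent(self, small_dataset):
        once = tic_normalize(small_dataset)
        twice = tic_normalize(once)
        assert np.allclose(once.intensities, twice.intensities, rtol=1e-12)

    def test_preserves_within_pixel_ratios(self, small_dataset):
        out = tic_normalize(small_dataset)
        raw, norm = small_dataset.intensities, out.intensities
        ratio_raw = raw[:, 1] / raw[:, 0]
        ratio_norm = norm[:, 1] / norm[:, 0]
        assert np.allclose(ratio_raw, ratio_norm, rtol=1e-10)

    def test_zero_tic_pixels_kept_and_flagged(self):
        ds = make_dataset([[0.0, 0.0], [2.0, 2.0]])
        out = tic_normalize(ds)
        assert np.allclose(out.intensities[0], 0.0)
        assert out.metadata["zero_tic_pixels"] == 1
        assert out.n_pixels == 2

    def test_all_zero_dataset_rejected(self):
        with pytest.raises(ValueError):
            tic_normalize(make_dataset(np.zeros((3, 2))))


class TestPickPeaks:
    @staticmethod
    def _gaussian_spectrum(rng, centers, heights, n=2000):
        mz = np.linspace(100, 200, n)
        spec = rng.normal(0, 1, n)  # sigma ~ 1 baseline noise
        for c, h in zip(centers, heights):
            spec += h * np.exp(-((mz - c) ** 2) / (2 * 0.05**2))
        return mz, spec

    def test_single_peak_detected(self):
        rng = np.random.default_rng(5)
        mz, spec = self._gaussian_spectrum(rng, [150.0], [100.0])
        peaks = pick_peaks(mz, spec, PreprocessConfig(snr_min=6))
        strong = [p for p in peaks if p[2] >= 6 and abs(p[0] - 150.0) < 0.2]
        assert len(strong) == 1

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        mz, spec = self._gaussian_spectrum(rng, [150.0], [100.0])
        lo = pick_peaks(mz, spec, PreprocessConfig(snr_min=6))
        hi = pick_peaks(mz, spec, PreprocessConfig(snr_min=1e6))
        assert len(hi) == 0 and len(lo) >= 1

    def test_matches_direct_snr_oracle(self):
        """Retained peaks are exactly the local maxima with height/noise >= 6."""
        from scipy.signal import find_peaks

        rng = np.random.default_rng(6)
        mz, spec = self._gaussian_spectrum(rng, [130.0, 170.0], [100.0, 5.0])
        noise = 1.4826 * np.median(np.abs(spec - np.median(spec)))
        idx, props = find_peaks(spec, height=0)
        expected = sorted(mz[i] for i, h in zip(idx, props["peak_heights"]) if h / noise >= 6)
        peaks = pick_peaks(mz, spec, PreprocessConfig(snr_min=6))
        assert sorted(p[0] for p in peaks) == pytest.approx(expected)
        # every retained peak satisfies the threshold; the strong one survives
        assert all(p[2] >= 6 for p in peaks)
        assert any(abs(p[0] - 130.0) < 0.2 for p in peaks)

    def test_flat_spectrum_warns_empty(self):
        with pytest.warns(UserWarning):
            assert pick_peaks(np.linspace(100, 200, 50), np.zeros(50)) == []


class TestRecalibrate:
    def test_constant_shift_recovered(self):
        true_axis = np.array([200.0, 400.0, 600.0])
        ds = make_dataset(np.ones((2, 3)), mz_axis=true_axis + 0.002)
        out = recalibrate(ds, [400.0], window=0.01)
        assert np.allclose(out.mz_axis, true_axis, atol=1e-6)

    def test_linear_distortion_recovered(self):
        true_axis = np.array([200.0, 400.0, 800.0])
        distorted = true_axis * (1 + 2e-6) + 0.001  # 2 ppm slope + 1 mDa offset
        ds = make_dataset(np.ones((2, 3)), mz_axis=distorted)
        out = recalibrate(ds, [200.0, 800.0], window=0.01)
        assert np.allclose(out.mz_axis, true_axis, atol=1e-6)
        assert np.all(np.abs(out.metadata["recalibration"]["residuals_da"]) <= 1e-6)

    def test_no_reference_matched_errors(self):
        ds = make_dataset(np.ones((2, 2)), mz_axis=[100.0, 200.0])
        with pytest.raises(ValueError, match="windows searched"):
            recalibrate(ds, [500.0], window=0.01)


class TestExtractIonImage:
    def test_window_sums_member_features_only(self):
        # 611.160 and 611.1635 lie inside 611.161 +/- 0.003; 650 does not
        ds = make_dataset([[2.0, 3.0, 7.0]], mz_axis=[611.16, 611.1635, 650.0])
        img = extract_ion_image(ds, 611.161, tol=0.003)
        assert img.values[0] == pytest.approx(5.0)

    def test_window_excludes_feature_beyond_tol(self):
        ds = make_dataset([[2.0, 3.0]], mz_axis=[611.16, 611.165])
        img = extract_ion_image(ds, 611.161, tol=0.003)  # 611.165 is 4 mDa away
        assert img.values[0] == pytest.approx(2.0)

    def test_far_query_zero_image_with_warning(self, small_dataset):
        with pytest.warns(UserWarning):
            img = extract_ion_image(small_dataset, 5000.0)
        assert np.all(img.values == 0)

    def test_zero_tol_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            extract_ion_image(small_dataset, 100.0, tol=0.0)

    def test_additive_over_disjoint_subwindows(self, small_dataset):
        # axis is 100..170 step 10; [95,125] and (125,175] split [95,175]
        full = extract_ion_image(small_dataset, 135.0, tol=40.0).values
        left = extract_ion_image(small_dataset, 110.0, tol=15.0).values
        right = extract_ion_image(small_dataset, 150.5, tol=24.5).values
        assert np.allclose(left + right, full)


class TestRenderIonImage:
    @staticmethod
    def _image(values, w, h):
        X, Y = np.meshgrid(np.arange(1, w + 1), np.arange(1, h + 1))
        coords = np.column_stack([X.ravel(), Y.ravel()])
        return IonImage(mz=100.0, tol=0.003, values=values, coords=coords)

    def test_constant_image_uniform(self):
        img = self._image(np.full(25, 3.0), 5, 5)
        grid = render_ion_image(img, smoothing=False, contrast=False)
        assert np.allclose(grid, 3.0)

    def test_smoothing_preserves_mass(self):
        values = np.zeros(441)
        values[220] = 100.0  # center pixel of a 21x21 grid
        img = self._image(values, 21, 21)
        grid = render_ion_image(img, smoothing=True, contrast=False)
        assert grid.sum() == pytest.approx(100.0, rel=0.01)

    def test_contrast_keeps_argmax(self):
        rng = np.random.default_rng(3)
        values = rng.gamma(2.0, 5.0, 100)
        img = self._image(values, 10, 10)
        g_off = render_ion_image(img, smoothing=False, contrast=False)
        g_on = render_ion_image(img, smoothing=False, contrast=True)
        # clipping is monotone: the uncontrasted argmax still attains the max
        pos = np.unravel_index(g_off.argmax(), g_off.shape)
        assert g_on[pos] == g_on.max()

    def test_png_written(self, tmp_path):
        img = self._image(np.arange(25, dtype=float), 5, 5)
        out = tmp_path / "img.png"
        render_ion_image(img, path=out)
        assert out.stat().st_size > 0

    def test_non_grid_coords_error(self):
        img = IonImage(mz=100.0, tol=0.003, values=[1.0], coords=np.array([[0, 0]]))
        with pytest.raises(ValueError):
            render_ion_image(img)
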