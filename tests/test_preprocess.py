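"""Registration, nuisance regression, smoothing, and band-pass filtering."""
import numpy as np
import pytest
from scipy import signal

from oiconnect._filters import zero_phase_sos
from oiconnect.datatypes import ChromophoreMovie, CortexMask, PhysioTraces
from oiconnect.preprocess import (
    bandpass,
    bandpass_series,
    build_design_matrix,
    filter_settling_samples,
    fit_projective,
    regress_nuisance,
    smooth_spatial,
    warp_movie,
)


def _movie(arr, fs=5.0, **kw):
    return ChromophoreMovie(data={"HbO2": np.asarray(arr)}, fs=fs, **kw)


class TestProjective:
    def test_identity_points(self):
        pts = np.array([[0, 0], [0, 10], [10, 0], [10, 10], [5, 7]], float)
        t = fit_projective(pts, pts)
        assert np.allclose(t.H / t.H[2, 2], np.eye(3), atol=1e-8)
        assert t.rms_error < 1e-8

    def test_recovers_known_homography(self, rng):
        H = np.array([[1.02, 0.03, 2.0], [-0.01, 0.98, -1.5], [1e-4, -2e-4, 1.0]])
        src = rng.uniform(0, 100, size=(12, 2))
        xy = np.column_stack([src[:, 1], src[:, 0], np.ones(12)]) @ H.T
        dst = np.column_stack([xy[:, 1] / xy[:, 2], xy[:, 0] / xy[:, 2]])[:, ::-1]
        dst = dst[:, ::-1]  # back to (row, col)
        t = fit_projective(src, dst)
        assert np.abs(t.H / t.H[2, 2] - H / H[2, 2]).max() < 1e-6

    def test_three_pairs_raise(self):
        pts = np.array([[0, 0], [0, 1], [1, 0]], float)
        with pytest.raises(ValueError, match=">= 4"):
            fit_projective(pts, pts)

    def test_collinear_raises(self):
        src = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float)
        with pytest.raises(ValueError, match="degenerate"):
            fit_projective(src, src)


class TestWarp:
    def test_identity_transform(self, rng):
        movie = _movie(rng.normal(size=(3, 16, 16)))
        t = fit_projective(
            np.array([[2, 2], [2, 13], [13, 2], [13, 13]], float),
            np.array([[2, 2], [2, 13], [13, 2], [13, 13]], float),
        )
        out = warp_movie(movie, t)
        assert np.allclose(out.data["HbO2"], movie.data["HbO2"], atol=1e-10)

    def test_translation_moves_impulse(self):
        arr = np.zeros((1, 16, 16))
        arr[0, 8, 5] = 1.0
        src = np.array([[0, 0], [0, 10], [10, 0], [10, 10]], float)
        dst = src + [0, 2]  # shift columns by +2
        t = fit_projective(src, dst)
        out = warp_movie(_movie(arr), t)
        assert out.data["HbO2"][0, 8, 7] == pytest.approx(1.0, abs=1e-6)

    def test_warp_inverse_roundtrip(self, rng):
        # smooth field: bilinear resampling error scales with curvature, so
        # the identity roundtrip only holds for band-limited images
        yy, xx = np.mgrid[:64, :64]
        arr = np.exp(-((yy - 32.0) ** 2 + (xx - 30.0) ** 2) / (2 * 26.0**2))[None]
        src = np.array([[8, 8], [8, 55], [55, 8], [55, 55]], float)
        dst = src + rng.uniform(-1.5, 1.5, size=src.shape)
        t = fit_projective(src, dst)
        out = warp_movie(warp_movie(_movie(arr), t), t.inverse())
        inner = (slice(None), slice(10, 54), slice(10, 54))
        err = np.abs(out.data["HbO2"][inner] - arr[inner])
        assert err.max() / np.ptp(arr) < 1e-3
        assert out.valid[10:54, 10:54].all()


def _physio(n, fs=5.0, seed=0):
    rng = np.random.default_rng(seed)
    return PhysioTraces(
        heart_rate=300 + rng.normal(size=n),
        resp_signal=rng.normal(size=n),
        ecg=rng.normal(size=n),
        resp_rate=60 + rng.normal(size=n),
        fs=fs,
    )


class TestRegression:
    def test_perfect_fit_gives_zero_residual(self):
        n = 200
        physio = _physio(n)
        mask = CortexMask(mask=np.ones((4, 4), bool))
        arr = np.tile(physio.ecg[:, None, None], (1, 4, 4))
        out = regress_nuisance(
            _movie(arr), physio, mask, regressors=("ecg",)
        )
        assert np.abs(out.data["HbO2"]).max() < 1e-10
        assert out.residual

    def test_intercept_only_demeans(self, rng):
        arr = rng.normal(size=(100, 3, 3)) + 5.0
        mask = CortexMask(mask=np.ones((3, 3), bool))
        out = regress_nuisance(_movie(arr), None, mask, regressors=())
        expected = arr - arr.mean(axis=0)
        assert np.allclose(out.data["HbO2"], expected, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        n = 300
        physio = _physio(n, seed=3)
        mask = CortexMask(mask=np.ones((5, 5), bool))
        arr = rng.normal(size=(n, 5, 5))
        out = regress_nuisance(_movie(arr), physio, mask)
        gs = arr.reshape(n, -1).mean(axis=1)
        X, _ = build_design_matrix(physio, n, 5.0, gs)
        resid = out.data["HbO2"].reshape(n, -1)
        assert np.abs(X.T @ resid).max() < 1e-8

    def test_collinear_column_dropped_with_warning(self):
        n = 100
        physio = _physio(n)
        physio.resp_rate = physio.heart_rate.copy()  # exact duplicate
        with pytest.warns(UserWarning, match="collinear"):
            X, names = build_design_matrix(
                physio, n, 5.0, None, ("heart_rate", "resp_rate")
            )
        assert names == ["intercept", "heart_rate"]

    def test_packed_matches_frames(self, rng):
        n = 120
        physio = _physio(n, seed=5)
        mask = CortexMask(mask=np.ones((4, 4), bool))
        arr = rng.normal(size=(n, 4, 4))
        frames = regress_nuisance(_movie(arr), physio, mask)
        packed = regress_nuisance(
            _movie(arr).to_packed(mask.mask), physio, mask
        )
        rows, cols = packed.pixels
        assert np.allclose(
            packed.data["HbO2"], frames.data["HbO2"][:, rows, cols], atol=1e-12
        )


class TestSmoothing:
    def test_constant_image_preserved_in_mask(self):
        mask = CortexMask(mask=np.zeros((20, 20), bool))
        mask.mask[4:16, 4:16] = True
        arr = np.zeros((2, 20, 20))
        arr[:, mask.mask] = 3.7
        out = smooth_spatial(_movie(arr), mask)
        assert np.allclose(out.data["HbO2"][:, mask.mask], 3.7, atol=1e-6)

    def test_impulse_response_peak_ratio(self):
        arr = np.zeros((1, 31, 31))
        arr[0, 15, 15] = 1.0
        out = smooth_spatial(_movie(arr))
        sm = out.data["HbO2"][0]
        # adjacent-pixel ratio of a sigma = 3 Gaussian: exp(1/(2*9))
        assert sm[15, 15] / sm[15, 16] == pytest.approx(np.exp(1 / 18), rel=1e-6)

    def test_unit_sum_conservation_interior(self):
        arr = np.zeros((1, 31, 31))
        arr[0, 15, 15] = 1.0
        out = smooth_spatial(_movie(arr))
        assert out.data["HbO2"].sum() == pytest.approx(1.0, abs=1e-6)

    def test_packed_matches_frame_path(self, rng):
        from oiconnect.synthetic import make_cortex_mask

        mask = make_cortex_mask(48, 48, 4)
        arr = np.zeros((3, 48, 48), np.float32)
        arr[:, mask.mask] = rng.normal(size=(3, mask.n_pixels)).astype(np.float32)
        frames = smooth_spatial(_movie(arr), mask)
        packed = smooth_spatial(_movie(arr).to_packed(mask.mask), mask)
        rows, cols = packed.pixels
        assert np.allclose(
            packed.data["HbO2"], frames.data["HbO2"][:, rows, cols], atol=1e-5
        )


class TestBandpass:
    def test_constant_suppressed(self):
        y = bandpass_series(np.full(2100, 8.0), 5.0)
        assert np.abs(y).max() < 1e-6 * 8.0

    def test_too_short_record_raises(self):
        settle = filter_settling_samples(0.009, 0.08, 5.0)
        with pytest.raises(ValueError, match=str(3 * settle)):
            bandpass_series(np.zeros(3 * settle - 1), 5.0)

    def test_high_cutoff_above_nyquist_raises(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_series(np.zeros(2100), 5.0, 0.009, 3.0)

    def test_zero_phase_midband(self):
        t = np.arange(2100) / 5.0
        x = np.sin(2 * np.pi * 0.04 * t)
        y = bandpass_series(x, 5.0)
        lags = signal.correlation_lags(len(y), len(x))
        xc = signal.correlate(y, x)
        assert lags[np.argmax(xc)] == 0

    def test_float32_path_matches_scipy(self, rng):
        sos = signal.butter(4, [0.009, 0.08], btype="band", fs=5.0, output="sos")
        x = rng.normal(size=(2100, 40))
        ref = zero_phase_sos(sos, x, padlen=846)  # float64 -> scipy path
        fast = zero_phase_sos(sos, x.astype(np.float32), padlen=846)
        scale = np.abs(ref).max()
        assert np.abs(fast - ref).max() / scale < 1e-3

    def test_movie_masked_filtering(self, rng):
        from oiconnect.synthetic import make_cortex_mask

        mask = make_cortex_mask(32, 32, 2)
        arr = rng.normal(size=(900, 32, 32)).astype(np.float32)
        out = bandpass(_movie(arr), mask=mask)
        assert np.allclose(out.data["HbO2"][:, ~mask.mask], 0.0)
        packed = bandpass(_movie(arr).to_packed(mask.mask))
        rows, cols = packed.pixels
        assert np.allclose(
            packed.data["HbO2"], out.data["HbO2"][:, rows, cols], atol=1e-5
        )
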