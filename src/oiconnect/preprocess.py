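"""Preprocessing of chromophore movies before connectivity analysis.

The pipeline order is: unmixing -> nuisance regression -> spatial smoothing ->
temporal band-pass -> seed analysis on the registered geometry.  Each stage is
individually skippable through the run configuration.

Nuisance regression is an ordinary GLM per pixel: the chromophore series is
regressed on standardized physiological traces (heart rate, respiration
signal, ECG, respiration rate) plus the mean signal of all cortex pixels, and
the residual C'(t) is carried forward.  Spatial smoothing uses an 11 x 11
Gaussian kernel (sigma = 3 px) renormalized over the in-mask support so the
cortex border does not bleed into the background.  Temporal filtering is a
fourth-order Butterworth band-pass (0.009-0.08 Hz) applied forward-backward,
i.e. zero-phase with an eighth-order magnitude response.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage, signal
from skimage import transform as sktransform

from ._filters import zero_phase_sos
from .datatypes import ChromophoreMovie, CortexMask, PhysioTraces

__all__ = [
    "ProjectiveTransform",
    "fit_projective",
    "warp_movie",
    "build_design_matrix",
    "regress_nuisance",
    "smooth_spatial",
    "bandpass",
    "bandpass_series",
    "filter_settling_samples",
]


# ---------------------------------------------------------------------------
# projective registration
# ---------------------------------------------------------------------------

@dataclass
class ProjectiveTransform:
    """3x3 homography mapping source (row, col) points to atlas space."""

    H: np.ndarray
    control_points: tuple  # (src (N, 2), dst (N, 2)) in (row, col) order
    rms_error: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) (row, col) points through the homography."""
        pts = np.asarray(points, dtype=float)
        xy = np.column_stack([pts[:, 1], pts[:, 0], np.ones(len(pts))])
        mapped = xy @ self.H.T
        mapped = mapped[:, :2] / mapped[:, 2:3]
        return np.column_stack([mapped[:, 1], mapped[:, 0]])

    def inverse(self) -> "ProjectiveTransform":
        Hinv = np.linalg.inv(self.H)
        src, dst = self.control_points
        return ProjectiveTransform(
            H=Hinv / Hinv[2, 2], control_points=(dst, src), rms_error=self.rms_error
        )


def fit_projective(src: np.ndarray, dst: np.ndarray) -> ProjectiveTransform:
    """Least-squares homography from >= 4 control-point pairs.

    Points are (row, col) pixel coordinates.  Uses the normalized direct
    linear transform; raises for fewer than four pairs or a degenerate
    (e.g. collinear) configuration.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must both be (N, 2) point arrays")
    if len(src) < 4:
        raise ValueError(f"projective registration needs >= 4 point pairs, got {len(src)}")
    # skimage works in (x, y) = (col, row)
    tf = sktransform.ProjectiveTransform.from_estimate(src[:, ::-1], dst[:, ::-1])
    if not tf or not np.all(np.isfinite(tf.params)) or abs(np.linalg.det(tf.params)) < 1e-12:
        raise ValueError("degenerate control-point configuration")
    H = tf.params / tf.params[2, 2]
    t = ProjectiveTransform(H=H, control_points=(src, dst), rms_error=0.0)
    resid = t.apply(src) - dst
    t.rms_error = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return t


def warp_movie(
    movie: ChromophoreMovie,
    t: ProjectiveTransform,
    out_shape: tuple | None = None,
) -> ChromophoreMovie:
    """Resample every frame through the homography (bilinear interpolation).

    Pixels that map outside the source image are flagged invalid in the
    returned movie's ``valid`` mask and must be excluded from the cortex mask
    downstream.
    """
    if out_shape is None:
        out_shape = movie.frame_shape
    # skimage.warp expects the output->input map; build it in (x, y)
    Hxy = t.H
    inv = np.linalg.inv(Hxy)
    sk = sktransform.ProjectiveTransform(matrix=inv)
    data = {}
    for contrast, arr in movie.data.items():
        out = np.empty((arr.shape[0],) + tuple(out_shape), dtype=arr.dtype)
        for f in range(arr.shape[0]):
            out[f] = sktransform.warp(
                arr[f].astype(float),
                sk,
                output_shape=out_shape,
                order=1,
                mode="constant",
                cval=0.0,
                preserve_range=True,
            ).astype(arr.dtype)
        data[contrast] = out
    coverage = sktransform.warp(
        np.ones(movie.frame_shape),
        sk,
        output_shape=out_shape,
        order=1,
        mode="constant",
        cval=0.0,
    )
    valid = coverage > 0.999
    if movie.valid is not None:
        prev = sktransform.warp(
            movie.valid.astype(float), sk, output_shape=out_shape, order=0,
            mode="constant", cval=0.0,
        )
        valid &= prev > 0.5
    out_movie = movie.copy_with(data)
    out_movie.valid = valid
    return out_movie


# ---------------------------------------------------------------------------
# nuisance regression
# ---------------------------------------------------------------------------

def _resample_to_frames(x: np.ndarray, fs_in: float, n_frames: int, fs_out: float) -> np.ndarray:
    """Linear interpolation of a physiological trace onto frame timestamps."""
    t_in = np.arange(len(x)) / fs_in
    t_out = np.arange(n_frames) / fs_out
    return np.interp(t_out, t_in, np.asarray(x, float))


def build_design_matrix(
    physio: PhysioTraces,
    n_frames: int,
    fs: float,
    global_signal: np.ndarray | None = None,
    regressors: tuple = ("heart_rate", "resp_signal", "ecg", "resp_rate", "global"),
) -> tuple:
    """Standardized GLM design matrix with intercept.

    Returns ``(X, names)``.  Collinear columns (rank-deficient after
    standardization) are dropped with a warning; the intercept is always
    kept.
    """
    cols = [np.ones(n_frames)]
    names = ["intercept"]
    traces = physio.as_columns() if physio is not None else {}
    for name in regressors:
        if name == "global":
            if global_signal is None:
                continue
            x = np.asarray(global_signal, float)
            if len(x) != n_frames:
                raise ValueError("global signal length does not match n_frames")
        else:
            if physio is None:
                continue
            x = _resample_to_frames(traces[name], physio.fs, n_frames, fs)
        sd = x.std()
        x = (x - x.mean()) / sd if sd > 0 else x - x.mean()
        cols.append(x)
        names.append(name)
    X = np.column_stack(cols)
    # drop collinear columns, never the intercept
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial, tol=1e-8) == len(keep) + 1:
            keep.append(j)
        else:
            warnings.warn(
                f"dropping collinear nuisance regressor '{names[j]}'", stacklevel=2
            )
    return X[:, keep], [names[j] for j in keep]


def regress_nuisance(
    movie: ChromophoreMovie,
    physio: PhysioTraces | None,
    mask: CortexMask,
    regressors: tuple = ("heart_rate", "resp_signal", "ecg", "resp_rate", "global"),
) -> ChromophoreMovie:
    """Per-pixel GLM nuisance regression; returns the residual movie C'.

    The global regressor is the mean over cortex pixels of the chromophore
    being regressed, computed before smoothing.  Residuals are exactly
    orthogonal to all design columns (ordinary least squares).  Pixels
    outside the mask are left unchanged.
    """
    inmask = mask.mask
    if not inmask.any():
        raise ValueError("cortex mask is empty")
    if movie.valid is not None:
        inmask = inmask & movie.valid
    n = movie.n_frames
    data = {}
    for contrast, arr in movie.data.items():
        Y = arr[:, inmask].astype(np.float64) if not movie.packed else arr.astype(np.float64)
        gs = Y.mean(axis=1) if "global" in regressors else None
        X, _ = build_design_matrix(physio, n, movie.fs, gs, regressors)
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
        if movie.packed:
            data[contrast] = resid.astype(arr.dtype)
        else:
            out = arr.copy()
            out[:, inmask] = resid.astype(arr.dtype)
            data[contrast] = out
    return movie.copy_with(data, residual=True)


# ---------------------------------------------------------------------------
# spatial smoothing
# ---------------------------------------------------------------------------

def _gaussian_kernel_1d(sigma: float, radius: int) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def smooth_spatial(
    movie: ChromophoreMovie,
    mask: CortexMask | None = None,
    size: int = 11,
    sigma: float = 3.0,
) -> ChromophoreMovie:
    """Per-frame Gaussian smoothing (default 11 x 11 kernel, sigma 3 px).

    With a mask, normalized convolution is used: the kernel is renormalized
    over the in-mask support so border pixels average only cortical
    neighbours.  Without a mask the unit-sum truncated kernel is applied to
    the full frame.
    """
    if size % 2 != 1:
        raise ValueError("kernel size must be odd")
    h, w = movie.frame_shape
    if size > min(h, w):
        raise ValueError("kernel larger than image")
    radius = size // 2
    k = _gaussian_kernel_1d(sigma, radius)

    if movie.packed:
        # packed layout: the pixel set itself is the mask; scatter into the
        # bounding box, convolve, renormalise, and gather back
        rows, cols = movie.pixels
        r0, r1 = max(rows.min() - radius, 0), min(rows.max() + radius + 1, h)
        c0, c1 = max(cols.min() - radius, 0), min(cols.max() + radius + 1, w)
        rr, cc = rows - r0, cols - c0
        mb = np.zeros((r1 - r0, c1 - c0), np.float32)
        mb[rr, cc] = 1.0
        den = ndimage.correlate1d(mb, k.astype(np.float32), axis=0, mode="constant")
        den = ndimage.correlate1d(den, k.astype(np.float32), axis=1, mode="constant")
        denp = den[rr, cc]
        data = {}
        for contrast, arr in movie.data.items():
            kc = k.astype(arr.dtype)
            buf = np.zeros((arr.shape[0],) + mb.shape, arr.dtype)
            buf[:, rr, cc] = arr
            buf = ndimage.correlate1d(buf, kc, axis=1, mode="constant")
            buf = ndimage.correlate1d(buf, kc, axis=2, mode="constant")
            out = buf[:, rr, cc]
            out /= denp
            data[contrast] = out
        return movie.copy_with(data)

    if mask is None:
        data = {}
        for contrast, arr in movie.data.items():
            out = ndimage.correlate1d(arr, k.astype(arr.dtype), axis=1, mode="constant")
            out = ndimage.correlate1d(out, k.astype(arr.dtype), axis=2, mode="constant")
            data[contrast] = out
        return movie.copy_with(data)

    m = mask.mask
    if movie.valid is not None:
        m = m & movie.valid
    rows, cols = np.nonzero(m)
    r0, r1 = max(rows.min() - radius, 0), min(rows.max() + radius + 1, h)
    c0, c1 = max(cols.min() - radius, 0), min(cols.max() + radius + 1, w)
    mb = m[r0:r1, c0:c1].astype(np.float32)
    den = ndimage.correlate1d(mb, k.astype(np.float32), axis=0, mode="constant")
    den = ndimage.correlate1d(den, k.astype(np.float32), axis=1, mode="constant")
    data = {}
    for contrast, arr in movie.data.items():
        kc = k.astype(arr.dtype)
        sub = arr[:, r0:r1, c0:c1] * mb
        num = ndimage.correlate1d(sub, kc, axis=1, mode="constant")
        num = ndimage.correlate1d(num, kc, axis=2, mode="constant")
        out = np.zeros_like(arr)
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = num / den
        sm[:, mb < 0.5] = 0.0
        out[:, r0:r1, c0:c1] = sm
        data[contrast] = out
    return movie.copy_with(data)


# ---------------------------------------------------------------------------
# temporal band-pass
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _design_sos(low: float, high: float, fs: float, order: int) -> tuple:
    sos = signal.butter(order, [low, high], btype="band", fs=fs, output="sos")
    return tuple(map(tuple, sos))


@lru_cache(maxsize=8)
def filter_settling_samples(
    low: float, high: float, fs: float, order: int = 4
) -> int:
    """Impulse-response decay length: samples until |h| stays below 10% of
    its peak.  Used for the minimum record length (3x decay) and the
    odd-reflection padding (3x decay)."""
    sos = np.asarray(_design_sos(low, high, fs, order))
    imp = np.zeros(int(50 * fs / low))
    imp[0] = 1.0
    h = signal.sosfilt(sos, imp)
    env = np.abs(h) / np.abs(h).max()
    return int(np.max(np.nonzero(env >= 0.1)[0])) + 1


def bandpass_series(
    x: np.ndarray,
    fs: float,
    low: float = 0.009,
    high: float = 0.08,
    order: int = 4,
    padlen: int | None = None,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along axis 0 of (T,) or (T, n) data.

    Forward-backward application squares the magnitude response (eighth-order
    roll-off for the default fourth-order design) and cancels the phase.
    Edges are handled by odd-reflection padding of three times the filter's
    impulse-response decay length; records shorter than that minimum raise.
    """
    x = np.asarray(x)
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= fs / 2:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist ({fs / 2} Hz)")
    settle = filter_settling_samples(low, high, fs, order)
    min_len = 3 * settle
    n = x.shape[0]
    if n < min_len:
        raise ValueError(
            f"record of {n} samples is too short for the {low}-{high} Hz "
            f"band at {fs} Hz; need at least {min_len}"
        )
    if padlen is None:
        padlen = min(3 * settle, n - 1)
    sos = np.asarray(_design_sos(low, high, fs, order))
    return zero_phase_sos(sos, x, padlen)


def bandpass(
    movie: ChromophoreMovie,
    low: float = 0.009,
    high: float = 0.08,
    order: int = 4,
    mask: CortexMask | None = None,
) -> ChromophoreMovie:
    """Band-pass every pixel's time course (in-mask only when a mask is given)."""
    data = {}
    for contrast, arr in movie.data.items():
        if movie.packed:
            data[contrast] = bandpass_series(arr, movie.fs, low, high, order).astype(
                arr.dtype, copy=False
            )
        elif mask is None:
            flat = arr.reshape(arr.shape[0], -1)
            out = bandpass_series(flat, movie.fs, low, high, order)
            data[contrast] = out.reshape(arr.shape).astype(arr.dtype, copy=False)
        else:
            m = mask.mask
            if movie.valid is not None:
                m = m & movie.valid
            out = np.zeros_like(arr)
            out[:, m] = bandpass_series(arr[:, m], movie.fs, low, high, order).astype(
                arr.dtype, copy=False
            )
            data[contrast] = out
    return movie.copy_with(data)
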