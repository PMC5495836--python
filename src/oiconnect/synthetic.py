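"""Synthetic multispectral optical-imaging cohorts with known ground truth.

The generator emulates a resting-state intrinsic-optical-signal experiment in
the neonatal rat: bilateral cortical networks fluctuate coherently in the
0.009-0.08 Hz band, oxy- and deoxy-hemoglobin movies are rendered through a
Beer-Lambert forward model onto a multispectral camera, nuisance physiology
(respiration, heart rate) contaminates the signal, and an "injured" group has
its interhemispheric coupling attenuated in proportion to a lesion-size
covariate.  Matching synthetic histology provides an analytic phantom for the
ventricular-volume pipeline.

Band-limited signals are realised by spectral synthesis: the in-band Fourier
coefficients of white Gaussian noise are drawn directly and inverse
transformed, which is distributionally identical to zeroing the out-of-band
coefficients of a white series and guarantees exact band control.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from scipy.ndimage import gaussian_filter1d

from .datatypes import (
    CHROMOPHORES,
    ChromophoreMovie,
    CortexMask,
    GroundTruth,
    HistologyStack,
    OpticalStack,
    OpticsConfig,
    PhysioTraces,
    SeedAtlas,
    Subject,
)

__all__ = [
    "make_cortex_mask",
    "default_seed_spec",
    "make_seed_atlas",
    "default_coupling",
    "effective_coupling",
    "network_assignment",
    "simulate_chromophores",
    "simulate_physiology",
    "forward_optics",
    "CohortDesign",
    "CohortDataset",
    "simulate_cohort",
    "simulate_histology",
    "ellipsoid_volume",
]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def make_cortex_mask(
    height: int,
    width: int,
    margin: int = 4,
    *,
    height_frac: float = 0.82,
    width_frac: float = 0.60,
) -> CortexMask:
    """Elliptical cortical mask, bilaterally symmetric about the midline.

    The ellipse stands in for the exposed cortical window, which is longer
    along the anterior-posterior axis than it is wide and does not fill the
    camera's field of view.  ``height_frac``/``width_frac`` scale the ellipse
    semi-axes relative to the margin-reduced half-image.
    """
    if height < 32 or width < 32:
        raise ValueError("mask dimensions must be at least 32 x 32")
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    ry = (height / 2.0 - margin) * height_frac
    rx = (width / 2.0 - margin) * width_frac
    rows = np.arange(height)[:, None]
    cols = np.arange(width)[None, :]
    mask = ((rows - cy) / ry) ** 2 + ((cols - cx) / rx) ** 2 <= 1.0
    return CortexMask(mask=mask, center=(cy, cx), semi_axes=(ry, rx))


#: Seed positions in normalised ellipse coordinates (u: anterior->posterior in
#: [-1, 1], v: absolute lateral offset from the midline in [0, 1]).  The
#: layout mimics the rodent atlas topology: motor anterior-lateral, cingulate
#: anterior-medial, somatosensory lateral, retrosplenial posterior-medial.
_SEED_LAYOUT = {
    "M": (-0.50, 0.45),
    "C": (-0.20, 0.16),
    "S": (0.15, 0.65),
    "R": (0.60, 0.22),
}


def default_seed_spec(mask: CortexMask) -> dict:
    """Default 8-seed bilateral layout (M, C, S, R in each hemisphere)."""
    if mask.center is None or mask.semi_axes is None:
        h, w = mask.shape
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
        rows, cols = np.nonzero(mask.mask)
        semi = ((rows.max() - rows.min()) / 2.0, (cols.max() - cols.min()) / 2.0)
    else:
        center, semi = mask.center, mask.semi_axes
    cy, cx = center
    ry, rx = semi
    spec = {}
    for region, (u, v) in _SEED_LAYOUT.items():
        row = int(round(cy + u * ry))
        for hemi, sign in (("L", -1.0), ("R", 1.0)):
            col = int(round(cx + sign * v * rx))
            spec[f"{region}_{hemi}"] = (row, col)
    return spec


def make_seed_atlas(
    mask: CortexMask,
    seed_spec: dict | None = None,
    *,
    n_pixels: int = 17,
    max_radius: float = 4.0,
) -> SeedAtlas:
    """Build a seed atlas by growing each seed to its nearest in-mask pixels.

    Each seed takes the ``n_pixels`` in-mask pixels closest to its centre
    (Euclidean distance, ties broken by angle then row-major order), mirroring
    a ~17-pixel disk.  A seed whose members would extend past ``max_radius``
    pixels from the centre (e.g. a centre on the mask border) is rejected.
    """
    if seed_spec is None:
        seed_spec = default_seed_spec(mask)
    rows, cols = np.nonzero(mask.mask)
    coords = np.column_stack([rows, cols])
    seeds, centers = {}, {}
    for name, (r0, c0) in seed_spec.items():
        if not (0 <= r0 < mask.shape[0] and 0 <= c0 < mask.shape[1]) or not mask.mask[r0, c0]:
            raise ValueError(f"seed {name}: centre ({r0}, {c0}) is outside the cortex mask")
        d2 = (coords[:, 0] - r0) ** 2 + (coords[:, 1] - c0) ** 2
        ang = np.arctan2(coords[:, 0] - r0, coords[:, 1] - c0)
        order = np.lexsort((coords[:, 1], coords[:, 0], ang, d2))
        chosen = coords[order[:n_pixels]]
        if len(chosen) < n_pixels or d2[order[n_pixels - 1]] > max_radius**2:
            raise ValueError(
                f"seed {name}: fewer than {n_pixels} in-mask pixels within "
                f"{max_radius} px of the centre"
            )
        seeds[name] = chosen
        centers[name] = (r0, c0)
    return SeedAtlas(seeds=seeds, centers=centers, mask=mask)


def network_assignment(atlas: SeedAtlas) -> np.ndarray:
    """Assign every in-mask pixel to the network of its nearest seed centre.

    Returns an (H, W) int array of seed indices, -1 outside the mask.
    """
    out = np.full(atlas.mask.shape, -1, dtype=np.int32)
    rows, cols = np.nonzero(atlas.mask.mask)
    centers = np.array([atlas.centers[name] for name in atlas.seed_names], float)
    d2 = (rows[:, None] - centers[None, :, 0]) ** 2 + (
        cols[:, None] - centers[None, :, 1]
    ) ** 2
    out[rows, cols] = np.argmin(d2, axis=1)
    return out


# ---------------------------------------------------------------------------
# coupling structure
# ---------------------------------------------------------------------------

def default_coupling(
    seed_names,
    *,
    homotopic: float = 0.7,
    intra: float = 0.3,
    inter: float = 0.15,
) -> np.ndarray:
    """Symmetric PSD coupling matrix for a bilateral seed set.

    Homotopic pairs (same region, opposite hemisphere) couple at
    ``homotopic``; same-hemisphere pairs at ``intra``; remaining
    interhemispheric pairs at ``inter``.
    """
    s = len(seed_names)
    c = np.full((s, s), np.nan)
    for i, a in enumerate(seed_names):
        for j, b in enumerate(seed_names):
            if i == j:
                c[i, j] = 1.0
            elif a[:-2] == b[:-2]:
                c[i, j] = homotopic
            elif a[-1] == b[-1]:
                c[i, j] = intra
            else:
                c[i, j] = inter
    return c


def _hemisphere(name: str) -> str | None:
    return name[-1] if name.endswith(("_L", "_R")) else None


def effective_coupling(truth: GroundTruth) -> np.ndarray:
    """Apply the injury model: interhemispheric couplings are multiplied by
    ``(1 - kappa * lesion_fraction)``, clipped to [0, 1]."""
    c = truth.coupling.copy()
    if truth.group == "injured":
        factor = float(np.clip(1.0 - truth.kappa * truth.lesion_fraction, 0.0, 1.0))
        names = list(truth.seed_names)
        for i in range(len(names)):
            for j in range(len(names)):
                hi, hj = _hemisphere(names[i]), _hemisphere(names[j])
                if i != j and hi is not None and hj is not None and hi != hj:
                    c[i, j] *= factor
    w = np.linalg.eigvalsh(c)
    if w.min() < -1e-10:
        off = np.abs(c - np.diag(np.diag(c)))
        i, j = np.unravel_index(np.argmax(off), c.shape)
        raise ValueError(
            "effective coupling matrix is not positive semidefinite "
            f"(min eigenvalue {w.min():.3g}); largest off-diagonal coupling is "
            f"({truth.seed_names[i]}, {truth.seed_names[j]}) = {c[i, j]:.3f}"
        )
    return c


# ---------------------------------------------------------------------------
# band-limited signal synthesis
# ---------------------------------------------------------------------------

def _band_bins(n_frames: int, fs: float, band: tuple) -> tuple:
    low, high = band
    kmin = max(1, int(np.ceil(low * n_frames / fs)))
    kmax = int(np.floor(high * n_frames / fs))
    if kmax < kmin:
        raise ValueError(
            f"record of {n_frames} frames at {fs} Hz has no Fourier bins in "
            f"the {band} Hz band"
        )
    return kmin, kmax


def _inband_noise(
    rng: np.random.Generator,
    n_series: int,
    n_frames: int,
    fs: float,
    band: tuple,
    scale: float = 1.0,
) -> np.ndarray:
    """(n_frames, n_series) Gaussian series of SD ``scale`` with all power in
    ``band``, synthesised from in-band Fourier coefficients (time-major
    layout so downstream frame operations stay contiguous)."""
    kmin, kmax = _band_bins(n_frames, fs, band)
    m = kmax - kmin + 1
    spec = np.zeros((n_frames // 2 + 1, n_series), dtype=np.complex64)
    coef = rng.standard_normal((m, n_series, 2), dtype=np.float32)
    # unit-coefficient synthesis has stationary variance 4 m / n^2
    amp = np.float32(scale * n_frames / (2.0 * np.sqrt(m)))
    spec[kmin : kmax + 1] = amp * coef[..., 0] + 1j * (amp * coef[..., 1])
    return scipy.fft.irfft(spec, n=n_frames, axis=0)


# ---------------------------------------------------------------------------
# chromophore simulation
# ---------------------------------------------------------------------------

def _jitter_coupling(
    sigma: np.ndarray, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """Add symmetric off-diagonal noise, then project back to a unit-diagonal
    PSD correlation matrix (eigenvalue clipping)."""
    s = sigma.shape[0]
    noise = rng.normal(0.0, jitter, size=(s, s))
    noise = (noise + noise.T) / 2.0
    np.fill_diagonal(noise, 0.0)
    c = sigma + noise
    w, v = np.linalg.eigh(c)
    c = (v * np.clip(w, 1e-6, None)) @ v.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def simulate_chromophores(
    atlas: SeedAtlas,
    truth: GroundTruth,
    n_frames: int,
    fs: float = 5.0,
    *,
    band: tuple = (0.009, 0.08),
    amplitude_um: float = 1.0,
    pixel_noise: float = 0.5,
    hbr_ratio: float = -0.5,
    network_radius_px: float | None = None,
    coupling_jitter: float = 0.12,
    center_jitter_px: float | None = None,
    dtype=np.float32,
    rng: np.random.Generator | None = None,
    packed: bool = False,
) -> ChromophoreMovie:
    """Simulate HbO2/HbR concentration movies with known network coupling.

    Each seed anchors a cortical network patch with a Gaussian spatial
    profile of scale ``network_radius_px``; every in-mask pixel carries the
    profile-weighted sum of the band-limited latent network signals plus
    independent in-band pixel noise of relative amplitude ``pixel_noise``.
    Cortex between patches therefore expresses mostly noise, as in real
    resting-state maps.  HbR is ``hbr_ratio`` times the HbO2 network signal
    plus its own noise, so both contrasts express the same networks with
    anti-correlated polarity.

    Two per-subject variability terms emulate biological and registration
    scatter: the subject's latent correlation matrix is the
    (injury-attenuated) coupling matrix plus symmetric jitter of SD
    ``coupling_jitter`` (PSD-projected), and the functional patch centres
    are displaced from the atlas seed centres by isotropic Gaussian jitter
    of SD ``center_jitter_px``.  Seed-region mean traces have pairwise
    correlations converging, in expectation over subjects, to the coupling
    matrix up to a small noise-dilution factor
    1/(1 + pixel_noise^2 / seed_size).

    With ``packed=True`` the movie is returned in the cortex-pixels-only
    layout (see :class:`~oiconnect.datatypes.ChromophoreMovie`).
    """
    if rng is None:
        rng = np.random.default_rng(truth.rng_seed)
    # spatial scales are physical: defaults are fixed in field-of-view units
    # and converted to pixels for the actual grid (4.5 px and 2 px on the
    # reference 128 x 128 grid, i.e. ~0.5 mm and ~0.2 mm on the emulated
    # (14.7 mm)^2 field of view)
    grid_scale = float(np.sqrt(np.prod(atlas.mask.shape))) / 128.0
    if network_radius_px is None:
        network_radius_px = 4.5 * grid_scale
    if center_jitter_px is None:
        center_jitter_px = 2.0 * grid_scale
    sigma = effective_coupling(truth)
    names = list(truth.seed_names)
    if names != atlas.seed_names:
        raise ValueError("truth.seed_names must match the atlas seed set")
    s = len(names)
    if coupling_jitter > 0:
        sigma = _jitter_coupling(sigma, coupling_jitter, rng)

    # correlated latent network signals: unit-variance in-band noise mixed by
    # a PSD factor of the (subject-level) coupling matrix
    w, v = np.linalg.eigh(sigma)
    factor = (v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))).astype(np.float32)
    latents = _inband_noise(rng, s, n_frames, fs, band) @ factor.T  # (T, S)

    rows, cols = np.nonzero(atlas.mask.mask)
    centers = np.array([atlas.centers[n] for n in names], dtype=float)
    if center_jitter_px > 0:
        centers = centers + rng.normal(0.0, center_jitter_px, size=centers.shape)
    d2 = (rows[:, None] - centers[None, :, 0]) ** 2 + (
        cols[:, None] - centers[None, :, 1]
    ) ** 2
    weights = np.exp(-d2 / (2.0 * network_radius_px**2)).astype(np.float32)  # (n_pix, S)

    shape = (n_frames,) + atlas.mask.shape
    data = {}
    gains = {"HbO2": 1.0, "HbR": hbr_ratio}
    for contrast in CHROMOPHORES:
        g = gains[contrast]
        scaled = (np.float32(g * amplitude_um) * latents).astype(np.float32)
        pix = scaled @ weights.T  # (T, n_pix)
        pix += _inband_noise(
            rng, len(rows), n_frames, fs, band,
            scale=abs(g) * pixel_noise * amplitude_um,
        )
        if packed:
            data[contrast] = pix.astype(dtype, copy=False)
        else:
            movie = np.zeros(shape, dtype=dtype)
            movie[:, rows, cols] = pix.astype(dtype, copy=False)
            data[contrast] = movie
    if packed:
        return ChromophoreMovie(
            data=data, fs=fs, pixels=(rows, cols), image_shape=atlas.mask.shape
        )
    return ChromophoreMovie(data=data, fs=fs)


# ---------------------------------------------------------------------------
# physiology
# ---------------------------------------------------------------------------

def _slow_drift(rng, n, fs, sigma_s=20.0):
    x = rng.standard_normal(n)
    x = gaussian_filter1d(x, sigma=sigma_s * fs, mode="reflect")
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_physiology(
    n_frames: int,
    fs: float,
    rng_seed: int,
    *,
    resp_hz: float = 1.0,
    heart_rate_bpm: float = 330.0,
) -> PhysioTraces:
    """Quasi-periodic respiration and slowly drifting cardiac traces.

    Defaults approximate a urethane-anaesthetised rat pup (respiration ~1 Hz,
    heart rate ~330 bpm).  The cardiac cycle itself is far above the frame
    Nyquist rate, so the ECG trace is represented at its aliased frequency.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(rng_seed)
    t = np.arange(n_frames) / fs

    heart_rate = heart_rate_bpm + 15.0 * _slow_drift(rng, n_frames, fs)
    resp_rate = resp_hz * 60.0 + 6.0 * _slow_drift(rng, n_frames, fs)

    phase = 2 * np.pi * np.cumsum(resp_rate / 60.0) / fs
    resp_signal = (
        np.sin(phase)
        + 0.3 * np.sin(2 * phase)
        + 0.05 * rng.standard_normal(n_frames)
    )

    f_ecg = (heart_rate_bpm / 60.0) % (fs / 2.0)
    ecg = np.sin(2 * np.pi * f_ecg * t) + 0.2 * rng.standard_normal(n_frames)
    return PhysioTraces(
        heart_rate=heart_rate,
        resp_signal=resp_signal,
        ecg=ecg,
        resp_rate=resp_rate,
        fs=fs,
    )


# ---------------------------------------------------------------------------
# forward optics
# ---------------------------------------------------------------------------

def forward_optics(
    chromo: ChromophoreMovie,
    cfg: OpticsConfig,
    rng_seed: int = 0,
) -> OpticalStack:
    """Render chromophore movies to camera intensities.

    dOD(lambda, t) = sum_i eps_i(lambda) C_i(t) D(lambda) (base-10, per uM),
    then I = I0 * 10^(-dOD) plus additive Gaussian noise.  Uses the same
    corrected extinction system as the inverse model, so a noiseless forward
    pass followed by unmixing is the identity.
    """
    from .unmixing import build_extinction_system

    if chromo.packed:
        raise ValueError("forward optics renders images; unpack the movie first")
    system = build_extinction_system(cfg)
    rng = np.random.default_rng(rng_seed)
    hbo = chromo.data["HbO2"]
    hbr = chromo.data["HbR"]
    dtype = hbo.dtype
    T = chromo.n_frames
    H, W = chromo.frame_shape
    L = len(cfg.wavelengths_nm)
    out = np.empty((T, L, H, W), dtype=dtype)
    n_clamped = 0
    for li in range(L):
        dod = float(system.E[li, 0]) * hbo + float(system.E[li, 1]) * hbr
        # python-float scalars keep the array precision (float32 movies stay
        # float32; the float64 path remains exact for round-trip checks)
        intens = (cfg.i0 * np.power(10.0, -dod)).astype(dtype, copy=False)
        if cfg.noise_sd > 0:
            intens = intens + rng.normal(0.0, cfg.noise_sd, size=intens.shape).astype(dtype)
            bad = intens <= 0
            if bad.any():
                if cfg.nonpositive == "resample":
                    for _ in range(100):
                        intens[bad] = (
                            cfg.i0 * np.power(10.0, -dod[bad])
                            + rng.normal(0.0, cfg.noise_sd, size=int(bad.sum()))
                        ).astype(dtype)
                        bad = intens <= 0
                        if not bad.any():
                            break
                if bad.any():
                    n_clamped += int(bad.sum())
                    intens[bad] = cfg.clamp_eps
        out[:, li] = intens
    if n_clamped:
        warnings.warn(
            f"forward_optics: clamped {n_clamped} nonpositive intensities to "
            f"{cfg.clamp_eps}",
            stacklevel=2,
        )
    i0 = np.full(L, float(cfg.i0))
    return OpticalStack(
        intensities=out, i0=i0, wavelengths_nm=tuple(cfg.wavelengths_nm), fs=chromo.fs
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Study-design parameters of a simulated two-group cohort.

    Defaults mirror the emulated experiment: 5 Hz full-frame sampling, 7 min
    records (2100 frames), a 128 x 128 sensor grid covering the (14.7 mm)^2
    field of view, homotopic coupling 0.7 in controls, and full attenuation
    (kappa = 1) scaled by a lesion fraction drawn from [0.6, 1.0] in injured
    animals.
    """

    shape: tuple = (128, 128)
    margin: int = 4
    n_frames: int = 2100
    fs: float = 5.0
    band: tuple = (0.009, 0.08)
    amplitude_um: float = 1.0
    pixel_noise: float = 0.5
    hbr_ratio: float = -0.5
    network_radius_px: float | None = None  # default: 4.5 px at 128 x 128
    coupling_jitter: float = 0.12
    center_jitter_px: float | None = None  # default: 2 px at 128 x 128
    coupling_homotopic: float = 0.7
    coupling_intra: float = 0.3
    coupling_inter: float = 0.15
    kappa: float = 1.0
    lesion_range: tuple = (0.6, 1.0)
    seed_pixels: int = 17
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    include_optics: bool = True
    include_physio: bool = True
    physio_leak_resp: float = 0.1
    global_drift: float = 0.3
    dtype: str = "float32"
    packed: bool = False  # cortex-pixels-only movies (implies no optics)


@dataclass
class CohortDataset:
    """Simulated cohort with lazy, per-subject materialisation.

    Holds the ground truths and per-subject RNG seeds; full movies are
    (re)generated deterministically on demand via :meth:`subject`, keeping
    memory use per-subject rather than per-cohort.
    """

    design: CohortDesign
    atlas: SeedAtlas
    truths: list
    subject_ids: list
    subject_seeds: list

    def __len__(self) -> int:
        return len(self.truths)

    @property
    def labels(self) -> list:
        return [t.group for t in self.truths]

    def subject(self, i: int) -> Subject:
        d = self.design
        truth = self.truths[i]
        rng = np.random.default_rng(self.subject_seeds[i])
        chromo = simulate_chromophores(
            self.atlas,
            truth,
            d.n_frames,
            d.fs,
            band=d.band,
            amplitude_um=d.amplitude_um,
            pixel_noise=d.pixel_noise,
            hbr_ratio=d.hbr_ratio,
            network_radius_px=d.network_radius_px,
            coupling_jitter=d.coupling_jitter,
            center_jitter_px=d.center_jitter_px,
            dtype=np.dtype(d.dtype).type,
            rng=rng,
            packed=d.packed,
        )
        physio = None
        if d.include_physio:
            physio = simulate_physiology(
                d.n_frames, d.fs, int(rng.integers(0, 2**31 - 1))
            )
            drift = d.global_drift * d.amplitude_um * _slow_drift(
                rng, d.n_frames, d.fs, sigma_s=40.0
            )
            leak = d.physio_leak_resp * d.amplitude_um * physio.resp_signal
            contam = (drift + leak).astype(chromo.data["HbO2"].dtype)
            for contrast, g in (("HbO2", 1.0), ("HbR", abs(d.hbr_ratio))):
                if d.packed:
                    chromo.data[contrast] += g * contam[:, None]
                else:
                    inmask = self.atlas.mask.mask
                    chromo.data[contrast][:, inmask] += g * contam[:, None]
        stack = None
        if d.include_optics and not d.packed:
            stack = forward_optics(
                chromo, d.optics, rng_seed=int(rng.integers(0, 2**31 - 1))
            )
        return Subject(
            subject_id=self.subject_ids[i],
            truth=truth,
            chromo=chromo,
            stack=stack,
            physio=physio,
        )

    def iter_subjects(self):
        for i in range(len(self)):
            yield self.subject(i)


def simulate_cohort(
    n_control: int = 8,
    n_injured: int = 5,
    design: CohortDesign | None = None,
    rng_seed: int = 0,
) -> CohortDataset:
    """Simulate a two-group cohort (default 8 control + 5 injured).

    Per-subject RNG streams are derived by hashing ``(rng_seed, subject
    index)`` through :class:`numpy.random.SeedSequence`, so cohorts are
    bit-reproducible and subjects statistically independent.
    """
    if n_control + n_injured < 4:
        raise ValueError("cohort must contain at least 4 subjects")
    if design is None:
        design = CohortDesign()
    h, w = design.shape
    mask = make_cortex_mask(h, w, design.margin)
    atlas = make_seed_atlas(mask, n_pixels=design.seed_pixels)
    coupling = default_coupling(
        atlas.seed_names,
        homotopic=design.coupling_homotopic,
        intra=design.coupling_intra,
        inter=design.coupling_inter,
    )
    truths, ids, seeds = [], [], []
    groups = ["control"] * n_control + ["injured"] * n_injured
    for i, group in enumerate(groups):
        ss = np.random.SeedSequence(entropy=rng_seed, spawn_key=(i,))
        sub_seed = int(ss.generate_state(1)[0])
        sub_rng = np.random.default_rng(sub_seed)
        lesion = (
            float(sub_rng.uniform(*design.lesion_range))
            if group == "injured"
            else 0.0
        )
        truths.append(
            GroundTruth(
                coupling=coupling,
                seed_names=atlas.seed_names,
                group=group,
                lesion_fraction=lesion,
                kappa=design.kappa,
                rng_seed=sub_seed,
            )
        )
        ids.append(f"{'ctl' if group == 'control' else 'inj'}{i:02d}")
        seeds.append(sub_seed)
    return CohortDataset(
        design=design, atlas=atlas, truths=truths, subject_ids=ids, subject_seeds=seeds
    )


# ---------------------------------------------------------------------------
# histology phantom
# ---------------------------------------------------------------------------

def ellipsoid_volume(axes_mm) -> float:
    """Volume of an ellipsoid with the given semi-axes, mm^3."""
    a, b, c = axes_mm
    return 4.0 / 3.0 * np.pi * a * b * c


def simulate_histology(
    lesion_fraction: float,
    n_slices: int = 20,
    px_per_mm: float = 228.0,
    slice_thickness_um: float = 50.0,
    rng_seed: int = 0,
    *,
    slice_spacing_um: float = 300.0,
    brain_axes_mm: tuple = (4.5, 3.5, 3.0),
    noise_sd: float = 4.0,
) -> HistologyStack:
    """Serial coronal sections of an ellipsoidal brain phantom.

    The brain is an ellipsoid with semi-axes ``brain_axes_mm`` (lateral,
    dorsoventral, anteroposterior); a concentric brighter ellipsoid models
    the dilated ventricle, scaled so its analytic volume is exactly
    ``lesion_fraction`` times the brain volume.  Slices are taken
    perpendicular to the AP axis at ``slice_spacing_um`` intervals.
    """
    if not 0.0 <= lesion_fraction <= 1.0:
        raise ValueError("lesion_fraction must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    a, b, c = brain_axes_mm
    s = lesion_fraction ** (1.0 / 3.0)
    va, vb, vc = s * a, s * b, s * c
    spacing_mm = slice_spacing_um / 1000.0
    pad = 8
    W = int(np.ceil(2 * a * px_per_mm)) + 2 * pad
    H = int(np.ceil(2 * b * px_per_mm)) + 2 * pad
    x_mm = (np.arange(W) - (W - 1) / 2.0) / px_per_mm
    y_mm = (np.arange(H) - (H - 1) / 2.0) / px_per_mm
    xx = x_mm[None, :]
    yy = y_mm[:, None]
    slices = np.empty((n_slices, H, W), dtype=np.uint8)
    for j in range(n_slices):
        z = (j - (n_slices - 1) / 2.0) * spacing_mm
        img = np.full((H, W), 10.0)
        if abs(z) < c:
            f = np.sqrt(1.0 - (z / c) ** 2)
            brain = (xx / (a * f)) ** 2 + (yy / (b * f)) ** 2 <= 1.0
            img[brain] = 110.0
        if vc > 0 and abs(z) < vc:
            fv = np.sqrt(1.0 - (z / vc) ** 2)
            vent = (xx / (va * fv)) ** 2 + (yy / (vb * fv)) ** 2 <= 1.0
            img[vent] = 230.0
        img += rng.normal(0.0, noise_sd, size=img.shape)
        slices[j] = np.clip(img, 0, 255).astype(np.uint8)
    return HistologyStack(
        slices=slices,
        px_per_mm=px_per_mm,
        slice_thickness_um=slice_thickness_um,
        slice_spacing_um=slice_spacing_um,
    )
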