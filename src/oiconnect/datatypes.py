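"""Core data containers for the intrinsic-optical-imaging connectivity pipeline.

The containers are deliberately thin :class:`dataclasses.dataclass` wrappers
around numpy arrays plus the metadata needed to interpret them (sampling rate,
wavelengths, pixel pitch).  Validation happens at construction time so that
downstream stages can assume well-formed inputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Canonical chromophore order used throughout the package.
CHROMOPHORES = ("HbO2", "HbR")

#: Canonical cortical region order (motor, cingulate, somatosensory,
#: retrosplenial) used for seed naming and feature ordering.
REGION_ORDER = ("M", "C", "S", "R")


# ---------------------------------------------------------------------------
# optics
# ---------------------------------------------------------------------------

@dataclass
class OpticsConfig:
    """Forward-model configuration for multispectral reflectance imaging.

    Parameters
    ----------
    wavelengths_nm
        Illumination wavelengths in nm.
    extinction
        Mapping chromophore name -> per-wavelength molar extinction
        coefficients epsilon(lambda) in cm^-1 M^-1 (base-10 convention).
    pathlength_cm
        Differential pathlength factor D(lambda) in cm, one per wavelength.
    baseline_um
        Baseline chromophore concentrations in uM.  The differential
        Beer-Lambert model only uses concentration *changes*; the baseline is
        recorded for documentation and possible absolute extensions.
    i0
        Reference (incident) intensity in camera counts.
    noise_sd
        Additive Gaussian noise on counts.
    correction_weights
        Per-wavelength scalar factors folding the sensor spectral response
        and LED emission profile into effective coefficients.
    nonpositive
        Policy when noise drives an intensity <= 0: "resample" redraws the
        offending noise values, "clamp" clips at ``clamp_eps``.
    """

    wavelengths_nm: tuple = (525.0, 590.0, 630.0)
    extinction: Mapping[str, tuple] = field(
        default_factory=lambda: {
            # representative base-10 molar extinction values, cm^-1 M^-1;
            # editable -- treat as configuration, not physical constants
            "HbO2": (47500.0, 20000.0, 610.0),
            "HbR": (45000.0, 37000.0, 5150.0),
        }
    )
    pathlength_cm: tuple = (0.15, 0.25, 0.45)
    baseline_um: Mapping[str, float] = field(
        default_factory=lambda: {"HbO2": 60.0, "HbR": 40.0}
    )
    i0: float = 3000.0
    noise_sd: float = 2.0
    correction_weights: tuple = (1.0, 1.0, 1.0)
    nonpositive: str = "resample"
    clamp_eps: float = 1e-3

    def __post_init__(self) -> None:
        n = len(self.wavelengths_nm)
        for name, eps in self.extinction.items():
            if len(eps) != n:
                raise ValueError(
                    f"extinction table for {name} has {len(eps)} entries, "
                    f"expected one per wavelength ({n})"
                )
        if len(self.pathlength_cm) != n or any(d <= 0 for d in self.pathlength_cm):
            raise ValueError("pathlength_cm must be positive, one per wavelength")
        if len(self.correction_weights) != n:
            raise ValueError("one correction weight per wavelength required")
        if self.i0 <= 0:
            raise ValueError("i0 must be positive")
        if self.nonpositive not in ("resample", "clamp"):
            raise ValueError("nonpositive must be 'resample' or 'clamp'")


@dataclass
class OpticalStack:
    """Raw multispectral reflectance movie I(t, lambda, y, x)."""

    intensities: np.ndarray  # (T, L, H, W)
    i0: np.ndarray | float  # scalar, (L,), or (L, H, W)
    wavelengths_nm: tuple
    fs: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 4:
            raise ValueError("intensities must have shape (T, L, H, W)")
        if self.intensities.shape[1] != len(self.wavelengths_nm):
            raise ValueError("wavelength axis does not match wavelengths_nm")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.intensities.shape[2:]


@dataclass
class ODMovie:
    """Differential optical density dOD(t, lambda, y, x) = log10(I0 / I)."""

    od: np.ndarray  # (T, L, H, W)
    wavelengths_nm: tuple
    fs: float

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od)
        if self.od.ndim != 4:
            raise ValueError("od must have shape (T, L, H, W)")
        if not np.all(np.isfinite(self.od)):
            raise ValueError("optical density contains non-finite values")


@dataclass
class ChromophoreMovie:
    """Per-pixel chromophore concentration-change movies, in uM.

    ``data`` maps contrast name ("HbO2"/"HbR") to either a (T, H, W) frame
    array or, in the packed layout, a (T, n_pixels) array restricted to the
    cortex pixels listed in ``pixels`` (a ``(rows, cols)`` pair) on an image
    of ``image_shape``.  Packing is the first analysis step anyway -- only
    cortical pixels enter connectivity statistics -- and cuts the memory
    traffic of the per-pixel stages several-fold.

    ``residual`` marks movies that passed through nuisance regression (the
    C' series used for connectivity analysis).  ``valid`` flags pixels with
    trustworthy data (e.g. inside the warped source image).
    """

    data: dict
    fs: float
    residual: bool = False
    valid: np.ndarray | None = None
    pixels: tuple | None = None  # (rows, cols) of packed columns
    image_shape: tuple | None = None

    def __post_init__(self) -> None:
        shapes = {k: np.asarray(v).shape for k, v in self.data.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"inconsistent contrast shapes: {shapes}")
        ndim = 2 if self.pixels is not None else 3
        for k in self.data:
            self.data[k] = np.asarray(self.data[k])
            if self.data[k].ndim != ndim:
                raise ValueError(
                    "each contrast must be (T, H, W), or (T, n_pixels) with "
                    "`pixels` set"
                )
        if self.pixels is not None:
            if self.image_shape is None:
                raise ValueError("packed movies need image_shape")
            n = len(self.pixels[0])
            if any(v.shape[1] != n for v in self.data.values()):
                raise ValueError("packed data width must match len(pixels)")

    @property
    def packed(self) -> bool:
        return self.pixels is not None

    @property
    def n_frames(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def frame_shape(self) -> tuple:
        if self.packed:
            return tuple(self.image_shape)
        return next(iter(self.data.values())).shape[1:]

    @property
    def contrasts(self) -> tuple:
        return tuple(self.data.keys())

    def copy_with(self, data: dict, residual: bool | None = None) -> "ChromophoreMovie":
        return ChromophoreMovie(
            data=data,
            fs=self.fs,
            residual=self.residual if residual is None else residual,
            valid=self.valid,
            pixels=self.pixels,
            image_shape=self.image_shape,
        )

    def pixel_index_image(self) -> np.ndarray:
        """(H, W) map from pixel to packed column index (-1 elsewhere)."""
        if not self.packed:
            raise ValueError("movie is not packed")
        idx = np.full(self.frame_shape, -1, dtype=np.int64)
        idx[self.pixels] = np.arange(len(self.pixels[0]))
        return idx

    def to_packed(self, mask: np.ndarray) -> "ChromophoreMovie":
        """Restrict to the True pixels of ``mask`` (row-major order)."""
        if self.packed:
            raise ValueError("movie is already packed")
        m = np.asarray(mask, dtype=bool)
        if self.valid is not None:
            m = m & self.valid
        rows, cols = np.nonzero(m)
        data = {k: v[:, rows, cols] for k, v in self.data.items()}
        return ChromophoreMovie(
            data=data,
            fs=self.fs,
            residual=self.residual,
            valid=None,
            pixels=(rows, cols),
            image_shape=self.frame_shape,
        )

    def to_frames(self, fill: float = 0.0) -> "ChromophoreMovie":
        """Scatter a packed movie back onto full frames."""
        if not self.packed:
            return self
        data = {}
        for k, v in self.data.items():
            out = np.full((self.n_frames,) + self.frame_shape, fill, dtype=v.dtype)
            out[:, self.pixels[0], self.pixels[1]] = v
            data[k] = out
        valid = np.zeros(self.frame_shape, bool)
        valid[self.pixels] = True
        return ChromophoreMovie(
            data=data, fs=self.fs, residual=self.residual, valid=valid
        )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class CortexMask:
    """Boolean cortical mask with the elliptical geometry that produced it."""

    mask: np.ndarray  # (H, W) bool
    center: tuple | None = None  # (row, col) of the ellipse centre
    semi_axes: tuple | None = None  # (ry, rx) in pixels

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class SeedAtlas:
    """Named seed regions on a cortical mask.

    ``seeds`` maps seed name to an (k, 2) integer array of (row, col) member
    pixels; ``centers`` holds the nominal seed centres.  Homotopic pairs are
    seeds whose names differ only in the hemisphere suffix (``_L``/``_R``).
    """

    seeds: dict
    centers: dict
    mask: CortexMask

    def __post_init__(self) -> None:
        seen: set = set()
        for name, px in self.seeds.items():
            px = np.asarray(px, dtype=int)
            if px.ndim != 2 or px.shape[1] != 2:
                raise ValueError(f"seed {name}: pixels must be (k, 2)")
            self.seeds[name] = px
            tuples = set(map(tuple, px))
            if tuples & seen:
                raise ValueError(f"seed {name} overlaps another seed's pixel set")
            seen |= tuples

    @property
    def seed_names(self) -> list:
        return list(self.seeds.keys())

    @property
    def n_seeds(self) -> int:
        return len(self.seeds)

    @property
    def homotopic_pairs(self) -> list:
        """(left, right) name pairs present in both hemispheres."""
        pairs = []
        for name in self.seeds:
            if name.endswith("_L"):
                partner = name[:-2] + "_R"
                if partner in self.seeds:
                    pairs.append((name, partner))
        return pairs


# ---------------------------------------------------------------------------
# simulation ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Generative parameters of one simulated subject."""

    coupling: np.ndarray  # (S, S) target seed-pair correlations
    seed_names: Sequence[str]
    group: str  # "control" | "injured"
    lesion_fraction: float = 0.0
    kappa: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.coupling, dtype=float)
        if c.shape != (len(self.seed_names),) * 2:
            raise ValueError("coupling shape does not match seed_names")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("coupling matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-12):
            raise ValueError("coupling matrix must have unit diagonal")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("coupling matrix must be positive semidefinite")
        if self.group not in ("control", "injured"):
            raise ValueError("group must be 'control' or 'injured'")
        if not 0.0 <= self.lesion_fraction <= 1.0:
            raise ValueError("lesion_fraction must be in [0, 1]")
        if self.group == "control" and self.lesion_fraction != 0.0:
            raise ValueError("control subjects must have lesion_fraction 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        self.coupling = c


@dataclass
class PhysioTraces:
    """Physiological recordings resampled to the imaging frame clock."""

    heart_rate: np.ndarray  # bpm
    resp_signal: np.ndarray  # a.u.
    ecg: np.ndarray  # a.u.
    resp_rate: np.ndarray  # breaths/min
    fs: float

    def __post_init__(self) -> None:
        lengths = {
            len(self.heart_rate),
            len(self.resp_signal),
            len(self.ecg),
            len(self.resp_rate),
        }
        if len(lengths) != 1:
            raise ValueError("all physiological traces must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.heart_rate)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def as_columns(self) -> dict:
        return {
            "heart_rate": np.asarray(self.heart_rate, float),
            "resp_signal": np.asarray(self.resp_signal, float),
            "ecg": np.asarray(self.ecg, float),
            "resp_rate": np.asarray(self.resp_rate, float),
        }


@dataclass
class HistologyStack:
    """Serial coronal sections with the scanning geometry."""

    slices: np.ndarray  # (n_slices, H, W) grayscale
    px_per_mm: float = 228.0
    slice_thickness_um: float = 50.0
    slice_spacing_um: float = 300.0

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3:
            raise ValueError("slices must have shape (n, H, W)")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


@dataclass
class Subject:
    """One simulated animal: raw movie, chromophores, physiology, truth."""

    subject_id: str
    truth: GroundTruth
    chromo: ChromophoreMovie | None = None
    stack: OpticalStack | None = None
    physio: PhysioTraces | None = None


# ---------------------------------------------------------------------------
# connectivity results
# ---------------------------------------------------------------------------

@dataclass
class SeedTimecourses:
    data: np.ndarray  # (T, S)
    seed_names: Sequence[str]
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.seed_names):
            raise ValueError("data must be (T, n_seeds)")


@dataclass
class ConnectivityMatrix:
    r: np.ndarray  # (S, S) Pearson correlations
    z: np.ndarray  # Fisher-transformed values
    seed_names: Sequence[str]
    contrast: str

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        s = len(self.seed_names)
        if self.r.shape != (s, s) or self.z.shape != (s, s):
            raise ValueError("r and z must be (S, S)")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("z must be finite (clip r before transforming)")


@dataclass
class FcMap:
    """Seed-to-pixel Fisher-Z correlation map (optionally normalized)."""

    values: np.ndarray  # (H, W); NaN outside mask / invalid pixels
    seed_name: str
    contrast: str
    subject_id: str = ""
    normalized: bool = False

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class GroupMapStats:
    """Group one-sample t statistics for a seed map, with thresholding."""

    t_map: np.ndarray  # (H, W); NaN where invalid
    p_map: np.ndarray  # two-tailed p; NaN where invalid
    mask: np.ndarray  # (H, W) bool cortex mask (test family)
    n_subjects: int
    seed_name: str = ""
    contrast: str = ""
    supra_mask: np.ndarray | None = None
    cluster_labels: np.ndarray | None = None
    cluster_sizes: np.ndarray | None = None
    spatial_extent: float | None = None


@dataclass
class EffectSize:
    g: float
    n1: int
    n2: int
    pooled_sd: float


@dataclass
class FeatureVector:
    """Seed-pair connectivity features of one subject (both contrasts)."""

    values: np.ndarray
    names: Sequence[str]
    subject_id: str = ""
    label: str | None = None  # "control" | "injured"
    lesion_fraction: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("values and names length mismatch")


@dataclass
class ClassifierReport:
    confusion: np.ndarray  # rows: true (neg, pos); cols: predicted (neg, pos)
    metrics: dict  # Se, Sp, PPV, NPV, Acc from the aggregate confusion
    per_repeat_accuracy: list = field(default_factory=list)
    selected_params: list = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return self.metrics["Acc"]


@dataclass
class RegressionReport:
    r: float | None  # Pearson r of pooled predictions vs targets
    rmsep: float  # root-mean-square error of prediction, target units
    predictions: np.ndarray = field(default_factory=lambda: np.empty(0))
    targets: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_value: float | None = None
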