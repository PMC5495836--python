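"""Spectral unmixing of multispectral reflectance into HbO2/HbR movies.

The differential (modified) Beer-Lambert model relates the change in optical
density at each wavelength to chromophore concentration changes,

    dOD(lambda, t) = sum_i eps_i(lambda) * dC_i(t) * D(lambda),

with eps_i the base-10 molar extinction coefficients and D(lambda) the
differential pathlength factor.  With three wavelengths and two chromophores
the system is overdetermined and solved per pixel and frame by the
Moore-Penrose pseudoinverse (ordinary least squares).  Concentration changes
are reported in uM relative to baseline; absolute concentrations are out of
scope.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import (
    CHROMOPHORES,
    ChromophoreMovie,
    ODMovie,
    OpticalStack,
    OpticsConfig,
)

__all__ = ["ExtinctionSystem", "optical_density", "build_extinction_system", "unmix"]


@dataclass
class ExtinctionSystem:
    """Corrected extinction system E and its cached pseudoinverse.

    ``E[l, i] = w_l * eps_i(lambda_l) * D(lambda_l) * 1e-6`` maps uM
    concentration changes to optical density; ``pinv`` maps back.
    """

    E: np.ndarray  # (L, 2), OD per uM
    correction_weights: np.ndarray  # (L,)
    pinv: np.ndarray  # (2, L)
    wavelengths_nm: tuple
    chromophores: tuple = CHROMOPHORES

    def __post_init__(self) -> None:
        resid = self.pinv @ self.E - np.eye(self.E.shape[1])
        if np.abs(resid).max() > 1e-10:
            raise ValueError("pinv is not a left inverse of E")


def optical_density(stack: OpticalStack, i0: str | np.ndarray = "stored") -> ODMovie:
    """Differential optical density dOD = log10(I0 / I).

    ``i0`` selects the reference intensity: "stored" uses the stack's own I0
    (falling back to the temporal mean when absent), "temporal_mean" uses the
    per-pixel per-wavelength temporal mean, or an explicit array/scalar may
    be given.  With a temporal-mean reference the dOD time series of every
    pixel is shifted by a constant, which the differential analysis ignores.
    """
    I = stack.intensities
    n_bad = int(np.count_nonzero(I <= 0))
    if n_bad:
        raise ValueError(f"{n_bad} nonpositive intensity value(s); cannot take log")
    if isinstance(i0, str):
        if i0 == "temporal_mean" or (i0 == "stored" and stack.i0 is None):
            ref = I.mean(axis=0)  # (L, H, W)
        elif i0 == "stored":
            ref = np.asarray(stack.i0, dtype=float)
        else:
            raise ValueError("i0 must be 'stored', 'temporal_mean', or an array")
    else:
        ref = np.asarray(i0, dtype=float)
    if ref.ndim == 1:  # (L,) -> broadcast over pixels
        ref = ref[:, None, None]
    if np.any(ref <= 0):
        raise ValueError("reference intensity I0 must be positive")
    # keep the stack's precision: float32 movies stay float32 end to end
    od = np.log10(ref[None].astype(I.dtype, copy=False) / I)
    return ODMovie(od=od, wavelengths_nm=stack.wavelengths_nm, fs=stack.fs)


def build_extinction_system(cfg: OpticsConfig) -> ExtinctionSystem:
    """Assemble the corrected extinction matrix and its pseudoinverse.

    Rows are weighted by the per-wavelength sensor/LED correction factors;
    the same weights apply to the optical-density data in :func:`unmix`, so
    the correction acts as a least-squares row weighting.
    """
    L = len(cfg.wavelengths_nm)
    if L < 2:
        raise ValueError("at least two wavelengths are required")
    eps = np.column_stack([np.asarray(cfg.extinction[c], float) for c in CHROMOPHORES])
    D = np.asarray(cfg.pathlength_cm, float)
    w = np.asarray(cfg.correction_weights, float)
    E = w[:, None] * eps * D[:, None] * 1e-6  # OD per uM
    sv = np.linalg.svd(E, compute_uv=False)
    if sv[-1] <= 1e-10 * sv[0]:
        raise ValueError(
            "extinction system is rank deficient (proportional rows?); "
            "cannot separate HbO2 from HbR"
        )
    return ExtinctionSystem(
        E=E,
        correction_weights=w,
        pinv=np.linalg.pinv(E),
        wavelengths_nm=tuple(cfg.wavelengths_nm),
    )


def unmix(
    od: ODMovie,
    system: ExtinctionSystem,
    keep_residual: bool = False,
) -> ChromophoreMovie:
    """Least-squares chromophore concentrations from multispectral dOD.

    Applies the cached pseudoinverse per pixel and frame:
    ``C = pinv(E) @ (w * dOD)``.  Optionally attaches the per-pixel
    root-mean-square spectral residual as ``movie.residual_norm``.
    """
    if tuple(od.wavelengths_nm) != tuple(system.wavelengths_nm):
        raise ValueError(
            f"wavelength mismatch: data {od.wavelengths_nm} vs "
            f"system {system.wavelengths_nm}"
        )
    dtype = od.od.dtype
    w = system.correction_weights.astype(dtype)
    weighted = od.od * w[None, :, None, None]
    conc = np.einsum(
        "cl,tlhw->tchw", system.pinv.astype(dtype, copy=False), weighted
    )
    data = {c: conc[:, i].astype(dtype, copy=False) for i, c in enumerate(CHROMOPHORES)}
    movie = ChromophoreMovie(data=data, fs=od.fs)
    if keep_residual:
        fit = np.einsum("lc,tchw->tlhw", system.E, conc)
        movie.residual_norm = np.sqrt(((weighted - fit) ** 2).mean(axis=(0, 1)))
    return movie
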