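"""Seed-based functional connectivity and spatial-extent statistics.

Seed time courses are unweighted means over each seed's member pixels.
Seed-to-seed connectivity is Pearson correlation, Fisher-Z transformed for
group statistics.  Seed-to-pixel maps are per-pixel correlations with a seed
trace, Fisher-Z transformed and normalized to zero mean / unit SD over the
cortex mask.  Group maps are per-pixel one-sample t tests of the normalized
maps against zero; significance is controlled by a Benjamini-Hochberg FDR
height threshold followed by a cluster-extent filter that removes clusters
smaller than a fraction (default 5%) of the surviving pixel count.  The
spatial extent of a network is the surviving-pixel count divided by the
cortex-mask pixel count.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .datatypes import (
    ChromophoreMovie,
    ConnectivityMatrix,
    CortexMask,
    FcMap,
    GroupMapStats,
    SeedAtlas,
    SeedTimecourses,
)
from .group_stats import bh_fdr

__all__ = [
    "extract_seed_timecourses",
    "seed_to_seed",
    "fisher_z",
    "homotopic_connectivity",
    "seed_to_pixel_map",
    "seed_to_pixel_maps",
    "group_tmap",
    "threshold_map",
    "spatial_extent_by_network",
]

#: r is clamped to +/- (1 - _R_CLIP) before the Fisher transform so that
#: self-correlation pixels stay finite.
_R_CLIP = 1e-7


def extract_seed_timecourses(
    movie: ChromophoreMovie | np.ndarray,
    atlas: SeedAtlas,
    contrast: str | None = None,
) -> SeedTimecourses | dict:
    """Per-seed mean time courses (unweighted mean over member pixels).

    Given a :class:`ChromophoreMovie` without ``contrast``, returns a dict
    mapping contrast name to :class:`SeedTimecourses`; with ``contrast`` or a
    plain (T, H, W) array, returns a single :class:`SeedTimecourses`.
    """
    if isinstance(movie, ChromophoreMovie):
        if contrast is None:
            return {
                c: extract_seed_timecourses(movie, atlas, c) for c in movie.contrasts
            }
        arr = movie.data[contrast]
        fs = movie.fs
        valid = movie.valid
        idx = movie.pixel_index_image() if movie.packed else None
    else:
        arr = np.asarray(movie)
        fs = float("nan")
        valid = None
        idx = None
    traces = np.empty((arr.shape[0], atlas.n_seeds))
    for j, name in enumerate(atlas.seed_names):
        px = atlas.seeds[name]
        if idx is not None:
            cols = idx[px[:, 0], px[:, 1]]
            if np.any(cols < 0):
                raise ValueError(f"seed {name} contains invalid pixels")
            traces[:, j] = arr[:, cols].mean(axis=1, dtype=np.float64)
        else:
            if valid is not None and not valid[px[:, 0], px[:, 1]].all():
                raise ValueError(f"seed {name} contains invalid pixels")
            traces[:, j] = arr[:, px[:, 0], px[:, 1]].mean(axis=1, dtype=np.float64)
    return SeedTimecourses(data=traces, seed_names=list(atlas.seed_names), fs=fs)


def fisher_z(r):
    """Variance-stabilising Fisher transform z = atanh(r) = 1/2 ln((1+r)/(1-r)).

    Accepts scalars or arrays with |r| <= 1; values at exactly +/- 1 are
    clipped to +/- (1 - 1e-7) so the result stays finite.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("|r| must be <= 1")
    out = np.arctanh(np.clip(r, -1 + _R_CLIP, 1 - _R_CLIP))
    return out if out.ndim else float(out)


def seed_to_seed(tc: SeedTimecourses, contrast: str = "") -> ConnectivityMatrix:
    """Pearson correlation (and Fisher Z) between all seed-pair time traces."""
    X = tc.data
    if X.shape[0] < 3:
        raise ValueError("need at least 3 frames to correlate")
    sd = X.std(axis=0)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(
            f"zero-variance seed trace(s): {[tc.seed_names[i] for i in bad]}"
        )
    r = np.atleast_2d(np.corrcoef(X.T))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(
        r=r, z=fisher_z(r), seed_names=list(tc.seed_names), contrast=contrast
    )


def homotopic_connectivity(m: ConnectivityMatrix, atlas: SeedAtlas) -> dict:
    """Fisher-Z connectivity of each left/right homotopic seed pair."""
    pairs = atlas.homotopic_pairs
    if not pairs:
        raise ValueError("atlas defines no homotopic (left/right) pairs")
    names = list(m.seed_names)
    out = {}
    for left, right in pairs:
        if left not in names or right not in names:
            raise ValueError(f"missing hemisphere partner for pair ({left}, {right})")
        out[(left, right)] = float(m.z[names.index(left), names.index(right)])
    return out


def _pixel_series(movie, mask: CortexMask, contrast: str) -> tuple:
    """(Y (T, n), rows, cols, image shape) of the cortex-pixel time courses."""
    if isinstance(movie, ChromophoreMovie):
        arr = movie.data[contrast] if contrast else next(iter(movie.data.values()))
        if movie.packed:
            return arr, movie.pixels[0], movie.pixels[1], movie.frame_shape
        valid = movie.valid
    else:
        arr = np.asarray(movie)
        valid = None
    m = mask.mask if valid is None else (mask.mask & valid)
    rows, cols = np.nonzero(m)
    return arr[:, rows, cols], rows, cols, mask.shape


def seed_to_pixel_maps(
    movie: ChromophoreMovie | np.ndarray,
    tc: SeedTimecourses,
    mask: CortexMask,
    *,
    contrast: str = "",
    subject_id: str = "",
    normalize: bool = True,
) -> dict:
    """Normalized Fisher-Z correlation maps for every seed of ``tc``.

    Standardizes the pixel time courses once and correlates all seed traces
    against them in a single pass; returns ``{seed_name: FcMap}``.
    """
    Y, rows, cols, shape = _pixel_series(movie, mask, contrast)
    n = Y.shape[0]
    mu = Y.mean(axis=0, dtype=np.float64)
    Y0 = Y - mu.astype(Y.dtype)
    y_sd = np.sqrt(np.einsum("ij,ij->j", Y0, Y0, dtype=np.float64) / n)
    good = y_sd > 0
    S = tc.data  # (T, S) float64
    S0 = S - S.mean(axis=0)
    s_sd = S0.std(axis=0)
    if np.any(s_sd == 0):
        bad = [tc.seed_names[i] for i in np.nonzero(s_sd == 0)[0]]
        raise ValueError(f"seed trace(s) with zero variance: {bad}")
    R = (S0.T.astype(Y0.dtype) @ Y0).astype(np.float64)  # (S, n)
    R /= n * s_sd[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        R /= y_sd[None, :]
    R = np.clip(R, -1.0, 1.0)
    out = {}
    for j, seed_name in enumerate(tc.seed_names):
        z_flat = np.where(
            good, np.arctanh(np.clip(R[j], -1 + _R_CLIP, 1 - _R_CLIP)), np.nan
        )
        if normalize:
            vals = z_flat[good]
            sd = vals.std()
            if sd == 0:
                raise ValueError("cannot normalize a spatially constant map")
            z_flat = (z_flat - vals.mean()) / sd
        z = np.full(shape, np.nan)
        z[rows, cols] = z_flat
        out[seed_name] = FcMap(
            values=z,
            seed_name=seed_name,
            contrast=contrast,
            subject_id=subject_id,
            normalized=normalize,
        )
    return out


def seed_to_pixel_map(
    movie: ChromophoreMovie | np.ndarray,
    seed_trace: np.ndarray,
    mask: CortexMask,
    *,
    contrast: str = "",
    seed_name: str = "",
    subject_id: str = "",
    normalize: bool = True,
) -> FcMap:
    """Correlation of one seed trace with every cortex pixel's time course.

    Per-pixel Pearson r is Fisher-Z transformed and, by default, normalized
    to zero mean and unit SD over the valid in-mask pixels.  Zero-variance
    pixels are marked invalid (NaN) and excluded from the normalization.
    """
    s = np.asarray(seed_trace, dtype=np.float64)
    tc = SeedTimecourses(data=s[:, None], seed_names=[seed_name or "seed"], fs=float("nan"))
    maps = seed_to_pixel_maps(
        movie, tc, mask, contrast=contrast, subject_id=subject_id, normalize=normalize
    )
    fm = next(iter(maps.values()))
    fm.seed_name = seed_name
    return fm


def group_tmap(
    maps: list[FcMap],
    mask: CortexMask,
    *,
    seed_name: str = "",
    contrast: str = "",
) -> GroupMapStats:
    """Per-pixel two-tailed one-sample t test of subject maps against zero.

    Pixels with fewer than 3 valid subjects, or zero variance across
    subjects, are marked invalid (NaN) rather than infinite.
    """
    if len(maps) < 3:
        raise ValueError("need at least 3 subject maps")
    stackv = np.stack([fm.values for fm in maps])  # (n, H, W)
    m = mask.mask
    valid_n = np.isfinite(stackv).sum(axis=0)
    with warnings_suppressed():
        mean = np.nanmean(stackv, axis=0)
        sd = np.nanstd(stackv, axis=0, ddof=1)
    ok = m & (valid_n >= 3) & (sd > 0)
    t = np.full(mask.shape, np.nan)
    p = np.full(mask.shape, np.nan)
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(valid_n[ok]))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), valid_n[ok] - 1)
    return GroupMapStats(
        t_map=t,
        p_map=p,
        mask=m,
        n_subjects=len(maps),
        seed_name=seed_name or (maps[0].seed_name if maps else ""),
        contrast=contrast or (maps[0].contrast if maps else ""),
    )


class warnings_suppressed:
    """Silence the all-NaN-slice warnings nanmean emits outside the mask."""

    def __enter__(self):
        import warnings as _w

        self._cm = _w.catch_warnings()
        self._cm.__enter__()
        _w.simplefilter("ignore", RuntimeWarning)
        return self

    def __exit__(self, *exc):
        return self._cm.__exit__(*exc)


def threshold_map(
    gstats: GroupMapStats,
    q: float = 0.05,
    extent_frac: float = 0.05,
    connectivity: int = 8,
) -> GroupMapStats:
    """FDR height threshold plus cluster-extent filter; fills in the
    suprathreshold mask, cluster labels, and the spatial extent.

    Steps: (1) Benjamini-Hochberg over the valid in-mask p values at level
    ``q``; (2) connected components of the surviving pixels (8-connectivity
    by default); (3) clusters strictly smaller than ``extent_frac`` times the
    number of height-surviving pixels are removed; (4) spatial extent =
    surviving pixels / cortex-mask pixels.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    m = gstats.mask
    valid = m & np.isfinite(gstats.p_map)
    height = np.zeros_like(m)
    pv = gstats.p_map[valid]
    if pv.size:
        rejected, _ = bh_fdr(pv, q)
        height[valid] = rejected
    n_height = int(height.sum())
    structure = np.ones((3, 3), bool) if connectivity == 8 else ndimage.generate_binary_structure(2, 1)
    labels, n_lab = ndimage.label(height, structure=structure)
    sizes = np.bincount(labels.ravel(), minlength=n_lab + 1)[1:]
    supra = height.copy()
    min_size = extent_frac * n_height
    for lab, size in enumerate(sizes, start=1):
        if size < min_size:
            supra[labels == lab] = False
    extent = float(supra.sum()) / float(m.sum()) if m.sum() else 0.0
    return GroupMapStats(
        t_map=gstats.t_map,
        p_map=gstats.p_map,
        mask=m,
        n_subjects=gstats.n_subjects,
        seed_name=gstats.seed_name,
        contrast=gstats.contrast,
        supra_mask=supra,
        cluster_labels=labels,
        cluster_sizes=sizes,
        spatial_extent=extent,
    )


def spatial_extent_by_network(
    maps_by_seed: dict,
    mask: CortexMask,
    q: float = 0.05,
    extent_frac: float = 0.05,
    contrast: str = "",
) -> pd.DataFrame:
    """Spatial extent of each seed network's group map.

    ``maps_by_seed`` maps seed name -> list of per-subject normalized
    :class:`FcMap`.  Returns a DataFrame with one row per seed (columns:
    seed, contrast, spatial_extent).  The group summary used elsewhere is the
    distribution of these per-seed extents; its headline number is the mean.
    """
    rows = []
    for seed_name, maps in maps_by_seed.items():
        g = group_tmap(maps, mask, seed_name=seed_name, contrast=contrast)
        g = threshold_map(g, q=q, extent_frac=extent_frac)
        surviving = g.cluster_sizes[g.cluster_sizes >= extent_frac * g.cluster_sizes.sum()] \
            if g.cluster_sizes.size else g.cluster_sizes
        rows.append(
            {
                "seed": seed_name,
                "contrast": contrast or g.contrast,
                "spatial_extent": g.spatial_extent,
                "n_clusters": int(len(surviving)),
                "largest_cluster_px": int(surviving.max()) if surviving.size else 0,
            }
        )
    return pd.DataFrame(rows)
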