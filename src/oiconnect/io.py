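"""Standard-format I/O: HDF5 movies, CSV traces/tables, JSON geometry, TIFF maps."""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .datatypes import (
    ChromophoreMovie,
    CortexMask,
    GroundTruth,
    OpticalStack,
    PhysioTraces,
    SeedAtlas,
)

__all__ = [
    "save_stack",
    "load_stack",
    "save_chromophores",
    "load_chromophores",
    "save_physio",
    "load_physio",
    "save_atlas",
    "load_atlas",
    "save_ground_truth",
    "load_ground_truth",
    "save_connectivity_csv",
    "save_map_tiff",
]


def save_stack(path, stack: OpticalStack) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("intensities", data=stack.intensities, compression="gzip")
        f.create_dataset("I0", data=np.asarray(stack.i0))
        f.create_dataset("wavelengths", data=np.asarray(stack.wavelengths_nm))
        f.attrs["fs"] = stack.fs


def load_stack(path) -> OpticalStack:
    with h5py.File(path, "r") as f:
        return OpticalStack(
            intensities=f["intensities"][()],
            i0=f["I0"][()],
            wavelengths_nm=tuple(float(w) for w in f["wavelengths"][()]),
            fs=float(f.attrs["fs"]),
        )


def save_chromophores(path, movie: ChromophoreMovie) -> None:
    with h5py.File(path, "w") as f:
        for contrast, arr in movie.data.items():
            f.create_dataset(contrast, data=arr, compression="gzip")
        f.attrs["fs"] = movie.fs
        f.attrs["residual"] = movie.residual
        if movie.valid is not None:
            f.create_dataset("valid", data=movie.valid)


def load_chromophores(path) -> ChromophoreMovie:
    with h5py.File(path, "r") as f:
        data = {k: f[k][()] for k in f.keys() if k != "valid"}
        valid = f["valid"][()] if "valid" in f else None
        return ChromophoreMovie(
            data=data,
            fs=float(f.attrs["fs"]),
            residual=bool(f.attrs.get("residual", False)),
            valid=valid,
        )


def save_physio(path, physio: PhysioTraces) -> None:
    df = pd.DataFrame({"t": physio.t, **physio.as_columns()})
    df.to_csv(path, index=False)


def load_physio(path) -> PhysioTraces:
    df = pd.read_csv(path)
    dt = np.diff(df["t"].to_numpy())
    fs = 1.0 / float(np.median(dt)) if len(dt) else 1.0
    return PhysioTraces(
        heart_rate=df["heart_rate"].to_numpy(),
        resp_signal=df["resp_signal"].to_numpy(),
        ecg=df["ecg"].to_numpy(),
        resp_rate=df["resp_rate"].to_numpy(),
        fs=fs,
    )


def save_atlas(path, atlas: SeedAtlas) -> None:
    payload = {
        "mask": {
            "shape": list(atlas.mask.shape),
            "pixels": np.flatnonzero(atlas.mask.mask).tolist(),
            "center": list(atlas.mask.center) if atlas.mask.center else None,
            "semi_axes": list(atlas.mask.semi_axes) if atlas.mask.semi_axes else None,
        },
        "seeds": {
            name: {
                "center": [int(v) for v in atlas.centers[name]],
                "pixels": atlas.seeds[name].tolist(),
            }
            for name in atlas.seed_names
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_atlas(path) -> SeedAtlas:
    payload = json.loads(Path(path).read_text())
    shape = tuple(payload["mask"]["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    flat[payload["mask"]["pixels"]] = True
    mask = CortexMask(
        mask=flat.reshape(shape),
        center=tuple(payload["mask"]["center"]) if payload["mask"]["center"] else None,
        semi_axes=(
            tuple(payload["mask"]["semi_axes"]) if payload["mask"]["semi_axes"] else None
        ),
    )
    seeds = {n: np.asarray(s["pixels"], int) for n, s in payload["seeds"].items()}
    centers = {n: tuple(s["center"]) for n, s in payload["seeds"].items()}
    return SeedAtlas(seeds=seeds, centers=centers, mask=mask)


def save_ground_truth(path, truth: GroundTruth) -> None:
    payload = {
        "coupling": truth.coupling.tolist(),
        "seed_names": list(truth.seed_names),
        "group": truth.group,
        "lesion_fraction": truth.lesion_fraction,
        "kappa": truth.kappa,
        "rng_seed": truth.rng_seed,
    }
    Path(path).write_text(json.dumps(payload))


def load_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        coupling=np.asarray(d["coupling"]),
        seed_names=d["seed_names"],
        group=d["group"],
        lesion_fraction=d["lesion_fraction"],
        kappa=d["kappa"],
        rng_seed=d["rng_seed"],
    )


def save_connectivity_csv(path, matrix) -> None:
    df = pd.DataFrame(matrix.z, index=matrix.seed_names, columns=matrix.seed_names)
    df.to_csv(path, float_format="%.6f")


def save_map_tiff(path, values: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
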