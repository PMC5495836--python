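"""End-to-end orchestration: simulate -> unmix -> preprocess -> connectivity
-> spatial extent -> group statistics -> machine learning.

A :class:`RunConfig` captures every stage parameter and the RNG seed, so a
saved config reproduces a run bit-for-bit for the deterministic stages.  Each
stage is individually skippable, and every artifact lands in the run
directory together with a manifest (checksums, parameters, versions, seeds)
and a per-stage log.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import Subject
from .group_stats import hedges_g, rank_sum_test
from .io import save_connectivity_csv
from .ml import build_feature_vector, cross_validate_ann, cross_validate_svm
from .preprocess import bandpass, regress_nuisance, smooth_spatial
from .seed_fc import (
    extract_seed_timecourses,
    seed_to_pixel_maps,
    seed_to_seed,
    spatial_extent_by_network,
)
from .synthetic import CohortDesign, simulate_cohort
from .unmixing import build_extinction_system, optical_density, unmix

log = logging.getLogger("oiconnect")

__all__ = ["RunConfig", "SubjectResult", "analyze_subject", "run_pipeline", "report"]


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    out_dir: str = "runs/run"
    rng_seed: int = 0
    n_control: int = 8
    n_injured: int = 5
    design: CohortDesign = field(default_factory=CohortDesign)
    # stage toggles
    do_unmix: bool = True
    do_regress: bool = True
    do_smooth: bool = True
    do_bandpass: bool = True
    do_ml: bool = True
    save_subject_artifacts: bool = True
    # stage parameters
    kernel_size: int = 11
    kernel_sigma: float = 3.0
    band: tuple = (0.009, 0.08)
    filter_order: int = 4
    regressors: tuple = ("heart_rate", "resp_signal", "ecg", "resp_rate", "global")
    q: float = 0.05
    extent_frac: float = 0.05
    svm_folds: int = 10
    svm_repeats: int = 10
    ann_folds: int | None = None

    def validate(self) -> None:
        if self.band[1] >= self.design.fs / 2:
            raise ValueError(
                f"band high {self.band[1]} Hz must be below Nyquist "
                f"({self.design.fs / 2} Hz)"
            )
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("need 0 < band low < band high")
        if not 0 < self.q < 1 or not 0 <= self.extent_frac < 1:
            raise ValueError("q must be in (0,1) and extent_frac in [0,1)")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_as_plain(dataclasses.asdict(self))))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        design = raw.pop("design", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in _field_names(cls)})
        optics = design.pop("optics", None)
        if design:
            cfg.design = CohortDesign(
                **{k: _tupled(v) for k, v in design.items() if k in _field_names(CohortDesign)}
            )
        if optics:
            from .datatypes import OpticsConfig

            cfg.design.optics = OpticsConfig(
                **{k: _tupled(v) for k, v in optics.items() if k in _field_names(OpticsConfig)}
            )
        cfg.band = tuple(cfg.band)
        cfg.regressors = tuple(cfg.regressors)
        return cfg


def _field_names(cls) -> set:
    return {f.name for f in dataclasses.fields(cls)}


def _tupled(v):
    return tuple(v) if isinstance(v, list) else v


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    lesion_fraction: float
    matrices: dict  # contrast -> ConnectivityMatrix
    maps: dict  # (contrast, seed) -> FcMap


def analyze_subject(subject: Subject, atlas, config: RunConfig) -> SubjectResult:
    """Run the per-subject chain: (unmix) -> GLM -> smooth -> band-pass ->
    seed time courses, connectivity matrices, and normalized seed maps."""
    chromo = subject.chromo
    if config.do_unmix and subject.stack is not None:
        od = optical_density(subject.stack)
        system = build_extinction_system(config.design.optics)
        chromo = unmix(od, system)
    if chromo is None:
        raise ValueError(f"subject {subject.subject_id} has no movie data")
    if not chromo.packed:
        chromo = chromo.to_packed(atlas.mask.mask)
    if config.do_regress:
        chromo = regress_nuisance(
            chromo, subject.physio, atlas.mask, regressors=config.regressors
        )
    if config.do_smooth:
        chromo = smooth_spatial(
            chromo, atlas.mask, size=config.kernel_size, sigma=config.kernel_sigma
        )
    if config.do_bandpass:
        chromo = bandpass(
            chromo, config.band[0], config.band[1], config.filter_order, atlas.mask
        )
    matrices, maps = {}, {}
    for contrast in chromo.contrasts:
        tc = extract_seed_timecourses(chromo, atlas, contrast)
        matrices[contrast] = seed_to_seed(tc, contrast)
        seed_maps = seed_to_pixel_maps(
            chromo, tc, atlas.mask, contrast=contrast, subject_id=subject.subject_id
        )
        for seed, fmap in seed_maps.items():
            maps[(contrast, seed)] = fmap
    return SubjectResult(
        subject_id=subject.subject_id,
        group=subject.truth.group,
        lesion_fraction=subject.truth.lesion_fraction,
        matrices=matrices,
        maps=maps,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def group_extent_tables(results: list, atlas, config: RunConfig) -> pd.DataFrame:
    """Per-seed spatial extents for every group x contrast."""
    frames = []
    contrasts = sorted({c for r in results for c in r.matrices})
    for group in ("control", "injured"):
        members = [r for r in results if r.group == group]
        if len(members) < 3:
            continue
        for contrast in contrasts:
            maps_by_seed = {
                seed: [r.maps[(contrast, seed)] for r in members]
                for seed in atlas.seed_names
            }
            df = spatial_extent_by_network(
                maps_by_seed, atlas.mask, q=config.q,
                extent_frac=config.extent_frac, contrast=contrast,
            )
            df["group"] = group
            frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def extent_group_stats(extents: pd.DataFrame) -> pd.DataFrame:
    """Control-vs-injured rank-sum and Hedges' g on per-seed extents."""
    rows = []
    for contrast, sub in extents.groupby("contrast"):
        ctl = sub.loc[sub.group == "control", "spatial_extent"].to_numpy()
        inj = sub.loc[sub.group == "injured", "spatial_extent"].to_numpy()
        if len(ctl) < 2 or len(inj) < 2:
            continue
        p, u = rank_sum_test(ctl, inj)
        g = hedges_g(ctl, inj)
        rows.append(
            {
                "comparison": f"spatial_extent_{contrast}",
                "statistic": u,
                "p": p,
                "g": g.g,
                "n1": g.n1,
                "n2": g.n2,
                "control_mean": ctl.mean(),
                "injured_mean": inj.mean(),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig):
    """Execute every enabled stage and write artifacts plus a manifest.

    Returns ``(out_dir, manifest)``.  Any stage failure is recorded in a
    partial manifest before the exception propagates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest = {
        "version": __version__,
        "rng_seed": config.rng_seed,
        "config": _as_plain(dataclasses.asdict(config)),
        "stages": [],
        "artifacts": {},
    }

    def _record(path: Path):
        manifest["artifacts"][str(path.relative_to(out))] = _sha256(path)

    def _stage(name):
        t0 = time.time()

        def done(status="ok"):
            manifest["stages"].append(
                {"name": name, "status": status, "seconds": round(time.time() - t0, 2)}
            )
            log.info("stage %s: %s (%.1fs)", name, status, time.time() - t0)

        return done

    try:
        done = _stage("simulate")
        cohort = simulate_cohort(
            config.n_control, config.n_injured, config.design, config.rng_seed
        )
        from .io import save_atlas

        save_atlas(out / "atlas.json", cohort.atlas)
        _record(out / "atlas.json")
        done()

        done = _stage("subjects")
        results = []
        for i in range(len(cohort)):
            subject = cohort.subject(i)
            res = analyze_subject(subject, cohort.atlas, config)
            results.append(res)
            if config.save_subject_artifacts:
                for contrast, mat in res.matrices.items():
                    p = out / f"connectivity_{res.subject_id}_{contrast}.csv"
                    save_connectivity_csv(p, mat)
                    _record(p)
            log.info("subject %s analysed", subject.subject_id)
        done()

        done = _stage("extent")
        extents = group_extent_tables(results, cohort.atlas, config)
        extents.to_csv(out / "spatial_extent.csv", index=False)
        _record(out / "spatial_extent.csv")
        done()

        done = _stage("stats")
        stats_df = extent_group_stats(extents)
        stats_df.to_csv(out / "group_stats.csv", index=False)
        _record(out / "group_stats.csv")
        done()

        if config.do_ml:
            done = _stage("ml")
            features = [
                build_feature_vector(
                    r.matrices,
                    subject_id=r.subject_id,
                    label=r.group,
                    lesion_fraction=r.lesion_fraction,
                )
                for r in results
            ]
            svm_report = cross_validate_svm(
                features,
                k=config.svm_folds,
                repeats=config.svm_repeats,
                rng_seed=config.rng_seed,
            )
            ann_report = cross_validate_ann(
                features, k=config.ann_folds, rng_seed=config.rng_seed
            )
            ml_payload = {
                "svm": {
                    "confusion": svm_report.confusion.tolist(),
                    "metrics": svm_report.metrics,
                    "per_repeat_accuracy": svm_report.per_repeat_accuracy,
                },
                "ann": {
                    "r": ann_report.r,
                    "rmsep": ann_report.rmsep,
                    "p": ann_report.p_value,
                    "predictions": ann_report.predictions.tolist(),
                    "targets": ann_report.targets.tolist(),
                },
            }
            (out / "ml_reports.json").write_text(json.dumps(ml_payload, indent=2))
            _record(out / "ml_reports.json")
            done()

        config.to_yaml(out / "config.yaml")
        _record(out / "config.yaml")
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        log.removeHandler(handler)
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.removeHandler(handler)
    return out, manifest


def report(run_dir) -> Path:
    """Assemble a plain-text/markdown summary with heatmap figures.

    Missing artifacts are listed and the report is still emitted.
    """
    run_dir = Path(run_dir)
    lines = ["# oiconnect run report", ""]
    missing = []

    extent_path = run_dir / "spatial_extent.csv"
    if extent_path.exists():
        extents = pd.read_csv(extent_path)
        lines += ["## Spatial extent (fraction of cortex mask)", ""]
        lines.append(extents.to_string(index=False))
        lines.append("")
        summary = (
            extents.groupby(["group", "contrast"])["spatial_extent"]
            .agg(["mean", "std"])
            .reset_index()
        )
        lines += ["### Group summary", summary.to_string(index=False), ""]
    else:
        missing.append(extent_path.name)

    stats_path = run_dir / "group_stats.csv"
    if stats_path.exists():
        lines += ["## Group statistics", pd.read_csv(stats_path).to_string(index=False), ""]
    else:
        missing.append(stats_path.name)

    ml_path = run_dir / "ml_reports.json"
    if ml_path.exists():
        ml = json.loads(ml_path.read_text())
        lines += ["## Machine learning", json.dumps(ml["svm"]["metrics"], indent=2)]
        lines += [f"ANN r = {ml['ann']['r']}, RMSEP = {ml['ann']['rmsep']}", ""]

    conn_files = sorted(run_dir.glob("connectivity_*.csv"))
    if conn_files:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        frames = {}
        for f in conn_files:
            df = pd.read_csv(f, index_col=0)
            contrast = f.stem.split("_")[-1]
            frames.setdefault(contrast, []).append(df)
        for contrast, dfs in frames.items():
            mean = sum(df.to_numpy() for df in dfs) / len(dfs)
            fig, ax = plt.subplots(figsize=(5, 4))
            im = ax.imshow(mean, vmin=-1.5, vmax=1.5, cmap="RdBu_r")
            ax.set_xticks(range(len(dfs[0].columns)), dfs[0].columns, rotation=90)
            ax.set_yticks(range(len(dfs[0].index)), dfs[0].index)
            ax.set_title(f"mean seed-to-seed Z ({contrast})")
            fig.colorbar(im)
            fig.tight_layout()
            fig.savefig(run_dir / f"connectivity_mean_{contrast}.png", dpi=120)
            plt.close(fig)
        lines += ["Mean connectivity heatmaps written as PNG.", ""]

    if missing:
        lines += ["## Missing artifacts", *missing, ""]
    out_path = run_dir / "report.md"
    out_path.write_text("\n".join(lines))
    return out_path
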