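"""Canned reproduction experiments on synthetic cohorts.

These functions bundle the study designs used to validate the pipeline
end-to-end: the injury contrast in spatial extent (group difference in
FDR-thresholded seed-map coverage) and machine-learning recovery of group
membership and lesion size from connectivity features with a known
feature-to-lesion mapping.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np

from .datatypes import CHROMOPHORES, FeatureVector, GroundTruth
from .pipeline import RunConfig, analyze_subject, extent_group_stats, group_extent_tables
from .seed_fc import fisher_z
from .synthetic import (
    CohortDesign,
    default_coupling,
    effective_coupling,
    make_cortex_mask,
    make_seed_atlas,
    simulate_cohort,
)

__all__ = ["extent_study_design", "injury_extent_replicate", "feature_cohort"]


def extent_study_design(**overrides) -> CohortDesign:
    """Cohort design for the spatial-extent injury contrast.

    The experiment works at the chromophore level (band-limited coupled
    fluctuations on the 128 x 128 grid, 2100 frames at 5 Hz); the optics
    round-trip is the identity on noiseless data and nuisance physiology is
    absent by design, so neither stage is simulated here.
    """
    return replace(
        CohortDesign(),
        packed=True,
        include_optics=False,
        include_physio=False,
        **overrides,
    )


def injury_extent_replicate(
    rng_seed: int,
    n_control: int = 8,
    n_injured: int = 5,
    design: CohortDesign | None = None,
    q: float = 0.05,
    extent_frac: float = 0.05,
) -> dict:
    """One replicate of the injury-vs-control spatial-extent experiment.

    Simulates a cohort, runs smoothing, band-pass filtering, seed maps, and
    group thresholding, and compares per-seed spatial extents between groups
    (rank-sum test and Hedges' g per contrast).

    Returns a dict with the extent table (``extents``), the group statistics
    table (``stats``), and per-contrast summaries.
    """
    if design is None:
        design = extent_study_design()
    config = RunConfig(
        rng_seed=rng_seed,
        n_control=n_control,
        n_injured=n_injured,
        design=design,
        do_unmix=False,
        do_regress=design.include_physio,
        q=q,
        extent_frac=extent_frac,
        do_ml=False,
    )
    cohort = simulate_cohort(n_control, n_injured, design, rng_seed)
    results = [
        analyze_subject(cohort.subject(i), cohort.atlas, config)
        for i in range(len(cohort))
    ]
    extents = group_extent_tables(results, cohort.atlas, config)
    stats = extent_group_stats(extents)
    summary = {}
    for _, row in stats.iterrows():
        contrast = row["comparison"].replace("spatial_extent_", "")
        summary[contrast] = {
            "control_mean": row["control_mean"],
            "injured_mean": row["injured_mean"],
            "p": row["p"],
            "g": row["g"],
        }
    return {"extents": extents, "stats": stats, "summary": summary, "results": results}


def feature_cohort(
    n_control: int = 10,
    n_injured: int = 10,
    rng_seed: int = 0,
    noise_sd: float = 0.1,
    lesion_range: tuple = (0.2, 1.0),
    kappa: float = 1.0,
    coupling_kwargs: dict | None = None,
) -> list:
    """Feature-level synthetic cohort with a linear fc-to-lesion mapping.

    Each subject's 56 features are the Fisher-Z values of its effective
    (injury-attenuated) coupling matrix for both contrasts, plus independent
    Gaussian noise of SD ``noise_sd`` (z units).  Because the attenuation of
    interhemispheric coupling is linear in the lesion fraction, lesion size
    is (locally) a linear function of the noiseless features -- the setting
    in which classifier and regressor recovery can be validated against
    ground truth.
    """
    rng = np.random.default_rng(rng_seed)
    mask = make_cortex_mask(64, 64, 4)
    atlas = make_seed_atlas(mask)
    coupling = default_coupling(atlas.seed_names, **(coupling_kwargs or {}))
    s = atlas.n_seeds
    iu = np.triu_indices(s, k=1)
    features = []
    groups = ["control"] * n_control + ["injured"] * n_injured
    for i, group in enumerate(groups):
        lesion = float(rng.uniform(*lesion_range)) if group == "injured" else 0.0
        truth = GroundTruth(
            coupling=coupling,
            seed_names=atlas.seed_names,
            group=group,
            lesion_fraction=lesion,
            kappa=kappa,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        z_true = fisher_z(effective_coupling(truth))[iu]
        values, names = [], []
        for contrast in CHROMOPHORES:
            values.append(z_true + rng.normal(0.0, noise_sd, size=z_true.size))
            names += [
                f"{contrast}:{atlas.seed_names[a]}~{atlas.seed_names[b]}"
                for a, b in zip(*iu)
            ]
        features.append(
            FeatureVector(
                values=np.concatenate(values),
                names=names,
                subject_id=f"s{i:02d}",
                label=group,
                lesion_fraction=lesion,
            )
        )
    return features
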