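"""Validation experiments on synthetic cohorts.

Two simulation studies back the statistical machinery:

* **Null calibration** — cohorts with no planted effect (severity is pure
  Gaussian noise). At each analysis level the family-wise error is the
  fraction of cohorts with any Bonferroni-significant unit; it should sit
  at or below the nominal family alpha.
* **Parameter recovery** — cohorts with a single planted effect (unit
  effect size, small noise). Recovery succeeds when the global peak z of
  the voxel map falls inside the planted region, and when the planted
  tract / edge ranks first by adjusted R^2 at its level.

Both use a compact study: a 24^3 grid at 1 mm, 200 patients, a 15-node
mirrored parcellation and a 12-edge streamline pseudo-atlas. Severities
enter the analyses directly from the generator's emitted ground truth,
so these experiments probe the mapping statistics, not the response
renderer (the scoring path is exercised by the pipeline tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .disconnect import (
    Parcellation,
    StreamlineSet,
    disconnection_matrices,
    tract_disconnection_table,
)
from .regression import run_edge_analysis, run_tract_analysis
from .synthetic import (
    EffectSpec,
    SyntheticAnatomy,
    box_region,
    default_tract_grouping,
    make_behavior,
    make_lesions,
    make_parcellation,
    make_streamlines,
    make_template,
)
from .vlsm import dtlvc_stack, fit_voxelwise
from .volumes import coverage_filter, lesion_volume, overlay

__all__ = [
    "StudySetup",
    "build_study",
    "null_calibration",
    "recovery_study",
]

PLANTED_REGION = "planted_region"


@dataclass
class StudySetup:
    anatomy: SyntheticAnatomy
    masks: list
    planted_tract: str
    planted_edge: tuple[int, int]


def build_study(
    seed: int,
    n_patients: int = 200,
    shape: tuple[int, int, int] = (24, 24, 24),
) -> StudySetup:
    """One synthetic study: anatomy plus a lesion cohort, all from ``seed``."""
    template = make_template(shape)
    parcellation = make_parcellation(template, n_cortical_per_hemi=6,
                                     n_subcortical=3, seed=seed)
    grouping = default_tract_grouping(parcellation, n_tracts=6,
                                      edges_per_tract=2, seed=seed)
    streamlines = make_streamlines(parcellation, grouping, n_per_edge=8,
                                   curvature_jitter=0.25, seed=seed + 1)
    regions = {PLANTED_REGION: box_region(template, side="right", size=(5, 5, 5))}
    anatomy = SyntheticAnatomy(template=template, parcellation=parcellation,
                               streamlines=streamlines, regions=regions)
    masks = make_lesions(template, n_patients, seed=seed + 2)
    return StudySetup(
        anatomy=anatomy,
        masks=masks,
        planted_tract="tract_1",
        planted_edge=tuple(grouping["tract_1"][0]),
    )


def _severity(study: StudySetup, spec: EffectSpec, seed: int) -> np.ndarray:
    records, truth = make_behavior(study.masks, study.anatomy, [spec], seed=seed)
    return truth.ego_severity if spec.dimension == "ego" else truth.allo_severity


def _three_levels(study: StudySetup, severity: np.ndarray, min_coverage: int = 10):
    """Voxel StatMap + tract and edge analysis results for one severity vector."""
    masks = study.masks
    volumes = np.array([lesion_volume(m) for m in masks])
    mask = coverage_filter(overlay(masks), min_coverage)
    statmap = None
    if mask.any():
        statmap = fit_voxelwise(dtlvc_stack(masks), severity, mask,
                                study.anatomy.template)
    tract_res = run_tract_analysis(
        severity, tract_disconnection_table(study.anatomy.streamlines, masks),
        volumes,
    )
    edge_res = run_edge_analysis(
        severity,
        disconnection_matrices(study.anatomy.streamlines,
                               study.anatomy.parcellation, masks),
        volumes,
    )
    return statmap, tract_res, edge_res


def null_calibration(
    n_seeds: int = 100, base_seed: int = 0, n_patients: int = 200
) -> dict:
    """Family-wise error of the three Bonferroni-corrected levels under the null.

    Each cohort's severity is generated by a planted effect of size 0 with
    unit noise, i.e. independent of all damage.
    """
    any_sig = {"voxel": 0, "tract": 0, "edge": 0}
    for i in range(n_seeds):
        seed = base_seed + 1000 * i
        study = build_study(seed, n_patients=n_patients)
        spec = EffectSpec("voxel_region", PLANTED_REGION, effect_size=0.0,
                          noise_sd=1.0)
        severity = _severity(study, spec, seed + 3)
        statmap, tract_res, edge_res = _three_levels(study, severity)
        if statmap is not None and statmap.significant.any():
            any_sig["voxel"] += 1
        if tract_res.table["significant_bonferroni"].any():
            any_sig["tract"] += 1
        if not edge_res.table.empty and edge_res.table["significant_bonferroni"].any():
            any_sig["edge"] += 1
    return {
        "n_seeds": n_seeds,
        "n_patients": n_patients,
        "fwer": {k: v / n_seeds for k, v in any_sig.items()},
    }


def recovery_study(
    n_seeds: int = 20,
    base_seed: int = 0,
    effect_size: float = 1.0,
    noise_sd: float = 0.1,
    n_patients: int = 200,
) -> dict:
    """How often a single planted effect is recovered at each level.

    Voxel level: the global peak z lies inside the planted region.
    Tract / edge level: the planted unit ranks first by adjusted R^2.
    """
    hits = {"voxel": 0, "tract": 0, "edge": 0}
    for i in range(n_seeds):
        seed = base_seed + 1000 * i
        study = build_study(seed, n_patients=n_patients)
        region = study.anatomy.regions[PLANTED_REGION]

        spec = EffectSpec("voxel_region", PLANTED_REGION, effect_size=effect_size,
                          noise_sd=noise_sd)
        statmap, _, _ = _three_levels(study, _severity(study, spec, seed + 3))
        if statmap is not None:
            # peak by t (z is a monotone transform of t but clamped)
            t_grid = np.where(statmap.analysis_mask, statmap.t, -np.inf)
            peak = np.unravel_index(int(np.argmax(t_grid)), t_grid.shape)
            if region[peak]:
                hits["voxel"] += 1

        spec = EffectSpec("tract", study.planted_tract, effect_size=effect_size,
                          noise_sd=noise_sd)
        _, tract_res, _ = _three_levels(study, _severity(study, spec, seed + 4))
        if not tract_res.table.empty and tract_res.table.iloc[0]["unit"] == study.planted_tract:
            hits["tract"] += 1

        spec = EffectSpec("edge", study.planted_edge, effect_size=effect_size,
                          noise_sd=noise_sd)
        _, _, edge_res = _three_levels(study, _severity(study, spec, seed + 5))
        a, b = study.planted_edge
        if not edge_res.table.empty and edge_res.table.iloc[0]["unit"] == f"{a}-{b}":
            hits["edge"] += 1
    return {
        "n_seeds": n_seeds,
        "n_patients": n_patients,
        "effect_size": effect_size,
        "noise_sd": noise_sd,
        "recovery_rate": {k: v / n_seeds for k, v in hits.items()},
    }
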