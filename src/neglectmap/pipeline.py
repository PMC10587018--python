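"""End-to-end orchestration: simulate -> score -> map at three levels.

One :class:`RunConfig` drives the whole study: a synthetic cohort is
generated, cancellation responses are scored into zero-constrained
severity vectors, and each of the four conditions (left/right x
egocentric/allocentric neglect) is analysed at the voxel, tract and
network-edge level. A single voxel coverage mask is shared by all four
voxel-wise analyses so statistical power is constant across them.
Homologue comparisons (left vs right correlates, mirrored across the
midline) close the run. Everything is reproducible from (config, seed),
and every written file is listed in a manifest with a content hash.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import scoring, synthetic
from .disconnect import disconnection_matrices, tract_disconnection_table
from .overlap import homologous_units, mirrored_overlap
from .regression import MassAnalysisResult, run_edge_analysis, run_tract_analysis
from .scoring import CONDITIONS, constrained_severity, score_response
from .synthetic import (
    EffectSpec,
    GammaVolumes,
    SyntheticAnatomy,
    box_region,
    make_behavior,
    make_lesions,
    make_parcellation,
    make_streamlines,
    make_template,
)
from .vlsm import cluster_table, dtlvc_stack, extract_clusters, fit_voxelwise
from .volumes import coverage_filter, lesion_volume, overlay, save_volume

__all__ = ["RunConfig", "SimulatedStudy", "simulate", "run_condition", "run_all"]


def _default_effects() -> list[EffectSpec]:
    # left-lateralized deficits from right-hemisphere targets and vice versa
    return [
        EffectSpec("voxel_region", "right_temporoparietal", effect_size=0.8,
                   noise_sd=0.08, laterality="left", dimension="ego"),
        EffectSpec("tract", "tract_1", effect_size=0.5, noise_sd=0.05,
                   laterality="right", dimension="ego"),
        EffectSpec("edge", None, effect_size=0.5, noise_sd=0.05,
                   laterality="left", dimension="allo"),
    ]


@dataclass
class RunConfig:
    """Study conditions for one synthetic run (all randomness from ``seed``)."""

    seed: int = 0
    shape: tuple[int, int, int] = (40, 48, 40)
    spacing_mm: float = 1.0
    n_patients: int = 150
    side_probabilities: tuple[float, float, float] = synthetic.DEFAULT_SIDE_PROBABILITIES
    volume_mean_fraction: float = 0.10  # of hemisphere voxels
    volume_cv: float = 0.6
    n_cortical_per_hemi: int = 12
    n_subcortical: int = 5
    n_tracts: int = 8
    edges_per_tract: int = 2
    n_per_edge: int = 10
    curvature_jitter: float = 0.25
    effects: list[EffectSpec] = field(default_factory=_default_effects)
    min_coverage: int = 10
    coverage_inclusive: bool = False
    family_alpha: float = 0.05
    fdr_q: float = 0.05
    min_edge_patients: int = 10
    damage_definition: str | float = "any_positive"
    sidedness: str = "greater"
    signed_severity: bool = False

    def __post_init__(self) -> None:
        for name in ("min_coverage", "family_alpha", "fdr_q", "min_edge_patients"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["effects"] = [asdict(e) for e in self.effects]
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["effects"] = [EffectSpec(**e) for e in d.get("effects", [])]
        for key in ("shape", "side_probabilities"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimulatedStudy:
    config: RunConfig
    anatomy: SyntheticAnatomy
    masks: list
    records: list
    truth: synthetic.GroundTruth
    layout: scoring.CancellationLayout
    scores: list


def simulate(config: RunConfig) -> SimulatedStudy:
    """Generate the full synthetic study a run analyses."""
    template = make_template(config.shape, config.spacing_mm)
    parcellation = make_parcellation(
        template,
        n_cortical_per_hemi=config.n_cortical_per_hemi,
        n_subcortical=config.n_subcortical,
        seed=config.seed,
    )
    grouping = synthetic.default_tract_grouping(
        parcellation, n_tracts=config.n_tracts,
        edges_per_tract=config.edges_per_tract, seed=config.seed,
    )
    streamlines = make_streamlines(
        parcellation, grouping, n_per_edge=config.n_per_edge,
        curvature_jitter=config.curvature_jitter, seed=config.seed + 1,
    )
    regions = {
        "right_temporoparietal": box_region(template, side="right", size=(7, 9, 9)),
        "left_temporoparietal": box_region(template, side="left", size=(7, 9, 9)),
    }
    anatomy = SyntheticAnatomy(
        template=template, parcellation=parcellation,
        streamlines=streamlines, regions=regions,
    )
    effects = []
    for e in config.effects:
        if e.target_kind == "edge" and e.target_id is None:
            e = replace(e, target_id=tuple(grouping["tract_1"][0]))
        effects.append(e)
    cx = template.midline_column
    hemi_vox = cx * template.shape[1] * template.shape[2]
    masks = make_lesions(
        template,
        config.n_patients,
        side_probabilities=config.side_probabilities,
        volume_distribution=GammaVolumes(
            mean=config.volume_mean_fraction * hemi_vox, cv=config.volume_cv
        ),
        seed=config.seed + 2,
    )
    layout = scoring.default_layout()
    records, truth = make_behavior(
        masks, anatomy, effects, seed=config.seed + 3, layout=layout
    )
    scores = [score_response(layout, r.response) for r in records]
    return SimulatedStudy(
        config=config, anatomy=anatomy, masks=masks, records=records,
        truth=truth, layout=layout, scores=scores,
    )


def _mass_summary(res: MassAnalysisResult) -> dict:
    return {
        "n_units_tested": res.n_units_tested,
        "alpha_bonferroni": res.alpha_bonferroni,
        "fdr_fallback_applied": res.fdr_fallback_applied,
        "status": res.status,
        "significant_units": [str(u) for u in res.significant_units],
    }


def run_condition(
    study: SimulatedStudy,
    condition: str,
    analysis_mask: np.ndarray | None = None,
) -> dict:
    """All three analysis levels for one neglect condition.

    Only valid records (>= 5 correctly marked targets) enter the
    analyses. ``analysis_mask`` lets the caller share one voxel coverage
    mask across conditions; by default it is computed from this
    condition's (identical) cohort.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    cfg = study.config
    valid = [i for i, s in enumerate(study.scores) if s.valid]
    masks = [study.masks[i] for i in valid]
    scores = [study.scores[i] for i in valid]
    severity = constrained_severity(scores, condition, signed=cfg.signed_severity)
    volumes = np.array([lesion_volume(m) for m in masks])
    report: dict = {
        "condition": condition,
        "n_patients": len(masks),
        "n_excluded_invalid": len(study.masks) - len(masks),
        "n_impaired": int(np.sum(severity != 0)),
    }
    if analysis_mask is None:
        analysis_mask = coverage_filter(
            overlay(masks), cfg.min_coverage, inclusive=cfg.coverage_inclusive
        )
    t0 = time.perf_counter()
    if analysis_mask.sum() == 0:
        report["voxel"] = {"status": "no voxels pass the coverage filter",
                          "n_tests": 0}
        statmap, clusters = None, []
    elif np.ptp(severity) == 0:
        report["voxel"] = {"status": "degenerate outcome: severity constant",
                          "n_tests": int(analysis_mask.sum())}
        statmap, clusters = None, []
    else:
        statmap = fit_voxelwise(
            dtlvc_stack(masks), severity, analysis_mask,
            study.anatomy.template, sidedness=cfg.sidedness,
            family_alpha=cfg.family_alpha,
        )
        clusters = extract_clusters(statmap)
        report["voxel"] = {
            "n_tests": statmap.n_tests,
            "alpha_corrected": statmap.alpha_corrected,
            "n_significant_voxels": int(statmap.significant.sum()),
            "clusters": cluster_table(clusters).to_dict(orient="records"),
        }
    report["voxel"]["seconds"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    tract_table = tract_disconnection_table(study.anatomy.streamlines, masks)
    if np.ptp(severity) == 0:
        report["tract"] = {"status": "degenerate outcome: severity constant"}
        tract_res = None
    else:
        tract_res = run_tract_analysis(
            severity, tract_table, volumes,
            family_alpha=cfg.family_alpha, fdr_q=cfg.fdr_q, sidedness=cfg.sidedness,
        )
        report["tract"] = _mass_summary(tract_res)
    report["tract"]["seconds"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    matrices = disconnection_matrices(
        study.anatomy.streamlines, study.anatomy.parcellation, masks
    )
    if np.ptp(severity) == 0:
        report["edge"] = {"status": "degenerate outcome: severity constant"}
        edge_res = None
    else:
        edge_res = run_edge_analysis(
            severity, matrices, volumes,
            min_patients=cfg.min_edge_patients,
            damage_definition=cfg.damage_definition,
            family_alpha=cfg.family_alpha, fdr_q=cfg.fdr_q, sidedness=cfg.sidedness,
        )
        report["edge"] = _mass_summary(edge_res)
    report["edge"]["seconds"] = round(time.perf_counter() - t0, 3)

    report["_objects"] = {
        "statmap": statmap,
        "clusters": clusters,
        "tract_result": tract_res,
        "edge_result": edge_res,
        "severity": severity,
    }
    return report


def _edge_units(res: MassAnalysisResult | None) -> list[tuple[int, int]]:
    if res is None:
        return []
    out = []
    for u in res.significant_units:
        a, b = str(u).split("-")
        out.append((int(a), int(b)))
    return out


def _overlap_section(reports: dict, study: SimulatedStudy) -> dict:
    """Mirrored voxel overlap plus tract/edge homologue comparisons."""
    section: dict = {}
    for frame in ("ego", "allo"):
        left = reports[f"left_{frame}"]["_objects"]
        right = reports[f"right_{frame}"]["_objects"]
        sm_l, sm_r = left["statmap"], right["statmap"]
        entry: dict = {}
        if sm_l is not None and sm_r is not None:
            sig_l, sig_r = sm_l.significant, sm_r.significant
            if sig_l.any() or sig_r.any():
                entry["voxel"] = mirrored_overlap(sig_l, sig_r).to_dict()
            else:
                entry["voxel"] = {"status": "no significant voxels in either map"}
        tr_l, tr_r = left["tract_result"], right["tract_result"]
        if tr_l is not None and tr_r is not None:
            comp = homologous_units(
                tr_l.significant_units, tr_r.significant_units, "tract"
            )
            entry["tract"] = {
                "shared": comp.shared, "only_left_condition": comp.only_a,
                "only_right_condition": comp.only_b,
                "unmatched": comp.unmatched_a + comp.unmatched_b,
            }
        ed_l, ed_r = left["edge_result"], right["edge_result"]
        if ed_l is not None and ed_r is not None:
            comp = homologous_units(
                _edge_units(ed_l), _edge_units(ed_r), "edge",
                parcellation=study.anatomy.parcellation,
            )
            entry["edge"] = {
                "shared": [f"{a}-{b}" for a, b in comp.shared],
                "only_left_condition": [f"{a}-{b}" for a, b in comp.only_a],
                "only_right_condition": [f"{a}-{b}" for a, b in comp.only_b],
                "unmatched": [f"{a}-{b}" for a, b in comp.unmatched_a + comp.unmatched_b],
            }
        section[frame] = entry
    return section


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Simulate once, analyse all four conditions, compare homologues.

    Returns the run report; with ``outdir`` the severity tables,
    statistical maps, unit tables and the JSON/Markdown report are
    written and listed in a content-hashed manifest.
    """
    study = simulate(config)
    valid = [i for i, s in enumerate(study.scores) if s.valid]
    masks = [study.masks[i] for i in valid]
    shared_mask = coverage_filter(
        overlay(masks), config.min_coverage, inclusive=config.coverage_inclusive
    )
    reports = {
        c: run_condition(study, c, analysis_mask=shared_mask) for c in CONDITIONS
    }
    report = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "n_valid": len(valid),
        "shared_coverage_voxels": int(shared_mask.sum()),
        "conditions": {c: {k: v for k, v in r.items() if k != "_objects"}
                       for c, r in reports.items()},
        "homologue_overlap": _overlap_section(reports, study),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []

        def _w(path: Path):
            written.append(path)

        config.to_yaml(outdir / "config.yaml"); _w(outdir / "config.yaml")
        synthetic.write_behavior_tsv(study.records, study.layout,
                                     outdir / "behaviour.tsv")
        _w(outdir / "behaviour.tsv")
        save_volume(outdir / "coverage_mask.nii.gz", shared_mask,
                    study.anatomy.template)
        _w(outdir / "coverage_mask.nii.gz")
        for c, r in reports.items():
            obj = r["_objects"]
            if obj["statmap"] is not None:
                save_volume(outdir / f"{c}_z.nii.gz", obj["statmap"].z,
                            study.anatomy.template)
                _w(outdir / f"{c}_z.nii.gz")
            if obj["tract_result"] is not None:
                obj["tract_result"].table.to_csv(
                    outdir / f"{c}_tracts.tsv", sep="\t", index=False)
                _w(outdir / f"{c}_tracts.tsv")
            if obj["edge_result"] is not None:
                obj["edge_result"].table.to_csv(
                    outdir / f"{c}_edges.tsv", sep="\t", index=False)
                _w(outdir / f"{c}_edges.tsv")
        (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
        _w(outdir / "report.json")
        (outdir / "report.md").write_text(_markdown_report(report))
        _w(outdir / "report.md")
        manifest = {str(p.name): _sha256(p) for p in written}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        report["manifest"] = manifest
    return report


def _markdown_report(report: dict) -> str:
    lines = [
        "# Synthetic lesion-mapping run",
        f"seed {report['seed']}, {report['n_valid']}/{report['n_patients']} valid patients, "
        f"{report['shared_coverage_voxels']} voxels in the shared coverage mask",
        "",
    ]
    for c, r in report["conditions"].items():
        lines.append(f"## {c}")
        lines.append(f"- impaired patients: {r['n_impaired']}")
        vox = r["voxel"]
        if "n_significant_voxels" in vox:
            lines.append(
                f"- voxel level: {vox['n_significant_voxels']} significant voxels "
                f"in {len(vox['clusters'])} clusters "
                f"({vox['n_tests']} tests, alpha {vox['alpha_corrected']:.3g})"
            )
        for level in ("tract", "edge"):
            sec = r[level]
            if "significant_units" in sec:
                tag = " (FDR fallback)" if sec["fdr_fallback_applied"] else ""
                lines.append(
                    f"- {level} level: {len(sec['significant_units'])} significant "
                    f"of {sec['n_units_tested']} tested{tag}"
                )
        lines.append("")
    return "\n".join(lines)
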