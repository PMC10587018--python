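"""Tract- and network-edge-level lesion-symptom regressions.

For each of the four conditions, regresses severity on percent
disconnection per unit with lesion volume as a covariate; Bonferroni
control over the tested units with the 5% FDR step-up as the documented
fallback when nothing survives.
"""

from pathlib import Path

import numpy as np

from neglectmap.disconnect import disconnection_matrices, tract_disconnection_table
from neglectmap.pipeline import RunConfig, simulate
from neglectmap.regression import run_edge_analysis, run_tract_analysis
from neglectmap.scoring import CONDITIONS, constrained_severity
from neglectmap.volumes import lesion_volume

SIM = Path(__file__).resolve().parent.parent / "results" / "simulated"
OUT = Path(__file__).resolve().parent.parent / "results" / "regressions"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = RunConfig.from_yaml(SIM / "config.yaml")
    study = simulate(config)
    valid = [i for i, s in enumerate(study.scores) if s.valid]
    masks = [study.masks[i] for i in valid]
    scores = [study.scores[i] for i in valid]
    volumes = np.array([lesion_volume(m) for m in masks])
    tract_table = tract_disconnection_table(study.anatomy.streamlines, masks)
    matrices = disconnection_matrices(
        study.anatomy.streamlines, study.anatomy.parcellation, masks
    )
    for condition in CONDITIONS:
        severity = constrained_severity(scores, condition)
        if np.ptp(severity) == 0:
            print(f"{condition}: severity constant, skipped")
            continue
        tr = run_tract_analysis(severity, tract_table, volumes,
                                family_alpha=config.family_alpha)
        tr.table.to_csv(OUT / f"{condition}_tracts.tsv", sep="\t", index=False)
        ed = run_edge_analysis(severity, matrices, volumes,
                               min_patients=config.min_edge_patients,
                               family_alpha=config.family_alpha)
        ed.table.to_csv(OUT / f"{condition}_edges.tsv", sep="\t", index=False)
        tag_t = " via FDR fallback" if tr.fdr_fallback_applied else ""
        tag_e = " via FDR fallback" if ed.fdr_fallback_applied else ""
        print(f"{condition}:")
        print(f"  tracts: {len(tr.significant_units)}/{tr.n_units_tested} significant"
              f" (alpha {tr.alpha_bonferroni:.2g}){tag_t}: {tr.significant_units}")
        alpha_e = f"{ed.alpha_bonferroni:.2g}" if ed.alpha_bonferroni else "n/a"
        print(f"  edges:  {len(ed.significant_units)}/{ed.n_units_tested} significant"
              f" (alpha {alpha_e}){tag_e}: {ed.significant_units}")
        if not tr.table.empty:
            top = tr.table.iloc[0]
            print(f"  best tract by adjusted R^2: {top['unit']} "
                  f"(adj R^2 = {top['adjusted_r2']:.3f})")
    print(f"wrote unit tables to {OUT}")


if __name__ == "__main__":
    main()
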