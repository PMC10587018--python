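"""Simulate the synthetic stroke cohort every later step analyses.

Generates the toy template, mirrored parcellation, streamline
pseudo-atlas, lateralized lesion cohort and planted-effect behaviour for
the default study configuration, and writes the shared inputs (config,
behaviour table, anatomy, ground truth, lesion overlay) under
results/simulated/.
"""

import json
import sys
from pathlib import Path

import numpy as np

from neglectmap.disconnect import save_streamlines_json
from neglectmap.pipeline import RunConfig, simulate
from neglectmap.synthetic import write_behavior_tsv
from neglectmap.volumes import lesion_volume, overlay, save_volume

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = RunConfig(seed=seed)
    study = simulate(config)

    config.to_yaml(OUT / "config.yaml")
    study.layout.to_json(OUT / "layout.json")
    write_behavior_tsv(study.records, study.layout, OUT / "behaviour.tsv")
    study.anatomy.parcellation.save(OUT / "parcellation.nii.gz", OUT / "nodes.json")
    save_streamlines_json(study.anatomy.streamlines, OUT / "streamlines.json")
    (OUT / "ground_truth.json").write_text(
        json.dumps(study.truth.to_manifest(), indent=1)
    )
    masks_dir = OUT / "lesions"
    masks_dir.mkdir(exist_ok=True)
    for rec, mask in zip(study.records, study.masks):
        save_volume(masks_dir / f"{rec.patient_id}.nii.gz", mask.data, study.anatomy.template)
    ov = overlay(study.masks)
    save_volume(OUT / "lesion_overlay.nii.gz", ov.counts, study.anatomy.template)

    vols = np.array([lesion_volume(m, "cm3") for m in study.masks])
    sides = {"left": 0, "right": 0, "bilateral": 0}
    cx = study.anatomy.template.midline_column
    for m in study.masks:
        l, r = m.data[:cx].any(), m.data[cx:].any()
        sides["bilateral" if (l and r) else "left" if l else "right"] += 1
    print(f"simulated {config.n_patients} patients (seed {seed}) "
          f"on a {'x'.join(map(str, config.shape))} grid")
    print(f"  lesion sides: {sides}")
    print(f"  lesion volume: mean {vols.mean():.2f} cm^3 (sd {vols.std():.2f})")
    print(f"  max voxel overlap: {int(ov.counts.max())} patients")
    print(f"  planted effects: {study.truth.effect_names}")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
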