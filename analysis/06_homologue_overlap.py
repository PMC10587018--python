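"""Compare the correlates of left- and right-lateralized neglect.

Mirrors each condition's significant-voxel map across the midline onto
the opposite hemisphere and quantifies the overlap with Dice
coefficients; matches significant tracts by contralateral name and
significant edges by mirrored node identity.
"""

import json
from pathlib import Path

from neglectmap.pipeline import RunConfig, run_all

SIM = Path(__file__).resolve().parent.parent / "results" / "simulated"
OUT = Path(__file__).resolve().parent.parent / "results" / "overlap"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = RunConfig.from_yaml(SIM / "config.yaml")
    report = run_all(config)
    section = report["homologue_overlap"]
    (OUT / "homologue_overlap.json").write_text(json.dumps(section, indent=1))
    for frame, entry in section.items():
        print(f"{frame}centric neglect, left vs right correlates:")
        vox = entry.get("voxel", {})
        if "dice" in vox:
            print(f"  voxel: {vox['overlap']} homologous voxels shared "
                  f"(Dice = {vox['dice']:.5f}, {vox['interpretation']})")
        else:
            print(f"  voxel: {vox.get('status', 'not compared')}")
        for level in ("tract", "edge"):
            if level in entry:
                e = entry[level]
                print(f"  {level}: {len(e['shared'])} homologous shared, "
                      f"{len(e['only_left_condition'])} left-only, "
                      f"{len(e['only_right_condition'])} right-only, "
                      f"{len(e['unmatched'])} without a defined homologue")
    print(f"wrote {OUT / 'homologue_overlap.json'}")


if __name__ == "__main__":
    main()
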