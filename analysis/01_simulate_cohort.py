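"""Generate the study-condition synthetic cohort.

45 capsular-stroke patients and 93 controls on a 16x16x16 grid at 1.5 mm:
diffuse 20% ipsilesional subfield atrophy, one planted VPL-seeded
covariance effect (patient slope 2, control slope 1, contrast SNR 1),
right-hemisphere capsular lesions, three scanners, and clinical scores.
Tables go to results/data as TSV; images (NIfTI) go to scratch/.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from thalscn.io_core import write_cohort_table, write_gmv_stack, write_image
from thalscn.synthetic import SimulationDesign, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=ROOT / "scratch" / "data")
    ap.add_argument("--image-dir", type=Path, default=ROOT / "scratch" / "images")
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)
    args.image_dir.mkdir(parents=True, exist_ok=True)

    design = SimulationDesign()
    sim = simulate_cohort(design, seed=args.seed)

    write_cohort_table(sim.cohort, args.out_dir / "cohort.tsv")
    sim.subfields.to_csv(args.out_dir / "subfields.tsv", sep="\t", index=False)
    write_gmv_stack(sim.stack, args.image_dir / "gmv")
    grid = sim.stack.grid
    for sid, m in sim.lesion_masks.items():
        write_image(m.astype(np.uint8), grid, args.image_dir / f"lesion_{sid}.nii.gz", np.uint8)
    write_image(sim.atlas_labels, grid, args.image_dir / "atlas.nii.gz", np.int16)
    (args.image_dir / "atlas_names.json").write_text(json.dumps(sim.atlas_names, indent=2))
    truth = {k: v for k, v in sim.truth.items() if k != "design"}
    (args.out_dir / "truth.json").write_text(json.dumps(truth, indent=2))

    n_cs = (sim.cohort["group"] == "CS").sum()
    print(f"cohort: {n_cs} CS / {(sim.cohort['group'] == 'NC').sum()} NC, "
          f"{sim.stack.grid.n_voxels} voxels, {len(sim.lesion_masks)} lesion masks")
    print(f"planted effect: {sim.truth['effects'][0]['subfield']} "
          f"slopes {sim.truth['effects'][0]['slope_cs']}/{sim.truth['effects'][0]['slope_nc']}, "
          f"noise sd {sim.truth['noise_sd']}")
    print(f"tables -> {args.out_dir}; images -> {args.image_dir}")


if __name__ == "__main__":
    main()
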