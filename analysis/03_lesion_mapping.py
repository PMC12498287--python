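"""Lesion probability map and the lesion-excluded analysis mask.

Loads the per-patient lesion masks, builds the group probability map
(fraction of patients lesioned per voxel), removes every voxel lesioned in
any patient from the analysis mask, and reports per-patient lesion volumes.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from thalscn.io_core import ImageGrid, read_mask, write_image
from thalscn.lesions import (
    lesion_exclusion_mask,
    lesion_probability_map,
    lesion_volumes_mm3,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--image-dir", type=Path, default=ROOT / "scratch" / "images")
    ap.add_argument("--out-dir", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    lesion_paths = sorted(args.image_dir.glob("lesion_*.nii.gz"))
    masks = [read_mask(p) for p in lesion_paths]
    analysis = read_mask(args.image_dir / "gmv" / "analysis_mask.nii.gz")

    prob = lesion_probability_map(masks)
    final = lesion_exclusion_mask(analysis, masks)
    import nibabel as nib

    grid = ImageGrid.from_image(nib.load(args.image_dir / "gmv" / "analysis_mask.nii.gz"))
    write_image(prob, grid, args.image_dir / "lesion_prob.nii.gz")
    write_image(final.astype(np.uint8), grid, args.image_dir / "analysis_mask_final.nii.gz", np.uint8)

    vols = lesion_volumes_mm3(masks, grid.voxel_volume)
    summary = pd.DataFrame(
        {
            "patient": [p.stem.replace("lesion_", "").replace(".nii", "") for p in lesion_paths],
            "lesion_volume_mm3": vols,
        }
    )
    summary.to_csv(args.out_dir / "lesion_volumes.tsv", sep="\t", index=False)

    print(f"{len(masks)} lesion masks; peak lesion probability {prob.max():.2f}")
    print(f"analysis mask: {int(analysis.sum())} -> {int(final.sum())} voxels after exclusion")
    print(f"lesion volume (mm3): mean {vols.mean():.0f}, range [{vols.min():.0f}, {vols.max():.0f}]")


if __name__ == "__main__":
    main()
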