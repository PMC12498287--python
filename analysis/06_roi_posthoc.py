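"""Target-ROI extraction and the post-hoc ROI covariance GLM.

Binarizes the FWE-significant clusters of the VPL-seed analysis, unions
them, intersects with the atlas, selects regions with > 10% overlap,
extracts per-subject mean GMV on the lesion-excluded mask, and refits the
covariance GLM per (seed, ROI) with Bonferroni adjustment.
"""

import argparse
from pathlib import Path

from thalscn.io_core import (
    read_atlas,
    read_cohort_table,
    read_gmv_stack,
    read_mask,
    read_subfield_table,
    subfield_vector,
)
from thalscn.multiplicity import cluster_fwe_permutation
from thalscn.roi import run_roi_pipeline
from thalscn.scn_glm import build_scn_design

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--perms", type=int, default=1000)
    ap.add_argument("--threshold", type=float, default=0.10)
    ap.add_argument("--data-dir", type=Path, default=ROOT / "scratch" / "data")
    ap.add_argument("--image-dir", type=Path, default=ROOT / "scratch" / "images")
    ap.add_argument("--out-dir", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort_table(args.data_dir / "cohort.tsv")
    subfields = read_subfield_table(args.data_dir / "subfields.tsv")
    paths = [args.image_dir / "gmv" / f"{sid}.nii.gz" for sid in cohort["subject_id"]]
    stack = read_gmv_stack(paths, args.image_dir / "analysis_mask_final.nii.gz")
    atlas_labels, atlas_names, _ = read_atlas(
        args.image_dir / "atlas.nii.gz",
        stack.grid,
        names=args.image_dir / "atlas_names.json",
    )
    mask_final = read_mask(args.image_dir / "analysis_mask_final.nii.gz", stack.grid)

    vols = subfield_vector(subfields, cohort["subject_id"], "VPL", "ipsi")
    design = build_scn_design(cohort, vols, "VPL_ipsi")
    res = cluster_fwe_permutation(stack, design, B=args.perms, seed=args.seed)

    report, means, posthoc = run_roi_pipeline(
        {"VPL_ipsi": res}, atlas_labels, atlas_names, stack, {"VPL_ipsi": design},
        analysis_mask=mask_final, overlap_threshold=args.threshold,
    )
    report.to_csv(args.out_dir / "overlap_report.tsv", sep="\t", index=False)
    means.rename_axis("subject_id").to_csv(args.out_dir / "roi_means.tsv", sep="\t")
    posthoc.to_csv(args.out_dir / "posthoc.tsv", sep="\t", index=False)

    print(report.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    n_sel = int(report["selected"].sum())
    print(f"\n{n_sel} target ROI(s) selected (overlap ratio > {args.threshold})")
    if len(posthoc):
        print(posthoc.to_string(index=False, float_format=lambda v: f"{v:.4g}"))


if __name__ == "__main__":
    main()
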