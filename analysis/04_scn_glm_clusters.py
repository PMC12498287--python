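"""Seed-based covariance GLM with permutation cluster inference.

For the planted VPL seed (ipsilesional) and for the whole thalamus, fits
the per-voxel model GMV ~ group intercepts + group-specific z-volume
slopes + confounds on the lesion-excluded mask, tests the patient-minus-
control slope contrast one-tailed at voxel p < 0.001, and assigns
cluster-extent FWE p-values from 1000 Freedman-Lane permutations.
"""

import argparse
from pathlib import Path

from thalscn.io_core import (
    read_cohort_table,
    read_gmv_stack,
    read_subfield_table,
    subfield_vector,
    write_image,
    write_run_log,
)
from thalscn.multiplicity import cluster_fwe_permutation
from thalscn.scn_glm import build_scn_design

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--perms", type=int, default=1000)
    ap.add_argument("--data-dir", type=Path, default=ROOT / "scratch" / "data")
    ap.add_argument("--image-dir", type=Path, default=ROOT / "scratch" / "images")
    ap.add_argument("--out-dir", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort_table(args.data_dir / "cohort.tsv")
    subfields = read_subfield_table(args.data_dir / "subfields.tsv")
    paths = [args.image_dir / "gmv" / f"{sid}.nii.gz" for sid in cohort["subject_id"]]
    stack = read_gmv_stack(paths, args.image_dir / "analysis_mask_final.nii.gz")

    for label, (name, hemi) in {
        "VPL_ipsi": ("VPL", "ipsi"),
        "whole_thalamus_ipsi": ("whole_thalamus", "ipsi"),
    }.items():
        vols = subfield_vector(subfields, cohort["subject_id"], name, hemi)
        design = build_scn_design(cohort, vols, label)
        res = cluster_fwe_permutation(
            stack, design, B=args.perms, seed=args.seed, p_voxel=0.001
        )
        res.table.to_csv(args.out_dir / f"clusters_{label}.tsv", sep="\t", index=False)
        write_image(res.fit.t_map(), stack.grid, args.image_dir / f"tmap_{label}.nii.gz")
        write_run_log(
            args.out_dir / f"fit_{label}.json",
            seed_region=label, df=res.fit.df, t_crit=res.t_crit,
            n_clusters=len(res.table), B=args.perms, perm_seed=args.seed,
        )
        n_sig = int((res.table["p_fwe"] < 0.05).sum()) if len(res.table) else 0
        print(f"{label}: df={res.fit.df}, t_crit={res.t_crit:.2f}, "
              f"{len(res.table)} suprathreshold cluster(s), {n_sig} FWE-significant")
        if len(res.table):
            print(res.table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))


if __name__ == "__main__":
    main()
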