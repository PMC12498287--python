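"""Partial Spearman screen of SCN measures against clinical scores.

For each group, the per-subject SCN measure (z-scored seed volume times
mean GMV over the selected target ROIs) is correlated with each clinical
metric, controlling age, gender and scanner; BH-FDR over the grid plus an
uncorrected p < 0.05 exploratory tier with per-metric/per-seed counts.
"""

import argparse
from pathlib import Path

import pandas as pd

from thalscn.behavior import correlation_screen, scn_measure
from thalscn.io_core import read_cohort_table, read_subfield_table, subfield_vector

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, default=ROOT / "scratch" / "data")
    ap.add_argument("--out-dir", type=Path, default=ROOT / "results")
    ap.add_argument("--seeds", nargs="+", default=["VPL", "MDm", "AV", "PuM", "LGN"])
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort_table(args.data_dir / "cohort.tsv")
    subfields = read_subfield_table(args.data_dir / "subfields.tsv")
    roi_means = pd.read_csv(args.out_dir / "roi_means.tsv", sep="\t", index_col="subject_id")
    if roi_means.shape[1] == 0:
        print("no selected ROIs: nothing to correlate")
        return
    roi_means = roi_means.loc[cohort["subject_id"]]

    measures = pd.DataFrame(index=pd.Index(cohort["subject_id"], name="subject_id"))
    for name in args.seeds:
        vols = subfield_vector(subfields, cohort["subject_id"], name, "ipsi")
        measures[f"{name}_ipsi"] = scn_measure(roi_means, vols)

    for group in ("CS", "NC"):
        grid, per_metric, per_seed = correlation_screen(measures, cohort, group=group)
        grid.to_csv(args.out_dir / f"correlation_grid_{group}.tsv", sep="\t", index=False)
        n_fdr = int(grid["fdr_significant"].sum())
        n_unc = int(grid["uncorrected_hit"].sum())
        print(f"{group}: {len(grid)} seed x metric tests, {n_fdr} FDR-significant, "
              f"{n_unc} uncorrected hits")
        print("  per metric:", dict(zip(per_metric["metric"], per_metric["n_hits"])))
        print("  per seed:  ", dict(zip(per_seed["seed"], per_seed["n_hits"])))


if __name__ == "__main__":
    main()
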