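"""Target-ROI extraction from significant clusters and the post-hoc ROI GLM.

The pipeline step sequence: binarize each seed's FWE-significant clusters,
union the binary maps across seeds, intersect the union with an atlas,
select regions whose overlap ratio (intersection / region size) strictly
exceeds 10%, average each subject's GMV within each selected region, and
refit the covariance GLM with the ROI mean as response.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_core import GMVStack
from .multiplicity import ClusterResult, bonferroni
from .scn_glm import ScnDesign, fit_scn
from scipy import stats


def binarize_significant(result: ClusterResult, alpha_fwe: float = 0.05) -> np.ndarray:
    """Flat boolean map of voxels in clusters with p_fwe < alpha_fwe."""
    labels = result.labels.reshape(-1)
    out = np.zeros(labels.size, dtype=bool)
    if "p_fwe" not in result.table.columns:
        raise ValueError("cluster table lacks p_fwe; run permutation inference first")
    for _, row in result.table.iterrows():
        if row["p_fwe"] < alpha_fwe:
            out |= labels == row["cluster_id"]
    return out


def union_mask(masks: list[np.ndarray]) -> np.ndarray:
    """Voxelwise OR of equally-shaped boolean maps."""
    if not masks:
        raise ValueError("union of an empty mask list is undefined")
    arr = np.asarray([np.asarray(m, bool).reshape(-1) for m in masks])
    if len({m.size for m in arr}) > 1:  # pragma: no cover - asarray already throws
        raise ValueError("masks are on different grids")
    return arr.any(axis=0)


def select_rois(
    union: np.ndarray,
    atlas_labels: np.ndarray,
    atlas_names: dict[int, str] | None = None,
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Overlap report for every atlas region; selected iff ratio > threshold.

    The denominator is the atlas region's size ("overlap ratio between the
    intersecting voxels and each region"); the criterion is a strict
    inequality, so a region at exactly the threshold is not selected.
    """
    u = np.asarray(union, bool).reshape(-1)
    labels = np.asarray(atlas_labels, int).reshape(-1)
    if labels.size != u.size:
        raise ValueError("atlas and union mask are on different grids")
    ids = np.unique(labels[labels > 0])
    if ids.size == 0:
        raise ValueError("atlas contains no labeled regions")
    names = atlas_names or {}
    rows = []
    for rid in ids:
        region = labels == rid
        size = int(region.sum())
        inter = int((region & u).sum())
        ratio = inter / size
        rows.append(
            {
                "region_id": int(rid),
                "region_name": names.get(int(rid), f"region_{rid}"),
                "region_size": size,
                "intersection": inter,
                "overlap_ratio": ratio,
                "selected": ratio > threshold,
            }
        )
    return pd.DataFrame(rows)


def roi_masks_from_report(
    report: pd.DataFrame, atlas_labels: np.ndarray
) -> dict[int, np.ndarray]:
    labels = np.asarray(atlas_labels, int).reshape(-1)
    return {
        int(r.region_id): labels == int(r.region_id)
        for r in report.itertuples()
        if r.selected
    }


def extract_mean_gmv(
    stack: GMVStack,
    roi_masks: dict[int, np.ndarray],
    analysis_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-subject mean GMV within each ROI (subjects x ROIs).

    ROI voxels are restricted to ``analysis_mask`` (the lesion-excluded
    mask) so patients' lesioned voxels never enter a mean; ROIs emptied by
    the restriction are dropped with a warning.
    """
    base = (
        np.ones(stack.grid.n_voxels, bool)
        if analysis_mask is None
        else np.asarray(analysis_mask, bool).reshape(-1)
    )
    out = {}
    for rid, m in roi_masks.items():
        mm = np.asarray(m, bool).reshape(-1) & base
        if not mm.any():
            warnings.warn(f"ROI {rid} emptied by the analysis mask; dropped", stacklevel=2)
            continue
        out[rid] = stack.data[:, mm].mean(axis=1)
    return pd.DataFrame(out, index=stack.subject_ids)


def posthoc_roi_glm(
    roi_means: pd.DataFrame,
    designs: dict[str, ScnDesign],
    family_size: int | None = None,
) -> pd.DataFrame:
    """Covariance GLM refit with each ROI mean as response, per seed design.

    Returns one row per (seed, ROI) with the slope-contrast estimate, t,
    raw p (two-sided) and Bonferroni-adjusted p over the whole family of
    (seed, ROI) tests actually run (or ``family_size`` if given).
    """
    if roi_means.shape[1] == 0:
        raise ValueError("no ROIs to test")
    rows = []
    for seed_name, design in designs.items():
        X = design.matrix
        XtX_inv = np.linalg.inv(X.T @ X)
        c = design.slope_contrast
        cvc = float(c @ XtX_inv @ c)
        df = design.df_resid
        for rid in roi_means.columns:
            y = roi_means[rid].to_numpy(float)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            sigma2 = resid @ resid / df
            est = float(c @ beta)
            t = est / np.sqrt(sigma2 * cvc) if sigma2 > 0 else np.nan
            p = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
            rows.append(
                {"seed": seed_name, "roi": rid, "contrast": est, "t": t, "p": p, "df": df}
            )
    out = pd.DataFrame(rows)
    m = family_size if family_size is not None else len(out)
    out["p_bonf"] = bonferroni(out["p"].to_numpy(), m)
    return out


def run_roi_pipeline(
    cluster_results: dict[str, ClusterResult],
    atlas_labels: np.ndarray,
    atlas_names: dict[int, str],
    stack: GMVStack,
    designs: dict[str, ScnDesign],
    analysis_mask: np.ndarray | None = None,
    alpha_fwe: float = 0.05,
    overlap_threshold: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Steps 1-5 plus the post-hoc GLM; returns (report, roi_means, posthoc).

    ``cluster_results`` maps seed name -> permutation cluster result; the
    union is pooled over all seeds' significant maps.
    """
    binaries = [binarize_significant(r, alpha_fwe) for r in cluster_results.values()]
    union = union_mask(binaries)
    report = select_rois(union, atlas_labels, atlas_names, overlap_threshold)
    masks = roi_masks_from_report(report, atlas_labels)
    if not masks:
        return report, pd.DataFrame(index=stack.subject_ids), pd.DataFrame()
    means = extract_mean_gmv(stack, masks, analysis_mask)
    posthoc = posthoc_roi_glm(means, designs)
    return report, means, posthoc
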