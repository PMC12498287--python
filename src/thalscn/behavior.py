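"""Spearman partial correlations between SCN-derived measures and behavior.

The per-subject SCN measure is, by default, the cross-term the covariance
GLM models at group level: the subject's z-scored seed volume times their
mean GMV over the selected target ROIs. The study never defines a
per-subject covariance scalar, so the operationalization is isolated in
``scn_measure`` and pluggable (e.g. plain ROI-mean GMV).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import CLINICAL_COLUMNS
from .multiplicity import fdr_bh
from .scn_glm import confound_columns, zscore


def spearman_partial(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float, int]:
    """Partial Spearman rho of x and y given covariate columns.

    All variables are average-rank transformed; the covariates (plus an
    intercept) are regressed out of the ranked x and y, and the Pearson
    correlation of the residuals is returned with a t-approximation p-value
    on n - k - 2 df. Rows with any missing value are dropped pairwise.
    Returns (rho, p, n_effective).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if covariates is None:
        Z = np.empty((x.size, 0))
    else:
        Z = np.asarray(covariates, float)
        if Z.ndim == 1:
            Z = Z[:, None]
    ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(Z), axis=1)
    x, y, Z = x[ok], y[ok], Z[ok]
    n, k = x.size, Z.shape[1]
    if n < k + 3:
        raise ValueError(f"need at least k+3={k+3} complete cases, have {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant variable after pairwise deletion")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rz = np.column_stack([np.ones(n)] + [stats.rankdata(Z[:, j]) for j in range(k)])
    ex = rx - rz @ np.linalg.lstsq(rz, rx, rcond=None)[0]
    ey = ry - rz @ np.linalg.lstsq(rz, ry, rcond=None)[0]
    denom = np.sqrt((ex @ ex) * (ey @ ey))
    rho = float(np.clip((ex @ ey) / denom, -1.0, 1.0)) if denom > 0 else np.nan
    df = n - k - 2
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return rho, p, n


def scn_measure(
    roi_means: pd.DataFrame,
    seed_volumes: np.ndarray,
    kind: str = "cross_term",
) -> np.ndarray:
    """Per-subject SCN scalar for one seed.

    "cross_term": z(seed volume) * mean-over-ROIs GMV — the subject-level
    quantity whose group covariance the GLM slope measures. "roi_mean":
    the ROI-profile mean GMV alone.
    """
    profile = roi_means.to_numpy(float).mean(axis=1)
    if kind == "cross_term":
        return zscore(np.asarray(seed_volumes, float)) * profile
    if kind == "roi_mean":
        return profile
    raise ValueError(f"unknown SCN measure kind {kind!r}")


def correlation_screen(
    measures: pd.DataFrame,
    cohort: pd.DataFrame,
    metrics: tuple[str, ...] = CLINICAL_COLUMNS,
    group: str | None = "CS",
    q: float = 0.05,
    alpha_uncorrected: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full seed x clinical-metric partial-correlation grid for one group.

    ``measures`` is subjects x seeds, row-aligned to ``cohort``. Covariates
    are age, gender and scanner dummies. BH-FDR runs over the whole grid;
    uncorrected hits (p < alpha_uncorrected) are counted per metric and per
    seed. Returns (grid, counts_per_metric, counts_per_seed).
    """
    if not measures.index.equals(pd.Index(cohort["subject_id"])):
        measures = measures.loc[cohort["subject_id"]]
    if group is not None:
        keep = (cohort["group"].astype(str) == group).to_numpy()
        cohort = cohort.loc[keep].reset_index(drop=True)
        measures = measures.iloc[keep.nonzero()[0]]
    conf, conf_names = confound_columns(cohort)
    # drop TIV: the screen controls age, gender and scanner only
    keep_cols = [i for i, nm in enumerate(conf_names) if nm != "tiv_c"]
    Z = conf[:, keep_cols]
    rows = []
    for seed_name in measures.columns:
        x = measures[seed_name].to_numpy(float)
        for metric in metrics:
            if metric not in cohort.columns:
                continue
            y = cohort[metric].to_numpy(float)
            if not np.any(np.isfinite(y)):
                raise ValueError(f"metric {metric} entirely missing")
            try:
                rho, p, n_eff = spearman_partial(x, y, Z)
            except ValueError:
                rho, p, n_eff = np.nan, np.nan, 0
            rows.append(
                {"seed": seed_name, "metric": metric, "rho": rho, "p_raw": p,
                 "n_effective": n_eff}
            )
    grid = pd.DataFrame(rows)
    valid = grid["p_raw"].notna()
    grid["p_fdr"] = np.nan
    grid["fdr_significant"] = False
    if valid.any():
        adj, rej = fdr_bh(grid.loc[valid, "p_raw"].to_numpy(), q=q)
        grid.loc[valid, "p_fdr"] = adj
        grid.loc[valid, "fdr_significant"] = rej
    grid["uncorrected_hit"] = grid["p_raw"] < alpha_uncorrected
    per_metric = (
        grid.groupby("metric", observed=True)["uncorrected_hit"].sum().rename("n_hits").reset_index()
    )
    per_seed = (
        grid.groupby("seed", observed=True)["uncorrected_hit"].sum().rename("n_hits").reset_index()
    )
    return grid, per_metric, per_seed
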