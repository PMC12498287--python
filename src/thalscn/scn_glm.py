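"""Seed-based structural covariance GLM.

The per-voxel model regresses gray matter volume on group intercepts,
group-specific (z-scored) seed-volume slopes, and nuisance covariates:

    GMV_v = b1*I_CS + b2*I_NC + b3*z(vol)*I_CS + b4*z(vol)*I_NC
            + age_c + gender + scanner dummies + TIV_c + noise

b3 and b4 are the CS and NC covariance slopes between the seed structure's
volume and voxel GMV; the contrast of interest is b3 - b4. The same model
with a region's mean GMV as response gives the post-hoc ROI analysis, and
with subfield volume as response and group as the effect of interest gives
the subfield atrophy comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import GMVStack

LABEL_CS = "label_cs"
LABEL_NC = "label_nc"
VOL_CS = "vol_cs"
VOL_NC = "vol_nc"


def zscore(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0 and sample SD 1 (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("z-scoring needs n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant vector cannot be z-scored")
    return (x - x.mean()) / sd


@dataclass
class ScnDesign:
    """Design matrix for the covariance GLM, rows aligned to the cohort."""

    matrix: np.ndarray
    columns: list[str]
    seed_name: str = "seed"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.columns):
            raise ValueError("column names do not match matrix width")
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < self.matrix.shape[1]:
            raise ValueError(
                f"design is rank deficient (rank {rank} < {self.matrix.shape[1]} "
                f"columns: {self.columns})"
            )

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def df_resid(self) -> int:
        return self.n - self.matrix.shape[1]

    def contrast(self, plus: str, minus: str | None = None) -> np.ndarray:
        c = np.zeros(len(self.columns))
        c[self.columns.index(plus)] = 1.0
        if minus is not None:
            c[self.columns.index(minus)] -= 1.0
        return c

    @property
    def slope_contrast(self) -> np.ndarray:
        """The CS-minus-NC covariance-slope contrast [b3 - b4]."""
        return self.contrast(VOL_CS, VOL_NC)

    def reduced_matrix(self) -> np.ndarray:
        """Design without the seed-volume columns (group means + confounds)."""
        keep = [i for i, c in enumerate(self.columns) if c not in (VOL_CS, VOL_NC)]
        return self.matrix[:, keep]


def confound_columns(cohort: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Centered age/TIV, 0/1 gender (male=0) and K-1 scanner dummies.

    Scanner reference level is the first alphabetically; centering age and
    TIV makes the group intercepts interpretable as adjusted group means.
    """
    age = cohort["age"].to_numpy(dtype=float)
    tiv = cohort["tiv"].to_numpy(dtype=float)
    gender = (cohort["gender"].astype(str) == "female").to_numpy(dtype=float)
    cols = [age - age.mean(), gender]
    names = ["age_c", "gender"]
    scanners = sorted(set(cohort["scanner"].astype(str)))
    for s in scanners[1:]:
        cols.append((cohort["scanner"].astype(str) == s).to_numpy(dtype=float))
        names.append(f"scanner_{s}")
    cols.append(tiv - tiv.mean())
    names.append("tiv_c")
    return np.column_stack(cols), names


def build_scn_design(
    cohort: pd.DataFrame,
    seed_volumes: np.ndarray,
    seed_name: str = "seed",
    zscore_mode: str = "pooled",
) -> ScnDesign:
    """Assemble the covariance-GLM design for one seed structure.

    Seed volumes are z-scored over the pooled sample by default ("pooled");
    "per-group" standardizes within each group instead (changes what the
    slope contrast measures; exposed for sensitivity analyses).
    """
    vols = np.asarray(seed_volumes, dtype=float)
    if vols.size != len(cohort):
        raise ValueError("seed_volumes must align with cohort rows")
    is_cs = (cohort["group"].astype(str) == "CS").to_numpy()
    is_nc = (cohort["group"].astype(str) == "NC").to_numpy()
    if not is_cs.any() or not is_nc.any():
        raise ValueError("both groups must be non-empty")
    if zscore_mode == "pooled":
        z = zscore(vols)
    elif zscore_mode == "per-group":
        z = np.empty_like(vols)
        z[is_cs] = zscore(vols[is_cs])
        z[is_nc] = zscore(vols[is_nc])
    else:
        raise ValueError(f"unknown zscore_mode {zscore_mode!r}")
    conf, conf_names = confound_columns(cohort)
    X = np.column_stack(
        [
            is_cs.astype(float),
            is_nc.astype(float),
            z * is_cs,
            z * is_nc,
            conf,
        ]
    )
    cols = [LABEL_CS, LABEL_NC, VOL_CS, VOL_NC, *conf_names]
    return ScnDesign(matrix=X, columns=cols, seed_name=seed_name)


@dataclass
class ScnFitResult:
    """Per-voxel OLS fit of the covariance GLM over the analysis mask."""

    design: ScnDesign
    mask: np.ndarray  # flat boolean, full grid
    beta: np.ndarray  # (p, n_mask_voxels)
    sigma2: np.ndarray  # (n_mask_voxels,) residual variance (df denominator)
    df: int
    contrast: np.ndarray
    contrast_estimate: np.ndarray = field(init=False)
    t_masked: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        c = self.contrast
        XtX_inv = np.linalg.inv(self.design.matrix.T @ self.design.matrix)
        cvc = float(c @ XtX_inv @ c)
        self.contrast_estimate = c @ self.beta
        se = np.sqrt(self.sigma2 * cvc)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.contrast_estimate / se
        t[se == 0] = np.nan  # constant-GMV voxels carry no information
        self.t_masked = t

    def t_map(self) -> np.ndarray:
        """Full-grid flat t-map; NaN outside the mask or where GMV is constant."""
        out = np.full(self.mask.size, np.nan)
        out[self.mask] = self.t_masked
        return out

    def beta_map(self, column: str) -> np.ndarray:
        out = np.full(self.mask.size, np.nan)
        out[self.mask] = self.beta[self.design.columns.index(column)]
        return out

    def p_one_tailed(self) -> np.ndarray:
        """Upper-tail p of the contrast t, over mask voxels (NaN preserved)."""
        return stats.t.sf(self.t_masked, self.df)


def _ols_stack(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS of every column of Y on X; returns (beta, sigma2, df)."""
    n, p = X.shape
    df = n - np.linalg.matrix_rank(X)
    if df <= 0:
        raise ValueError(f"non-positive residual df ({df})")
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    return beta, sigma2, df


def fit_scn(
    stack: GMVStack,
    design: ScnDesign,
    contrast: np.ndarray | None = None,
) -> ScnFitResult:
    """Mass-univariate OLS of the covariance GLM over the analysis mask.

    ``contrast`` defaults to the slope contrast [b3 - b4]; t is computed as
    c'beta / sqrt(sigma2 * c'(X'X)^-1 c) with df = n - rank(X).
    """
    if stack.n_subjects != design.n:
        raise ValueError("stack and design have different numbers of subjects")
    Y = stack.data[:, stack.mask]
    beta, sigma2, df = _ols_stack(design.matrix, Y)
    # constant-GMV voxels carry no information: force sigma2 to exact zero so
    # the t-map is NaN there rather than rounding-noise garbage
    sigma2[np.ptp(Y, axis=0) == 0] = 0.0
    c = design.slope_contrast if contrast is None else np.asarray(contrast, float)
    return ScnFitResult(
        design=design, mask=stack.mask.copy(), beta=beta, sigma2=sigma2, df=df, contrast=c
    )


def compare_subfield_volumes(
    cohort: pd.DataFrame,
    subfields: pd.DataFrame,
    q: float = 0.05,
    fdr_family: str = "pooled",
) -> pd.DataFrame:
    """Group effect on each (hemisphere, subfield) volume, with BH-FDR.

    One OLS per subfield: volume ~ group + age + gender + scanner + TIV.
    The reported t is for the CS-minus-NC group effect (negative t means
    atrophy in patients). ``fdr_family`` is "pooled" (one family across all
    hemispheres, the default) or "per-hemisphere".
    """
    from .multiplicity import fdr_bh

    conf, conf_names = confound_columns(cohort)
    is_cs = (cohort["group"].astype(str) == "CS").to_numpy(dtype=float)
    if is_cs.sum() == 0 or is_cs.sum() == len(cohort):
        raise ValueError("both groups must be non-empty")
    X = np.column_stack([np.ones(len(cohort)), is_cs, conf])
    names = ["intercept", "group_cs", *conf_names]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient subfield design ({names})")
    df = len(cohort) - rank
    XtX_inv = np.linalg.inv(X.T @ X)
    cvc = XtX_inv[1, 1]
    rows = []
    sub = subfields[subfields["subfield"] != "whole_thalamus"]
    for (hemi, name), grp in sub.groupby(["hemisphere", "subfield"], observed=True, sort=True):
        vols = grp.set_index("subject_id")["volume_mm3"].loc[
            cohort["subject_id"].tolist()
        ].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, vols, rcond=None)
        resid = vols - X @ beta
        sigma2 = resid @ resid / df
        t = beta[1] / np.sqrt(sigma2 * cvc) if sigma2 > 0 else np.nan
        p = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
        rows.append({"hemisphere": hemi, "subfield": name, "t": t, "p": p})
    out = pd.DataFrame(rows)
    if fdr_family == "pooled":
        adj, rej = fdr_bh(out["p"].to_numpy(), q=q)
        out["p_fdr"] = adj
        out["significant"] = rej
    elif fdr_family == "per-hemisphere":
        out["p_fdr"] = np.nan
        out["significant"] = False
        for hemi in out["hemisphere"].unique():
            m = out["hemisphere"] == hemi
            adj, rej = fdr_bh(out.loc[m, "p"].to_numpy(), q=q)
            out.loc[m, "p_fdr"] = adj
            out.loc[m, "significant"] = rej
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    return out
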