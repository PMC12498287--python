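"""Synthetic cohorts with the statistical structure the covariance GLM assumes.

Every downstream stage is exercised against data with known ground truth:
group-specific seed-to-voxel covariance slopes planted in rectangular
blobs, additive confound effects (age, gender, scanner offset, TIV),
spatially smooth Gaussian noise, focal right-hemisphere lesions that zero
patients' GMV, an integer-labeled atlas whose regions contain the planted
blobs, and clinical scores linked (weakly, by default) to subfield volumes.

The default design mirrors the study conditions: 45 patients / 93 controls
from three scanners, a 16x16x16 grid at 1.5 mm, 6 mm FWHM noise smoothing,
25 thalamic subfields per hemisphere with diffuse ipsilesional atrophy in
patients, and a seed whose patient-group covariance slope exceeds the
control slope (2 vs 1 GMV units per SD of seed volume) at contrast
signal-to-noise |slope_cs - slope_nc| / noise_sd = 1.

Effects are block-shaped and the smoothing is applied to the noise field
only, so the planted slopes are exactly recoverable on noise-free data.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io_core import CLINICAL_COLUMNS, GMVStack, ImageGrid, validate_cohort

#: FreeSurfer-style nomenclature for the 25 thalamic subfields per hemisphere.
SUBFIELD_NAMES = (
    "AV", "CL", "CM", "CeM", "LD", "LGN", "LP", "L_Sg", "MDl", "MDm",
    "MGN", "MV_re", "Pc", "Pf", "Pt", "PuA", "PuI", "PuL", "PuM",
    "VA", "VAmc", "VLa", "VLp", "VM", "VPL",
)

HEMISPHERES = ("ipsi", "contra")

#: Plausible mean subfield volumes (mm^3); magnitudes follow histological
#: atlas proportions (large pulvinar/VPL/MD, small midline nuclei).
_BASE_VOLUMES = {
    "AV": 130, "CL": 35, "CM": 240, "CeM": 80, "LD": 28, "LGN": 260,
    "LP": 120, "L_Sg": 27, "MDl": 280, "MDm": 680, "MGN": 110,
    "MV_re": 12, "Pc": 4, "Pf": 55, "Pt": 7, "PuA": 220, "PuI": 230,
    "PuL": 180, "PuM": 980, "VA": 400, "VAmc": 30, "VLa": 600,
    "VLp": 850, "VM": 21, "VPL": 800,
}


@dataclass(frozen=True)
class EffectSpec:
    """A planted seed-to-voxel covariance effect in a rectangular blob."""

    subfield: str
    hemisphere: str
    center: tuple[int, int, int]
    half_size: int
    slope_cs: float
    slope_nc: float

    def blob_mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        lo = [c - self.half_size for c in self.center]
        hi = [c + self.half_size + 1 for c in self.center]
        if any(a < 0 for a in lo) or any(b > s for b, s in zip(hi, shape)):
            raise ValueError(f"effect blob {self.center}±{self.half_size} leaves grid {shape}")
        m = np.zeros(shape, dtype=bool)
        m[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
        return m


@dataclass
class SimulationDesign:
    """All knobs of the synthetic cohort generator."""

    n_cs: int = 45
    n_nc: int = 93
    shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 1.5
    smoothing_fwhm_mm: float = 6.0
    noise_sd: float = 1.0  # per-voxel GMV noise SD after smoothing
    baseline_gmv: float = 10.0
    effects: list[EffectSpec] = field(
        default_factory=lambda: [
            EffectSpec("VPL", "ipsi", center=(4, 8, 8), half_size=2,
                       slope_cs=2.0, slope_nc=1.0)
        ]
    )
    # confound effects on GMV (per unit of the centered covariate)
    age_coef: float = -0.02
    gender_coef: float = 0.1
    scanner_offsets: tuple[float, ...] = (0.0, 0.15, -0.1)
    tiv_coef: float = 2e-7
    # subfield volume model
    volume_cv: float = 0.20
    volume_correlation: float = 0.3  # inter-subfield correlation via a subject factor
    ipsi_atrophy: float = 0.20  # fractional CS volume loss, ipsilesional subfields
    contra_atrophy: float = 0.0
    # lesions (right hemisphere = ipsilesional; affine is RAS with +x at high i)
    lesion_center: tuple[int, int, int] = (11, 8, 7)
    lesion_jitter: int = 1
    lesion_radius_vox: tuple[float, float] = (1.2, 2.2)
    # clinical model: score -> (subfield, hemisphere, coefficient in score units per SD)
    clinical_links: dict = field(
        default_factory=lambda: {
            "RAVLT_SR": ("MDm", "ipsi", 2.0),
            "S_ACC": ("L_Sg", "ipsi", 0.01),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cs < 3 or self.n_nc < 3:
            raise ValueError("need at least 3 subjects per group")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for e in self.effects:
            e.blob_mask(self.shape)  # validates bounds
        # overlapping blobs with different slopes are contradictory
        for i, a in enumerate(self.effects):
            for b in self.effects[i + 1 :]:
                overlap = a.blob_mask(self.shape) & b.blob_mask(self.shape)
                if overlap.any() and (a.slope_cs, a.slope_nc) != (b.slope_cs, b.slope_nc):
                    raise ValueError(
                        f"overlapping effect blobs with contradictory slopes: {a} vs {b}"
                    )

    @property
    def n_total(self) -> int:
        return self.n_cs + self.n_nc

    def grid(self) -> ImageGrid:
        v = self.voxel_size_mm
        affine = np.diag([v, v, v, 1.0])
        affine[:3, 3] = -(np.array(self.shape) - 1) / 2.0 * v
        return ImageGrid(shape=self.shape, affine=affine)

    def with_snr(self, snr: float) -> "SimulationDesign":
        """Copy with noise_sd set so |slope_cs - slope_nc| / noise_sd = snr."""
        delta = max(abs(e.slope_cs - e.slope_nc) for e in self.effects)
        return replace(self, noise_sd=delta / snr)

    def to_yaml(self, path) -> None:
        import dataclasses

        import yaml

        d = dataclasses.asdict(self)
        d["effects"] = [dataclasses.asdict(e) for e in self.effects]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationDesign":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["effects"] = [
            EffectSpec(**{**e, "center": tuple(e["center"])}) for e in d.get("effects", [])
        ]
        for key in ("shape", "scanner_offsets", "lesion_center", "lesion_radius_vox"):
            if key in d:
                d[key] = tuple(d[key])
        d["clinical_links"] = {
            k: (v[0], v[1], float(v[2])) for k, v in d.get("clinical_links", {}).items()
        }
        return cls(**d)


def null_design(**kwargs) -> SimulationDesign:
    """Study-condition design with no group difference in covariance slopes."""
    base = SimulationDesign(**kwargs)
    base.effects = [replace(e, slope_cs=e.slope_nc) for e in base.effects]
    return base


@dataclass
class SimulatedCohort:
    cohort: pd.DataFrame
    stack: GMVStack
    subfields: pd.DataFrame
    lesion_masks: dict[str, np.ndarray]  # subject_id -> flat boolean
    atlas_labels: np.ndarray  # flat int
    atlas_names: dict[int, str]
    truth: dict


def smoothed_noise_field(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    fwhm_mm: float,
    voxel_size_mm: float,
) -> np.ndarray:
    """Unit-variance stationary Gaussian field with the requested FWHM.

    White noise is convolved with a Gaussian kernel (wrap-around boundary,
    so the field is exactly stationary) and rescaled by the kernel's L2
    norm, giving marginal variance 1 at every voxel.
    """
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    white = rng.standard_normal(shape)
    if sigma_vox == 0:
        return white
    smooth = gaussian_filter(white, sigma_vox, mode="wrap")
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    kernel = gaussian_filter(impulse, sigma_vox, mode="wrap")
    norm = np.sqrt((kernel**2).sum())
    return smooth / norm


def estimate_smoothness_fwhm(field: np.ndarray, voxel_size_mm: float) -> float:
    """Estimate the generating-kernel FWHM of a smooth field from its lag-1
    autocorrelation.

    For white noise convolved with a Gaussian of SD sigma, the field
    autocorrelation at lag d is exp(-d^2 / (4 sigma^2)); inverting at d = 1
    voxel (averaged over the three axes) gives sigma and hence FWHM in mm.
    """
    f = np.asarray(field, float)
    f = f - f.mean()
    denom = (f**2).mean()
    rs = []
    for ax in range(3):
        shifted = np.roll(f, 1, axis=ax)
        rs.append((f * shifted).mean() / denom)
    r = float(np.mean(rs))
    if not 0 < r < 1:
        raise ValueError(f"lag-1 autocorrelation {r:.3f} outside (0, 1); field too rough")
    sigma_vox = np.sqrt(-1.0 / (4.0 * np.log(r)))
    return float(2.0 * np.sqrt(2.0 * np.log(2.0)) * sigma_vox * voxel_size_mm)


def _sphere_mask(shape, center, radius) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def _simulate_demographics(design: SimulationDesign, rng: np.random.Generator) -> pd.DataFrame:
    n = design.n_total
    groups = ["CS"] * design.n_cs + ["NC"] * design.n_nc
    ids = [f"sub-{i:03d}" for i in range(n)]
    age = rng.normal(55.5, 7.4, n).clip(30, 85)
    # male fractions follow the study margins (27/45 CS, 50/93 NC)
    p_male = np.where(np.array(groups) == "CS", 27 / 45, 50 / 93)
    gender = np.where(rng.random(n) < p_male, "male", "female")
    scanner = rng.choice([f"scanner{k}" for k in range(len(design.scanner_offsets))], n)
    tiv = rng.normal(1.45e6, 1.3e5, n).clip(9e5, None)
    return validate_cohort(
        pd.DataFrame(
            {
                "subject_id": ids,
                "group": groups,
                "age": age,
                "gender": gender,
                "scanner": scanner,
                "tiv": tiv,
            }
        )
    )


def _simulate_subfield_volumes(
    design: SimulationDesign, cohort: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(cohort)
    is_cs = (cohort["group"].astype(str) == "CS").to_numpy()
    rho = design.volume_correlation
    subject_factor = rng.standard_normal(n)
    rows = []
    for hemi in HEMISPHERES:
        atrophy = design.ipsi_atrophy if hemi == "ipsi" else design.contra_atrophy
        for name in SUBFIELD_NAMES:
            base = _BASE_VOLUMES[name]
            noise = rng.standard_normal(n)
            rel = design.volume_cv * (np.sqrt(rho) * subject_factor + np.sqrt(1 - rho) * noise)
            vol = base * (1.0 + rel)
            vol = np.where(is_cs, vol * (1.0 - atrophy), vol)
            vol = np.clip(vol, base * 0.2, None)
            for sid, v in zip(cohort["subject_id"], vol):
                rows.append(
                    {"subject_id": sid, "hemisphere": hemi, "subfield": name,
                     "volume_mm3": float(v)}
                )
    df = pd.DataFrame(rows)
    totals = (
        df.groupby(["subject_id", "hemisphere"], observed=True, sort=False)["volume_mm3"]
        .sum()
        .reset_index()
    )
    totals["subfield"] = "whole_thalamus"
    return pd.concat([df, totals[df.columns.tolist()]], ignore_index=True)


def simulate_clinical_scores(
    design: SimulationDesign,
    cohort: pd.DataFrame,
    subfields: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Clinical scores as linear functions of chosen subfield volumes plus noise.

    Baselines follow the study's score ranges per group; the coefficients in
    ``design.clinical_links`` add score-units-per-SD-of-volume dependence.
    Accuracy columns are clipped to [0, 1]; reaction times are kept positive.
    """
    n = len(cohort)
    is_cs = (cohort["group"].astype(str) == "CS").to_numpy()
    base = {
        # (CS mean, NC mean, residual SD)
        "FMA": (92.0, 100.0, 8.0),
        "RAVLT_SR": (42.8, 49.5, 9.0),
        "RAVLT_LR": (10.7, 12.0, 2.5),
        "N_ACC": (0.90, 0.92, 0.05),
        "N_RT": (860.0, 790.0, 140.0),
        "S_ACC": (0.90, 0.92, 0.05),
        "S_RT": (890.0, 810.0, 150.0),
    }
    out = {}
    for score in CLINICAL_COLUMNS:
        mu_cs, mu_nc, sd = base[score]
        vals = np.where(is_cs, mu_cs, mu_nc) + rng.normal(0.0, sd, n)
        if score in design.clinical_links:
            name, hemi, coef = design.clinical_links[score]
            sel = subfields[
                (subfields["subfield"] == name) & (subfields["hemisphere"] == hemi)
            ].set_index("subject_id")["volume_mm3"]
            v = sel.loc[cohort["subject_id"].tolist()].to_numpy(dtype=float)
            z = (v - v.mean()) / v.std(ddof=1)
            vals = vals + coef * z
        if score == "FMA":
            vals = np.clip(vals, 0.0, 100.0)
        if score.endswith("_ACC"):
            vals = np.clip(vals, 0.0, 1.0)
        if score.endswith("_RT"):
            vals = np.clip(vals, 100.0, None)
        out[score] = vals
    return pd.DataFrame(out, index=cohort.index)


def _paint_atlas(
    design: SimulationDesign,
) -> tuple[np.ndarray, dict[int, str], dict[str, int]]:
    """Boxes around each effect blob (so overlap ratios exceed 10%) plus
    distractor regions away from effects and lesions."""
    shape = design.shape
    labels = np.zeros(shape, dtype=int)
    names: dict[int, str] = {}
    blob_region: dict[str, int] = {}
    next_id = 1
    occupied = np.zeros(shape, dtype=bool)
    for e in design.effects:
        half = e.half_size + 1  # region strictly contains the blob
        lo = [max(0, c - half) for c in e.center]
        hi = [min(s, c + half + 1) for c, s in zip(e.center, shape)]
        labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = next_id
        occupied[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
        names[next_id] = f"target_{e.subfield}_{e.hemisphere}"
        blob_region[f"{e.subfield}:{e.hemisphere}"] = next_id
        next_id += 1
    # distractor boxes in free corners
    for corner in [(1, 1, 1), (1, 12, 12), (12, 1, 12)]:
        lo = corner
        hi = [min(s, c + 3) for c, s in zip(corner, shape)]
        box = np.zeros(shape, dtype=bool)
        box[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
        if (box & occupied).any():
            continue
        labels[box] = next_id
        names[next_id] = f"distractor_{next_id}"
        occupied |= box
        next_id += 1
    return labels.reshape(-1), names, blob_region


def simulate_cohort(
    design: SimulationDesign, seed: int | None = None
) -> SimulatedCohort:
    """Generate a full synthetic cohort with a ground-truth record.

    GMV at voxel v of subject i is
    baseline + sum_effects slope_group(i) * z(seed volume_i) * blob(v)
    + confound terms + smoothed Gaussian noise; patients additionally get a
    spherical right-hemisphere lesion that zeroes their GMV inside it.
    Identical (design, seed) pairs give bit-identical outputs.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    grid = design.grid()
    cohort = _simulate_demographics(design, rng)
    subfields = _simulate_subfield_volumes(design, cohort, rng)
    n = len(cohort)
    is_cs = (cohort["group"].astype(str) == "CS").to_numpy()

    # confound contribution (centered covariates; scanner additive offsets)
    age = cohort["age"].to_numpy(float)
    tiv = cohort["tiv"].to_numpy(float)
    female = (cohort["gender"].astype(str) == "female").to_numpy(float)
    scanner_idx = (
        cohort["scanner"].astype(str).str.replace("scanner", "", regex=False).astype(int)
    ).to_numpy()
    subj_offset = (
        design.age_coef * (age - age.mean())
        + design.gender_coef * female
        + np.asarray(design.scanner_offsets)[scanner_idx]
        + design.tiv_coef * (tiv - tiv.mean())
    )

    data = np.full((n, grid.n_voxels), design.baseline_gmv)
    data += subj_offset[:, None]

    truth_effects = []
    for e in design.effects:
        sel = subfields[
            (subfields["subfield"] == e.subfield) & (subfields["hemisphere"] == e.hemisphere)
        ].set_index("subject_id")["volume_mm3"]
        v = sel.loc[cohort["subject_id"].tolist()].to_numpy(float)
        z = (v - v.mean()) / v.std(ddof=1)  # pooled z-score, as the design matrix uses
        slope = np.where(is_cs, e.slope_cs, e.slope_nc)
        blob = e.blob_mask(design.shape).reshape(-1)
        data[:, blob] += (slope * z)[:, None]
        truth_effects.append(
            {
                "subfield": e.subfield,
                "hemisphere": e.hemisphere,
                "slope_cs": e.slope_cs,
                "slope_nc": e.slope_nc,
                "blob_voxels": np.flatnonzero(blob).tolist(),
            }
        )

    if design.noise_sd > 0:
        for i in range(n):
            data[i] += design.noise_sd * smoothed_noise_field(
                rng, design.shape, design.smoothing_fwhm_mm, design.voxel_size_mm
            ).reshape(-1)

    # lesions: spherical blobs in the right (ipsilesional) hemisphere
    lesion_masks: dict[str, np.ndarray] = {}
    lo_r, hi_r = design.lesion_radius_vox
    nx = design.shape[0]
    for i in np.flatnonzero(is_cs):
        center = np.array(design.lesion_center) + rng.integers(
            -design.lesion_jitter, design.lesion_jitter + 1, 3
        )
        center[0] = np.clip(center[0], nx // 2 + int(np.ceil(hi_r)), nx - 1 - int(np.ceil(hi_r)))
        center[1:] = np.clip(center[1:], int(np.ceil(hi_r)), np.array(design.shape[1:]) - 1 - int(np.ceil(hi_r)))
        radius = rng.uniform(lo_r, hi_r)
        m = _sphere_mask(design.shape, center, radius).reshape(-1)
        data[i, m] = 0.0
        lesion_masks[cohort["subject_id"].iloc[i]] = m

    clinical = simulate_clinical_scores(design, cohort, subfields, rng)
    cohort = pd.concat([cohort, clinical], axis=1)

    atlas_labels, atlas_names, blob_region = _paint_atlas(design)
    stack = GMVStack(
        grid=grid,
        data=data,
        mask=np.ones(grid.n_voxels, dtype=bool),
        subject_ids=cohort["subject_id"].tolist(),
    )
    truth = {
        "design": copy.deepcopy(design),
        "effects": truth_effects,
        "blob_region": blob_region,
        "noise_sd": design.noise_sd,
        "confounds": {
            "age_coef": design.age_coef,
            "gender_coef": design.gender_coef,
            "scanner_offsets": list(design.scanner_offsets),
            "tiv_coef": design.tiv_coef,
        },
        "ipsi_atrophy": design.ipsi_atrophy,
        "contra_atrophy": design.contra_atrophy,
        "clinical_links": dict(design.clinical_links),
    }
    return SimulatedCohort(
        cohort=cohort,
        stack=stack,
        subfields=subfields,
        lesion_masks=lesion_masks,
        atlas_labels=atlas_labels,
        atlas_names=atlas_names,
        truth=truth,
    )
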