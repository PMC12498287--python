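"""Readers/writers for the image and table formats the pipeline touches.

Images are NIfTI-1 (via nibabel) on a shared analysis grid; tables are TSV
with a header row. All readers validate grid compatibility and categorical
levels so downstream stages can assume clean inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: Maximum absolute elementwise affine difference (mm) still treated as the
#: same grid; header jitter below this has no physical meaning.
AFFINE_TOL = 1e-4

GROUP_LEVELS = ("CS", "NC")
GENDER_LEVELS = ("male", "female")

#: Clinical score columns carried by the cohort table (missing allowed).
CLINICAL_COLUMNS = ("FMA", "RAVLT_SR", "RAVLT_LR", "N_ACC", "N_RT", "S_ACC", "S_RT")

REQUIRED_COHORT_COLUMNS = ("subject_id", "group", "age", "gender", "scanner", "tiv")


class GridError(ValueError):
    """Raised when images do not share the analysis grid."""


@dataclass(frozen=True)
class ImageGrid:
    """A 3D voxel grid with its world (mm) affine.

    Voxel indices are 0-based; world coordinates follow the NIfTI affine.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the 3x3 affine block)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def matches(self, other: "ImageGrid", tol: float = AFFINE_TOL) -> bool:
        return self.shape == other.shape and bool(
            np.max(np.abs(self.affine - other.affine)) <= tol
        )

    @classmethod
    def from_image(cls, img: nib.spatialimages.SpatialImage) -> "ImageGrid":
        return cls(shape=tuple(img.shape[:3]), affine=np.asarray(img.affine))


@dataclass
class GMVStack:
    """Subjects x voxels gray-matter-volume array on a shared grid.

    ``data`` is 2D (n_subjects, n_voxels) in C voxel order; ``mask`` flags
    the voxels that enter any analysis. Subject order matches the cohort
    table used to build the design matrix.
    """

    grid: ImageGrid
    data: np.ndarray
    mask: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool).reshape(-1)
        if self.data.ndim != 2:
            raise ValueError("GMV data must be 2D (subjects x voxels)")
        if self.data.shape[1] != self.grid.n_voxels:
            raise ValueError("data voxel count does not match grid")
        if self.mask.size != self.grid.n_voxels:
            raise ValueError("mask size does not match grid")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:03d}" for i in range(self.data.shape[0])]
        if not np.all(np.isfinite(self.data[:, self.mask])):
            raise ValueError("non-finite GMV inside the analysis mask")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def volume(self, subject_index: int) -> np.ndarray:
        """The 3D image of one subject."""
        return self.data[subject_index].reshape(self.grid.shape)


def _check_grid(img_grid: ImageGrid, ref: ImageGrid, name: str) -> None:
    if img_grid.shape != ref.shape:
        raise GridError(f"{name}: shape {img_grid.shape} != reference {ref.shape}")
    diff = float(np.max(np.abs(img_grid.affine - ref.affine)))
    if diff > AFFINE_TOL:
        raise GridError(
            f"{name}: affine differs from reference by {diff:.2e} mm (tol {AFFINE_TOL})"
        )


def read_gmv_stack(
    image_paths: Sequence[str | Path],
    mask_path: str | Path | None = None,
) -> GMVStack:
    """Read per-subject GMV images into a stack, preserving order.

    Without an explicit mask, the analysis mask defaults to voxels whose GMV
    varies across subjects (nonzero variance).
    """
    if not image_paths:
        raise ValueError("no images given")
    imgs = []
    ref: ImageGrid | None = None
    for p in image_paths:
        img = nib.load(str(p))
        grid = ImageGrid.from_image(img)
        if ref is None:
            ref = grid
        else:
            _check_grid(grid, ref, str(p))
        imgs.append(np.asarray(img.dataobj, dtype=float).reshape(-1))
    data = np.vstack(imgs)
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        _check_grid(ImageGrid.from_image(mimg), ref, str(mask_path))
        mask = np.asarray(mimg.dataobj).reshape(-1) > 0
    else:
        mask = np.var(data, axis=0) > 0
    ids = [Path(p).name.split(".")[0] for p in image_paths]
    return GMVStack(grid=ref, data=data, mask=mask, subject_ids=ids)


def write_gmv_stack(stack: GMVStack, out_dir: str | Path) -> list[Path]:
    """Write one NIfTI per subject plus the analysis mask; returns image paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, sid in enumerate(stack.subject_ids):
        img = nib.Nifti1Image(stack.volume(i).astype(np.float64), stack.grid.affine)
        p = out / f"{sid}.nii.gz"
        nib.save(img, p)
        paths.append(p)
    mask_img = nib.Nifti1Image(
        stack.mask.reshape(stack.grid.shape).astype(np.uint8), stack.grid.affine
    )
    nib.save(mask_img, out / "analysis_mask.nii.gz")
    return paths


def write_image(
    data: np.ndarray, grid: ImageGrid, path: str | Path, dtype=np.float64
) -> Path:
    arr = np.asarray(data).reshape(grid.shape).astype(dtype)
    nib.save(nib.Nifti1Image(arr, grid.affine), str(path))
    return Path(path)


def read_mask(path: str | Path, grid: ImageGrid | None = None) -> np.ndarray:
    img = nib.load(str(path))
    if grid is not None:
        _check_grid(ImageGrid.from_image(img), grid, str(path))
    return np.asarray(img.dataobj).reshape(-1) > 0


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the cohort TSV (one row per subject).

    Categorical levels are checked; missing clinical scores stay missing
    (pairwise deletion is each analysis's responsibility, never imputation).
    """
    df = pd.read_csv(path, sep="\t")
    return validate_cohort(df)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id values: {dupes}")
    bad_group = set(df["group"]) - set(GROUP_LEVELS)
    if bad_group:
        raise ValueError(f"unknown group levels: {sorted(bad_group)}")
    bad_gender = set(df["gender"]) - set(GENDER_LEVELS)
    if bad_gender:
        raise ValueError(f"unknown gender levels: {sorted(bad_gender)}")
    if (df["tiv"] <= 0).any():
        raise ValueError("tiv must be positive")
    df = df.copy()
    df["group"] = pd.Categorical(df["group"], categories=list(GROUP_LEVELS))
    df["gender"] = pd.Categorical(df["gender"], categories=list(GENDER_LEVELS))
    df["scanner"] = pd.Categorical(df["scanner"])
    return df


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_subfield_table(path: str | Path) -> pd.DataFrame:
    """Read the long-format subfield volume TSV.

    Columns: subject_id, hemisphere ('ipsi'/'contra'), subfield, volume_mm3.
    Whole-thalamus rows use subfield == 'whole_thalamus'.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "hemisphere", "subfield", "volume_mm3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subfield table missing columns: {sorted(missing)}")
    if (df["volume_mm3"] <= 0).any():
        raise ValueError("subfield volumes must be positive")
    counts = df.groupby(["subject_id", "hemisphere"], observed=True)["subfield"].nunique()
    if counts.nunique() > 1:
        raise ValueError("inconsistent subfield set across subjects/hemispheres")
    return df


def subfield_vector(
    table: pd.DataFrame,
    subject_ids: Sequence[str],
    subfield: str,
    hemisphere: str,
) -> np.ndarray:
    """Seed-volume vector aligned to ``subject_ids`` for one (subfield, hemisphere)."""
    sel = table[(table["subfield"] == subfield) & (table["hemisphere"] == hemisphere)]
    if sel.empty:
        raise KeyError(f"no rows for subfield={subfield!r} hemisphere={hemisphere!r}")
    by_subject = sel.set_index("subject_id")["volume_mm3"]
    try:
        return by_subject.loc[list(subject_ids)].to_numpy(dtype=float)
    except KeyError as e:  # pragma: no cover - defensive
        raise KeyError(f"subject missing from subfield table: {e}") from e


def read_atlas(
    path: str | Path,
    grid: ImageGrid | None = None,
    names: Mapping[int, str] | str | Path | None = None,
) -> tuple[np.ndarray, dict[int, str], dict[int, int]]:
    """Read an integer-labeled atlas image.

    Returns (flat label array, id->name map, id->voxel-count map). ``names``
    may be a mapping or a path to a JSON {id: name} sidecar; unnamed regions
    get ``region_<id>``.
    """
    img = nib.load(str(path))
    if grid is not None:
        _check_grid(ImageGrid.from_image(img), grid, str(path))
    data = np.asarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"atlas {path} has non-integer values")
    labels = np.round(data).astype(int).reshape(-1)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    sizes = {int(i): int(c) for i, c in zip(ids, counts)}
    name_map: dict[int, str] = {}
    if isinstance(names, (str, Path)):
        raw = json.loads(Path(names).read_text())
        name_map = {int(k): str(v) for k, v in raw.items()}
    elif names is not None:
        name_map = {int(k): str(v) for k, v in names.items()}
    region_names = {i: name_map.get(i, f"region_{i}") for i in sizes}
    return labels, region_names, sizes


def write_run_log(path: str | Path, **entries) -> Path:
    """Write a JSON run-log capturing parameters of an analysis step."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(entries, indent=2, default=_default) + "\n")
    return path
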