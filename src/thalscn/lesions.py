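"""Group lesion probability map and the lesion-exclusion analysis mask.

All patient lesion masks live on the shared analysis grid. Voxels lesioned
in ANY patient are removed from the analysis mask so every voxel-wise model
sees the same subjects (constant degrees of freedom across voxels).
"""

from __future__ import annotations

import warnings

import numpy as np


def _as_mask_array(masks) -> np.ndarray:
    arr = np.asarray([np.asarray(m, dtype=bool).reshape(-1) for m in masks])
    if arr.ndim != 2:
        raise ValueError("masks must be a list of equally-shaped boolean images")
    return arr


def lesion_probability_map(masks, allow_empty: bool = False) -> np.ndarray:
    """Per-voxel fraction of patients whose lesion covers the voxel.

    value(v) = #{patients with lesion at v} / n_patients, in [0, 1].
    """
    arr = _as_mask_array(masks)
    if arr.shape[0] < 1:
        raise ValueError("need at least one lesion mask")
    empty = ~arr.any(axis=1)
    if empty.any() and not allow_empty:
        raise ValueError(
            f"{int(empty.sum())} empty lesion mask(s); pass allow_empty=True to accept"
        )
    return arr.sum(axis=0) / arr.shape[0]


def lesion_exclusion_mask(
    analysis_mask: np.ndarray, masks, allow_empty: bool = False
) -> np.ndarray:
    """Analysis mask minus the union of all patients' lesions."""
    base = np.asarray(analysis_mask, dtype=bool).reshape(-1)
    arr = _as_mask_array(masks)
    if arr.shape[1] != base.size:
        raise ValueError("lesion masks and analysis mask are on different grids")
    empty = ~arr.any(axis=1)
    if empty.any() and not allow_empty:
        raise ValueError(
            f"{int(empty.sum())} empty lesion mask(s); pass allow_empty=True to accept"
        )
    out = base & ~arr.any(axis=0)
    if base.any() and not out.any():
        warnings.warn("lesion union covers the entire analysis mask", stacklevel=2)
    return out


def lesion_volumes_mm3(masks, voxel_volume: float) -> np.ndarray:
    """Per-patient lesion volume in mm^3."""
    arr = _as_mask_array(masks)
    return arr.sum(axis=1) * float(voxel_volume)
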