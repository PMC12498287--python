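"""Convenience composition of the full seed-SCN analysis chain.

Thin glue used by the analysis drivers, the test suite and the acceptance
script: lesion-exclude the mask, build the per-seed design, run the
permutation cluster inference, and (optionally) the ROI follow-up.
"""

from __future__ import annotations

import numpy as np

from .io_core import subfield_vector
from .lesions import lesion_exclusion_mask
from .multiplicity import ClusterResult, cluster_fwe_permutation
from .roi import run_roi_pipeline
from .scn_glm import ScnDesign, build_scn_design
from .synthetic import SimulatedCohort


def apply_lesion_exclusion(sim: SimulatedCohort) -> np.ndarray:
    """Replace the cohort stack's mask with the lesion-excluded one."""
    if sim.lesion_masks:
        sim.stack.mask = lesion_exclusion_mask(
            sim.stack.mask, list(sim.lesion_masks.values())
        )
    return sim.stack.mask


def seed_design(
    sim: SimulatedCohort, subfield: str, hemisphere: str, **kwargs
) -> ScnDesign:
    vols = subfield_vector(sim.subfields, sim.cohort["subject_id"], subfield, hemisphere)
    return build_scn_design(sim.cohort, vols, f"{subfield}_{hemisphere}", **kwargs)


def seed_cluster_analysis(
    sim: SimulatedCohort,
    subfield: str,
    hemisphere: str,
    B: int = 1000,
    seed: int = 0,
    p_voxel: float = 0.001,
    **kwargs,
) -> tuple[ScnDesign, ClusterResult]:
    """Design + permutation cluster inference for one seed structure.

    Assumes ``apply_lesion_exclusion`` has already been applied to the stack.
    """
    design = seed_design(sim, subfield, hemisphere)
    result = cluster_fwe_permutation(
        sim.stack, design, p_voxel=p_voxel, B=B, seed=seed, **kwargs
    )
    return design, result


def full_pipeline(
    sim: SimulatedCohort,
    seeds: list[tuple[str, str]],
    B: int = 1000,
    seed: int = 0,
    alpha_fwe: float = 0.05,
):
    """Fit -> clusters -> ROI selection -> post-hoc for a list of seeds.

    Returns (designs, cluster_results, overlap_report, roi_means, posthoc).
    """
    apply_lesion_exclusion(sim)
    designs, results = {}, {}
    for i, (sf, hemi) in enumerate(seeds):
        name = f"{sf}_{hemi}"
        designs[name], results[name] = seed_cluster_analysis(
            sim, sf, hemi, B=B, seed=seed + i
        )
    report, means, posthoc = run_roi_pipeline(
        results,
        sim.atlas_labels,
        sim.atlas_names,
        sim.stack,
        designs,
        analysis_mask=sim.stack.mask,
        alpha_fwe=alpha_fwe,
    )
    return designs, results, report, means, posthoc
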