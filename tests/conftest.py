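import numpy as np
import pytest

from thalscn.pipeline import apply_lesion_exclusion, seed_cluster_analysis
from thalscn.synthetic import SimulationDesign, simulate_cohort


@pytest.fixture(scope="session")
def snr1_sim():
    """Study-condition cohort (45 CS / 93 NC, SNR 1, seed 11), lesion-excluded."""
    sim = simulate_cohort(SimulationDesign(), seed=11)
    apply_lesion_exclusion(sim)
    return sim


@pytest.fixture(scope="session")
def snr1_analysis(snr1_sim):
    """Design + permutation cluster result for the default VPL-ipsi seed."""
    design, result = seed_cluster_analysis(snr1_sim, "VPL", "ipsi", B=300, seed=77)
    return design, result


@pytest.fixture(scope="session")
def noisefree_sim():
    """Noise-free cohort: planted slopes must be exactly recoverable."""
    import dataclasses

    sim = simulate_cohort(
        dataclasses.replace(SimulationDesign(), noise_sd=0.0), seed=5
    )
    apply_lesion_exclusion(sim)
    return sim


@pytest.fixture
def rng():
    return np.random.default_rng(0)
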