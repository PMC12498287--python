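import dataclasses

import numpy as np
import pytest
from scipy import stats

from thalscn.pipeline import seed_design
from thalscn.scn_glm import fit_scn
from thalscn.synthetic import (
    EffectSpec,
    SimulationDesign,
    estimate_smoothness_fwhm,
    null_design,
    simulate_cohort,
    simulate_clinical_scores,
    smoothed_noise_field,
)


class TestDesignValidation:
    def test_blob_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            SimulationDesign(
                effects=[EffectSpec("VPL", "ipsi", (15, 8, 8), 2, 1.0, 0.5)]
            )

    def test_contradictory_overlapping_blobs_rejected(self):
        with pytest.raises(ValueError, match="contradictory"):
            SimulationDesign(
                effects=[
                    EffectSpec("VPL", "ipsi", (4, 8, 8), 2, 2.0, 1.0),
                    EffectSpec("AV", "ipsi", (5, 8, 8), 2, 3.0, 1.0),
                ]
            )

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            SimulationDesign(n_cs=2)

    def test_with_snr_sets_noise_sd(self):
        d = SimulationDesign().with_snr(0.5)
        assert d.noise_sd == pytest.approx(2.0)

    def test_yaml_round_trip_preserves_design(self, tmp_path):
        d = SimulationDesign(n_cs=5, n_nc=7, noise_sd=0.3)
        d.to_yaml(tmp_path / "design.yaml")
        back = SimulationDesign.from_yaml(tmp_path / "design.yaml")
        assert back == d
        a = simulate_cohort(back, seed=1)
        b = simulate_cohort(d, seed=1)
        assert np.array_equal(a.stack.data, b.stack.data)


class TestReproducibility:
    def test_same_seed_bit_identical(self):
        a = simulate_cohort(SimulationDesign(), seed=4)
        b = simulate_cohort(SimulationDesign(), seed=4)
        assert np.array_equal(a.stack.data, b.stack.data)
        assert a.cohort.equals(b.cohort)
        assert a.subfields.equals(b.subfields)
        assert all(
            np.array_equal(a.lesion_masks[k], b.lesion_masks[k]) for k in a.lesion_masks
        )

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimulationDesign(), seed=4)
        b = simulate_cohort(SimulationDesign(), seed=5)
        assert not np.array_equal(a.stack.data, b.stack.data)


class TestPlantedStructure:
    def test_null_design_plants_no_contrast(self):
        d = null_design()
        assert all(e.slope_cs == e.slope_nc for e in d.effects)
        sim = simulate_cohort(dataclasses.replace(d, noise_sd=0.0), seed=3)
        fit = fit_scn(sim.stack, seed_design(sim, "VPL", "ipsi"))
        blob = np.array(sim.truth["effects"][0]["blob_voxels"])
        assert np.max(np.abs(fit.contrast_estimate[blob])) < 1e-9

    def test_noise_free_identity(self, noisefree_sim):
        fit = fit_scn(noisefree_sim.stack, seed_design(noisefree_sim, "VPL", "ipsi"))
        blob = np.array(noisefree_sim.truth["effects"][0]["blob_voxels"])
        blob = blob[noisefree_sim.stack.mask[blob]]
        assert fit.beta_map("vol_cs")[blob] == pytest.approx(2.0, abs=1e-9)
        assert fit.beta_map("vol_nc")[blob] == pytest.approx(1.0, abs=1e-9)

    def test_group_covariances_differ_in_planted_direction(self):
        """At SNR 0.5 the empirical seed-to-blob covariance is larger in the
        patient group (slope 2 vs 1) in most replicates.

        The raw covariance equals slope x within-group z-variance, and the
        multiplicative 20% atrophy shrinks patients' volume dispersion by
        0.8, so the covariance gap (2x0.58 vs 1x0.91 pooled-z units) is much
        smaller than the slope gap the GLM estimates; the Monte-Carlo
        direction rate is ~0.80 (measured over 200 replicates), not ~1."""
        d = SimulationDesign().with_snr(0.5)
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            sim = simulate_cohort(d, seed=seed)
            blob = np.array(sim.truth["effects"][0]["blob_voxels"])
            from thalscn.io_core import subfield_vector

            vols = subfield_vector(sim.subfields, sim.cohort["subject_id"], "VPL", "ipsi")
            z = (vols - vols.mean()) / vols.std(ddof=1)
            gmv = sim.stack.data[:, blob].mean(axis=1)
            is_cs = (sim.cohort["group"] == "CS").to_numpy()
            cov_cs = np.cov(z[is_cs], gmv[is_cs])[0, 1]
            cov_nc = np.cov(z[~is_cs], gmv[~is_cs])[0, 1]
            hits += cov_cs > cov_nc
        assert hits / n_rep >= 0.75

    def test_truth_record_blob_voxels_match_effect_spec(self):
        sim = simulate_cohort(SimulationDesign(), seed=0)
        e = SimulationDesign().effects[0]
        expected = np.flatnonzero(e.blob_mask((16, 16, 16)).reshape(-1))
        assert sim.truth["effects"][0]["blob_voxels"] == expected.tolist()


class TestNoiseField:
    def test_empirical_fwhm_within_20_percent(self, rng):
        f = smoothed_noise_field(rng, (48, 48, 48), 6.0, 1.5)
        est = estimate_smoothness_fwhm(f, 1.5)
        assert abs(est - 6.0) / 6.0 < 0.2

    def test_unit_marginal_variance(self, rng):
        f = smoothed_noise_field(rng, (48, 48, 48), 6.0, 1.5)
        assert f.std() == pytest.approx(1.0, abs=0.05)


class TestLesions:
    def test_lesions_confined_to_ipsilesional_hemisphere(self, snr1_sim):
        nx = snr1_sim.stack.grid.shape[0]
        for m in snr1_sim.lesion_masks.values():
            xs = np.unravel_index(np.flatnonzero(m), snr1_sim.stack.grid.shape)[0]
            assert xs.min() >= nx // 2  # right hemisphere under the RAS affine

    def test_lesions_zero_patient_gmv(self, snr1_sim):
        sid = next(iter(snr1_sim.lesion_masks))
        i = snr1_sim.cohort.index[snr1_sim.cohort["subject_id"] == sid][0]
        m = snr1_sim.lesion_masks[sid]
        assert np.all(snr1_sim.stack.data[i, m] == 0.0)

    def test_only_patients_have_lesions(self, snr1_sim):
        cs_ids = set(snr1_sim.cohort.loc[snr1_sim.cohort["group"] == "CS", "subject_id"])
        assert set(snr1_sim.lesion_masks) == cs_ids


class TestClinicalScores:
    def test_accuracy_clipped_to_unit_interval(self):
        for seed in range(5):
            sim = simulate_cohort(SimulationDesign(), seed=seed)
            for col in ("N_ACC", "S_ACC"):
                assert sim.cohort[col].between(0, 1).all()
            assert (sim.cohort[["N_RT", "S_RT"]] > 0).all().all()

    def test_zero_coefficients_give_null_association(self):
        # atrophy off so the group label cannot confound volume with score
        d = dataclasses.replace(SimulationDesign(), ipsi_atrophy=0.0, clinical_links={})
        rhos = []
        for seed in range(25):
            sim = simulate_cohort(d, seed=seed)
            from thalscn.io_core import subfield_vector

            v = subfield_vector(sim.subfields, sim.cohort["subject_id"], "MDm", "ipsi")
            rho, _ = stats.spearmanr(v, sim.cohort["RAVLT_SR"])
            rhos.append(abs(rho))
        assert np.mean(rhos) < 0.1

    def test_strong_coefficient_drives_high_correlation(self):
        d = dataclasses.replace(
            SimulationDesign(),
            ipsi_atrophy=0.0,
            clinical_links={"RAVLT_SR": ("MDm", "ipsi", 9.0)},
        )
        hits = 0
        for seed in range(20):
            sim = simulate_cohort(d, seed=seed)
            from thalscn.io_core import subfield_vector

            v = subfield_vector(sim.subfields, sim.cohort["subject_id"], "MDm", "ipsi")
            rho, _ = stats.spearmanr(v, sim.cohort["RAVLT_SR"])
            hits += rho > 0.5
        assert hits / 20 >= 0.9
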