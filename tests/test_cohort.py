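"""Synthetic cohort generator: masks, subjects, cohorts, file round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from midfc import io as mio
from midfc.cohort import (
    SITE_TABLE,
    ConnectivityDesign,
    SubjectRecord,
    _band_limited,
    make_seed_masks,
    simulate_cohort,
    simulate_subject,
    write_cohort,
)
from midfc.connectivity import fisher_z, seed_timecourse
from midfc.motion import framewise_displacement
from midfc.volume import default_grid


class TestSeedMasks:
    def test_disjoint_on_small_grid(self):
        grid = default_grid((20, 20, 20))
        masks = make_seed_masks(grid, seed=1)
        assert (masks.vta & masks.snc).sum() == 0
        assert masks.vta.sum() > 0 and masks.snc.sum() > 0

    def test_deterministic(self):
        grid = default_grid((20, 20, 20))
        a = make_seed_masks(grid, seed=1)
        b = make_seed_masks(grid, seed=1)
        np.testing.assert_array_equal(a.vta, b.vta)
        np.testing.assert_array_equal(a.snc, b.snc)

    def test_tiny_grid_raises_instead_of_empty_masks(self):
        with pytest.raises(ValueError, match="at least 10"):
            make_seed_masks(default_grid((4, 4, 4)), seed=1)


class TestDesignFeasibility:
    def test_infeasible_rho_raises(self):
        design = ConnectivityDesign(base_rho=0.9, beta_age=0.05)
        rec = SubjectRecord("s0", 49.0, "female", "Yale", 2.0, 295)
        with pytest.raises(ValueError, match="infeasible"):
            design.rho_for(rec)

    def test_clip_warns_and_stays_inside_unit_interval(self):
        design = ConnectivityDesign(base_rho=0.9, beta_age=0.05, clip=True)
        rec = SubjectRecord("s0", 49.0, "female", "Yale", 2.0, 295)
        with pytest.warns(UserWarning, match="clipped"):
            rho = design.rho_for(rec)
        assert abs(rho) < 1

    def test_sex_specific_slopes(self):
        design = ConnectivityDesign(base_rho=0.3, beta_age_male=0.01,
                                    beta_age_female=0.0, age_ref=30.0)
        man = SubjectRecord("m", 40.0, "male", "Yale", 2.0, 295)
        woman = SubjectRecord("w", 40.0, "female", "Yale", 2.0, 295)
        assert design.rho_for(man) == pytest.approx(0.4)
        assert design.rho_for(woman) == pytest.approx(0.3)


class TestSimulateSubject:
    def test_deterministic_bit_identical(self, null_design, record):
        grid = default_grid((16, 18, 16))
        masks = make_seed_masks(grid, seed=2)
        a_bold, a_mot = simulate_subject(record, null_design, masks, seed=7)
        b_bold, b_mot = simulate_subject(record, null_design, masks, seed=7)
        np.testing.assert_array_equal(a_bold.data, b_bold.data)
        np.testing.assert_array_equal(a_mot, b_mot)

    def test_latent_signal_band_limited(self, rng):
        # >90% of the latent power lies within the 0.009-0.08 Hz band
        x = _band_limited(rng, (3000,), 2.0)
        freqs, pxx = signal.periodogram(x, fs=0.5)
        band = (freqs > 0.009) & (freqs < 0.08)
        assert pxx[band].sum() / pxx.sum() > 0.9

    def test_spike_frame_exceeds_fd_threshold(self, null_design, record):
        grid = default_grid((16, 18, 16))
        masks = make_seed_masks(grid, seed=2)
        design = ConnectivityDesign(
            base_rho=0.0, spike_frames={record.subject_id: (50,)})
        _, motion = simulate_subject(record, design, masks, seed=3)
        fd = framewise_displacement(motion)
        assert fd[50] > 0.5
        assert np.all(np.delete(fd, 50) < 0.5)

    def test_planted_correlation_within_fisher_ci(self, record):
        # base_rho = 0.6 with nuisance amplitudes 0: the raw sample
        # correlation between the seed time course and the target region
        # lies within the Fisher 95% CI of the planted value
        grid = default_grid((16, 18, 16))
        masks = make_seed_masks(grid, seed=2)
        design = ConnectivityDesign(
            base_rho=0.6,
            nuisance_amplitudes={"global": 0.0, "white_matter": 0.0,
                                 "ventricle": 0.0})
        from midfc.cohort import make_effect_regions, make_tissue_masks
        tissues = make_tissue_masks(grid)
        target, _ = make_effect_regions(grid, tissues.whole_brain, masks)
        design.target_region = target
        bold, _ = simulate_subject(record, design, masks, tissues=tissues,
                                   seed=5)
        # skip the initial transient frames: the correlation of interest is
        # between the stationary parts of the series
        tc = seed_timecourse(bold, masks.vta)[10:]
        vox = bold.data[target][:, 10:]
        r = np.array([np.corrcoef(tc, v)[0, 1] for v in vox]).mean()
        T = record.n_timepoints - 10
        assert abs(fisher_z(r) - fisher_z(0.6)) < 1.96 / np.sqrt(T - 3)

    def test_null_design_correlation_near_zero(self, null_design, record):
        grid = default_grid((16, 18, 16))
        masks = make_seed_masks(grid, seed=2)
        from midfc.cohort import make_effect_regions, make_tissue_masks
        tissues = make_tissue_masks(grid)
        _, nulls = make_effect_regions(grid, tissues.whole_brain, masks)
        zs = []
        for s in range(8):
            bold, _ = simulate_subject(record, null_design, masks,
                                       tissues=tissues, seed=s)
            tc = seed_timecourse(bold, masks.vta)[10:]   # past the transient
            vox = bold.data[nulls["null"]].mean(axis=0)[10:]
            zs.append(fisher_z(np.corrcoef(tc, vox)[0, 1]))
        zs = np.asarray(zs)
        # mean over 8 independent subjects within its own empirical null
        # band (band-limited signals have fewer effective dof than frames,
        # so the per-subject sd exceeds 1/sqrt(T-3))
        assert abs(zs.mean()) < 3.0 * zs.std(ddof=1) / np.sqrt(len(zs))


class TestSimulateCohort:
    def test_metadata_reproducible(self):
        design = ConnectivityDesign(base_rho=0.2)
        a = simulate_cohort(10, design, seed=9)
        b = simulate_cohort(10, design, seed=9)
        assert len(a.metadata) == 10
        assert a.metadata.to_csv(index=False) == b.metadata.to_csv(index=False)

    def test_site_table_matches_study_parameters(self):
        design = ConnectivityDesign(base_rho=0.2)
        cohort = simulate_cohort({"Beijing_Zang": 3}, design, seed=1)
        rec = cohort.records[0]
        assert rec.n_timepoints == 225
        assert rec.tr == 2.0
        assert SITE_TABLE["Leiden_2180"]["tr"] == 2.18
        assert SITE_TABLE["Newark"]["n_timepoints"] == 135

    def test_male_count_within_binomial_bounds(self):
        design = ConnectivityDesign(base_rho=0.2)
        cohort = simulate_cohort(200, design, seed=12, male_fraction=0.5)
        males = (cohort.metadata["sex"] == "male").sum()
        # 99% binomial interval for n=200, p=0.5
        assert 82 <= males <= 118

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="positive|empty"):
            simulate_cohort(0, ConnectivityDesign(), seed=1)


class TestWriteCohort(object):
    @pytest.fixture
    def small_cohort(self):
        design = ConnectivityDesign(base_rho=0.2)
        return simulate_cohort({"Newark": 3}, design, seed=4,
                               grid=default_grid((14, 16, 14)))

    def test_manifest_counts_and_roundtrip(self, small_cohort, tmp_path):
        manifest = write_cohort(small_cohort, tmp_path)
        assert len(manifest["bold"]) == 3
        assert len(manifest["motion"]) == 3
        rec = small_cohort.records[0]
        bold, motion = small_cohort.subject_data(rec)
        loaded = mio.load_bold(tmp_path / manifest["bold"][0])
        np.testing.assert_allclose(loaded.data, bold.data, rtol=1e-6)
        np.testing.assert_allclose(loaded.affine, bold.affine)
        assert loaded.tr == pytest.approx(bold.tr)
        got = mio.load_motion(tmp_path / manifest["motion"][0])
        assert got.shape == (rec.n_timepoints, 6)
        np.testing.assert_allclose(got, motion, atol=1e-7)

    def test_collision_requires_overwrite(self, small_cohort, tmp_path):
        write_cohort(small_cohort, tmp_path)
        with pytest.raises(FileExistsError):
            write_cohort(small_cohort, tmp_path)
        write_cohort(small_cohort, tmp_path, overwrite=True)

    def test_metadata_written(self, small_cohort, tmp_path):
        write_cohort(small_cohort, tmp_path)
        meta = pd.read_csv(tmp_path / "metadata.csv")
        assert list(meta.columns) == ["subject_id", "age", "sex", "site",
                                      "tr", "n_timepoints"]
        assert len(meta) == 3
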