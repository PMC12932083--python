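import numpy as np
import pandas as pd
import pytest

from wmconn.preprocess import framewise_displacement
from wmconn.synthetic import (
    SyntheticCohortSpec,
    SyntheticVolumeSpec,
    make_bold_volume,
    make_cohort_connectomes,
    make_tissue_maps,
    pack_years,
)


class TestPackYears:
    @pytest.mark.parametrize(
        "duration, cpd, expected",
        [
            (4.40, 16.23, 3.57),  # cohort-mean worked example
            (0.0, 20.0, 0.0),
            (1.0, 20.0, 1.0),  # one pack a day for one year
        ],
    )
    def test_worked_examples(self, duration, cpd, expected):
        assert round(pack_years(duration, cpd), 2) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pack_years(-1.0, 10.0)


class TestTissueMaps:
    def test_seeded_determinism(self, volume_spec):
        a = make_tissue_maps(volume_spec)
        b = make_tissue_maps(volume_spec)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_wm_core_exists(self, wm_blob):
        assert (wm_blob > 0.9).any()

    def test_probability_partition(self, volume_spec):
        wm, gm, csf = make_tissue_maps(volume_spec)
        total = wm + gm + csf
        assert total.max() <= 1.0 + 1e-12
        assert wm.min() >= 0 and gm.min() >= 0 and csf.min() >= 0

    def test_too_many_truth_parcels_rejected(self):
        spec = SyntheticVolumeSpec(grid_dims=(8, 8, 8), n_parcels_truth=500)
        with pytest.raises(ValueError, match="too small"):
            make_tissue_maps(spec)


class TestBoldVolume:
    def test_fd_spikes_land_exactly_where_requested(self):
        spec = SyntheticVolumeSpec(fd_spike_times=(20, 40), fd_spike_mm=1.0, seed=3)
        wm, _, _ = make_tissue_maps(spec)
        _, motion = make_bold_volume(spec, wm)
        fd = framewise_displacement(motion)
        above = set(np.flatnonzero(fd.fd > 0.5).tolist())
        assert above == {20, 40}
        quiet = np.delete(fd.fd, [20, 40])
        assert quiet.max() < 0.2

    def test_noiseless_parcel_voxels_perfectly_correlated(self):
        spec = SyntheticVolumeSpec(noise_sd=0.0, seed=5)
        wm, _, _ = make_tissue_maps(spec)
        from wmconn.synthetic import ground_truth_parcels

        bold, _ = make_bold_volume(spec, wm)
        labels = ground_truth_parcels(spec, wm)
        vox = np.argwhere(labels == 1)[:2]
        a = bold[tuple(vox[0])]
        b = bold[tuple(vox[1])]
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(1.0)

    def test_seeded_determinism(self, volume_spec, wm_blob):
        b1, m1 = make_bold_volume(volume_spec, wm_blob)
        b2, m2 = make_bold_volume(volume_spec, wm_blob)
        np.testing.assert_array_equal(b1, b2)
        np.testing.assert_array_equal(m1, m2)


class TestCohortGenerator:
    def test_seeded_determinism(self):
        spec = SyntheticCohortSpec(n_per_group=3, n_nodes=16, n_timepoints=40, seed=9)
        a = make_cohort_connectomes(spec)
        b = make_cohort_connectomes(spec)
        for x, y in zip(a.series, b.series):
            np.testing.assert_array_equal(x.values, y.values)
        pd.testing.assert_frame_equal(a.clinical, b.clinical)

    def test_infeasible_correlation_rejected(self):
        with pytest.raises(ValueError, match="[Ii]nfeasible"):
            SyntheticCohortSpec(within_module_corr=0.8, effect=0.3)

    def test_correlation_calibration_long_series(self):
        """Sample within-module correlation converges to the target and
        between-module correlation converges to zero."""
        spec = SyntheticCohortSpec(
            n_per_group=2, n_nodes=64, n_timepoints=2000, n_modules=4, seed=11
        )
        cohort = make_cohort_connectomes(spec)
        mod = cohort.module_of_node
        off = ~np.eye(spec.n_nodes, dtype=bool)
        same = (mod[:, None] == mod[None, :]) & off
        for ts, grp in zip(cohort.series, cohort.groups):
            r = np.corrcoef(ts.values)
            target = spec.within_module_corr + (spec.effect if grp == "smoker" else 0)
            assert abs(r[same].mean() - target) < 0.05
            assert abs(r[~same & off].mean()) < 0.05

    def test_clinical_table_invariants(self):
        spec = SyntheticCohortSpec(n_per_group=10, n_nodes=16, n_timepoints=40, seed=2)
        clin = make_cohort_connectomes(spec).clinical
        smokers = clin[clin.group == "smoker"]
        controls = clin[clin.group == "control"]
        np.testing.assert_allclose(
            smokers.pack_years, smokers.duration * smokers.cpd / 20.0
        )
        for col in ("ftnd", "cpd", "duration", "onset_age", "pack_years"):
            assert smokers[col].notna().all()
            assert controls[col].isna().all()

    def test_effect_raises_smoker_coherence(self):
        spec = SyntheticCohortSpec(
            n_per_group=12, n_nodes=32, n_timepoints=120, effect=0.3, seed=4
        )
        cohort = make_cohort_connectomes(spec)
        coh = cohort.coherence
        n = spec.n_per_group
        assert coh[:n].mean() > coh[n:].mean()
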