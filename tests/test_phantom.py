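"""Phantom geometry, ground truth and synthetic-fixture generators."""

import math

import numpy as np
import pandas as pd
import pytest

from stereoplacenta import (
    GROUPS,
    LABELS,
    PackingError,
    StudySynthSpec,
    make_placenta_phantom,
    make_shell_phantom,
    make_sphere_phantom,
    make_step_tablet,
    synth_blot_fixture,
    synth_study_table,
    voxel_surface_area,
    voxel_volumes,
    voxelize,
)


class TestSpherePhantom:
    def test_closed_form_volume_and_surface(self):
        _, gt = make_sphere_phantom(100.0)
        assert gt.total_volume_um3 == pytest.approx(4_188_790.2, rel=1e-6)
        assert gt.surfaces_um2["tissue"] == pytest.approx(125_663.7, rel=1e-6)
        assert gt.provenance["tissue.volume"] == "closed-form"

    @pytest.mark.parametrize("radius", [0.0, -5.0])
    def test_nonpositive_radius_rejected(self, radius):
        with pytest.raises(ValueError, match="radius"):
            make_sphere_phantom(radius)

    def test_voxel_oracle_agrees_with_closed_form(self):
        ph, gt = make_sphere_phantom(50.0)
        vols = voxel_volumes(ph, 0.5)
        assert vols["tissue"] == pytest.approx(gt.total_volume_um3, rel=0.01)
        s = voxel_surface_area(ph, "tissue", 0.5)
        assert s == pytest.approx(gt.surfaces_um2["tissue"], rel=0.01)


class TestShellPhantom:
    def test_thickness_and_shell_volume(self, shell_80_5):
        _, gt = shell_80_5
        assert gt.tau_true_um == 5.0
        expected = 4.0 / 3.0 * math.pi * (85.0 ** 3 - 80.0 ** 3)
        assert gt.volumes_um3["membrane"] == pytest.approx(expected, rel=1e-9)

    def test_degenerate_shell_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            make_shell_phantom(80.0, 80.0)

    def test_radial_chord_through_membrane_at_least_thickness(self, shell_80_5):
        ph, _ = shell_80_5
        # march outward along random radial directions; the membrane chord
        # (between inner and outer crossings) must be >= the thickness
        rng = np.random.default_rng(0)
        dirs = rng.normal(size=(50, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        radii = np.linspace(70.0, 95.0, 501)
        for d in dirs:
            pts = radii[:, None] * d[None, :]
            labels = ph.label_points(pts)
            in_membrane = labels == LABELS["membrane"]
            chord = in_membrane.sum() * (radii[1] - radii[0])
            assert chord >= 5.0 - 2 * (radii[1] - radii[0])


class TestPlacentaPhantom:
    def test_zone_volumes_in_requested_proportions(self, small_placenta):
        ph, gt = small_placenta
        total = gt.total_volume_um3
        assert gt.volumes_um3["decidua"] / total == pytest.approx(0.15, abs=1e-12)
        assert gt.volumes_um3["junctional"] / total == pytest.approx(0.30, abs=1e-12)
        assert gt.volumes_um3["labyrinth"] / total == pytest.approx(0.55, abs=1e-12)

    def test_voxel_oracle_confirms_zone_partition(self, small_placenta):
        ph, gt = small_placenta
        vols = voxel_volumes(ph, 2.0)
        lz = vols["labyrinth"] + vols.get("capillary", 0) + vols.get("blood_space", 0)
        assert vols["decidua"] == pytest.approx(gt.volumes_um3["decidua"], rel=0.05)
        assert vols["junctional"] == pytest.approx(gt.volumes_um3["junctional"], rel=0.05)
        assert lz == pytest.approx(gt.volumes_um3["labyrinth"], rel=0.05)
        assert vols["capillary"] == pytest.approx(gt.volumes_um3["capillary"], rel=0.05)
        # zone partition: every voxel inside the body carries exactly one label
        vox = voxelize(ph, 4.0)
        assert set(np.unique(vox)) <= {LABELS[k] for k in
                                       ("background", "decidua", "junctional",
                                        "labyrinth", "capillary", "blood_space")}

    def test_zero_capillaries_means_zero_capillary_truth(self):
        ph, gt = make_placenta_phantom(
            semi_axes=(300.0, 300.0, 160.0), n_capillaries=0,
            capillary_radius=14.0, n_channels=4, channel_radius=10.0,
            seed=3)
        assert gt.volumes_um3["capillary"] == 0.0
        assert gt.surfaces_um2["capillary"] == 0.0

    def test_same_seed_identical_phantom(self):
        kw = dict(semi_axes=(300.0, 300.0, 160.0), n_capillaries=10,
                  capillary_radius=12.0, n_channels=6, channel_radius=14.0,
                  seed=11)
        ph1, gt1 = make_placenta_phantom(**kw)
        ph2, gt2 = make_placenta_phantom(**kw)
        assert np.array_equal(ph1.tube_y, ph2.tube_y)
        assert np.array_equal(ph1.tube_label, ph2.tube_label)
        assert gt1.volumes_um3 == gt2.volumes_um3
        assert gt1.surfaces_um2 == gt2.surfaces_um2

    def test_membrane_separation_enforced(self, small_placenta):
        ph, gt = small_placenta
        cap = ph.tube_label == LABELS["capillary"]
        chan = ph.tube_label == LABELS["blood_space"]
        dy = ph.tube_y[cap][:, None] - ph.tube_y[chan][None, :]
        dz = ph.tube_z[cap][:, None] - ph.tube_z[chan][None, :]
        gap = np.hypot(dy, dz) - ph.tube_r[cap][:, None] - ph.tube_r[chan][None, :]
        assert gap.min() >= gt.tau_true_um - 1e-9

    def test_infeasible_packing_fails_explicitly(self):
        with pytest.raises(PackingError, match="tau_true"):
            make_placenta_phantom(semi_axes=(200.0, 200.0, 120.0),
                                  n_capillaries=500, capillary_radius=14.0,
                                  n_channels=5, channel_radius=16.0,
                                  seed=0, max_tries=200)

    def test_bad_zone_fractions_rejected(self):
        with pytest.raises(ValueError, match="fractions"):
            make_placenta_phantom(zone_fractions=(0.5, 0.3, 0.3))


class TestStudyTable:
    def test_zero_noise_reproduces_group_means(self):
        means = {"y": {"N": 1.0, "H": 2.0, "HM": 3.0, "NM": 4.0}}
        spec = StudySynthSpec(group_means=means, sigma_litter={"y": 0.0},
                              sigma_resid={"y": 0.0}, seed=0)
        df = synth_study_table(spec)
        for g in GROUPS:
            assert (df.loc[df.group == g, "y"] == means["y"][g]).all()

    def test_paper_design_row_count(self):
        spec = StudySynthSpec(seed=0)
        df = synth_study_table(spec)
        assert len(df) == (16 + 16 + 18 + 16) * 8
        assert df.groupby("group")["dam_id"].nunique().to_dict() == \
            {"N": 16, "H": 16, "HM": 18, "NM": 16}
        # factor decomposition is a full 2x2
        assert set(map(tuple, df[["group", "hypoxia", "mitoq"]]
                       .drop_duplicates().itertuples(index=False))) == \
            {("N", 0, 0), ("H", 1, 0), ("HM", 1, 1), ("NM", 0, 1)}

    def test_empirical_variance_components_match_spec(self):
        # moment estimates pooled over replicate tables recover the
        # programmed between-litter and residual variances
        s_l, s_r = 1.5, 0.7
        between, within = [], []
        for seed in range(300):
            spec = StudySynthSpec(
                litters_per_group={"N": 2, "H": 2, "HM": 2, "NM": 2},
                fetuses_per_litter=6,
                group_means={"y": {g: 0.0 for g in GROUPS}},
                sigma_litter={"y": math.sqrt(s_l)},
                sigma_resid={"y": math.sqrt(s_r)}, seed=seed)
            df = synth_study_table(spec)
            litter_means = df.groupby("dam_id")["y"].mean()
            within.append(df.groupby("dam_id")["y"].var(ddof=1).mean())
            between.append(litter_means.var(ddof=1) - within[-1] / 6)
        assert np.mean(within) == pytest.approx(s_r, rel=0.05)
        assert np.mean(between) == pytest.approx(s_l, rel=0.05)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="litters"):
            StudySynthSpec(litters_per_group={"N": 1, "H": 2, "HM": 2,
                                              "NM": 2}).validate()
        with pytest.raises(ValueError, match="variance"):
            StudySynthSpec(sigma_litter={"outcome": -1.0}).validate()


class TestBlotFixture:
    def test_noise_free_unit_gain_identity(self):
        truth = np.array([10.0, 20.0, 30.0])
        df, _, _ = synth_blot_fixture(truth, np.array([1.0]), noise_sd=0.0)
        assert np.allclose(df["intensity"], truth)
        assert not df["saturated"].any()

    def test_clipping_flags_saturation(self):
        truth = np.array([10.0, 100.0])
        df, _, _ = synth_blot_fixture(truth, np.array([1.0, 1000.0]),
                                      saturation_level=5000.0, noise_sd=0.0)
        hot = df[(df.exposure == 1) & (df.lane == 1)]
        assert bool(hot["saturated"].iloc[0])
        assert hot["intensity"].iloc[0] == 5000.0

    def test_step_tablet_monotone(self):
        img, pairs = make_step_tablet()
        grays = [g for g, _ in pairs]
        ods = [od for _, od in pairs]
        assert all(g1 > g2 for g1, g2 in zip(grays, grays[1:]))
        assert all(o1 < o2 for o1, o2 in zip(ods, ods[1:]))
        assert img.dtype == np.uint16

    def test_same_seed_identical_fixture(self):
        truth = np.array([5.0, 7.0])
        a, _, _ = synth_blot_fixture(truth, np.array([1.0, 2.0]), seed=9)
        b, _, _ = synth_blot_fixture(truth, np.array([1.0, 2.0]), seed=9)
        pd.testing.assert_frame_equal(a, b)
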