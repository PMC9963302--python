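"""Ground-truth generator: determinism, invariants, and analytic limits."""

import numpy as np
import pandas as pd
import pytest

from synquant.coloc import pcc
from synquant.synthetic import (
    GroundTruth,
    StackSpec,
    SynapseSpec,
    render_movie,
    render_stack,
    render_synapse,
    render_transfer_events,
)


class TestRenderSynapse:
    def test_zero_signal_gives_constant_background(self):
        spec = SynapseSpec(
            n_microclusters=0,
            channel_amplitudes={"brightfield": 0, "adhesion": 0, "receptor": 0, "adaptor": 0},
            background_level=3.5,
        )
        img, _ = render_synapse(spec)
        for name in img.channel_names:
            np.testing.assert_allclose(img[name], 3.5)

    def test_perfect_mixing_makes_adaptor_proportional_to_receptor(self):
        spec = SynapseSpec(coloc_mixing=1.0, background_level=0.0)
        img, gt = render_synapse(spec)
        rec, ada = img["receptor"], img["adaptor"]
        scale = spec.channel_amplitudes["adaptor"] / spec.channel_amplitudes["receptor"]
        np.testing.assert_allclose(ada, scale * rec, rtol=1e-12, atol=1e-12)
        assert pcc(rec, ada, gt.cell_mask) == 1.0

    def test_same_seed_bit_identical(self):
        spec = SynapseSpec(poisson_noise=True, gaussian_noise_sd=1.0, seed=5)
        a, _ = render_synapse(spec)
        b, _ = render_synapse(spec)
        for name in a.channel_names:
            np.testing.assert_array_equal(a[name], b[name])

    def test_noise_free_images_nonnegative(self, synapse_image):
        img, _ = synapse_image
        for name in img.channel_names:
            assert (img[name] >= 0).all()

    def test_ground_truth_counts_match_request(self):
        img, gt = render_synapse(SynapseSpec(n_microclusters=13))
        assert len(gt.microclusters) == 13
        assert gt.cell_mask.shape == img.shape

    @pytest.mark.parametrize(
        "bad",
        [
            dict(csmac_radius_um=4.0),  # cSMAC outside ring
            dict(ring_radius_um=10.0),  # ring outside field
            dict(coloc_mixing=1.5),
            dict(gaussian_noise_sd=-1.0),
            dict(n_microclusters=-1),
        ],
    )
    def test_invalid_geometry_rejected(self, bad):
        with pytest.raises(ValueError):
            render_synapse(SynapseSpec(**bad))

    def test_downstream_pcc_tracks_oracle_on_noise_free_pair(self):
        """Measured PCC with noise sits in a band around the noise-free value."""
        spec = SynapseSpec(coloc_mixing=0.7, gaussian_noise_sd=1.0, seed=11)
        img, gt = render_synapse(spec)
        clean, _ = render_synapse(
            SynapseSpec(coloc_mixing=0.7, gaussian_noise_sd=0.0, seed=11)
        )
        noise_free = pcc(clean["receptor"], clean["adaptor"], gt.cell_mask)
        measured = pcc(img["receptor"], img["adaptor"], gt.cell_mask)
        assert abs(measured - noise_free) < 0.1


class TestRenderMovie:
    def test_zero_drift_tracks_stationary(self):
        _, gt = render_movie(SynapseSpec(n_microclusters=4), n_frames=5, drift_per_frame_um=0.0)
        for _, tr in gt.tracks.groupby("track_id"):
            assert tr["x_px"].nunique() == 1 and tr["y_px"].nunique() == 1

    def test_kinematics_radius_decreases_by_drift_until_clamped(self):
        spec = SynapseSpec(n_microclusters=1, csmac_radius_um=1.0)
        _, gt = render_movie(
            spec, n_frames=8, drift_per_frame_um=0.3, initial_radii_um=[2.2], angles_deg=[30]
        )
        r = gt.tracks.sort_values("frame")["radius_um"].to_numpy()
        expected = np.maximum(1.0, 2.2 - 0.3 * np.arange(8))
        np.testing.assert_allclose(r, expected, rtol=1e-12)

    def test_negative_drift_rejected(self):
        with pytest.raises(ValueError):
            render_movie(SynapseSpec(), n_frames=3, drift_per_frame_um=-0.1)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            render_movie(SynapseSpec(), n_frames=1, drift_per_frame_um=0.1)

    def test_adaptor_ramp_scales_signal(self):
        spec = SynapseSpec(n_microclusters=2, background_level=2.0)
        frames, _ = render_movie(
            spec, n_frames=3, drift_per_frame_um=0.0, adaptor_scale_per_frame=[1.0, 2.0, 3.0]
        )
        sig = [f["adaptor"] - 2.0 for f in frames]
        np.testing.assert_allclose(sig[1], 2.0 * sig[0], rtol=1e-10, atol=1e-10)
        np.testing.assert_allclose(sig[2], 3.0 * sig[0], rtol=1e-10, atol=1e-10)


class TestRenderStack:
    def test_no_vesicles_antigen_is_pure_background(self):
        spec = StackSpec(
            n_internal_vesicles=0,
            n_released_vesicles=0,
            poisson_noise=False,
            gaussian_noise_sd=0.0,
        )
        stack, gt = render_stack(spec)
        np.testing.assert_allclose(stack["antigen"], spec.background_level)
        assert len(gt.vesicles) == 0

    def test_ground_truth_counts_per_class(self, small_stack):
        _, gt = small_stack
        counts = gt.vesicles["location"].value_counts()
        assert counts.get("internal", 0) == 7
        assert counts.get("released", 0) == 4

    def test_vesicle_sidedness_strict(self, small_stack_spec, small_stack):
        _, gt = small_stack
        c = np.array(small_stack_spec.center_um)
        semi = np.array(small_stack_spec.cell_semiaxes_um)
        for _, v in gt.vesicles.iterrows():
            p = np.array([v.x_um, v.y_um, v.z_um])
            norm = np.sqrt((((p - c) / semi) ** 2).sum())
            if v.location == "internal":
                assert norm < 1.0
            else:
                assert norm > 1.0

    def test_ball_voxelization_matches_analytic_volume(self, small_stack_spec, small_stack):
        _, gt = small_stack
        voxvol = small_stack_spec.pixel_size_um**2 * small_stack_spec.z_step_um
        analytic = (4 / 3) * np.pi * small_stack_spec.vesicle_radius_um**3
        rendered = gt.vesicles["voxels"].to_numpy() * voxvol
        np.testing.assert_allclose(rendered, analytic, rtol=0.15)

    def test_same_seed_bit_identical(self):
        spec = StackSpec(seed=3)
        a, _ = render_stack(spec)
        b, _ = render_stack(spec)
        for name in a.channel_names:
            np.testing.assert_array_equal(a[name], b[name])

    def test_released_count_does_not_perturb_internal_placement(self):
        """Separate RNG streams: object classes are placement-independent."""
        _, gt_a = render_stack(StackSpec(n_released_vesicles=0, seed=9))
        _, gt_b = render_stack(StackSpec(n_released_vesicles=4, seed=9))
        int_a = gt_a.vesicles[gt_a.vesicles.location == "internal"]
        int_b = gt_b.vesicles[gt_b.vesicles.location == "internal"]
        np.testing.assert_allclose(
            int_a[["x_um", "y_um", "z_um"]].to_numpy(),
            int_b[["x_um", "y_um", "z_um"]].to_numpy(),
        )

    def test_impossible_placement_raises_with_constraint_name(self):
        spec = StackSpec(
            volume_size_px=(16, 32, 32),
            cell_semiaxes_um=(1.5, 1.5, 1.2),
            n_internal_vesicles=500,
        )
        with pytest.raises(RuntimeError, match="non-overlap"):
            render_stack(spec)


class TestRenderTransferEvents:
    def test_population_labels_and_counts(self):
        df = render_transfer_events(10, 20, 5.0, 9.0, 0.0, seed=0)
        assert (df["population"] == "bead").sum() == 10
        assert (df["population"] == "cell").sum() == 20
        assert (df["fluorescence"] >= 0).all()

    def test_noise_free_means_exact(self):
        df = render_transfer_events(5, 5, 30.0, 70.0, 0.0, seed=1)
        assert df[df.population == "bead"].fluorescence.unique().tolist() == [30.0]
        assert df[df.population == "cell"].fluorescence.unique().tolist() == [70.0]

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            render_transfer_events(5, 5, -1.0, 70.0, 0.0, seed=1)

    def test_labels_attached(self):
        df = render_transfer_events(
            2, 2, 1.0, 1.0, 0.0, seed=0, condition="ko", ligand_density=30.0, experiment="e1"
        )
        assert set(df["condition"]) == {"ko"} and set(df["experiment"]) == {"e1"}


def test_ground_truth_serializes_to_plain_dict(small_stack):
    _, gt = small_stack
    d = gt.to_dict()
    assert isinstance(d["vesicles"], list)
    assert isinstance(GroundTruth().to_dict(), dict)
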