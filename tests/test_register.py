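"""Similarity-transform estimation and pull-back resampling."""

import numpy as np
import pytest

from neuromap3d.register import (
    LandmarkSet,
    RegistrationError,
    SimilarityTransform,
    apply_to_volume,
    estimate_similarity,
    transfer,
)
from neuromap3d.volume import IonVolume


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def make_cloud(rng, n=10, spread=200.0):
    return rng.uniform(-spread, spread, (n, 3))


class TestEstimateSimilarity:
    def test_identical_points_give_identity(self, rng):
        pts = make_cloud(rng)
        T, rms = estimate_similarity(LandmarkSet(pts, pts))
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)
        assert T.scale == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(T.translation, 0.0, atol=1e-6)
        assert rms == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_recovery_to_1e6(self, rng):
        R = random_rotation(rng)
        s = 2.5
        t = np.array([120.0, -40.0, 310.0])
        moving = make_cloud(rng)
        fixed = (s * (R @ moving.T)).T + t
        T, rms = estimate_similarity(LandmarkSet(moving, fixed))
        np.testing.assert_allclose(T.rotation, R, atol=1e-6)
        assert T.scale == pytest.approx(s, abs=1e-6)
        np.testing.assert_allclose(T.translation, t, atol=1e-6)
        assert rms < 1e-6

    def test_noisy_rms_in_expected_band(self):
        """Monte-Carlo: isotropic sigma=1 µm noise on 10 landmarks."""
        sigma = 1.0
        values = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            R = random_rotation(r)
            moving = make_cloud(r)
            fixed = (1.7 * (R @ moving.T)).T + np.array([5.0, 6.0, 7.0])
            fixed = fixed + r.normal(0, sigma, fixed.shape)
            _, rms = estimate_similarity(LandmarkSet(moving, fixed))
            values.append(rms)
        assert 0.3 * sigma <= np.mean(values) <= 2 * sigma

    def test_equivariant_under_rotation_of_fixed_frame(self, rng):
        moving = make_cloud(rng)
        R = random_rotation(rng)
        fixed = (2.0 * (R @ moving.T)).T + np.array([1.0, 2.0, 3.0])
        T0, _ = estimate_similarity(LandmarkSet(moving, fixed))
        Q = random_rotation(rng)
        Tq, _ = estimate_similarity(LandmarkSet(moving, (Q @ fixed.T).T))
        np.testing.assert_allclose(Tq.rotation, Q @ T0.rotation, atol=1e-8)
        assert Tq.scale == pytest.approx(T0.scale, abs=1e-9)

    def test_rms_invariant_under_pair_reordering(self, rng):
        moving = make_cloud(rng)
        fixed = moving * 1.3 + rng.normal(0, 2.0, moving.shape)
        _, rms_a = estimate_similarity(LandmarkSet(moving, fixed))
        perm = rng.permutation(len(moving))
        _, rms_b = estimate_similarity(
            LandmarkSet(moving[perm], fixed[perm])
        )
        assert rms_a == pytest.approx(rms_b, abs=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(RegistrationError, match="3 landmark"):
            LandmarkSet(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_moving_points_rejected(self):
        moving = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(RegistrationError, match="collinear"):
            LandmarkSet(moving, moving * 2)


def iso_volume(data, voxel=10.0):
    data = np.asarray(data, float)
    return IonVolume(
        data=data, plane_mask=np.ones(data.shape[0], bool),
        pixel_size=voxel, z_spacing=voxel,
    )


class TestApplyToVolume:
    def test_identity_same_grid_is_no_op(self, rng):
        v = iso_volume(rng.uniform(0, 1, (4, 5, 6)))
        out = apply_to_volume(
            v, SimilarityTransform.identity(), v.data.shape, 10.0,
            interp="trilinear",
        )
        np.testing.assert_allclose(out.data, v.data, atol=1e-9)

    def test_voxel_pitch_translation_nearest_is_shifted_copy(self, rng):
        v = iso_volume(rng.uniform(0, 1, (4, 5, 6)))
        T = SimilarityTransform(np.eye(3), 1.0, np.array([10.0, 0.0, 0.0]))
        out = apply_to_volume(v, T, v.data.shape, 10.0, interp="nearest")
        np.testing.assert_allclose(out.data[:, :, 1:], v.data[:, :, :-1])

    def test_pitch_translation_conserves_intensity_multiset(self, rng):
        v = iso_volume(rng.uniform(0, 1, (4, 4, 4)))
        T = SimilarityTransform(np.eye(3), 1.0, np.array([0.0, 10.0, 0.0]))
        big = (6, 6, 6)
        out = apply_to_volume(v, T, big, 10.0, interp="nearest")
        inside = out.data[out.meta["voxel_mask"]]
        assert sorted(inside) == sorted(v.data.ravel())

    def test_gap_planes_treated_as_missing_not_zero(self):
        data = np.zeros((4, 1, 1))
        data[0] = 4.0
        data[2] = 8.0
        data[3] = 8.0
        mask = np.array([True, False, True, True])
        v = IonVolume(data=data, plane_mask=mask, pixel_size=10.0,
                      z_spacing=10.0)
        # sample halfway between planes: weights over the gap plane are
        # renormalised onto the measured neighbor instead of averaging a
        # zero in, so values never dip toward the gap
        out = apply_to_volume(
            v, SimilarityTransform.identity(), (3, 1, 1), 10.0,
            target_origin=(0.0, 0.0, 5.0), interp="trilinear",
        )
        np.testing.assert_allclose(out.data[:, 0, 0], [4.0, 8.0, 8.0])
        # a voxel exactly on the gap plane has no measured support at all
        on_plane = apply_to_volume(
            v, SimilarityTransform.identity(), (4, 1, 1), 10.0,
            interp="trilinear",
        )
        assert not on_plane.meta["voxel_mask"][1, 0, 0]

    def test_fully_missing_support_marked_unmeasured(self):
        data = np.zeros((2, 2, 2))
        v = IonVolume(data=data, plane_mask=np.zeros(2, bool),
                      pixel_size=10.0, z_spacing=10.0)
        with pytest.warns(UserWarning, match="empty overlap"):
            out = apply_to_volume(
                v, SimilarityTransform.identity(), (2, 2, 2), 10.0,
            )
        assert not out.meta["voxel_mask"].any()

    def test_phantom_pose_maps_signal_into_target_regions(
        self, phantom_data, default_config
    ):
        """Resampled peptide mask lands inside its seeded regions."""
        from neuromap3d.masscalc import monoisotopic_mh
        from neuromap3d.phantom import ion_volume_for

        plan = default_config.peptides[0]
        vol = ion_volume_for(
            phantom_data.sections, phantom_data.z_positions,
            monoisotopic_mh(plan.peptide),
        )
        out = apply_to_volume(
            vol, phantom_data.true_pose, phantom_data.ct.data.shape,
            phantom_data.ct.voxel_size, interp="trilinear",
        )
        hot = out.data > 0.2 * out.data.max()
        target_labels = {
            lab for lab, name in phantom_data.regions.name_map.items()
            if name in plan.target_regions
        }
        labels = phantom_data.regions.labels
        in_target = np.isin(labels, list(target_labels))
        dice = 2 * (hot & in_target).sum() / (hot.sum() + in_target.sum())
        assert dice >= 0.5
        # bleed past the seeded ellipsoid stays within about one MSI
        # pixel footprint and never reaches a different region
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(
            ~in_target, sampling=phantom_data.ct.voxel_size
        )
        assert dist[hot].max() <= 2 * default_config.pixel_size
        assert not (hot & (labels > 0) & ~in_target).any()


class TestTransfer:
    def test_same_transform_applied_with_provenance(self, rng):
        optical = iso_volume(rng.uniform(0, 1, (3, 4, 4)))
        ions = [iso_volume(rng.uniform(0, 1, (3, 4, 4))) for _ in range(2)]
        T = SimilarityTransform.identity()
        outs = transfer(T, optical, ions, (3, 4, 4), 10.0)
        assert all(o.meta["transform"] == T.to_dict() for o in outs)

    def test_pixel_size_mismatch_rejected(self, rng):
        optical = iso_volume(rng.uniform(0, 1, (3, 4, 4)))
        bad = IonVolume(
            data=np.zeros((3, 4, 4)), plane_mask=np.ones(3, bool),
            pixel_size=99.0, z_spacing=10.0,
        )
        with pytest.raises(RegistrationError, match="pixel_size"):
            transfer(SimilarityTransform.identity(), optical, [bad],
                     (3, 4, 4), 10.0)


def test_transform_json_round_trip(tmp_path, rng):
    T = SimilarityTransform(random_rotation(rng), 1.25,
                            np.array([1.0, 2.0, 3.0]))
    path = tmp_path / "T.json"
    T.to_json(str(path))
    back = SimilarityTransform.from_json(str(path))
    np.testing.assert_allclose(back.rotation, T.rotation, atol=1e-12)
    assert back.scale == T.scale
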