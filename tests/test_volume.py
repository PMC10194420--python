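"""Serial-section stacking, gap bookkeeping and thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuromap3d.volume import (
    IonVolume,
    VolumeError,
    load_volume_nrrd,
    save_volume_nrrd,
    stack_sections,
    threshold_volume,
    transparency_map,
)


def planes(n, shape=(4, 4), seed=0):
    rng = np.random.default_rng(seed)
    return [rng.uniform(0, 10, shape) for _ in range(n)]


class TestStackSections:
    def test_44_sections_at_10um(self):
        imgs = planes(44)
        v = stack_sections(imgs, [10.0 * i for i in range(44)],
                           pixel_size=40.0)
        assert v.depth == 44
        assert v.z_spacing == 10.0
        x, y, z = v.physical_points()
        assert z[-1] - z[0] == pytest.approx(430.0)

    def test_gap_plane_masked_and_zero(self):
        imgs = planes(2)
        v = stack_sections(imgs, [0.0, 20.0], z_spacing=10.0,
                           pixel_size=30.0)
        assert v.depth == 3
        assert not v.plane_mask[1]
        assert v.data[1].sum() == 0.0
        np.testing.assert_array_equal(v.data[0], imgs[0])
        np.testing.assert_array_equal(v.data[2], imgs[1])

    def test_single_section(self):
        v = stack_sections(planes(1), [0.0], pixel_size=30.0)
        assert v.depth == 1

    def test_intensities_preserved_bit_exactly(self):
        imgs = planes(5, seed=3)
        v = stack_sections(imgs, [10.0 * i for i in range(5)],
                           pixel_size=30.0)
        for i, img in enumerate(imgs):
            assert (v.data[i] == img).all()

    def test_inconsistent_shapes_rejected(self):
        imgs = [np.zeros((4, 4)), np.zeros((5, 4))]
        with pytest.raises(VolumeError, match="shape"):
            stack_sections(imgs, [0.0, 10.0], pixel_size=30.0)

    def test_gaps_without_fill_rejected(self):
        with pytest.raises(VolumeError):
            stack_sections(planes(2), [0.0, 20.0], z_spacing=10.0,
                           pixel_size=30.0, fill_gaps=False)


@settings(max_examples=60, derandomize=True)
@given(
    st.sets(st.integers(min_value=0, max_value=29), min_size=1,
            max_size=30)
)
def test_depth_and_gap_bookkeeping_for_arbitrary_dropouts(measured):
    """depth = span + 1; gap planes = depth − measured sections, exact."""
    idx = sorted(measured)
    imgs = [np.full((2, 2), float(i + 1)) for i in idx]
    v = stack_sections(imgs, [10.0 * i for i in idx], z_spacing=10.0,
                       pixel_size=30.0)
    assert v.depth == idx[-1] - idx[0] + 1
    assert v.plane_mask.sum() == len(idx)
    assert (~v.plane_mask).sum() == v.depth - len(idx)
    for img, i in zip(imgs, idx):
        assert (v.data[i - idx[0]] == img).all()


class TestThreshold:
    def make_volume(self, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.uniform(0, 1, (6, 5, 5))
        mask = np.ones(6, dtype=bool)
        mask[2] = False
        data[2] = 0.0
        return IonVolume(data=data, plane_mask=mask, pixel_size=30.0,
                         z_spacing=10.0)

    def test_tiny_fraction_keeps_all_measured_nonzero(self):
        v = self.make_volume()
        m = threshold_volume(v, 1e-12)
        expected = (v.data > 0) & v.plane_mask[:, None, None]
        np.testing.assert_array_equal(m, expected)

    def test_fraction_one_keeps_only_argmax(self):
        v = self.make_volume()
        m = threshold_volume(v, 1.0)
        assert m.sum() == 1
        assert v.data[m][0] == v.data[v.plane_mask].max()

    def test_monotone_in_fraction(self):
        v = self.make_volume(seed=5)
        for f1, f2 in [(0.1, 0.2), (0.2, 0.5), (0.5, 0.9)]:
            m1 = threshold_volume(v, f1)
            m2 = threshold_volume(v, f2)
            assert (m2 <= m1).all()

    def test_phantom_peptide_mask_matches_seeded_footprint(
        self, phantom_data, default_config
    ):
        """Thresholded ion volume recovers the seeded pixel footprint."""
        from neuromap3d.masscalc import monoisotopic_mh
        from neuromap3d.phantom import ion_volume_for

        plan = default_config.peptides[0]
        vol = ion_volume_for(
            phantom_data.sections, phantom_data.z_positions,
            monoisotopic_mh(plan.peptide),
        )
        mask = threshold_volume(vol, 0.2)
        # ground-truth footprint: pixels whose CT-space position under
        # the true pose falls inside the peptide's target regions
        target_labels = [
            lab for lab, name in phantom_data.regions.name_map.items()
            if name in plan.target_regions
        ]
        labels = phantom_data.regions.labels
        vox = phantom_data.regions.voxel_size
        truth = np.zeros_like(mask)
        px = default_config.pixel_size
        for k, z_um in enumerate(phantom_data.z_positions):
            i = int(round((z_um - phantom_data.z_positions[0])
                          / vol.z_spacing))
            for r in range(mask.shape[1]):
                for c in range(mask.shape[2]):
                    p = phantom_data.true_pose.apply(
                        [c * px, r * px, z_um]
                    )[0]
                    iz, iy, ix = (int(round(p[2] / vox)),
                                  int(round(p[1] / vox)),
                                  int(round(p[0] / vox)))
                    if (0 <= iz < labels.shape[0]
                            and 0 <= iy < labels.shape[1]
                            and 0 <= ix < labels.shape[2]):
                        truth[i, r, c] = labels[iz, iy, ix] in target_labels
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.9

    def test_all_zero_volume_rejected(self):
        v = IonVolume(
            data=np.zeros((2, 2, 2)), plane_mask=np.ones(2, bool),
            pixel_size=30.0, z_spacing=10.0,
        )
        with pytest.raises(VolumeError):
            threshold_volume(v, 0.5)


class TestTransparency:
    def test_linear_ramp(self):
        data = np.zeros((1, 1, 3))
        data[0, 0] = [0.0, 5.0, 10.0]
        v = IonVolume(data=data, plane_mask=np.ones(1, bool),
                      pixel_size=30.0, z_spacing=10.0)
        alpha = transparency_map(v, frac=0.25)
        assert alpha[0, 0, 0] == 0.0
        assert alpha[0, 0, 1] == pytest.approx(0.5)
        assert alpha[0, 0, 2] == pytest.approx(1.0)

    def test_below_cutoff_fully_transparent(self):
        data = np.zeros((1, 1, 2))
        data[0, 0] = [1.0, 10.0]
        v = IonVolume(data=data, plane_mask=np.ones(1, bool),
                      pixel_size=30.0, z_spacing=10.0)
        alpha = transparency_map(v, frac=0.25)
        assert alpha[0, 0, 0] == 0.0


def test_nrrd_round_trip(tmp_path):
    rng = np.random.default_rng(1)
    v = IonVolume(
        data=rng.uniform(0, 1, (3, 4, 5)),
        plane_mask=np.ones(3, bool),
        pixel_size=30.0,
        z_spacing=10.0,
        origin=(1.0, 2.0, 3.0),
    )
    path = tmp_path / "v.nrrd"
    save_volume_nrrd(v, str(path))
    back = load_volume_nrrd(str(path))
    np.testing.assert_allclose(back.data, v.data, atol=1e-6)
    assert back.pixel_size == pytest.approx(30.0)
    assert back.z_spacing == pytest.approx(10.0)
    assert back.origin == pytest.approx((1.0, 2.0, 3.0))
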