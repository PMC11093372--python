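"""DoG binarization, pore classification and the calcein region mask."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcnet import segmentation, synthgen
from lcnet.segmentation import (
    CalceinBandError,
    DoGParams,
    build_region_mask,
    classify_pores,
    dog_binarize,
    roi_volume,
)
from lcnet.synthgen import ImagingSpec, SurfaceSpec, generate_calcein_surfaces
from lcnet.types import (
    PORE_CANALICULAR,
    PORE_LACUNAR,
    PORE_VASCULAR,
    REGION_ENDOSTEAL_NEW,
    REGION_INTERCORTEX,
    BinaryVolume,
    ImageVolume,
    LCNetwork,
    RegionMask,
)

from conftest import NOISE_FREE, dice, make_tube_network


@pytest.fixture(scope="module")
def lacuna_with_tubes():
    """An ellipsoidal lacuna (151 um^3) with three attached 10 um tubes."""
    net = LCNetwork()
    centre = np.array([15.0, 15.0, 7.0])
    semi = np.array([6.0, 3.0, 2.0])
    net.add_node(0, centre, "lacunar")
    for i, d in enumerate([np.array([0, 1.0, 0]), np.array([1.0, 0, 0]),
                           np.array([0, -1.0, 0])]):
        p0 = centre + d / np.sqrt(np.sum((d / semi) ** 2))
        p1 = p0 + 10.0 * d
        net.add_node(i + 1, p1, "endpoint")
        net.add_edge(0, i + 1, np.vstack([p0, p1]))
    gt = synthgen.GroundTruth(network=net, total_length=30.0,
                              per_cell_lengths={}, lacunae=[(centre, semi)],
                              domain_size=(30.0, 30.0, 14.0))
    image, mask = synthgen.render_volume(
        net, gt, ImagingSpec(**NOISE_FREE), canalicular_radius=0.4)
    return image, mask


class TestDogBinarize:
    def test_uniform_volume_empty(self):
        img = ImageVolume(np.full((30, 30, 20), 5.0), (0.3, 0.3, 0.3))
        assert not dog_binarize(img).foreground.any()

    def test_tube_phantom_dice(self):
        net, gt = make_tube_network([[(10, 2, 5), (10, 18, 5)]], (20, 20, 10))
        image, mask = synthgen.render_volume(
            net, gt, ImagingSpec(voxel_size=(0.3, 0.3, 0.3), **NOISE_FREE),
            canalicular_radius=0.5)
        binary = dog_binarize(image)
        assert dice(binary.foreground, mask > 0) >= 0.8

    def test_union_of_single_passes(self, lacuna_with_tubes):
        image, _mask = lacuna_with_tubes
        binary = dog_binarize(image)
        thin = segmentation._single_pass(image, segmentation.CANALICULAR_DOG)
        bulky = segmentation._single_pass(image, segmentation.LACUNAR_DOG)
        assert np.array_equal(binary.foreground, thin | bulky)

    @settings(deadline=None, max_examples=5)
    @given(shift=st.floats(min_value=-500.0, max_value=500.0,
                           allow_nan=False, allow_infinity=False))
    def test_intensity_shift_invariance(self, lacuna_with_tubes, shift):
        image, _mask = lacuna_with_tubes
        base = dog_binarize(image).foreground
        shifted = dog_binarize(ImageVolume(image.voxels + shift,
                                           image.voxel_size))
        assert np.array_equal(shifted.foreground, base)

    def test_bad_sigmas_rejected(self):
        with pytest.raises(ValueError):
            DoGParams(sigma_small=-1.0, sigma_large=0.5)
        with pytest.raises(ValueError):
            DoGParams(sigma_small=0.7, sigma_large=0.5)


class TestClassifyPores:
    def test_lacuna_and_tubes_agreement(self, lacuna_with_tubes):
        """Ellipsoid voxels come back lacunar, tube voxels canalicular."""
        image, mask = lacuna_with_tubes
        binary = classify_pores(dog_binarize(image))
        lac_agree = (binary.class_labels[mask == PORE_LACUNAR]
                     == PORE_LACUNAR).mean()
        can_agree = (binary.class_labels[mask == PORE_CANALICULAR]
                     == PORE_CANALICULAR).mean()
        assert lac_agree >= 0.95
        assert can_agree >= 0.95

    def test_small_tube_is_canalicular(self):
        fg = np.zeros((20, 20, 10), dtype=bool)
        fg[5:10, 10, 5] = True  # ~0.2 um^3 at (0.35 um)^3 voxels
        binary = classify_pores(BinaryVolume(fg, (0.35, 0.35, 0.35)))
        assert np.all(binary.class_labels[fg] == PORE_CANALICULAR)

    def test_long_channel_is_vascular(self):
        vs = (0.5, 0.5, 0.5)
        fg = np.zeros((60, 20, 20), dtype=bool)
        fg[2:58, 5:12, 5:12] = True  # 28 um long, >> 300 um^3
        binary = classify_pores(BinaryVolume(fg, vs))
        assert np.all(binary.class_labels[fg] == PORE_VASCULAR)

    def test_idempotent_and_partition(self, lacuna_with_tubes):
        image, _mask = lacuna_with_tubes
        once = classify_pores(dog_binarize(image))
        twice = classify_pores(once)
        assert np.array_equal(once.class_labels, twice.class_labels)
        assert np.array_equal(once.class_labels > 0, once.foreground)

    def test_empty_input(self):
        binary = classify_pores(BinaryVolume(np.zeros((5, 5, 5), bool),
                                             (0.5, 0.5, 0.5)))
        assert not binary.class_labels.any()


class TestRegionMask:
    def test_planar_bands_recovered_within_one_voxel(self):
        calcein, truth = generate_calcein_surfaces(
            (30, 50, 8), (SurfaceSpec(15.0), SurfaceSpec(40.0)),
            voxel_size=(0.5, 0.5, 0.5))
        mask = build_region_mask(calcein)
        for fitted, true_b in zip(mask.boundary_positions,
                                  truth.boundary_positions):
            assert np.max(np.abs(fitted - true_b)) <= 0.5
        agree = (mask.labels == truth.labels).mean()
        assert agree > 0.98

    def test_sinusoidal_bands_recovered(self):
        calcein, truth = generate_calcein_surfaces(
            (40, 50, 8),
            (SurfaceSpec(15.0, kind="sinusoidal", amplitude=2.0, period=20.0),
             SurfaceSpec(38.0)), voxel_size=(0.5, 0.5, 0.5))
        mask = build_region_mask(calcein)
        for fitted, true_b in zip(mask.boundary_positions,
                                  truth.boundary_positions):
            assert np.median(np.abs(fitted - true_b)) <= 0.75

    def test_partition_property(self):
        calcein, _ = generate_calcein_surfaces(
            (30, 50, 8), (SurfaceSpec(15.0), SurfaceSpec(40.0)),
            voxel_size=(0.5, 0.5, 0.5))
        bone = np.ones(calcein.shape, dtype=bool)
        bone[:5] = False
        mask = build_region_mask(calcein, bone_mask=bone)
        assert (mask.labels > 0).sum() == bone.sum()
        counts = np.bincount(mask.labels[bone].ravel(), minlength=4)
        assert counts[1:].sum() == bone.sum()

    def test_missing_band_raises(self):
        calcein, _ = generate_calcein_surfaces(
            (30, 50, 8), (SurfaceSpec(15.0), SurfaceSpec(40.0)),
            voxel_size=(0.5, 0.5, 0.5))
        one_band = ImageVolume(np.where(
            (np.arange(calcein.shape[1]) * 0.5)[None, :, None] < 25,
            calcein.voxels, 0.0), calcein.voxel_size, channel="calcein")
        with pytest.raises(CalceinBandError, match="band"):
            build_region_mask(one_band)
        flat = ImageVolume(np.zeros_like(calcein.voxels), calcein.voxel_size)
        with pytest.raises(CalceinBandError, match="missing both"):
            build_region_mask(flat)


class TestRoiVolume:
    def _mask(self, shape, vs):
        labels = np.full(shape, REGION_INTERCORTEX, dtype=np.uint8)
        return RegionMask(labels, vs, [np.zeros((shape[0], shape[2]))] * 2)

    def test_pure_region_volume(self):
        mask = self._mask((10, 10, 10), (0.5, 0.5, 0.5))
        assert roi_volume(mask, None) == pytest.approx(125.0)

    def test_region_fully_lacunar_is_zero(self):
        shape = (10, 10, 10)
        mask = self._mask(shape, (0.5, 0.5, 0.5))
        fg = np.ones(shape, dtype=bool)
        labels = np.full(shape, PORE_LACUNAR, dtype=np.uint8)
        binary = BinaryVolume(fg, (0.5, 0.5, 0.5), class_labels=labels)
        assert roi_volume(mask, binary) == 0.0

    def test_known_lacuna_volume_excluded(self, lacuna_with_tubes):
        image, pore_mask = lacuna_with_tubes
        vs = image.voxel_size
        labels = np.full(image.shape, REGION_INTERCORTEX, dtype=np.uint8)
        mask = RegionMask(labels, vs, [np.zeros((image.shape[0],
                                                 image.shape[2]))] * 2)
        class_labels = pore_mask.astype(np.uint8)  # ground-truth classes
        binary = BinaryVolume(pore_mask > 0, vs, class_labels=class_labels)
        v_l = 4.0 / 3.0 * np.pi * 6.0 * 3.0 * 2.0
        expected = labels.size * np.prod(vs) - v_l
        surface_tol = 150.0 * np.prod(vs) / min(vs)  # ~one voxel shell
        assert abs(roi_volume(mask, binary)
                   - expected) < surface_tol + 30.0 * np.pi * 0.4 ** 2
        # additivity over regions
        half = labels.copy()
        half[:, :30] = REGION_ENDOSTEAL_NEW
        mask2 = RegionMask(half, vs, mask.boundary_positions)
        total = roi_volume(mask2, binary, REGION_ENDOSTEAL_NEW) + \
            roi_volume(mask2, binary, REGION_INTERCORTEX)
        assert total == pytest.approx(roi_volume(mask2, binary))

    def test_mismatched_grids_rejected(self):
        mask = self._mask((10, 10, 10), (0.5, 0.5, 0.5))
        binary = BinaryVolume(np.zeros((5, 5, 5), bool), (0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="match"):
            roi_volume(mask, binary)
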