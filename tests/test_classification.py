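"""Lung splitting and anatomical fissure labeling."""

import numpy as np
import pytest

from fissint.classification import (
    ClassificationError,
    classify_patches,
    label_volume,
    split_lungs,
)
from fissint.detection import compute_plateness, extract_fissure_voxels
from fissint.phantom import FISSURE_LABELS
from fissint.surfaces import components

SPACING = (0.7, 0.7, 0.625)


def _detected_patches(volume, truth, spacing):
    pm = compute_plateness(volume, lung_mask=truth.lung_mask)
    det = extract_fissure_voxels(pm)
    left, right = split_lungs(truth.lung_mask)
    patches = {}
    for side, lung in (("left", left), ("right", right)):
        comps = components(det & lung)
        for p in classify_patches(comps, side, lung, spacing):
            patches[p.label] = p
    return patches


class TestSplitLungs:
    def test_labeled_mask_honored(self, phantom_noise_free):
        _, _, truth = phantom_noise_free
        left, right = split_lungs(truth.lung_mask)
        assert np.array_equal(left, truth.lung_mask == 1)
        assert np.array_equal(right, truth.lung_mask == 2)

    def test_binary_mask_split_by_position(self, phantom_noise_free):
        _, _, truth = phantom_noise_free
        left, right = split_lungs((truth.lung_mask > 0).astype(np.uint8))
        assert np.array_equal(left, truth.lung_mask == 1)
        assert np.array_equal(right, truth.lung_mask == 2)

    def test_mirrored_volume_swaps_sides(self, phantom_noise_free):
        _, _, truth = phantom_noise_free
        mirrored = (truth.lung_mask > 0).astype(np.uint8)[::-1]
        left, right = split_lungs(mirrored)
        # what was the right lung (high x) is now at low x -> left
        assert np.array_equal(left, (truth.lung_mask == 2)[::-1])
        assert np.array_equal(right, (truth.lung_mask == 1)[::-1])

    def test_single_component_without_labels_raises(self):
        blob = np.zeros((20, 20, 20), dtype=np.uint8)
        blob[5:15, 5:15, 5:15] = 1
        with pytest.raises(ClassificationError):
            split_lungs(blob)


class TestClassifyPatches:
    def test_phantom_sheets_get_their_anatomical_labels(self, phantom_noise_free):
        _, volume, truth = phantom_noise_free
        patches = _detected_patches(volume, truth, volume.spacing)
        assert set(patches) == set(FISSURE_LABELS)
        # each label's voxels should overwhelmingly match its truth sheet
        for lb in FISSURE_LABELS:
            vox = patches[lb].voxels
            near = truth.boundary_truth[lb]
            from scipy import ndimage

            halo = ndimage.binary_dilation(near, np.ones((3, 3, 3)), iterations=2)
            assert (vox & halo).sum() / vox.sum() >= 0.95

    def test_per_voxel_accuracy_under_noise(self, phantom_noisy):
        _, volume, truth = phantom_noisy
        patches = _detected_patches(volume, truth, volume.spacing)
        from scipy import ndimage

        correct = total = 0
        for lb in FISSURE_LABELS:
            vox = patches[lb].voxels
            halo = ndimage.binary_dilation(
                truth.boundary_truth[lb], np.ones((3, 3, 3)), iterations=2
            )
            correct += (vox & halo).sum()
            total += vox.sum()
        assert correct / total >= 0.95

    def test_left_lung_components_always_lof(self, phantom_noise_free):
        _, volume, truth = phantom_noise_free
        left, _ = split_lungs(truth.lung_mask)
        # any blob handed in as a left-lung component gets LOF
        blob = np.zeros_like(left)
        blob[30:33, 40:60, 40:60] = left[30:33, 40:60, 40:60]
        patches = classify_patches([blob], "left", left, volume.spacing)
        assert [p.label for p in patches] == ["LOF"]

    def test_translation_invariance(self, phantom_noise_free):
        _, volume, truth = phantom_noise_free
        _, right = split_lungs(truth.lung_mask)
        sheet = truth.fissure_truth["RHF"]
        patches = classify_patches([sheet], "right", right, volume.spacing)
        shift = (3, -2, 2)
        sheet_t = np.roll(sheet, shift, axis=(0, 1, 2))
        right_t = np.roll(right, shift, axis=(0, 1, 2))
        patches_t = classify_patches([sheet_t], "right", right_t, volume.spacing)
        assert {p.label for p in patches} == {p.label for p in patches_t} == {"RHF"}

    def test_oblique_truth_sheet_is_rof(self, phantom_noise_free):
        _, volume, truth = phantom_noise_free
        _, right = split_lungs(truth.lung_mask)
        patches = classify_patches(
            [truth.fissure_truth["ROF"]], "right", right, volume.spacing
        )
        assert [p.label for p in patches] == ["ROF"]

    def test_empty_component_rejected(self, phantom_noise_free):
        _, volume, truth = phantom_noise_free
        _, right = split_lungs(truth.lung_mask)
        with pytest.raises(ClassificationError):
            classify_patches(
                [np.zeros_like(right)], "right", right, volume.spacing
            )

    def test_label_volume_encoding(self, phantom_noise_free):
        _, volume, truth = phantom_noise_free
        patches = _detected_patches(volume, truth, volume.spacing)
        encoded = label_volume(list(patches.values()))
        assert set(np.unique(encoded)) <= {0, 1, 2, 3}
        assert (encoded[patches["ROF"].voxels] == 1).all()
        assert (encoded[patches["RHF"].voxels] == 2).all()
        assert (encoded[patches["LOF"].voxels] == 3).all()
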