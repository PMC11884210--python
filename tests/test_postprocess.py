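"""Thresholding, connected components, object selection and hole filling."""

import numpy as np
import pytest

from triseg.postprocess import (
    TABLE_PRESETS,
    ClassRule,
    ConfigurationError,
    PostProcessSpec,
    apply_postprocess,
    enforce_touch,
    fill_holes,
    label_components,
    remove_small_objects,
    select_n_largest,
    threshold_probabilities,
)
from triseg.triplanar import ProbabilityVolume
from triseg.volumes import LabelVolume, one_hot_probabilities


def flood_fill_components(mask):
    """Brute-force 26-connectivity component labelling (independent oracle)."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, int)
    current = 0
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= n[i] < mask.shape[i] for i in range(3)):
                    if mask[n] and not labels[n]:
                        labels[n] = current
                        stack.append(n)
    return labels, current


def prob_volume(vectors, spacing=(1.0, 1.0, 1.0)):
    """Build a 1-voxel-deep ProbabilityVolume from a list of class vectors."""
    arr = np.array(vectors, np.float32).T[:, :, None, None]
    return ProbabilityVolume(arr, spacing)


class TestThreshold:
    def _spec(self, **thr):
        return PostProcessSpec({k: ClassRule(v) for k, v in thr.items()})

    def test_majority_class_wins(self):
        prob = prob_volume([[0.3, 0.6, 0.1]])
        out = threshold_probabilities(prob, self._spec(A=0.5, B=0.5))
        assert out.data[0, 0, 0] == 1

    def test_lowered_threshold_beats_background_majority(self):
        prob = prob_volume([[0.55, 0.30, 0.15]])
        out = threshold_probabilities(prob, self._spec(A=0.125, B=0.125))
        assert out.data[0, 0, 0] == 1  # A wins among passers despite bg 0.55

    def test_no_passer_gives_background(self):
        prob = prob_volume([[0.6, 0.4]])
        out = threshold_probabilities(prob, self._spec(A=0.5))
        assert out.data[0, 0, 0] == 0

    def test_tie_goes_to_lower_class_index(self):
        prob = prob_volume([[0.2, 0.4, 0.4]])
        out = threshold_probabilities(prob, self._spec(A=0.25, B=0.25))
        assert out.data[0, 0, 0] == 1

    def test_class_count_mismatch_rejected(self):
        prob = prob_volume([[0.5, 0.5]])
        with pytest.raises(ConfigurationError):
            threshold_probabilities(prob, self._spec(A=0.5, B=0.5))


class TestComponents:
    def test_corner_adjacency_is_connected(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        _, counts = label_components(mask)
        assert len(counts) == 1

    def test_gap_of_two_disconnects(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = mask[2, 2, 2] = True
        _, counts = label_components(mask)
        assert len(counts) == 2

    def test_empty_mask(self):
        _, counts = label_components(np.zeros((3, 3, 3), bool))
        assert len(counts) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((10, 10, 10)) < 0.2
        comp, counts = label_components(mask)
        oracle, n_oracle = flood_fill_components(mask)
        assert len(counts) == n_oracle
        # same partition: component ids must map one-to-one
        for cid in range(1, len(counts) + 1):
            ids = np.unique(oracle[comp == cid])
            assert len(ids) == 1


class TestSelectNLargest:
    def _blobs(self):
        mask = np.zeros((10, 30, 10), bool)
        mask[2:7, 1:5, 2:7] = True  # 100 voxels
        mask[2:6, 10:15, 2:4] = True  # 40 voxels
        mask[2:3, 20:23, 2:3] = True  # 3 voxels
        return mask

    def test_keeps_two_largest(self):
        out = select_n_largest(self._blobs(), 2)
        _, counts = label_components(out)
        assert sorted(counts.tolist(), reverse=True) == [100, 40]

    def test_single_component_identity(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        np.testing.assert_array_equal(select_n_largest(mask, 1), mask)

    @pytest.mark.parametrize("n", [1, 2, 3, 5])
    def test_component_count_bounded(self, n):
        out = select_n_largest(self._blobs(), n)
        _, counts = label_components(out)
        assert len(counts) <= n


class TestRemoveSmall:
    def test_point_one_ml_rule_at_1mm(self):
        mask = np.zeros((6, 20, 20), bool)
        mask[1:5, 1:6, 1:6] = True  # 4*5*5 = 100 voxels = 0.1 ml: kept
        mask2 = np.zeros((6, 20, 20), bool)
        mask2[0:4, 10:15, 10:15] = True
        mask2[0, 10, 10] = False  # 99 voxels = 0.099 ml: removed
        out_keep = remove_small_objects(mask, (1, 1, 1), 0.1)
        out_drop = remove_small_objects(mask2, (1, 1, 1), 0.1)
        assert out_keep.sum() == 100
        assert out_drop.sum() == 0

    def test_voxel_volume_scales_with_spacing(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[1:2, 1:5, 1:4] = True  # 12 voxels
        mask[1, 1, 4] = True  # +1 adjacent voxel -> 13, one component
        assert mask.sum() == 13
        # 13 voxels x 8 mm^3 = 0.104 ml >= 0.1 ml: kept
        out = remove_small_objects(mask, (2, 2, 2), 0.1)
        assert out.sum() == 13

    def test_empty_mask(self):
        out = remove_small_objects(np.zeros((3, 3, 3), bool), (1, 1, 1), 0.1)
        assert not out.any()

    def test_all_survivors_meet_minimum(self):
        rng = np.random.default_rng(0)
        mask = rng.random((12, 12, 12)) < 0.3
        out = remove_small_objects(mask, (1, 1, 1), 0.01)
        _, counts = label_components(out)
        assert all(c >= 10 for c in counts)


class TestEnforceTouch:
    def _slab_and_tubes(self):
        slab = np.zeros((10, 20, 20), bool)
        slab[2:8, 2:8, 2:18] = True
        touching = np.zeros_like(slab)
        touching[2:8, 8:10, 5:8] = True  # abuts slab at y=8
        detached = np.zeros_like(slab)
        detached[2:8, 12:14, 5:8] = True  # 3 voxels away
        return slab, touching, detached

    def test_abutting_kept_detached_removed(self):
        slab, touching, detached = self._slab_and_tubes()
        mask = touching | detached
        out = enforce_touch(mask, slab)
        np.testing.assert_array_equal(out, touching)

    def test_full_other_is_identity(self):
        _, touching, detached = self._slab_and_tubes()
        mask = touching | detached
        out = enforce_touch(mask, np.ones_like(mask))
        np.testing.assert_array_equal(out, mask)

    def test_empty_other_empties_result(self):
        _, touching, _ = self._slab_and_tubes()
        out = enforce_touch(touching, np.zeros_like(touching))
        assert not out.any()

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(1)
        mask = rng.random((8, 8, 8)) < 0.3
        other = rng.random((8, 8, 8)) < 0.1
        out = enforce_touch(mask, other)
        assert not (out & ~mask).any()


class TestFillHoles:
    def test_hollow_shell_becomes_solid(self):
        shell = np.zeros((7, 7, 7), bool)
        shell[1:6, 1:6, 1:6] = True
        shell[2:5, 2:5, 2:5] = False
        out = fill_holes(shell)
        expected = np.zeros((7, 7, 7), bool)
        expected[1:6, 1:6, 1:6] = True
        np.testing.assert_array_equal(out, expected)

    def test_solid_cube_unchanged_and_idempotent(self):
        cube = np.zeros((5, 5, 5), bool)
        cube[1:4, 1:4, 1:4] = True
        once = fill_holes(cube)
        np.testing.assert_array_equal(once, cube)
        np.testing.assert_array_equal(fill_holes(once), once)

    def test_open_cavity_not_filled(self):
        # C-shape: cavity connected to the border through an opening
        c = np.zeros((5, 7, 7), bool)
        c[1:4, 1:6, 1:6] = True
        c[1:4, 2:5, 2:5] = False  # cavity
        c[1:4, 0:3, 3] = False  # channel from cavity to border
        c[1:4, 2:5, 2:5] = False
        out = fill_holes(c)
        np.testing.assert_array_equal(out, c)

    def test_monotone(self):
        rng = np.random.default_rng(2)
        mask = rng.random((8, 8, 8)) < 0.4
        out = fill_holes(mask)
        assert (out | mask == out).all()


class TestApplySpec:
    def test_circular_must_touch_rejected(self):
        spec = PostProcessSpec(
            {"a": ClassRule(0.5, must_touch="b"), "b": ClassRule(0.5, must_touch="a")}
        )
        with pytest.raises(ConfigurationError):
            spec.processing_order()

    def test_unknown_must_touch_rejected(self):
        with pytest.raises(ConfigurationError):
            PostProcessSpec({"a": ClassRule(0.5, must_touch="ghost")})

    def test_presets_cover_published_settings(self):
        spec = TABLE_PRESETS["pulmonary_tracheal"]
        assert spec.rules["trachea"].must_touch == "parenchyma"
        assert spec.rules["parenchyma"].n_largest == 2
        assert TABLE_PRESETS["oculo_cranial"].rules["eyes"].n_largest == 2
        assert TABLE_PRESETS["oculo_cranial"].rules["orbita"].threshold == 0.125

    def _trachea_scene(self):
        """Parenchyma slab + one abutting and one detached trachea candidate."""
        labels = np.zeros((10, 24, 24), np.int16)
        labels[2:8, 2:10, 2:22] = 1  # parenchyma
        # candidates are > 100 voxels so the 0.1 ml rule keeps both
        labels[2:8, 10:13, 4:10] = 2  # trachea candidate touching parenchyma
        labels[2:8, 16:19, 14:20] = 2  # detached candidate
        return LabelVolume(labels, (1.0, 1.0, 1.0), ["parenchyma", "trachea"])

    def test_trachea_touch_rule_keeps_one_candidate(self):
        lab = self._trachea_scene()
        prob = ProbabilityVolume(one_hot_probabilities(lab), lab.spacing, lab.class_names)
        spec = PostProcessSpec(
            {
                "parenchyma": ClassRule(0.5, n_largest=2),
                "trachea": ClassRule(0.5, n_largest=1, must_touch="parenchyma"),
            }
        )
        out = apply_postprocess(prob, spec)
        _, counts = label_components(out.data == 2)
        assert len(counts) == 1
        # the survivor is the touching candidate
        assert (out.data[2:8, 10:13, 4:10] == 2).all()
        assert not (out.data[2:8, 16:19, 14:20] == 2).any()

    def test_default_path_equals_primitive_chain(self):
        lab = self._trachea_scene()
        prob = ProbabilityVolume(one_hot_probabilities(lab), lab.spacing, lab.class_names)
        spec = PostProcessSpec(
            {"parenchyma": ClassRule(0.5), "trachea": ClassRule(0.5)}
        )
        out = apply_postprocess(prob, spec)
        expected = threshold_probabilities(prob, spec)
        for cid in (1, 2):
            m = fill_holes(expected.data == cid)
            m = remove_small_objects(m, prob.spacing, 0.1)
            np.testing.assert_array_equal(out.data == cid, m)

    def test_idempotent_on_one_hot_reencoding(self):
        lab = self._trachea_scene()
        prob = ProbabilityVolume(one_hot_probabilities(lab), lab.spacing, lab.class_names)
        spec = PostProcessSpec(
            {
                "parenchyma": ClassRule(0.5, n_largest=2),
                "trachea": ClassRule(0.5, n_largest=1, must_touch="parenchyma"),
            }
        )
        once = apply_postprocess(prob, spec)
        prob2 = ProbabilityVolume(
            one_hot_probabilities(once, 2), once.spacing, once.class_names
        )
        twice = apply_postprocess(prob2, spec)
        np.testing.assert_array_equal(once.data, twice.data)
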