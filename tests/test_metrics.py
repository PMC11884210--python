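"""Dice/Jaccard scores and surface-distance metrics against brute-force oracles."""

import numpy as np
import pytest

from triseg.metrics import (
    ConfusionCounts,
    EmptySurfaceError,
    confusion_counts,
    evaluate_case,
    extract_surface,
    nearest_on_surface,
    overlap_scores,
    surface_distance_summary,
    surface_distances,
)
from triseg.volumes import LabelVolume, ValidationError


def brute_force_overlap(gt_mask, pred_mask):
    """Independent set-overlap computation of Dice and Jaccard."""
    g = {tuple(v) for v in np.argwhere(gt_mask)}
    p = {tuple(v) for v in np.argwhere(pred_mask)}
    inter = len(g & p)
    union = len(g | p)
    if not union:
        return 1.0, 1.0
    return 2 * inter / (len(g) + len(p)), inter / union


def brute_force_point_triangle(point, tri):
    """Closest distance from a point to one triangle by dense sampling-free math.

    Minimises |p - (a + u*(b-a) + v*(c-a))| over the barycentric simplex with
    a fine grid — slow but independent of the analytic implementation.
    """
    a, b, c = tri
    us = np.linspace(0, 1, 60)
    best = np.inf
    for u in us:
        vs = np.linspace(0, 1 - u, max(2, int(60 * (1 - u)) + 1))
        pts = a + u * (b - a) + np.outer(vs, c - a)
        d = np.linalg.norm(pts - point, axis=1).min()
        best = min(best, d)
    return best


class TestOverlapScores:
    def test_exact_values(self):
        dice, jaccard = overlap_scores(ConfusionCounts(10, 5, 5))
        assert dice == pytest.approx(2 / 3, abs=1e-4)
        assert jaccard == pytest.approx(0.5)

    def test_perfect_overlap(self):
        assert overlap_scores(ConfusionCounts(42, 0, 0)) == (1.0, 1.0)

    def test_empty_vs_empty_convention(self):
        assert overlap_scores(ConfusionCounts(0, 0, 0)) == (1.0, 1.0)

    def test_jaccard_dice_identity_random_triples(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            tp, fp, fn = rng.integers(0, 1000, 3)
            if 2 * tp + fp + fn == 0:
                continue
            dice, jaccard = overlap_scores(ConfusionCounts(int(tp), int(fp), int(fn)))
            assert abs(jaccard - dice / (2 - dice)) <= 1e-9

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionCounts(-1, 0, 0)


class TestConfusionCounts:
    def _lab(self, data):
        return LabelVolume(np.asarray(data, np.int16), (1.0, 1.0, 1.0))

    def test_identical_volumes(self, rng):
        data = rng.integers(0, 3, (6, 6, 6)).astype(np.int16)
        c = confusion_counts(self._lab(data), self._lab(data), 1)
        assert c.fp == 0 and c.fn == 0

    def test_superset_prediction(self):
        gt = np.zeros((4, 4, 4), np.int16)
        gt[1, 1, :2] = 1
        gt[1, 2, :] = 1
        gt[2, 1, :] = 1  # 10 voxels
        pred = gt.copy()
        pred[3, 3, :] = 1
        pred[3, 2, 3] = 1  # 5 extra
        c = confusion_counts(self._lab(gt), self._lab(pred), 1)
        assert (c.tp, c.fp, c.fn) == (10, 5, 0)

    def test_disjoint_masks(self):
        gt = np.zeros((3, 3, 3), np.int16)
        gt[0, 0, 0] = 1
        pred = np.zeros((3, 3, 3), np.int16)
        pred[2, 2, 2] = 1
        c = confusion_counts(self._lab(gt), self._lab(pred), 1)
        assert c.tp == 0

    def test_lattice_mismatch_rejected(self):
        a = self._lab(np.zeros((3, 3, 3)))
        b = LabelVolume(np.zeros((3, 3, 3), np.int16), (2.0, 1.0, 1.0))
        with pytest.raises(ValidationError):
            confusion_counts(a, b, 1)

    @pytest.mark.parametrize("seed", range(4))
    def test_oracle_equivalence_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            gt = (rng.random((16, 16, 16)) < 0.3).astype(np.int16)
            pred = (rng.random((16, 16, 16)) < 0.3).astype(np.int16)
            dice, jaccard = overlap_scores(
                confusion_counts(self._lab(gt), self._lab(pred), 1)
            )
            bf_dice, bf_jaccard = brute_force_overlap(gt == 1, pred == 1)
            assert dice == bf_dice and jaccard == bf_jaccard


class TestSurfaceExtraction:
    def test_cube_area_within_10pct(self):
        mask = np.zeros((14, 14, 14), bool)
        mask[2:12, 2:12, 2:12] = True  # 10 mm cube at 1 mm spacing
        mesh = extract_surface(mask, (1, 1, 1)).as_trimesh()
        assert mesh.area == pytest.approx(600.0, rel=0.10)

    def test_sphere_area_within_10pct(self):
        zz, yy, xx = np.meshgrid(*[np.arange(24)] * 3, indexing="ij")
        mask = (zz - 11.5) ** 2 + (yy - 11.5) ** 2 + (xx - 11.5) ** 2 <= 64
        mesh = extract_surface(mask, (1, 1, 1)).as_trimesh()
        assert mesh.area == pytest.approx(4 * np.pi * 64, rel=0.10)

    def test_watertight(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        assert extract_surface(mask, (1, 1, 1)).as_trimesh().is_watertight

    def test_outward_normals_on_sphere(self):
        zz, yy, xx = np.meshgrid(*[np.arange(20)] * 3, indexing="ij")
        mask = (zz - 9.5) ** 2 + (yy - 9.5) ** 2 + (xx - 9.5) ** 2 <= 36
        mesh = extract_surface(mask, (1, 1, 1))
        radial = mesh.vertices - np.array([9.5, 9.5, 9.5])
        outward = np.einsum("ij,ij->i", radial, mesh.vertex_normals)
        assert (outward > 0).mean() > 0.99

    def test_spacing_scales_world_coordinates(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[1:5, 1:5, 1:5] = True
        m1 = extract_surface(mask, (1, 1, 1)).as_trimesh()
        m2 = extract_surface(mask, (2, 2, 2)).as_trimesh()
        assert m2.area == pytest.approx(4 * m1.area, rel=1e-6)

    def test_empty_mask_raises(self):
        with pytest.raises(EmptySurfaceError):
            extract_surface(np.zeros((4, 4, 4), bool), (1, 1, 1))


class TestSurfaceDistances:
    def _cube_mesh(self, lo, hi, n=14):
        mask = np.zeros((n, n, n), bool)
        mask[lo:hi, lo:hi, lo:hi] = True
        return extract_surface(mask, (1, 1, 1))

    def test_identical_meshes_zero(self):
        m = self._cube_mesh(2, 12)
        assert surface_distance_summary(m, m) == (0.0, 0.0, 0.0)

    def test_nested_cubes_p95_near_1mm(self):
        inner = self._cube_mesh(2, 12)
        outer = self._cube_mesh(1, 13)
        p95_signed, p95_abs, _ = surface_distance_summary(inner, outer)
        assert p95_abs == pytest.approx(1.0, abs=0.3)
        # dilated prediction lies outside the truth: signed distances positive
        assert p95_signed > 0

    def test_shrunk_prediction_signed_negative(self):
        outer = self._cube_mesh(1, 13)
        inner = self._cube_mesh(2, 12)
        d = surface_distances(outer, inner)
        assert np.median(d) < 0

    def test_signed_magnitude_bounded_by_absolute(self, rng):
        a = self._cube_mesh(2, 12)
        b = self._cube_mesh(3, 11)
        p95_signed, p95_abs, _ = surface_distance_summary(a, b)
        assert abs(p95_signed) <= p95_abs + 1e-12

    def test_nearest_distance_matches_brute_force(self, rng):
        zz, yy, xx = np.meshgrid(*[np.arange(10)] * 3, indexing="ij")
        mask = (zz - 4.5) ** 2 + (yy - 4.5) ** 2 + (xx - 4.5) ** 2 <= 9
        mesh = extract_surface(mask, (1, 1, 1))
        assert mesh.num_triangles <= 500
        points = rng.uniform(0, 9, size=(25, 3))
        _, dists = nearest_on_surface(points, mesh)
        tri = mesh.vertices[mesh.triangles]
        for p, d in zip(points, dists):
            bf = min(brute_force_point_triangle(p, t) for t in tri)
            assert d == pytest.approx(bf, abs=5e-3)


class TestEvaluateCase:
    def _sphere_label(self, radius, n=20, class_id=1):
        zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        c = (n - 1) / 2
        mask = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
        return LabelVolume(mask.astype(np.int16) * class_id, (1.0, 1.0, 1.0), ["obj"])

    def test_perfect_prediction(self):
        gt = self._sphere_label(6)
        report = evaluate_case(gt, gt)
        m = report[1]
        assert m.dice == 1.0 and m.jaccard == 1.0
        assert m.p95_abs_mm == 0.0 and m.median_abs_mm == 0.0

    def test_empty_prediction_convention(self):
        gt = self._sphere_label(6)
        pred = LabelVolume(np.zeros(gt.shape, np.int16), gt.spacing, ["obj"])
        m = evaluate_case(gt, pred)[1]
        assert m.dice == 0.0
        assert m.p95_abs_mm is None and m.median_abs_mm is None

    def test_report_satisfies_jaccard_identity(self, rng):
        gt = self._sphere_label(6)
        pred = self._sphere_label(5)
        m = evaluate_case(gt, pred)[1]
        assert m.jaccard == pytest.approx(m.dice / (2 - m.dice), abs=1e-9)

    def test_shrinking_prediction_decreases_dice(self):
        gt = self._sphere_label(7)
        dices = [evaluate_case(gt, self._sphere_label(r), surface=False)[1].dice
                 for r in (7, 6, 5, 4)]
        assert dices == sorted(dices, reverse=True)
        assert dices[0] > dices[-1]

    def test_dice_symmetric(self, rng):
        a = self._sphere_label(6)
        b = self._sphere_label(4)
        assert evaluate_case(a, b, surface=False)[1].dice == pytest.approx(
            evaluate_case(b, a, surface=False)[1].dice
        )

    def test_dataframe_export(self):
        gt = self._sphere_label(5)
        df = evaluate_case(gt, gt, surface=False).to_dataframe()
        assert {"class_name", "dice", "jaccard"} <= set(df.columns)
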