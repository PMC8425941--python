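import csv
import json

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from dwiseg.metrics import (
    CaseEvaluation,
    DegenerateInputError,
    UndefinedDistanceError,
    cases_to_csv,
    dice,
    evaluate_case,
    hausdorff,
    paired_t,
    pearson,
    soft_dice_loss,
    summarize_group,
    summary_to_json,
)
from dwiseg.volume_io import ImageVolume, LabelVolume, ProbabilityVolume, ShapeError


def brute_hausdorff(a, b):
    """O(|A||B|) oracle: symmetrized max of directed nearest distances."""
    pa, pb = np.argwhere(a).astype(float), np.argwhere(b).astype(float)
    d = cdist(pa, pb)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def random_mask(rng, p=0.2, shape=(8, 8, 8)):
    while True:
        m = rng.random(shape) < p
        if m.any():
            return m


class TestDice:
    def test_identity(self):
        a = np.zeros((4, 4, 4), bool)
        a[1:3, 1:3, 1:3] = True
        assert dice(a, a) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4, 1), bool)
        b = np.zeros((4, 4, 1), bool)
        a[0, 0, 0], b[3, 3, 0] = True, True
        assert dice(a, b) == 0.0

    def test_half_overlap(self):
        # |A| = |B| = 4, |A n B| = 2 -> 2*2/(4+4) = 0.5
        a = np.zeros((8, 8, 1), bool)
        b = np.zeros((8, 8, 1), bool)
        a[0, 0:4, 0] = True
        b[0, 2:6, 0] = True
        assert dice(a, b) == 0.5

    def test_both_empty_is_one(self):
        z = np.zeros((3, 3, 3), bool)
        assert dice(z, z) == 1.0

    def test_empty_vs_nonempty_is_zero(self):
        a = np.zeros((3, 3, 3), bool)
        b = a.copy()
        b[1, 1, 1] = True
        assert dice(a, b) == 0.0

    def test_symmetry_and_range(self, rng):
        for _ in range(50):
            a, b = random_mask(rng), random_mask(rng)
            d = dice(a, b)
            assert d == dice(b, a)
            assert 0.0 <= d <= 1.0

    def test_lattice_mismatch(self):
        with pytest.raises(ShapeError):
            dice(np.zeros((2, 2, 2), bool), np.zeros((3, 3, 3), bool))


class TestSoftDiceLoss:
    def test_perfect_prediction_near_zero(self):
        a = np.zeros((4, 4, 4), bool)
        a[1:3, 1:3, 1:3] = True
        assert soft_dice_loss(a.astype(float), a) < 1e-6

    def test_total_disagreement_near_one(self):
        a = np.zeros((4, 4, 4), bool)
        a[:2] = True
        assert soft_dice_loss((~a).astype(float), a) > 1 - 1e-6

    def test_uniform_half_closed_form(self):
        # P = 0.5 everywhere, |A| = k, n voxels: 1 - (k+eps)/(n/2+k+eps)
        a = np.zeros((4, 4, 4), bool)
        a[0, 0, :3] = True
        k, n, eps = 3, 64, 1e-6
        p = np.full((4, 4, 4), 0.5)
        expected = 1 - (k + eps) / (0.5 * n + k + eps)
        assert np.isclose(soft_dice_loss(p, a, eps), expected, atol=1e-12)

    def test_matches_hard_dice_on_binary(self, rng):
        for _ in range(20):
            a, b = random_mask(rng), random_mask(rng)
            assert np.isclose(
                soft_dice_loss(b.astype(float), a), 1 - dice(a, b), atol=1e-5
            )


class TestHausdorff:
    def test_identity_zero(self):
        a = np.zeros((5, 5, 5), bool)
        a[2, 2, 2] = True
        assert hausdorff(a, a) == 0.0

    def test_single_points(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0, 0, 0], b[3, 0, 0] = True, True
        assert hausdorff(a, b) == 3.0

    def test_asymmetric_directed_distances(self):
        a = np.zeros((11, 3, 3), bool)
        b = np.zeros((11, 3, 3), bool)
        a[0, 0, 0], a[10, 0, 0] = True, True
        b[0, 0, 0] = True
        assert hausdorff(a, b) == 10.0

    def test_empty_is_undefined(self):
        a = np.zeros((3, 3, 3), bool)
        b = a.copy()
        b[0, 0, 0] = True
        with pytest.raises(UndefinedDistanceError):
            hausdorff(a, b)

    def test_against_brute_force(self, rng):
        for _ in range(50):
            a, b = random_mask(rng), random_mask(rng)
            assert np.isclose(hausdorff(a, b), brute_hausdorff(a, b),
                              atol=1e-10)

    def test_mm_scaling_with_isotropic_spacing(self, rng):
        a = random_mask(rng)
        b = random_mask(rng)
        va = LabelVolume(a.astype(np.uint8), spacing=(2.0, 2.0, 2.0))
        vb = LabelVolume(b.astype(np.uint8), spacing=(2.0, 2.0, 2.0))
        assert np.isclose(hausdorff(va, vb, units="mm"),
                          2.0 * hausdorff(va, vb, units="voxel"))

    def test_mm_needs_matching_spacing(self, rng):
        a = LabelVolume(random_mask(rng).astype(np.uint8), spacing=(1, 1, 1))
        b = LabelVolume(random_mask(rng).astype(np.uint8), spacing=(2, 2, 2))
        with pytest.raises(ShapeError):
            hausdorff(a, b, units="mm")


class TestGroupSummary:
    def _case(self, i, dsc, hd=1.0):
        return CaseEvaluation(str(i), dsc, hd, 10, 10)

    def test_singleton(self):
        s = summarize_group([self._case(0, 0.7)])
        assert s.dsc_mean == s.dsc_median == s.dsc_max == s.dsc_min == 0.7
        assert s.dsc_std == 0.0

    def test_three_values(self):
        s = summarize_group([self._case(i, v) for i, v in
                             enumerate([0.2, 0.4, 0.6])])
        assert np.isclose(s.dsc_mean, 0.4)
        assert np.isclose(s.dsc_median, 0.4)
        assert np.isclose(s.dsc_std, np.std([0.2, 0.4, 0.6], ddof=1))

    def test_undefined_hd_excluded_and_counted(self):
        cases = [self._case(0, 0.5, hd=2.0), self._case(1, 0.6, hd=None)]
        s = summarize_group(cases)
        assert s.hd_mean == 2.0
        assert s.n_hd_undefined == 1

    def test_ordering_invariant(self):
        s = summarize_group([self._case(i, v) for i, v in
                             enumerate([0.9, 0.1, 0.5, 0.5])])
        assert s.dsc_min <= s.dsc_median <= s.dsc_max

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([])


class TestEvaluateCase:
    def test_records_volumes_and_undefined_hd(self):
        truth = np.zeros((4, 4, 4), np.uint8)
        truth[1:3, 1:3, 1:3] = 1
        pred = np.zeros_like(truth)
        ev = evaluate_case(LabelVolume(truth), LabelVolume(pred), "c1")
        assert ev.dsc == 0.0 and ev.hd is None
        assert ev.truth_volume == 8 and ev.seg_volume == 0

    def test_csv_and_json_round_trip(self, tmp_path):
        cases = [CaseEvaluation("a", 0.8, 1.5, 100, 90),
                 CaseEvaluation("b", 0.6, None, 50, 70)]
        cases_to_csv(cases, tmp_path / "cases.csv")
        with open(tmp_path / "cases.csv") as fh:
            rows = list(csv.DictReader(fh))
        assert [r["case_id"] for r in rows] == ["a", "b"]
        s = summarize_group(cases)
        summary_to_json(s, tmp_path / "s.json")
        d = json.loads((tmp_path / "s.json").read_text())
        assert d["n_cases"] == 2 and np.isclose(d["dsc_mean"], 0.7)


class TestComparisonStatistics:
    def test_paired_t_matches_textbook_formula(self, rng):
        x = rng.normal(0.6, 0.1, 30)
        y = x + rng.normal(0.02, 0.05, 30)
        t, p = paired_t(x, y)
        d = x - y
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert np.isclose(t, t_ref, atol=1e-10)
        assert 0 <= p <= 1

    def test_paired_t_zero_mean_difference(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = x + np.array([1.0, -1.0, 1.0, -1.0])
        t, _ = paired_t(x, y)
        assert t == 0.0

    def test_paired_t_degenerate(self):
        x = np.array([0.5, 0.6, 0.7])
        with pytest.raises(DegenerateInputError):
            paired_t(x, x)

    def test_pearson_perfect_linear(self):
        x = np.arange(10.0)
        r, _ = pearson(x, 2 * x + 1)
        assert np.isclose(r, 1.0)
        r, _ = pearson(x, -x)
        assert np.isclose(r, -1.0)

    def test_pearson_matches_covariance_formula(self, rng):
        x = rng.normal(size=60)
        y = 0.4 * x + rng.normal(size=60)
        r, p = pearson(x, y)
        r_ref = (((x - x.mean()) * (y - y.mean())).sum()
                 / np.sqrt(((x - x.mean()) ** 2).sum()
                           * ((y - y.mean()) ** 2).sum()))
        assert np.isclose(r, r_ref, atol=1e-10)

    def test_pearson_constant_input(self):
        with pytest.raises(DegenerateInputError):
            pearson(np.ones(5), np.arange(5.0))
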