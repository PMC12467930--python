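"""Evaluation metrics against brute-force and closed-form oracles."""

import numpy as np
import pytest

from gliomark.metrics import (
    calibration_curve,
    classification_metrics,
    evaluate_cohort,
    hd95,
    mcnemar_test,
    segmentation_metrics,
)


class TestSegmentationMetrics:
    def test_perfect_prediction(self):
        lab = np.zeros((8, 8, 8), dtype=int)
        lab[2:5, 2:5, 2:5] = 1
        lab[5:7, 5:7, 5:7] = 3
        m = segmentation_metrics(lab, lab)
        for c in (1, 3):
            assert m[c]["dice"] == 1.0
            assert m[c]["hd95"] == 0.0
            assert m[c]["sensitivity"] == 1.0
            assert m[c]["specificity"] == 1.0

    def test_half_overlap_dice(self):
        truth = np.zeros((6, 6, 6), dtype=int)
        truth[0, 0, :4] = 1
        truth[0, 1, :4] = 1  # 8 voxels
        pred = np.zeros_like(truth)
        pred[0, 0, :4] = 1  # 4 overlap
        pred[0, 2, :4] = 1  # 4 stray
        assert segmentation_metrics(pred, truth)[1]["dice"] == pytest.approx(0.5)

    def test_hd95_matches_exhaustive_pairwise_oracle(self):
        a = np.zeros((12, 12, 12), dtype=bool)
        b = np.zeros_like(a)
        a[2:4, 2:4, 2:4] = True
        b[5:7, 2:4, 2:4] = True  # offset by 3 along axis 0
        h = hd95(a, b, (1.0, 1.0, 1.0))
        # brute force: every cube voxel is a surface voxel of its 2^3 cube
        pa = np.argwhere(a)
        pb = np.argwhere(b)
        d_ab = [min(np.linalg.norm(p - q) for q in pb) for p in pa]
        d_ba = [min(np.linalg.norm(p - q) for q in pa) for p in pb]
        expect = np.percentile(d_ab + d_ba, 95)
        assert h == pytest.approx(expect, abs=1e-9)

    def test_hd95_is_symmetric(self, rng):
        a = rng.random((10, 10, 10)) < 0.3
        b = rng.random((10, 10, 10)) < 0.3
        assert hd95(a, b) == pytest.approx(hd95(b, a))

    def test_hd95_spacing_scales_distances(self):
        a = np.zeros((10, 10, 10), dtype=bool)
        b = np.zeros_like(a)
        a[2, 2, 2] = True
        b[4, 2, 2] = True
        assert hd95(a, b, (2.0, 1.0, 1.0)) == pytest.approx(2 * hd95(a, b, (1.0, 1.0, 1.0)))

    def test_absent_class_conventions(self):
        empty = np.zeros((6, 6, 6), dtype=int)
        one = empty.copy()
        one[3, 3, 3] = 2
        both_absent = segmentation_metrics(empty, empty)
        assert both_absent[2]["dice"] == 1.0 and both_absent[2]["hd95"] == 0.0
        one_absent = segmentation_metrics(empty, one)
        assert one_absent[2]["dice"] == 0.0
        assert one_absent[2]["hd95"] == pytest.approx(np.linalg.norm([6, 6, 6]))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            segmentation_metrics(np.zeros((4, 4, 4), int), np.zeros((5, 5, 5), int))


class TestClassificationMetrics:
    def test_perfect_separation_auc_one(self):
        m = classification_metrics([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert m["auc"] == 1.0

    def test_binary_scores_equal_labels_give_zero_brier(self):
        m = classification_metrics([0.0, 1.0, 1.0, 0.0], [0, 1, 1, 0])
        assert m["brier"] == 0.0
        assert m["accuracy"] == 1.0

    def test_auc_equals_concordant_pair_fraction(self, rng):
        scores = rng.random(6)
        labels = np.array([0, 1, 0, 1, 1, 0])
        auc = classification_metrics(scores, labels)["auc"]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        pairs = [(p > n) + 0.5 * (p == n) for p in pos for n in neg]
        assert auc == pytest.approx(np.mean(pairs))

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.random(20)
        labels = rng.integers(0, 2, 20)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        a1 = classification_metrics(scores, labels)["auc"]
        a2 = classification_metrics(np.exp(5 * scores), labels)["auc"]
        assert a1 == pytest.approx(a2)

    def test_single_class_raises_for_auc(self):
        with pytest.raises(ValueError, match="single class"):
            classification_metrics([0.5, 0.6], [1, 1])


class TestCalibration:
    def test_well_calibrated_scores_land_near_diagonal(self):
        rng = np.random.default_rng(0)
        scores = rng.random(5000)
        labels = (rng.random(5000) < scores).astype(int)
        cal = calibration_curve(scores, labels, 10)
        pop = cal["counts"] > 0
        dev = np.nanmax(np.abs(cal["observed_frequency"][pop] - cal["mean_predicted"][pop]))
        assert dev < 0.05

    def test_all_scores_in_one_bin_conserves_counts(self):
        cal = calibration_curve([0.31, 0.32, 0.33], [1, 0, 1], 10)
        assert cal["counts"].sum() == 3
        assert (cal["counts"] > 0).sum() == 1

    def test_bin_assignment_matches_loop_oracle(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        n_bins = 7
        cal = calibration_curve(scores, labels, n_bins)
        edges = cal["edges"]
        counts = np.zeros(n_bins, int)
        for s in scores:
            for b in range(n_bins):
                hi = edges[b + 1] if b < n_bins - 1 else 1.0 + 1e-9
                if edges[b] <= s < hi or (b == n_bins - 1 and s == 1.0):
                    counts[b] += 1
                    break
        np.testing.assert_array_equal(cal["counts"], counts)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            calibration_curve([0.5], [1], 1)


class TestMcNemar:
    def test_identical_correctness_gives_p_one(self):
        r = mcnemar_test([1, 0, 1, 1], [1, 0, 1, 1])
        assert r["p_value"] == 1.0

    def test_exact_binomial_closed_form(self):
        # b=15, c=5 -> two-sided exact p = 2 * sum_{k<=5} C(20,k) / 2^20
        a = [1] * 15 + [0] * 5 + [1] * 30
        b = [0] * 15 + [1] * 5 + [1] * 30
        r = mcnemar_test(a, b)
        from math import comb

        expect = 2 * sum(comb(20, k) for k in range(6)) / 2**20
        assert r["method"] == "exact_binomial"
        assert r["p_value"] == pytest.approx(expect, rel=1e-9)  # ~0.0414

    def test_chi_square_closed_form(self):
        a = [1] * 40 + [0] * 20 + [1] * 10
        b = [0] * 40 + [1] * 20 + [1] * 10
        r = mcnemar_test(a, b)
        assert r["method"] == "chi2_continuity"
        assert r["statistic"] == pytest.approx(361 / 60)  # ~6.0167

    def test_depends_only_on_discordant_pairs(self, rng):
        a = np.array([1, 0, 1, 1, 0, 1, 0, 1])
        b = np.array([0, 0, 1, 0, 1, 1, 0, 1])
        r1 = mcnemar_test(a, b)
        # permute the concordant entries
        conc = np.where(a == b)[0]
        perm = rng.permutation(conc)
        a2, b2 = a.copy(), b.copy()
        a2[conc], b2[conc] = a[perm], b[perm]
        r2 = mcnemar_test(a2, b2)
        assert (r1["statistic"], r1["p_value"]) == (r2["statistic"], r2["p_value"])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            mcnemar_test([1, 0], [1])


class TestEvaluateCohort:
    def _case(self, seed):
        from gliomark.phantom import PhantomSpec, generate_phantom

        return generate_phantom(PhantomSpec(volume_shape=(24, 24, 24), core_radius=4.0,
                                            rim_thickness=1.5, halo_width=2.0, seed=seed))

    def test_single_case_report_equals_per_case(self):
        case = self._case(0)
        pred = {"labels": case.labels.labels,
                "markers": {"idh": 0.9, "1p19q": 0.2, "tert": 0.6}}
        report = evaluate_cohort([pred], [case])
        assert report.segmentation[2]["dice"] == report.per_case[0]["segmentation"][2]["dice"]

    def test_mean_dice_over_three_cases_matches_hand_average(self):
        cases = [self._case(s) for s in (1, 2, 3)]
        preds = []
        dices = []
        for c in cases:
            lab = c.labels.labels.copy()
            lab[lab == 3] = 0  # degrade SNFH
            preds.append({"labels": lab, "markers": {"idh": 0.5, "1p19q": 0.5, "tert": 0.5}})
            from gliomark.metrics import segmentation_metrics as sm

            dices.append(sm(lab, c.labels)[2]["dice"])
        report = evaluate_cohort(preds, cases)
        assert report.segmentation[2]["dice"] == pytest.approx(np.mean(dices))

    def test_report_round_trips_through_json(self):
        import json

        case = self._case(4)
        pred = {"labels": case.labels.labels,
                "markers": {"idh": 0.9, "1p19q": 0.2, "tert": 0.6}}
        report = evaluate_cohort([pred], [case])
        j = json.loads(json.dumps(report.to_dict()))
        assert j["segmentation"]["2"]["dice"] == report.segmentation[2]["dice"]

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate_cohort([], [])
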