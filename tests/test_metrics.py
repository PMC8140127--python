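import math

import numpy as np
import pytest

from cmhseg import (BinaryMask, ConfusionCounts, bland_altman, confusion,
                    dice, icc_absolute_agreement, percent_error,
                    pool_confusion, roc_sweep, sensitivity_specificity)
from cmhseg.metrics import agreement_report
from cmhseg.ratiometric import compute_ratio, segment_by_ratio

from conftest import random_image, random_mask


def brute_force_icc(x):
    """Two-way ANOVA mean squares by explicit loops, then ICC(A,1)."""
    n, k = len(x), len(x[0])
    grand = sum(sum(row) for row in x) / (n * k)
    row_means = [sum(row) / k for row in x]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((m - grand) ** 2 for m in row_means)
    ssc = n * sum((m - grand) ** 2 for m in col_means)
    sse = sum((x[i][j] - row_means[i] - col_means[j] + grand) ** 2
              for i in range(n) for j in range(k))
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n), \
        (msr, msc, mse)


class TestConfusion:
    def test_identity_prediction(self, rng):
        m = random_mask(rng)
        c = confusion(m, m)
        assert c.fp == 0 and c.fn == 0
        sens, spec = sensitivity_specificity(c)
        assert sens == 1.0 and spec == 1.0

    def test_complement_prediction(self, rng):
        t = random_mask(rng)
        p = BinaryMask(~t.values, t.pixel_size_um)
        c = confusion(p, t)
        assert c.tp == 0 and c.tn == 0

    def test_matches_per_pixel_loop(self, rng):
        p, t = random_mask(rng), random_mask(rng)
        c = confusion(p, t)
        tp = fp = tn = fn = 0
        for i in range(16):
            for j in range(16):
                if p.values[i, j] and t.values[i, j]:
                    tp += 1
                elif p.values[i, j]:
                    fp += 1
                elif t.values[i, j]:
                    fn += 1
                else:
                    tn += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
        assert c.total == 256

    def test_pooling_is_additive(self, rng):
        counts = [confusion(random_mask(rng), random_mask(rng))
                  for _ in range(5)]
        pooled = pool_confusion(counts)
        assert pooled.tp == sum(c.tp for c in counts)
        assert pooled.total == sum(c.total for c in counts)


class TestSensitivitySpecificity:
    def test_arithmetic(self):
        sens, spec = sensitivity_specificity(
            ConfusionCounts(tp=80, fp=10, tn=990, fn=20))
        assert sens == pytest.approx(0.8)
        assert spec == pytest.approx(0.99)

    def test_all_negative_truth_rejected(self):
        with pytest.raises(ValueError, match="sensitivity undefined"):
            sensitivity_specificity(ConfusionCounts(0, 5, 95, 0))


class TestDice:
    def test_identical_nonempty(self, rng):
        m = random_mask(rng)
        assert dice(m, m) == 1.0

    def test_disjoint_nonempty(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0] = b[3, 3] = True
        assert dice(BinaryMask(a, 1.0), BinaryMask(b, 1.0)) == 0.0

    def test_half_overlap(self):
        a = np.zeros((20, 10), dtype=bool)
        b = np.zeros((20, 10), dtype=bool)
        a[:10] = True                          # |A| = 100
        b[5:15] = True                         # |B| = 100, overlap 50
        assert dice(BinaryMask(a, 1.0), BinaryMask(b, 1.0)) == 0.5

    def test_both_empty_is_perfect_agreement(self):
        e = BinaryMask(np.zeros((4, 4), dtype=bool), 1.0)
        assert dice(e, e) == 1.0


class TestPercentError:
    def test_signed_examples(self):
        assert percent_error(90.0, 100.0) == pytest.approx(-10.0)
        assert percent_error(100.0, 100.0) == 0.0

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            percent_error(10.0, 0.0)


class TestIcc:
    def test_identical_raters_give_one(self, rng):
        col = rng.random(8) * 100
        icc, ci = icc_absolute_agreement(np.column_stack([col, col]))
        assert icc == pytest.approx(1.0)

    def test_constant_offset_penalized(self):
        """Absolute agreement punishes a systematic offset between raters
        when between-subject variance is small, unlike consistency ICC."""
        subjects = np.array([10.0, 10.5, 9.5, 10.2, 9.8, 10.1])
        x = np.column_stack([subjects, subjects + 50.0])
        icc, _ = icc_absolute_agreement(x)
        assert icc < 0.2

    def test_matches_brute_force_anova(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 12))
            k = int(rng.integers(2, 6))
            x = rng.random((n, k)) * 100
            icc, _ = icc_absolute_agreement(x)
            expected, _ = brute_force_icc(x.tolist())
            assert icc == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.random((8, 4)) * 100
            icc, (lo, hi) = icc_absolute_agreement(x)
            long = pd.DataFrame({
                "subject": np.repeat(np.arange(8), 4),
                "rater": np.tile(np.arange(4), 8),
                "score": x.ravel()})
            ref = pingouin.intraclass_corr(long, targets="subject",
                                           raters="rater", ratings="score")
            ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
            row = ref[ref["Type"].str.contains(r"A,\s*1|^ICC2$")].iloc[0]
            assert icc == pytest.approx(row["ICC"], abs=1e-8)
            # pingouin rounds the interval to two decimals
            assert lo == pytest.approx(row[ci_col][0], abs=6e-3)
            assert hi == pytest.approx(row[ci_col][1], abs=6e-3)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate|undefined"):
            icc_absolute_agreement(np.full((6, 3), 7.0))

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement(np.ones((1, 3)))


class TestBlandAltman:
    def test_identical_vectors(self):
        a = np.array([10.0, 20.0, 30.0])
        assert bland_altman(a, a) == (0.0, 0.0, 0.0)

    def test_constant_ten_percent_scale(self):
        b = np.array([10.0, 50.0, 200.0])
        mean_diff, lo, hi = bland_altman(1.1 * b, b)
        expected = 0.1 / 1.05 * 100           # ≈ 9.5238 %
        assert mean_diff == pytest.approx(expected)
        assert lo == pytest.approx(expected)  # SD = 0
        assert hi == pytest.approx(expected)

    def test_matches_direct_formula(self, rng):
        a = rng.random(20) * 100 + 1
        b = rng.random(20) * 100 + 1
        mean_diff, lo, hi = bland_altman(a, b)
        diffs = [(ai - bi) / ((ai + bi) / 2) * 100 for ai, bi in zip(a, b)]
        m = sum(diffs) / len(diffs)
        sd = math.sqrt(sum((d - m) ** 2 for d in diffs) / (len(diffs) - 1))
        assert mean_diff == pytest.approx(m, abs=1e-10)
        assert lo == pytest.approx(m - 1.96 * sd, abs=1e-10)
        assert hi == pytest.approx(m + 1.96 * sd, abs=1e-10)

    def test_zero_mean_pair_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero-mean"):
            mean_diff, _, _ = bland_altman([0.0, 10.0], [0.0, 10.0])
        assert mean_diff == 0.0

    def test_absolute_mode(self, rng):
        a = rng.random(10) * 100
        b = rng.random(10) * 100
        mean_diff, _, _ = bland_altman(a, b, percent=False)
        assert mean_diff == pytest.approx((a - b).mean())


class TestRocSweep:
    def test_truth_returning_segmenter_is_perfect(self, rng):
        imgs = [random_image(rng, shape=(12, 12)) for _ in range(3)]
        truths = [random_mask(rng, shape=(12, 12)) for _ in range(3)]
        by_id = {id(im): t for im, t in zip(imgs, truths)}
        curve = roc_sweep(imgs, truths,
                          lambda im, p: by_id[id(im)],
                          grid=[0.1, 0.5, 1.0], apply_partial_chain=False)
        assert curve.auc == 1.0
        assert all(s == 1.0 and sp == 1.0 for _, s, sp in curve.points)

    def test_nested_sweep_monotone(self, rng):
        imgs = [random_image(rng, shape=(24, 24)) for _ in range(2)]
        truths = [random_mask(rng, shape=(24, 24)) for _ in range(2)]
        grid = np.geomspace(0.05, 5.0, 25)
        curve = roc_sweep(
            imgs, truths,
            lambda im, t: segment_by_ratio(compute_ratio(im), t),
            grid=grid, apply_partial_chain=False)
        pts = sorted((1 - sp, s) for _, s, sp in curve.points)
        fprs = [p[0] for p in pts]
        senss = [p[1] for p in pts]
        assert all(a <= b + 1e-12 for a, b in zip(senss, senss[1:]))
        assert all(a <= b for a, b in zip(fprs, fprs[1:]))

    def test_auc_stable_under_grid_refinement(self, small_sample):
        img, truth = small_sample.image, small_sample.truth
        coarse = roc_sweep([img], [truth],
                           lambda im, t: segment_by_ratio(compute_ratio(im), t),
                           grid=np.geomspace(0.05, 5.0, 50),
                           apply_partial_chain=False)
        fine = roc_sweep([img], [truth],
                         lambda im, t: segment_by_ratio(compute_ratio(im), t),
                         grid=np.geomspace(0.05, 5.0, 500),
                         apply_partial_chain=False)
        assert abs(coarse.auc - fine.auc) < 0.01

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="grid"):
            roc_sweep([random_image(rng)], [random_mask(rng)],
                      lambda im, p: random_mask(rng), grid=[])


class TestAgreementReport:
    def test_perfect_prediction_report(self, rng):
        masks = [random_mask(rng, shape=(12, 12), p=0.4) for _ in range(6)]
        rep = agreement_report(masks, masks)
        assert rep.icc == pytest.approx(1.0)
        assert rep.ba_mean_diff_pct == 0.0
        assert rep.mean_dice == 1.0
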