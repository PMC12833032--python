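"""Metrics against brute-force oracles; protocol fidelity (lr, augmentation,
folds); a short smoke-scale training run."""

import numpy as np
import pytest

from onsdnet import (TrainConfig, augment, lr_at, split_folds,
                     confusion_counts, se_sp_f1, hd95, auroc, dice_score,
                     diameter_agreement, dice_loss)
from onsdnet.train_eval import evaluate_segmentation, train
from onsdnet import presets


# ---------------------------------------------------------------------------
# confusion counts / SE / SP / F1
# ---------------------------------------------------------------------------

class TestConfusion:
    def test_equal_maps(self, rng):
        g = rng.uniform(size=(16, 16)) > 0.5
        tp, fp, tn, fn = confusion_counts(g, g)
        assert fp == fn == 0 and tp + tn == g.size

    def test_complement_maps(self, rng):
        g = rng.uniform(size=(16, 16)) > 0.5
        tp, fp, tn, fn = confusion_counts(~g, g)
        assert tp == tn == 0 and fp + fn == g.size

    def test_matches_pixel_loop_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(size=(16, 16)) > 0.4
            g = rng.uniform(size=(16, 16)) > 0.6
            tp = sum(int(p[i, j] and g[i, j]) for i in range(16) for j in range(16))
            fp = sum(int(p[i, j] and not g[i, j]) for i in range(16) for j in range(16))
            tn = sum(int(not p[i, j] and not g[i, j]) for i in range(16) for j in range(16))
            fn = sum(int(not p[i, j] and g[i, j]) for i in range(16) for j in range(16))
            assert confusion_counts(p, g) == (tp, fp, tn, fn)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))


class TestSeSpF1:
    def test_printed_formula_arithmetic(self):
        se, _, _ = se_sp_f1((9, 0, 0, 1))
        assert se == pytest.approx(90.0)
        _, sp, _ = se_sp_f1((0, 3, 97, 0))
        assert sp == pytest.approx(97.0)

    def test_perfect_prediction(self):
        se, sp, f1 = se_sp_f1((10, 0, 20, 0))
        assert se == sp == f1 == 100.0

    def test_undefined_denominators_flagged_as_none(self):
        se, sp, f1 = se_sp_f1((0, 0, 5, 0))
        assert se is None and sp == 100.0 and f1 is None

    def test_dice_score_consistent_with_dice_loss(self, rng):
        """F1% on binary masks equals 100 * (1 - soft-Dice loss)."""
        for _ in range(10):
            p = (rng.uniform(size=(20, 20)) > 0.5).astype(float)
            g = (rng.uniform(size=(20, 20)) > 0.5).astype(float)
            d = dice_score(p.astype(bool), g.astype(bool))
            assert d == pytest.approx(100 * (1 - dice_loss(p, g)), abs=1e-3)


# ---------------------------------------------------------------------------
# HD95
# ---------------------------------------------------------------------------

def brute_force_hd95(pred, gt, spacing=1.0):
    from scipy.ndimage import binary_erosion

    def boundary(m):
        return m & ~binary_erosion(m, np.ones((3, 3), bool), border_value=0)

    pb = np.argwhere(boundary(pred))
    gb = np.argwhere(boundary(gt))
    d_pg = [min(np.hypot(*(p - q)) for q in gb) for p in pb]
    d_gp = [min(np.hypot(*(q - p)) for p in pb) for q in gb]
    return max(np.percentile(d_pg, 95), np.percentile(d_gp, 95)) * spacing


class TestHD95:
    def test_identical_masks_zero(self, rng):
        g = np.zeros((16, 16), bool)
        g[4:10, 5:12] = True
        assert hd95(g, g) == 0.0

    def test_two_single_pixels(self):
        a = np.zeros((16, 16), bool); a[3, 3] = True
        b = np.zeros((16, 16), bool); b[3, 8] = True
        assert hd95(a, b, spacing=1.0) == pytest.approx(5.0)
        assert hd95(a, b, spacing=0.5) == pytest.approx(2.5)

    def test_matches_all_pairs_oracle_on_random_masks(self, rng):
        for _ in range(15):
            a = rng.uniform(size=(24, 24)) > 0.6
            b = rng.uniform(size=(24, 24)) > 0.6
            if not a.any() or not b.any():
                continue
            assert hd95(a, b) == pytest.approx(brute_force_hd95(a, b), abs=1e-9)

    def test_never_exceeds_exact_hausdorff(self, rng):
        from scipy.spatial.distance import directed_hausdorff

        for _ in range(10):
            a = rng.uniform(size=(20, 20)) > 0.55
            b = rng.uniform(size=(20, 20)) > 0.55
            if not a.any() or not b.any():
                continue
            from onsdnet.train_eval import _boundary
            pa, pb_ = np.argwhere(_boundary(a)), np.argwhere(_boundary(b))
            exact = max(directed_hausdorff(pa, pb_)[0],
                        directed_hausdorff(pb_, pa)[0])
            assert hd95(a, b) <= exact + 1e-12

    def test_empty_mask_undefined(self):
        g = np.zeros((8, 8), bool)
        g[2, 2] = True
        assert hd95(np.zeros((8, 8), bool), g) is None


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------

def brute_force_auroc(prob, gt):
    pos = prob[gt.astype(bool)].ravel()
    neg = prob[~gt.astype(bool)].ravel()
    wins = sum((pos > n).sum() + 0.5 * (pos == n).sum() for n in neg)
    return 100.0 * wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_ranking(self, rng):
        g = rng.uniform(size=(16, 16)) > 0.5
        assert auroc(g.astype(float), g) == pytest.approx(100.0)

    def test_random_scores_near_half(self, rng):
        g = np.zeros((256, 256), bool)
        g[:, :128] = True
        p = rng.uniform(size=(256, 256))
        n_pos = n_neg = 256 * 128
        se = 100 * np.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
        assert abs(auroc(p, g) - 50.0) < 3 * se

    def test_matches_concordant_pair_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(size=20)
            g = rng.uniform(size=20) > 0.5
            if g.all() or not g.any():
                continue
            assert auroc(p, g) == pytest.approx(brute_force_auroc(p, g), abs=1e-9)

    def test_invariant_under_monotone_transform(self, rng):
        p = rng.uniform(size=(16, 16))
        g = rng.uniform(size=(16, 16)) > 0.5
        assert auroc(p, g) == pytest.approx(auroc(np.exp(3 * p) - 0.5, g), abs=1e-9)

    def test_single_class_undefined(self):
        assert auroc(np.random.default_rng(0).uniform(size=(4, 4)),
                     np.ones((4, 4), bool)) is None


# ---------------------------------------------------------------------------
# diameter agreement (MAE / Pearson / ICC)
# ---------------------------------------------------------------------------

def icc_two_way_anova_oracle(x, y):
    """ICC(2,1): two-way random effects, absolute agreement, single rater,
    from the classical ANOVA mean squares."""
    data = np.column_stack([x, y])
    n, k = data.shape
    mean_t = data.mean(axis=1)
    mean_r = data.mean(axis=0)
    grand = data.mean()
    msr = k * np.sum((mean_t - grand) ** 2) / (n - 1)
    msc = n * np.sum((mean_r - grand) ** 2) / (k - 1)
    sse = np.sum((data - mean_t[:, None] - mean_r[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestAgreement:
    def test_perfect_agreement(self, rng):
        x = rng.uniform(4, 7, size=10)
        rep = diameter_agreement(x, x)
        assert rep.mae == 0.0
        assert rep.pearson == pytest.approx(1.0)
        assert rep.icc == pytest.approx(1.0, abs=1e-6)

    def test_constant_offset_penalized_by_icc_not_pearson(self, rng):
        t = rng.uniform(4, 7, size=12)
        rep = diameter_agreement(t + 1.0, t)
        assert rep.mae == pytest.approx(1.0, abs=1e-12)
        assert rep.pearson == pytest.approx(1.0, abs=1e-9)
        assert rep.icc < 0.9

    def test_icc_matches_anova_oracle(self, rng):
        x = rng.uniform(4, 7, size=10)
        y = x + rng.normal(0, 0.3, size=10)
        rep = diameter_agreement(y, x)
        assert rep.icc == pytest.approx(icc_two_way_anova_oracle(y, x), abs=1e-9)

    def test_zero_variance_flagged(self):
        rep = diameter_agreement([5.0, 5.0, 5.0], [4.0, 5.0, 6.0])
        assert rep.icc is None and rep.pearson is None
        assert "variance" in rep.reason

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match=">= 3"):
            diameter_agreement([1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# protocol: learning-rate schedule, augmentation, folds
# ---------------------------------------------------------------------------

class TestSchedule:
    def test_reference_values(self):
        cfg = TrainConfig()
        assert lr_at(0, cfg) == pytest.approx(5e-3)
        assert lr_at(100, cfg) == pytest.approx(5e-3 * 0.99)
        assert lr_at(250, cfg) == pytest.approx(5e-3 * 0.99 ** 2)

    def test_exact_closed_form(self):
        cfg = TrainConfig()
        for it in (0, 1, 99, 100, 101, 999, 12345):
            assert lr_at(it, cfg) == cfg.lr0 * cfg.decay_factor ** (it // 100)


class TestAugment:
    @staticmethod
    def _marked_image():
        img = np.zeros((32, 32))
        img[:, :16] = 0.25   # asymmetric: flips are detectable
        img[4, 4] = 1.0
        lab = np.zeros((32, 32), dtype=np.uint8)
        lab[10:20, 12:20] = 1
        return img, lab

    def test_deterministic_and_aligned(self):
        img, lab = self._marked_image()
        a = augment(img, lab, seed=5)
        b = augment(img, lab, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_noop_branch_returns_input(self):
        img, lab = self._marked_image()
        # find a seed whose two uniform draws both exceed 0.30
        for seed in range(100):
            r = np.random.default_rng(seed)
            if r.uniform() >= 0.3 and r.uniform() >= 0.3:
                out_img, out_lab = augment(img, lab, seed=seed)
                np.testing.assert_array_equal(out_img, img)
                np.testing.assert_array_equal(out_lab, lab)
                return
        pytest.fail("no no-op seed found in 100 tries")

    def test_flip_frequency_is_30_percent(self):
        # zero-range rotation keeps the flip marker pristine when the
        # rotation branch fires, so flips are counted exactly
        img = np.zeros((8, 8))
        img[:, 0] = 1.0
        lab = np.zeros((8, 8), dtype=np.uint8)
        flips = 0
        for seed in range(10_000):
            out, _ = augment(img, lab, seed=seed, rot_range_deg=(0.0, 0.0))
            if out[0, -1] == 1.0:
                flips += 1
        assert abs(flips / 10_000 - 0.30) <= 0.015

    def test_rotation_angles_bounded(self):
        # the angle draw is the second uniform; replicate the generator to
        # verify every sampled angle respects the [-20, 20] bound
        for seed in range(2000):
            r = np.random.default_rng(seed)
            if r.uniform() < 0.3:
                pass
            if r.uniform() < 0.3:
                angle = r.uniform(-20.0, 20.0)
                assert -20.0 <= angle <= 20.0


class TestFolds:
    def test_disjoint_cover_and_subject_integrity(self):
        subjects = np.repeat(np.arange(23), [3] * 10 + [5] * 10 + [2] * 3)
        folds = split_folds(subjects, n_folds=5, seed=1)
        all_test = np.concatenate([t for _, t in folds])
        assert sorted(all_test) == list(range(len(subjects)))
        for trainv, test in folds:
            assert set(trainv) & set(test) == set()
            assert set(subjects[trainv]) & set(subjects[test]) == set()

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="subjects"):
            split_folds([1, 1, 2, 2], n_folds=5)


# ---------------------------------------------------------------------------
# training smoke test
# ---------------------------------------------------------------------------

class TestTraining:
    def test_two_epoch_smoke_and_determinism(self):
        phs = presets.tiny_phantoms(8, seed=3)
        cfg = TrainConfig(epochs=2, batch_size=4, seed=1, loss_mode="kendall")
        from onsdnet import NetConfig
        net1, h1 = train(phs, cfg, net_config=NetConfig(width=2, seed=1))
        assert len(h1.epochs) == 2
        assert all(np.isfinite(e["train_loss"]) for e in h1.epochs)
        net2, h2 = train(phs, cfg, net_config=NetConfig(width=2, seed=1))
        assert abs(h1.epochs[-1]["train_loss"] - h2.epochs[-1]["train_loss"]) < 1e-6

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], TrainConfig())


def test_evaluate_segmentation_aggregates_per_image(rng):
    gts = [rng.uniform(size=(32, 32)) > 0.6 for _ in range(3)]
    probs = [g.astype(float) * 0.9 + 0.05 for g in gts]
    rep = evaluate_segmentation(probs, gts)
    assert rep.dice == pytest.approx(100.0, abs=1e-6)
    assert rep.auroc == pytest.approx(100.0, abs=1e-6)
    assert len(rep.per_image) == 3
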