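"""Brute-force reference implementations used only to cross-check metrics."""

import numpy as np
from scipy.ndimage import binary_erosion


def loop_confusion(pred, gt):
    tp = fp = tn = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            if pred[i, j] and gt[i, j]:
                tp += 1
            elif pred[i, j]:
                fp += 1
            elif gt[i, j]:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn


def _boundary(m):
    return m & ~binary_erosion(m, np.ones((3, 3), bool), border_value=0)


def all_pairs_hd95(pred, gt, spacing=1.0):
    pb = np.argwhere(_boundary(pred))
    gb = np.argwhere(_boundary(gt))
    d_pg = [min(float(np.hypot(*(p - q))) for q in gb) for p in pb]
    d_gp = [min(float(np.hypot(*(q - p))) for p in pb) for q in gb]
    return max(np.percentile(d_pg, 95), np.percentile(d_gp, 95)) * spacing


def concordant_pair_auroc(prob, gt):
    prob = np.asarray(prob, dtype=float).ravel()
    gt = np.asarray(gt).astype(bool).ravel()
    pos = prob[gt]
    neg = prob[~gt]
    wins = sum(float((pos > n).sum()) + 0.5 * float((pos == n).sum())
               for n in neg)
    return 100.0 * wins / (len(pos) * len(neg))
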