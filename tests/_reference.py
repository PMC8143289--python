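"""Independent brute-force reference implementations used as test oracles.

These deliberately take the slow, obvious route (double loops, standard
scipy estimators, exhaustive scans) and share no code with the package.
"""

import numpy as np
import scipy.stats as st


def naive_local_stats(patch):
    """Seven first-order statistics of one patch via scipy estimators."""
    v = np.asarray(patch, dtype=float).ravel()
    if np.all(v == v[0]):
        return np.array([v[0], v[0], 0.0, 0.0, 0.0, 0.0, 0.0])
    mean = v.mean()
    med = float(np.median(v))
    skew = float(st.skew(v, bias=True))
    kurt = float(st.kurtosis(v, fisher=True, bias=True))
    iqr = float(st.iqr(v))
    cv = float(v.std(ddof=0) / mean) if mean != 0 else 0.0
    counts, _ = np.histogram(v, bins=16, range=(v.min(), v.max()))
    p = counts / counts.sum()
    p = p[p > 0]
    entropy = float(-(p * np.log2(p)).sum())
    return np.array([mean, med, skew, kurt, iqr, cv, entropy])


def naive_sweep(voxels, mask, side):
    """Per-voxel local statistics by an explicit double loop with truncation."""
    h = side // 2
    _, n_rows, n_cols = voxels.shape
    out = {}
    for z, r, c in np.argwhere(mask > 0):
        patch = voxels[
            z,
            max(r - h, 0): min(r + h + 1, n_rows),
            max(c - h, 0): min(c + h + 1, n_cols),
        ]
        out[(z, r, c)] = naive_local_stats(patch)
    return out


def pair_count_auc(scores, labels):
    """AUC as the normalized Mann-Whitney pair count (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def stepdown_holm(pvalues, alpha=0.05):
    """Holm rejections by literally walking the sorted list."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    rejected = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order, start=1):
        if p[idx] <= alpha / (m - i + 1):
            rejected[idx] = True
        else:
            break
    return rejected


def scan_youden(scores, labels):
    """Best threshold by scanning every achievable operating point."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    candidates = np.unique(scores)
    thresholds = np.concatenate([[np.inf], candidates[::-1]])
    best = None  # (J, -fpr, threshold)
    for t in thresholds:
        pred = scores >= t
        tpr = (pred & (labels == 1)).sum() / n_pos
        fpr = (pred & (labels == 0)).sum() / n_neg
        j = tpr - fpr
        key = (j, -fpr, t)
        if best is None or key > best:
            best = key
    return best[2], best[0]
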