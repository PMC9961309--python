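"""Independent brute-force reference implementations used only by tests.

These are deliberately naive (explicit Python double loops, closed forms)
so they cannot share a defect with the vectorized implementations they
check.
"""

import math

import numpy as np


def brute_haralick13(p) -> np.ndarray:
    """The 13 Haralick features by explicit double loops over the formulas."""
    p = np.asarray(p, dtype=float)
    n = p.shape[0]

    def log(v):
        return math.log(v) if v > 0 else 0.0

    px = [sum(p[i][j] for j in range(n)) for i in range(n)]
    py = [sum(p[i][j] for i in range(n)) for j in range(n)]
    mu_x = sum(i * px[i] for i in range(n))
    mu_y = sum(j * py[j] for j in range(n))
    sig_x = math.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(n)))
    sig_y = math.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(n)))
    pxy = [
        sum(p[i][j] for i in range(n) for j in range(n) if i + j == k)
        for k in range(2 * n - 1)
    ]
    pxmy = [
        sum(p[i][j] for i in range(n) for j in range(n) if abs(i - j) == k)
        for k in range(n)
    ]
    f1 = sum(p[i][j] ** 2 for i in range(n) for j in range(n))
    f2 = sum(k * k * pxmy[k] for k in range(n))
    f3 = (
        (sum(i * j * p[i][j] for i in range(n) for j in range(n)) - mu_x * mu_y)
        / (sig_x * sig_y)
        if sig_x > 0 and sig_y > 0
        else 0.0
    )
    pooled = [(px[i] + py[i]) / 2 for i in range(n)]
    mu = sum(i * pooled[i] for i in range(n))
    f4 = sum((i - mu) ** 2 * pooled[i] for i in range(n))
    f5 = sum(p[i][j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    f6 = sum(k * pxy[k] for k in range(2 * n - 1))
    f8 = -sum(pxy[k] * log(pxy[k]) for k in range(2 * n - 1))
    f7 = sum((k - f8) ** 2 * pxy[k] for k in range(2 * n - 1))
    f9 = -sum(p[i][j] * log(p[i][j]) for i in range(n) for j in range(n))
    mu_d = sum(k * pxmy[k] for k in range(n))
    f10 = sum((k - mu_d) ** 2 * pxmy[k] for k in range(n))
    f11 = -sum(pxmy[k] * log(pxmy[k]) for k in range(n))
    hx = -sum(px[i] * log(px[i]) for i in range(n))
    hy = -sum(py[j] * log(py[j]) for j in range(n))
    hxy = f9
    hxy1 = -sum(
        p[i][j] * log(px[i] * py[j]) for i in range(n) for j in range(n)
    )
    hxy2 = -sum(
        px[i] * py[j] * log(px[i] * py[j]) for i in range(n) for j in range(n)
    )
    f12 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    f13 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    return np.array([f1, f2, f3, f4, f5, f6, f7, f8, f9, f10, f11, f12, f13])


def brute_glcm(levels, d, theta, n_levels) -> np.ndarray:
    """Pair counting by explicit loops, offsets in (row, col) convention."""
    offs = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}[theta]
    dr, dc = offs[0] * d, offs[1] * d
    h, w = levels.shape
    m = np.zeros((n_levels, n_levels), dtype=int)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                m[levels[r, c], levels[r2, c2]] += 1
    return m


def brute_auc(y_true, scores) -> float:
    """Exhaustive positive-negative pair comparison, ties count 1/2."""
    pos = [s for t, s in zip(y_true, scores) if t == 1]
    neg = [s for t, s in zip(y_true, scores) if t == 0]
    wins = sum(1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def brute_metrics(tp, fn, tn, fp) -> dict:
    """The eight measures straight from their definitions (unit scale)."""
    total = tp + fn + tn + fp
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    pr = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    f1 = 2 * pr * sn / (pr + sn) if pr + sn else 0.0
    den = (tp + fn) * (tn + fn) * (tp + fp) * (tn + fp)
    mcc = (tp * tn - fp * fn) / math.sqrt(den) if den else 0.0
    fpr = fp / (tn + fp) if tn + fp else 0.0
    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": sn,
        "specificity": sp,
        "precision": pr,
        "npv": npv,
        "f1": f1,
        "mcc": mcc,
        "fpr": fpr,
    }
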