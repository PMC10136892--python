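"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (explicit loops, direct formulas) and
shares no code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def bf_moment_skewness(values) -> float:
    """Population moment-ratio skewness mu3 / sigma^3."""
    x = np.asarray(values, dtype=float)
    mu = sum(x) / len(x)
    m2 = sum((v - mu) ** 2 for v in x) / len(x)
    m3 = sum((v - mu) ** 3 for v in x) / len(x)
    return m3 / m2 ** 1.5


def bf_glcm(levels: np.ndarray, mask: np.ndarray, offset, n_levels: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix by explicit voxel loops."""
    counts = np.zeros((n_levels, n_levels))
    oz, oy, ox = offset
    nz, ny, nx = levels.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                z2, y2, x2 = z + oz, y + oy, x + ox
                if 0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx and mask[z2, y2, x2]:
                    i, j = levels[z, y, x] - 1, levels[z2, y2, x2] - 1
                    counts[i, j] += 1
                    counts[j, i] += 1
    total = counts.sum()
    return counts / total if total else counts


def bf_glcm_stats(P: np.ndarray) -> dict:
    """A few co-occurrence statistics evaluated by direct double loops."""
    ng = P.shape[0]
    contrast = joint_energy = dissim = autocorr = mu = 0.0
    for i in range(ng):
        for j in range(ng):
            p = P[i, j]
            contrast += (i - j) ** 2 * p
            joint_energy += p * p
            dissim += abs(i - j) * p
            autocorr += (i + 1) * (j + 1) * p
            mu += (i + 1) * p
    sigma2 = 0.0
    for i in range(ng):
        for j in range(ng):
            sigma2 += ((i + 1) - mu) ** 2 * P[i, j]
    return {
        "Contrast": contrast,
        "JointEnergy": joint_energy,
        "Dissimilarity": dissim,
        "Autocorrelation": autocorr,
        "MaximumProbability": float(P.max()),
        "SumOfSquares": sigma2,
        "Correlation": (autocorr - mu * mu) / sigma2 if sigma2 > 1e-15 else 0.0,
    }


def bf_auc(scores, labels) -> float:
    """Probability a positive outranks a negative (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def bf_youden(scores, labels) -> tuple[float, float]:
    """Exhaustive Youden scan with the rule score >= t => positive.

    Ties broken toward higher sensitivity, then lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    best = (-np.inf, -np.inf, np.inf)  # (J, sens, -(-threshold))
    for t in np.unique(scores):
        pred = scores >= t
        sens = np.mean(pred[labels == 1])
        spec = np.mean(~pred[labels == 0])
        j = sens + spec - 1.0
        key = (round(j, 12), sens, -t)
        if key > (round(best[0], 12), best[1], -best[2]):
            best = (j, sens, t)
    return best[2], best[0]


def bf_corr_prune(X, confirmed, importance, r_max) -> list:
    """Greedy correlation pruning re-implemented with explicit loops."""
    order = sorted(confirmed, key=lambda f: (-float(importance[f]), f))
    kept = []
    for feat in order:
        ok = True
        for other in kept:
            r = np.corrcoef(X[feat], X[other])[0, 1]
            if np.isfinite(r) and abs(r) >= r_max:
                ok = False
                break
        if ok:
            kept.append(feat)
    return kept


def bf_km(times, events):
    """Product-limit estimator by hand: returns (event_times, survival)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    s = 1.0
    out_t, out_s = [], []
    for t in np.unique(times[events]):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & events)
        s *= 1.0 - d / at_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)
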