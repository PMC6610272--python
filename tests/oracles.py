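"""Independent brute-force oracles used by the test suite.

Everything here is written as plain, exhaustive enumeration — per-voxel
loops, all-pairs counts, explicit risk-set tabulation, grid scans — kept
deliberately separate from the package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- texture


def binning_oracle(values, bin_count):
    """Per-value min-max equal-width binning by direct comparison."""
    lo, hi = min(values), max(values)
    levels = []
    for v in values:
        if hi == lo:
            levels.append(0)
            continue
        k = int(math.floor((v - lo) / (hi - lo) * bin_count))
        levels.append(min(k, bin_count - 1))
    probs = [levels.count(k) / len(levels) for k in range(bin_count)]
    return levels, probs


def first_order_oracle(values, bin_count):
    """The five histogram features by direct summation."""
    _, p = binning_oracle(values, bin_count)
    entropy = -sum(pi * math.log2(pi) for pi in p if pi > 0)
    uniformity = sum(pi * pi for pi in p)
    n = len(values)
    mu = sum(values) / n
    m2 = sum((v - mu) ** 2 for v in values) / n
    m3 = sum((v - mu) ** 3 for v in values) / n
    m4 = sum((v - mu) ** 4 for v in values) / n
    skew = m3 / m2**1.5 if m2 > 0 else 0.0
    kurt = m4 / m2**2 if m2 > 0 else 0.0
    return {
        "entropy": entropy,
        "uniformity": uniformity,
        "variance": m2,
        "skewness": skew,
        "kurtosis": kurt,
    }


def glcm_oracle(levels, mask, offsets, bin_count, symmetric=True):
    """Co-occurrence matrix by looping over every voxel and offset."""
    shape = mask.shape
    counts = np.zeros((bin_count, bin_count), dtype=float)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not mask[x, y, z]:
                    continue
                for dx, dy, dz in offsets:
                    u, v, w = x + dx, y + dy, z + dz
                    if not (0 <= u < shape[0] and 0 <= v < shape[1] and 0 <= w < shape[2]):
                        continue
                    if not mask[u, v, w]:
                        continue
                    counts[levels[x, y, z], levels[u, v, w]] += 1
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    return counts / total if total > 0 else counts


def glcm_features_oracle(P):
    """GLCM entropy / ASM / cluster shade / prominence by double loops."""
    n = P.shape[0]
    mu_x = sum(i * P[i, j] for i in range(n) for j in range(n))
    mu_y = sum(j * P[i, j] for i in range(n) for j in range(n))
    ent = -sum(
        P[i, j] * math.log2(P[i, j])
        for i in range(n)
        for j in range(n)
        if P[i, j] > 0
    )
    asm = sum(P[i, j] ** 2 for i in range(n) for j in range(n))
    shade = sum(
        (i + j - mu_x - mu_y) ** 3 * P[i, j] for i in range(n) for j in range(n)
    )
    prom = sum(
        (i + j - mu_x - mu_y) ** 4 * P[i, j] for i in range(n) for j in range(n)
    )
    return {
        "glcm_entropy": ent,
        "angular_second_moment": asm,
        "cluster_prominence": prom,
        "cluster_shade": shade,
    }


def all_features_oracle(grid, mask, bin_count, offsets):
    """The nine features for one VOI, fully by enumeration."""
    values = [float(grid[i]) for i in zip(*np.nonzero(mask))]
    feats = first_order_oracle(values, bin_count)
    levels_flat, _ = binning_oracle(values, bin_count)
    levels = np.zeros(mask.shape, dtype=int)
    for lev, idx in zip(levels_flat, zip(*np.nonzero(mask))):
        levels[idx] = lev
    P = glcm_oracle(levels, mask, offsets, bin_count)
    feats.update(glcm_features_oracle(P))
    return feats


# --------------------------------------------------------------- survival


def cox_loglik_oracle(beta, times, events, x):
    """Cox log partial likelihood (Breslow form; call with tie-free data)."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


def cox_beta_grid_oracle(times, events, x, lo=-4.0, hi=4.0, step=1e-3):
    """Argmax of the partial likelihood over a dense grid."""
    grid = np.arange(lo, hi + step, step)
    lls = [cox_loglik_oracle(b, times, events, x) for b in grid]
    return float(grid[int(np.argmax(lls))])


def km_oracle(times, events):
    """Product-limit estimator by explicit risk-set tabulation."""
    order = sorted(set(t for t, e in zip(times, events) if e == 1))
    surv = []
    s = 1.0
    for t in order:
        at_risk = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        s *= 1.0 - d / at_risk
        surv.append((t, s, at_risk))
    return surv


def logrank_oracle(times_a, events_a, times_b, events_b):
    """Two-sample log-rank chi-square by explicit 2x2 tables."""
    times = sorted(
        set([t for t, e in zip(times_a, events_a) if e == 1]
            + [t for t, e in zip(times_b, events_b) if e == 1])
    )
    O_minus_E = 0.0
    V = 0.0
    for t in times:
        n_a = sum(1 for ti in times_a if ti >= t)
        n_b = sum(1 for ti in times_b if ti >= t)
        d_a = sum(1 for ti, ei in zip(times_a, events_a) if ti == t and ei == 1)
        d_b = sum(1 for ti, ei in zip(times_b, events_b) if ti == t and ei == 1)
        n = n_a + n_b
        d = d_a + d_b
        if n < 2:
            continue
        e_a = d * n_a / n
        O_minus_E += d_a - e_a
        V += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1) if n > 1 else 0.0
    return O_minus_E**2 / V if V > 0 else 0.0


# ------------------------------------------------------------- evaluation


def auc_oracle(scores, outcomes):
    """All positive/negative pairs, half credit for ties."""
    pos = [s for s, y in zip(scores, outcomes) if y == 1]
    neg = [s for s, y in zip(scores, outcomes) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def c_index_oracle(times, events, risk):
    """Harrell's C over explicitly enumerated usable pairs."""
    conc = 0.0
    usable = 0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # usable: i had the event, and j outlived i (or was censored at t_i)
            if events[i] != 1:
                continue
            if times[j] > times[i] or (times[j] == times[i] and events[j] == 0):
                usable += 1
                if risk[i] > risk[j]:
                    conc += 1.0
                elif risk[i] == risk[j]:
                    conc += 0.5
    return conc / usable if usable else float("nan")


def youden_oracle(scores, outcomes, positive="high"):
    """Exhaustive threshold scan; ties toward the lower cutoff."""
    best = None
    for t in sorted(set(scores)):
        tp = fp = tn = fn = 0
        for s, y in zip(scores, outcomes):
            pred = (s >= t) if positive == "high" else (s < t)
            if pred and y == 1:
                tp += 1
            elif pred and y == 0:
                fp += 1
            elif not pred and y == 0:
                tn += 1
            else:
                fn += 1
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    return best[1], best[2], best[3]
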