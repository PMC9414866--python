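"""Independent brute-force reference implementations.

Everything here is written as direct, loop-based enumeration from the
defining formulas, deliberately sharing no code with the package: these
are the oracles the fast implementations are checked against.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import statsmodels.api as sm


def _cheb(u, v):
    return max(abs(a - b) for a, b in zip(u, v))


def _all_windows(x, h, w):
    """Flattened h x w windows at stride 1, row-major anchors."""
    rows, cols = x.shape
    out = []
    for i in range(rows - h + 1):
        for j in range(cols - w + 1):
            out.append([x[i + a][j + b] for a in range(h) for b in range(w)])
    return out


def sampen2d_bf(x, m, r):
    """Exhaustive pair enumeration over the shared (m+1)-anchor grid."""
    x = np.asarray(x, dtype=float)
    wm1 = _all_windows(x, m + 1, m + 1)
    sub = [i * (m + 1) + j for i in range(m) for j in range(m)]
    wm = [[win[k] for k in sub] for win in wm1]
    a = len(wm1)
    cm = cm1 = 0
    for i in range(a):
        for j in range(a):
            if i == j:
                continue
            if _cheb(wm[i], wm[j]) <= r:
                cm += 1
            if _cheb(wm1[i], wm1[j]) <= r:
                cm1 += 1
    if cm == 0 or cm1 == 0:
        return None
    return -math.log(cm1 / cm)


def fuzzen2d_bf(x, m, r, n, center=True):
    x = np.asarray(x, dtype=float)

    def phi(wins):
        if center:
            wins = [[v - sum(w) / len(w) for v in w] for w in wins]
        a = len(wins)
        tot = 0.0
        for i in range(a):
            for j in range(a):
                if i != j:
                    tot += math.exp(-(_cheb(wins[i], wins[j]) ** n) / r)
        return tot / (a * (a - 1))

    wm1 = _all_windows(x, m + 1, m + 1)
    sub = [i * (m + 1) + j for i in range(m) for j in range(m)]
    wm = [[win[k] for k in sub] for win in wm1]
    return -math.log(phi(wm1) / phi(wm))


def permen2d_bf(x, dn, dm, normalized=True, paper_literal=False):
    """Direct census of stable-ranked ordinal patterns."""
    x = np.asarray(x, dtype=float)
    wins = _all_windows(x, dn, dm)
    census: dict[tuple, int] = {}
    for w in wins:
        pattern = tuple(sorted(range(len(w)), key=lambda k: (w[k], k)))
        census[pattern] = census.get(pattern, 0) + 1
    total = len(wins)
    ent = -sum((c / total) * math.log(c / total) for c in census.values())
    if paper_literal:
        return ent / total
    if normalized:
        return ent / math.log(math.factorial(dn * dm))
    return ent


def dispen2d_bf(x, dn, dm, c, normalized=True, paper_literal=False):
    """Normal-CDF mapping, half-away rounding, direct pattern census."""
    x = np.asarray(x, dtype=float)
    mu = x.mean()
    sigma = x.std()
    if sigma == 0:
        return 0.0
    v = 0.5 * (1 + np.vectorize(math.erf)((x - mu) / (sigma * math.sqrt(2))))
    z = np.clip(np.floor(c * v + 0.5 + 0.5), 1, c)  # round-half-away of c*v+0.5
    wins = _all_windows(z, dn, dm)
    census: dict[tuple, int] = {}
    for w in wins:
        key = tuple(int(t) for t in w)
        census[key] = census.get(key, 0) + 1
    total = len(wins)
    ent = -sum((cnt / total) * math.log(cnt / total) for cnt in census.values())
    if paper_literal:
        return ent / total
    if normalized:
        return ent / math.log(float(c) ** (dn * dm))
    return ent


def disten2d_bf(x, m, bins, normalized=True):
    """Histogram of all distinct-pair window distances over [0, d_max]."""
    x = np.asarray(x, dtype=float)
    wins = _all_windows(x, m, m)
    a = len(wins)
    dists = []
    for i in range(a):
        for j in range(a):
            if i != j:
                dists.append(_cheb(wins[i], wins[j]))
    d_max = max(dists)
    if d_max == 0:
        return 0.0
    counts = [0] * bins
    for d in dists:
        k = min(int(d / d_max * bins), bins - 1)
        counts[k] += 1
    total = len(dists)
    ent = -sum((c / total) * math.log2(c / total) for c in counts if c > 0)
    if normalized:
        ent /= math.log2(bins)
    return ent


def glcm_bf(patch, levels, offsets, symmetric=True):
    """Hand accumulation of co-occurrence probabilities per offset, averaged."""
    q = (np.asarray(patch, dtype=np.int64) * levels) // 256
    rows, cols = q.shape
    mats = []
    for dr, dc in offsets:
        P = np.zeros((levels, levels))
        for i in range(rows):
            for j in range(cols):
                i2, j2 = i + dr, j + dc
                if 0 <= i2 < rows and 0 <= j2 < cols:
                    P[q[i, j], q[i2, j2]] += 1
                    if symmetric:
                        P[q[i2, j2], q[i, j]] += 1
        mats.append(P / P.sum())
    return np.mean(mats, axis=0)


def glcm_entropy_features_bf(P):
    """SumEntrp / Entropy / DifEntrp from a probability matrix, by loops."""
    L = P.shape[0]
    p_sum = [0.0] * (2 * L - 1)
    p_diff = [0.0] * L
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]

    def h(ps):
        return -sum(p * math.log(p) for p in ps if p > 0)

    return {"SumEntrp": h(p_sum), "Entropy": h(P.ravel()), "DifEntrp": h(p_diff)}


def ancova_slope_f_bf(x, y1, y2):
    """Slope-equality F statistic via statsmodels OLS model comparison.

    Full model: y ~ x * group; reduced: y ~ x + group.  The F-test on the
    interaction term is the textbook ANCOVA slope-homogeneity test.
    """
    x = np.asarray(x, float)
    y = np.concatenate([y1, y2])
    g = np.concatenate([np.zeros(len(y1)), np.ones(len(y2))])
    xs = np.concatenate([x, x])
    X_full = sm.add_constant(np.column_stack([xs, g, xs * g]))
    X_red = sm.add_constant(np.column_stack([xs, g]))
    full = sm.OLS(y, X_full).fit()
    red = sm.OLS(y, X_red).fit()
    df_resid = full.df_resid
    f = (red.ssr - full.ssr) / (full.ssr / df_resid)
    from scipy.stats import f as fdist

    return f, float(fdist.sf(f, 1, df_resid))
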