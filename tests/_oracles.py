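"""Brute-force reference implementations used to cross-check the package.

Everything here is written with explicit Python loops over subjects, cells
and resamples — no vectorization — so it constitutes an independent oracle
for the array-based implementation. The resampling oracles reproduce the
implementation's documented random-draw protocol (a fresh
``np.random.default_rng(seed)`` drawing ``rng.permutation(n)`` once per
replicate) and must then agree with it exactly.
"""

from __future__ import annotations

import math

import numpy as np


def brute_cell_counts(genotypes, phenotype, loci):
    """Case/control counts per genotype cell by per-subject iteration."""
    k = len(loci)
    ncells = 3**k
    X = [0] * ncells
    Y = [0] * ncells
    for i in range(len(phenotype)):
        j = 0
        for locus in loci:
            j = 3 * j + int(genotypes[i, locus])
        if phenotype[i] == 1:
            X[j] += 1
        else:
            Y[j] += 1
    return X, Y


def brute_table(X, Y, p0):
    """Indicator-sum evaluation of the 2x2 predisposing table."""
    n11 = n12 = n21 = n22 = 0
    high = []
    for j in range(len(X)):
        tot = X[j] + Y[j]
        ratio = X[j] / tot if tot > 0 else 0.0
        if ratio > p0:
            high.append(j)
            n11 += X[j]
            n12 += Y[j]
        else:
            n21 += X[j]
            n22 += Y[j]
    return n11, n12, n21, n22, high


def brute_raw_stats(n11, n12, n21, n22):
    """OR/RR with the +0.5 correction on any zero cell; Pearson chi-square."""
    shift = 0.5 if 0 in (n11, n12, n21, n22) else 0.0
    a, b, c, d = n11 + shift, n12 + shift, n21 + shift, n22 + shift
    odds = (a * d) / (b * c)
    rr = (a / (a + b)) / (c / (c + d))
    n = n11 + n12 + n21 + n22
    r1, r2, c1, c2 = n11 + n12, n21 + n22, n11 + n21, n12 + n22
    if r1 * r2 * c1 * c2 > 0:
        chi = n * (n11 * n22 - n12 * n21) ** 2 / (r1 * r2 * c1 * c2)
    else:
        chi = 0.0
    return odds, rr, chi


def brute_permutation_null(genotypes, phenotype, loci, B, seed):
    """Null resamples drawn with the implementation's permutation protocol."""
    rng = np.random.default_rng(seed)
    n = len(phenotype)
    p0 = sum(int(p) for p in phenotype) / n
    out = {"OR": [], "RR": [], "Chi": []}
    for _ in range(B):
        perm = rng.permutation(n)
        pheno = [phenotype[perm[i]] for i in range(n)]
        X, Y = brute_cell_counts(genotypes, pheno, loci)
        n11, n12, n21, n22, _ = brute_table(X, Y, p0)
        odds, rr, chi = brute_raw_stats(n11, n12, n21, n22)
        out["OR"].append(odds)
        out["RR"].append(rr)
        out["Chi"].append(chi)
    return out


def brute_ecdf(samples, x):
    return sum(1 for s in samples if s <= x) / len(samples)


def brute_quantile(samples, p):
    s = sorted(samples)
    if p <= 0:
        return s[0]
    idx = math.ceil(p * len(s)) - 1
    return s[min(max(idx, 0), len(s) - 1)]


def brute_corrected(x_obs, null_samples, alt_samples):
    rank = brute_ecdf(alt_samples, x_obs)
    denom = brute_quantile(null_samples, rank)
    if denom <= 0:
        denom = min(s for s in null_samples if s > 0)
    return x_obs / denom


def brute_pvalue(x_obs, perm_samples):
    return sum(1 for z in perm_samples if z > x_obs) / len(perm_samples)


def brute_risk_scores(genotypes, results, alpha):
    """Per-subject count of significant interactions with a high-risk cell."""
    n = genotypes.shape[0]
    scores = [0] * n
    for res in results:
        if not res.pvalue < alpha:
            continue
        high = set(res.table.high_risk_cells)
        for i in range(n):
            j = 0
            for locus in res.spec.loci:
                j = 3 * j + int(genotypes[i, locus])
            if j in high:
                scores[i] += 1
    return scores


def brute_auc(scores, phenotype):
    """Concordance by explicit case-control pair counting."""
    cases = [s for s, p in zip(scores, phenotype) if p == 1]
    controls = [s for s, p in zip(scores, phenotype) if p == 0]
    wins = 0.0
    for sc in cases:
        for st in controls:
            if sc > st:
                wins += 1.0
            elif sc == st:
                wins += 0.5
    return wins / (len(cases) * len(controls))


def brute_best_cutoff(scores, phenotype):
    """Exhaustive scan over midpoint and boundary cutoffs."""
    distinct = sorted(set(scores))
    candidates = [distinct[0] - 0.5]
    for a, b in zip(distinct, distinct[1:]):
        candidates.append((a + b) / 2)
    candidates.append(distinct[-1] + 0.5)
    best_c, best_acc = None, -1.0
    for c in candidates:
        acc = sum(
            1 for s, p in zip(scores, phenotype) if (1 if s > c else 0) == p
        ) / len(scores)
        if acc > best_acc:
            best_c, best_acc = c, acc
    return best_c, best_acc


def brute_bh(pvalues):
    """Step-up Benjamini-Hochberg by hand."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvalues[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj
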