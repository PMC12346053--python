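"""Independent brute-force oracles used only by the test suite.

Each function re-derives a quantity from first principles (exhaustive
enumeration, explicit pairwise counting, direct formula evaluation) without
touching the implementation paths it checks.
"""

from fractions import Fraction
from itertools import combinations
from math import comb, sqrt

import numpy as np


def bruteforce_runs(states, positions, min_snps, min_length,
                    max_opposite, max_missing, max_gap):
    """Accepted runs by exhaustive window enumeration + greedy selection.

    ``states``: sequence of 'T' (target), 'O' (opposite), 'M' (missing).
    A window (i, j) is valid when it starts and ends on 'T', holds at most
    max_opposite 'O' and max_missing 'M', and no adjacent gap exceeds
    max_gap.  Candidates are chosen greedily left to right (smallest start,
    then largest end, non-overlapping), then filtered on the minimum SNP
    count and span.
    """
    n = len(states)

    def valid(i, j):
        if states[i] != "T" or states[j] != "T":
            return False
        window = states[i:j + 1]
        if window.count("O") > max_opposite:
            return False
        if window.count("M") > max_missing:
            return False
        return all(
            positions[k + 1] - positions[k] <= max_gap
            for k in range(i, j)
        )

    accepted = []
    cursor = 0
    while cursor < n:
        candidates = [
            (i, j)
            for i in range(cursor, n)
            for j in range(i, n)
            if valid(i, j)
        ]
        if not candidates:
            break
        start = min(i for i, _ in candidates)
        end = max(j for i, j in candidates if i == start)
        n_target = states[start:end + 1].count("T")
        span = positions[end] - positions[start]
        if n_target >= min_snps and span >= min_length:
            accepted.append((positions[start], positions[end], n_target))
        cursor = end + 1
    return accepted


def bruteforce_mwu(x, y, alternative="two-sided"):
    """Exact Mann-Whitney p by enumerating group assignments, with U
    computed by direct pairwise comparison (ties count one half)."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(group_x, group_y):
        u = 0.0
        for a in group_x:
            for b in group_y:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    u_obs = u_of(x, y)
    mu = n1 * len(y) / 2
    total = comb(len(pooled), n1)
    count = 0
    for idx in combinations(range(len(pooled)), n1):
        gx = [pooled[i] for i in idx]
        gy = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_of(gx, gy)
        if alternative == "two-sided":
            hit = abs(u - mu) >= abs(u_obs - mu) - 1e-12
        elif alternative == "greater":
            hit = u >= u_obs - 1e-12
        else:
            hit = u <= u_obs + 1e-12
        count += hit
    return count / total


def bruteforce_tajima_d(genotypes):
    """Tajima's D from explicit sequences and all-pairs difference counts.

    ``genotypes``: individuals x sites matrix of B-allele dosages
    (0/1/2; no missing).  Each individual contributes two sequences; the
    heterozygote split is phase-free for pairwise differences.
    """
    g = np.asarray(genotypes)
    n_ind, n_sites = g.shape
    seqs = np.zeros((2 * n_ind, n_sites), dtype=int)
    for i in range(n_ind):
        for j in range(n_sites):
            d = g[i, j]
            if d == 1:
                seqs[2 * i, j], seqs[2 * i + 1, j] = 0, 1
            else:
                seqs[2 * i, j] = seqs[2 * i + 1, j] = d // 2
    n = 2 * n_ind
    s = sum(
        1 for j in range(n_sites)
        if 0 < seqs[:, j].sum() < n
    )
    if s == 0:
        return float("nan")
    total_diff = 0
    n_pairs = 0
    for a, b in combinations(range(n), 2):
        total_diff += int((seqs[a] != seqs[b]).sum())
        n_pairs += 1
    pi = total_diff / n_pairs

    a1 = float(sum(Fraction(1, i) for i in range(1, n)))
    a2 = float(sum(Fraction(1, i * i) for i in range(1, n)))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = float(b1) - 1.0 / a1
    c2 = float(b2) - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - s / a1) / sqrt(e1 * s + e2 * s * (s - 1))


def weir_cockerham_fst(counts_per_herd, sizes):
    """Multi-locus Weir-Cockerham theta from per-herd genotype data.

    ``counts_per_herd``: list over herds of (n_ind x n_markers) dosage
    matrices (0/1/2, no missing).  Returns the ratio-of-sums estimate.
    """
    r = len(counts_per_herd)
    p = np.array([m.mean(axis=0) / 2 for m in counts_per_herd])
    h = np.array([(m == 1).mean(axis=0) for m in counts_per_herd])
    n = np.asarray(sizes, dtype=float)
    n_bar = n.mean()
    n_c = (r * n_bar - (n**2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n[:, None] * p).sum(axis=0) / (r * n_bar)
    s2 = (n[:, None] * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n[:, None] * h).sum(axis=0) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2
        - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return float(a.sum() / (a + b + c).sum())


def spearman_by_hand(x, y):
    """Spearman rho via midranks and the Pearson formula on ranks."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / sqrt((rx**2).sum() * (ry**2).sum()))
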