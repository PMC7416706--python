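"""Independent brute-force reference implementations.

Deliberately naive (plain Python loops, itertools enumeration) so they stay
independent of the library code paths they are used to check.
"""

from __future__ import annotations

import itertools
import math


# --- diversity -------------------------------------------------------------

def brute_shannon(freqs):
    return -sum(p * math.log(p) for p in freqs if p > 0)


def brute_normalized_shannon(freqs):
    s = len(freqs)
    if s == 1:
        return 0.0
    return brute_shannon(freqs) / math.log(s)


def brute_clonality(freqs):
    s = len(freqs)
    if s == 1:
        return 1.0
    return 1.0 - brute_shannon(freqs) / math.log(s)


def brute_inverse_simpson(freqs):
    return 1.0 / sum(p * p for p in freqs)


def brute_gini_simpson(freqs):
    return 1.0 - sum(p * p for p in freqs)


def brute_chao1(counts):
    s = len(counts)
    f1 = sum(1 for c in counts if c == 1)
    f2 = sum(1 for c in counts if c == 2)
    if f2 > 0:
        return s + f1 * f1 / (2.0 * f2)
    return s + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def brute_d50(freqs):
    total = 0.0
    for i, f in enumerate(sorted(freqs, reverse=True), start=1):
        total += f
        if total >= 0.5:
            return i
    return len(freqs)


# --- similarity ------------------------------------------------------------

def brute_jaccard(keys_a, keys_b):
    a, b = set(keys_a), set(keys_b)
    return len(a & b) / len(a | b) if a | b else 0.0


def brute_overlap_coefficient(keys_a, keys_b):
    a, b = set(keys_a), set(keys_b)
    m = min(len(a), len(b))
    return len(a & b) / m if m else 0.0


def brute_morisita_horn(freq_a: dict, freq_b: dict):
    keys = set(freq_a) | set(freq_b)
    num = 2 * sum(freq_a.get(k, 0.0) * freq_b.get(k, 0.0) for k in keys)
    den = sum(v * v for v in freq_a.values()) + sum(v * v for v in freq_b.values())
    return num / den if den else 0.0


def brute_bhattacharyya(freq_a: dict, freq_b: dict):
    keys = set(freq_a) | set(freq_b)
    return sum(math.sqrt(freq_a.get(k, 0.0) * freq_b.get(k, 0.0)) for k in keys)


# --- homeostasis -----------------------------------------------------------

def brute_homeostasis(freq_count_pairs, edges):
    """Per-clone scan; returns (mass per bin, reads per bin)."""
    mass = [0.0] * len(edges)
    reads = [0] * len(edges)
    for freq, count in freq_count_pairs:
        for i, upper in enumerate(edges):
            lower = 0.0 if i == 0 else edges[i - 1]
            if lower < freq <= upper:
                mass[i] += freq
                reads[i] += count
                break
        else:
            raise AssertionError(f"frequency {freq} fell outside all bins")
    return mass, reads


# --- chi-square ------------------------------------------------------------

def brute_chi2(table):
    """Pearson chi-square of a 2 x k table via sum (O - E)^2 / E."""
    rows = len(table)
    cols = len(table[0])
    total = sum(sum(r) for r in table)
    row_sums = [sum(r) for r in table]
    col_sums = [sum(table[r][c] for r in range(rows)) for c in range(cols)]
    chi2 = 0.0
    for r in range(rows):
        for c in range(cols):
            e = row_sums[r] * col_sums[c] / total
            chi2 += (table[r][c] - e) ** 2 / e
    return chi2, (rows - 1) * (cols - 1)


# --- Mann-Whitney exact ----------------------------------------------------

def brute_mannwhitney_exact_p(xs, ys):
    """Two-sided exact p by enumerating every assignment of pooled ranks.

    Assumes no ties.  U statistic for the first group; p is the fraction of
    assignments with |U - mean| >= |U_obs - mean|.
    """
    n, m = len(xs), len(ys)
    values = sorted(list(xs) + list(ys))

    def u_from_indices(idx):
        group = [values[i] for i in idx]
        rest = [values[i] for i in range(n + m) if i not in idx]
        return sum(1 for x in group for y in rest if x > y)

    u_obs = sum(1 for x in xs for y in ys if x > y)
    mean = n * m / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(n + m), n):
        u = u_from_indices(set(idx))
        total += 1
        if abs(u - mean) >= abs(u_obs - mean):
            count += 1
    return count / total


# --- agglomerative clustering ----------------------------------------------

def brute_agglomerate(labels, dist, linkage):
    """O(n^3) agglomeration; returns merge list [(label_a, label_b, height)].

    Cluster label = lexicographically smallest member; ties in merge
    distance broken by the sorted label pair.
    """
    clusters = {lab: [i] for i, lab in enumerate(labels)}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            pairs = [dist[i][j] for i in clusters[a] for j in clusters[b]]
            if linkage == "single":
                d = min(pairs)
            elif linkage == "complete":
                d = max(pairs)
            else:
                d = sum(pairs) / len(pairs)
            if best is None or (d, a, b) < best:
                best = (d, a, b)
        d, a, b = best
        members = clusters.pop(a) + clusters.pop(b)
        clusters[min(a, b)] = members
        merges.append((a, b, d))
    return merges
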