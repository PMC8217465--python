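"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: Fisher by direct
hypergeometric enumeration over margin-preserving tables, the rank-sum test
by explicit enumeration of all group assignments, and candidate runs by a
literal scan over peak runs.
"""

import itertools
import math

import numpy as np


def fisher_two_sided_enumeration(table) -> float:
    """Sum of hypergeometric probabilities <= that of the observed table,
    over all 2x2 tables with the observed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return (math.comb(r1, x) * math.comb(r2, c1 - x)
                / math.comb(n, c1))

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def rank_sum_permutation(group_a, group_b) -> float:
    """Two-sided p by full enumeration of rank assignments (midranks)."""
    from scipy.stats import rankdata

    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    n = a.size
    ranks = rankdata(np.concatenate([a, b]))
    w_obs = ranks[:n].sum()
    mu = n * (ranks.size + 1) / 2.0
    dev = abs(w_obs - mu)
    count = total = 0
    for comb in itertools.combinations(range(ranks.size), n):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mu) >= dev - 1e-9:
            count += 1
    return count / total


def scan_candidate_runs(peak_amps, long_thr, high_thr, long_peaks=8,
                        short_peaks=6):
    """Literal scan for maximal runs of >=long_peaks peaks above long_thr
    containing >=short_peaks consecutive peaks above high_thr. Returns
    (start_index, end_index) pairs into the peak series."""
    above = [amp > t for amp, t in zip(peak_amps, long_thr)]
    runs = []
    i = 0
    while i < len(above):
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(above) and above[j + 1]:
            j += 1
        if j - i + 1 >= long_peaks:
            best = cur = 0
            for k in range(i, j + 1):
                cur = cur + 1 if peak_amps[k] > high_thr else 0
                best = max(best, cur)
            if best >= short_peaks:
                runs.append((i, j))
        i = j + 1
    return runs
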