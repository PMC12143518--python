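"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: ARI by explicit
pair counting over all cell pairs, NMI by direct plug-in entropy sums,
the DWT matrix by a naive per-row loop, and set intersections by
per-gene enumeration over all subsets.
"""

import itertools
import math

import numpy as np


def ari_pair_counting(a, b) -> float:
    """ARI via explicit agreement counts over all unordered cell pairs."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa = a[i] == a[j]
            sb = b[i] == b[j]
            n11 += sa and sb
            n00 += (not sa) and (not sb)
            n10 += sa and not sb
            n01 += (not sa) and sb
    total = n * (n - 1) / 2
    sum_ij = n11
    sum_a = n11 + n10
    sum_b = n11 + n01
    expected = sum_a * sum_b / total
    denom = 0.5 * (sum_a + sum_b) - expected
    if denom == 0:
        raise ZeroDivisionError("degenerate pair counts")
    return (sum_ij - expected) / denom


def nmi_plugin(a, b) -> float:
    """NMI via dictionary-based joint counts and plug-in entropies."""
    a, b = list(a), list(b)
    n = len(a)
    joint, ca, cb = {}, {}, {}
    for x, y in zip(a, b):
        joint[(x, y)] = joint.get((x, y), 0) + 1
        ca[x] = ca.get(x, 0) + 1
        cb[y] = cb.get(y, 0) + 1
    ha = -sum(c / n * math.log(c / n) for c in ca.values())
    hb = -sum(c / n * math.log(c / n) for c in cb.values())
    mi = 0.0
    for (x, y), c in joint.items():
        p = c / n
        mi += p * math.log(p * n * n / (ca[x] * cb[y]))
    return mi / math.sqrt(ha * hb)


def naive_dwt_matrix(taps, n) -> np.ndarray:
    """Transform matrix built by an independent element-wise loop."""
    M = len(taps)
    L = len(taps[0])
    k = n // M
    W = np.zeros((n, n))
    for i in range(M):
        for r in range(k):
            for t in range(L):
                W[i * k + r, (M * r + t) % n] += taps[i][t]
    return W


def exclusive_cells_bruteforce(sets):
    """Per-subset exclusive membership by per-gene enumeration."""
    m = len(sets)
    union = set().union(*sets)
    out = {}
    for r in range(1, m + 1):
        for L in itertools.combinations(range(m), r):
            Ls = set(L)
            members = {
                g for g in union
                if all(g in sets[i] for i in Ls)
                and all(g not in sets[j] for j in range(m) if j not in Ls)
            }
            out[frozenset(L)] = members
    return out
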