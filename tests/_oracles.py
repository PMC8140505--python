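"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's alignment machinery: the
Smith-Waterman here is a plain Gotoh dynamic program with explicit
traceback, written against the same scoring scheme (BLOSUM62, -11/-1)
so count-based quantities can be compared exactly.
"""

from __future__ import annotations

import math

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

KA_LAMBDA = 0.267
KA_K = 0.041

NEG = -1e9


def sw_gotoh(a: str, b: str, gap_open: float = -11.0, gap_extend: float = -1.0):
    """Local affine-gap alignment by explicit dynamic programming.

    Returns (score, matches, columns, a_span, b_span) of the best local
    alignment, or None when the best score is <= 0.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), 0.0)
    Ix = np.full((n + 1, m + 1), NEG)   # gap in b (consuming a)
    Iy = np.full((n + 1, m + 1), NEG)   # gap in a (consuming b)
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)   # 0 start,1 M,2 Ix,3 Iy
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)   # 1 open from M, 2 extend
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    best, best_pos = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            x_open = M[i - 1, j] + gap_open
            x_ext = Ix[i - 1, j] + gap_extend
            if x_open >= x_ext:
                Ix[i, j], ptr_x[i, j] = x_open, 1
            else:
                Ix[i, j], ptr_x[i, j] = x_ext, 2
            y_open = M[i, j - 1] + gap_open
            y_ext = Iy[i, j - 1] + gap_extend
            if y_open >= y_ext:
                Iy[i, j], ptr_y[i, j] = y_open, 1
            else:
                Iy[i, j], ptr_y[i, j] = y_ext, 2
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            cands = (
                (0.0, 0),       # restart: the alignment begins with this pair
                (M[i - 1, j - 1], 1),
                (Ix[i - 1, j - 1], 2),
                (Iy[i - 1, j - 1], 3),
            )
            prev, came = max(cands, key=lambda t: t[0])
            M[i, j], ptr_m[i, j] = prev + s, came
            if M[i, j] > best:
                best, best_pos = M[i, j], (i, j)
    if best <= 0 or best_pos is None:
        return None
    # traceback from best_pos in state M
    i, j = best_pos
    state = "M"
    matches = columns = 0
    a_end, b_end = i, j
    while True:
        if state == "M":
            came = ptr_m[i, j]
            columns += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            i, j = i - 1, j - 1
            if came == 0:
                break
            state = {1: "M", 2: "X", 3: "Y"}[came]
        elif state == "X":
            columns += 1
            came = ptr_x[i, j]
            i -= 1
            state = "M" if came == 1 else "X"
        else:
            columns += 1
            came = ptr_y[i, j]
            j -= 1
            state = "M" if came == 1 else "Y"
    return best, matches, columns, a_end - i, b_end - j


def pocp_oracle(prot1, prot2) -> float:
    """POCP by brute-force all-pairs Smith-Waterman with the standard hit
    criteria (E < 1e-5, identity > 40%, alignable region > 50% of query)."""

    def conserved(queries, subjects) -> int:
        count = 0
        for _, q in queries:
            for _, s in subjects:
                res = sw_gotoh(q, s)
                if res is None:
                    continue
                score, matches, columns, q_span, _ = res
                evalue = KA_K * len(q) * len(s) * math.exp(-KA_LAMBDA * score)
                if (
                    evalue < 1e-5
                    and matches / columns > 0.4
                    and q_span > 0.5 * len(q)
                ):
                    count += 1
                    break
        return count

    c1 = conserved(prot1, prot2)
    c2 = conserved(prot2, prot1)
    return 100.0 * (c1 + c2) / (len(prot1) + len(prot2))


def n50_oracle(lengths) -> int:
    """N50 by exhaustively testing every candidate length L."""
    lengths = sorted(lengths)
    total = sum(lengths)
    best = 0
    for L in lengths:
        covered = sum(x for x in lengths if x >= L)
        if covered >= total / 2 and L > best:
            best = L
    return best


def mash_distance_oracle(j: float, k: int) -> float:
    """Closed-form Mash distance from a known Jaccard index."""
    if j == 0:
        return 1.0
    return -math.log(2 * j / (1 + j)) / k


def k2p_oracle(p: float, q: float) -> float:
    """Closed-form Kimura 2-parameter distance from fractions P and Q."""
    return -0.5 * math.log((1 - 2 * p - q) * math.sqrt(1 - 2 * q))
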