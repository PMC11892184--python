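"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the IR oracle
enumerates maximal complementary runs along alignment anti-diagonals with
numpy, and the Fisher oracle enumerates every margin-fixed 2x2 table with
exact integer arithmetic.
"""

from __future__ import annotations

import math

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP_CODE = {0: 3, 1: 2, 2: 1, 3: 0, 4: 9}  # N complements to nothing


def brute_force_ir_pairs(
    seq: str,
    min_ir_len: int = 10,
    max_ir_len: int = 100,
    max_span: int = 750,
    min_loop: int = 0,
    min_score: int = 50,
    match_score: int = 3,
):
    """All maximal exact inverted-repeat pairs meeting the bounds.

    Enumerates, for every anti-diagonal, maximal runs of positions i < j
    with seq[i] complementary to seq[j]; trims inner pairs to honor the
    loop bound; filters by length, span and score.  Returns sorted
    (a, b, c, d) tuples (0-based half-open IR coordinates).
    """
    s = np.array([_CODE[ch] for ch in seq.upper()], dtype=np.int16)
    comp = np.array([_COMP_CODE[int(x)] if int(x) in _COMP_CODE else 9 for x in s])
    n = len(s)
    out = []
    for diag in range(2 * n - 2 + 1):
        i_lo = max(0, diag - (n - 1))
        # only the half where i < j = diag - i
        i_hi = (diag - 1) // 2
        if i_hi < i_lo:
            continue
        ii = np.arange(i_lo, i_hi + 1)
        jj = diag - ii
        b = s[ii] == comp[jj]
        # maximal runs of True
        idx = np.nonzero(b)[0]
        if len(idx) == 0:
            continue
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [len(idx) - 1]])
        for rs, re in zip(run_starts, run_ends):
            i0, i1 = int(ii[idx[rs]]), int(ii[idx[re]])
            # innermost pair (i1, diag - i1): trim until loop >= min_loop
            while i1 >= i0 and (diag - i1) - i1 - 1 < min_loop:
                i1 -= 1
            if i1 < i0:
                continue
            a, bb = i0, i1 + 1
            c, d = diag - i1, diag - i0 + 1
            L = bb - a
            if L < min_ir_len or L > max_ir_len:
                continue
            if d - a > max_span:
                continue
            if match_score * L < min_score:
                continue
            out.append((a, bb, c, d))
    return sorted(set(out))


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration of margin-fixed tables
    using exact integer weights."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    w_obs = math.comb(r1, a) * math.comb(r2, c)
    total = math.comb(n, c1)
    acc = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, x) * math.comb(r2, c1 - x)
        if w <= w_obs:
            acc += w
    return acc / total
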