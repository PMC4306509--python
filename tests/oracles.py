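"""Independent brute-force oracles used only by the test suite.

These are deliberately naive: exact integer arithmetic and exhaustive
enumeration, sharing no code with the implementation they check.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def fisher_2x2_oracle(table) -> float:
    """Two-sided Fisher p by integer-weight enumeration of one free cell."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    weights = {
        k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)
    }
    # integer form of w <= w_obs * (1 + 1e-7): exact, no rounding anywhere
    w_obs = weights[a]
    num = sum(w for w in weights.values() if w * 10**7 <= w_obs * (10**7 + 1))
    return num / sum(weights.values())


def fisher_rxc_oracle(table) -> float:
    """Two-sided Fisher p by exhaustive enumeration with exact fractions.

    P(T) with fixed margins is proportional to 1 / prod(cells!), so table
    probabilities are compared through the exact integer prod(cells!).
    """
    arr = [list(map(int, row)) for row in table]
    row_sums = [sum(r) for r in arr]
    col_sums = [sum(col) for col in zip(*arr)]

    def cellfact(t) -> int:
        out = 1
        for row in t:
            for x in row:
                out *= math.factorial(x)
        return out

    def tables(rows_left, cols_left):
        if len(rows_left) == 1:
            yield [list(cols_left)]
            return
        target = rows_left[0]
        ranges = [range(min(target, c) + 1) for c in cols_left[:-1]]
        for head in itertools.product(*ranges):
            last = target - sum(head)
            if 0 <= last <= cols_left[-1]:
                row = list(head) + [last]
                rest_cols = [c - r for c, r in zip(cols_left, row)]
                for tail in tables(rows_left[1:], rest_cols):
                    yield [row] + tail

    inv_obs = Fraction(1, cellfact(arr))
    cutoff = inv_obs * (1 + Fraction(1, 10**7))
    num = Fraction(0)
    den = Fraction(0)
    for t in tables(row_sums, col_sums):
        p = Fraction(1, cellfact(t))
        den += p
        if p <= cutoff:
            num += p
    return float(num / den)


def ranksum_exact_oracle(x, y) -> float:
    """Two-sided rank-sum p by enumeration of all group assignments."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    ranks = {v: r + 1 for r, v in enumerate(pooled)}  # no ties expected
    n = len(x)
    obs = sum(ranks[v] for v in x)
    mean = n * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        total += 1
        stat = sum(r + 1 for r in combo)
        if abs(stat - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


def ranksum_permutation_oracle(x, y, n_draws: int, seed: int) -> float:
    """Monte-Carlo permutation p for the rank-sum statistic with midranks."""
    from scipy.stats import rankdata

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n = x.size
    obs = ranks[:n].sum()
    mean = n * (pooled.size + 1) / 2
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_draws):
        perm = rng.permutation(ranks)
        if abs(perm[:n].sum() - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / n_draws


def scan_oracle(sequence: str, pattern, min_len: int, max_len: int):
    """All (start0, longest matching length) via full substring enumeration."""
    import re

    pat = re.compile(pattern)
    out = {}
    for start in range(len(sequence)):
        for length in range(min(max_len, len(sequence) - start), min_len - 1, -1):
            if pat.fullmatch(sequence[start : start + length]):
                out[start] = length
                break
    return out
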