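"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive and self-contained: exact
rational binomial tails, an all-windows scan with union/trim done
with plain Python sets, a dynamic-programming LCS, and the direct
chi-square formula. None of it calls chargescan.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from math import comb
from typing import List, Set, Tuple

POSITIVE = set("KR")
NEGATIVE = set("DE")


@lru_cache(maxsize=None)
def exact_binomial_tail(k: int, n: int, p_num: int, p_den: int) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, p_num/p_den), exact rational."""
    p = Fraction(p_num, p_den)
    q = 1 - p
    return sum(
        (comb(n, j) * p**j * q ** (n - j) for j in range(k, n + 1)), Fraction(0)
    )


def tail_float(k: int, n: int, p: float) -> float:
    frac = Fraction(p)
    return float(exact_binomial_tail(k, n, frac.numerator, frac.denominator))


def brute_force_critical_count(w: int, p: float, alpha: float):
    """Smallest k with exact tail <= alpha, by linear search."""
    frac = Fraction(p)
    alpha_frac = Fraction(alpha)
    for k in range(w + 1):
        if exact_binomial_tail(k, w, frac.numerator, frac.denominator) <= alpha_frac:
            return k
    return None


def brute_force_scan(
    sequence: str, alphabet: Set[str], p0: float, w: int, alpha: float
) -> List[Tuple[int, int]]:
    """All-windows scan: exact tails, union of covered positions, runs,
    trim to class residues. Returns 1-based inclusive intervals."""
    length = len(sequence)
    width = min(w, length)
    frac = Fraction(p0)
    alpha_frac = Fraction(alpha)
    covered: Set[int] = set()
    for i in range(length - width + 1):
        window = sequence[i : i + width]
        k = sum(ch in alphabet for ch in window)
        if exact_binomial_tail(k, width, frac.numerator, frac.denominator) <= alpha_frac:
            covered.update(range(i, i + width))
    intervals = []
    for run in _runs(covered):
        charged = [i for i in run if sequence[i] in alphabet]
        if not charged:
            continue
        intervals.append((charged[0] + 1, charged[-1] + 1))
    return intervals


def _runs(positions: Set[int]) -> List[List[int]]:
    runs: List[List[int]] = []
    for i in sorted(positions):
        if runs and i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    return runs


def lcs_length(a: str, b: str) -> int:
    """Longest common subsequence by dynamic programming."""
    table = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                table[i][j] = table[i - 1][j - 1] + 1
            else:
                table[i][j] = max(table[i - 1][j], table[i][j - 1])
    return table[len(a)][len(b)]


def chi_square_direct(table) -> Tuple[float, int]:
    """Pearson chi-square statistic and df, straight from the formula."""
    rows = len(table)
    cols = len(table[0])
    total = sum(sum(row) for row in table)
    row_sums = [sum(row) for row in table]
    col_sums = [sum(table[i][j] for i in range(rows)) for j in range(cols)]
    stat = 0.0
    for i in range(rows):
        for j in range(cols):
            expected = row_sums[i] * col_sums[j] / total
            stat += (table[i][j] - expected) ** 2 / expected
    return stat, (rows - 1) * (cols - 1)
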