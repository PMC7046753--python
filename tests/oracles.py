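"""Independent brute-force oracles used to validate the package's statistics.

Deliberately naive: plain Python loops and log-gamma series, no scipy and no
code shared with the implementation under test.
"""

from __future__ import annotations

import math


def poisson_upper_tail(k: int, lam: float, tol: float = 1e-18) -> float:
    """P(X >= k) for X ~ Poisson(lam), by direct term-by-term summation."""
    if lam == 0:
        return 1.0 if k <= 0 else 0.0
    # start at the term for x = k, computed in log space for stability
    log_term = -lam + k * math.log(lam) - math.lgamma(k + 1)
    term = math.exp(log_term)
    total = 0.0
    x = k
    while True:
        total += term
        x += 1
        term *= lam / x
        if term < tol * max(total, 1e-300) and x > lam:
            break
    return min(total, 1.0)


def poisson_lower_tail(k: int, lam: float) -> float:
    """P(X <= k) by summing x = 0..k."""
    if lam == 0:
        return 1.0
    total = 0.0
    term = math.exp(-lam)
    for x in range(k + 1):
        total += term
        term *= lam / (x + 1)
    return min(total, 1.0)


def _log_hyper_pmf(x: int, N: int, n: int, m: int) -> float:
    return (
        math.lgamma(n + 1) - math.lgamma(x + 1) - math.lgamma(n - x + 1)
        + math.lgamma(N - n + 1) - math.lgamma(m - x + 1)
        - math.lgamma(N - n - m + x + 1)
        - (math.lgamma(N + 1) - math.lgamma(m + 1) - math.lgamma(N - m + 1))
    )


def hypergeom_upper_tail(k: int, N: int, n: int, m: int) -> float:
    """P(X >= k), population N, n successes, m draws; exhaustive summation."""
    hi = min(n, m)
    total = 0.0
    for x in range(max(k, max(0, n + m - N)), hi + 1):
        total += math.exp(_log_hyper_pmf(x, N, n, m))
    return min(total, 1.0)


def hypergeom_lower_tail(k: int, N: int, n: int, m: int) -> float:
    total = 0.0
    for x in range(max(0, n + m - N), min(k, min(n, m)) + 1):
        total += math.exp(_log_hyper_pmf(x, N, n, m))
    return min(total, 1.0)


def hypergeom_upper_exact(k: int, N: int, n: int, m: int):
    """Exact rational P(X >= k) via integer combinatorics (small inputs)."""
    from fractions import Fraction

    denom = math.comb(N, m)
    num = sum(
        math.comb(n, x) * math.comb(N - n, m - x)
        for x in range(max(k, max(0, n + m - N)), min(n, m) + 1)
    )
    return Fraction(num, denom)


def count_cobinding_allpairs(
    summits_a: dict[str, list[int]],
    summits_b: dict[str, list[int]],
    d_s: int,
) -> int:
    """O(n*m) oracle: count a-summits with any b-summit within d_s, per chrom."""
    k = 0
    for chrom, sa in summits_a.items():
        sb = summits_b.get(chrom, [])
        for pa in sa:
            if any(abs(pa - pb) <= d_s for pb in sb):
                k += 1
    return k


def best_instance(seq: str, freq, tie_plus: bool = True):
    """Exhaustive best-motif-instance search matching the scan contract.

    freq: 4xL nested list of frequencies (A, C, G, T rows).  Returns
    (raw_score, offset, strand) with ties toward '+' then the lower offset;
    ambiguous bases contribute the column mean.
    """
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(freq[0])
    col_mean = [sum(freq[b][j] for b in range(4)) / 4.0 for j in range(L)]
    comp = {0: 3, 1: 2, 2: 1, 3: 0}

    def score(offset: int, strand: str) -> float:
        s = 0.0
        for j in range(L):
            base = seq[offset + j].upper()
            b = idx.get(base)
            if strand == "+":
                s += col_mean[j] if b is None else freq[b][j]
            else:
                # instance read on the reverse strand: position j of the
                # motif aligns to forward position offset + L - 1 - j
                base = seq[offset + L - 1 - j].upper()
                b = idx.get(base)
                s += col_mean[j] if b is None else freq[comp[b]][j]
        return s

    best = (-math.inf, 0, "+")
    for strand in ("+", "-"):
        for offset in range(len(seq) - L + 1):
            sc = score(offset, strand)
            better = sc > best[0] + 1e-9
            if better:
                best = (sc, offset, strand)
    return best
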