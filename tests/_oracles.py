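"""Independent brute-force oracles used to validate the implementation.

Each oracle is deliberately naive (direct summation, exhaustive
enumeration, character-by-character scanning) and shares no code with
the implementation path it checks.
"""

from __future__ import annotations

from itertools import combinations

import mpmath as mp

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def oracle_tagcount_pvalue(x: int, y: int, n1: float, n2: float, dps: int = 50) -> float:
    """Arbitrary-precision direct tail summation of the tag-count test."""
    with mp.workdps(dps):
        def pmf(a: int, k: int, q: mp.mpf, omq: mp.mpf) -> mp.mpf:
            return mp.binomial(a + k, k) * q**k * omq ** (a + 1)

        def upper(a: int, b: int, q: mp.mpf, omq: mp.mpf) -> mp.mpf:
            # P(B >= b | a): sum_{k>=b} C(a+k, k) q^k (1-q)^(a+1)
            if b <= 0:
                return mp.mpf(1)
            mode = q * (a + 1) / omq
            if b <= mode:
                # short complementary sum; the tail here is of order one
                lower = mp.mpf(0)
                term = pmf(a, 0, q, omq)
                for k in range(b):
                    if k > 0:
                        term = term * q * (a + k) / k
                    lower += term
                return min(max(1 - lower, mp.mpf(0)), mp.mpf(1))
            term = pmf(a, b, q, omq)
            total = term
            k = b
            while term > 0:
                k += 1
                term = term * q * (a + k) / k
                total += term
                ratio = q * (a + k + 1) / (k + 1)
                if ratio < 1 and term * ratio / (1 - ratio) < total * mp.mpf(10) ** (-dps - 5):
                    break
            return min(total, mp.mpf(1))

        q12 = mp.mpf(n2) / (n1 + n2)
        q21 = mp.mpf(n1) / (n1 + n2)
        p = 2 * min(upper(x, y, q12, q21), upper(y, x, q21, q12))
        return float(min(p, mp.mpf(1)))


def oracle_hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws (N <= 12)."""
    population = list(range(N))
    marked = set(range(K))
    hits = 0
    total = 0
    for draw in combinations(population, n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def oracle_scan_genome(tag: str, genome: dict[str, str]):
    """All exact occurrences of tag (both strands) by O(nm) comparison."""
    hits = []
    rc = oracle_revcomp(tag)
    m = len(tag)
    for chrom, seq in genome.items():
        for i in range(len(seq) - m + 1):
            window = seq[i : i + m]
            if all(a == b for a, b in zip(window, tag)):
                hits.append((chrom, i, i + m, "+"))
            if all(a == b for a, b in zip(window, rc)):
                hits.append((chrom, i, i + m, "-"))
    return sorted(hits)


def oracle_best_stem(seq: str, min_loop: int = 3) -> tuple[float, int]:
    """(score, paired count) of the best contiguous stem, by triple loop."""
    n = len(seq)
    wc = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    gu = {("G", "T"), ("T", "G")}
    best_score, best_len = 0.0, 0
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            weight, length = 0.0, 0
            for k in range(n):
                a, b = i + k, j - k
                if b - a - 1 < min_loop:
                    break
                pair = (seq[a], seq[b])
                if pair in wc:
                    weight += 1.0
                elif pair in gu:
                    weight += 0.5
                else:
                    break
                length += 1
                score = -weight
                if (score, -length) < (best_score, -best_len):
                    best_score, best_len = score, length
    return best_score, best_len


def oracle_target_penalty(mirna: str, window: str) -> float:
    """Recount the duplex penalty from explicit per-position states."""
    L = len(mirna)
    assert len(window) == L
    penalty = 0.0
    for p in range(1, L + 1):  # 1-based from miRNA 5' end
        m = mirna[p - 1]
        t = window[L - p]  # antiparallel partner
        pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
        weight = 2.0 if 2 <= p <= 13 else 1.0
        if (m, t) in pairs:
            continue
        if (m, t) in {("G", "T"), ("T", "G")}:
            # G:U wobble: miRNA G with target U, or miRNA U with target G
            penalty += 0.5 * weight
        else:
            penalty += 1.0 * weight
    return penalty
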