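"""Independent brute-force oracles used to check the implementation.

Everything here works base-by-base or by exhaustive enumeration and is
deliberately independent of the interval arithmetic in the package.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

from tfosmap.formats import Chain
from tfosmap.reciprocal_map import _chain_sort_key


def oracle_pair_table(chains: list[Chain]) -> dict:
    """Per-base greedy claim table: visit chains in the same score order
    and claim free (ref base, qry base) pairs one base at a time.

    Returns {(chromA, pos): ((chromB, pos), chain_id)}.
    """
    claimed_a: set = set()
    claimed_b: set = set()
    pairs: dict = {}
    for chain in sorted(chains, key=_chain_sort_key):
        for seg in chain.paired_segments():
            for i in range(seg.ref_end - seg.ref_start):
                a = (seg.ref_chrom, seg.ref_start + i)
                if seg.orientation == "same":
                    b = (seg.qry_chrom, seg.qry_start + i)
                else:
                    b = (seg.qry_chrom, seg.qry_end - 1 - i)
                if a in claimed_a or b in claimed_b:
                    continue
                claimed_a.add(a)
                claimed_b.add(b)
                pairs[a] = (b, chain.id)
    return pairs


def oracle_map_interval(chrom: str, start: int, end: int, pairs: dict):
    """Base-dictionary version of interval mapping with the same
    filtering rules: returns (status, target, mapped_bases) where target
    is (chrom, start, end) or None."""
    hits = [(pos, *pairs[(chrom, pos)])
            for pos in range(start, end) if (chrom, pos) in pairs]
    if not hits:
        return "UNMAPPED", None, 0
    ids = {cid for _, _, cid in hits}
    if len(ids) > 1:
        return "FILTERED_MULTI_CHAIN", None, 0
    chroms = {b[0] for _, b, _ in hits}
    if len(chroms) > 1:
        return "FILTERED_MULTI_CHROM", None, 0
    positions = [b[1] for _, b, _ in hits]
    return ("MAPPED", (chroms.pop(), min(positions), max(positions) + 1),
            len(hits))


def binom_tail_greater(n: int, k: int, p: Fraction) -> Fraction:
    """P(X >= k) for X ~ Binomial(n, p), exact rational arithmetic."""
    p = Fraction(p)
    return sum(comb(n, j) * p**j * (1 - p) ** (n - j)
               for j in range(k, n + 1))


def signed_rank_p_greater(diffs: list[float]) -> float:
    """Exact one-sided (greater) signed-rank p-value by enumerating all
    sign assignments; requires no zeros and no tied magnitudes."""
    mags = sorted(abs(d) for d in diffs)
    assert len(set(mags)) == len(mags) and all(m > 0 for m in mags)
    ranks = {m: i + 1 for i, m in enumerate(mags)}
    w_obs = sum(ranks[abs(d)] for d in diffs if d > 0)
    n = len(diffs)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, (ranks[abs(d)] for d in diffs)) if s)
        if w >= w_obs:
            count += 1
    return count / 2**n


def rank_sum_p_greater(x: list[float], y: list[float]) -> float:
    """Exact one-sided (x stochastically greater) Mann-Whitney p-value
    by enumerating group-label assignments; requires no ties."""
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(x)
    u_obs = sum(rank[v] for v in x) - n1 * (n1 + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = sum(i + 1 for i in combo) - n1 * (n1 + 1) / 2
        total += 1
        if u >= u_obs:
            count += 1
    return count / total
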