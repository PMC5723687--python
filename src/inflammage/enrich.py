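"""Gene-set enrichment: per-set Fisher's exact tests with BH-FDR, enrichment
ratios, and the overlap test against a prior gene list.

The universe defaults to all genes tested in the expression scan; the 2x2
table for a set is (hits, significant-not-in-set, set-not-significant, rest
of universe).  The enrichment ratio is observed/expected hits,
n_hit / (n_set * |sig| / |universe|).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Sequence, Set

import numpy as np
from scipy import stats


@dataclass
class EnrichmentResult:
    set_name: str
    n_set: int  # genes in set ∩ universe
    n_hit: int
    ratio: float
    p: float
    fdr: float
    hits: tuple


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     alternative: str = "two-sided") -> tuple[float, bool]:
    """Fisher's exact p for the table [[a, b], [c, d]].

    Two-sided p by the point-probability method (sum of hypergeometric
    probabilities <= that of the observed table).  A zero row or column
    margin makes the table degenerate: p = 1 with the flag set.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be nonnegative integers")
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    if degenerate:
        return 1.0, True
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative).pvalue)
    return min(p, 1.0), False


def bh_fdr(p: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j); ties keep
    their stable order.  ``m`` defaults to len(p) but may exceed it when the
    p-values are a subset of a larger family of tests.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = int(m) if m is not None else p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _uppercase(genes: Iterable[str]) -> set:
    return {str(g).upper() for g in genes}


def pathway_enrichment(
    sig_genes: Iterable[str],
    collection: Dict[str, Set[str]],
    universe: Iterable[str],
    min_set_size: int = 10,
    alternative: str = "two-sided",
) -> list[EnrichmentResult]:
    """Fisher enrichment of the significant genes in each gene set.

    Symbols are matched exactly after one uppercase pass.  Sets are
    intersected with the universe; sets with fewer than ``min_set_size``
    universe genes are not tested (and do not count toward the BH family).
    Results are sorted by p.
    """
    universe = _uppercase(universe)
    if not universe:
        raise ValueError("empty universe")
    sig = _uppercase(sig_genes) & universe
    tested = []
    for name, members in collection.items():
        mem = _uppercase(members) & universe
        if len(mem) < min_set_size:
            continue
        hit = sig & mem
        a = len(hit)
        b = len(sig) - a
        c = len(mem) - a
        d = len(universe) - len(sig) - c
        p, _ = fisher_exact_2x2(a, b, c, d, alternative=alternative)
        expected = len(mem) * len(sig) / len(universe)
        ratio = a / expected if expected > 0 else 0.0
        tested.append((name, len(mem), a, ratio, p, tuple(sorted(hit))))
    if not tested:
        return []
    q = bh_fdr([t[4] for t in tested], m=len(tested))
    out = [
        EnrichmentResult(set_name=n, n_set=ns, n_hit=nh, ratio=r, p=p, fdr=float(f), hits=h)
        for (n, ns, nh, r, p, h), f in zip(tested, q)
    ]
    out.sort(key=lambda e: (e.p, e.set_name))
    return out


def overlap_test(
    list_a: Iterable[str],
    list_b: Iterable[str],
    universe: Iterable[str],
    alternative: str = "two-sided",
) -> tuple[int, float]:
    """Fisher test of the overlap between two gene lists within a universe.

    Returns (n_overlap, p).  The 2x2 is (|a∩b|, |a\\b|, |b\\a|, rest).
    """
    universe = _uppercase(universe)
    a = _uppercase(list_a) & universe
    b = _uppercase(list_b) & universe
    n_ab = len(a & b)
    table = (n_ab, len(a) - n_ab, len(b) - n_ab, len(universe) - len(a | b))
    p, _ = fisher_exact_2x2(*table, alternative=alternative)
    return n_ab, p


def overlap_test_counts(
    n_universe: int, n_a: int, n_b: int, n_overlap: int,
    alternative: str = "two-sided",
) -> float:
    """Overlap Fisher test from published counts rather than explicit lists."""
    a = n_overlap
    b = n_a - n_overlap
    c = n_b - n_overlap
    d = n_universe - n_a - c
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent counts")
    p, _ = fisher_exact_2x2(a, b, c, d, alternative=alternative)
    return p
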