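"""Cutoff-free unweighted gene-set enrichment with an exact DP null.

Genes are sorted by the absolute median case-control methylation difference.
For a category of k genes inside a list of n, the unweighted running sum
gains (n - k) at every category hit and loses k at every miss; its maximum
prefix value RS_max measures how strongly the category concentrates at the
top of the list. Because the walk always ends at 0, RS_max is a nonnegative
integer bounded by k * (n - k).

Under the null every placement of the k hits among the n positions is
equally likely, and P(RS_max >= s) is computed exactly by counting, with a
dynamic program over (position, hits used), the arrangements whose walk
stays strictly below s everywhere. The prefix sum after i positions with h
hits equals h*n - i*k, so the stay-below constraint is a per-position cap on
h and the DP is a constrained Pascal recurrence. All counting uses exact
integer arithmetic (Python integers are arbitrary precision, so no overflow
or log-space fallback is needed at any list size); the final probability is
the ratio count / C(n, k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SortedGeneList",
    "EnrichmentResult",
    "build_sorted_list",
    "running_sum_statistic",
    "exact_pvalue_dp",
    "enrich_categories",
    "bh_adjust",
    "read_gmt",
]


@dataclass
class SortedGeneList:
    """Genes ordered by decreasing differential-methylation score.

    ``genes`` is the final order (position 1 = most differential);
    ``median_positions`` records where each gene's features sat in the
    feature-level sorted list; ``scores`` is the per-gene median feature
    score.
    """

    genes: list[str]
    median_positions: dict[str, float]
    scores: dict[str, float]

    def __len__(self) -> int:
        return len(self.genes)

    def positions_of(self, gene_set: Iterable[str]) -> set[int]:
        """1-based list positions of the genes present in ``gene_set``."""
        idx = {g: i + 1 for i, g in enumerate(self.genes)}
        return {idx[g] for g in gene_set if g in idx}


@dataclass
class EnrichmentResult:
    category: str
    k: int
    n: int
    rs_max: int
    p_exact: float
    q_bh: float = float("nan")
    empty_intersection: bool = False


def build_sorted_list(
    feature_scores: Mapping[str, float],
    feature_to_gene: Mapping[str, str],
) -> SortedGeneList:
    """Collapse feature-level scores to a sorted gene list.

    Features (array probes / methylation sites) are sorted by score
    descending (ties by feature id, for determinism). A gene represented by
    several features is placed at the median of its feature positions; the
    final gene order is by median position ascending, half-integer medians
    sorting before the integer position above them, ties broken by gene id.
    """
    feats = list(feature_scores)
    if len(set(feats)) != len(feats):  # Mapping keys are unique; guard list input
        raise ValueError("duplicate feature ids")
    missing = [f for f in feats if f not in feature_to_gene]
    if missing:
        raise ValueError(f"features without gene mapping: {missing[:5]}")
    order = sorted(feats, key=lambda f: (-feature_scores[f], f))
    positions: dict[str, list[int]] = {}
    for pos, f in enumerate(order, start=1):
        positions.setdefault(feature_to_gene[f], []).append(pos)
    med_pos = {g: float(np.median(p)) for g, p in positions.items()}
    scores = {
        g: float(np.median([feature_scores[order[p - 1]] for p in pos]))
        for g, pos in positions.items()
    }
    genes = sorted(med_pos, key=lambda g: (med_pos[g], g))
    return SortedGeneList(genes=genes, median_positions=med_pos, scores=scores)


def running_sum_statistic(n: int, hit_positions: Iterable[int]) -> int:
    """Maximum prefix sum of the +(n-k)/-k running-sum walk.

    ``hit_positions`` are 1-based positions within the sorted list. The walk
    ends at 0, so the maximum is always >= 0 ("hits-last" placements score 0
    under this one-sided, top-of-list convention).
    """
    hits = set(hit_positions)
    k = len(hits)
    if k == 0 or k > n:
        raise ValueError("need 1 <= k <= n hits")
    if any(p < 1 or p > n for p in hits):
        raise ValueError("hit positions must lie in 1..n")
    best = 0
    s = 0
    for i in range(1, n + 1):
        s += (n - k) if i in hits else -k
        if s > best:
            best = s
    return best


def _count_below(n: int, k: int, s: int) -> int:
    """Number of k-subsets of 1..n whose running-sum walk stays < s everywhere."""
    if s <= 0:
        return 0
    # dp[h] = number of prefixes of length i with h hits, all prefix sums < s.
    dp = [0] * (k + 1)
    dp[0] = 1
    for i in range(1, n + 1):
        hi = min(k, i)
        lo = max(0, k - (n - i))  # must still be able to place remaining hits
        for h in range(hi, lo - 1, -1):
            v = dp[h] + (dp[h - 1] if h > 0 else 0)
            # prefix sum h*n - i*k must stay strictly below s
            dp[h] = v if h * n - i * k < s else 0
        for h in range(lo):
            dp[h] = 0
    return dp[k]


def exact_pvalue_dp(n: int, k: int, observed: int) -> float:
    """Exact P(RS_max >= observed) under uniform placement of k hits in n slots.

    ``observed`` must lie in [0, k*(n-k)]. Counting is exact; the returned
    float is the correctly rounded ratio.
    """
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    if observed < 0:
        raise ValueError("observed RS_max cannot be negative")
    if observed > k * (n - k):
        raise ValueError("observed exceeds the maximum k*(n-k)")
    if observed == 0:
        return 1.0
    total = math.comb(n, k)
    below = _count_below(n, k, observed)
    return float(Fraction(total - below, total))


def enrich_categories(
    sorted_list: SortedGeneList,
    collection: Mapping[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """Test every category of the collection on the sorted gene list.

    Each category is reduced to its intersection with the list; the
    running-sum maximum and its exact DP p-value are computed, then all
    p-values are Benjamini-Hochberg adjusted across the collection.
    Categories with an empty intersection are reported with p = 1 and
    flagged.
    """
    n = len(sorted_list)
    results = []
    for cat in sorted(collection):
        pos = sorted_list.positions_of(collection[cat])
        if not pos:
            results.append(EnrichmentResult(cat, 0, n, 0, 1.0, empty_intersection=True))
            continue
        rs = running_sum_statistic(n, pos)
        p = exact_pvalue_dp(n, len(pos), rs)
        results.append(EnrichmentResult(cat, len(pos), n, rs, p))
    qs = bh_adjust([r.p_exact for r in results])
    for r, q in zip(results, qs):
        r.q_bh = float(q)
    return results


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: category <tab> description <tab> genes..."""
    collection: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            collection[parts[0]] = [g for g in parts[2:] if g]
    return collection


def write_gmt(collection: Mapping[str, Iterable[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for cat in collection:
            genes = "\t".join(collection[cat])
            fh.write(f"{cat}\t{description}\t{genes}\n")
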