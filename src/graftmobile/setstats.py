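"""Set-overlap analytics: Venn partitions, coverage, hypergeometric tests.

Used to compare mobile-mRNA sets across growth conditions and against
transcript lists from other phloem studies.  The universe size N of the
hypergeometric test is always an explicit parameter: for within-system
comparisons a natural choice is the number of scion reference transcripts,
while cross-system comparisons must supply their own (e.g., the number of
ortholog pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "EnrichmentResult",
    "overlap",
    "covered_percent",
    "hypergeom_pmf",
    "hypergeom_test",
    "venn_partition",
    "enrichment_table",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric overlap test between a mobile set and a reference set.

    k successes drawn in a sample of n from a universe of N containing K
    marked items.  ``p_over`` = P(X >= k), ``p_under`` = P(X <= k); the two
    share the point mass at k.  ``direction`` compares the two tails and
    ``p_value`` is their minimum.  ``covered_pct`` = 100 * k / K, half-up to
    two decimals.
    """

    k: int
    K: int
    n: int
    N: int
    p_over: float
    p_under: float
    direction: str
    covered_pct: float

    @property
    def p_value(self) -> float:
        return min(self.p_over, self.p_under)


def _as_map(ortholog_map) -> dict[str, str]:
    if ortholog_map is None:
        return {}
    if isinstance(ortholog_map, Mapping):
        return dict(ortholog_map)
    return {pair[0]: pair[1] for pair in ortholog_map}


def overlap(mobile_ids: set[str], previous_ids: set[str],
            ortholog_map=None) -> int:
    """|translated(mobile) ∩ previous|.

    ``ortholog_map`` (pairs or a mapping, mobile-side id -> reference-side
    id) translates mobile ids before intersecting; ids without an ortholog
    drop out of the comparison.
    """
    if ortholog_map is not None:
        amap = _as_map(ortholog_map)
        translated = {amap[i] for i in mobile_ids if i in amap}
    else:
        translated = set(mobile_ids)
    return len(translated & set(previous_ids))


def covered_percent(k: int, K: int) -> float:
    """100 * k / K, rounded half-up to two decimals."""
    if K <= 0:
        raise ValueError("reference set size K must be > 0")
    if k < 0 or k > K:
        raise ValueError("need 0 <= k <= K")
    pct = Decimal(100 * k) / Decimal(K)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _validate(k: int, K: int, n: int, N: int) -> None:
    if N <= 0 or K < 0 or n < 0 or k < 0:
        raise ValueError("parameters must be non-negative with N > 0")
    if K > N or n > N:
        raise ValueError("need K <= N and n <= N")
    if k > min(K, n):
        raise ValueError("need k <= min(K, n)")


def hypergeom_pmf(x: int, K: int, n: int, N: int) -> float:
    """P(X = x) for X ~ Hypergeometric(N, K, n)."""
    return float(hypergeom.pmf(x, N, K, n))


def hypergeom_test(k: int, K: int, n: int, N: int) -> EnrichmentResult:
    """Two one-sided hypergeometric tail tests of an overlap of size k."""
    _validate(k, K, n, N)
    p_over = float(hypergeom.sf(k - 1, N, K, n))
    p_under = float(hypergeom.cdf(k, N, K, n))
    p_over = min(p_over, 1.0)
    p_under = min(p_under, 1.0)
    if p_over < p_under:
        direction = "over"
    elif p_under < p_over:
        direction = "under"
    else:
        direction = "none"
    return EnrichmentResult(k=k, K=K, n=n, N=N, p_over=p_over,
                            p_under=p_under, direction=direction,
                            covered_pct=covered_percent(k, K) if K else 0.0)


def venn_partition(named_sets: dict[str, set[str]],
                   ) -> dict[tuple[str, ...], tuple[int, set[str]]]:
    """Exclusive Venn regions of 2-4 named sets.

    Returns every non-empty signature (tuple of member set names, in input
    order) mapped to (count, member ids); counts sum to the union size.
    """
    names = list(named_sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("venn_partition supports 2 to 4 sets")
    union = set().union(*named_sets.values())
    regions: dict[tuple[str, ...], set[str]] = {}
    for mask in range(1, 2 ** len(names)):
        sig = tuple(n for i, n in enumerate(names) if mask >> i & 1)
        regions[sig] = set()
    for item in union:
        sig = tuple(n for n in names if item in named_sets[n])
        regions[sig].add(item)
    return {sig: (len(ids), ids) for sig, ids in regions.items()}


def enrichment_table(mobile_ids: set[str],
                     previous_sets: dict[str, set[str]],
                     universe: int,
                     ortholog_map=None,
                     include_all_sets: bool = True) -> pd.DataFrame:
    """Per-reference-set enrichment report in the layout of the published
    comparison tables (one column per previous study plus "All Sets").

    Rows: reference set size, overlap count, covered %, direction (``N/A``
    when the overlap is empty), and the reported p-value.
    """
    columns = dict(previous_sets)
    if include_all_sets:
        columns["All Sets"] = set().union(*previous_sets.values())
    amap = _as_map(ortholog_map) if ortholog_map is not None else None
    if amap is not None:
        translated = {amap[i] for i in mobile_ids if i in amap}
    else:
        translated = set(mobile_ids)
    n = len(translated)
    out: dict[str, dict] = {}
    for name, prev in columns.items():
        k = len(translated & prev)
        res = hypergeom_test(k, len(prev), n, universe)
        out[name] = {
            "Number of mRNAs in previous studies": len(prev),
            "Number of mobile mRNAs": k,
            "Covered %": res.covered_pct,
            "Over- or under-enrichment": "N/A" if k == 0 else f"{res.direction}-",
            "P-Value (Hypergeometric test)": res.p_value,
        }
    return pd.DataFrame(out)
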