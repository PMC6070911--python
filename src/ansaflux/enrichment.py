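"""Hypergeometric enrichment of gene or reaction sets over subsystems.

For a universe of ``N`` ids of which ``M_j`` belong to subsystem ``j``, and a
query set of ``n`` ids with ``m`` of them in the subsystem, the enrichment
p-value is the upper tail ``P(X >= m)`` of ``X ~ Hypergeometric(N, M_j, n)``.
Benjamini-Hochberg adjusted p-values are reported alongside the raw ones;
the raw p drives ranking, matching how such scans are usually plotted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Set, Union

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "hypergeom_p", "enrich"]


@dataclass
class EnrichmentResult:
    subsystem: str
    N: int
    M: int
    n: int
    m: int
    p_value: float
    adjusted_p: float


def hypergeom_p(N: int, M: int, n: int, m: int) -> float:
    """Upper-tail probability ``P(X >= m)`` for ``X ~ Hypergeometric(N, M, n)``.

    Computed through scipy's survival function, which works in log-space
    internally and is stable for large counts.
    """
    for name, value in (("N", N), ("M", M), ("n", n), ("m", m)):
        if int(value) != value or value < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
    if M > N or n > N:
        raise ValueError(f"M ({M}) and n ({n}) must not exceed N ({N})")
    if m > min(M, n):
        raise ValueError(f"m ({m}) cannot exceed min(M, n) = {min(M, n)}")
    if m == 0:
        return 1.0
    return float(hypergeom.sf(m - 1, N, M, n))


def _memberships(subsystem_map: Dict[str, Union[str, Iterable[str]]], item: str) -> Set[str]:
    value = subsystem_map.get(item, "")
    if isinstance(value, str):
        return {value} if value else set()
    return {v for v in value if v}


def enrich(
    universe: Iterable[str],
    subsystem_map: Dict[str, Union[str, Iterable[str]]],
    query: Iterable[str],
) -> List[EnrichmentResult]:
    """One enrichment result per subsystem overlapping the query.

    ``subsystem_map`` maps each universe id to its subsystem label (or a
    collection of labels for ids annotated to several pathways; each counts
    once per pathway).  Ids with no label are kept in ``N`` only if labelled;
    unlabelled ids are excluded from the universe, since membership is what
    the test is about.  Results are sorted by ascending raw p-value.
    """
    universe = set(universe)
    query = set(query)
    strays = sorted(query - universe)
    if strays:
        raise ValueError(f"query ids outside the universe: {strays}")

    annotated = {u for u in universe if _memberships(subsystem_map, u)}
    query = query & annotated
    N, n = len(annotated), len(query)

    by_subsystem: Dict[str, Set[str]] = {}
    for item in annotated:
        for label in _memberships(subsystem_map, item):
            by_subsystem.setdefault(label, set()).add(item)

    results = []
    for label in sorted(by_subsystem):
        members = by_subsystem[label]
        m = len(members & query)
        if m == 0:
            continue
        results.append(
            EnrichmentResult(
                subsystem=label,
                N=N,
                M=len(members),
                n=n,
                m=m,
                p_value=hypergeom_p(N, len(members), n, m),
                adjusted_p=1.0,
            )
        )
    if results:
        _, adjusted, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, adj in zip(results, adjusted):
            r.adjusted_p = float(max(adj, r.p_value))
    results.sort(key=lambda r: (r.p_value, r.subsystem))
    return results
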