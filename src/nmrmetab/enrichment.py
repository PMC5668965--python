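"""Pathway over-representation analysis of a differential-metabolite set.

Self-contained hypergeometric ORA against a bundled (curated) pathway
annotation: for each pathway with at least one hit, the upper-tail
probability of observing that many members of the pathway in the query set
under random draws from the annotated universe.  Raw p-values are
thresholded (default p < 0.01) with no multiple-testing correction, mirroring
the usual compound-enrichment report; a Benjamini-Hochberg FDR column is
emitted alongside for reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .library import PathwayMap

__all__ = ["EnrichmentResult", "hypergeometric_p", "enrich"]


def hypergeometric_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``k`` hits in a query of size ``n`` against a pathway of size ``K``
    within a universe of ``N`` annotated metabolites.
    """
    if min(k, n, K) < 0 or n > N or K > N or k > min(n, K):
        raise ValueError(
            f"inconsistent counts k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    hits: int            # k
    query_size: int      # n (annotated query metabolites)
    pathway_size: int    # K
    universe_size: int   # N
    p_value: float
    bh_fdr: float
    passes_threshold: bool
    hit_abbreviations: tuple[str, ...] = ()


def enrich(
    significant: Iterable[str],
    pathway_map: PathwayMap,
    threshold: float = 0.01,
    universe: Iterable[str] | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric ORA of a significant-metabolite set.

    Query abbreviations outside the universe are dropped with a warning.
    One result per pathway with at least one hit, sorted by ascending p then
    pathway id; ``passes_threshold`` is raw p < ``threshold``.  The universe
    defaults to all annotated metabolites of the map and is configurable
    (e.g. the whole assignment library).
    """
    uni = set(universe) if universe is not None else set(pathway_map.universe)
    query = set(significant)
    outside = query - uni
    if outside:
        warnings.warn(
            f"{len(outside)} query metabolite(s) outside the universe "
            f"dropped: {sorted(outside)}", stacklevel=2,
        )
    query &= uni
    n, N = len(query), len(uni)
    if n == 0:
        return []
    raw: list[tuple[str, str, int, int, tuple[str, ...]]] = []
    for pid, (pname, members) in pathway_map:
        members_in = members & uni
        hits = tuple(sorted(query & members_in))
        if not hits or not members_in:
            continue
        raw.append((pid, pname, len(hits), len(members_in), hits))
    if not raw:
        return []
    pvals = [hypergeometric_p(k, n, K, N) for (_, _, k, K, _) in raw]
    fdr = multipletests(pvals, method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            pathway_id=pid, pathway_name=pname, hits=k, query_size=n,
            pathway_size=K, universe_size=N, p_value=p, bh_fdr=float(q),
            passes_threshold=bool(p < threshold), hit_abbreviations=hit_ab,
        )
        for (pid, pname, k, K, hit_ab), p, q in zip(raw, pvals, fdr)
    ]
    results.sort(key=lambda e: (e.p_value, e.pathway_id))
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    cols = ["pathway_id", "pathway_name", "hits", "pathway_size",
            "query_size", "universe_size", "p_value", "bh_fdr",
            "passes_threshold", "hit_abbreviations"]
    if not results:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([
        {
            "pathway_id": e.pathway_id,
            "pathway_name": e.pathway_name,
            "hits": e.hits,
            "pathway_size": e.pathway_size,
            "query_size": e.query_size,
            "universe_size": e.universe_size,
            "p_value": e.p_value,
            "bh_fdr": e.bh_fdr,
            "passes_threshold": e.passes_threshold,
            "hit_abbreviations": ";".join(e.hit_abbreviations),
        }
        for e in results
    ])
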