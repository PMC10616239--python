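"""Hypergeometric over-representation analysis (ORA) over GMT gene sets.

A generic stand-in for GO/KEGG enrichment: for each term, the upper-tail
hypergeometric probability of drawing at least the observed overlap between
the query and the term's members from the universe. Shares its kernel with
the ceRNA shared-miRNA test, so the two agree bit-for-bit on identical
(N, K, n, k). Raw p <= 0.05 flags enrichment; BH adjustment is available
behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from .hypergeom import hypergeom_upper_tail
from .models import GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OraResult:
    term_id: str
    term_name: str
    overlap_k: int
    set_K: int
    query_n: int
    universe_N: int
    p: float
    enriched: bool


def ora(
    query: set[str],
    collection: GeneSetCollection,
    p_threshold: float = 0.05,
    bh_adjust: bool = False,
) -> list[OraResult]:
    """Over-representation of the query in every gene set of the collection.

    Query ids outside the universe are dropped (with a logged count); an
    empty query after restriction is a hard error. Results are sorted by
    ascending p, then term id.
    """
    restricted = set(query) & collection.universe
    dropped = len(set(query)) - len(restricted)
    if dropped:
        logger.warning("dropped %d query id(s) outside the universe", dropped)
    if not restricted:
        raise ValidationError("query is empty after restriction to the universe")
    N = len(collection.universe)
    n = len(restricted)
    rows = []
    for term_id in sorted(collection.sets):
        name, members = collection.sets[term_id]
        members = frozenset(members) & collection.universe
        K = len(members)
        k = len(members & restricted)
        p = hypergeom_upper_tail(k, N, K, n)
        rows.append((term_id, name, k, K, p))
    ps = [r[4] for r in rows]
    screen_ps = list(stats.false_discovery_control(ps, method="bh")) if bh_adjust else ps
    results = [
        OraResult(
            term_id=term_id,
            term_name=name,
            overlap_k=k,
            set_K=K,
            query_n=n,
            universe_N=N,
            p=p,
            enriched=bool(sp <= p_threshold),
        )
        for (term_id, name, k, K, p), sp in zip(rows, screen_ps)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results
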