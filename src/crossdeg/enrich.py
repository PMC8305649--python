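"""Over-representation analysis (ORA) of gene lists against GMT collections.

Given a query gene list and a collection of named gene sets, each term is
scored with the one-sided hypergeometric tail probability (equivalently the
one-sided Fisher exact p of the 2x2 overlap table), corrected across terms
with the Benjamini-Hochberg step-up procedure.  The background universe
defaults to the union of all collection members and can be overridden with
a user-supplied gene list.

Only over-representation is tested (enriched terms, not depleted), and BH is
applied to terms with at least one query hit; zero-overlap terms carry p = 1
and would only dilute the ranking.  Both choices are echoed into run
manifests downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from .ingest import DataError, canonicalize_symbol

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets plus the background universe they imply.

    ``sets`` maps term_id -> (term_name, frozenset of canonical symbols).
    Unless ``universe`` was overridden it is the union of all members.
    """

    sets: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    @classmethod
    def from_sets(
        cls,
        sets: dict[str, tuple[str, frozenset[str]]],
        universe: Optional[Iterable[str]] = None,
    ) -> "GeneSetCollection":
        if universe is None:
            members: set[str] = set()
            for _, genes in sets.values():
                members |= genes
            universe = members
        return cls(sets=sets, universe=frozenset(universe))


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's overlap statistics.

    k: query hits in the set; K: set size within the universe;
    n: query size within the universe; N: universe size.
    """

    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float
    fold_enrichment: float


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line, term_id, description, then member symbols.

    Members are canonicalized with the same rule as ingest and deduplicated
    within a set.  Duplicate term ids and malformed lines are fatal.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"GMT file not found: {path}")
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            term_id, description = fields[0], fields[1]
            if term_id in sets:
                raise DataError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            members = frozenset(
                canonicalize_symbol(g) for g in fields[2:] if g.strip()
            )
            if not members:
                raise DataError(f"{path}:{lineno}: gene set {term_id!r} is empty")
            sets[term_id] = (description, members)
    if not sets:
        raise DataError(f"{path}: GMT file contains no gene sets")
    return GeneSetCollection.from_sets(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for term_id, (name, members) in collection.sets.items():
            handle.write("\t".join([term_id, name, *sorted(members)]) + "\n")


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Drawing n query genes from a universe of N containing K set members,
    this is the one-sided Fisher exact p of the 2x2 table
    (k, n-k; K-k, N-K-n+k).  k = 0 returns exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent hypergeometric counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in the input order.

    q_(i) = min_{j >= i} m * p_(j) / j over the ascending order statistics,
    clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe_override: Optional[Iterable[str]] = None,
) -> list[EnrichmentRow]:
    """Score every term with at least one query hit; sort by p then term id.

    Query symbols absent from the universe are dropped with a logged count.
    BH correction runs over all tested (k >= 1) terms.
    """
    raw_query = [canonicalize_symbol(g) for g in query]
    if universe_override is not None:
        universe = frozenset(canonicalize_symbol(g) for g in universe_override)
    else:
        universe = collection.universe
    query_set = set(raw_query) & universe
    if not query_set:
        raise DataError(
            f"no query symbols matched the universe "
            f"({len(set(raw_query))} distinct query symbols, universe size {len(universe)})"
        )
    dropped = len(set(raw_query)) - len(query_set)
    if dropped:
        logger.warning("%d query symbols absent from the universe were dropped", dropped)

    n = len(query_set)
    N = len(universe)
    if n > N:
        raise DataError("universe smaller than the query it must contain")

    tested: list[tuple[str, str, int, int]] = []
    for term_id, (name, members) in collection.sets.items():
        members_in_universe = members & universe
        k = len(query_set & members_in_universe)
        if k >= 1:
            tested.append((term_id, name, k, len(members_in_universe)))
    if not tested:
        logger.warning("query overlaps no gene set in the collection")
        return []

    ks = np.array([t[2] for t in tested])
    Ks = np.array([t[3] for t in tested])
    p = np.minimum(1.0, hypergeom.sf(ks - 1, N, Ks, n))
    q = bh_adjust(p)
    rows = [
        EnrichmentRow(
            term_id=term_id,
            term_name=name,
            k=int(k),
            K=int(K),
            n=n,
            N=N,
            p_value=float(pv),
            q_value=float(qv),
            fold_enrichment=(k / n) / (K / N),
        )
        for (term_id, name, k, K), pv, qv in zip(tested, p, q)
    ]
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


def top_terms(
    rows: Sequence[EnrichmentRow], max_fdr: float = 0.05, top_n: int = 20
) -> list[EnrichmentRow]:
    """Significant terms (q strictly below ``max_fdr``), truncated to the
    ``top_n`` smallest p-values (ties by term id)."""
    kept = [r for r in rows if r.q_value < max_fdr]
    kept.sort(key=lambda r: (r.p_value, r.term_id))
    return kept[:top_n]


def rows_to_records(rows: Sequence[EnrichmentRow]) -> list[dict]:
    """Flat dict form for TSV export."""
    return [
        {
            "term_id": r.term_id,
            "term_name": r.term_name,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "fold_enrichment": r.fold_enrichment,
            "p_value": r.p_value,
            "q_value": r.q_value,
        }
        for r in rows
    ]


def bubble_table(rows: Sequence[EnrichmentRow]) -> list[dict]:
    """Bubble-chart-ready table: term, -log10 q, gene ratio k/n, k."""
    return [
        {
            "term": f"{r.term_id} {r.term_name}".strip(),
            "neg_log10_q": float(-np.log10(max(r.q_value, 1e-300))),
            "gene_ratio": r.k / r.n,
            "k": r.k,
        }
        for r in rows
    ]
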