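"""Organ-level gene-set grouping and exact multi-set Venn partitioning.

Studies of the same organ (three cerebral models here) have their DEG lists
united into one organ set; the resulting 2-6 sets are partitioned into the
2^k - 1 exclusive membership signatures of a Venn diagram, from which the
cross-organ core (genes present in every organ) is read off.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .ingest import ORGANS, DataError, StudyCall, StudyMeta


@dataclass(frozen=True)
class OrganSetMap:
    """Per-organ symbol sets and the studies that contributed to each."""

    sets: dict[str, frozenset[str]]
    provenance: dict[str, tuple[str, ...]]


@dataclass(frozen=True)
class VennPartition:
    """Exclusive membership signatures over the organ sets.

    ``memberships`` maps each non-empty subset of organs (a tuple in
    canonical organ order) to the sorted genes found in exactly those
    organs; empty signatures are present with an empty list.
    """

    organs: tuple[str, ...]
    memberships: dict[tuple[str, ...], tuple[str, ...]]

    @property
    def counts(self) -> dict[tuple[str, ...], int]:
        return {sig: len(genes) for sig, genes in self.memberships.items()}


def _directional_element(symbol: str, direction: int) -> str:
    return f"{symbol}/up" if direction > 0 else f"{symbol}/down"


def build_organ_sets(
    calls: Sequence[StudyCall],
    metadata: Sequence[StudyMeta],
    directional: bool = False,
) -> OrganSetMap:
    """Union each organ's study call lists into one symbol set per organ.

    With ``directional=True`` the up- and down-regulated variants of a gene
    are distinct elements (``SYM/up`` vs ``SYM/down``); the default mirrors
    plain undirected symbol sets, where a gene up in one organ and down in
    another still co-occurs.
    """
    organ_of = {m.study_id: m.organ for m in metadata}
    sets: dict[str, set[str]] = {m.organ: set() for m in metadata}
    prov: dict[str, set[str]] = {m.organ: set() for m in metadata}
    for call in calls:
        organ = organ_of.get(call.study_id)
        if organ is None:
            raise DataError(f"call from study {call.study_id!r} absent from metadata")
        element = (
            _directional_element(call.canonical_symbol, call.direction)
            if directional
            else call.canonical_symbol
        )
        sets[organ].add(element)
        prov[organ].add(call.study_id)
    return OrganSetMap(
        sets={o: frozenset(s) for o, s in sets.items()},
        provenance={o: tuple(sorted(p)) for o, p in prov.items()},
    )


def _canonical_organ_order(organs: Sequence[str]) -> tuple[str, ...]:
    known = [o for o in ORGANS if o in organs]
    extra = sorted(o for o in organs if o not in ORGANS)
    return tuple(known + extra)


def venn_partition(organ_sets: OrganSetMap) -> VennPartition:
    """Assign every gene in the union to its exact combination of organs."""
    organs = _canonical_organ_order(list(organ_sets.sets))
    if not 2 <= len(organs) <= 6:
        raise DataError(f"Venn partition needs 2-6 organ sets, got {len(organs)}")
    buckets: dict[tuple[str, ...], list[str]] = {
        sig: []
        for r in range(1, len(organs) + 1)
        for sig in combinations(organs, r)
    }
    union = set().union(*organ_sets.sets.values())
    for gene in union:
        sig = tuple(o for o in organs if gene in organ_sets.sets[o])
        buckets[sig].append(gene)
    return VennPartition(
        organs=organs,
        memberships={sig: tuple(sorted(genes)) for sig, genes in buckets.items()},
    )


def core_intersection(partition: VennPartition) -> list[str]:
    """Genes present in every organ set (the all-organs signature), sorted."""
    if len(partition.organs) < 2:
        raise DataError("core intersection needs a partition over >= 2 organs")
    return list(partition.memberships[partition.organs])


def partition_to_records(partition: VennPartition) -> list[dict]:
    """Tabular form: signature (semicolon-joined organs), count, genes."""
    return [
        {
            "signature": ";".join(sig),
            "count": len(genes),
            "genes": ",".join(genes),
        }
        for sig, genes in sorted(
            partition.memberships.items(), key=lambda kv: (len(kv[0]), kv[0])
        )
    ]
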