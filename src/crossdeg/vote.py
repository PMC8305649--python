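"""Cross-study vote counting with directional-consistency filtering.

Every study contributes at most one direction call per gene; a gene's
"score" is the number of studies reporting it.  Genes are kept only when at
least a threshold fraction of their reports (default 75%) agree on
direction, then split into up- and down-regulated lists.  Genes reported by
at least ``min_reports`` studies (default 4) form the commonly-reported
signature; the full ranking by report count gives the highly-reported list.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .ingest import DataError, StudyCall

CONSISTENT = "consistent"
INCONSISTENT = "inconsistent"


@dataclass(frozen=True)
class VoteRecord:
    """Per-gene cross-study tally."""

    canonical_symbol: str
    n_reports: int
    n_up: int
    n_down: int
    consistency: float  # max(n_up, n_down) / n_reports
    consensus_direction: Optional[int] = None  # +1, -1, or None
    status: Optional[str] = None  # CONSISTENT / INCONSISTENT once filtered


@dataclass(frozen=True)
class SignatureLists:
    """Ordered up/down gene lists with the thresholds that produced them."""

    up: tuple[str, ...]
    down: tuple[str, ...]
    min_reports_used: int
    min_consistency_used: float


def tally_votes(calls: Sequence[StudyCall]) -> list[VoteRecord]:
    """Tally one VoteRecord per distinct symbol across collapsed study calls.

    Raises if any (study, symbol) pair occurs twice — that means the
    per-study collapse contract was violated upstream.
    """
    seen: set[tuple[str, str]] = set()
    counts: dict[str, list[int]] = {}
    for call in calls:
        key = (call.study_id, call.canonical_symbol)
        if key in seen:
            raise DataError(f"duplicate call for {key}: input not collapsed per study")
        seen.add(key)
        up_down = counts.setdefault(call.canonical_symbol, [0, 0])
        if call.direction > 0:
            up_down[0] += 1
        else:
            up_down[1] += 1
    records = []
    for symbol in sorted(counts):
        n_up, n_down = counts[symbol]
        n = n_up + n_down
        records.append(
            VoteRecord(
                canonical_symbol=symbol,
                n_reports=n,
                n_up=n_up,
                n_down=n_down,
                consistency=max(n_up, n_down) / n,
            )
        )
    return records


def apply_consistency_filter(
    votes: Sequence[VoteRecord], min_consistency: float = 0.75
) -> list[VoteRecord]:
    """Set status and consensus direction on every record.

    A gene is consistent when at least ``min_consistency`` of its reports
    agree on direction (inclusive threshold: 3 up of 4 reports passes at the
    default 0.75).  Exact 50/50 splits are always inconsistent; inconsistent
    genes get no consensus direction.
    """
    if not 0.5 < min_consistency <= 1.0:
        raise ValueError(f"min_consistency must be in (0.5, 1], got {min_consistency}")
    out = []
    for v in votes:
        consistent = v.consistency >= min_consistency and v.n_up != v.n_down
        out.append(
            replace(
                v,
                status=CONSISTENT if consistent else INCONSISTENT,
                consensus_direction=(1 if v.n_up > v.n_down else -1) if consistent else None,
            )
        )
    return out


def _consistent_only(votes: Sequence[VoteRecord]) -> list[VoteRecord]:
    if any(v.status is None for v in votes):
        raise ValueError("votes must pass through apply_consistency_filter first")
    return [v for v in votes if v.status == CONSISTENT]


def select_commonly_reported(
    votes: Sequence[VoteRecord],
    min_reports: int = 4,
    n_studies: Optional[int] = None,
    min_consistency: float = 0.75,
) -> SignatureLists:
    """Select the commonly-reported signature: consistent genes with at least
    ``min_reports`` reports, split by consensus direction.

    ``min_consistency`` only echoes the threshold already applied by
    :func:`apply_consistency_filter` into the result's provenance fields.
    Lists are ordered by descending report count, ties by ascending symbol.
    """
    if min_reports < 1:
        raise ValueError(f"min_reports must be >= 1, got {min_reports}")
    if n_studies is not None and min_reports > n_studies:
        raise ValueError(
            f"min_reports={min_reports} exceeds the number of studies ({n_studies})"
        )
    kept = [v for v in _consistent_only(votes) if v.n_reports >= min_reports]
    kept.sort(key=lambda v: (-v.n_reports, v.canonical_symbol))
    return SignatureLists(
        up=tuple(v.canonical_symbol for v in kept if v.consensus_direction == 1),
        down=tuple(v.canonical_symbol for v in kept if v.consensus_direction == -1),
        min_reports_used=min_reports,
        min_consistency_used=min_consistency,
    )


def rank_highly_reported(
    votes: Sequence[VoteRecord], top_k: Optional[int] = None
) -> SignatureLists:
    """Rank consistent genes by report count; truncate per direction if asked.

    Ties on report count break by descending consistency, then ascending
    symbol, so output order is fully deterministic.
    """
    ranked = sorted(
        _consistent_only(votes),
        key=lambda v: (-v.n_reports, -v.consistency, v.canonical_symbol),
    )
    up = [v.canonical_symbol for v in ranked if v.consensus_direction == 1]
    down = [v.canonical_symbol for v in ranked if v.consensus_direction == -1]
    if top_k is not None:
        up, down = up[:top_k], down[:top_k]
    return SignatureLists(
        up=tuple(up), down=tuple(down), min_reports_used=1, min_consistency_used=0.0
    )


def votes_to_rows(votes: Sequence[VoteRecord]) -> list[dict]:
    """Tabular form of the votes for TSV export."""
    return [
        {
            "symbol": v.canonical_symbol,
            "n_reports": v.n_reports,
            "n_up": v.n_up,
            "n_down": v.n_down,
            "consistency": v.consistency,
            "consensus": {1: "up", -1: "down", None: "none"}[v.consensus_direction],
            "status": v.status or "unfiltered",
        }
        for v in votes
    ]
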