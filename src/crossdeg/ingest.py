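"""Reading, validation and per-study collapsing of DEG report tables.

Each source study contributes a delimited table of differentially expressed
genes (one row per reported gene: symbol, direction or signed log2
fold-change, adjusted p-value).  This module turns those raw tables into at
most one direction call per gene per study, the unit later tallied across
studies.

Gene symbols are harmonized across species by case-folded string identity
("Icam1" in mouse and "ICAM1" in human collide on "ICAM1"); no ortholog
database is consulted, but a user-supplied synonym map may be applied after
case folding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The five organ systems an included study may model, in canonical order.
ORGANS = ("spinal_cord", "cerebral", "hepatic", "renal", "myocardial")

#: Accepted spellings in a textual direction column.
_DIRECTION_CODES = {
    "up": 1, "upregulated": 1, "+": 1, "+1": 1, "1": 1,
    "down": -1, "downregulated": -1, "-": -1, "-1": -1,
}


class DataError(ValueError):
    """Fatal problem with input data (missing columns, unparseable tables)."""


@dataclass(frozen=True)
class StudyMeta:
    """One row of the study-metadata table."""

    study_id: str
    organ: str
    species: str
    timepoint_label: str
    in_crossref: bool

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise DataError(
                f"study {self.study_id!r}: organ {self.organ!r} not one of {ORGANS}"
            )


@dataclass(frozen=True)
class DEGRecord:
    """One gene report from one study, as extracted from its DEG table."""

    study_id: str
    raw_symbol: str
    canonical_symbol: str
    direction: int  # +1 or -1
    log2fc: Optional[float]
    adj_p: float


@dataclass(frozen=True)
class StudyCall:
    """The single direction call a study contributes for one gene."""

    study_id: str
    canonical_symbol: str
    direction: int
    best_adj_p: float


@dataclass
class IngestReport:
    """Row-accounting for one study's ingest; counts reconcile exactly.

    ``rows_read`` equals kept records plus the two dropped categories;
    ``duplicate_symbols_collapsed`` is bookkeeping for the later
    per-study collapse and is not part of that sum.
    """

    rows_read: int = 0
    rows_dropped_nonsignificant: int = 0
    rows_dropped_malformed: int = 0
    duplicate_symbols_collapsed: int = 0
    messages: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "rows_read": self.rows_read,
            "rows_dropped_nonsignificant": self.rows_dropped_nonsignificant,
            "rows_dropped_malformed": self.rows_dropped_malformed,
            "duplicate_symbols_collapsed": self.duplicate_symbols_collapsed,
        }


def canonicalize_symbol(
    raw_symbol: str, synonym_map: Optional[Mapping[str, str]] = None
) -> str:
    """Map a printed gene symbol to its cross-study matching key.

    Deterministic: strip surrounding whitespace, upper-case, then apply the
    optional synonym map (whose keys/values are themselves case-folded).
    Mouse/rat title case and human upper case of the same symbol collide.
    """
    key = raw_symbol.strip().upper()
    if not key:
        raise DataError("empty gene symbol after trimming")
    if synonym_map is not None:
        key = synonym_map.get(key, key)
    return key


def _parse_direction(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    code = str(value).strip().lower()
    return _DIRECTION_CODES.get(code)


def read_deg_table(
    path: str | Path,
    column_map: Mapping[str, str],
    study_id: str,
    synonym_map: Optional[Mapping[str, str]] = None,
) -> tuple[list[DEGRecord], IngestReport]:
    """Read one study's DEG table into validated records.

    Parameters
    ----------
    path
        Delimited text file; delimiter chosen by extension (``.tsv`` tab,
        ``.csv`` comma).  A header row is required.
    column_map
        Maps logical names (``symbol``, ``adj_p`` and at least one of
        ``direction`` / ``log2fc``) to the table's actual column names.
    study_id
        Stamped onto every returned record.

    Malformed rows (empty symbol, unparseable numbers, zero log2fc with no
    direction column, direction/log2fc sign conflict) are counted, logged and
    skipped — never silently coerced.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"DEG table not found: {path}")
    if "symbol" not in column_map or "adj_p" not in column_map:
        missing = {"symbol", "adj_p"} - set(column_map)
        raise DataError(f"column_map missing mandatory logical columns: {sorted(missing)}")
    if "direction" not in column_map and "log2fc" not in column_map:
        raise DataError("column_map must name a 'direction' or a 'log2fc' column")

    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")
    for logical, actual in column_map.items():
        if actual not in frame.columns:
            raise DataError(f"{path}: missing column {actual!r} (mapped from {logical!r})")

    report = IngestReport(rows_read=len(frame))
    records: list[DEGRecord] = []
    has_dir = "direction" in column_map
    has_fc = "log2fc" in column_map

    for idx, row in frame.iterrows():
        reason = None
        symbol = row[column_map["symbol"]]
        symbol = "" if symbol is None or (isinstance(symbol, float) and math.isnan(symbol)) else str(symbol)
        log2fc: Optional[float] = None
        direction: Optional[int] = None
        try:
            canonical = canonicalize_symbol(symbol, synonym_map)
        except DataError:
            canonical, reason = None, "empty symbol"
        if reason is None:
            try:
                adj_p = float(row[column_map["adj_p"]])
            except (TypeError, ValueError):
                adj_p, reason = None, "unparseable adjusted p-value"
            else:
                if math.isnan(adj_p) or not 0.0 <= adj_p <= 1.0:
                    reason = "adjusted p-value outside [0, 1]"
        if reason is None and has_fc:
            raw_fc = row[column_map["log2fc"]]
            try:
                log2fc = float(raw_fc)
            except (TypeError, ValueError):
                reason = "unparseable log2 fold-change"
            else:
                if math.isnan(log2fc):
                    reason = "unparseable log2 fold-change"
        if reason is None:
            # Explicit direction column wins; its conflict with sign(log2fc)
            # marks the row malformed rather than trusting either source.
            if has_dir:
                direction = _parse_direction(row[column_map["direction"]])
                if direction is None:
                    reason = "unrecognized direction code"
                elif log2fc is not None and log2fc != 0 and direction != _sign(log2fc):
                    reason = "direction column conflicts with sign of log2fc"
            else:
                if log2fc == 0:
                    reason = "log2fc is zero: no direction derivable"
                else:
                    direction = _sign(log2fc)
        if reason is not None:
            report.rows_dropped_malformed += 1
            msg = f"{path.name} row {idx}: dropped malformed row ({reason})"
            report.messages.append(msg)
            logger.warning(msg)
            continue
        records.append(
            DEGRecord(
                study_id=study_id,
                raw_symbol=symbol.strip(),
                canonical_symbol=canonical,
                direction=direction,
                log2fc=log2fc,
                adj_p=adj_p,
            )
        )

    if not records:
        raise DataError(f"{path}: zero parseable rows")
    return records, report


def _sign(x: float) -> int:
    return 1 if x > 0 else -1


def filter_significant(
    records: Sequence[DEGRecord], alpha: float = 0.05
) -> list[DEGRecord]:
    """Keep records with adjusted p strictly below ``alpha``; order preserved."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return [r for r in records if r.adj_p < alpha]


def collapse_study(records: Sequence[DEGRecord]) -> list[StudyCall]:
    """Collapse one study's records to a single call per gene.

    A study contributes at most one report per gene to the cross-study tally,
    so multi-timepoint duplicates are reduced to the record with the smallest
    adjusted p-value; ties on adjusted p break toward the larger \\|log2fc\\|,
    then toward up-regulation.  Calls are returned sorted by symbol.
    """
    study_ids = {r.study_id for r in records}
    if len(study_ids) > 1:
        raise DataError(f"collapse_study got records from multiple studies: {sorted(study_ids)}")

    best: dict[str, DEGRecord] = {}
    for rec in records:
        cur = best.get(rec.canonical_symbol)
        if cur is None or _collapse_key(rec) < _collapse_key(cur):
            best[rec.canonical_symbol] = rec
    return [
        StudyCall(r.study_id, sym, r.direction, r.adj_p)
        for sym, r in sorted(best.items())
    ]


def _collapse_key(rec: DEGRecord) -> tuple:
    magnitude = abs(rec.log2fc) if rec.log2fc is not None else 0.0
    return (rec.adj_p, -magnitude, -rec.direction)


def ingest_study(
    path: str | Path,
    column_map: Mapping[str, str],
    study_id: str,
    alpha: float = 0.05,
    synonym_map: Optional[Mapping[str, str]] = None,
) -> tuple[list[StudyCall], IngestReport]:
    """Read, significance-filter and collapse one study's table in one step."""
    records, report = read_deg_table(path, column_map, study_id, synonym_map)
    kept = filter_significant(records, alpha)
    report.rows_dropped_nonsignificant = len(records) - len(kept)
    calls = collapse_study(kept) if kept else []
    report.duplicate_symbols_collapsed = len(kept) - len(calls)
    return calls, report


def read_metadata(path: str | Path) -> list[StudyMeta]:
    """Read the study-metadata TSV.

    Required columns: study_id, organ, species, timepoint_label, in_crossref.
    Study ids must be unique; organs must be one of the five modeled systems.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"metadata table not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    required = ["study_id", "organ", "species", "timepoint_label", "in_crossref"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DataError(f"{path}: metadata missing columns {missing}")
    metas = []
    for _, row in frame.iterrows():
        metas.append(
            StudyMeta(
                study_id=str(row["study_id"]),
                organ=str(row["organ"]),
                species=str(row["species"]),
                timepoint_label=str(row["timepoint_label"]),
                in_crossref=str(row["in_crossref"]).strip().lower()
                in {"1", "true", "yes", "y"},
            )
        )
    ids = [m.study_id for m in metas]
    if len(set(ids)) != len(ids):
        raise DataError(f"{path}: duplicate study_id values")
    return metas


def calls_to_frame(calls: Sequence[StudyCall]) -> pd.DataFrame:
    """Normalized study-call table (study_id, symbol, direction, best_adj_p)."""
    return pd.DataFrame(
        [(c.study_id, c.canonical_symbol, c.direction, c.best_adj_p) for c in calls],
        columns=["study_id", "symbol", "direction", "best_adj_p"],
    )


def calls_from_frame(frame: pd.DataFrame) -> list[StudyCall]:
    return [
        StudyCall(str(r.study_id), str(r.symbol), int(r.direction), float(r.best_adj_p))
        for r in frame.itertuples(index=False)
    ]
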