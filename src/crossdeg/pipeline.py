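"""Full-pipeline orchestration: ingest -> vote tally -> enrichment -> Venn.

A single :class:`RunConfig` (loadable from YAML) drives the stages and
every threshold is echoed, together with input hashes and the package
version, into a deterministic run-manifest JSON.  All dropped rows and
unmatched symbols are logged at WARN level, never silent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .enrich import bubble_table, read_gmt, rows_to_records, run_ora, top_terms
from .ingest import (
    DataError,
    calls_to_frame,
    ingest_study,
    read_metadata,
)
from .setops import (
    build_organ_sets,
    core_intersection,
    partition_to_records,
    venn_partition,
)
from .simulate import DEFAULT_COLUMN_MAP
from .vote import (
    apply_consistency_filter,
    select_commonly_reported,
    tally_votes,
    votes_to_rows,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; defaults carry the standard
    thresholds (adjusted p < 0.05, 75% directional consistency, >= 4
    reports, FDR < 0.05, top 20 terms)."""

    metadata: str
    deg_tables: dict  # study_id -> path, or -> {"path": ..., "column_map": {...}}
    outdir: str
    alpha: float = 0.05
    min_consistency: float = 0.75
    min_reports: int = 4
    gmt_collections: dict = field(default_factory=dict)  # name -> GMT path
    universe: Optional[str] = None  # optional background gene list file
    max_fdr: float = 0.05
    top_n: int = 20
    venn_studies: Optional[list] = None  # default: all studies with tables
    directional_venn: bool = False
    figures: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle)
        if not isinstance(raw, dict):
            raise DataError(f"{path}: config must be a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise DataError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise DataError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.5 < self.min_consistency <= 1.0:
            raise DataError(
                f"min_consistency must be in (0.5, 1], got {self.min_consistency}"
            )
        if self.min_reports < 1:
            raise DataError(f"min_reports must be >= 1, got {self.min_reports}")
        if not Path(self.metadata).exists():
            raise DataError(f"metadata table not found: {self.metadata}")
        for sid, entry in self.deg_tables.items():
            path = entry["path"] if isinstance(entry, dict) else entry
            if not Path(path).exists():
                raise DataError(f"DEG table for study {sid!r} not found: {path}")
        for name, path in self.gmt_collections.items():
            if not Path(path).exists():
                raise DataError(f"GMT collection {name!r} not found: {path}")


def _table_spec(entry) -> tuple[str, dict]:
    if isinstance(entry, dict):
        return entry["path"], entry.get("column_map", DEFAULT_COLUMN_MAP)
    return entry, DEFAULT_COLUMN_MAP


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_gene_list(genes, path: Path) -> None:
    path.write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")


def _bubble_chart(rows, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = bubble_table(rows)
    if not table:
        return
    fig, ax = plt.subplots(figsize=(7, max(2, 0.3 * len(table))))
    y = range(len(table))
    sizes = [20 + 15 * row["k"] for row in table]
    colors = [row["neg_log10_q"] for row in table]
    sc = ax.scatter([row["gene_ratio"] for row in table], list(y), s=sizes, c=colors)
    ax.set_yticks(list(y))
    ax.set_yticklabels([row["term"] for row in table], fontsize=7)
    ax.invert_yaxis()
    ax.set_xlabel("gene ratio (k/n)")
    ax.set_title(title)
    fig.colorbar(sc, ax=ax, label="-log10 q")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the output bundle.

    Returns a dict with in-memory results (``votes``, ``signature``,
    ``enrichment``, ``partition``, ``core``, ``manifest``) alongside the
    files written under ``config.outdir``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    metadata = read_metadata(config.metadata)
    meta_ids = {m.study_id for m in metadata}
    unknown = set(config.deg_tables) - meta_ids
    if unknown:
        raise DataError(f"DEG tables for studies absent from metadata: {sorted(unknown)}")

    n_crossref = sum(
        1 for m in metadata if m.in_crossref and m.study_id in config.deg_tables
    )
    if config.min_reports > n_crossref:
        raise DataError(
            f"min_reports={config.min_reports} exceeds the "
            f"{n_crossref} cross-referenced studies with tables"
        )

    # --- ingest ---------------------------------------------------------
    calls_by_study = {}
    reports = {}
    for sid in sorted(config.deg_tables):
        path, column_map = _table_spec(config.deg_tables[sid])
        calls, report = ingest_study(path, column_map, sid, alpha=config.alpha)
        calls_by_study[sid] = calls
        reports[sid] = report.as_dict()
        logger.info(
            "ingested %s: %d calls (%d rows read)", sid, len(calls), report.rows_read
        )
    all_calls = [c for sid in sorted(calls_by_study) for c in calls_by_study[sid]]
    calls_frame = calls_to_frame(all_calls)
    calls_frame.to_csv(outdir / "study_calls.tsv", sep="\t", index=False)
    (outdir / "ingest_report.json").write_text(
        json.dumps(reports, indent=1, sort_keys=True), encoding="utf-8"
    )

    # --- vote counting --------------------------------------------------
    crossref_ids = {
        m.study_id
        for m in metadata
        if m.in_crossref and m.study_id in calls_by_study
    }
    crossref_calls = [c for c in all_calls if c.study_id in crossref_ids]
    votes = apply_consistency_filter(
        tally_votes(crossref_calls), config.min_consistency
    )
    pd.DataFrame(votes_to_rows(votes)).to_csv(outdir / "votes.tsv", sep="\t", index=False)
    signature = select_commonly_reported(
        votes,
        min_reports=config.min_reports,
        n_studies=len(crossref_ids),
        min_consistency=config.min_consistency,
    )
    _write_gene_list(signature.up, outdir / "commonly_reported_up.txt")
    _write_gene_list(signature.down, outdir / "commonly_reported_down.txt")

    # --- enrichment -----------------------------------------------------
    universe_override = None
    if config.universe:
        universe_override = [
            line.strip()
            for line in Path(config.universe).read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]
    enrichment = {}
    for name, gmt_path in sorted(config.gmt_collections.items()):
        collection = read_gmt(gmt_path)
        for direction, genes in (("up", signature.up), ("down", signature.down)):
            key = f"{name}_{direction}"
            if not genes:
                logger.warning("empty %s-regulated list: skipping enrichment %s", direction, name)
                enrichment[key] = []
                continue
            rows = run_ora(genes, collection, universe_override=universe_override)
            selected = top_terms(rows, max_fdr=config.max_fdr, top_n=config.top_n)
            enrichment[key] = selected
            pd.DataFrame(rows_to_records(rows)).to_csv(
                outdir / f"enrichment_{key}.tsv", sep="\t", index=False
            )
            pd.DataFrame(bubble_table(selected)).to_csv(
                outdir / f"bubble_{key}.tsv", sep="\t", index=False
            )
            if config.figures:
                _bubble_chart(selected, outdir / f"bubble_{key}.png", key)

    # --- organ set operations ------------------------------------------
    venn_ids = (
        set(config.venn_studies) if config.venn_studies else set(calls_by_study)
    )
    missing = venn_ids - set(calls_by_study)
    if missing:
        raise DataError(f"venn_studies without DEG tables: {sorted(missing)}")
    venn_calls = [c for c in all_calls if c.study_id in venn_ids]
    venn_meta = [m for m in metadata if m.study_id in venn_ids]
    organ_sets = build_organ_sets(venn_calls, venn_meta, directional=config.directional_venn)
    partition = venn_partition(organ_sets)
    core = core_intersection(partition)
    pd.DataFrame(partition_to_records(partition)).to_csv(
        outdir / "venn_partition.tsv", sep="\t", index=False
    )
    _write_gene_list(core, outdir / "core_intersection.txt")

    # --- manifest -------------------------------------------------------
    manifest = {
        "tool": "crossdeg",
        "version": __version__,
        "seed": config.seed,
        "prng": "numpy default_rng (PCG64)",
        "thresholds": {
            "alpha": config.alpha,
            "min_consistency": config.min_consistency,
            "min_reports": config.min_reports,
            "max_fdr": config.max_fdr,
            "top_n": config.top_n,
        },
        "decisions": {
            "significance_inequality": "strict (adj_p < alpha)",
            "within_study_collapse": "minimum adjusted p per gene",
            "symbol_matching": "case-folded string identity",
            "bh_scope": "terms with k >= 1 only",
            "universe": "user-supplied" if config.universe else "union of collection members",
            "venn_mode": "directional" if config.directional_venn else "undirected symbols",
        },
        "inputs": {
            "metadata": _sha256(config.metadata),
            "deg_tables": {
                sid: _sha256(_table_spec(entry)[0])
                for sid, entry in sorted(config.deg_tables.items())
            },
            "gmt_collections": {
                name: _sha256(path)
                for name, path in sorted(config.gmt_collections.items())
            },
        },
        "venn_studies": sorted(venn_ids),
        "crossref_studies": sorted(crossref_ids),
        "counts": {
            "study_calls": len(all_calls),
            "genes_tallied": len(votes),
            "commonly_reported_up": len(signature.up),
            "commonly_reported_down": len(signature.down),
            "core_intersection": len(core),
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )
    return {
        "votes": votes,
        "signature": signature,
        "enrichment": enrichment,
        "partition": partition,
        "core": core,
        "manifest": manifest,
        "outdir": str(outdir),
    }
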