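"""Synthetic study corpora with known ground truth.

The generator emulates the structure of an acute ischemia-reperfusion DEG
literature corpus: seven studies over five organs (three cerebral, one for
each of spinal cord, liver, kidney, heart), a planted pan-organ signature
reported by most studies with consistent direction, organ-specific DEGs,
direction-flip noise, per-study dropout, and sporadic background genes
significant in only 1-3 studies.  The unit of simulation is the DEG report
(symbol, signed fold-change, adjusted p), not read counts — matching the
unit of the downstream vote-counting analysis.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
instance, so a fixed seed yields byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .enrich import GeneSetCollection
from .ingest import ORGANS, DataError, StudyCall, StudyMeta
from .vote import SignatureLists

#: Logical -> actual column names of the tables this generator writes.
DEFAULT_COLUMN_MAP = {"symbol": "gene_symbol", "log2fc": "log2fc", "adj_p": "adj_p"}

ROLE_SIGNATURE_UP = "signature_up"
ROLE_SIGNATURE_DOWN = "signature_down"
ROLE_BACKGROUND = "background"
ROLE_CONTAMINANT = "contaminant"


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults mirror the seven-study, five-organ
    corpus design with a 38-up / 20-down planted pan-organ signature."""

    n_studies_per_organ: dict = field(
        default_factory=lambda: {
            "spinal_cord": 1, "cerebral": 3, "hepatic": 1, "renal": 1, "myocardial": 1,
        }
    )
    n_signature_up: int = 38
    n_signature_down: int = 20
    report_prob: float = 0.8
    flip_prob: float = 0.1
    n_organ_specific: int = 30
    n_background: int = 150
    adj_p_low: float = 1e-6
    adj_p_high: float = 0.049
    n_contaminant_rows_per_study: int = 0  # rows with adj_p >= 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.report_prob, self.flip_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probabilities must lie in [0, 1], got {p}")
        for c in (
            self.n_signature_up, self.n_signature_down,
            self.n_organ_specific, self.n_background,
            self.n_contaminant_rows_per_study,
        ):
            if c < 0:
                raise ValueError("gene counts must be nonnegative")
        if sum(self.n_studies_per_organ.values()) < 1:
            raise DataError("corpus needs at least one study")
        for organ in self.n_studies_per_organ:
            if organ not in ORGANS:
                raise DataError(f"unknown organ {organ!r}")

    @property
    def n_studies(self) -> int:
        return sum(self.n_studies_per_organ.values())


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated corpus.

    ``roles`` maps gene -> role; for planted signature genes ``true_direction``
    carries the planted sign.  ``emissions`` records every emitted (gene,
    study) report exactly once as (direction, adj_p).
    """

    roles: dict[str, str]
    true_direction: dict[str, int]
    emissions: dict[tuple[str, str], tuple[int, float]]
    config: SimulationConfig

    @property
    def signature_up(self) -> list[str]:
        return sorted(g for g, r in self.roles.items() if r == ROLE_SIGNATURE_UP)

    @property
    def signature_down(self) -> list[str]:
        return sorted(g for g, r in self.roles.items() if r == ROLE_SIGNATURE_DOWN)


@dataclass
class SimulatedCorpus:
    tables: dict[str, pd.DataFrame]  # study_id -> DEG table
    metadata: list[StudyMeta]
    truth: SyntheticTruth


@dataclass(frozen=True)
class RecoveryScore:
    """Planted-signature recovery, per direction.

    An empty recovered list leaves precision undefined; it is reported as
    1.0 by convention with the corresponding ``*_precision_defined`` flag
    cleared.
    """

    up_recall: float
    up_precision: float
    up_precision_defined: bool
    down_recall: float
    down_precision: float
    down_precision_defined: bool


def _study_ids(config: SimulationConfig) -> list[tuple[str, str]]:
    out = []
    for organ in ORGANS:
        for i in range(config.n_studies_per_organ.get(organ, 0)):
            out.append((f"{organ}_{i + 1}", organ))
    return out


def simulate_corpus(
    config: Optional[SimulationConfig] = None, seed: Optional[int] = None
) -> SimulatedCorpus:
    """Draw one corpus: per-study DEG tables, study metadata, ground truth.

    Signature genes are reported by each study independently with
    ``report_prob`` and flipped with ``flip_prob``; organ-specific genes
    appear only in their organ's studies; background genes land in exactly
    1-3 random studies with random directions.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    studies = _study_ids(config)
    if not studies:
        raise DataError("configuration yields zero studies")

    roles: dict[str, str] = {}
    true_dir: dict[str, int] = {}
    genes: list[tuple[str, int, list[str]]] = []  # (gene, true direction, eligible studies)
    all_ids = [sid for sid, _ in studies]

    for i in range(config.n_signature_up):
        g = f"SIGU{i:04d}"
        roles[g], true_dir[g] = ROLE_SIGNATURE_UP, 1
        genes.append((g, 1, all_ids))
    for i in range(config.n_signature_down):
        g = f"SIGD{i:04d}"
        roles[g], true_dir[g] = ROLE_SIGNATURE_DOWN, -1
        genes.append((g, -1, all_ids))
    for organ in ORGANS:
        organ_ids = [sid for sid, o in studies if o == organ]
        if not organ_ids:
            continue
        for i in range(config.n_organ_specific):
            g = f"ORG_{organ.upper()}_{i:04d}"
            roles[g] = f"organ_specific({organ})"
            d = int(rng.choice([1, -1]))
            true_dir[g] = d
            genes.append((g, d, organ_ids))

    rows: dict[str, list[tuple[str, float, float]]] = {sid: [] for sid, _ in studies}
    emissions: dict[tuple[str, str], tuple[int, float]] = {}

    def emit(gene: str, sid: str, direction: int) -> None:
        adj_p = float(rng.uniform(config.adj_p_low, config.adj_p_high))
        magnitude = float(rng.lognormal(mean=0.0, sigma=0.5))
        rows[sid].append((gene, direction * magnitude, adj_p))
        emissions[(gene, sid)] = (direction, adj_p)

    for gene, d, eligible in genes:
        for sid in eligible:
            if rng.random() < config.report_prob:
                direction = -d if rng.random() < config.flip_prob else d
                emit(gene, sid, direction)

    for i in range(config.n_background):
        g = f"BG{i:04d}"
        roles[g] = ROLE_BACKGROUND
        m = int(rng.integers(1, min(3, len(all_ids)) + 1))
        chosen = rng.choice(len(all_ids), size=m, replace=False)
        for j in sorted(chosen):
            emit(g, all_ids[j], int(rng.choice([1, -1])))

    for sid, _ in studies:
        for i in range(config.n_contaminant_rows_per_study):
            g = f"NS_{sid.upper()}_{i:04d}"
            roles[g] = ROLE_CONTAMINANT
            adj_p = float(rng.uniform(0.05, 0.5))
            magnitude = float(rng.lognormal(mean=0.0, sigma=0.5))
            d = int(rng.choice([1, -1]))
            rows[sid].append((g, d * magnitude, adj_p))
            emissions[(g, sid)] = (d, adj_p)

    tables = {
        sid: pd.DataFrame(rows[sid], columns=["gene_symbol", "log2fc", "adj_p"])
        for sid, _ in studies
    }
    metadata = [
        StudyMeta(
            study_id=sid,
            organ=organ,
            species="synthetic",
            timepoint_label="24 h",
            in_crossref=True,
        )
        for sid, organ in studies
    ]
    truth = SyntheticTruth(
        roles=roles, true_direction=true_dir, emissions=emissions, config=config
    )
    return SimulatedCorpus(tables=tables, metadata=metadata, truth=truth)


def corpus_to_calls(corpus: SimulatedCorpus, alpha: float = 0.05) -> list[StudyCall]:
    """In-memory significant study calls, bypassing file round-trips.

    Emissions are already one report per (gene, study), so the per-study
    collapse is the identity here.
    """
    calls = [
        StudyCall(sid, gene, direction, adj_p)
        for (gene, sid), (direction, adj_p) in corpus.truth.emissions.items()
        if adj_p < alpha
    ]
    calls.sort(key=lambda c: (c.study_id, c.canonical_symbol))
    return calls


def write_corpus(corpus: SimulatedCorpus, outdir: str | Path) -> dict:
    """Write DEG TSVs, metadata TSV and a truth JSON; returns the file map."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table_paths = {}
    for sid, frame in corpus.tables.items():
        p = outdir / f"deg_{sid}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        table_paths[sid] = str(p)
    meta_path = outdir / "metadata.tsv"
    pd.DataFrame(
        [
            (m.study_id, m.organ, m.species, m.timepoint_label, str(m.in_crossref).lower())
            for m in corpus.metadata
        ],
        columns=["study_id", "organ", "species", "timepoint_label", "in_crossref"],
    ).to_csv(meta_path, sep="\t", index=False)
    truth_path = outdir / "truth.json"
    with open(truth_path, "w", encoding="utf-8") as handle:
        json.dump(
            {
                "roles": corpus.truth.roles,
                "true_direction": corpus.truth.true_direction,
                "emissions": {
                    f"{gene}\t{sid}": [d, p]
                    for (gene, sid), (d, p) in corpus.truth.emissions.items()
                },
                "config": asdict(corpus.truth.config),
                "prng": "numpy default_rng (PCG64)",
            },
            handle,
            indent=1,
        )
    return {"tables": table_paths, "metadata": str(meta_path), "truth": str(truth_path)}


def evaluate_recovery(truth: SyntheticTruth, lists: SignatureLists) -> RecoveryScore:
    """Precision/recall of the recovered signature against the planted one.

    A planted up gene counts as recovered only if it lands in the up list
    (direction-aware), and symmetrically for down.
    """

    def score(planted: Sequence[str], recovered: Sequence[str]) -> tuple[float, float, bool]:
        planted_set, recovered_set = set(planted), set(recovered)
        hits = len(planted_set & recovered_set)
        recall = hits / len(planted_set) if planted_set else 1.0
        if recovered_set:
            return recall, hits / len(recovered_set), True
        return recall, 1.0, False

    up_recall, up_prec, up_def = score(truth.signature_up, lists.up)
    down_recall, down_prec, down_def = score(truth.signature_down, lists.down)
    return RecoveryScore(
        up_recall=up_recall,
        up_precision=up_prec,
        up_precision_defined=up_def,
        down_recall=down_recall,
        down_precision=down_prec,
        down_precision_defined=down_def,
    )


def simulate_gmt(
    n_terms: int,
    term_size_range: tuple[int, int],
    n_planted_terms: int,
    planted_overlap: float,
    query: Sequence[str],
    universe: Sequence[str],
    seed: int,
) -> tuple[GeneSetCollection, list[str]]:
    """Build a gene-set collection with planted enriched terms.

    Planted terms receive ``round(planted_overlap * size)`` members from the
    query (the rest from outside it); decoy terms sample members uniformly
    from the whole universe.  Returns the collection (universe fixed to the
    supplied background) and the planted term ids.
    """
    rng = np.random.default_rng(seed)
    query = list(dict.fromkeys(query))
    universe_list = list(dict.fromkeys(universe))
    universe_set = set(universe_list)
    if not set(query) <= universe_set:
        raise DataError("query must be a subset of the universe")
    if not 0.0 <= planted_overlap <= 1.0:
        raise ValueError("planted_overlap must lie in [0, 1]")
    lo, hi = term_size_range
    if not 1 <= lo <= hi <= len(universe_list):
        raise DataError(f"infeasible term size range {term_size_range}")
    if n_planted_terms > n_terms:
        raise DataError("more planted terms than terms")
    non_query = [g for g in universe_list if g not in set(query)]

    sets: dict[str, tuple[str, frozenset[str]]] = {}
    planted_ids = []
    for i in range(n_planted_terms):
        size = int(rng.integers(lo, hi + 1))
        k_query = int(round(planted_overlap * size))
        if k_query > len(query) or size - k_query > len(non_query):
            raise DataError(
                f"infeasible planted term: size {size}, overlap {planted_overlap}, "
                f"query size {len(query)}"
            )
        from_query = rng.choice(len(query), size=k_query, replace=False)
        from_rest = rng.choice(len(non_query), size=size - k_query, replace=False)
        members = frozenset(
            [query[j] for j in from_query] + [non_query[j] for j in from_rest]
        )
        term_id = f"PLANTED{i:03d}"
        sets[term_id] = ("planted enriched term", members)
        planted_ids.append(term_id)
    for i in range(n_terms - n_planted_terms):
        size = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(universe_list), size=size, replace=False)
        sets[f"DECOY{i:04d}"] = (
            "decoy term",
            frozenset(universe_list[j] for j in chosen),
        )
    return GeneSetCollection.from_sets(sets, universe=universe_set), planted_ids
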