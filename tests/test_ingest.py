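"""Reading, validating and collapsing per-study DEG tables."""

from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from crossdeg.ingest import (
    DataError,
    DEGRecord,
    canonicalize_symbol,
    collapse_study,
    filter_significant,
    ingest_study,
    read_deg_table,
    read_metadata,
)


def rec(symbol="GENE", direction=1, log2fc=None, adj_p=0.01, study="S1"):
    return DEGRecord(
        study_id=study,
        raw_symbol=symbol,
        canonical_symbol=canonicalize_symbol(symbol),
        direction=direction,
        log2fc=log2fc,
        adj_p=adj_p,
    )


class TestReadDegTable:
    COLMAP = {"symbol": "gene_symbol", "log2fc": "log2fc", "adj_p": "adj_p"}

    def test_directions_follow_sign_of_log2fc(self, deg_tsv):
        path = deg_tsv(["Icam1\t2.5\t0.001", "Kcng1\t-1.2\t0.01", "Myc\t0.3\t0.04"])
        records, report = read_deg_table(path, self.COLMAP, "S1")
        assert [r.direction for r in records] == [1, -1, 1]
        assert all(r.study_id == "S1" for r in records)
        assert report.rows_read == 3 and report.rows_dropped_malformed == 0

    def test_zero_log2fc_without_direction_column_is_malformed(self, deg_tsv):
        path = deg_tsv(["Icam1\t0.0\t0.001", "Myc\t1.0\t0.01"])
        records, report = read_deg_table(path, self.COLMAP, "S1")
        assert [r.canonical_symbol for r in records] == ["MYC"]
        assert report.rows_dropped_malformed == 1

    def test_textual_direction_column(self, deg_tsv):
        path = deg_tsv(
            ["Icam1,up,0.001", "Kcng1,down,0.01", "Myc,UP,0.02"],
            header="sym,dir,padj",
            name="study.csv",
        )
        records, _ = read_deg_table(
            path, {"symbol": "sym", "direction": "dir", "adj_p": "padj"}, "S1"
        )
        assert [r.direction for r in records] == [1, -1, 1]

    def test_direction_log2fc_conflict_is_malformed(self, deg_tsv):
        path = deg_tsv(
            ["Icam1\tup\t-2.0\t0.001", "Myc\tdown\t-1.0\t0.01"],
            header="gene_symbol\tdir\tlog2fc\tadj_p",
        )
        records, report = read_deg_table(
            path,
            {"symbol": "gene_symbol", "direction": "dir", "log2fc": "log2fc", "adj_p": "adj_p"},
            "S1",
        )
        assert [r.canonical_symbol for r in records] == ["MYC"]
        assert report.rows_dropped_malformed == 1

    @pytest.mark.parametrize(
        "bad_row, reason",
        [
            ("\t1.0\t0.01", "empty symbol"),
            ("Myc\tnot_a_number\t0.01", "bad log2fc"),
            ("Myc\t1.0\t1.5", "adjusted p outside [0,1]"),
            ("Myc\t1.0\tnope", "bad adjusted p"),
        ],
    )
    def test_malformed_rows_counted_not_coerced(self, deg_tsv, bad_row, reason):
        path = deg_tsv(["Icam1\t2.0\t0.001", bad_row])
        records, report = read_deg_table(path, self.COLMAP, "S1")
        assert len(records) == 1, reason
        assert report.rows_dropped_malformed == 1
        assert report.rows_read == 2

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(DataError, match="not found"):
            read_deg_table(tmp_path / "nope.tsv", self.COLMAP, "S1")

    def test_missing_column_fatal_names_the_column(self, deg_tsv):
        path = deg_tsv(["Icam1\t1.0\t0.01"])
        with pytest.raises(DataError, match="padj"):
            read_deg_table(
                path, {"symbol": "gene_symbol", "log2fc": "log2fc", "adj_p": "padj"}, "S1"
            )

    def test_zero_parseable_rows_fatal(self, deg_tsv):
        path = deg_tsv(["\t1.0\t0.01", "x\tbad\tbad"])
        with pytest.raises(DataError, match="zero parseable"):
            read_deg_table(path, self.COLMAP, "S1")

    def test_column_map_must_offer_a_direction_source(self, deg_tsv):
        path = deg_tsv(["Icam1\t1.0\t0.01"])
        with pytest.raises(DataError, match="direction"):
            read_deg_table(path, {"symbol": "gene_symbol", "adj_p": "adj_p"}, "S1")


class TestFilterSignificant:
    def test_boundary_is_strict(self):
        records = [rec(adj_p=p) for p in (0.049, 0.05, 0.2)]
        kept = filter_significant(records, alpha=0.05)
        assert [r.adj_p for r in kept] == [0.049]

    def test_empty_input(self):
        assert filter_significant([], alpha=0.05) == []

    def test_bad_alpha(self):
        with pytest.raises(ValueError):
            filter_significant([], alpha=1.0)

    @given(
        ps=st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), max_size=30),
        alphas=st.tuples(
            st.floats(min_value=0.01, max_value=0.99),
            st.floats(min_value=0.01, max_value=0.99),
        ),
    )
    def test_monotone_in_alpha(self, ps, alphas):
        """Shrinking alpha never adds records."""
        lo, hi = sorted(alphas)
        records = [rec(symbol=f"G{i}", adj_p=p) for i, p in enumerate(ps)]
        kept_lo = {r.canonical_symbol for r in filter_significant(records, lo)}
        kept_hi = {r.canonical_symbol for r in filter_significant(records, hi)}
        assert kept_lo <= kept_hi


class TestCanonicalizeSymbol:
    @pytest.mark.parametrize(
        "raw, expected",
        [("Icam1", "ICAM1"), (" Tnfrsf1a ", "TNFRSF1A"), ("HMOX1", "HMOX1")],
    )
    def test_examples(self, raw, expected):
        assert canonicalize_symbol(raw) == expected

    def test_empty_after_trim_fatal(self):
        with pytest.raises(DataError):
            canonicalize_symbol("   ")

    def test_synonym_map_applied_after_folding(self):
        assert canonicalize_symbol("Ccn1", {"CCN1": "CYR61"}) == "CYR61"

    @given(st.text(st.characters(min_codepoint=33, max_codepoint=126), min_size=1))
    def test_idempotent_and_case_insensitive(self, raw):
        once = canonicalize_symbol(raw)
        assert canonicalize_symbol(once) == once
        assert canonicalize_symbol(raw.swapcase()) == once


class TestCollapseStudy:
    def test_min_p_wins_on_direction_conflict(self):
        records = [rec(direction=1, adj_p=0.001), rec(direction=-1, adj_p=0.04)]
        (call,) = collapse_study(records)
        assert call.direction == 1 and call.best_adj_p == 0.001

    def test_single_record_identity(self):
        records = [rec(direction=-1, adj_p=0.02, log2fc=-1.5)]
        (call,) = collapse_study(records)
        assert (call.canonical_symbol, call.direction, call.best_adj_p) == ("GENE", -1, 0.02)

    def test_distinct_genes_pass_through(self):
        records = [rec(symbol=f"G{i}") for i in range(5)]
        assert len(collapse_study(records)) == 5

    def test_adj_p_tie_breaks_on_magnitude_then_up(self):
        by_magnitude = [
            rec(direction=1, log2fc=0.5, adj_p=0.01),
            rec(direction=-1, log2fc=-3.0, adj_p=0.01),
        ]
        assert collapse_study(by_magnitude)[0].direction == -1
        dead_tie = [
            rec(direction=-1, log2fc=-1.0, adj_p=0.01),
            rec(direction=1, log2fc=1.0, adj_p=0.01),
        ]
        assert collapse_study(dead_tie)[0].direction == 1

    def test_idempotent(self, rng):
        records = [
            rec(symbol=f"G{rng.integers(8)}", direction=int(rng.choice([1, -1])),
                adj_p=float(rng.uniform(0, 0.05)), log2fc=float(rng.normal()))
            for _ in range(40)
        ]
        calls = collapse_study(records)
        as_records = [
            rec(symbol=c.canonical_symbol, direction=c.direction, adj_p=c.best_adj_p)
            for c in calls
        ]
        again = collapse_study(as_records)
        assert [(c.canonical_symbol, c.direction, c.best_adj_p) for c in again] == [
            (c.canonical_symbol, c.direction, c.best_adj_p) for c in calls
        ]

    def test_mixed_studies_rejected(self):
        with pytest.raises(DataError, match="multiple studies"):
            collapse_study([rec(study="S1"), rec(study="S2")])


class TestIngestStudy:
    def test_report_counts_reconcile(self, deg_tsv):
        rows = [
            "Icam1\t2.0\t0.001",   # kept
            "Icam1\t1.0\t0.002",   # kept, collapsed as duplicate
            "Myc\t1.0\t0.2",       # nonsignificant
            "\t1.0\t0.01",         # malformed
            "Kcng1\t-1.0\t0.01",   # kept
        ]
        calls, report = ingest_study(
            deg_tsv(rows), TestReadDegTable.COLMAP, "S1", alpha=0.05
        )
        assert report.rows_read == 5
        kept = report.rows_read - report.rows_dropped_malformed - report.rows_dropped_nonsignificant
        assert kept == 3
        assert report.duplicate_symbols_collapsed == 1
        assert {c.canonical_symbol for c in calls} == {"ICAM1", "KCNG1"}


class TestReadMetadata:
    def _write(self, tmp_path, rows):
        path = tmp_path / "meta.tsv"
        header = "study_id\torgan\tspecies\ttimepoint_label\tin_crossref"
        path.write_text("\n".join([header, *rows]) + "\n")
        return path

    def test_roundtrip(self, tmp_path):
        path = self._write(
            tmp_path,
            ["s1\tcerebral\tmouse\t24 h\ttrue", "s2\trenal\trat\t4 h\tfalse"],
        )
        metas = read_metadata(path)
        assert [m.in_crossref for m in metas] == [True, False]
        assert metas[0].organ == "cerebral"

    def test_unknown_organ_fatal(self, tmp_path):
        path = self._write(tmp_path, ["s1\tlung\tmouse\t24 h\ttrue"])
        with pytest.raises(DataError, match="organ"):
            read_metadata(path)

    def test_duplicate_study_id_fatal(self, tmp_path):
        path = self._write(
            tmp_path, ["s1\tcerebral\tmouse\t24 h\ttrue", "s1\trenal\trat\t4 h\ttrue"]
        )
        with pytest.raises(DataError, match="duplicate"):
            read_metadata(path)
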