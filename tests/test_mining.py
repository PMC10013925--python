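"""Filename prefilter, table reading, column-role regexes, validity screens,
tool inference and the sample-size rule."""

import gzip

import numpy as np
import pandas as pd
import pytest

from pvalscan import (
    FixtureSpec, assign_column_roles, determine_sample_size,
    filename_passes_prefilter, find_expression_columns, find_pvalue_columns,
    infer_de_tool, read_table, try_read_table, validate_pvalue_set,
    write_fixture,
)
from pvalscan.mining import ADJUSTED_RE, ProcessedTable, TableImportError
from pvalscan.synthetic import DIALECTS, DIALECT_TOOL


class TestFilenamePrefilter:
    @pytest.mark.parametrize("name,expected", [
        ("GSE1_series_matrix.txt.gz", False),
        ("sample1.bam", False),
        ("deg_results.tsv", True),
        ("results.csv.gz", True),
        ("counts.mtx.gz", False),
        ("genome.fasta", False),
        ("coverage.bigWig", False),
        ("my_README.txt", False),
        ("GSE99_RAW.tar", True),  # accepted extension, not a drop pattern
        ("table.diff", True),
        ("notes.docx", False),
    ])
    def test_examples(self, name, expected):
        assert filename_passes_prefilter(name) is expected

    def test_empty_name_rejected(self):
        with pytest.raises(ValueError):
            filename_passes_prefilter("")


class TestReadTable:
    def _frame(self):
        return pd.DataFrame({"gene": ["a", "b", "c"],
                             "pvalue": [0.1, 0.2, 0.3],
                             "baseMean": [1.0, 2.0, 3.0]})

    def test_gzip_roundtrip_matches_plain(self, tmp_path):
        df = self._frame()
        plain = tmp_path / "t.tsv"
        packed = tmp_path / "t.tsv.gz"
        df.to_csv(plain, sep="\t", index=False)
        with gzip.open(packed, "wt") as fh:
            df.to_csv(fh, sep="\t", index=False)
        a, b = read_table(plain), read_table(packed)
        np.testing.assert_allclose(a.numeric("pvalue"), b.numeric("pvalue"))
        assert list(a.df.columns) == list(b.df.columns)

    @pytest.mark.parametrize("sep", [",", ";"])
    def test_delimiter_dialects_parse_identically(self, tmp_path, sep):
        df = self._frame()
        path = tmp_path / "t.csv"
        df.to_csv(path, sep=sep, index=False)
        table = read_table(path)
        np.testing.assert_allclose(table.numeric("baseMean"), [1.0, 2.0, 3.0])

    def test_binary_junk_is_import_failure(self, tmp_path):
        path = tmp_path / "junk.csv"
        path.write_bytes(bytes(range(256)) * 10)
        table, reason = try_read_table(path)
        assert table is None and reason

    def test_no_delimiter_is_import_failure(self, tmp_path):
        path = tmp_path / "one.txt"
        path.write_text("header\n1\n2\n")
        with pytest.raises(TableImportError):
            read_table(path)

    def test_xlsx_supported_xls_not(self, tmp_path):
        df = self._frame()
        xlsx = tmp_path / "t.xlsx"
        df.to_excel(xlsx, index=False)
        assert read_table(xlsx).n_rows == 3
        xls = tmp_path / "t.xls"
        xls.write_bytes(b"\xd0\xcf\x11\xe0junk")
        table, reason = try_read_table(xls)
        assert table is None and "unsupported" in reason

    def test_reparse_idempotence(self, tmp_path):
        path = tmp_path / "t.tsv"
        self._frame().to_csv(path, sep="\t", index=False)
        first = read_table(path)
        rewritten = tmp_path / "t2.tsv"
        first.df.to_csv(rewritten, sep="\t", index=False)
        second = read_table(rewritten)
        np.testing.assert_allclose(first.numeric("pvalue"), second.numeric("pvalue"))

    def test_non_numeric_cells_coerce_to_nan(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("pvalue,score\n0.1,ok\nNA,2\n0.3,3\n")
        table = read_table(path)
        pv = table.numeric("pvalue")
        assert np.isnan(pv[1]) and pv[0] == 0.1


class TestColumnRoles:
    @pytest.mark.parametrize("columns,expected_p", [
        (["p_value", "q_value", "padj"], ["p_value"]),
        (["PValue", "FDR"], ["PValue"]),
        (["log2FC", "baseMean"], []),
        (["pvalue", "pvalue_2", "adj.P.Val"], ["pvalue", "pvalue_2"]),
    ])
    def test_find_pvalue_columns(self, columns, expected_p):
        table = ProcessedTable(df=pd.DataFrame(columns=columns, dtype=float))
        assert find_pvalue_columns(table) == expected_p

    def test_pvalue_columns_never_match_adjusted_pattern(self):
        names = ["pval", "padj", "p.value", "fdr_pval", "p_value_corrected",
                 "Pvalue", "p-val", "adj_pvalue", "pval_thresh"]
        table = ProcessedTable(df=pd.DataFrame(columns=names, dtype=float))
        for col in find_pvalue_columns(table):
            assert not ADJUSTED_RE.search(col.lower())

    @pytest.mark.parametrize("columns,expected", [
        (["baseMean", "pvalue"], [("baseMean", "basemean")]),
        (["value_1", "value_2"], [("value_1", "value"), ("value_2", "value")]),
        (["AveExpr"], [("AveExpr", "aveexpr")]),
        (["logCPM", "logFC"], [("logCPM", "logcpm")]),
    ])
    def test_find_expression_columns(self, columns, expected):
        table = ProcessedTable(df=pd.DataFrame(columns=columns, dtype=float))
        assert find_expression_columns(table) == expected

    def test_every_column_gets_exactly_one_role(self):
        names = ["gene", "pvalue", "padj", "baseMean", "q_value", "stat"]
        roles = assign_column_roles(names)
        assert set(roles) == set(names)
        assert [roles[n].role for n in names] == [
            "other", "pvalue", "adjusted", "expression", "adjusted", "other"]


class TestValidation:
    def test_all_nan(self):
        assert validate_pvalue_set([np.nan] * 5).status == "all_nan"

    def test_out_of_range(self):
        assert validate_pvalue_set([0.1, 1.2]).status == "out_of_range"
        assert validate_pvalue_set([-0.01, 0.5, 1.0]).status == "out_of_range"

    def test_truncated_significant_only_export(self, rng):
        values = rng.random(1000) * 0.049
        assert validate_pvalue_set(values).status == "truncated"

    def test_right_skewed_score_like_column(self, rng):
        values = rng.random(5000) ** 0.25  # mass piled towards 1
        assert validate_pvalue_set(values).status == "right_skewed"

    def test_uniform_and_anticonservative_pass(self, rng):
        assert validate_pvalue_set(rng.random(5000)).status == "ok"
        anti = np.concatenate([rng.random(5000), rng.random(500) * 0.01])
        assert validate_pvalue_set(anti).status == "ok"

    def test_ok_implies_in_range(self, rng):
        values = np.concatenate([rng.random(500), [np.nan]])
        verdict = validate_pvalue_set(values)
        if verdict.ok:
            finite = values[np.isfinite(values)]
            assert finite.min() >= 0 and finite.max() <= 1


class TestToolInference:
    def _table(self, columns):
        return ProcessedTable(df=pd.DataFrame(columns=columns, dtype=float))

    @pytest.mark.parametrize("columns,tool", [
        (["baseMean", "pvalue", "padj"], "deseq2"),
        (["baseMean", "pval", "padj"], "deseq"),
        (["logCPM", "PValue", "FDR"], "edger"),
        (["value_1", "value_2", "p_value", "q_value"], "cuffdiff"),
        (["weird", "p_val"], "unknown"),
    ])
    def test_column_heuristics(self, columns, tool):
        assert infer_de_tool(self._table(columns)).tool == tool

    def test_limma_requires_recent_publication(self):
        cols = ["AveExpr", "P.Value", "adj.P.Val"]
        assert infer_de_tool(self._table(cols), pub_date="2016-01-01").tool == "limma"
        assert infer_de_tool(self._table(cols), pub_date="2012-01-01").tool == "unknown"
        assert infer_de_tool(self._table(cols)).tool == "unknown"

    def test_text_regex_beats_column_heuristic(self):
        table = self._table(["baseMean", "pvalue"])
        label = infer_de_tool(table, free_text="Data analysed with Rockhopper v2")
        assert label.tool == "rockhopper" and label.evidence == "text_regex"
        assert infer_de_tool(table, free_text="counts via voom").tool == "limma"


class TestSampleSize:
    @pytest.mark.parametrize("n_samples,n_sets,expected", [
        (6, 1, 3), (2, 1, 1), (7, 1, None), (12, 2, 4), (11, 2, None)])
    def test_balanced_rule(self, n_samples, n_sets, expected):
        assert determine_sample_size(n_samples, n_sets).per_group_n == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            determine_sample_size(0, 1)
        with pytest.raises(ValueError):
            determine_sample_size(4, 0)


class TestMiningFidelityOnFixtures:
    """Round-trip precision/recall of roles and tool labels across dialects."""

    @pytest.mark.parametrize("dialect", DIALECTS)
    @pytest.mark.parametrize("delimiter,gz", [("\t", False), (",", True), (";", False)])
    def test_roles_and_tools_exact(self, tmp_path, small_count_table,
                                   dialect, delimiter, gz):
        spec = FixtureSpec(dialect=dialect, delimiter=delimiter, gzip=gz)
        suffix = ".tsv.gz" if gz else ".tsv"
        path = tmp_path / f"fx_{dialect}{suffix}"
        manifest = write_fixture(spec, small_count_table, path)
        table = read_table(path)
        for col in manifest["columns"]:
            got = table.roles[col["name"]]
            assert got.role == col["role"]
            assert (got.metric or None) == (col["metric"] or None)
        assert infer_de_tool(table, pub_date="2016-05-01").tool == manifest["tool"]

    def test_fixture_without_adjusted_columns(self, tmp_path, small_count_table):
        spec = FixtureSpec(dialect="deseq2", include_adjusted=False)
        manifest = write_fixture(spec, small_count_table, tmp_path / "f.tsv")
        assert all(c["role"] != "adjusted" for c in manifest["columns"])

    def test_multiple_pvalue_columns(self, tmp_path, small_count_table):
        spec = FixtureSpec(dialect="edger", n_pvalue_columns=3)
        write_fixture(spec, small_count_table, tmp_path / "f.tsv")
        table = read_table(tmp_path / "f.tsv")
        assert len(find_pvalue_columns(table)) == 3
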