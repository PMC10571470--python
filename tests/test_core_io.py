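"""Containers, file round-trips, QC semantics and the marker finder."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cafscape import (
    CellMap,
    ExpressionMatrix,
    QCThresholds,
    SchemaError,
    UnitsError,
    find_markers,
    log_normalize,
    qc_filter,
    read_cell_map,
    read_expression,
    read_gmt,
    top_markers,
    write_cell_map,
)

from conftest import make_counts_matrix


class TestCellMapIO:
    def test_parse_two_slices(self, tmp_path):
        path = tmp_path / "cells.csv"
        path.write_text(
            "cell_id,slice_id,x,y,cell_type\n"
            "a,s1,0.0,1.0,T\n"
            "b,s1,2.0,3.0,B\n"
            "a,s2,4.0,5.0,T\n"
        )
        cm = read_cell_map(path)
        assert cm.n_cells == 3
        assert cm.slices == ["s1", "s2"]
        assert cm.table["cell_id"].tolist() == ["a", "b", "a"]  # row order preserved

    def test_duplicate_cell_id_within_slice_rejected(self):
        df = pd.DataFrame(
            {
                "cell_id": ["a", "a"],
                "slice_id": ["s1", "s1"],
                "x": [0.0, 1.0],
                "y": [0.0, 1.0],
                "cell_type": ["T", "B"],
            }
        )
        with pytest.raises(SchemaError, match="duplicated cell_id"):
            CellMap(df)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "cells.csv"
        path.write_text("cell_id,slice_id,x,y\na,s1,0,1\n")
        with pytest.raises(SchemaError, match="cell_type"):
            read_cell_map(path)

    def test_bad_coordinate_reports_row(self, tmp_path):
        path = tmp_path / "cells.csv"
        path.write_text(
            "cell_id,slice_id,x,y,cell_type\na,s1,0,1,T\nb,s1,oops,2,B\n"
        )
        with pytest.raises(SchemaError, match="row 1"):
            read_cell_map(path)

    @pytest.mark.parametrize("dialect", ["csv", "tsv"])
    def test_round_trip(self, tmp_path, dialect, small_cell_map):
        path = tmp_path / f"cells.{dialect}"
        write_cell_map(small_cell_map, path, dialect=dialect)
        back = read_cell_map(path, dialect=dialect)
        pd.testing.assert_frame_equal(back.table, small_cell_map.table)


class TestExpressionIO:
    def test_dense_csv_total_counts(self, tmp_path):
        path = tmp_path / "expr.csv"
        path.write_text(",c1,c2\ng1,1,0\ng2,3,2\n")
        expr = read_expression(path, format="dense-csv")
        assert expr.total_counts().tolist() == [4.0, 2.0]

    def test_mtx_zero_nonzeros(self, tmp_path):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n2 3 0\n"
        )
        (tmp_path / "genes.tsv").write_text("g1\ng2\n")
        (tmp_path / "barcodes.tsv").write_text("c1\nc2\nc3\n")
        expr = read_expression(tmp_path / "m.mtx", format="mtx-triplet")
        assert expr.shape == (2, 3)
        assert (expr.values.to_numpy() == 0).all()

    def test_mtx_sidecar_mismatch(self, tmp_path):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n2 3 1\n1 1 5\n"
        )
        (tmp_path / "genes.tsv").write_text("g1\n")
        (tmp_path / "barcodes.tsv").write_text("c1\nc2\nc3\n")
        with pytest.raises(SchemaError, match="does not match"):
            read_expression(tmp_path / "m.mtx", format="mtx-triplet")

    def test_negative_value_rejected(self, tmp_path):
        path = tmp_path / "expr.csv"
        path.write_text(",c1\ng1,-1\n")
        with pytest.raises(SchemaError, match="non-negative"):
            read_expression(path, format="dense-csv")

    def test_gmt_parsing(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("setA\tdesc\tg1\tg2\nsetB\t-\tg3\n")
        sets = read_gmt(path)
        assert sets["setA"] == ["g1", "g2"]
        assert sets.names() == ["setA", "setB"]


def _qc_fixture():
    """600 ordinary genes + one mitochondrial gene, five crafted cells."""
    n = 600
    genes = [f"G{i:03d}" for i in range(n)] + ["MT-ND1"]
    mat = np.ones((n + 1, 5))
    mat[-1, :] = 0.0
    # cell 0: passes everything (600 UMI, 600 genes)
    # cell 1: 40,001 UMIs
    mat[0, 1] = 40_001 - (n - 1)
    # cell 2: exactly 40,000 UMIs -> retained (strict inequality)
    mat[0, 2] = 40_000 - (n - 1)
    # cell 3: only 499 detected genes
    mat[n - 101 :, 3] = 0.0
    mat[-1, 3] = 0.0
    # cell 4: mito fraction 200/800 = 0.25 > 0.20
    mat[-1, 4] = 200.0
    return make_counts_matrix(mat, genes=genes)


class TestQCFilter:
    def test_umi_boundary_is_strict(self):
        expr = _qc_fixture()
        _, report = qc_filter(expr, QCThresholds())
        by_cell = report.set_index("cell_id")
        assert not by_cell.loc["c1", "pass"] and by_cell.loc["c1", "reason"] == "umi"
        assert by_cell.loc["c2", "pass"]  # exactly 40,000 retained

    def test_min_genes_and_mito_reasons(self):
        expr = _qc_fixture()
        _, report = qc_filter(expr, QCThresholds())
        by_cell = report.set_index("cell_id")
        assert by_cell.loc["c3", "reason"] == "min_genes"
        assert by_cell.loc["c4", "reason"] == "mito"
        assert by_cell.loc["c0", "pass"]

    def test_all_passing_is_identity_and_idempotent(self):
        expr = make_counts_matrix(np.ones((600, 4)))
        out, report = qc_filter(expr)
        pd.testing.assert_frame_equal(out.values, expr.values)
        assert report["pass"].all()
        again, report2 = qc_filter(out)
        pd.testing.assert_frame_equal(again.values, out.values)
        assert report2["pass"].all()

    def test_log_units_rejected(self):
        expr = ExpressionMatrix(pd.DataFrame({"c1": [1.0]}, index=["g1"]), units="log")
        with pytest.raises(UnitsError):
            qc_filter(expr)


def exact_ranksum_two_sided(a, b):
    """Independent oracle: enumerate every assignment of pooled ranks.

    Two-sided p = P(U as or more extreme than observed), using the symmetry
    of the tie-free Mann-Whitney null distribution.
    """
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    lo, hi = min(u_obs, n1 * n2 - u_obs), max(u_obs, n1 * n2 - u_obs)
    count = total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if u <= lo or u >= hi:
            count += 1
    return count / total


class TestFindMarkers:
    def _expr(self, mat, groups):
        expr = ExpressionMatrix(
            pd.DataFrame(
                mat,
                index=[f"G{i}" for i in range(mat.shape[0])],
                columns=[f"c{i}" for i in range(mat.shape[1])],
            ),
            units="log",
        )
        labels = pd.Series(groups, index=expr.cells)
        return expr, labels

    def test_forced_separation(self):
        mat = np.zeros((2, 20))
        mat[0, :10] = 5.0
        mat[1, :] = 1.0  # identically distributed
        expr, labels = self._expr(mat, ["A"] * 10 + ["B"] * 10)
        table = find_markers(expr, labels).table.set_index(["gene", "group"])
        assert table.loc[("G0", "A"), "log2fc"] == pytest.approx(5.0)
        assert table.loc[("G0", "A"), "significant"]
        assert table.loc[("G1", "A"), "log2fc"] == pytest.approx(0.0)
        assert not table.loc[("G1", "A"), "significant"]

    def test_pvalue_matches_exact_enumeration(self):
        rng = np.random.default_rng(3)
        mat = rng.uniform(1.0, 5.0, size=(3, 6)).round(3)  # tie-free
        expr, labels = self._expr(mat, ["A", "A", "A", "B", "B", "B"])
        table = find_markers(expr, labels).table
        for gi in range(3):
            expected = exact_ranksum_two_sided(mat[gi, :3], mat[gi, 3:])
            row = table[(table["gene"] == f"G{gi}") & (table["group"] == "A")]
            assert row["pvalue"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_cell_order_and_constant_shift(self):
        rng = np.random.default_rng(11)
        mat = rng.gamma(2.0, 1.0, size=(4, 12))
        expr, labels = self._expr(mat, ["A"] * 6 + ["B"] * 6)
        base = find_markers(expr, labels).table

        perm = rng.permutation(12)
        expr2 = ExpressionMatrix(expr.values.iloc[:, perm], units="log")
        shuffled = find_markers(expr2, labels[expr2.cells]).table
        pd.testing.assert_frame_equal(base, shuffled)

        expr3 = ExpressionMatrix(expr.values + 7.0, units="log")
        shifted = find_markers(expr3, labels).table
        np.testing.assert_allclose(base["log2fc"], shifted["log2fc"], atol=1e-12)
        np.testing.assert_allclose(base["pvalue"], shifted["pvalue"], atol=1e-12)

    def test_bh_monotone_in_raw_p(self):
        rng = np.random.default_rng(5)
        mat = rng.random(size=(30, 16))
        expr, labels = self._expr(mat, ["A"] * 8 + ["B"] * 8)
        table = find_markers(expr, labels).table
        for _, sub in table.groupby("group"):
            sub = sub.sort_values("pvalue")
            assert (np.diff(sub["padj"]) >= -1e-12).all()
            assert (sub["padj"] >= sub["pvalue"] - 1e-12).all()

    def test_small_group_rejected(self):
        mat = np.ones((2, 3))
        expr, labels = self._expr(mat, ["A", "A", "B"])
        with pytest.raises(ValueError, match="B"):
            find_markers(expr, labels)

    def test_top_markers_returns_largest_lfc(self):
        mat = np.zeros((3, 20))
        mat[0, :10] = 3.0
        mat[1, :10] = 5.0
        mat[2, :10] = 4.0
        expr, labels = self._expr(mat, ["A"] * 10 + ["B"] * 10)
        markers = find_markers(expr, labels)
        assert top_markers(markers, "A", 2) == ["G1", "G2"]


def test_log_normalize_units_and_scale():
    expr = make_counts_matrix(np.array([[10.0, 0.0], [90.0, 50.0]]))
    logged = log_normalize(expr, scale=100.0)
    assert logged.units == "log"
    assert logged.values.iloc[0, 0] == pytest.approx(np.log2(11.0))
    with pytest.raises(UnitsError):
        log_normalize(logged)
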