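import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirsm import (
    EdgeSet,
    align_samples,
    average_replicates,
    drop_unnamed,
    filter_missing,
    knn_impute,
    load_binding_table,
    load_edge_list,
    load_expression,
)
from mirsm.data_io import write_expression


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadExpression:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0], [0.5, 0.25, -1.0, 0.0]],
            index=["g1", "g2", "g3"],
            columns=["s1", "s2", "s3", "s4"],
        )
        write_expression(df, tmp_path / "e.tsv")
        back = load_expression(tmp_path / "e.tsv", "mRNA")
        pd.testing.assert_frame_equal(back, df)
        assert back.attrs["entity_kind"] == "mRNA"

    def test_na_tokens_become_missing(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "id\ts1\ts2\ts3\ng1\t1.0\tNA\t\ng2\tNaN\t2\t3\n")
        df = load_expression(p)
        assert df.isna().sum().sum() == 3
        assert df.loc["g2", "s2"] == 2.0

    def test_duplicate_sample_column_rejected(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "id\ts1\ts1\ng1\t1\t2\n")
        with pytest.raises(ValueError, match="duplicate sample"):
            load_expression(p)

    def test_non_numeric_cell_rejected(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "id\ts1\ts2\ng1\t1.0\tbogus\n")
        with pytest.raises(ValueError, match="non-numeric"):
            load_expression(p)


class TestFilterMissing:
    def test_strict_majority_rule(self):
        # missing fractions 0, .2, .5, .6, 1 over 10 samples -> 3 rows survive
        n = 10
        rows = {}
        for name, k in [("a", 0), ("b", 2), ("c", 5), ("d", 6), ("e", 10)]:
            v = np.ones(n)
            v[:k] = np.nan
            rows[name] = v
        df = pd.DataFrame(rows).T
        out = filter_missing(df, 0.5)
        assert list(out.index) == ["a", "b", "c"]  # exactly half is kept (strict >)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            filter_missing(pd.DataFrame([[1.0]]), 1.5)


class TestKnnImpute:
    def test_complete_matrix_unchanged(self):
        df = pd.DataFrame(np.arange(12.0).reshape(3, 4))
        pd.testing.assert_frame_equal(knn_impute(df, k=2), df)

    def test_single_neighbour_copies_value(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0],
             [1.0, 2.0, 3.0, np.nan],
             [50.0, 60.0, 70.0, 80.0]],
            index=["a", "b", "c"],
        )
        out = knn_impute(df, k=1)
        assert out.loc["b", 3] == 4.0  # row a is the forced nearest neighbour

    def test_two_neighbour_average_matches_oracle(self):
        # independent oracle: nan-Euclidean distance over co-observed columns,
        # unweighted mean of the k nearest rows observed at the missing column
        values = np.array(
            [
                [0.0, 0.0, 0.0, np.nan],
                [0.0, 0.0, 0.1, 10.0],
                [0.1, 0.0, 0.0, 20.0],
                [5.0, 5.0, 5.0, 30.0],
                [6.0, 6.0, 6.0, np.nan],
                [6.0, 6.1, 6.0, 50.0],
            ]
        )

        def oracle(mat, i, j, k):
            target = mat[i]
            cands = []
            for r in range(mat.shape[0]):
                if r == i or np.isnan(mat[r, j]):
                    continue
                shared = ~(np.isnan(target) | np.isnan(mat[r]))
                d = np.sqrt(mat.shape[1] / shared.sum() * ((target - mat[r])[shared] ** 2).sum())
                cands.append((d, r))
            cands.sort()
            return np.mean([mat[r, j] for _, r in cands[:k]])

        df = pd.DataFrame(values)
        out = knn_impute(df, k=2)
        assert out.iloc[0, 3] == pytest.approx(oracle(values, 0, 3, 2))  # (10+20)/2
        assert out.iloc[4, 3] == pytest.approx(oracle(values, 4, 3, 2))  # (30+50)/2
        assert not out.isna().any().any()

    def test_fully_missing_row_rejected(self):
        df = pd.DataFrame([[1.0, 2.0], [np.nan, np.nan], [3.0, 4.0]])
        with pytest.raises(ValueError, match="fully missing"):
            knn_impute(df, k=1)

    def test_k_bounds(self):
        df = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            knn_impute(df, k=2)

    def test_filter_then_impute_leaves_no_missing(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.standard_normal((30, 12)))
        mask = rng.random((30, 12)) < 0.25
        df[mask] = np.nan
        out = knn_impute(filter_missing(df), k=5)
        assert not out.isna().any().any()


class TestAverageReplicates:
    def test_pairwise_mean(self):
        df = pd.DataFrame([[1.0, 3.0], [3.0, 5.0]], index=["GENEA", "GENEA"])
        out = average_replicates(df)
        assert out.shape == (1, 2)
        assert list(out.loc["GENEA"]) == [2.0, 4.0]

    def test_triplicate_collapse(self):
        df = pd.DataFrame(
            [[1.0], [2.0], [6.0], [9.0]], index=["x", "y", "y", "y"]
        )
        out = average_replicates(df)
        assert out.shape[0] == 2
        assert out.loc["y", 0] == pytest.approx((2 + 6 + 9) / 3)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.sampled_from(["a", "b", "c"]), min_size=1, max_size=8))
    def test_idempotent(self, ids):
        df = pd.DataFrame(
            np.arange(2.0 * len(ids)).reshape(len(ids), 2), index=ids
        )
        once = average_replicates(df)
        pd.testing.assert_frame_equal(average_replicates(once), once)


class TestBindingTable:
    def test_counts_after_filter_and_collapse(self, tmp_path):
        lines = [
            "miR-1\tGA\t-0.5",
            "miR-1\tGB\t0.0",    # non-negative: dropped
            "miR-2\tGA\t-0.1",   # duplicated below
            "miR-2\tGA\t-0.4",
            "miR-2\tGB\t0.3",    # dropped
            "miR-3\tGA\t-0.2",
            "miR-3\tGB\t-0.7",
            "miR-3\tGC\t0.1",    # dropped
            "miR-4\tGA\t-0.9",
            "miR-4\tGB\t-0.3",
        ]
        p = _write(tmp_path, "b.tsv", "\n".join(lines) + "\n")
        df = load_binding_table(p)
        assert len(df) == 6
        assert df.set_index(["mirna", "mrna"]).loc[("miR-2", "GA"), "score"] == -0.4
        assert df.set_index(["mirna", "mrna"]).loc[("miR-4", "GA"), "score"] == -0.9
        assert (df["score"] < 0).all()

    def test_header_line_skipped(self, tmp_path):
        p = _write(tmp_path, "b.tsv", "mirna\tgene\tscore\nmiR-1\tGA\t-0.5\n")
        assert len(load_binding_table(p)) == 1

    def test_malformed_row_reports_line(self, tmp_path):
        p = _write(tmp_path, "b.tsv", "miR-1\tGA\t-0.5\nmiR-2\tGA\n")
        with pytest.raises(ValueError, match="line 2"):
            load_binding_table(p)


class TestEdgeSets:
    def test_unordered_membership(self):
        es = EdgeSet.from_pairs([("b", "a")], "ppi")
        assert ("a", "b") in es and ("b", "a") in es

    def test_ordered_membership_and_unordered_probe(self):
        es = EdgeSet.from_pairs([("tf1", "g1")], "tf")
        assert ("tf1", "g1") in es
        assert ("g1", "tf1") not in es
        assert es.contains_unordered(("g1", "tf1"))

    def test_self_pairs_dropped_on_load(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "a\tb\nc\tc\n")
        with pytest.warns(UserWarning, match="self-pair"):
            es = load_edge_list(p, "ppi")
        assert len(es) == 1

    def test_malformed_edge_row(self, tmp_path):
        p = _write(tmp_path, "e.tsv", "a\tb\na\tb\tc\n")
        with pytest.raises(ValueError, match="line 2"):
            load_edge_list(p, "ppi")


class TestAlignAndSymbols:
    def test_align_reorders(self):
        mrna = pd.DataFrame([[1, 2, 3]], index=["g"], columns=["s1", "s2", "s3"])
        mirna = pd.DataFrame([[30, 10, 20]], index=["m"], columns=["s3", "s1", "s2"])
        _, mi = align_samples(mrna, mirna)
        assert list(mi.columns) == ["s1", "s2", "s3"]
        assert list(mi.loc["m"]) == [10, 20, 30]

    def test_align_mismatch_raises(self):
        mrna = pd.DataFrame([[1, 2]], index=["g"], columns=["s1", "s2"])
        mirna = pd.DataFrame([[1, 2]], index=["m"], columns=["s1", "s9"])
        with pytest.raises(ValueError, match="sample sets differ"):
            align_samples(mrna, mirna)

    def test_drop_unnamed(self):
        df = pd.DataFrame([[1.0]] * 4, index=["TP53", "?", "", "KRAS"])
        assert list(drop_unnamed(df).index) == ["TP53", "KRAS"]
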