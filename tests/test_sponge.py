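from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from mirsm import (
    Bicluster,
    EdgeSet,
    SpongeModuleDetector,
    infer_module,
    pair_correlation,
    run_pipeline,
    shared_mirna_test,
)


def exact_upper_tail(x, n, m, k):
    """Rational-arithmetic oracle: p = 1 - sum_{i<x} C(M,i) C(N-M,K-i) / C(N,K)."""
    num = sum(comb(m, i) * comb(n - m, k - i) for i in range(x) if 0 <= k - i <= n - m)
    return float(1 - Fraction(num, comb(n, k)))


class TestSharedMiRNATest:
    def test_no_sharing_is_certain(self):
        assert shared_mirna_test({"a", "b"}, {"c"}, 10).p == 1.0

    def test_symmetric_in_the_two_sets(self):
        t1 = {f"m{i}" for i in range(8)}
        t2 = {f"m{i}" for i in range(4, 14)}
        s12 = shared_mirna_test(t1, t2, 20)
        s21 = shared_mirna_test(t2, t1, 20)
        assert s12.p == pytest.approx(s21.p, abs=1e-15)

    def test_matches_exact_rational_oracle(self):
        # N=20, M=8, K=10, x=5: p = sum_{i=5}^{8} C(8,i) C(12,10-i) / C(20,10)
        t1 = {f"m{i}" for i in range(8)}
        t2 = {f"m{i}" for i in range(3, 13)}  # overlap = {m3..m7}, x = 5
        stat = shared_mirna_test(t1, t2, 20)
        assert (stat.M, stat.K, stat.x) == (8, 10, 5)
        assert stat.p == pytest.approx(60038 / 184756, abs=1e-12)
        assert stat.p == pytest.approx(exact_upper_tail(5, 20, 8, 10), abs=1e-12)

    def test_more_sharing_is_more_significant(self):
        n, m, k = 30, 10, 12
        pool = [f"m{i}" for i in range(n)]
        prev = 1.1
        for x in range(0, min(m, k) + 1):
            t1 = set(pool[:m])
            t2 = set(pool[:x]) | set(pool[m:m + k - x])
            p = shared_mirna_test(t1, t2, n).p
            assert p <= prev + 1e-15
            prev = p

    def test_universe_violation(self):
        with pytest.raises(ValueError, match="universe"):
            shared_mirna_test({"a", "b", "c"}, {"a"}, 2)


class TestPairCorrelation:
    def _frame(self, rows, ids):
        return pd.DataFrame(rows, index=ids, columns=[f"s{i}" for i in range(len(rows[0]))])

    def test_identical_profiles(self):
        expr = self._frame([np.arange(10.0), np.arange(10.0)], ["a", "b"])
        r, p = pair_correlation(expr, "a", "b")
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_matches_t_distribution_oracle(self):
        from scipy import stats

        x = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 4.0, 3.5, 5.0])
        y = np.array([2.0, 1.0, 2.5, 2.0, 4.0, 3.0, 5.0, 4.5])
        expr = self._frame([x, y], ["a", "b"])
        r, p = pair_correlation(expr, "a", "b")
        n = 8
        r_oracle = float(np.corrcoef(x, y)[0, 1])
        t = r_oracle * np.sqrt(n - 2) / np.sqrt(1 - r_oracle ** 2)
        p_oracle = 2 * stats.t.sf(abs(t), df=n - 2)
        assert r == pytest.approx(r_oracle, abs=1e-12)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_zero_variance_warns(self):
        expr = self._frame([[1.0] * 5, np.arange(5.0)], ["a", "b"])
        with pytest.warns(UserWarning, match="zero-variance"):
            r, p = pair_correlation(expr, "a", "b")
        assert (r, p) == (0.0, 1.0)

    def test_independent_profiles_rarely_significant(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(2000 + rep)
            expr = self._frame(rng.standard_normal((2, 72)), ["a", "b"])
            _, p = pair_correlation(expr, "a", "b")
            hits += p < 0.05
        # 5% nominal level; allow ~3 binomial SDs of slack
        assert hits <= 12


def engineered_bicluster():
    """Six mRNAs, 15 pairs, exactly 4 passing both tests, one a planted TF edge.

    A, B, C share driver z1 and target set {m0..m7}; D, E share driver z2
    and target set {m8..m15}; F is independent noise without targets.
    Passing pairs: (A,B), (A,C), (B,C), (D,E).  (A,B) is a TF edge.
    """
    rng = np.random.default_rng(99)
    n = 40
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    rows = {
        "A": z1 + 0.1 * rng.standard_normal(n),
        "B": z1 + 0.1 * rng.standard_normal(n),
        "C": z1 + 0.1 * rng.standard_normal(n),
        "D": z2 + 0.1 * rng.standard_normal(n),
        "E": z2 + 0.1 * rng.standard_normal(n),
        "F": rng.standard_normal(n),
    }
    expr = pd.DataFrame(rows).T
    expr.columns = [f"s{i}" for i in range(n)]
    s1 = {f"m{i}" for i in range(8)}
    s2 = {f"m{i}" for i in range(8, 16)}
    tset = {"A": s1, "B": s1, "C": s1, "D": s2, "E": s2}
    bic = Bicluster(mrna_ids=tuple("ABCDEF"), mirna_ids=tuple(sorted(s1 | s2)))
    return expr, tset, bic


class TestInferModule:
    def test_engineered_fixture(self):
        expr, tset, bic = engineered_bicluster()
        tf = EdgeSet.from_pairs([("A", "B")], "tf")
        module = infer_module(bic, expr, tset, tf=tf, p_cut=0.01, n_mirnas=40)
        assert module.interaction_pairs() == {("A", "C"), ("B", "C"), ("D", "E")}
        assert set(module.sponge_ids) == {"A", "B", "C", "D", "E"}
        assert "F" not in module.sponge_ids

    def test_without_tf_filter_four_pairs_pass(self):
        expr, tset, bic = engineered_bicluster()
        module = infer_module(bic, expr, tset, p_cut=0.01, n_mirnas=40)
        assert module.interaction_pairs() == {
            ("A", "B"), ("A", "C"), ("B", "C"), ("D", "E"),
        }

    def test_ppi_filter_removes_pair(self):
        expr, tset, bic = engineered_bicluster()
        ppi = EdgeSet.from_pairs([("E", "D")], "ppi")
        module = infer_module(bic, expr, tset, ppi=ppi, p_cut=0.01, n_mirnas=40)
        assert ("D", "E") not in module.interaction_pairs()
        assert "D" not in module.sponge_ids and "E" not in module.sponge_ids

    def test_module_invariants(self):
        expr, tset, bic = engineered_bicluster()
        tf = EdgeSet.from_pairs([("A", "B")], "tf")
        ppi = EdgeSet.from_pairs([("D", "E")], "ppi")
        module = infer_module(bic, expr, tset, tf=tf, ppi=ppi, p_cut=0.01, n_mirnas=40)
        in_pairs = {g for p in module.interaction_pairs() for g in p}
        assert set(module.sponge_ids) == in_pairs  # no isolated sponges
        for pair in module.interaction_pairs():
            assert not tf.contains_unordered(pair)
            assert pair not in ppi
            assert set(pair) <= set(module.sponge_ids)

    def test_p_cut_monotone_nesting(self):
        expr, tset, bic = engineered_bicluster()
        loose = infer_module(bic, expr, tset, p_cut=0.05, n_mirnas=40)
        strict = infer_module(bic, expr, tset, p_cut=0.001, n_mirnas=40)
        assert strict.interaction_pairs() <= loose.interaction_pairs()


class TestRunPipeline:
    def test_recovers_implanted_modules(self, small_dataset):
        ds = small_dataset
        modules = run_pipeline(
            ds.mrna_expr, ds.mirna_expr, ds.binding,
            tf_edges=ds.tf_edges, ppi_edges=ds.ppi_edges, random_state=0,
        )
        assert modules
        truth_sets = [set(mr) for _, mr in ds.truth.modules]
        for truth in truth_sets:
            best = max(
                len(set(m.sponge_ids) & truth) / len(set(m.sponge_ids) | truth)
                for m in modules
            )
            assert best >= 0.7

    def test_planted_direct_interactions_filtered(self, small_dataset):
        ds = small_dataset
        modules = run_pipeline(
            ds.mrna_expr, ds.mirna_expr, ds.binding,
            tf_edges=ds.tf_edges, ppi_edges=ds.ppi_edges, random_state=0,
        )
        planted = ds.truth.planted_tf | ds.truth.planted_ppi
        for m in modules:
            assert not planted & m.interaction_pairs()

    def test_no_negative_scores_no_modules(self):
        # mRNAs mirror the miRNAs exactly: W = +1 everywhere, empty binding,
        # so S is non-negative and no target edge can be reconstructed
        rng = np.random.default_rng(0)
        profiles = rng.standard_normal((4, 30))
        cols = [f"s{i}" for i in range(30)]
        mirna = pd.DataFrame(profiles, index=[f"m{i}" for i in range(4)], columns=cols)
        mrna = pd.DataFrame(
            np.vstack([profiles, profiles]),
            index=[f"g{i}" for i in range(8)],
            columns=cols,
        )
        binding = pd.DataFrame(columns=["mirna", "mrna", "score"])
        modules = run_pipeline(mrna, mirna, binding, random_state=0)
        assert modules == []

    def test_deterministic_given_seed(self, small_dataset):
        ds = small_dataset
        kwargs = dict(tf_edges=ds.tf_edges, ppi_edges=ds.ppi_edges, random_state=5)
        m1 = run_pipeline(ds.mrna_expr, ds.mirna_expr, ds.binding, **kwargs)
        m2 = run_pipeline(ds.mrna_expr, ds.mirna_expr, ds.binding, **kwargs)
        assert m1 == m2

    def test_detector_exposes_stage_outputs(self, small_dataset):
        ds = small_dataset
        det = SpongeModuleDetector(random_state=0).fit(
            ds.mrna_expr, ds.mirna_expr, ds.binding,
            tf_edges=ds.tf_edges, ppi_edges=ds.ppi_edges,
        )
        assert det.scores_.shape == (ds.mrna_expr.shape[0], ds.mirna_expr.shape[0])
        assert det.correlation_.to_numpy().min() >= -1.0
        assert len(det.modules_) <= len(det.biclusters_)
        assert list(det.summary_.columns) == ["module", "n_mirnas", "n_sponges", "n_interactions"]
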