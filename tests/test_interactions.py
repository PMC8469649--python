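import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirswitch.errors import ConfigurationError, UndefinedStatisticError
from mirswitch.interactions import (InteractionTable, annotate_correlations,
                                    filter_anticorrelated, kendall_tau,
                                    merge_resources, restrict_to_expressed)

from conftest import build_study


def make_table(pairs, source="src", evidence="predicted"):
    return InteractionTable(records=pd.DataFrame(
        [{"mirna_id": m, "gene_id": g, "sources": frozenset([source]),
          "evidence": evidence} for m, g in pairs]), name=source)


class TestKendallTau:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3, 4], [1, 3, 2, 4], 2 / 3),
        ([1, 1, 2], [1, 2, 3], 2 / np.sqrt(6)),  # one tied pair in x
    ])
    def test_hand_counted_examples(self, x, y, expected):
        assert kendall_tau(x, y) == pytest.approx(expected, abs=1e-12)

    def test_all_tied_vector_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            kendall_tau([1, 1, 1], [1, 2, 3])

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5)),
                    min_size=3, max_size=8))
    def test_matches_brute_force_pair_count(self, pairs):
        x = np.array([a for a, _ in pairs], dtype=float)
        y = np.array([b for _, b in pairs], dtype=float)
        # independent brute force over all i<j pairs
        C = D = Tx = Ty = 0
        n = len(x)
        for i in range(n):
            for j in range(i + 1, n):
                sx = int(x[i] > x[j]) - int(x[i] < x[j])
                sy = int(y[i] > y[j]) - int(y[i] < y[j])
                if sx and sy:
                    if sx == sy:
                        C += 1
                    else:
                        D += 1
                elif sx and not sy:
                    Ty += 1
                elif sy and not sx:
                    Tx += 1
        denom = np.sqrt((C + D + Tx) * (C + D + Ty))
        if denom == 0:
            with pytest.raises(UndefinedStatisticError):
                kendall_tau(x, y)
            return
        assert kendall_tau(x, y) == pytest.approx((C - D) / denom, abs=0)
        # second, library-independent route
        ref = stats.kendalltau(x, y).statistic
        assert kendall_tau(x, y) == pytest.approx(ref, abs=1e-12)


class TestMerge:
    def test_sources_accumulate(self):
        t1 = make_table([("m1", "g1")], "A")
        t2 = make_table([("m1", "g1"), ("m2", "g2")], "B")
        merged = merge_resources([t1, t2])
        assert len(merged) == 2
        rec = merged.records.set_index(["mirna_id", "gene_id"])
        assert rec.loc[("m1", "g1"), "sources"] == frozenset({"A", "B"})

    def test_disjoint_tables_concatenate(self):
        merged = merge_resources([
            make_table([("m1", "g1"), ("m2", "g2"), ("m3", "g3")], "A"),
            make_table([("m4", "g4"), ("m5", "g5"), ("m6", "g6"), ("m7", "g7")], "B")])
        assert len(merged) == 7

    def test_experimental_wins(self):
        merged = merge_resources([
            make_table([("m1", "g1")], "A", "predicted"),
            make_table([("m1", "g1")], "B", "experimental")])
        assert merged.records.loc[0, "evidence"] == "experimental"

    def test_idempotent_associative_commutative(self):
        t1 = make_table([("m1", "g1"), ("m2", "g2")], "A")
        t2 = make_table([("m2", "g2"), ("m3", "g3")], "B")
        t3 = make_table([("m1", "g3")], "C")
        self_merge = merge_resources([t1, t1])
        assert self_merge.records.equals(merge_resources([t1]).records)
        left = merge_resources([merge_resources([t1, t2]), t3])
        right = merge_resources([t1, merge_resources([t2, t3])])
        swapped = merge_resources([t3, t2, t1])
        for other in (right, swapped):
            assert left.pairs() == other.pairs()
            assert left.records["sources"].tolist() == other.records["sources"].tolist()


class TestRestrict:
    def test_drops_unexpressed_members(self):
        table = make_table([("m1", "g1"), ("m1", "g2"), ("m2", "g1")])
        out = restrict_to_expressed(table, {"m1"}, {"g1"})
        assert out.pairs() == {("m1", "g1")}

    def test_empty_sets_empty_table(self):
        table = make_table([("m1", "g1")])
        assert len(restrict_to_expressed(table, set(), set())) == 0

    def test_commutes_with_merge(self):
        t1 = make_table([("m1", "g1"), ("m2", "g2")], "A")
        t2 = make_table([("m1", "g1"), ("m3", "g3")], "B")
        mirnas, genes = {"m1", "m3"}, {"g1", "g3"}
        a = restrict_to_expressed(merge_resources([t1, t2]), mirnas, genes)
        b = merge_resources([restrict_to_expressed(t1, mirnas, genes),
                             restrict_to_expressed(t2, mirnas, genes)])
        assert a.pairs() == b.pairs()


class TestAnnotate:
    def _studies(self):
        mirna = build_study({
            "m1": {0: [9.0], 4: [8.0], 8: [7.0], 12: [6.0], 16: [5.0]},
            "m2": {0: [5.0], 4: [5.0], 8: [5.0], 12: [5.0], 16: [5.0]},
        }, feature_kind="miRNA")
        mrna = build_study({
            "g1": {0: [5.0], 4: [6.0], 8: [7.0], 12: [8.0], 16: [9.0]},
            "g2": {0: [9.0], 4: [8.0], 8: [7.0], 12: [6.0], 16: [5.0]},
        })
        return mirna, mrna

    def test_antimonotone_pair_scores_minus_one(self):
        mirna, mrna = self._studies()
        out = annotate_correlations(make_table([("m1", "g1")]), mirna, mrna)
        assert out.loc[0, "tau"] == -1.0
        assert out.loc[0, "n_days"] == 5

    def test_identical_profiles_score_plus_one(self):
        mirna, mrna = self._studies()
        out = annotate_correlations(make_table([("m1", "g2")]), mirna, mrna)
        assert out.loc[0, "tau"] == 1.0

    def test_flat_mirna_is_skipped(self):
        mirna, mrna = self._studies()
        out = annotate_correlations(make_table([("m2", "g1")]), mirna, mrna)
        assert out.empty

    def test_day_grid_mismatch_is_a_configuration_error(self):
        mirna, _ = self._studies()
        other = build_study({"g1": {0: [5.0], 2: [6.0], 4: [7.0]}})
        with pytest.raises(ConfigurationError):
            annotate_correlations(make_table([("m1", "g1")]), mirna, other)

    def test_null_taus_average_near_zero(self):
        rng = np.random.default_rng(4)
        taus = []
        for _ in range(1000):
            taus.append(kendall_tau(rng.normal(size=5), rng.normal(size=5)))
        assert abs(np.mean(taus)) < 0.05


class TestFilterAnticorrelated:
    def test_threshold_is_strict(self):
        df = pd.DataFrame({"mirna_id": list("abc"), "gene_id": list("xyz"),
                           "tau": [-0.5, -0.2, 0.3], "n_days": 5})
        out = filter_anticorrelated(df, -0.2)
        assert out["tau"].tolist() == [-0.5]

    def test_chain_shrinks_monotonically(self):
        table = make_table([("m1", "g1"), ("m2", "g2")])
        restricted = restrict_to_expressed(table, {"m1", "m2"}, {"g1"})
        assert restricted.pairs() <= table.pairs()
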