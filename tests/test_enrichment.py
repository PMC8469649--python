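from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirswitch.enrichment import (OntologyDAG, conditional_enrichment,
                                  enrichment_frame, hypergeom_upper_tail,
                                  propagate_annotations)
from mirswitch.errors import OntologyStructureError, ValidationError


def exact_upper_tail(k, K, n, N):
    """Independent oracle: exact enumeration with rational arithmetic."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return float(total)


class TestPropagation:
    def _dag(self):
        return OntologyDAG(
            terms=["root", "p1", "p2", "c"],
            edges=[("p1", "root"), ("p2", "root"), ("c", "p1"), ("c", "p2")],
            direct_annotations={"c": {"g1"}, "p1": set(), "p2": {"g2"},
                                "root": set()})

    def test_child_genes_flow_to_all_parents(self):
        dag = propagate_annotations(self._dag())
        assert dag.propagated_annotations["p1"] == {"g1"}
        assert dag.propagated_annotations["p2"] == {"g1", "g2"}
        assert dag.propagated_annotations["root"] == {"g1", "g2"}

    def test_idempotent(self):
        once = propagate_annotations(self._dag())
        twice = propagate_annotations(once)
        assert once.propagated_annotations == twice.propagated_annotations

    def test_root_keeps_every_distinct_gene(self):
        dag = propagate_annotations(self._dag())
        everything = set().union(*dag.direct_annotations.values())
        assert dag.propagated_annotations["root"] == everything

    def test_cycle_is_reported(self):
        dag = OntologyDAG(terms=["a", "b"], edges=[("a", "b"), ("b", "a")],
                          direct_annotations={})
        with pytest.raises(OntologyStructureError):
            propagate_annotations(dag)


class TestHypergeom:
    @pytest.mark.parametrize("k,K,n,N,expected", [
        (0, 4, 5, 10, 1.0),
        (3, 4, 5, 10, 66 / 252),
        (5, 5, 5, 5, 1.0),
    ])
    def test_enumerated_examples(self, k, K, n, N, expected):
        assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(expected,
                                                                 abs=1e-12)

    def test_inconsistent_counts(self):
        with pytest.raises(ValidationError):
            hypergeom_upper_tail(6, 4, 5, 10)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.integers(1, 30), st.data())
    def test_matches_rational_enumeration(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
            exact_upper_tail(k, K, n, N), abs=1e-12)


class TestConditional:
    def _leaf_signal_fixture(self):
        """root <- parent <- child; the child carries the whole signal."""
        genes = [f"g{i}" for i in range(50)]
        selected = set(genes[:10])
        dag = OntologyDAG(
            terms=["root", "parent", "child"],
            edges=[("child", "parent"), ("parent", "root")],
            direct_annotations={"child": set(genes[:10]),
                                "parent": set(genes[10:15]),
                                "root": set(genes)})
        return dag, selected, set(genes)

    def test_parent_loses_significance_after_conditioning(self):
        dag, selected, universe = self._leaf_signal_fixture()
        res = {r.term: r for r in conditional_enrichment(dag, selected, universe)}
        assert res["child"].p_value <= 0.01
        # unconditional parent test would be significant by inclusion
        prop = propagate_annotations(dag).propagated_annotations
        p_uncond = hypergeom_upper_tail(10, len(prop["parent"]), 10, 50)
        assert p_uncond <= 0.01
        # conditioned on the child, nothing is left
        assert res["parent"].conditioned
        assert res["parent"].p_value == pytest.approx(1.0)
        assert res["parent"].excluded_genes == prop["child"]

    def test_conditioning_never_adds_significant_terms(self):
        dag, selected, universe = self._leaf_signal_fixture()
        cond = conditional_enrichment(dag, selected, universe)
        n_cond = sum(r.p_value <= 0.01 for r in cond)
        prop = propagate_annotations(dag).propagated_annotations
        n_uncond = sum(
            hypergeom_upper_tail(len(prop[t] & selected), len(prop[t]),
                                 len(selected), len(universe)) <= 0.01
            for t in dag.terms)
        assert n_cond <= n_uncond

    def test_no_significant_child_reduces_to_unconditional(self):
        genes = [f"g{i}" for i in range(40)]
        dag = OntologyDAG(
            terms=["root", "parent", "child"],
            edges=[("child", "parent"), ("parent", "root")],
            direct_annotations={"child": set(genes[20:25]),
                                "parent": set(genes[:20]), "root": set()})
        selected = set(genes[:10])
        res = {r.term: r for r in conditional_enrichment(dag, selected,
                                                         set(genes))}
        prop = propagate_annotations(dag).propagated_annotations
        expected = hypergeom_upper_tail(len(prop["parent"] & selected),
                                        len(prop["parent"]), 10, 40)
        assert not res["parent"].conditioned
        assert res["parent"].p_value == pytest.approx(expected, abs=1e-12)

    def test_result_independent_of_input_order(self):
        dag, selected, universe = self._leaf_signal_fixture()
        shuffled = OntologyDAG(terms=dag.terms[::-1], edges=dag.edges[::-1],
                               direct_annotations=dag.direct_annotations)
        a = enrichment_frame(conditional_enrichment(dag, selected, universe))
        b = enrichment_frame(conditional_enrichment(shuffled, selected, universe))
        merged = a.merge(b, on="term", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["p_a"], merged["p_b"], atol=1e-12)

    def test_selection_outside_universe_is_rejected(self):
        dag, selected, universe = self._leaf_signal_fixture()
        with pytest.raises(ValidationError):
            conditional_enrichment(dag, selected | {"alien"}, universe)
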