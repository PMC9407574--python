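"""Orientation rules: PC, FCI, entropy-reduction, path predicates."""

import pytest

from ctmi import ARROW, CIRCLE, TAIL, CTMIResult, SepsetStore, SummaryGraph
from ctmi.rules import (
    apply_er_rules,
    apply_fci_rule0,
    apply_fci_rules,
    apply_pc_rule0,
    apply_pc_rules,
    possible_dsep,
    possible_spurious_correlation,
)


def chain_graph(mode="cpdag", *edges, nodes=None):
    names = nodes or sorted({n for e in edges for n in e})
    g = SummaryGraph(names, mode=mode)
    for p, q in edges:
        g.add_edge(p, q)
    return g


def fake_pair(p, q, gamma, lam_pq=1, lam_qp=1):
    return CTMIResult(
        p=p, q=q, value=1.0, gamma_bar=gamma, lambda_pq=lam_pq, lambda_qp=lam_qp, n=100
    )


class TestPossibleSpuriousCorrelation:
    def test_triangle_has_spurious_path(self):
        g = chain_graph("cpdag", ("p", "q"), ("p", "r"), ("r", "q"))
        assert possible_spurious_correlation(g, "p", "q")

    def test_collider_blocks_path(self):
        g = chain_graph("cpdag", ("p", "q"), ("p", "r"), ("q", "r"))
        g.orient("p", "r")
        g.orient("q", "r")
        assert not possible_spurious_correlation(g, "p", "q")

    def test_isolated_edge(self):
        g = chain_graph("cpdag", ("p", "q"))
        assert not possible_spurious_correlation(g, "p", "q")


class TestPCRules:
    def test_rule0_unshielded_collider(self):
        g = chain_graph("cpdag", ("p", "r"), ("r", "q"))
        sepsets = SepsetStore()
        sepsets.set("p", "q", set())  # r not in sepset
        apply_pc_rule0(g, sepsets)
        assert g.mark("p", "r", "r") == ARROW
        assert g.mark("q", "r", "r") == ARROW

    def test_rule0_respects_sepset(self):
        g = chain_graph("cpdag", ("p", "r"), ("r", "q"))
        sepsets = SepsetStore()
        sepsets.set("p", "q", {"r"})
        apply_pc_rule0(g, sepsets)
        assert g.is_undetermined("p", "r")

    def test_rule1_propagates(self):
        g = chain_graph("cpdag", ("p", "r"), ("r", "q"))
        g.orient("p", "r")
        sepsets = SepsetStore()
        sepsets.set("p", "q", {"r"})
        apply_pc_rules(g, sepsets, rule0=False)
        assert g.is_directed("r", "q")

    def test_rule2_direct_path(self):
        g = chain_graph("cpdag", ("p", "r"), ("r", "q"), ("p", "q"))
        g.orient("p", "r")
        g.orient("r", "q")
        apply_pc_rules(g, SepsetStore(), rule0=False)
        assert g.is_directed("p", "q")

    def test_rule3(self):
        g = chain_graph(
            "cpdag", ("p", "r"), ("q", "r"), ("p", "s"), ("q", "s"), ("s", "r")
        )
        g.orient("p", "r")
        g.orient("q", "r")
        apply_pc_rules(g, SepsetStore(), rule0=False)
        assert g.is_directed("s", "r")

    def test_conflicting_demand_reverts_edge(self):
        """A rule demanding the opposite arrowhead leaves the edge
        undetermined and frozen rather than flip-flopping."""
        from ctmi.rules import _Orienter

        g = chain_graph("cpdag", ("p", "q"))
        g.orient("p", "q")
        o = _Orienter(g)
        assert not o.orient("q", "p")  # conflict
        assert g.is_undetermined("p", "q")
        assert not o.orient("p", "q")  # frozen afterwards
        assert g.is_undetermined("p", "q")

    def test_orientation_refuses_directed_cycle(self):
        """Closing a directed cycle over distinct series is a conflict:
        the offending edge reverts to undirected."""
        from ctmi.rules import _Orienter

        g = chain_graph("cpdag", ("a", "b"), ("b", "c"), ("c", "a"))
        o = _Orienter(g)
        assert o.orient("a", "b") and o.orient("b", "c")
        assert not o.orient("c", "a")
        assert g.is_undetermined("c", "a")
        g.validate()

    def test_termination_and_arrow_preservation(self):
        g = chain_graph("cpdag", ("p", "r"), ("r", "q"), ("p", "q"))
        g.orient("p", "r")
        before = g.directed_pairs()
        apply_pc_rules(g, SepsetStore(), rule0=False)
        assert before <= g.directed_pairs()  # never removes an arrowhead
        g.validate()


class TestERRules:
    def test_lag_rule_orients_positive_lag(self):
        g = chain_graph("cpdag", ("p", "q"))
        cache = {frozenset(("p", "q")): fake_pair("p", "q", gamma=2)}
        apply_er_rules(g, cache)
        assert g.is_directed("p", "q")

    def test_lag_rule_orients_negative_lag(self):
        g = chain_graph("cpdag", ("p", "q"))
        cache = {frozenset(("p", "q")): fake_pair("p", "q", gamma=-1)}
        apply_er_rules(g, cache)
        assert g.is_directed("q", "p")

    def test_window_rule_at_zero_lag(self):
        g = chain_graph("cpdag", ("p", "q"))
        cache = {frozenset(("p", "q")): fake_pair("p", "q", 0, lam_pq=1, lam_qp=2)}
        apply_er_rules(g, cache)
        assert g.is_directed("p", "q")

    def test_equal_windows_zero_lag_unchanged(self):
        g = chain_graph("cpdag", ("p", "q"))
        cache = {frozenset(("p", "q")): fake_pair("p", "q", 0, lam_pq=2, lam_qp=2)}
        apply_er_rules(g, cache)
        assert g.is_undetermined("p", "q")

    def test_spurious_path_blocks_orientation(self):
        g = chain_graph("cpdag", ("p", "q"), ("p", "r"), ("r", "q"))
        cache = {frozenset(("p", "q")): fake_pair("p", "q", gamma=2)}
        apply_er_rules(g, cache)
        assert g.is_undetermined("p", "q")

    def test_latent_mode_writes_arrowhead_only(self):
        g = chain_graph("pag", ("p", "q"))
        cache = {frozenset(("p", "q")): fake_pair("p", "q", gamma=1)}
        apply_er_rules(g, cache, latent=True)
        assert g.mark("p", "q", "q") == ARROW
        assert g.mark("p", "q", "p") == CIRCLE


class TestPossibleDsep:
    def test_collider_clause(self):
        g = chain_graph("pag", ("p", "s"), ("s", "r"), ("p", "q"))
        g.set_mark("p", "s", "s", ARROW)
        g.set_mark("s", "r", "s", ARROW)
        assert "r" in possible_dsep(g, "p", "q")

    def test_triangle_clause(self):
        g = chain_graph("pag", ("p", "s"), ("s", "r"), ("p", "r"), ("p", "q"))
        assert "r" in possible_dsep(g, "p", "q")

    def test_non_collider_chain_excluded(self):
        g = chain_graph("pag", ("p", "s"), ("s", "r"), ("p", "q"))
        # s is not a collider (circle marks) and p, r are not adjacent
        assert "r" not in possible_dsep(g, "p", "q")

    def test_unreachable_node_excluded(self):
        g = SummaryGraph(["p", "q", "r"], mode="pag")
        g.add_edge("p", "q")
        assert possible_dsep(g, "p", "q") == set()


class TestFCIRules:
    def test_rule0_collider_with_circles(self):
        g = chain_graph("pag", ("p", "r"), ("r", "q"))
        sepsets = SepsetStore()
        sepsets.set("p", "q", set())
        apply_fci_rule0(g, sepsets)
        assert g.mark("p", "r", "r") == ARROW
        assert g.mark("q", "r", "r") == ARROW
        assert g.mark("p", "r", "p") == CIRCLE  # cause end stays undetermined

    def test_rule1(self):
        g = chain_graph("pag", ("p", "r"), ("r", "q"))
        g.set_mark("p", "r", "r", ARROW)
        sepsets = SepsetStore()
        sepsets.set("p", "q", {"r"})
        apply_fci_rules(g, sepsets)
        assert g.mark("r", "q", "q") == ARROW
        assert g.mark("r", "q", "r") == TAIL

    def test_rule2(self):
        g = chain_graph("pag", ("p", "r"), ("r", "q"), ("p", "q"))
        g.orient("p", "r")                      # p -> r
        g.set_mark("r", "q", "q", ARROW)        # r *-> q
        apply_fci_rules(g, SepsetStore())
        assert g.mark("p", "q", "q") == ARROW

    def test_rule3(self):
        g = chain_graph(
            "pag", ("p", "r"), ("q", "r"), ("p", "s"), ("q", "s"), ("s", "r")
        )
        g.set_mark("p", "r", "r", ARROW)
        g.set_mark("q", "r", "r", ARROW)
        apply_fci_rules(g, SepsetStore())
        assert g.mark("s", "r", "r") == ARROW

    def test_rule8(self):
        g = chain_graph("pag", ("p", "r"), ("r", "q"), ("p", "q"))
        g.orient("p", "r")
        g.orient("r", "q")
        g.set_mark("p", "q", "q", ARROW)
        g.set_mark("p", "q", "p", CIRCLE)
        apply_fci_rules(g, SepsetStore())
        assert g.mark("p", "q", "p") == TAIL

    def test_rule9(self):
        # p o-> q plus an uncovered potentially directed path p - r - s - q
        g = chain_graph("pag", ("p", "q"), ("p", "r"), ("r", "s"), ("s", "q"))
        g.set_mark("p", "q", "q", ARROW)
        apply_fci_rules(g, SepsetStore())
        assert g.mark("p", "q", "p") == TAIL

    def test_termination_on_dense_graph(self):
        g = SummaryGraph.complete(list("abcde"), mode="pag")
        sepsets = SepsetStore()
        apply_fci_rules(g, sepsets)  # must reach a fixed point
        g.validate()
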