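"""Profile set algebra, overlap tallies, and hypergeometric ORA vs. oracle."""

from fractions import Fraction
from math import comb

import pytest

from synergyseek.diffexpr import DEGeneSet
from synergyseek.io import GeneSetCollection
from synergyseek.signatures import (
    ExpressionSignature,
    build_resist_profile,
    build_response_profile,
    ora_enrichment,
    overlap_report,
)


def de_set(cl, tr, up=(), down=()):
    return DEGeneSet(cell_line=cl, treatment=tr, up=frozenset(up), down=frozenset(down))


@pytest.fixture
def de_map():
    return {
        ("R", "DNR"): de_set("R", "DNR", up={"a", "b", "c", "x"}, down={"d", "e"}),
        ("R", "COMBO"): de_set("R", "COMBO", up={"q"}, down=set()),
        ("S1", "DNR"): de_set("S1", "DNR", up={"b", "p", "q"}, down={"a", "r"}),
        ("S1", "COMBO"): de_set("S1", "COMBO", up={"c", "p", "q"}, down={"r"}),
        ("S2", "DNR"): de_set("S2", "DNR", up={"p", "q"}, down={"r", "e"}),
        ("S2", "COMBO"): de_set("S2", "COMBO", up={"p", "q"}, down={"r"}),
    }


class TestResistProfile:
    def test_unique_gene_retained(self, de_map):
        prof = build_resist_profile(de_map, "R", ["S1", "S2"], "DNR", "COMBO")
        assert "x" in prof.up  # up only in (R, DNR)

    def test_gene_shared_with_sensitive_combo_excluded(self, de_map):
        prof = build_resist_profile(de_map, "R", ["S1", "S2"], "DNR", "COMBO")
        assert "c" not in prof.up  # up in (S1, COMBO)
        assert "b" not in prof.up  # up in (S1, DNR)

    def test_direction_specific_exclusion(self, de_map):
        # "a" is up in (R, DNR) but only DOWN in S1; same-direction rule keeps it
        prof = build_resist_profile(de_map, "R", ["S1", "S2"], "DNR", "COMBO")
        assert "a" in prof.up
        # "e" is down in (R, DNR) and down in (S2, DNR): excluded
        assert "e" not in prof.down
        assert "d" in prof.down

    def test_no_same_direction_leakage(self, de_map):
        prof = build_resist_profile(de_map, "R", ["S1", "S2"], "DNR", "COMBO")
        for s in ("S1", "S2"):
            for t in ("DNR", "COMBO"):
                assert not prof.up & de_map[(s, t)].up
                assert not prof.down & de_map[(s, t)].down

    def test_missing_required_set_named(self, de_map):
        del de_map[("S2", "COMBO")]
        with pytest.raises(KeyError, match="S2.*COMBO"):
            build_resist_profile(de_map, "R", ["S1", "S2"], "DNR", "COMBO")


class TestResponseProfile:
    def test_common_to_all_sensitive_absent_from_resistant(self, de_map):
        prof = build_response_profile(de_map, "R", ["S1", "S2"], "DNR", "COMBO")
        assert "p" in prof.up  # in all four sensitive sets, not in R
        assert "r" in prof.down

    def test_intersection_rule_excludes_single_set_gene(self, de_map):
        prof = build_response_profile(de_map, "R", ["S1", "S2"], "DNR", "COMBO")
        assert "b" not in prof.up  # only in (S1, DNR)

    def test_resistant_presence_excludes(self, de_map):
        prof = build_response_profile(de_map, "R", ["S1", "S2"], "DNR", "COMBO")
        assert "q" not in prof.up  # up in (R, COMBO)

    def test_subset_of_every_sensitive_condition_set(self, de_map):
        prof = build_response_profile(de_map, "R", ["S1", "S2"], "DNR", "COMBO")
        for s in ("S1", "S2"):
            for t in ("DNR", "COMBO"):
                assert prof.up <= de_map[(s, t)].up
                assert prof.down <= de_map[(s, t)].down


class TestOverlapReport:
    def test_identical_sets_100_percent(self):
        de = {
            ("A", "t1"): de_set("A", "t1", up={"a", "b"}),
            ("A", "t2"): de_set("A", "t2", up={"a", "b"}),
        }
        rep = overlap_report(de, mode="by_treatment")
        row = rep[(rep.direction == "up")].iloc[0]
        assert row.pct == 100.0

    def test_disjoint_sets_0_percent(self):
        de = {
            ("A", "t1"): de_set("A", "t1", up={"a"}),
            ("A", "t2"): de_set("A", "t2", up={"b"}),
        }
        rep = overlap_report(de, mode="by_treatment")
        assert rep[(rep.direction == "up")].iloc[0].pct == 0.0

    def test_union_denominator(self):
        # A={a,b}, B={b,c}: shared 1, union denominator 3
        de = {
            ("A", "t1"): de_set("A", "t1", up={"a", "b"}),
            ("A", "t2"): de_set("A", "t2", up={"b", "c"}),
        }
        row = overlap_report(de, mode="by_treatment").query("direction == 'up'").iloc[0]
        assert row.shared == 1 and row.denominator == 3
        assert row.pct == pytest.approx(100.0 / 3.0)

    def test_by_cell_line_mode(self):
        de = {
            ("A", "t"): de_set("A", "t", up={"a", "b"}),
            ("B", "t"): de_set("B", "t", up={"b", "c"}),
        }
        rep = overlap_report(de, mode="by_cell_line")
        row = rep.query("direction == 'up'").iloc[0]
        assert (row.item_a, row.item_b) == ("A", "B")
        assert row.shared == 1


def hypergeom_upper_oracle(k, N, K, n):
    """Exact upper-tail P[X >= k] by pmf enumeration with rational arithmetic."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
    return float(total)


class TestORA:
    def test_perfect_overlap_combinatorial_p(self):
        # pathway == query == 5 genes out of a 20-gene universe: p = 1/C(20,5)
        genes = [f"g{i}" for i in range(20)]
        query = set(genes[:5])
        gc = GeneSetCollection(sets={"P": frozenset(query)})
        (row,) = ora_enrichment(query, gc, genes)
        assert row.pvalue == pytest.approx(1.0 / comb(20, 5), rel=1e-9)

    def test_zero_overlap_p_one(self):
        genes = [f"g{i}" for i in range(20)]
        gc = GeneSetCollection(sets={"P": frozenset(genes[10:15])})
        (row,) = ora_enrichment(set(genes[:3]), gc, genes)
        assert row.pvalue == 1.0

    def test_matches_enumeration_oracle(self, rng):
        genes = [f"g{i}" for i in range(30)]
        for _ in range(20):
            K = int(rng.integers(1, 15))
            n = int(rng.integers(1, 15))
            pathway = frozenset(rng.choice(genes, size=K, replace=False))
            query = frozenset(rng.choice(genes, size=n, replace=False))
            gc = GeneSetCollection(sets={"P": pathway})
            (row,) = ora_enrichment(query, gc, genes)
            k = len(query & pathway)
            assert row.pvalue == pytest.approx(
                hypergeom_upper_oracle(k, 30, K, n), rel=1e-9
            )

    def test_query_outside_universe_dropped_with_warning(self):
        genes = [f"g{i}" for i in range(10)]
        gc = GeneSetCollection(sets={"P": frozenset(genes[:3])})
        with pytest.warns(UserWarning, match="outside the universe"):
            (row,) = ora_enrichment(set(genes[:2]) | {"alien"}, gc, genes)
        assert row.query_size == 2

    def test_empty_universe_rejected(self):
        gc = GeneSetCollection(sets={"P": frozenset({"a"})})
        with pytest.raises(ValueError, match="universe"):
            ora_enrichment({"a"}, gc, set())


class TestSignatureInvariants:
    def test_overlapping_up_down_rejected(self):
        with pytest.raises(ValueError):
            ExpressionSignature("x", frozenset({"a"}), frozenset({"a"}))

    def test_empty_signature_rejected(self):
        with pytest.raises(ValueError):
            ExpressionSignature("x", frozenset(), frozenset())
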