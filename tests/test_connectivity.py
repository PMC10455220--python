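"""Enrichment-score machinery against a brute-force oracle, and filters."""

import itertools

import numpy as np
import pytest

from synergyseek.connectivity import (
    ConnectivityResult,
    enrichment_score,
    normalize_scores,
    predict_partners,
    wtcs,
)
from synergyseek.io import RankedReferenceSignature
from synergyseek.signatures import ExpressionSignature


def make_ranked(n, pid="p", ptype="compound", target="", cl="cl1", scores=None):
    genes = [f"g{i:02d}" for i in range(1, n + 1)]
    if scores is None:
        scores = np.arange(n, 0, -1, dtype=float)
    return RankedReferenceSignature(
        perturbagen_id=pid, pert_type=ptype, target_gene=target, cell_line=cl,
        genes=genes, scores=np.asarray(scores, dtype=float),
    )


def es_oracle(hit_positions, n):
    """Brute-force running sum at weight 0; positions are 1-based ranks."""
    hits = set(hit_positions)
    nh = len(hits)
    running, best = 0.0, 0.0
    for pos in range(1, n + 1):
        running += 1.0 / nh if pos in hits else -1.0 / (n - nh)
        if abs(running) > abs(best):
            best = running
    return best


class TestEnrichmentScore:
    def test_extreme_top_is_one(self):
        ranked = make_ranked(10)
        assert enrichment_score({"g01", "g02"}, ranked) == pytest.approx(1.0)

    def test_extreme_bottom_is_minus_one(self):
        ranked = make_ranked(10)
        assert enrichment_score({"g09", "g10"}, ranked) == pytest.approx(-1.0)

    def test_hand_computed_alternating(self):
        # N=4, hits at ranks {1,3}: running +0.5, 0, +0.5, 0 -> es 0.5
        ranked = make_ranked(4)
        assert enrichment_score({"g01", "g03"}, ranked) == pytest.approx(0.5)

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_exhaustive_subsets_match_oracle(self, n):
        ranked = make_ranked(n)
        for size in range(1, n + 1):
            for combo in itertools.combinations(range(1, n + 1), size):
                query = {f"g{i:02d}" for i in combo}
                assert enrichment_score(query, ranked) == pytest.approx(
                    es_oracle(combo, n)
                ), combo

    def test_reversing_list_negates_es(self, rng):
        n = 30
        ranked = make_ranked(n)
        reversed_ranked = make_ranked(n, scores=np.arange(1, n + 1, dtype=float))
        for _ in range(10):
            query = {f"g{i:02d}" for i in rng.choice(np.arange(1, n + 1), size=6, replace=False)}
            assert enrichment_score(query, ranked) == pytest.approx(
                -enrichment_score(query, reversed_ranked)
            )

    def test_disjoint_query_zero_with_warning(self):
        ranked = make_ranked(5)
        with pytest.warns(UserWarning, match="no gene"):
            assert enrichment_score({"absent"}, ranked) == 0.0

    def test_weighted_scores_shift_es(self):
        scores = np.array([100.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        ranked = make_ranked(6, scores=scores)
        es_w = enrichment_score({"g01", "g04"}, ranked, weight=1.0)
        es_0 = enrichment_score({"g01", "g04"}, ranked, weight=0.0)
        assert es_w > es_0  # heavy top hit dominates at weight 1


class TestWTCS:
    def test_opposite_signs_averaged(self):
        # engineered: up hits top (es_up ~ +), down hits bottom (es_down ~ -)
        ranked = make_ranked(10)
        a, b, w = wtcs({"g01", "g02"}, {"g09", "g10"}, ranked)
        assert (a, b) == (pytest.approx(1.0), pytest.approx(-1.0))
        assert w == pytest.approx(1.0)

    def test_same_sign_gives_zero(self):
        ranked = make_ranked(10)
        a, b, w = wtcs({"g01", "g02"}, {"g03", "g04"}, ranked)
        assert a > 0 and b > 0
        assert w == 0.0

    def test_empty_up_negates_down_es(self):
        ranked = make_ranked(10)
        _, b, w = wtcs(set(), {"g09", "g10"}, ranked)
        assert b == pytest.approx(-1.0)
        assert w == pytest.approx(1.0)

    def test_overlapping_sets_rejected(self):
        ranked = make_ranked(5)
        with pytest.raises(ValueError, match="overlap"):
            wtcs({"g01"}, {"g01"}, ranked)

    def test_invariant_to_outside_relabeling(self):
        # wtcs depends only on positions of up/down genes, not other labels
        up, down = {"g01"}, {"g05"}
        base = make_ranked(5)
        relabeled = RankedReferenceSignature(
            perturbagen_id="p", pert_type="compound", target_gene="", cell_line="cl1",
            genes=["g01", "xx", "yy", "zz", "g05"], scores=np.arange(5, 0, -1, dtype=float),
        )
        assert wtcs(up, down, base)[2] == pytest.approx(wtcs(up, down, relabeled)[2])


def cres(pid, cl, w, ptype="compound", target=""):
    return ConnectivityResult(
        perturbagen_id=pid, pert_type=ptype, target_gene=target, cell_line=cl,
        es_up=0.0, es_down=0.0, wtcs=w,
    )


class TestNCS:
    def test_group_mean_normalization(self):
        rs = [cres("a", "c", 0.2), cres("b", "c", 0.4)]
        normalize_scores(rs)
        assert rs[0].ncs == pytest.approx(0.2 / 0.3)
        assert rs[1].ncs == pytest.approx(0.4 / 0.3)

    def test_singleton_is_plus_minus_one(self):
        rs = [cres("a", "c", -0.5)]
        normalize_scores(rs)
        assert rs[0].ncs == pytest.approx(-1.0)

    def test_zero_wtcs_zero_ncs(self):
        rs = [cres("a", "c", 0.0), cres("b", "c", 0.3)]
        normalize_scores(rs)
        assert rs[0].ncs == 0.0

    def test_mean_abs_ncs_is_one_per_sign(self, rng):
        rs = [cres(f"p{i}", "c", float(w)) for i, w in enumerate(rng.normal(size=40))]
        normalize_scores(rs)
        pos = [r.ncs for r in rs if r.wtcs > 0]
        neg = [abs(r.ncs) for r in rs if r.wtcs < 0]
        assert np.mean(pos) == pytest.approx(1.0)
        assert np.mean(neg) == pytest.approx(1.0)


def planted_library(n=40, rng=None, decoy_kd=True):
    """Tiny handcrafted library: one reverser compound + its target KD,
    one ambiguous KD/OE pair, decoys."""
    rng = rng or np.random.default_rng(7)
    genes = [f"g{i:02d}" for i in range(1, n + 1)]
    up, down = set(genes[:5]), set(genes[-5:])

    def reverser():
        s = rng.normal(size=n)
        s[:5] -= 10  # query-up at the bottom -> reverses
        s[-5:] += 10
        return s

    def mimic():
        s = rng.normal(size=n)
        s[:5] += 10
        s[-5:] -= 10
        return s

    sigs = []
    for cl in ("c1", "c2"):
        sigs.append(RankedReferenceSignature("drugX", "compound", "TGT", cl, list(genes), reverser()))
        sigs.append(RankedReferenceSignature("KD_TGT", "knockdown", "TGT", cl, list(genes), reverser()))
        sigs.append(RankedReferenceSignature("KD_AMB", "knockdown", "AMB", cl, list(genes), reverser()))
        sigs.append(RankedReferenceSignature("OE_AMB", "overexpression", "AMB", cl, list(genes), reverser()))
        for k in range(8):
            sigs.append(RankedReferenceSignature(f"dec{k}", "compound", "", cl, list(genes), rng.normal(size=n)))
            if decoy_kd:
                sigs.append(
                    RankedReferenceSignature(f"KD_dec{k}", "knockdown", f"D{k}", cl, list(genes), rng.normal(size=n))
                )
    resist = ExpressionSignature("DNRResist", frozenset(up), frozenset(down))
    # response profile mimicked by the planted perturbagens: swap directions
    response = ExpressionSignature("DNRResponse", frozenset(down), frozenset(up))
    return resist, response, sigs


class TestPredictPartners:
    def test_planted_reverser_class_ranked_first(self):
        resist, response, lib = planted_library()
        cands = predict_partners(resist, response, lib)
        assert cands, "no candidates returned"
        assert cands[0].class_name == "TGT"
        assert "drugX" in cands[0].members

    def test_ambiguous_pair_removed(self):
        resist, response, lib = planted_library()
        cands = predict_partners(resist, response, lib)
        members = {m for c in cands for m in c.members}
        assert not members & {"KD_AMB", "OE_AMB"}

    def test_unannotated_compounds_never_ranked(self):
        resist, response, lib = planted_library()
        cands = predict_partners(resist, response, lib)
        members = {m for c in cands for m in c.members}
        assert not any(m.startswith("dec") for m in members)

    def test_row_order_invariance(self):
        resist, response, lib = planted_library()
        shuffled = list(reversed(lib))
        a = predict_partners(resist, response, lib)
        b = predict_partners(resist, response, shuffled)
        assert [(c.class_name, c.n_support_cell_lines, c.members) for c in a] == [
            (c.class_name, c.n_support_cell_lines, c.members) for c in b
        ]

    def test_empty_library_rejected(self):
        resist, response, _ = planted_library()
        with pytest.raises(ValueError, match="empty"):
            predict_partners(resist, response, [])
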