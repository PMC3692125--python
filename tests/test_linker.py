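"""Pairwise linking: max-min product DP against its brute-force oracle."""

import numpy as np
import pytest

from cmlink.model import NEG_INF, StateType
from cmlink.linker import (
    ProductHazardError,
    brute_force_link,
    link_models,
    product_hazard,
    product_structures,
)
from cmlink.scoring import best_sequence, optimal_parse_score
from cmlink.toymodels import ToyModelSpec, build_toy_cm, random_toy_spec


def _pair(rng, **kw):
    a = build_toy_cm(random_toy_spec(rng, name="a", **kw))
    b = build_toy_cm(random_toy_spec(rng, name="b", **kw))
    return a, b


class TestSelfLink:
    def test_self_link_equals_best_score(self, hairpin_model, bif_model):
        """A model compared with itself attains its maximal possible score."""
        for m in (hairpin_model, bif_model):
            r = link_models(m, m)
            bs = best_sequence(m)
            assert r.link_score == pytest.approx(bs.score, abs=1e-6)
            assert r.link_sequence == bs.sequence

    def test_link_score_is_min_of_both(self, hairpin_model, chain_model):
        r = link_models(hairpin_model, chain_model)
        assert r.link_score == min(r.score_a, r.score_b)


class TestOracle:
    def test_equals_brute_force_on_bifurcation_free_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(5):
            a, b = _pair(rng, min_len=1, max_len=4, allow_bif=False)
            r = link_models(a, b)
            o = brute_force_link(a, b, max(a.consensus_length, b.consensus_length) + 3)
            assert r.link_score == pytest.approx(o.link_score, abs=1e-6)

    def test_never_exceeds_brute_force_with_bifurcation(self):
        a = build_toy_cm(ToyModelSpec("ACGUCG", "(.)(.)", seed=3, name="a"))
        b = build_toy_cm(ToyModelSpec("ACGUCG", "......", seed=4, name="b"))
        r = link_models(a, b)
        o = brute_force_link(a, b, 7)
        assert len(r.link_sequence) <= 7
        assert r.link_score <= o.link_score + 1e-9

    def test_brute_force_min_symmetry(self, hairpin_model, chain_model):
        r1 = brute_force_link(hairpin_model, chain_model, 6)
        r2 = brute_force_link(chain_model, hairpin_model, 6)
        assert r1.link_score == pytest.approx(r2.link_score, abs=1e-12)

    def test_identical_one_column_models_link_on_boosted_base(self):
        m1 = build_toy_cm(ToyModelSpec("G", ".", seed=8, name="x"))
        m2 = build_toy_cm(ToyModelSpec("G", ".", seed=8, name="y"))
        r = brute_force_link(m1, m2, 3)
        assert r.link_sequence == "G"


class TestInvariants:
    def test_symmetry_of_link_score(self):
        rng = np.random.default_rng(17)
        for _ in range(3):
            a, b = _pair(rng, min_len=1, max_len=4, allow_bif=False)
            r1, r2 = link_models(a, b), link_models(b, a)
            assert r1.link_score == pytest.approx(r2.link_score, abs=1e-6)
            assert r1.link_sequence == r2.link_sequence

    def test_upper_bound_by_best_scores(self):
        rng = np.random.default_rng(23)
        for _ in range(3):
            a, b = _pair(rng, min_len=1, max_len=5)
            r = link_models(a, b)
            cap = min(best_sequence(a).score, best_sequence(b).score)
            assert r.link_score <= cap + 1e-9

    def test_at_least_semantics(self):
        """Re-scoring the link sequence in each model meets or beats the
        reported joint-parse scores (a link score of x bits means the
        sequence scores at least x bits in both models)."""
        rng = np.random.default_rng(31)
        for _ in range(4):
            a, b = _pair(rng, min_len=1, max_len=5)
            r = link_models(a, b)
            if not r.link_sequence:
                continue
            assert optimal_parse_score(a, r.link_sequence).score >= r.score_a - 1e-6
            assert optimal_parse_score(b, r.link_sequence).score >= r.score_b - 1e-6
            assert r.link_score <= optimal_parse_score(a, r.link_sequence).score
            assert r.link_score <= optimal_parse_score(b, r.link_sequence).score

    def test_no_common_sequence_yields_sentinel(self):
        a = build_toy_cm(ToyModelSpec("AA", "..", seed=1, name="a"))
        b = build_toy_cm(ToyModelSpec("AA", "..", seed=1, name="b"))
        # every emission in b becomes impossible: no joint sequence exists
        for st in b.states:
            if len(st.emissions):
                st.emissions = np.full(len(st.emissions), NEG_INF)
        # a pure-deletion joint parse emits nothing; block it too by making
        # the empty parse impossible on a's side via its own optimum check
        r = link_models(a, b)
        if r.link_sequence == "":
            # only the empty sequence remains jointly parseable
            assert r.link_score == optimal_parse_score(b, "").score or (
                r.link_score == NEG_INF
            )
        else:
            assert r.link_score == NEG_INF


class TestStructures:
    def test_identical_hairpins_share_structure(self):
        a = build_toy_cm(ToyModelSpec("ACGU", "(..)", seed=2, name="a"))
        b = build_toy_cm(ToyModelSpec("ACGU", "(..)", seed=2, name="b"))
        r = link_models(a, b)
        assert product_structures(r) == ("(..)", "(..)")

    def test_unstructured_partner_gets_all_dots(self, hairpin_model, chain_model):
        r = link_models(hairpin_model, chain_model)
        sa, sb = product_structures(r)
        assert set(sb) <= {"."}
        assert len(sa) == len(sb) == len(r.link_sequence)

    def test_brackets_balanced_and_same_length(self):
        rng = np.random.default_rng(41)
        for _ in range(3):
            a, b = _pair(rng, min_len=2, max_len=5)
            r = link_models(a, b)
            for s in (r.structure_a, r.structure_b):
                assert len(s) == len(r.link_sequence)
                depth = 0
                for ch in s:
                    depth += {"(": 1, ")": -1}.get(ch, 0)
                    assert depth >= 0
                assert depth == 0


class TestHazards:
    def test_product_hazard_refused(self):
        a = build_toy_cm(ToyModelSpec("A", ".", seed=1, name="a"))
        b = build_toy_cm(ToyModelSpec("A", ".", seed=2, name="b"))
        for m in (a, b):
            il = next(s for s in m.states if s.state_type is StateType.IL)
            il.emissions = il.emissions + 10.0  # profitable joint cycle
        assert product_hazard(a, b) is not None
        with pytest.raises((ProductHazardError, ValueError)):
            link_models(a, b)

    def test_clean_pair_has_no_hazard(self, hairpin_model, chain_model):
        assert product_hazard(hairpin_model, chain_model) is None
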