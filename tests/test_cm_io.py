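"""CM file reading, writing, toy construction and validation."""

import numpy as np
import pytest

from cmlink.alphabet import AlphabetError
from cmlink.cm_io import (
    CMFormatError,
    CMValidationError,
    build_from_stockholm,
    parse_cm_file,
    write_cm_file,
)
from cmlink.model import (
    NEG_INF,
    Dialect,
    NodeType,
    StateType,
    validate_model,
)
from cmlink.toymodels import (
    StructureError,
    ToyModelSpec,
    build_toy_cm,
    random_toy_spec,
)

MINIMAL_RECORD = """\
INFERNAL-1 [1.0]
NAME     mini
STATES   7
NODES    3
CLEN     1
ALPH     RNA
NULL     0.0 0.0 0.0 0.0
MODEL:
    [ ROOT 0 ]
     S     0     1     3  -0.10000 -5.00000 -5.00000
    IL     1     1     3  -4.00000 -4.50000 -0.20000  0.0 0.0 0.0 0.0
    IR     2     2     2  -4.00000 -0.30000  0.0 0.0 0.0 0.0
    [ MATL 1 ]
    ML     3     5     2  -4.00000 -0.10000  1.00000 -1.00000 -1.00000 -1.00000
     D     4     5     2  -4.00000 -0.10000
    IL     5     5     2  -4.00000 -0.10000  0.0 0.0 0.0 0.0
    [ END 2 ]
     E     6    -1     0
//
"""


def models_equal(m1, m2, tol=1e-4):
    assert m1.name == m2.name
    assert m1.consensus_length == m2.consensus_length
    assert len(m1.states) == len(m2.states)
    assert [n.node_type for n in m1.nodes] == [n.node_type for n in m2.nodes]
    assert np.allclose(m1.null, m2.null, atol=tol)
    for s1, s2 in zip(m1.states, m2.states):
        assert s1.state_type == s2.state_type
        assert s1.bif_children == s2.bif_children
        assert sorted(s1.transitions) == sorted(s2.transitions)
        for k, v in s1.transitions.items():
            assert s2.transitions[k] == pytest.approx(v, abs=tol)
        assert len(s1.emissions) == len(s2.emissions)
        if len(s1.emissions):
            np.testing.assert_allclose(s1.emissions, s2.emissions, atol=tol)


class TestParse:
    def test_minimal_hand_written_record(self):
        """ROOT + MATL + END: 7 states, single match column, one ML state."""
        (m,) = parse_cm_file(MINIMAL_RECORD)
        assert m.consensus_length == 1
        assert m.dialect is Dialect.INFERNAL_1_0
        types = [s.state_type for s in m.states]
        assert types.count(StateType.ML) == 1
        assert types == [
            StateType.S, StateType.IL, StateType.IR,
            StateType.ML, StateType.D, StateType.IL, StateType.E,
        ]
        assert [n.node_type for n in m.nodes] == [
            NodeType.ROOT, NodeType.MATL, NodeType.END,
        ]
        # emission converted against the uniform null: stored bits unchanged
        assert m.states[3].emission(0) == pytest.approx(1.0, abs=1e-6)

    def test_two_concatenated_records(self):
        doc = MINIMAL_RECORD + MINIMAL_RECORD.replace("NAME     mini", "NAME     mini2")
        models = parse_cm_file(doc)
        assert [m.name for m in models] == ["mini", "mini2"]

    def test_impossibility_marker_maps_to_sentinel(self):
        doc = MINIMAL_RECORD.replace(
            "1.00000 -1.00000 -1.00000 -1.00000", "1.00000 * -1.00000 -1.00000"
        )
        (m,) = parse_cm_file(doc)
        assert m.states[3].emission(1) == NEG_INF

    def test_malformed_header_names_line(self):
        with pytest.raises(CMFormatError, match="line 1"):
            parse_cm_file("INFERNAL-9000 [x]\n")

    def test_unknown_state_type(self):
        doc = MINIMAL_RECORD.replace("    IR     2", "    XX     2")
        with pytest.raises(CMFormatError, match="unknown state type"):
            parse_cm_file(doc)

    def test_out_of_range_transition_is_validation_error(self):
        doc = MINIMAL_RECORD.replace(
            "     S     0     1     3", "     S     0     5     3"
        )
        with pytest.raises(CMValidationError):
            parse_cm_file(doc)

    def test_not_a_cm_document(self):
        with pytest.raises(CMFormatError, match="expected an INFERNAL header"):
            parse_cm_file("hello world\n")


class TestWrite:
    def test_empty_list_gives_empty_document(self):
        assert write_cm_file([], Dialect.INFERNAL_1_0) == ""

    @pytest.mark.parametrize("dialect", list(Dialect))
    def test_round_trip_single_model(self, hairpin_model, dialect):
        doc = write_cm_file([hairpin_model], dialect)
        (back,) = parse_cm_file(doc)
        assert back.dialect is dialect
        models_equal(hairpin_model, back)

    def test_bifurcation_children_serialized(self, bif_model):
        doc = write_cm_file([bif_model], Dialect.INFERNAL_1_0)
        b_state = next(
            s for s in bif_model.states if s.state_type is StateType.B
        )
        left, right = b_state.bif_children
        b_lines = [ln for ln in doc.splitlines() if ln.strip().startswith("B ")]
        assert len(b_lines) == 1
        toks = b_lines[0].split()
        assert (int(toks[2]), int(toks[3])) == (left, right)
        models_equal(bif_model, parse_cm_file(doc)[0])

    def test_multi_model_round_trip(self, hairpin_model, chain_model, bif_model):
        doc = write_cm_file(
            [hairpin_model, chain_model, bif_model], Dialect.INFERNAL_1_1
        )
        back = parse_cm_file(doc)
        assert [m.name for m in back] == ["hairpin", "chain", "twohp"]

    def test_extras_preserved(self, single_column_model):
        m = single_column_model
        m2 = build_toy_cm(ToyModelSpec("A", ".", seed=1, name="one"))
        m2.extras = ["COM      built by hand", "CKSUM    12345"]
        doc = write_cm_file([m2], Dialect.INFERNAL_1_0)
        (back,) = parse_cm_file(doc)
        assert back.extras == m2.extras


@pytest.mark.parametrize("seed", range(50))
@pytest.mark.parametrize("dialect", list(Dialect))
def test_round_trip_seeded_specs(seed, dialect):
    """parse(write(M)) == M within 1e-4 bits for many random models."""
    rng = np.random.default_rng(seed)
    m = build_toy_cm(random_toy_spec(rng, name=f"rt{seed}"))
    models_equal(m, parse_cm_file(write_cm_file([m], dialect))[0])


class TestBuildToyCm:
    def test_deterministic_given_seed(self):
        spec = ToyModelSpec("A", ".", match_emit_boost=2, transition_spread=0.1, seed=1)
        m1, m2 = build_toy_cm(spec), build_toy_cm(spec)
        models_equal(m1, m2, tol=0.0)

    def test_paired_columns_become_matp(self):
        m = build_toy_cm(ToyModelSpec("ACGU", "(..)"))
        assert [n.node_type for n in m.nodes].count(NodeType.MATP) == 1
        assert sum(s.state_type is StateType.MP for s in m.states) == 1

    def test_branch_point_becomes_single_bif(self):
        m = build_toy_cm(ToyModelSpec("AAACCCUUUGGG", "((..))((..))"))
        assert sum(s.state_type is StateType.B for s in m.states) == 1

    def test_trailing_unpaired_after_stem_uses_matr(self):
        m = build_toy_cm(ToyModelSpec("GCGCA", "(..)."))
        assert NodeType.MATR in [n.node_type for n in m.nodes]

    def test_insert_self_loops_strictly_negative(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            m = build_toy_cm(random_toy_spec(rng))
            for s in m.states:
                gain = m.insert_self_loop_gain(s)
                if gain is not None:
                    assert gain < 0

    def test_unbalanced_structure_rejected(self):
        with pytest.raises(StructureError):
            build_toy_cm(ToyModelSpec("ACG", "(.."))
        with pytest.raises(StructureError):
            build_toy_cm(ToyModelSpec("ACG", ".))"))

    def test_dna_input_mapped_iupac_rejected(self):
        m = build_toy_cm(ToyModelSpec("ACGT", "...."))  # T accepted
        assert m.consensus_length == 4
        with pytest.raises(AlphabetError, match="IUPAC|invalid nucleotide"):
            build_toy_cm(ToyModelSpec("ACGN", "...."))


class TestValidate:
    def test_valid_model_has_no_diagnostics(self, bif_model):
        assert validate_model(bif_model) == []

    def test_bad_null_sum_flagged(self, single_column_model):
        m = build_toy_cm(ToyModelSpec("A", ".", seed=1))
        m.null = np.array([0.5, 0.5, 0.25, 0.25])
        diags = validate_model(m)
        assert any("null model" in d for d in diags)

    def test_positive_insert_self_loop_is_hazard(self):
        m = build_toy_cm(ToyModelSpec("A", ".", seed=1))
        il = next(s for s in m.states if s.state_type is StateType.IL)
        il.emissions = il.emissions + 10.0  # gain above zero
        diags = validate_model(m)
        assert sum("non-termination hazard" in d for d in diags) >= 1

    def test_missing_root_flagged(self):
        m = build_toy_cm(ToyModelSpec("A", ".", seed=1))
        m.states[0].state_type = StateType.D
        assert any("root" in d for d in validate_model(m))

    def test_out_of_range_transition_flagged(self):
        m = build_toy_cm(ToyModelSpec("A", ".", seed=1))
        m.states[0].transitions[99] = -1.0
        assert any("out of range" in d for d in validate_model(m))

    def test_backwards_transition_flagged(self):
        m = build_toy_cm(ToyModelSpec("AC", "..", seed=1))
        ml = next(s for s in m.states if s.state_type is StateType.ML)
        ml.transitions[0] = -1.0
        assert any("does not increase" in d for d in validate_model(m))

    def test_wrong_emission_arity_flagged(self):
        m = build_toy_cm(ToyModelSpec("A", ".", seed=1))
        ml = next(s for s in m.states if s.state_type is StateType.ML)
        ml.emissions = np.zeros(16)
        assert any("emission vector" in d for d in validate_model(m))

    def test_missing_end_state_flagged(self):
        m = build_toy_cm(ToyModelSpec("A", ".", seed=1))
        end = next(s for s in m.states if s.state_type is StateType.E)
        end.state_type = StateType.D
        assert any("at least one E state" in d for d in validate_model(m))

    def test_matp_without_mp_flagged(self):
        m = build_toy_cm(ToyModelSpec("AC", "()", seed=1))
        mp = next(s for s in m.states if s.state_type is StateType.MP)
        mp.state_type = StateType.ML
        diags = validate_model(m)
        assert any("MATP" in d for d in diags)

    def test_bif_without_two_s_children_flagged(self, bif_model):
        import copy

        m = copy.deepcopy(bif_model)
        b = next(s for s in m.states if s.state_type is StateType.B)
        b.bif_children = (b.bif_children[0], b.bif_children[0] + 1)
        assert any("not an S state" in d for d in validate_model(m))


def test_stockholm_hook_requires_infernal(tmp_path, monkeypatch):
    monkeypatch.setenv("PATH", str(tmp_path))  # hide any cmbuild
    sto = tmp_path / "aln.sto"
    sto.write_text("# STOCKHOLM 1.0\n//\n")
    with pytest.raises(RuntimeError, match="requires Infernal"):
        build_from_stockholm(sto)
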