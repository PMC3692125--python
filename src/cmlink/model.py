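"""In-memory covariance model: states, guide-tree nodes, validation.

A covariance model (CM) is a profile stochastic context-free grammar built on a
guide tree of nodes (ROOT, MATL, MATR, MATP, BIF, BEGL, BEGR, END), each node
owning a small set of states. States either emit nucleotides to the left
(ML/IL), to the right (MR/IR), as a base pair (MP), or are silent (S/D/B/E).
All scores are log-odds bits against the model's null (background)
distribution; transition scores are log2 transition probabilities. The file
dialect a model was read from is recorded but has no influence on scoring.

Impossibility is represented by a single absorbing sentinel, ``NEG_INF``
(float ``-inf``): it is strictly below every finite score and absorbing under
addition, so an impossible branch can never win a maximization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

#: global impossibility sentinel ("*" in CM files)
NEG_INF = float("-inf")


class StateType(str, Enum):
    S = "S"
    D = "D"
    IL = "IL"
    IR = "IR"
    ML = "ML"
    MR = "MR"
    MP = "MP"
    B = "B"
    E = "E"


class NodeType(str, Enum):
    ROOT = "ROOT"
    MATL = "MATL"
    MATR = "MATR"
    MATP = "MATP"
    BIF = "BIF"
    BEGL = "BEGL"
    BEGR = "BEGR"
    END = "END"


class Dialect(str, Enum):
    INFERNAL_1_0 = "INFERNAL_1_0"
    INFERNAL_1_1 = "INFERNAL_1_1"


LEFT_EMITTERS = frozenset({StateType.ML, StateType.IL})
RIGHT_EMITTERS = frozenset({StateType.MR, StateType.IR})
SINGLET_EMITTERS = LEFT_EMITTERS | RIGHT_EMITTERS
SILENT_TYPES = frozenset({StateType.S, StateType.D, StateType.B, StateType.E})
INSERT_TYPES = frozenset({StateType.IL, StateType.IR})

#: emission vector length required per state type
EMISSION_ARITY = {
    StateType.ML: 4,
    StateType.MR: 4,
    StateType.IL: 4,
    StateType.IR: 4,
    StateType.MP: 16,
    StateType.S: 0,
    StateType.D: 0,
    StateType.B: 0,
    StateType.E: 0,
}


@dataclass
class State:
    """One CM state.

    ``transitions`` maps child state index to a transition score in bits
    (log2 probability). ``emissions`` holds log-odds bits against the null
    model, ordered A,C,G,U for singlet emitters and AA,AC,...,UU row-major for
    MP. ``bif_children`` is the (left, right) start-state pair for B states.
    """

    index: int
    state_type: StateType
    transitions: dict[int, float] = field(default_factory=dict)
    bif_children: Optional[tuple[int, int]] = None
    emissions: np.ndarray = field(default_factory=lambda: np.zeros(0))
    node_index: int = 0

    def emission(self, i: int) -> float:
        return float(self.emissions[i])

    def max_emission(self) -> float:
        return float(np.max(self.emissions)) if len(self.emissions) else 0.0


@dataclass
class Node:
    """Guide-tree node owning a contiguous run of states."""

    index: int
    node_type: NodeType
    state_indices: list[int] = field(default_factory=list)


@dataclass
class CovarianceModel:
    name: str
    states: list[State]
    nodes: list[Node]
    null: np.ndarray  # 4 background probabilities over A,C,G,U
    accession: Optional[str] = None
    dialect: Dialect = Dialect.INFERNAL_1_0
    consensus_length: int = 0
    #: unparsed header lines (calibration stats, provenance, checksums)
    #: preserved verbatim for round-trip
    extras: list[str] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def insert_self_loop_gain(self, state: State) -> Optional[float]:
        """Self-loop transition score plus best emission, or None if no loop."""
        if state.state_type not in INSERT_TYPES:
            return None
        t_self = state.transitions.get(state.index)
        if t_self is None:
            return None
        return t_self + state.max_emission()


def validate_model(model: CovarianceModel) -> list[str]:
    """Check every structural invariant; return diagnostics (empty iff valid).

    Diagnostics name the offending state (or the null model) and the violated
    rule. Beyond structural checks, any insert self-loop whose transition score
    plus maximal emission score is >= 0 is flagged as a non-termination hazard:
    such a loop could be repeated indefinitely at no cost, so best-sequence and
    link computations refuse to run on it.
    """
    diags: list[str] = []
    n = len(model.states)

    if n == 0:
        return ["model has no states"]
    if model.states[0].state_type is not StateType.S:
        diags.append("state 0: root must be of type S")
    for i, st in enumerate(model.states):
        if st.index != i:
            diags.append(f"state {i}: stored index {st.index} does not match position")
    n_start = sum(1 for s in model.states if s.state_type is StateType.S)
    n_end = sum(1 for s in model.states if s.state_type is StateType.E)
    if n_end < 1:
        diags.append("model: needs at least one E state")
    if sum(1 for s in model.states[1:] if s.state_type is StateType.S) != n_start - 1:
        # unreachable by construction, kept for symmetry with the S-at-0 rule
        diags.append("model: extra root state")

    if abs(float(np.sum(model.null)) - 1.0) > 1e-6:
        diags.append(
            f"null model: probabilities sum to {float(np.sum(model.null)):.6f}, expected 1"
        )
    if len(model.null) != 4 or np.any(np.asarray(model.null) <= 0):
        diags.append("null model: must be 4 strictly positive probabilities")

    for st in model.states:
        arity = EMISSION_ARITY[st.state_type]
        if len(st.emissions) != arity:
            diags.append(
                f"state {st.index} ({st.state_type.value}): emission vector has "
                f"length {len(st.emissions)}, expected {arity}"
            )
        if st.state_type is StateType.B:
            if st.transitions:
                diags.append(f"state {st.index} (B): must not carry scored transitions")
            if st.bif_children is None or len(st.bif_children) != 2:
                diags.append(f"state {st.index} (B): needs exactly two children")
            else:
                for child in st.bif_children:
                    if not (0 <= child < n):
                        diags.append(
                            f"state {st.index} (B): child {child} out of range"
                        )
                    elif model.states[child].state_type is not StateType.S:
                        diags.append(
                            f"state {st.index} (B): child {child} is not an S state"
                        )
        elif st.state_type is StateType.E:
            if st.transitions:
                diags.append(f"state {st.index} (E): must not carry transitions")
        else:
            if not st.transitions:
                diags.append(f"state {st.index} ({st.state_type.value}): has no transitions")
            for child in st.transitions:
                if not (0 <= child < n):
                    diags.append(
                        f"state {st.index}: transition target {child} out of range"
                    )
                elif child <= st.index and not (
                    child == st.index and st.state_type in INSERT_TYPES
                ):
                    diags.append(
                        f"state {st.index}: transition target {child} does not "
                        "increase (only insert self-loops may stay)"
                    )

        gain = model.insert_self_loop_gain(st)
        if gain is not None and gain >= 0:
            diags.append(
                f"state {st.index} ({st.state_type.value}): insert self-loop gain "
                f"{gain:+.3f} bits >= 0 (non-termination hazard)"
            )

    for node in model.nodes:
        owned = [model.states[i].state_type for i in node.state_indices if i < n]
        if node.node_type is NodeType.BIF and owned.count(StateType.B) != 1:
            diags.append(f"node {node.index} (BIF): must own exactly one B state")
        if node.node_type is NodeType.MATP and owned.count(StateType.MP) != 1:
            diags.append(f"node {node.index} (MATP): must own exactly one MP state")

    return diags


def has_hazard(model: CovarianceModel) -> bool:
    """True if any insert self-loop has non-negative gain."""
    return any(
        g is not None and g >= 0
        for g in (model.insert_self_loop_gain(s) for s in model.states)
    )
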