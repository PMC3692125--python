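"""Synthetic covariance models for testing and benchmarking.

`build_toy_cm` turns a consensus sequence plus dot-bracket structure into a
small but fully valid covariance model with the standard guide-tree layout:
unpaired columns become MATL (or MATR, when the construction consumes from the
right) nodes, base-paired columns become MATP nodes, and multiloop branch
points become BIF/BEGL/BEGR node triples. Emission distributions concentrate
probability on the consensus nucleotide(s); a configurable probability mass is
spread over non-consensus transitions. Every numeric choice is drawn through a
seeded generator, so a ToyModelSpec is a reproducible recipe: same spec, same
model, bit for bit.

These models emulate what matters for model comparison — state topology,
bit-score bookkeeping, bifurcations, insert states with strictly negative
self-loop gains — not the estimation pipeline (no Dirichlet priors, no
effective sequence number weighting, no E-value calibration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import NT_INDEX, RNA, normalize_rna, pair_index
from .model import (
    CovarianceModel,
    Dialect,
    Node,
    NodeType,
    State,
    StateType,
)


class StructureError(ValueError):
    """Raised for unbalanced or pseudoknotted dot-bracket strings."""


@dataclass(frozen=True)
class ToyModelSpec:
    """Recipe for a small synthetic CM.

    consensus
        RNA string over {A,C,G,U} (T accepted, mapped to U).
    structure
        dot-bracket string of the same length; balanced, no pseudoknots.
    match_emit_boost
        log2 odds ratio, in bits, of the consensus nucleotide (or pair) over
        each alternative in match-state emissions.
    transition_spread
        probability mass in [0, 1) shared by all non-main transitions out of
        each state; the main (consensus-path) transition keeps the rest.
    seed
        seed for the jitter that decorrelates models built from the same
        consensus.
    name
        model name written into the CM record.
    """

    consensus: str
    structure: str
    match_emit_boost: float = 3.0
    transition_spread: float = 0.05
    seed: int = 0
    name: str = "toy"


def pair_map(structure: str) -> dict[int, int]:
    """Map each bracket position to its partner; validate balance/knots."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
        elif ch != ".":
            raise StructureError(f"invalid structure character {ch!r} at position {i}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


# states owned by each node type, in within-node order; the trailing inserts of
# one node are immediately followed by the next node's split set, which keeps
# every transition target range contiguous.
_NODE_STATES = {
    NodeType.ROOT: (StateType.S, StateType.IL, StateType.IR),
    NodeType.MATP: (
        StateType.MP,
        StateType.ML,
        StateType.MR,
        StateType.D,
        StateType.IL,
        StateType.IR,
    ),
    NodeType.MATL: (StateType.ML, StateType.D, StateType.IL),
    NodeType.MATR: (StateType.MR, StateType.D, StateType.IR),
    NodeType.BIF: (StateType.B,),
    NodeType.BEGL: (StateType.S,),
    NodeType.BEGR: (StateType.S, StateType.IL),
    NodeType.END: (StateType.E,),
}

_SPLIT_SET = {
    NodeType.ROOT: (StateType.S,),
    NodeType.MATP: (StateType.MP, StateType.ML, StateType.MR, StateType.D),
    NodeType.MATL: (StateType.ML, StateType.D),
    NodeType.MATR: (StateType.MR, StateType.D),
    NodeType.BIF: (StateType.B,),
    NodeType.BEGL: (StateType.S,),
    NodeType.BEGR: (StateType.S,),
    NodeType.END: (StateType.E,),
}

#: the consensus-path entry state of each node type
_PRIMARY = {
    NodeType.MATP: StateType.MP,
    NodeType.MATL: StateType.ML,
    NodeType.MATR: StateType.MR,
    NodeType.BIF: StateType.B,
    NodeType.END: StateType.E,
}


def _guide_tree(structure: str, pairs: dict[int, int]):
    """Preorder node list [(node_type, columns)] for a dot-bracket string."""
    nodes: list[tuple[NodeType, tuple[int, ...]]] = [(NodeType.ROOT, ())]

    def walk(i: int, j: int) -> None:
        if i > j:
            nodes.append((NodeType.END, ()))
            return
        if pairs.get(i) == j:
            nodes.append((NodeType.MATP, (i, j)))
            walk(i + 1, j - 1)
        elif structure[i] == ".":
            nodes.append((NodeType.MATL, (i,)))
            walk(i + 1, j)
        elif structure[j] == ".":
            nodes.append((NodeType.MATR, (j,)))
            walk(i, j - 1)
        else:
            # i pairs k < j: bifurcate into [i,k] and [k+1,j]
            k = pairs[i]
            nodes.append((NodeType.BIF, ()))
            nodes.append((NodeType.BEGL, ()))
            walk(i, k)
            nodes.append((NodeType.BEGR, ()))
            walk(k + 1, j)

    walk(0, len(structure) - 1)
    return nodes


def _jitter(rng: np.random.Generator, probs: np.ndarray, rel: float = 0.04) -> np.ndarray:
    p = probs * np.exp(rng.uniform(-rel, rel, size=probs.shape))
    return p / p.sum()


def _boosted(boost: float, size: int, hot: int) -> np.ndarray:
    odds = 2.0 ** boost
    p = np.full(size, 1.0 / (odds + size - 1))
    p[hot] = odds / (odds + size - 1)
    return p


def build_toy_cm(spec: ToyModelSpec) -> CovarianceModel:
    """Construct a valid covariance model from a ToyModelSpec.

    Deterministic given the spec (including its seed). Raises
    :class:`StructureError` for unbalanced structures and ``ValueError`` for
    mismatched lengths or out-of-range parameters.
    """
    consensus = normalize_rna(spec.consensus)
    if len(consensus) < 1:
        raise ValueError("consensus must have length >= 1")
    if len(spec.structure) != len(consensus):
        raise ValueError("structure and consensus must have equal length")
    if not (0.0 <= spec.transition_spread < 1.0):
        raise ValueError("transition_spread must be in [0, 1)")
    pairs = pair_map(spec.structure)
    rng = np.random.default_rng(spec.seed)

    node_plan = _guide_tree(spec.structure, pairs)
    null = _jitter(rng, np.full(4, 0.25), rel=0.02)
    log_null = np.log2(null)

    # lay out states
    states: list[State] = []
    nodes: list[Node] = []
    state_of: list[dict[StateType, int]] = []
    for ni, (ntype, cols) in enumerate(node_plan):
        owned: dict[StateType, int] = {}
        idxs: list[int] = []
        for stype in _NODE_STATES[ntype]:
            si = len(states)
            owned[stype] = si
            idxs.append(si)
            states.append(State(index=si, state_type=stype, node_index=ni))
        nodes.append(Node(index=ni, node_type=ntype, state_indices=idxs))
        state_of.append(owned)

    # subtree linkage: for every node, the node its inserts/splits feed into
    # is simply the next node in preorder, except that BIF wires through
    # bif_children and an END node terminates its branch.
    for ni, (ntype, cols) in enumerate(node_plan):
        owned = state_of[ni]
        if ntype is NodeType.BIF:
            # left child is the BEGL right after; right child is the BEGR that
            # follows the left subtree (next BEGL/BEGR balance scan)
            depth = 0
            right_ni = None
            for mj in range(ni + 1, len(node_plan)):
                mtype = node_plan[mj][0]
                if mtype is NodeType.BEGL:
                    depth += 1
                elif mtype is NodeType.BEGR:
                    depth -= 1
                    if depth == 0:
                        right_ni = mj
                        break
                elif mtype is NodeType.BIF:
                    pass
            assert right_ni is not None
            b = states[owned[StateType.B]]
            b.bif_children = (
                state_of[ni + 1][StateType.S],
                state_of[right_ni][StateType.S],
            )
            continue
        if ntype is NodeType.END:
            continue

        next_split = [state_of[ni + 1][t] for t in _SPLIT_SET[node_plan[ni + 1][0]]]
        inserts = [owned[t] for t in (StateType.IL, StateType.IR) if t in owned]
        primary_type = _PRIMARY.get(node_plan[ni + 1][0])
        main_target = (
            state_of[ni + 1][primary_type] if primary_type is not None else next_split[0]
        )

        sources = [owned[t] for t in _SPLIT_SET[ntype]] + inserts
        for src in sources:
            st = states[src]
            if st.state_type is StateType.IR:
                children = [owned[StateType.IR]] + next_split
            elif st.state_type is StateType.IL:
                children = inserts + next_split
            else:
                children = inserts + next_split
            children = sorted(set(children))
            k = len(children)
            if k == 1:
                p = np.array([1.0])
            else:
                p = np.full(k, spec.transition_spread / (k - 1))
                p[children.index(main_target)] = 1.0 - spec.transition_spread
            p = _jitter(rng, p)
            st.transitions = {c: float(np.log2(p[i])) for i, c in enumerate(children)}

    # emissions
    for ni, (ntype, cols) in enumerate(node_plan):
        owned = state_of[ni]
        for stype, si in owned.items():
            st = states[si]
            if stype is StateType.MP:
                i, j = cols
                hot = pair_index(consensus[i], consensus[j])
                p = _jitter(rng, _boosted(spec.match_emit_boost, 16, hot))
                outer = np.add.outer(log_null, log_null).reshape(16)
                st.emissions = np.log2(p) - outer
            elif stype is StateType.ML and ntype in (NodeType.MATL, NodeType.MATP):
                col = cols[0]
                p = _jitter(rng, _boosted(spec.match_emit_boost, 4, NT_INDEX[consensus[col]]))
                st.emissions = np.log2(p) - log_null
            elif stype is StateType.MR and ntype in (NodeType.MATR, NodeType.MATP):
                col = cols[-1]
                p = _jitter(rng, _boosted(spec.match_emit_boost, 4, NT_INDEX[consensus[col]]))
                st.emissions = np.log2(p) - log_null
            elif stype in (StateType.IL, StateType.IR):
                p = _jitter(rng, np.full(4, 0.25), rel=0.02)
                st.emissions = np.log2(p) - log_null

    return CovarianceModel(
        name=spec.name,
        accession=None,
        states=states,
        nodes=nodes,
        null=null,
        dialect=Dialect.INFERNAL_1_0,
        consensus_length=len(consensus),
    )


#: clan fixture layout: eight core columns shared by the four clan members,
#: five member-specific flank columns; the satellite carries member t1's
#: flank behind a core mutated away from the clan's.
_CLAN_CORE = "GCGCAAAA"
_CLAN_ANTICORE = "AUAUCCCC"
_CLAN_FLANKS = {"t1": "ACGUC", "t2": "CAUCG", "t3": "GUAGA", "t4": "UGCAU"}

#: link-score threshold separating the planted structure: clan edges sit
#: near 10 bits, the satellite's single genuine link near 7, and all spurious
#: satellite links at or below 3
CLAN_THRESHOLD = 5.0


def clan_fixture() -> list[CovarianceModel]:
    """Five models with a planted clan structure.

    Four "clan" models share an eight-column core and differ only in a
    five-column flank, so every clan pair links strongly. A fifth "satellite"
    model shares t1's flank but carries a core mutated away from the clan's:
    it links moderately to t1 and to nothing else — the pattern of a family
    that overlaps a single clan member without belonging to the clan.
    Thresholding the link graph at :data:`CLAN_THRESHOLD` recovers the
    partition: the clan forms a 4-clique and the satellite has degree one.
    """
    models = [
        build_toy_cm(
            ToyModelSpec(
                _CLAN_CORE + flank, "." * 13, seed=100 + i, name=name
            )
        )
        for i, (name, flank) in enumerate(_CLAN_FLANKS.items())
    ]
    models.append(
        build_toy_cm(
            ToyModelSpec(
                _CLAN_ANTICORE + _CLAN_FLANKS["t1"], "." * 13, seed=77, name="sat"
            )
        )
    )
    return models


def random_toy_spec(
    rng: np.random.Generator,
    min_len: int = 1,
    max_len: int = 8,
    allow_bif: bool = True,
    name: str = "toy",
    **kwargs,
) -> ToyModelSpec:
    """Draw a random consensus + structure of bounded length.

    Structures are sampled from a small grammar: runs of unpaired columns,
    hairpin stems, and (optionally) two-hairpin branch points — enough to
    exercise MATL/MATR/MATP/BIF topologies without generating degenerate
    models.
    """
    length = int(rng.integers(min_len, max_len + 1))
    consensus = "".join(RNA[i] for i in rng.integers(0, 4, size=length))
    structure = ["."] * length
    if length >= 4 and rng.random() < 0.6:
        # place one stem (or a branch of two stems when allowed and roomy)
        if allow_bif and length >= 8 and rng.random() < 0.5:
            half = length // 2
            structure[0], structure[half - 1] = "(", ")"
            structure[half], structure[length - 1] = "(", ")"
        else:
            depth = 1 if length < 6 else int(rng.integers(1, 3))
            for d in range(depth):
                structure[d], structure[length - 1 - d] = "(", ")"
    return ToyModelSpec(
        consensus=consensus,
        structure="".join(structure),
        seed=int(rng.integers(0, 2**31 - 1)),
        name=name,
        **kwargs,
    )
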