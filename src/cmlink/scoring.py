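"""Single-model scoring: optimal parses, best sequences, brute-force oracles.

All scoring is global: the whole sequence must be accounted for by the whole
model (no local begins/ends, no truncation). The optimal parse of a given
sequence is found by CYK over subsequences x states; the best achievable
sequence of a model by a dynamic program over states alone. Two independent
brute-force routes back these up in the test suite: exhaustive parse-tree
recursion (no memoization) for a fixed sequence, and an enumeration DP that
scores *every* sequence up to a length bound.

Tie-breaking is fully specified so results are bit-reproducible: lower child
state index first, then leftmost bifurcation split, then alphabetical
nucleotide order (A < C < G < U; pairs in row-major AA..UU order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from .alphabet import NT_INDEX, RNA, normalize_rna
from .model import (
    NEG_INF,
    CovarianceModel,
    State,
    StateType,
    validate_model,
)

#: hard guard for the brute-force sequence enumerations
BRUTE_FORCE_MAX_LEN = 8


class NonTerminationError(ValueError):
    """Model has an insert self-loop with non-negative gain."""


class BruteForceGuardError(ValueError):
    """Requested brute-force enumeration exceeds the tractability guard."""


@dataclass
class ParseNode:
    """One step of a parse tree: a state and the positions it emitted."""

    state: int
    positions: tuple[int, ...]
    children: list["ParseNode"] = field(default_factory=list)


@dataclass
class ParseResult:
    """A sequence scored against one model."""

    score: float
    sequence: str
    structure: str
    state_path: list[tuple[int, tuple[int, ...]]]
    tree: Optional[ParseNode] = None

    def rescore(self, model: CovarianceModel) -> float:
        """Re-derive the score by summing the tree's transition and emission
        bits; used to check score additivity."""
        if self.tree is None:
            return self.score

        def walk(node: ParseNode) -> float:
            st = model.states[node.state]
            total = _emission_at(st, self.sequence, node.positions)
            for child in node.children:
                if st.state_type is not StateType.B:
                    total += st.transitions[child.state]
                total += walk(child)
            return total

        return walk(self.tree)


def _emission_at(st: State, seq: str, positions: tuple[int, ...]) -> float:
    if not positions:
        return 0.0
    if st.state_type is StateType.MP:
        i, j = positions
        return st.emission(NT_INDEX[seq[i]] * 4 + NT_INDEX[seq[j]])
    return st.emission(NT_INDEX[seq[positions[0]]])


def _flatten(tree: ParseNode) -> list[tuple[int, tuple[int, ...]]]:
    path: list[tuple[int, tuple[int, ...]]] = []

    def walk(n: ParseNode) -> None:
        path.append((n.state, n.positions))
        for c in n.children:
            walk(c)

    walk(tree)
    return path


def _structure_from_tree(model: CovarianceModel, tree: ParseNode, length: int) -> str:
    chars = ["."] * length

    def walk(n: ParseNode) -> None:
        if model.states[n.state].state_type is StateType.MP:
            i, j = n.positions
            chars[i], chars[j] = "(", ")"
        for c in n.children:
            walk(c)

    walk(tree)
    return "".join(chars)


def optimal_parse_score(model: CovarianceModel, sequence: str) -> ParseResult:
    """Maximum-score global parse of ``sequence`` by ``model`` (CYK).

    The score is the sentinel (``-inf``) when no parse exists, in which case
    structure and path are empty. The empty sequence is legal and is scored
    via pure-deletion parses.
    """
    seq = normalize_rna(sequence)
    L = len(seq)
    states = model.states
    n = len(states)

    # M[v][(i, j)] over half-open subsequences; filled by increasing length,
    # states in decreasing index so all transition targets are ready.
    M: list[dict[tuple[int, int], float]] = [dict() for _ in range(n)]
    back: list[dict[tuple[int, int], tuple]] = [dict() for _ in range(n)]

    for span in range(L + 1):
        for i in range(L - span + 1):
            j = i + span
            cell = (i, j)
            for v in range(n - 1, -1, -1):
                st = states[v]
                t = st.state_type
                best = NEG_INF
                bb = None
                if t is StateType.E:
                    if i == j:
                        best, bb = 0.0, ("end",)
                elif t is StateType.B:
                    la, ra = st.bif_children
                    for k in range(i, j + 1):
                        x = M[la].get((i, k), NEG_INF)
                        y = M[ra].get((k, j), NEG_INF)
                        if x + y > best:
                            best, bb = x + y, ("bif", k)
                elif t in (StateType.S, StateType.D):
                    for w in sorted(st.transitions):
                        s = st.transitions[w] + M[w].get(cell, NEG_INF)
                        if s > best:
                            best, bb = s, ("silent", w)
                elif t in (StateType.ML, StateType.IL):
                    if span >= 1:
                        e = st.emission(NT_INDEX[seq[i]])
                        for w in sorted(st.transitions):
                            s = e + st.transitions[w] + M[w].get((i + 1, j), NEG_INF)
                            if s > best:
                                best, bb = s, ("left", w)
                elif t in (StateType.MR, StateType.IR):
                    if span >= 1:
                        e = st.emission(NT_INDEX[seq[j - 1]])
                        for w in sorted(st.transitions):
                            s = e + st.transitions[w] + M[w].get((i, j - 1), NEG_INF)
                            if s > best:
                                best, bb = s, ("right", w)
                elif t is StateType.MP:
                    if span >= 2:
                        e = st.emission(NT_INDEX[seq[i]] * 4 + NT_INDEX[seq[j - 1]])
                        for w in sorted(st.transitions):
                            s = e + st.transitions[w] + M[w].get((i + 1, j - 1), NEG_INF)
                            if s > best:
                                best, bb = s, ("pair", w)
                if best > NEG_INF:
                    M[v][cell] = best
                    back[v][cell] = bb

    score = M[0].get((0, L), NEG_INF)
    if score == NEG_INF:
        return ParseResult(NEG_INF, seq, "", [])

    def trace(v: int, i: int, j: int) -> ParseNode:
        bb = back[v][(i, j)]
        kind = bb[0]
        if kind == "end":
            return ParseNode(v, ())
        if kind == "bif":
            k = bb[1]
            la, ra = states[v].bif_children
            return ParseNode(v, (), [trace(la, i, k), trace(ra, k, j)])
        w = bb[1]
        if kind == "silent":
            return ParseNode(v, (), [trace(w, i, j)])
        if kind == "left":
            return ParseNode(v, (i,), [trace(w, i + 1, j)])
        if kind == "right":
            return ParseNode(v, (j - 1,), [trace(w, i, j - 1)])
        return ParseNode(v, (i, j - 1), [trace(w, i + 1, j - 1)])

    tree = trace(0, 0, L)
    return ParseResult(
        score=score,
        sequence=seq,
        structure=_structure_from_tree(model, tree, L),
        state_path=_flatten(tree),
        tree=tree,
    )


def enumerate_parse_score(model: CovarianceModel, sequence: str) -> float:
    """Exhaustive parse-tree recursion (no memoization): independent oracle
    for :func:`optimal_parse_score` on tiny models."""
    seq = normalize_rna(sequence)
    states = model.states

    def rec(v: int, i: int, j: int) -> float:
        st = states[v]
        t = st.state_type
        if t is StateType.E:
            return 0.0 if i == j else NEG_INF
        if t is StateType.B:
            la, ra = st.bif_children
            best = NEG_INF
            for k in range(i, j + 1):
                best = max(best, rec(la, i, k) + rec(ra, k, j))
            return best
        best = NEG_INF
        if t in (StateType.S, StateType.D):
            for w, tr in st.transitions.items():
                best = max(best, tr + rec(w, i, j))
        elif t in (StateType.ML, StateType.IL):
            if j > i:
                e = st.emission(NT_INDEX[seq[i]])
                for w, tr in st.transitions.items():
                    best = max(best, e + tr + rec(w, i + 1, j))
        elif t in (StateType.MR, StateType.IR):
            if j > i:
                e = st.emission(NT_INDEX[seq[j - 1]])
                for w, tr in st.transitions.items():
                    best = max(best, e + tr + rec(w, i, j - 1))
        elif t is StateType.MP:
            if j - i >= 2:
                e = st.emission(NT_INDEX[seq[i]] * 4 + NT_INDEX[seq[j - 1]])
                for w, tr in st.transitions.items():
                    best = max(best, e + tr + rec(w, i + 1, j - 1))
        return best

    return rec(0, 0, len(seq))


def best_sequence(model: CovarianceModel) -> ParseResult:
    """The sequence (and parse) maximizing the model's bit score.

    A dynamic program over states only: each emitting state contributes its
    maximal emission, bifurcations sum both children. Insert self-loops are
    never taken because their gain is strictly negative (validated up front);
    a model with a non-negative self-loop gain is refused with
    :class:`NonTerminationError` naming the offending state.
    """
    for st in model.states:
        gain = model.insert_self_loop_gain(st)
        if gain is not None and gain >= 0:
            raise NonTerminationError(
                f"state {st.index} ({st.state_type.value}) has insert self-loop "
                f"gain {gain:+.3f} bits >= 0; best sequence is unbounded"
            )
    states = model.states
    n = len(states)
    best: list[float] = [NEG_INF] * n
    choice: list[tuple] = [None] * n

    for v in range(n - 1, -1, -1):
        st = states[v]
        t = st.state_type
        if t is StateType.E:
            best[v], choice[v] = 0.0, ("end",)
        elif t is StateType.B:
            la, ra = st.bif_children
            best[v], choice[v] = best[la] + best[ra], ("bif",)
        else:
            e, ci = 0.0, None
            if t is StateType.MP:
                e, ci = NEG_INF, 0
                for k in range(16):
                    if st.emission(k) > e:
                        e, ci = st.emission(k), k
            elif len(st.emissions):
                e, ci = NEG_INF, 0
                for k in range(4):
                    if st.emission(k) > e:
                        e, ci = st.emission(k), k
            b, w_best = NEG_INF, None
            for w in sorted(st.transitions):
                if w == v:
                    continue  # negative-gain self-loop: never optimal
                s = st.transitions[w] + best[w]
                if s > b:
                    b, w_best = s, w
            best[v], choice[v] = e + b, ("emit", ci, w_best)

    if best[0] == NEG_INF:
        return ParseResult(NEG_INF, "", "", [])

    def build(v: int) -> tuple[str, str, ParseNode]:
        ch = choice[v]
        if ch[0] == "end":
            return "", "", ParseNode(v, ())
        if ch[0] == "bif":
            la, ra = states[v].bif_children
            s1, f1, t1 = build(la)
            s2, f2, t2 = build(ra)
            return s1 + s2, f1 + f2, ParseNode(v, (), [t1, t2])
        _, ci, w = ch
        s, f, sub = build(w)
        t = states[v].state_type
        if t is StateType.MP:
            c1, c2 = RNA[ci // 4], RNA[ci % 4]
            node = ParseNode(v, (-1, -1), [sub])
            return c1 + s + c2, "(" + f + ")", node
        if t in (StateType.ML, StateType.IL):
            return RNA[ci] + s, "." + f, ParseNode(v, (-1,), [sub])
        if t in (StateType.MR, StateType.IR):
            return s + RNA[ci], f + ".", ParseNode(v, (-1,), [sub])
        return s, f, ParseNode(v, (), [sub])

    seq, struct, tree = build(0)
    _assign_positions(model, tree, seq)
    return ParseResult(
        score=best[0],
        sequence=seq,
        structure=struct,
        state_path=_flatten(tree),
        tree=tree,
    )


def _assign_positions(model: CovarianceModel, tree: ParseNode, seq: str) -> None:
    """Fill in emitted positions of a generatively built parse tree."""

    def walk(n: ParseNode, i: int, j: int) -> None:
        st = model.states[n.state]
        t = st.state_type
        if t is StateType.B:
            left_len = _yield_len(model, n.children[0])
            walk(n.children[0], i, i + left_len)
            walk(n.children[1], i + left_len, j)
            return
        if n.positions == (-1, -1):
            n.positions = (i, j - 1)
            walk(n.children[0], i + 1, j - 1)
        elif n.positions == (-1,):
            if t in (StateType.ML, StateType.IL):
                n.positions = (i,)
                walk(n.children[0], i + 1, j)
            else:
                n.positions = (j - 1,)
                walk(n.children[0], i, j - 1)
        elif n.children:
            walk(n.children[0], i, j)

    walk(tree, 0, len(seq))


def _yield_len(model: CovarianceModel, tree: ParseNode) -> int:
    # positions may still be placeholders, so count emission arity instead
    st = model.states[tree.state].state_type
    total = 2 if st is StateType.MP else (1 if st in (
        StateType.ML, StateType.IL, StateType.MR, StateType.IR) else 0)
    return total + sum(_yield_len(model, c) for c in tree.children)


def all_sequences(max_len: int) -> Iterator[str]:
    """All RNA strings of length 0..max_len in length-then-lex order."""
    from itertools import product

    for L in range(max_len + 1):
        for tup in product(RNA, repeat=L):
            yield "".join(tup)


def all_sequence_scores(model: CovarianceModel, max_len: int) -> dict[str, float]:
    """Optimal parse score of *every* sequence of length <= max_len.

    Enumeration DP over (state, generated string): an independent route to the
    same quantities as per-sequence CYK, used as the brute-force oracle.
    Sequences absent from the result have no parse at all.
    """
    if max_len > BRUTE_FORCE_MAX_LEN:
        raise BruteForceGuardError(
            f"max_len {max_len} exceeds the guard ({BRUTE_FORCE_MAX_LEN})"
        )
    states = model.states
    n = len(states)
    table: list[dict[str, float]] = [dict() for _ in range(n)]

    def relax(d: dict[str, float], s: str, val: float) -> None:
        if val > d.get(s, NEG_INF):
            d[s] = val

    for v in range(n - 1, -1, -1):
        st = states[v]
        t = st.state_type
        d = table[v]
        if t is StateType.E:
            d[""] = 0.0
        elif t is StateType.B:
            la, ra = st.bif_children
            for s1, x1 in table[la].items():
                for s2, x2 in table[ra].items():
                    if len(s1) + len(s2) <= max_len:
                        relax(d, s1 + s2, x1 + x2)
        elif t in (StateType.S, StateType.D):
            for w, tr in st.transitions.items():
                for s, x in table[w].items():
                    relax(d, s, tr + x)
        elif t in (StateType.ML, StateType.IL, StateType.MR, StateType.IR):
            left = t in (StateType.ML, StateType.IL)
            for w, tr in st.transitions.items():
                if w == v:
                    continue
                for s, x in table[w].items():
                    if len(s) >= max_len:
                        continue
                    for ci, c in enumerate(RNA):
                        val = st.emission(ci) + tr + x
                        relax(d, c + s if left else s + c, val)
            if v in st.transitions:
                # self-loop: extend by increasing length so every repeat count
                # is represented exactly
                tr = st.transitions[v]
                by_len: dict[int, list[str]] = {}
                for s in d:
                    by_len.setdefault(len(s), []).append(s)
                for L in range(max_len):
                    for s in list(by_len.get(L, [])):
                        x = d[s]
                        for ci, c in enumerate(RNA):
                            s2 = c + s if left else s + c
                            val = st.emission(ci) + tr + x
                            if val > d.get(s2, NEG_INF):
                                d[s2] = val
                                if s2 not in by_len.setdefault(L + 1, []):
                                    by_len[L + 1].append(s2)
        elif t is StateType.MP:
            for w, tr in st.transitions.items():
                for s, x in table[w].items():
                    if len(s) + 2 > max_len:
                        continue
                    for ci in range(16):
                        c1, c2 = RNA[ci // 4], RNA[ci % 4]
                        relax(d, c1 + s + c2, st.emission(ci) + tr + x)

    return table[0]


def brute_force_best_sequence(model: CovarianceModel, max_len: int) -> ParseResult:
    """Exact maximum of the optimal parse score over all sequences of length
    <= max_len, by full enumeration. Ties resolved by length-then-lex order."""
    scores = all_sequence_scores(model, max_len)
    if not scores:
        return ParseResult(NEG_INF, "", "", [])
    winner = min(
        (s for s in scores),
        key=lambda s: (-scores[s], len(s), s),
    )
    return optimal_parse_score(model, winner)


def check_model(model: CovarianceModel) -> None:
    """Raise ValueError listing diagnostics if the model is invalid."""
    diags = validate_model(model)
    if diags:
        raise ValueError("invalid model: " + "; ".join(diags[:5]))
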