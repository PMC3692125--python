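"""Link sequence and Link score for a pair of covariance models.

The Link sequence of two models is the single sequence scoring highest in both
models *simultaneously*; its Link score is the lower of the two model scores.
A Link score of 20 bits therefore certifies a sequence scoring at least 20
bits in each model — the operational definition of model overlap used for
specificity checks and clan-candidate screening.

The computation is a dynamic program over the product of the two state
machines: a DP cell pairs one state of each model, so the table is quadratic
in the two state counts. Both models jointly emit one common sequence
outside-in. Emitting states pair only when their emission footprint matches
(left with left, right with right, pair with pair), so the two parses read the
identical string; silent states advance one model while the other waits. Two
asymmetric devices widen the representable space:

* **MP split** — a pair-emitting MP state of one model may be matched against
  a left-emitter *and* (later) a right-emitter of the other model. The
  deferred half of the pair is carried as a small "owed characters" ledger in
  the cell key, bounded by ``max_pending``.
* **One-sided bifurcation** — when exactly one model bifurcates, the other
  model's remaining linear state run is split at a chosen state between the
  two branches; inside the left branch the linear model is restricted to
  left emissions so that the split is a genuine parse of the common string.

Each cell stores the Pareto frontier of achievable score pairs (a, b) — every
pair not dominated in both coordinates — rather than a single greedy choice.
Because score pairs add componentwise along a parse, propagating frontiers
makes the final max-min selection exact over the representable joint-parse
space; on bifurcation-free pairs it matches exhaustive enumeration. The
representable space is a subset of all parse pairs (deep MP nesting against an
unpaired partner beyond ``max_pending``, or re-bifurcating subtrees inside a
one-sided branch, are not reachable), so in general the Link score is a lower
bound certified by an explicit joint parse: re-scoring the Link sequence in
either model can only score higher.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Optional

from .alphabet import RNA
from .model import (
    NEG_INF,
    CovarianceModel,
    StateType,
    validate_model,
)
from operator import itemgetter

from .scoring import (
    BRUTE_FORCE_MAX_LEN,
    BruteForceGuardError,
    all_sequence_scores,
    optimal_parse_score,
)

_AB_KEY = itemgetter(0, 1)

_SILENT = (StateType.S, StateType.D)
_LEFT = (StateType.ML, StateType.IL)
_RIGHT = (StateType.MR, StateType.IR)


class ProductHazardError(ValueError):
    """A reachable product cycle has non-negative min-gain."""


@dataclass
class LinkResult:
    """One pairwise model comparison."""

    model_a: str
    model_b: str
    score_a: float
    score_b: float
    link_sequence: str
    structure_a: str
    structure_b: str
    #: number of product-DP cells materialized (complexity diagnostics)
    cells: int = 0

    @property
    def link_score(self) -> float:
        return min(self.score_a, self.score_b)


def product_hazard(model_a: CovarianceModel, model_b: CovarianceModel) -> Optional[str]:
    """Check every reachable product cycle for non-negative min-gain.

    Product cycles arise only from simultaneous insert self-loops with the
    same emission direction; the cycle repeats profitably iff some nucleotide
    has non-negative gain in *both* models at once.
    """
    for kinds in (_LEFT, _RIGHT):
        ins_a = [
            s
            for s in model_a.states
            if s.state_type in kinds and s.index in s.transitions
        ]
        ins_b = [
            s
            for s in model_b.states
            if s.state_type in kinds and s.index in s.transitions
        ]
        for sa in ins_a:
            ta = sa.transitions[sa.index]
            for sb in ins_b:
                tb = sb.transitions[sb.index]
                for c in range(4):
                    g = min(ta + sa.emission(c), tb + sb.emission(c))
                    if g >= 0:
                        return (
                            f"product cycle {model_a.name}:{sa.index} x "
                            f"{model_b.name}:{sb.index} has min-gain {g:+.3f} "
                            f">= 0 on {RNA[c]}"
                        )
    return None


class _Engine:
    """Memoized product DP with Pareto frontiers per cell.

    Frontier entries are tuples ``(a, b, trace)``; traces reference child
    entries directly, so rendering the link sequence is a pure walk.
    """

    def __init__(
        self,
        model_a: CovarianceModel,
        model_b: CovarianceModel,
        max_pending: int = 2,
        max_frontier: Optional[int] = None,
    ):
        self.a = model_a.states
        self.b = model_b.states
        self.ch_a = [sorted(s.transitions) for s in self.a]
        self.ch_b = [sorted(s.transitions) for s in self.b]
        # solo emissions matter only when match-state emission order can
        # disagree between the models, i.e. when right match-emitters exist
        self.solo = any(
            s.state_type is StateType.MR for s in (*self.a, *self.b)
        )
        self.max_pending = max_pending
        self.max_frontier = max_frontier
        self.memo: dict = {}
        self.memo_g: dict = {}

    # -- frontier utilities -------------------------------------------------

    def _prune(self, cands: list) -> list:
        cands = [e for e in cands if e[0] > NEG_INF and e[1] > NEG_INF]
        if len(cands) <= 1:
            return cands
        # descending in a, then b: one sweep keeps the Pareto frontier
        cands.sort(key=_AB_KEY, reverse=True)
        kept = []
        best_b = NEG_INF
        for e in cands:
            if e[1] > best_b:
                kept.append(e)
                best_b = e[1]
        if self.max_frontier is not None and len(kept) > self.max_frontier:
            kept.sort(key=lambda e: (-min(e[0], e[1]), -max(e[0], e[1])))
            kept = kept[: self.max_frontier]
        return kept

    @staticmethod
    def _shift(entries: list, da: float, db: float, tag: str, payload) -> list:
        return [(da + e[0], db + e[1], (tag, payload, (e,))) for e in entries]

    @staticmethod
    def _lead_chars(deltas: list) -> list:
        """Drop nucleotide choices whose (da, db) increment is dominated:
        a dominated affine shift of the same child frontier can never
        contribute a Pareto-optimal candidate."""
        keep = []
        for i, (ci, da, db) in enumerate(deltas):
            if any(
                (da2 > da and db2 >= db) or (da2 >= da and db2 > db)
                for j, (cj, da2, db2) in enumerate(deltas)
                if j != i
            ):
                continue
            keep.append((ci, da, db))
        return keep

    # -- main recursion -----------------------------------------------------

    def frontier(self, key) -> list:
        hit = self.memo.get(key)
        if hit is not None:
            return hit
        self.memo[key] = []  # cycle guard; real cycles are excluded by moves
        va, vb, side, pl, pr, ok = key
        sa, sb = self.a[va], self.b[vb]
        ta, tb = sa.state_type, sb.state_type
        cands: list = []

        if ta is StateType.E and tb is StateType.E and not pl and not pr:
            cands.append((0.0, 0.0, ("end", None, ())))

        # silent advances
        if ta in _SILENT:
            for wa in sorted(sa.transitions):
                sub = self.frontier((wa, vb, side, pl, pr, ok))
                cands += self._shift(sub, sa.transitions[wa], 0.0, "silA", None)
        if tb in _SILENT:
            for wb in sorted(sb.transitions):
                sub = self.frontier((va, wb, side, pl, pr, ok))
                cands += self._shift(sub, 0.0, sb.transitions[wb], "silB", None)

        if ok:
            cands += self._emitting_moves(va, vb, side, pl, pr)
            cands += self._discharge_moves(va, vb, side, pl, pr)

        # bifurcations
        if ta is StateType.B and tb is StateType.B and not pl and not pr:
            la, ra = sa.bif_children
            lb, rb = sb.bif_children
            left = self.frontier((la, lb, None, (), (), ok))
            right = self.frontier((ra, rb, None, (), (), ok))
            for el in left:
                for er in right:
                    cands.append(
                        (el[0] + er[0], el[1] + er[1], ("bif", None, (el, er)))
                    )
        elif ta is StateType.B and tb is not StateType.B and not pl and not pr:
            cands += self._one_sided(va, vb, ok, bif_on_a=True)
        elif tb is StateType.B and ta is not StateType.B and not pl and not pr:
            cands += self._one_sided(va, vb, ok, bif_on_a=False)

        result = self._prune(cands)
        self.memo[key] = result
        return result

    def _emitting_moves(self, va, vb, side, pl, pr) -> list:
        sa, sb = self.a[va], self.b[vb]
        ta, tb = sa.state_type, sb.state_type
        cands: list = []

        # paired single emissions
        if ta in _LEFT and tb in _LEFT and not pl:
            lead = self._lead_chars(
                [(c, sa.emission(c), sb.emission(c)) for c in range(4)]
            )
            for wa in self.ch_a[va]:
                for wb in self.ch_b[vb]:
                    if wa == va and wb == vb:
                        continue  # joint self-loop: strictly negative cycle
                    sub = self.frontier((wa, wb, side, pl, pr, True))
                    if not sub:
                        continue
                    t2 = sa.transitions[wa], sb.transitions[wb]
                    for c, ea, eb in lead:
                        cands += self._shift(
                            sub, t2[0] + ea, t2[1] + eb, "pairL", RNA[c]
                        )
        if ta in _RIGHT and tb in _RIGHT and not pr:
            lead = self._lead_chars(
                [(c, sa.emission(c), sb.emission(c)) for c in range(4)]
            )
            for wa in self.ch_a[va]:
                for wb in self.ch_b[vb]:
                    if wa == va and wb == vb:
                        continue
                    sub = self.frontier((wa, wb, side, pl, pr, True))
                    if not sub:
                        continue
                    t2 = sa.transitions[wa], sb.transitions[wb]
                    for c, ea, eb in lead:
                        cands += self._shift(
                            sub, t2[0] + ea, t2[1] + eb, "pairR", RNA[c]
                        )

        # pair emitters
        if ta is StateType.MP and tb is StateType.MP and not pl and not pr:
            lead = self._lead_chars(
                [(ci, sa.emission(ci), sb.emission(ci)) for ci in range(16)]
            )
            for wa in self.ch_a[va]:
                for wb in self.ch_b[vb]:
                    sub = self.frontier((wa, wb, side, pl, pr, True))
                    if not sub:
                        continue
                    t2 = sa.transitions[wa], sb.transitions[wb]
                    for ci, ea, eb in lead:
                        cands += self._shift(
                            sub, t2[0] + ea, t2[1] + eb, "mpmp",
                            (RNA[ci // 4], RNA[ci % 4]),
                        )

        # MP of A split across two singlet emitters of B
        if ta is StateType.MP and side in (None, "B"):
            if tb in _LEFT and not pl and len(pr) < self.max_pending:
                leads = [
                    self._lead_chars(
                        [(c1, sa.emission(c1 * 4 + c2), sb.emission(c1)) for c1 in range(4)]
                    )
                    for c2 in range(4)
                ]
                for wa in self.ch_a[va]:
                    for wb in self.ch_b[vb]:
                        t2 = sa.transitions[wa], sb.transitions[wb]
                        for c2 in range(4):
                            sub = self.frontier((wa, wb, "B", pl, pr + (c2,), True))
                            if not sub:
                                continue
                            for c1, ea, eb in leads[c2]:
                                cands += self._shift(
                                    sub, t2[0] + ea, t2[1] + eb, "mpsA",
                                    (RNA[c1], RNA[c2]),
                                )
            if tb in _RIGHT and not pr and len(pl) < self.max_pending:
                leads = [
                    self._lead_chars(
                        [(c2, sa.emission(c1 * 4 + c2), sb.emission(c2)) for c2 in range(4)]
                    )
                    for c1 in range(4)
                ]
                for wa in self.ch_a[va]:
                    for wb in self.ch_b[vb]:
                        t2 = sa.transitions[wa], sb.transitions[wb]
                        for c1 in range(4):
                            sub = self.frontier((wa, wb, "B", pl + (c1,), pr, True))
                            if not sub:
                                continue
                            for c2, ea, eb in leads[c1]:
                                cands += self._shift(
                                    sub, t2[0] + ea, t2[1] + eb, "mpsA",
                                    (RNA[c1], RNA[c2]),
                                )

        # MP of B split across two singlet emitters of A
        if tb is StateType.MP and side in (None, "A"):
            if ta in _LEFT and not pl and len(pr) < self.max_pending:
                leads = [
                    self._lead_chars(
                        [(c1, sa.emission(c1), sb.emission(c1 * 4 + c2)) for c1 in range(4)]
                    )
                    for c2 in range(4)
                ]
                for wa in self.ch_a[va]:
                    for wb in self.ch_b[vb]:
                        t2 = sa.transitions[wa], sb.transitions[wb]
                        for c2 in range(4):
                            sub = self.frontier((wa, wb, "A", pl, pr + (c2,), True))
                            if not sub:
                                continue
                            for c1, ea, eb in leads[c2]:
                                cands += self._shift(
                                    sub, t2[0] + ea, t2[1] + eb, "mpsB",
                                    (RNA[c1], RNA[c2]),
                                )
            if ta in _RIGHT and not pr and len(pl) < self.max_pending:
                leads = [
                    self._lead_chars(
                        [(c2, sa.emission(c2), sb.emission(c1 * 4 + c2)) for c2 in range(4)]
                    )
                    for c1 in range(4)
                ]
                for wa in self.ch_a[va]:
                    for wb in self.ch_b[vb]:
                        t2 = sa.transitions[wa], sb.transitions[wb]
                        for c1 in range(4):
                            sub = self.frontier((wa, wb, "A", pl + (c1,), pr, True))
                            if not sub:
                                continue
                            for c2, ea, eb in leads[c1]:
                                cands += self._shift(
                                    sub, t2[0] + ea, t2[1] + eb, "mpsB",
                                    (RNA[c1], RNA[c2]),
                                )

        # solo match emissions: one model emits a boundary character now and
        # the partner owes it, making it up later through a discharge. This
        # reconciles parse pairs whose emission orders disagree (one model
        # reaching a character rightward early, the other leftward late).
        # a solo move is only needed when the partner sits at an emitter of
        # the opposite direction (or a pair emitter): if the partner could
        # pair the same boundary character, the paired move already covers
        # the parse, and silent partners can simply advance first.
        if self.solo:
            _solo_vs_left = (StateType.MR, StateType.IR, StateType.MP)
            _solo_vs_right = (StateType.ML, StateType.IL, StateType.MP)
            if (
                ta is StateType.ML
                and tb in _solo_vs_left
                and side in (None, "B")
                and len(pl) < self.max_pending
            ):
                for wa in self.ch_a[va]:
                    ta_w = sa.transitions[wa]
                    for c in range(4):
                        sub = self.frontier((wa, vb, "B", pl + (c,), pr, True))
                        if sub:
                            cands += self._shift(
                                sub, ta_w + sa.emission(c), 0.0, "soloL", RNA[c]
                            )
            if (
                ta is StateType.MR
                and tb in _solo_vs_right
                and side in (None, "B")
                and len(pr) < self.max_pending
            ):
                for wa in self.ch_a[va]:
                    ta_w = sa.transitions[wa]
                    for c in range(4):
                        sub = self.frontier((wa, vb, "B", pl, pr + (c,), True))
                        if sub:
                            cands += self._shift(
                                sub, ta_w + sa.emission(c), 0.0, "soloR", RNA[c]
                            )
            if (
                tb is StateType.ML
                and ta in _solo_vs_left
                and side in (None, "A")
                and len(pl) < self.max_pending
            ):
                for wb in self.ch_b[vb]:
                    tb_w = sb.transitions[wb]
                    for c in range(4):
                        sub = self.frontier((va, wb, "A", pl + (c,), pr, True))
                        if sub:
                            cands += self._shift(
                                sub, 0.0, tb_w + sb.emission(c), "soloL", RNA[c]
                            )
            if (
                tb is StateType.MR
                and ta in _solo_vs_right
                and side in (None, "A")
                and len(pr) < self.max_pending
            ):
                for wb in self.ch_b[vb]:
                    tb_w = sb.transitions[wb]
                    for c in range(4):
                        sub = self.frontier((va, wb, "A", pl, pr + (c,), True))
                        if sub:
                            cands += self._shift(
                                sub, 0.0, tb_w + sb.emission(c), "soloR", RNA[c]
                            )

        # crossed boundary pairing: a left emitter of one model against a
        # right emitter of the other is sound only when the remaining common
        # interval is that single character, enforced by forbidding any
        # further emission downstream.
        if not pl and not pr:
            if ta in _LEFT and tb in _RIGHT:
                cands += self._cross(va, vb, side)
            elif ta in _RIGHT and tb in _LEFT:
                cands += self._cross(va, vb, side)

        return cands

    def _cross(self, va, vb, side) -> list:
        sa, sb = self.a[va], self.b[vb]
        cands: list = []
        lead = self._lead_chars(
            [(c, sa.emission(c), sb.emission(c)) for c in range(4)]
        )
        for wa in self.ch_a[va]:
            for wb in self.ch_b[vb]:
                sub = self.frontier((wa, wb, side, (), (), False))
                if not sub:
                    continue
                t2 = sa.transitions[wa], sb.transitions[wb]
                for c, ea, eb in lead:
                    cands += self._shift(sub, t2[0] + ea, t2[1] + eb, "cross", RNA[c])
        return cands

    def _discharge_moves(self, va, vb, side, pl, pr) -> list:
        if side is None:
            return []
        cands: list = []
        if side == "B":
            st, other_done = self.b[vb], self.a[va].state_type is StateType.E
        else:
            st, other_done = self.a[va], self.b[vb].state_type is StateType.E
        t = st.state_type
        pops = []  # (char, new_pl, new_pr)
        if t in _RIGHT:
            if pr:
                pops.append((pr[0], pl, pr[1:]))
            elif other_done and pl:
                pops.append((pl[-1], pl[:-1], pr))
        elif t in _LEFT:
            if pl:
                pops.append((pl[0], pl[1:], pr))
            elif other_done and pr:
                pops.append((pr[-1], pl, pr[:-1]))
        for c, npl, npr in pops:
            nside = side if (npl or npr) else None
            for w in sorted(st.transitions):
                delta = st.transitions[w] + st.emission(c)
                if side == "B":
                    sub = self.frontier((va, w, nside, npl, npr, True))
                    cands += self._shift(sub, 0.0, delta, "disB", None)
                else:
                    sub = self.frontier((w, vb, nside, npl, npr, True))
                    cands += self._shift(sub, delta, 0.0, "disA", None)
        return cands

    # -- one-sided bifurcation ---------------------------------------------

    def _one_sided(self, va, vb, ok, bif_on_a: bool) -> list:
        cands: list = []
        if bif_on_a:
            la, ra = self.a[va].bif_children
            per_sigma = self.g_frontier((la, vb, (), ok, True))
            for sigma, entries in sorted(per_sigma.items()):
                right = self.frontier((ra, sigma, None, (), (), ok))
                for el in entries:
                    for er in right:
                        cands.append(
                            (el[0] + er[0], el[1] + er[1], ("bif1", None, (el, er)))
                        )
        else:
            lb, rb = self.b[vb].bif_children
            per_sigma = self.g_frontier((va, lb, (), ok, False))
            for sigma, entries in sorted(per_sigma.items()):
                right = self.frontier((sigma, rb, None, (), (), ok))
                for el in entries:
                    for er in right:
                        cands.append(
                            (el[0] + er[0], el[1] + er[1], ("bif1", None, (el, er)))
                        )
        return cands

    def g_frontier(self, key) -> dict:
        """Left branch of a one-sided bifurcation.

        The bifurcating model runs its left subtree to its E state; the linear
        model is restricted to silent moves, left emissions and MP-split
        discharges, and may stop at any state sigma, which keys the result.
        ``bif_on_a`` selects which model owns the subtree.
        """
        hit = self.memo_g.get(key)
        if hit is not None:
            return hit
        self.memo_g[key] = {}
        v_sub, v_lin, pr, ok, bif_on_a = key
        sub_states = self.a if bif_on_a else self.b
        lin_states = self.b if bif_on_a else self.a
        ss, sl = sub_states[v_sub], lin_states[v_lin]
        ts, tl = ss.state_type, sl.state_type
        out: dict[int, list] = {}

        def add(sigma, entries):
            out.setdefault(sigma, []).extend(entries)

        def shift2(entries, dsub, dlin, tag, payload):
            if bif_on_a:
                return self._shift(entries, dsub, dlin, tag, payload)
            return self._shift(entries, dlin, dsub, tag, payload)

        if ts is StateType.E:
            if not pr:
                gend = [(0.0, 0.0, ("gend", None, ()))]
                add(v_lin, gend)
            else:
                # owed right characters are emitted by the linear model's
                # next left emissions once the subtree is exhausted
                if tl in _LEFT:
                    c = pr[-1]
                    for w in sorted(sl.transitions):
                        sub = self.g_frontier((v_sub, w, pr[:-1], True, bif_on_a))
                        d = sl.transitions[w] + sl.emission(c)
                        for sigma, entries in sub.items():
                            add(sigma, shift2(entries, 0.0, d, "disB" if bif_on_a else "disA", None))
                if tl in _SILENT:
                    for w in sorted(sl.transitions):
                        sub = self.g_frontier((v_sub, w, pr, ok, bif_on_a))
                        for sigma, entries in sub.items():
                            add(sigma, shift2(entries, 0.0, sl.transitions[w], "silB" if bif_on_a else "silA", None))
            result = {s: self._prune(es) for s, es in out.items()}
            result = {s: es for s, es in result.items() if es}
            self.memo_g[key] = result
            return result

        if ts in _SILENT:
            for w in sorted(ss.transitions):
                sub = self.g_frontier((w, v_lin, pr, ok, bif_on_a))
                for sigma, entries in sub.items():
                    add(sigma, shift2(entries, ss.transitions[w], 0.0, "silA" if bif_on_a else "silB", None))
        if tl in _SILENT:
            for w in sorted(sl.transitions):
                sub = self.g_frontier((v_sub, w, pr, ok, bif_on_a))
                for sigma, entries in sub.items():
                    add(sigma, shift2(entries, 0.0, sl.transitions[w], "silB" if bif_on_a else "silA", None))
        if ok and ts in _LEFT and tl in _LEFT:
            for wa in sorted(ss.transitions):
                for wb in sorted(sl.transitions):
                    if wa == v_sub and wb == v_lin:
                        continue
                    sub = self.g_frontier((wa, wb, pr, True, bif_on_a))
                    for c in range(4):
                        ds = ss.transitions[wa] + ss.emission(c)
                        dl = sl.transitions[wb] + sl.emission(c)
                        for sigma, entries in sub.items():
                            add(sigma, shift2(entries, ds, dl, "pairL", RNA[c]))
        if ok and ts is StateType.MP and tl in _LEFT and len(pr) < self.max_pending:
            tag = "mpsA" if bif_on_a else "mpsB"
            for wa in sorted(ss.transitions):
                for wb in sorted(sl.transitions):
                    for c2 in range(4):
                        sub = self.g_frontier((wa, wb, pr + (c2,), True, bif_on_a))
                        if not sub:
                            continue
                        for c1 in range(4):
                            ci = c1 * 4 + c2
                            ds = ss.transitions[wa] + ss.emission(ci)
                            dl = sl.transitions[wb] + sl.emission(c1)
                            for sigma, entries in sub.items():
                                add(sigma, shift2(entries, ds, dl, tag, (RNA[c1], RNA[c2])))

        result = {s: self._prune(es) for s, es in out.items()}
        result = {s: es for s, es in result.items() if es}
        self.memo_g[key] = result
        return result

    @property
    def cell_count(self) -> int:
        return len(self.memo) + len(self.memo_g)


def _render(entry) -> tuple[str, str, str]:
    """Walk a frontier entry's trace into (sequence, structure_a, structure_b)."""
    a, b, trace = entry
    tag, payload, kids = trace
    if tag in ("end", "gend"):
        return "", "", ""
    if tag in ("silA", "silB", "disA", "disB"):
        return _render(kids[0])
    if tag in ("bif", "bif1"):
        s1, fa1, fb1 = _render(kids[0])
        s2, fa2, fb2 = _render(kids[1])
        return s1 + s2, fa1 + fa2, fb1 + fb2
    s, fa, fb = _render(kids[0])
    if tag in ("pairL", "cross", "soloL"):
        return payload + s, "." + fa, "." + fb
    if tag in ("pairR", "soloR"):
        return s + payload, fa + ".", fb + "."
    c1, c2 = payload
    if tag == "mpmp":
        return c1 + s + c2, "(" + fa + ")", "(" + fb + ")"
    if tag == "mpsA":
        return c1 + s + c2, "(" + fa + ")", "." + fb + "."
    if tag == "mpsB":
        return c1 + s + c2, "." + fa + ".", "(" + fb + ")"
    raise AssertionError(f"unknown trace tag {tag}")


def link_models(
    model_a: CovarianceModel,
    model_b: CovarianceModel,
    max_pending: int = 2,
    max_frontier: Optional[int] = None,
) -> LinkResult:
    """Compute the Link sequence and Link score of a model pair.

    Both models must be valid and free of insert self-loop hazards; a
    reachable product cycle with non-negative min-gain raises
    :class:`ProductHazardError`. When no joint parse exists at all, the result
    carries sentinel scores and an empty sequence.
    """
    for m in (model_a, model_b):
        diags = validate_model(m)
        if diags:
            raise ValueError(f"model {m.name} is invalid: " + "; ".join(diags[:3]))
    hazard = product_hazard(model_a, model_b)
    if hazard is not None:
        raise ProductHazardError(hazard)

    limit = 10000 + 50 * (len(model_a.states) + len(model_b.states))
    if sys.getrecursionlimit() < limit:
        sys.setrecursionlimit(limit)

    eng = _Engine(model_a, model_b, max_pending=max_pending, max_frontier=max_frontier)
    root = eng.frontier((0, 0, None, (), (), True))
    if not root:
        return LinkResult(
            model_a.name, model_b.name, NEG_INF, NEG_INF, "", "", "",
            cells=eng.cell_count,
        )
    winner = root[0]
    for e in root[1:]:
        if (min(e[0], e[1]), max(e[0], e[1])) > (
            min(winner[0], winner[1]),
            max(winner[0], winner[1]),
        ):
            winner = e
    seq, fa, fb = _render(winner)
    return LinkResult(
        model_a.name,
        model_b.name,
        winner[0],
        winner[1],
        seq,
        fa,
        fb,
        cells=eng.cell_count,
    )


def product_structures(result: LinkResult) -> tuple[str, str]:
    """The per-model consensus structures proposed for the link sequence.

    Brackets appear exactly at positions emitted through that model's MP
    states on the joint parse; positions the model emitted as singlets are
    dots. A position paired in one structure may therefore be unpaired in the
    other.
    """
    return result.structure_a, result.structure_b


def brute_force_link(
    model_a: CovarianceModel, model_b: CovarianceModel, max_len: int
) -> LinkResult:
    """Exact Link result by enumerating every sequence up to ``max_len``.

    For each sequence the true per-model optima are used, so this bounds
    :func:`link_models` from above on any pair small enough to enumerate.
    """
    if max_len > BRUTE_FORCE_MAX_LEN:
        raise BruteForceGuardError(
            f"max_len {max_len} exceeds the guard ({BRUTE_FORCE_MAX_LEN})"
        )
    da = all_sequence_scores(model_a, max_len)
    db = all_sequence_scores(model_b, max_len)
    common = set(da) & set(db)
    if not common:
        return LinkResult(model_a.name, model_b.name, NEG_INF, NEG_INF, "", "", "")
    winner = min(
        common,
        key=lambda s: (
            -min(da[s], db[s]),
            -max(da[s], db[s]),
            len(s),
            s,
        ),
    )
    ra = optimal_parse_score(model_a, winner)
    rb = optimal_parse_score(model_b, winner)
    return LinkResult(
        model_a.name,
        model_b.name,
        ra.score,
        rb.score,
        winner,
        ra.structure,
        rb.structure,
    )
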