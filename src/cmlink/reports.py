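"""Result rendering: TSV tables, link-score matrices, DOT graphs, detail view.

All renderers are pure functions of their inputs and byte-deterministic:
the same table always renders to the same text. Scores are printed to one
decimal; comparisons elsewhere in the library stay at full precision. TSV is
the canonical tabular output — sorting and styling belong to downstream
tools. DOT text is emitted but never rendered; layout is the renderer's job.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .linker import LinkResult
from .model import NEG_INF, CovarianceModel
from .scoring import optimal_parse_score
from .workflows import LinkGraph, LinkTable, TableMode

TSV_COLUMNS = (
    "modelA",
    "modelB",
    "scoreA",
    "scoreB",
    "linkScore",
    "linkSequence",
    "structureA",
    "structureB",
)


class DiagonalPolicy(str, Enum):
    BEST_SCORE = "BEST_SCORE"
    BLANK = "BLANK"


@dataclass
class ScoreMatrix:
    """Symmetric all-vs-all link-score matrix."""

    names: list[str]
    values: np.ndarray
    diagonal_policy: DiagonalPolicy

    def to_tsv(self) -> str:
        lines = ["\t".join(["model"] + self.names)]
        for i, name in enumerate(self.names):
            row = [name]
            for j in range(len(self.names)):
                v = self.values[i, j]
                row.append("-" if not np.isfinite(v) else f"{v:.1f}")
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def _fmt_score(v: float) -> str:
    return "-inf" if v == NEG_INF else f"{v:.1f}"


def to_tsv(table: LinkTable) -> str:
    """Sortable result list: header plus one row per comparison."""
    lines = ["\t".join(TSV_COLUMNS)]
    for e in table.entries:
        lines.append(
            "\t".join(
                (
                    e.model_a,
                    e.model_b,
                    _fmt_score(e.score_a),
                    _fmt_score(e.score_b),
                    _fmt_score(e.link_score),
                    e.link_sequence,
                    e.structure_a,
                    e.structure_b,
                )
            )
        )
    return "\n".join(lines) + "\n"


def parse_tsv(text: str) -> list[dict]:
    """Read back a result TSV (numeric fields at printed precision)."""
    lines = [ln for ln in text.splitlines() if ln]
    header = lines[0].split("\t")
    out = []
    for ln in lines[1:]:
        rec = dict(zip(header, ln.split("\t")))
        for k in ("scoreA", "scoreB", "linkScore"):
            rec[k] = float(rec[k])
        out.append(rec)
    return out


def to_matrix(
    table: LinkTable, diagonal_policy: DiagonalPolicy = DiagonalPolicy.BEST_SCORE
) -> ScoreMatrix:
    """Square symmetric matrix of link scores over the table's models.

    Only meaningful for all-vs-all tables. Missing pairs stay at the
    sentinel; the diagonal holds each model's best achievable score
    (BEST_SCORE) or NaN (BLANK).
    """
    if table.mode is not TableMode.ALL_VS_ALL:
        raise ValueError("link-score matrix requires an ALL_VS_ALL table")
    names = list(table.models)
    idx = {n: i for i, n in enumerate(names)}
    k = len(names)
    values = np.full((k, k), NEG_INF)
    for e in table.entries:
        i, j = idx[e.model_a], idx[e.model_b]
        values[i, j] = values[j, i] = e.link_score
    for n, i in idx.items():
        if diagonal_policy is DiagonalPolicy.BEST_SCORE:
            values[i, i] = table.self_scores.get(n, NEG_INF)
        else:
            values[i, i] = np.nan
    return ScoreMatrix(names=names, values=values, diagonal_policy=diagonal_policy)


def matrix_bins(matrix: ScoreMatrix, thresholds: tuple[float, ...] = (10.0, 20.0, 40.0)) -> str:
    """Discretized matrix: each cell replaced by its bin index (0 = below the
    first threshold). A plain-text stand-in for a color-coded heat map."""
    lines = ["\t".join(["model"] + matrix.names)]
    for i, name in enumerate(matrix.names):
        row = [name]
        for j in range(len(matrix.names)):
            v = matrix.values[i, j]
            if not np.isfinite(v):
                row.append("-")
            else:
                row.append(str(sum(1 for t in thresholds if v >= t)))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def _dot_quote(name: str) -> str:
    return '"' + name.replace("\\", "\\\\").replace('"', '\\"') + '"'


def to_dot(graph: LinkGraph) -> str:
    """Undirected DOT graph: model names as node labels, link scores as edge
    labels. No layout coordinates are emitted."""
    lines = ["graph links {"]
    for n in graph.nodes:
        lines.append(f"  {_dot_quote(n)};")
    for a, b, w in graph.edges:
        lines.append(f"  {_dot_quote(a)} -- {_dot_quote(b)} [label={w:.1f}];")
    lines.append("}")
    return "\n".join(lines) + "\n"


def detail_view(
    result: LinkResult, model_a: CovarianceModel, model_b: CovarianceModel
) -> str:
    """Human-readable block for one pairwise comparison.

    Shows the joint-parse scores whose minimum is the link score, the link
    sequence with both proposed structures aligned underneath, and — for
    transparency — each model's re-optimized score for the link sequence,
    which may exceed the joint-parse score.
    """
    if {result.model_a, result.model_b} != {model_a.name, model_b.name}:
        raise ValueError(
            f"result pairs {result.model_a}/{result.model_b}, got models "
            f"{model_a.name}/{model_b.name}"
        )
    if model_a.name != result.model_a:
        model_a, model_b = model_b, model_a
    lines = [
        f"model A       : {result.model_a}",
        f"model B       : {result.model_b}",
        f"score A       : {_fmt_score(result.score_a)} bits",
        f"score B       : {_fmt_score(result.score_b)} bits",
        f"Link score    : {_fmt_score(result.link_score)} bits",
        f"Link sequence : {result.link_sequence}",
        f"structure A   : {result.structure_a}",
        f"structure B   : {result.structure_b}",
    ]
    if result.link_sequence:
        ra = optimal_parse_score(model_a, result.link_sequence)
        rb = optimal_parse_score(model_b, result.link_sequence)
        lines += [
            f"re-optimized A: {_fmt_score(ra.score)} bits",
            f"re-optimized B: {_fmt_score(rb.score)} bits",
        ]
    return "\n".join(lines) + "\n"
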