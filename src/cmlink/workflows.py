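"""Batch comparison workflows: one-vs-many, all-vs-all, filtering, graphs.

"One versus many" compares query models against a model database — in
practice a directory of CM files standing in for Rfam or a subtype slice of
it; "all versus all" compares a model set against itself, the mode used to
inspect candidate clans. Failures are isolated per pair: one bad model never
aborts a batch. Pair order is deterministic and canonical regardless of how
the computation is scheduled.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import networkx as nx

from .linker import LinkResult, link_models
from .model import CovarianceModel, validate_model
from .scoring import best_sequence

logger = logging.getLogger(__name__)


class TableMode(str, Enum):
    ONE_VS_MANY = "ONE_VS_MANY"
    ALL_VS_ALL = "ALL_VS_ALL"


@dataclass
class LinkTable:
    """All pairwise results of one comparison run.

    ``self_scores`` holds each model's best achievable score (its self-link
    score), used for the matrix diagonal; ``errors`` records per-pair
    failures without aborting the batch.
    """

    models: list[str]
    entries: list[LinkResult]
    mode: TableMode
    self_scores: dict[str, float] = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class FilterSpec:
    """Result-list filter: name substring, score threshold, top-N cut."""

    name_pattern: Optional[str] = None
    min_link_score: Optional[float] = None
    top_n: Optional[int] = None

    def __post_init__(self):
        if self.top_n is not None and self.top_n < 1:
            raise ValueError("top_n must be >= 1")


@dataclass
class LinkGraph:
    """Weighted-graph view: models as nodes, link scores as edge weights."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g


def _checked_names(models: list[CovarianceModel]) -> None:
    seen = set()
    for m in models:
        if m.name in seen:
            raise ValueError(f"duplicate model name {m.name!r}; names must be unique")
        seen.add(m.name)


def _self_scores(models: list[CovarianceModel], errors: list[str]) -> dict[str, float]:
    out = {}
    for m in models:
        diags = validate_model(m)
        if diags:
            errors.append(f"{m.name}: invalid model: " + "; ".join(diags[:3]))
            continue
        try:
            out[m.name] = best_sequence(m).score
        except ValueError as exc:
            errors.append(f"{m.name}: {exc}")
    return out


def compare_one_vs_many(
    queries: list[CovarianceModel], database: list[CovarianceModel]
) -> LinkTable:
    """Link every query model against every database model.

    Entries appear in query order, then database order. A query that also
    sits in the database is compared against its own copy like any other
    pair. Subtype restriction ("only tRNAs", "only miRNAs") is expressed by
    passing a pre-filtered database list.
    """
    if not queries or not database:
        raise ValueError("need at least one query and one database model")
    _checked_names(queries)
    _checked_names(database)
    errors: list[str] = []
    entries: list[LinkResult] = []
    for q in queries:
        for d in database:
            t0 = time.perf_counter()
            try:
                entries.append(link_models(q, d))
                logger.info(
                    "linked %s vs %s in %.3fs", q.name, d.name,
                    time.perf_counter() - t0,
                )
            except ValueError as exc:
                errors.append(f"{q.name} vs {d.name}: {exc}")
                logger.warning("pair %s vs %s failed: %s", q.name, d.name, exc)
    names = [m.name for m in queries] + [
        m.name for m in database if m.name not in {q.name for q in queries}
    ]
    table = LinkTable(
        models=names, entries=entries, mode=TableMode.ONE_VS_MANY, errors=errors
    )
    table.self_scores = _self_scores(queries + database, errors)
    return table


def compare_all_vs_all(models: list[CovarianceModel]) -> LinkTable:
    """Link every unordered model pair once: k models give k(k-1)/2 entries.

    Self pairs are excluded from the table; the matrix view derives diagonal
    values from each model's best achievable score instead.
    """
    if len(models) < 2:
        raise ValueError("all-vs-all needs at least 2 models")
    _checked_names(models)
    errors: list[str] = []
    entries: list[LinkResult] = []
    for i, a in enumerate(models):
        for b in models[i + 1 :]:
            t0 = time.perf_counter()
            try:
                entries.append(link_models(a, b))
                logger.info(
                    "linked %s vs %s in %.3fs", a.name, b.name,
                    time.perf_counter() - t0,
                )
            except ValueError as exc:
                errors.append(f"{a.name} vs {b.name}: {exc}")
                logger.warning("pair %s vs %s failed: %s", a.name, b.name, exc)
    table = LinkTable(
        models=[m.name for m in models],
        entries=entries,
        mode=TableMode.ALL_VS_ALL,
        errors=errors,
    )
    table.self_scores = _self_scores(models, errors)
    return table


def _sort_key(e: LinkResult):
    return (-e.link_score, e.model_a, e.model_b)


def filter_results(table: LinkTable, spec: FilterSpec) -> LinkTable:
    """Apply name/score/top-N filtering; idempotent for a fixed spec.

    Entries are kept when either model name contains the pattern
    (case-insensitive) and the link score clears the threshold, then sorted
    by descending link score (ties by name pair) and truncated to the top N.
    """
    kept = list(table.entries)
    if spec.name_pattern is not None:
        pat = spec.name_pattern.lower()
        kept = [
            e for e in kept if pat in e.model_a.lower() or pat in e.model_b.lower()
        ]
    if spec.min_link_score is not None:
        kept = [e for e in kept if e.link_score >= spec.min_link_score]
    kept.sort(key=_sort_key)
    if spec.top_n is not None:
        kept = kept[: spec.top_n]
    return LinkTable(
        models=list(table.models),
        entries=kept,
        mode=table.mode,
        self_scores=dict(table.self_scores),
        errors=list(table.errors),
    )


def build_link_graph(table: LinkTable, spec: FilterSpec = FilterSpec()) -> LinkGraph:
    """Thresholded weighted-graph view of a link table.

    Every model of the table becomes a node (isolated nodes are kept — a
    model with no surviving link is itself informative); entries surviving
    the filter become edges weighted by link score. Self-pairs never produce
    edges. In one-vs-many mode edges connect only query and database models,
    which holds by construction since entries only pair queries with database
    models.
    """
    filtered = filter_results(table, spec)
    edges = [
        (e.model_a, e.model_b, e.link_score)
        for e in filtered.entries
        if e.model_a != e.model_b
    ]
    return LinkGraph(nodes=list(table.models), edges=edges)


def clan_components(graph: LinkGraph) -> list[set[str]]:
    """Connected components of the thresholded link graph.

    Groups of models with mutually high link scores are clan candidates;
    actual clan construction remains a curator's call.
    """
    comps = nx.connected_components(graph.to_networkx())
    return sorted((set(c) for c in comps), key=lambda c: sorted(c)[0])
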