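"""Lazy query construction as a directed acyclic operator graph.

A :class:`QueryNode` is a reference to a (not yet computed) dataset: source
nodes store only a path or an in-memory dataset handle, derived nodes store
an operator name, its parameters and their parent nodes.  No region data is
read and no operator runs until :func:`execute` or :func:`take` is called;
path existence is the one thing validated eagerly, so typos fail fast.

Execution evaluates the graph in topological order with per-execution
caching, so a node shared by several branches runs exactly once, and writes
every node tagged by :meth:`QueryNode.collect` through the deterministic
dataset writer.
"""

from __future__ import annotations

import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from . import algebra, io
from .expressions import parse_predicate
from .model import ArgumentError, GDMDataset, GDMError

__all__ = [
    "QueryNode",
    "read_dataset_node",
    "collect",
    "execute",
    "take",
    "ExecutionReport",
    "NodeReport",
]

_TAG_RE = re.compile(r"^[A-Za-z0-9._-]+$")


def _as_predicate(value):
    if value is None:
        return None
    return parse_predicate(value) if isinstance(value, str) else value


class QueryNode:
    """One operator of a lazily-evaluated query graph."""

    def __init__(
        self,
        op: str,
        params: Optional[dict] = None,
        parents: Sequence["QueryNode"] = (),
    ) -> None:
        self.op = op
        self.params = params or {}
        self.parents = list(parents)
        self.materialize_tag: Optional[str] = None

    def __repr__(self) -> str:
        tag = f", tag={self.materialize_tag!r}" if self.materialize_tag else ""
        return f"QueryNode({self.op!r}{tag})"

    # fluent builders -------------------------------------------------------

    def _derive(self, op: str, params: dict, *extra_parents: "QueryNode") -> "QueryNode":
        return QueryNode(op, params, (self, *extra_parents))

    def filter(self, meta=None, region=None, semijoin=None) -> "QueryNode":
        if semijoin is not None:
            keys, other, mode = semijoin
            semijoin_params = {"keys": list(keys), "mode": mode}
            node = self._derive(
                "filter",
                {
                    "meta": _as_predicate(meta),
                    "region": _as_predicate(region),
                    "semijoin": semijoin_params,
                },
                other,
            )
            return node
        return self._derive(
            "filter",
            {"meta": _as_predicate(meta), "region": _as_predicate(region), "semijoin": None},
        )

    def project(
        self,
        keep_region_attrs=None,
        keep_meta_keys=None,
        regions_update=(),
        metadata_update=(),
    ) -> "QueryNode":
        from .expressions import parse_scalar_expr

        updates = [
            (name, parse_scalar_expr(expr) if isinstance(expr, str) else expr)
            for name, expr in regions_update
        ]
        return self._derive(
            "project",
            {
                "keep_region_attrs": keep_region_attrs,
                "keep_meta_keys": keep_meta_keys,
                "regions_update": updates,
                "metadata_update": list(metadata_update),
            },
        )

    def extend(self, specs) -> "QueryNode":
        return self._derive("extend", {"specs": list(specs)})

    def order(self, meta_keys=(), region_keys=(), mtop=None, rtop=None) -> "QueryNode":
        return self._derive(
            "order",
            {
                "meta_keys": list(meta_keys),
                "region_keys": list(region_keys),
                "mtop": mtop,
                "rtop": rtop,
            },
        )

    def group(self, meta_keys) -> "QueryNode":
        return self._derive("group", {"meta_keys": list(meta_keys)})

    def merge(self, groupby=None) -> "QueryNode":
        return self._derive("merge", {"groupby": groupby})

    def union(self, other: "QueryNode") -> "QueryNode":
        return self._derive("union", {}, other)

    def difference(self, other: "QueryNode", joinby=None) -> "QueryNode":
        return self._derive("difference", {"joinby": joinby}, other)

    def map(self, exp: "QueryNode", aggregates=(), joinby=None, count_name=None) -> "QueryNode":
        return self._derive(
            "map",
            {"aggregates": list(aggregates), "joinby": joinby, "count_name": count_name},
            exp,
        )

    def join(self, exp: "QueryNode", predicate, output="LEFT", joinby=None) -> "QueryNode":
        clauses = [
            algebra.parse_genometric_clause(c) if isinstance(c, str) else c
            for c in predicate
        ]
        return self._derive(
            "join", {"predicate": clauses, "output": output, "joinby": joinby}, exp
        )

    def cover(self, min_acc=1, max_acc=algebra.ANY, groupby=None, aggregates=()) -> "QueryNode":
        return self._derive(
            "cover",
            {
                "min_acc": min_acc,
                "max_acc": max_acc,
                "groupby": groupby,
                "aggregates": list(aggregates),
            },
        )

    def rename(self, name: str) -> "QueryNode":
        """Relabel the node's result dataset (affects derived attribute names)."""
        return self._derive("rename", {"name": name})

    def collect(self, name: str) -> "QueryNode":
        """Tag this node for persistence at execute time; still no computation."""
        if not _TAG_RE.match(name or ""):
            raise ArgumentError(f"illegal materialization name {name!r}")
        self.materialize_tag = name
        return self


def read_dataset_node(source: Union[str, Path, GDMDataset]) -> QueryNode:
    """Create a source node; validates the path but parses no region data."""
    if isinstance(source, GDMDataset):
        return QueryNode("read", {"dataset": source})
    path = Path(source)
    if not path.is_dir():
        raise GDMError(f"dataset directory does not exist: {path}")
    return QueryNode("read", {"path": path})


def collect(node: QueryNode, name: str) -> QueryNode:
    return node.collect(name)


# ---------------------------------------------------------------------------
# execution


@dataclass
class NodeReport:
    op: str
    status: str  # ok | failed | skipped
    n_samples: Optional[int] = None
    n_regions: Optional[int] = None
    seconds: float = 0.0
    output: Optional[str] = None
    error: Optional[str] = None
    tag: Optional[str] = None

    def format_line(self) -> str:
        counts = (
            f"{self.n_samples} samples / {self.n_regions} regions"
            if self.n_samples is not None
            else "-"
        )
        extra = f" -> {self.output}" if self.output else ""
        err = f" ({self.error})" if self.error else ""
        return f"{self.op:<12} {self.status:<8} {counts}{extra}{err}"


@dataclass
class ExecutionReport:
    entries: list = field(default_factory=list)

    @property
    def failed(self) -> bool:
        return any(e.status == "failed" for e in self.entries)

    def format_lines(self) -> list:
        return [e.format_line() for e in self.entries]


def _reachable(roots: Sequence[QueryNode]) -> list:
    """All nodes reachable from ``roots`` in topological (parents-first) order."""
    order: list = []
    seen: set = set()
    on_stack: set = set()

    def visit(node: QueryNode) -> None:
        if id(node) in seen:
            return
        if id(node) in on_stack:
            raise GDMError("query graph contains a cycle")
        on_stack.add(id(node))
        for parent in node.parents:
            visit(parent)
        on_stack.discard(id(node))
        seen.add(id(node))
        order.append(node)

    for root in roots:
        visit(root)
    return order


def _apply(node: QueryNode, inputs: Sequence[GDMDataset]) -> GDMDataset:
    p = node.params
    if node.op == "read":
        if "dataset" in p:
            return p["dataset"]
        return io.read_gdm_dataset(p["path"])
    if node.op == "rename":
        dataset = inputs[0]
        return GDMDataset(dataset.schema, dataset.samples, name=p["name"])
    if node.op == "filter":
        semijoin = None
        if p["semijoin"] is not None:
            semijoin = (p["semijoin"]["keys"], inputs[1], p["semijoin"]["mode"])
        return algebra.op_filter(inputs[0], p["meta"], p["region"], semijoin)
    if node.op == "project":
        return algebra.op_project(
            inputs[0],
            p["keep_region_attrs"],
            p["keep_meta_keys"],
            p["regions_update"],
            p["metadata_update"],
        )
    if node.op == "extend":
        return algebra.op_extend(inputs[0], p["specs"])
    if node.op == "order":
        return algebra.op_order(
            inputs[0], p["meta_keys"], p["region_keys"], p["mtop"], p["rtop"]
        )
    if node.op == "group":
        return algebra.op_group(inputs[0], p["meta_keys"])
    if node.op == "merge":
        return algebra.op_merge(inputs[0], p["groupby"])
    if node.op == "union":
        return algebra.op_union(inputs[0], inputs[1])
    if node.op == "difference":
        return algebra.op_difference(inputs[0], inputs[1], p["joinby"])
    if node.op == "map":
        return algebra.op_map(
            inputs[0], inputs[1], p["aggregates"], p["joinby"], p["count_name"]
        )
    if node.op == "join":
        return algebra.op_join(
            inputs[0], inputs[1], p["predicate"], p["output"], p["joinby"]
        )
    if node.op == "cover":
        return algebra.op_cover(
            inputs[0], p["min_acc"], p["max_acc"], p["groupby"], p["aggregates"]
        )
    raise GDMError(f"unknown operator {node.op!r}")


def execute(
    roots: Union[QueryNode, Sequence[QueryNode]], out: Union[str, Path]
) -> ExecutionReport:
    """Evaluate the graph and write every collected node under ``out``.

    Nodes are evaluated parents-first and cached per execution; a failing
    node is recorded in the report and its descendants are skipped, while
    independent branches still materialize.  Raises when no node in the graph
    is tagged for materialization or two nodes share a tag.
    """
    if isinstance(roots, QueryNode):
        roots = [roots]
    nodes = _reachable(roots)
    tags = [n.materialize_tag for n in nodes if n.materialize_tag]
    if not tags:
        raise GDMError("nothing to materialize: no node tagged by collect()")
    if len(tags) != len(set(tags)):
        dup = sorted({t for t in tags if tags.count(t) > 1})
        raise GDMError(f"duplicate materialization names {dup}")

    out_dir = Path(out)
    cache: dict = {}
    status: dict = {}
    report = ExecutionReport()
    for node in nodes:
        entry = NodeReport(op=node.op, status="ok", tag=node.materialize_tag)
        if any(status.get(id(parent)) != "ok" for parent in node.parents):
            entry.status = "skipped"
        else:
            start = time.perf_counter()
            try:
                result = _apply(node, [cache[id(parent)] for parent in node.parents])
                cache[id(node)] = result
                entry.n_samples = len(result)
                entry.n_regions = result.n_regions
                if node.materialize_tag:
                    target = out_dir / node.materialize_tag
                    io.write_gdm_dataset(result, target, overwrite=True)
                    entry.output = str(target)
            except Exception as exc:  # noqa: BLE001 - isolate per-branch failures
                entry.status = "failed"
                entry.error = f"{type(exc).__name__}: {exc}"
            entry.seconds = time.perf_counter() - start
        status[id(node)] = entry.status
        report.entries.append(entry)
    return report


def take(node: QueryNode, k: Optional[int] = None) -> GDMDataset:
    """Evaluate this node's subgraph and return the in-memory dataset.

    ``k`` truncates to the first k samples.  Each call evaluates afresh
    (caching is per-execution only).
    """
    if k is not None and k <= 0:
        raise ArgumentError("take k must be positive")
    cache: dict = {}
    for n in _reachable([node]):
        cache[id(n)] = _apply(n, [cache[id(p)] for p in n.parents])
    result = cache[id(node)]
    if k is None:
        return result
    return GDMDataset(result.schema, result.samples[:k], name=result.name)
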