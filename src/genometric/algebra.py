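"""The region/metadata operator algebra: pure dataset -> dataset transforms.

Every operator takes and returns :class:`~genometric.model.GDMDataset` values
and never mutates its inputs.  Unary operators preserve sample identity;
binary operators derive deterministic sample ids from the parent ids.  After
every operator each sample's regions are re-sorted by coordinates.

Overlap between two regions requires the same chromosome, at least one shared
base under half-open coordinates, and compatible strands (identical, or
either side ``*``).  The signed genomic distance between two regions is
``later.left - earlier.right``: overlapping regions have negative distance
and adjacent regions distance 0.
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

from intervaltree import IntervalTree

from .expressions import (
    Attr,
    Predicate,
    ScalarExpr,
    evaluate_meta_predicate,
    evaluate_region_expr,
    evaluate_region_predicate,
)
from .model import (
    AggregateSpec,
    ArgumentError,
    GDMDataset,
    MetadataSet,
    Region,
    Sample,
    Schema,
    SchemaError,
    Value,
    apply_aggregate,
    format_value,
)

__all__ = [
    "GenometricClause",
    "parse_genometric_clause",
    "ANY",
    "op_filter",
    "op_project",
    "op_extend",
    "op_order",
    "op_group",
    "op_merge",
    "op_union",
    "op_difference",
    "op_map",
    "op_join",
    "op_cover",
    "strand_compatible",
    "regions_overlap",
    "signed_distance",
]

ANY = "ANY"

JOIN_OUTPUT_MODES = ("LEFT", "RIGHT", "INT", "BOTH", "CAT")


# ---------------------------------------------------------------------------
# shared helpers


def strand_compatible(a: str, b: str) -> bool:
    return a == b or a == "*" or b == "*"


def regions_overlap(a: Region, b: Region) -> bool:
    return (
        a.chrom == b.chrom
        and a.left < b.right
        and b.left < a.right
        and strand_compatible(a.strand, b.strand)
    )


def signed_distance(a: Region, b: Region) -> int:
    """Gap between two same-chromosome regions; overlap < 0, adjacency = 0."""
    if a.left <= b.left:
        return b.left - a.right
    return a.left - b.right


def _derived_id(op: str, *parent_ids: str) -> str:
    digest = hashlib.sha1("|".join(parent_ids).encode("utf-8")).hexdigest()[:8]
    return f"{op}_{digest}"


def _joinby_match(a: Sample, b: Sample, keys: Sequence[str]) -> bool:
    """True iff for every key the two samples' value-sets intersect."""
    for key in keys:
        if not set(a.metadata.values(key)) & set(b.metadata.values(key)):
            return False
    return True


def _group_signature(sample: Sample, keys: Sequence[str]) -> tuple:
    return tuple(tuple(sample.metadata.values(k)) for k in keys)


def _group_samples(samples: Sequence[Sample], keys: Sequence[str]) -> list:
    """Partition samples by their metadata value-sets on ``keys``.

    Returns ``[(signature, [samples...]), ...]`` sorted by signature; a sample
    lacking a key contributes an empty value tuple for it.
    """
    groups: dict = {}
    for sample in samples:
        groups.setdefault(_group_signature(sample, keys), []).append(sample)
    return sorted(groups.items(), key=lambda item: item[0])


def _interval_tree(regions: Iterable[Region]) -> Mapping[str, IntervalTree]:
    trees: dict = {}
    for region in regions:
        trees.setdefault(region.chrom, IntervalTree()).addi(
            region.left, region.right, region
        )
    return trees


def _overlapping(trees: Mapping[str, IntervalTree], region: Region) -> list:
    tree = trees.get(region.chrom)
    if tree is None:
        return []
    hits = [
        iv.data
        for iv in tree.overlap(region.left, region.right)
        if strand_compatible(region.strand, iv.data.strand)
    ]
    hits.sort(key=lambda r: r.sort_key)
    return hits


def _aggregate_dtype(spec: AggregateSpec) -> str:
    if spec.fn == "COUNT":
        return "integer"
    if spec.fn == "BAG":
        return "string"
    return "float"


def _format_meta_number(value: Value) -> str:
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return format_value(value)


# ---------------------------------------------------------------------------
# filter


def op_filter(
    dataset: GDMDataset,
    meta_predicate: Optional[Predicate] = None,
    region_predicate: Optional[Predicate] = None,
    semijoin: Optional[tuple] = None,
) -> GDMDataset:
    """Keep metadata-matching samples and, within them, matching regions.

    ``semijoin`` is ``(keys, other_dataset, mode)`` with mode ``"IN"`` or
    ``"NOT_IN"``: a sample passes IN when, for every listed key, one of its
    values for that key also occurs for that key in at least one sample of
    ``other_dataset``.  Samples emptied by the region predicate are retained
    with zero regions.
    """
    if semijoin is not None:
        keys, other, mode = semijoin
        keys = list(keys)
        if not keys:
            raise ArgumentError("semijoin key list must be non-empty")
        if mode not in ("IN", "NOT_IN"):
            raise ArgumentError(f"semijoin mode must be IN or NOT_IN, got {mode!r}")
        other_values = {
            key: {v for s in other.samples for v in s.metadata.values(key)}
            for key in keys
        }

    samples = []
    for sample in dataset.samples:
        if meta_predicate is not None and not evaluate_meta_predicate(
            meta_predicate, sample.metadata
        ):
            continue
        if semijoin is not None:
            condition = all(
                set(sample.metadata.values(key)) & other_values[key] for key in keys
            )
            if (mode == "IN") != condition:
                continue
        regions = sample.regions
        if region_predicate is not None:
            regions = [
                r
                for r in regions
                if evaluate_region_predicate(region_predicate, r, dataset.schema)
            ]
        samples.append(Sample(sample.id, list(regions), sample.metadata.copy()))
    return GDMDataset(dataset.schema, samples, name=dataset.name)


# ---------------------------------------------------------------------------
# project


def op_project(
    dataset: GDMDataset,
    keep_region_attrs: Optional[Sequence[str]] = None,
    keep_meta_keys: Optional[Sequence[str]] = None,
    regions_update: Sequence[tuple] = (),
    metadata_update: Sequence[tuple] = (),
) -> GDMDataset:
    """Project/extend region attributes and metadata keys.

    ``keep_region_attrs``/``keep_meta_keys`` of ``None`` keep everything;
    empty lists drop everything (coordinates are always preserved).
    ``regions_update`` entries are ``(name, ScalarExpr)`` and may overwrite a
    kept attribute in place; new attributes are appended in declaration order
    with dtype inferred from the computed values.  ``metadata_update`` entries
    ``(key, constant)`` replace all pairs of that key.
    """
    from .model import RESERVED_NAMES

    kept = list(dataset.schema.names) if keep_region_attrs is None else list(keep_region_attrs)
    for name in kept:
        dataset.schema.index(name)  # raises SchemaError when absent

    updates = [(name, expr) for name, expr in regions_update]
    for name, _ in updates:
        if name in RESERVED_NAMES:
            raise SchemaError(f"regions_update cannot target coordinate {name!r}")

    out_names = list(kept)
    for name, _ in updates:
        if name not in out_names:
            out_names.append(name)

    kept_indices = [dataset.schema.index(n) for n in kept]
    all_regions = [r for s in dataset.samples for r in s.regions]

    # Evaluate every update on every region once, then infer created dtypes.
    computed = {}
    for name, expr in updates:
        computed[name] = [
            evaluate_region_expr(expr, region, dataset.schema) for region in all_regions
        ]

    def infer_dtype(values: list, fallback: Optional[str]) -> str:
        present = [v for v in values if v is not None]
        if not present:
            return fallback or "float"
        if any(isinstance(v, str) for v in present):
            return "string"
        if any(isinstance(v, float) for v in present):
            return "float"
        if all(isinstance(v, bool) for v in present):
            return "boolean"
        return "integer"

    attributes = []
    for name in out_names:
        if name in computed:
            fallback = dataset.schema.dtype(name) if name in dataset.schema else None
            attributes.append((name, infer_dtype(computed[name], fallback)))
        else:
            attributes.append((name, dataset.schema.dtype(name)))
    schema = Schema(tuple(attributes))

    cursor = 0
    samples = []
    for sample in dataset.samples:
        regions = []
        for region in sample.regions:
            values = []
            for name, idx in zip(kept, kept_indices):
                values.append(region.values[idx])
            row = dict(zip(kept, values))
            for name, _ in updates:
                row[name] = computed[name][cursor]
            regions.append(
                Region(
                    region.chrom,
                    region.left,
                    region.right,
                    region.strand,
                    tuple(row[n] for n in out_names),
                )
            )
            cursor += 1
        metadata = sample.metadata.copy()
        if keep_meta_keys is not None:
            wanted = set(keep_meta_keys)
            metadata = MetadataSet((k, v) for k, v in metadata.pairs() if k in wanted)
        for key, constant in metadata_update:
            metadata.discard_key(key)
            metadata.add(key, str(constant))
        samples.append(Sample(sample.id, regions, metadata))
    return GDMDataset(schema, samples, name=dataset.name)


# ---------------------------------------------------------------------------
# extend / order / group


def op_extend(dataset: GDMDataset, specs: Sequence[AggregateSpec]) -> GDMDataset:
    """Add one metadata pair per aggregate to every sample; regions unchanged.

    Aggregates that evaluate to missing (e.g. MIN over zero regions) add no
    pair; COUNT over zero regions adds ``0``.
    """
    samples = []
    for sample in dataset.samples:
        metadata = sample.metadata.copy()
        for spec in specs:
            value = apply_aggregate(spec, sample.regions, dataset.schema)
            if value is not None:
                metadata.add(spec.output_name, _format_meta_number(value))
        samples.append(Sample(sample.id, list(sample.regions), metadata))
    return GDMDataset(dataset.schema, samples, name=dataset.name)


def _meta_sort_value(sample: Sample, key: str) -> Optional[str]:
    values = sample.metadata.values(key)
    return values[0] if values else None


def op_order(
    dataset: GDMDataset,
    meta_keys: Sequence[tuple] = (),
    region_keys: Sequence[tuple] = (),
    mtop: Optional[int] = None,
    rtop: Optional[int] = None,
) -> GDMDataset:
    """Order samples by metadata keys and regions by attribute keys.

    Sorting is stable with ties broken by sample id; a key whose values are
    all numeric sorts numerically, otherwise lexicographically.  ``mtop``
    keeps the first k samples, ``rtop`` the first k regions per sample (after
    which regions return to coordinate order, per the sample invariant).
    """
    if mtop is not None and mtop <= 0:
        raise ArgumentError("mtop must be positive")
    if rtop is not None and rtop <= 0:
        raise ArgumentError("rtop must be positive")
    for key, direction in list(meta_keys) + list(region_keys):
        if direction not in ("asc", "desc"):
            raise ArgumentError(f"sort direction must be asc or desc, got {direction!r}")

    samples = sorted(dataset.samples, key=lambda s: s.id)
    for key, direction in reversed(list(meta_keys)):
        raw = [_meta_sort_value(s, key) for s in samples]
        numeric = all(
            v is None or re.fullmatch(r"-?\d+(\.\d+)?([eE][+-]?\d+)?", v) for v in raw
        ) and any(v is not None for v in raw)

        def sort_key(sample: Sample):
            value = _meta_sort_value(sample, key)
            if value is None:
                return (1, 0)
            return (0, float(value) if numeric else value)

        samples = sorted(samples, key=sort_key, reverse=(direction == "desc"))
    if mtop is not None:
        samples = samples[:mtop]

    out = []
    for sample in samples:
        regions = list(sample.regions)
        for key, direction in reversed(list(region_keys)):

            def region_sort_key(region: Region):
                value = evaluate_region_expr(Attr(key), region, dataset.schema)
                if value is None:
                    return (1, 0)
                return (0, value)

            regions = sorted(regions, key=region_sort_key, reverse=(direction == "desc"))
        if rtop is not None:
            regions = regions[:rtop]
        out.append(Sample(sample.id, regions, sample.metadata.copy()))
    return GDMDataset(dataset.schema, out, name=dataset.name)


def op_group(dataset: GDMDataset, meta_keys: Sequence[str]) -> GDMDataset:
    """Tag samples sharing identical value-sets on ``meta_keys`` with ``_group``.

    Group numbers follow the sorted key-value signatures, starting at 1; a
    sample missing a key forms its signature with an empty marker.
    """
    meta_keys = list(meta_keys)
    if not meta_keys:
        raise ArgumentError("group requires at least one metadata key")
    groups = _group_samples(dataset.samples, meta_keys)
    numbering = {sig: i + 1 for i, (sig, _) in enumerate(groups)}
    samples = []
    for sample in dataset.samples:
        metadata = sample.metadata.copy()
        metadata.add("_group", str(numbering[_group_signature(sample, meta_keys)]))
        samples.append(Sample(sample.id, list(sample.regions), metadata))
    return GDMDataset(dataset.schema, samples, name=dataset.name)


# ---------------------------------------------------------------------------
# merge / union / difference


def _merged_sample(members: Sequence[Sample]) -> Sample:
    regions = [r for m in members for r in m.regions]
    metadata = MetadataSet()
    if members:
        metadata = members[0].metadata.union(*(m.metadata for m in members[1:]))
    return Sample(_derived_id("merge", *(m.id for m in members)), regions, metadata)


def op_merge(dataset: GDMDataset, groupby: Optional[Sequence[str]] = None) -> GDMDataset:
    """Combine all samples (or each metadata group) into single samples.

    Regions are the multiset union (duplicates kept); metadata pairs are
    unioned.
    """
    if groupby:
        groups = _group_samples(dataset.samples, list(groupby))
        samples = [_merged_sample(members) for _, members in groups]
    else:
        samples = [_merged_sample(list(dataset.samples))]
    return GDMDataset(dataset.schema, samples, name=dataset.name)


def _coerce(value: Value, dtype: str) -> Value:
    if value is None:
        return None
    try:
        if dtype == "string":
            return format_value(value)
        if dtype == "integer":
            as_float = float(value)
            return int(as_float) if as_float.is_integer() else None
        if dtype == "float":
            return float(value)
        if dtype == "boolean":
            return value if isinstance(value, bool) else None
    except (TypeError, ValueError):
        return None
    return None


def op_union(a: GDMDataset, b: GDMDataset) -> GDMDataset:
    """Concatenate the samples of two datasets under the first schema.

    Regions of ``b`` are coerced by attribute name: same-named attributes are
    copied (cast to the first schema's dtype when possible), all others become
    missing.  Sample ids get ``left_``/``right_`` provenance prefixes.
    """
    mapping = []
    for name, dtype in a.schema.attributes:
        mapping.append((b.schema.index(name), dtype) if name in b.schema else None)
    samples = [
        Sample(f"left_{s.id}", list(s.regions), s.metadata.copy()) for s in a.samples
    ]
    for sample in b.samples:
        regions = []
        for region in sample.regions:
            values = tuple(
                _coerce(region.values[slot[0]], slot[1]) if slot else None
                for slot in mapping
            )
            regions.append(
                Region(region.chrom, region.left, region.right, region.strand, values)
            )
        samples.append(Sample(f"right_{sample.id}", regions, sample.metadata.copy()))
    return GDMDataset(a.schema, samples, name=a.name)


def op_difference(
    a: GDMDataset, b: GDMDataset, joinby: Optional[Sequence[str]] = None
) -> GDMDataset:
    """Drop every region of ``a`` overlapping any region of ``b``.

    With ``joinby``, only ``b`` samples matching an ``a`` sample on those
    metadata keys contribute excluding regions.  Sample set and metadata of
    ``a`` are preserved.
    """
    joinby = list(joinby) if joinby else None
    if joinby is None:
        trees = _interval_tree(r for s in b.samples for r in s.regions)
    samples = []
    for sample in a.samples:
        if joinby is not None:
            relevant = [s for s in b.samples if _joinby_match(sample, s, joinby)]
            trees_local = _interval_tree(r for s in relevant for r in s.regions)
        else:
            trees_local = trees
        regions = [
            r for r in sample.regions if not _overlapping(trees_local, r)
        ]
        samples.append(Sample(sample.id, regions, sample.metadata.copy()))
    return GDMDataset(a.schema, samples, name=a.name)


# ---------------------------------------------------------------------------
# map


def op_map(
    ref: GDMDataset,
    exp: GDMDataset,
    aggregates: Sequence[AggregateSpec] = (),
    joinby: Optional[Sequence[str]] = None,
    count_name: Optional[str] = None,
) -> GDMDataset:
    """Aggregate experiment regions overlapping each reference region.

    One output sample per (ref sample x exp sample) pair passing ``joinby``
    (all pairs when absent).  Output regions are the reference regions,
    extended with an always-present overlap count attribute (named
    ``count_<ref name>_<exp name>`` by default) and one attribute per
    aggregate computed over the overlapping experiment regions.  Output
    metadata is the union of the pair's metadata with ``left.``/``right.``
    key prefixes.
    """
    if count_name is None:
        count_name = f"count_{ref.name}_{exp.name}"
    attributes = list(ref.schema.attributes) + [(count_name, "integer")]
    attributes += [(spec.output_name, _aggregate_dtype(spec)) for spec in aggregates]
    schema = Schema(tuple(attributes))

    joinby = list(joinby) if joinby else None
    samples = []
    for exp_sample in exp.samples:
        trees = _interval_tree(exp_sample.regions)
        for ref_sample in ref.samples:
            if joinby is not None and not _joinby_match(ref_sample, exp_sample, joinby):
                continue
            regions = []
            for region in ref_sample.regions:
                hits = _overlapping(trees, region)
                extra = [len(hits)]
                for spec in aggregates:
                    extra.append(apply_aggregate(spec, hits, exp.schema))
                regions.append(
                    Region(
                        region.chrom,
                        region.left,
                        region.right,
                        region.strand,
                        region.values + tuple(extra),
                    )
                )
            metadata = ref_sample.metadata.prefixed("left.").union(
                exp_sample.metadata.prefixed("right.")
            )
            samples.append(
                Sample(_derived_id("map", ref_sample.id, exp_sample.id), regions, metadata)
            )
    samples.sort(key=lambda s: s.id)
    return GDMDataset(schema, samples, name=f"map_{ref.name}_{exp.name}")


# ---------------------------------------------------------------------------
# genometric join


@dataclass(frozen=True)
class GenometricClause:
    """One clause of a genometric join predicate.

    ``MD(k)`` keeps the k candidates at minimum distance from each anchor
    region; ``DLE(n)``/``DGE(n)`` bound the signed distance; ``UP``/``DOWN``
    keep candidates on the anchor's upstream/downstream side, measured
    strand-aware from the anchor's 5' end ('*' behaves like '+').
    """

    kind: str
    k: Optional[int] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("MD", "DLE", "DGE", "UP", "DOWN"):
            raise ArgumentError(f"unknown genometric clause kind {self.kind!r}")
        if self.kind == "MD":
            if self.k is None or self.k <= 0:
                raise ArgumentError("MD requires a positive k")
        elif self.kind in ("DLE", "DGE"):
            if self.n is None:
                raise ArgumentError(f"{self.kind} requires a distance n")
        elif self.k is not None or self.n is not None:
            raise ArgumentError(f"{self.kind} takes no parameter")


_CLAUSE_RE = re.compile(r"^\s*(MD|DLE|DGE)\s*\(\s*(-?\d+)\s*\)\s*$|^\s*(UP|DOWN)\s*$")


def parse_genometric_clause(text: str) -> GenometricClause:
    """Parse clause text such as ``MD(1)``, ``DLE(1000)``, ``UP``."""
    match = _CLAUSE_RE.match(text)
    if not match:
        raise ArgumentError(f"cannot parse genometric clause {text!r}")
    if match.group(3):
        return GenometricClause(match.group(3))
    kind, number = match.group(1), int(match.group(2))
    if kind == "MD":
        return GenometricClause("MD", k=number)
    return GenometricClause(kind, n=number)


def _validate_join_predicate(predicate: Sequence[GenometricClause]) -> None:
    clauses = list(predicate)
    if not 1 <= len(clauses) <= 4:
        raise ArgumentError("join predicate must have 1-4 clauses")
    if sum(1 for c in clauses if c.kind == "MD") > 1:
        raise ArgumentError("join predicate allows at most one MD clause")


def _is_upstream(anchor: Region, candidate: Region) -> bool:
    if anchor.strand == "-":
        return candidate.left >= anchor.right
    return candidate.right <= anchor.left


def _join_pair_region(anchor: Region, candidate: Region, mode: str) -> Optional[Region]:
    if mode in ("LEFT", "BOTH"):
        chrom, left, right, strand = anchor.chrom, anchor.left, anchor.right, anchor.strand
    elif mode == "RIGHT":
        chrom, left, right, strand = (
            candidate.chrom,
            candidate.left,
            candidate.right,
            candidate.strand,
        )
    elif mode == "INT":
        left = max(anchor.left, candidate.left)
        right = min(anchor.right, candidate.right)
        if right <= left:
            return None  # documented contract: non-overlapping pair dropped
        chrom = anchor.chrom
        strand = anchor.strand if anchor.strand != "*" else candidate.strand
    else:  # CAT
        chrom = anchor.chrom
        left = min(anchor.left, candidate.left)
        right = max(anchor.right, candidate.right)
        strand = anchor.strand if anchor.strand != "*" else candidate.strand
    coords = (candidate.left, candidate.right) if mode == "BOTH" else ()
    return Region(
        chrom, left, right, strand, anchor.values + tuple(coords) + candidate.values
    )


def op_join(
    anchor: GDMDataset,
    exp: GDMDataset,
    predicate: Sequence[GenometricClause],
    output: str = "LEFT",
    joinby: Optional[Sequence[str]] = None,
) -> GDMDataset:
    """Join regions of two datasets on distance predicates.

    Candidates must share the chromosome and have a compatible strand.  The
    clause conjunction is applied per anchor region; ``MD(k)`` then keeps the
    k candidates with smallest ranking distance ``max(dist, 0)`` (all
    overlapping candidates rank equally closest; ties break by larger overlap,
    then smaller candidate coordinates).  ``output`` selects the emitted
    coordinates; attributes of both sides are carried with ``left.``/``right.``
    name prefixes (plus ``right.left``/``right.right`` for BOTH).
    """
    predicate = [
        parse_genometric_clause(c) if isinstance(c, str) else c for c in predicate
    ]
    _validate_join_predicate(predicate)
    if output not in JOIN_OUTPUT_MODES:
        raise ArgumentError(f"unknown join output mode {output!r}")

    md = next((c for c in predicate if c.kind == "MD"), None)
    filters = [c for c in predicate if c.kind != "MD"]

    attributes = [(f"left.{n}", t) for n, t in anchor.schema.attributes]
    if output == "BOTH":
        attributes += [("right.left", "integer"), ("right.right", "integer")]
    attributes += [(f"right.{n}", t) for n, t in exp.schema.attributes]
    schema = Schema(tuple(attributes))

    joinby = list(joinby) if joinby else None
    samples = []
    for exp_sample in exp.samples:
        by_chrom: dict = {}
        for region in exp_sample.regions:
            by_chrom.setdefault(region.chrom, []).append(region)
        for anchor_sample in anchor.samples:
            if joinby is not None and not _joinby_match(
                anchor_sample, exp_sample, joinby
            ):
                continue
            regions = []
            for a_region in anchor_sample.regions:
                candidates = [
                    c
                    for c in by_chrom.get(a_region.chrom, [])
                    if strand_compatible(a_region.strand, c.strand)
                ]
                survivors = []
                for c_region in candidates:
                    dist = signed_distance(a_region, c_region)
                    keep = True
                    for clause in filters:
                        if clause.kind == "DLE" and not dist <= clause.n:
                            keep = False
                        elif clause.kind == "DGE" and not dist >= clause.n:
                            keep = False
                        elif clause.kind == "UP" and not _is_upstream(a_region, c_region):
                            keep = False
                        elif clause.kind == "DOWN" and (
                            _is_upstream(a_region, c_region) or dist < 0
                        ):
                            keep = False
                    if keep:
                        survivors.append((dist, c_region))
                if md is not None:
                    survivors.sort(
                        key=lambda item: (
                            max(item[0], 0),
                            -_overlap_length(a_region, item[1]),
                            item[1].left,
                            item[1].right,
                        )
                    )
                    survivors = survivors[: md.k]
                for _, c_region in survivors:
                    region = _join_pair_region(a_region, c_region, output)
                    if region is not None:
                        regions.append(region)
            metadata = anchor_sample.metadata.prefixed("left.").union(
                exp_sample.metadata.prefixed("right.")
            )
            samples.append(
                Sample(
                    _derived_id("join", anchor_sample.id, exp_sample.id),
                    regions,
                    metadata,
                )
            )
    samples.sort(key=lambda s: s.id)
    return GDMDataset(schema, samples, name=f"join_{anchor.name}_{exp.name}")


def _overlap_length(a: Region, b: Region) -> int:
    return min(a.right, b.right) - max(a.left, b.left)


# ---------------------------------------------------------------------------
# cover


def _coverage_runs(
    regions: Sequence[Region], min_acc: int, max_acc: float
) -> list:
    """Maximal runs of bases whose coverage lies in [min_acc, max_acc].

    Sweep over coordinate breakpoints; returns ``[(left, right, acc_index,
    contributing_regions), ...]`` per chromosome-agnostic input (caller
    partitions by chromosome).
    """
    events: dict = {}
    for region in regions:
        events[region.left] = events.get(region.left, 0) + 1
        events[region.right] = events.get(region.right, 0) - 1
    points = sorted(events)
    runs = []
    coverage = 0
    run_start = None
    run_max = 0
    for i, point in enumerate(points):
        coverage += events[point]
        seg_start = point
        seg_end = points[i + 1] if i + 1 < len(points) else point
        qualifies = seg_end > seg_start and min_acc <= coverage <= max_acc
        if qualifies:
            if run_start is None:
                run_start = seg_start
                run_max = coverage
            else:
                run_max = max(run_max, coverage)
            run_end = seg_end
        elif run_start is not None:
            runs.append((run_start, run_end, run_max))
            run_start = None
    if run_start is not None:
        runs.append((run_start, run_end, run_max))
    return runs


def op_cover(
    dataset: GDMDataset,
    min_acc: Union[int, str] = 1,
    max_acc: Union[int, str, None] = ANY,
    groupby: Optional[Sequence[str]] = None,
    aggregates: Sequence[AggregateSpec] = (),
) -> GDMDataset:
    """Collapse samples into accumulation-defined regions.

    Samples are partitioned by ``groupby`` metadata keys (single group when
    absent); within each group and each chromosome/strand class the output
    regions are the maximal runs of bases covered by an in-bounds number of
    group regions.  ``min_acc``/``max_acc`` accept ``"ANY"`` (1 and unbounded
    respectively).  Each output region carries the integer ``AccIndex``
    attribute (maximum accumulation within the run) plus one attribute per
    aggregate, computed over the input regions contributing to the run.
    Output metadata is the union of the group members' pairs.
    """
    min_acc_v = 1 if min_acc == ANY else int(min_acc)
    max_acc_v = math.inf if max_acc in (ANY, None) else int(max_acc)
    if min_acc_v <= 0:
        raise ArgumentError("min_acc must be positive")
    if max_acc_v != math.inf and min_acc_v > max_acc_v:
        raise ArgumentError("min_acc must not exceed max_acc")

    attributes = [("AccIndex", "integer")]
    attributes += [(spec.output_name, _aggregate_dtype(spec)) for spec in aggregates]
    schema = Schema(tuple(attributes))

    if groupby:
        groups = [members for _, members in _group_samples(dataset.samples, list(groupby))]
    elif dataset.samples:
        groups = [list(dataset.samples)]
    else:
        groups = []

    samples = []
    for members in groups:
        regions_in = [r for m in members for r in m.regions]
        has_plus = any(r.strand == "+" for r in regions_in)
        has_minus = any(r.strand == "-" for r in regions_in)
        if has_plus or has_minus:
            classes = []
            if has_plus:
                classes.append(("+", [r for r in regions_in if r.strand in "+*"]))
            if has_minus:
                classes.append(("-", [r for r in regions_in if r.strand in "-*"]))
        else:
            classes = [("*", regions_in)]

        out_regions = []
        for strand, class_regions in classes:
            by_chrom: dict = {}
            for region in class_regions:
                by_chrom.setdefault(region.chrom, []).append(region)
            for chrom in sorted(by_chrom):
                chrom_regions = by_chrom[chrom]
                for left, right, acc_index in _coverage_runs(
                    chrom_regions, min_acc_v, max_acc_v
                ):
                    contributing = [
                        r for r in chrom_regions if r.left < right and left < r.right
                    ]
                    extra: list = [acc_index]
                    for spec in aggregates:
                        extra.append(apply_aggregate(spec, contributing, dataset.schema))
                    out_regions.append(Region(chrom, left, right, strand, tuple(extra)))
        metadata = MetadataSet()
        if members:
            metadata = members[0].metadata.union(*(m.metadata for m in members[1:]))
        samples.append(
            Sample(_derived_id("cover", *(m.id for m in members)), out_regions, metadata)
        )
    samples.sort(key=lambda s: s.id)
    return GDMDataset(schema, samples, name=dataset.name)
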