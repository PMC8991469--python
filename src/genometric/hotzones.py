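"""Transcription-factor accumulation and high-occupancy-target (HOT) zones.

A HOT zone is a maximal run of chromosome bases bound by an unusually large
number of distinct transcription factors.  The analysis proceeds in three
steps:

1. a region-length threshold — the length at the ceil(p*n)-th position of the
   ascending length list (outlier-wide binding regions would otherwise
   inflate the TF counts over the bases they span);
2. the per-base accumulation vector — for each base of the covered span of a
   chromosome, the number of *distinct* TF labels with a binding region
   covering it (replicate regions of one TF count once); a half-window ``w``
   widens each region by ``w`` bases on both sides before counting;
3. zone calling by the "overlaps" method — the threshold TH is the mean plus
   twice the sample standard deviation of the accumulation over every base of
   the span, and zones are the maximal runs of bases whose accumulation
   strictly exceeds TH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .model import ArgumentError, GDMDataset, GDMError

__all__ = [
    "AccumulationVector",
    "HotZoneSet",
    "length_percentile_threshold",
    "accumulation",
    "high_accumulation_zones",
    "zones_to_bed",
    "accumulation_to_bedgraph",
    "hot_zone_analysis",
    "HotZoneResult",
]


@dataclass
class AccumulationVector:
    """Per-base distinct-TF counts over the covered span of one chromosome."""

    chrom: str
    span_start: int
    values: np.ndarray  # one integer per base of [span_start, span_end)
    w: int = 0

    @property
    def span_end(self) -> int:
        return self.span_start + len(self.values)


@dataclass
class HotZoneSet:
    """Zones whose accumulation strictly exceeds the threshold TH."""

    threshold: float
    zones: list  # [(chrom, left, right), ...] disjoint and sorted

    @property
    def n_zones(self) -> int:
        return len(self.zones)


def length_percentile_threshold(dataset: GDMDataset, p: float) -> int:
    """Region length at the 1-based index ``ceil(p * n)`` of the sorted lengths.

    Lengths of all regions in all samples are sorted ascending; ``p`` is a
    fraction in (0, 1].  Deterministic; raises on an empty dataset.
    """
    if not 0 < p <= 1:
        raise ArgumentError(f"percentile fraction must be in (0, 1], got {p}")
    lengths = sorted(r.length for s in dataset.samples for r in s.regions)
    if not lengths:
        raise GDMError("cannot take a length percentile of an empty dataset")
    index = math.ceil(p * len(lengths))
    return lengths[index - 1]


def accumulation(
    regions: pd.DataFrame, chrom: str, w: int = 0, tf_col: str = "sample_label"
) -> AccumulationVector:
    """Per-base count of distinct TF labels covering each base of ``chrom``.

    ``regions`` is a flat region table with ``chrom``/``left``/``right``
    columns plus a TF label column (default the ``sample_label`` emitted by
    :func:`~genometric.io.filter_and_extract`).  With ``w > 0`` a TF counts at
    base x when it has a region intersecting ``[x-w, x+w+1)``, i.e. every
    region is widened by ``w`` on both sides; the span widens accordingly.
    """
    if w < 0:
        raise ArgumentError("half-window w must be non-negative")
    on_chrom = regions[regions["chrom"] == chrom]
    if on_chrom.empty:
        raise GDMError(f"no regions on chromosome {chrom!r}")
    span_start = max(0, int(on_chrom["left"].min()) - w)
    span_end = int(on_chrom["right"].max()) + w
    values = np.zeros(span_end - span_start, dtype=np.int64)
    for _, group in on_chrom.groupby(tf_col, sort=True):
        delta = np.zeros(span_end - span_start + 1, dtype=np.int64)
        for left, right in zip(group["left"], group["right"]):
            lo = max(span_start, int(left) - w) - span_start
            hi = int(right) + w - span_start
            delta[lo] += 1
            delta[hi] -= 1
        covered = np.cumsum(delta[:-1])
        values += np.minimum(covered, 1)  # replicate regions of one TF count once
    return AccumulationVector(chrom, span_start, values, w)


def high_accumulation_zones(
    acc: AccumulationVector, method: str = "overlaps"
) -> HotZoneSet:
    """Call HOT zones on an accumulation vector with the 'overlaps' method.

    TH = mean + 2 * sample standard deviation over every base of the span;
    zones are maximal runs of bases with accumulation strictly above TH
    (a constant vector therefore yields no zone).
    """
    if method != "overlaps":
        raise ArgumentError(f"unsupported zone identification method {method!r}")
    if len(acc.values) == 0:
        raise GDMError("empty accumulation vector")
    values = acc.values.astype(float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    threshold = mean + 2.0 * sd

    above = values > threshold
    zones = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        zones.append((acc.chrom, acc.span_start + int(start), acc.span_start + int(stop)))
    return HotZoneSet(threshold, zones)


# ---------------------------------------------------------------------------
# exports


def zones_to_bed(zones: HotZoneSet, path: Union[str, Path]) -> Path:
    """Write zones as BED3 (chrom, start, end)."""
    path = Path(path)
    lines = [f"{chrom}\t{left}\t{right}" for chrom, left, right in zones.zones]
    path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")
    return path


def accumulation_to_bedgraph(acc: AccumulationVector, path: Union[str, Path]) -> Path:
    """Write the accumulation vector as run-compressed bedGraph-style TSV."""
    path = Path(path)
    lines = []
    if len(acc.values):
        change = np.flatnonzero(np.diff(acc.values)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(acc.values)]))
        for start, end in zip(starts, ends):
            lines.append(
                f"{acc.chrom}\t{acc.span_start + int(start)}"
                f"\t{acc.span_start + int(end)}\t{int(acc.values[start])}"
            )
    path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class HotZoneResult:
    length_threshold: int
    accumulation: AccumulationVector
    zones: HotZoneSet
    n_tf_samples: int
    n_regions: int


def hot_zone_analysis(
    dataset: GDMDataset,
    chrom: str,
    w: int = 0,
    min_length: int = 100,
    percentile: float = 0.95,
    target_key: str = "experiment_target",
) -> HotZoneResult:
    """Full HOT-zone pipeline over a TF peak dataset.

    Steps: add a ``length`` region attribute; compute the superior length
    threshold as the ``percentile`` length over all regions pooled into one
    sample; keep regions with ``min_length < length < superior``; collapse
    replicate samples of the same TF with cover(1, ANY) grouped on
    ``target_key``; compute the accumulation vector on ``chrom`` and call
    zones at mean + 2 sd (strict inequality).
    """
    from . import algebra, io
    from .expressions import parse_predicate, parse_scalar_expr

    with_length = algebra.op_project(
        dataset, regions_update=[("length", parse_scalar_expr("right - left"))]
    )
    merged = algebra.op_merge(with_length)
    superior = length_percentile_threshold(merged, percentile)
    filtered = algebra.op_filter(
        with_length,
        region_predicate=parse_predicate(
            f"length < {superior} AND length > {min_length}"
        ),
    )
    covered = algebra.op_cover(filtered, 1, algebra.ANY, groupby=[target_key])
    table = io.filter_and_extract(covered, label_key=target_key)
    acc = accumulation(table, chrom, w=w)
    zones = high_accumulation_zones(acc, method="overlaps")
    return HotZoneResult(
        length_threshold=superior,
        accumulation=acc,
        zones=zones,
        n_tf_samples=len(covered),
        n_regions=covered.n_regions,
    )
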