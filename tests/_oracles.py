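"""Independent brute-force references for the operator algebra.

Everything here is deliberately naive — per-pair double loops and per-base
dictionaries — and shares nothing with the sweep/interval-tree implementations
under test beyond the data containers.
"""

from __future__ import annotations

import math


def strands_ok(a: str, b: str) -> bool:
    return a == b or a == "*" or b == "*"


def overlap(a, b) -> bool:
    return (
        a.chrom == b.chrom
        and a.left < b.right
        and b.left < a.right
        and strands_ok(a.strand, b.strand)
    )


def gap(a, b) -> int:
    if a.left <= b.left:
        return b.left - a.right
    return a.left - b.right


def map_counts(ref_regions, exp_regions) -> list:
    """Per ref-region overlap count via the all-pairs double loop."""
    return [sum(1 for e in exp_regions if overlap(r, e)) for r in ref_regions]


def difference_regions(a_regions, b_regions) -> list:
    return [r for r in a_regions if not any(overlap(r, b) for b in b_regions)]


def nearest_candidates(anchor, candidates, k: int) -> list:
    """MD(k) by exhaustive search with the documented ranking and tie-break."""
    eligible = [
        c
        for c in candidates
        if c.chrom == anchor.chrom and strands_ok(anchor.strand, c.strand)
    ]

    def rank(c):
        d = gap(anchor, c)
        ov = min(anchor.right, c.right) - max(anchor.left, c.left)
        return (max(d, 0), -ov, c.left, c.right)

    return sorted(eligible, key=rank)[:k]


def per_base_coverage(regions) -> dict:
    """{(chrom, base): count} over all bases covered by any region."""
    counts: dict = {}
    for r in regions:
        for base in range(r.left, r.right):
            key = (r.chrom, base)
            counts[key] = counts.get(key, 0) + 1
    return counts


def cover_runs(regions, min_acc: int, max_acc: float) -> list:
    """Maximal qualifying base runs per chromosome via per-base counting."""
    counts = per_base_coverage(regions)
    runs = []
    for chrom in sorted({c for c, _ in counts}):
        bases = sorted(b for c, b in counts if c == chrom)
        if not bases:
            continue
        lo, hi = bases[0], bases[-1]
        run_start = None
        run_max = 0
        for base in range(lo, hi + 2):
            acc = counts.get((chrom, base), 0)
            if base <= hi and min_acc <= acc <= max_acc:
                if run_start is None:
                    run_start = base
                    run_max = acc
                else:
                    run_max = max(run_max, acc)
            elif run_start is not None:
                runs.append((chrom, run_start, base, run_max))
                run_start = None
    return runs


def accumulation_per_base(rows, chrom: str) -> dict:
    """{base: n distinct TF labels} from (tf, chrom, left, right) tuples."""
    tf_bases: dict = {}
    for tf, c, left, right in rows:
        if c != chrom:
            continue
        for base in range(left, right):
            tf_bases.setdefault(base, set()).add(tf)
    return {base: len(tfs) for base, tfs in tf_bases.items()}


def percentile_length(lengths, p: float) -> int:
    ordered = sorted(lengths)
    return ordered[math.ceil(p * len(ordered)) - 1]
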