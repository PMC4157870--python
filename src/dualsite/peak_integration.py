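"""Combine replicate, cross-cell-line and cross-factor ChIP-seq peak sets.

Replicated experiments in one cell line keep only reproducible signal
(overlapping peak locations); independent experiments in different cell
lines are pooled; FOXA1 and FOXA2 are pooled into a single FOXA set on the
grounds of their redundant regulation in liver.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

from .core_io import GenomicInterval, PeakSet, ValidationError


def _merge_sorted(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or bookended intervals; input must be sorted."""
    merged: list[GenomicInterval] = []
    for iv in intervals:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = replace(merged[-1], end=iv.end)
        else:
            merged.append(replace(iv, strand="."))
    return merged


def intersect_replicates(a: PeakSet, b: PeakSet, keep: str = "intersection") -> PeakSet:
    """Reproducible peaks between two replicates of the same experiment.

    For every pair of intervals sharing >= 1 bp, retain either the shared span
    (``keep="intersection"``, default) or the merged pair span
    (``keep="union"``). Output is sorted and deduplicated.
    """
    if a.factor != b.factor or a.cell_line != b.cell_line:
        raise ValidationError(
            f"replicates must share factor and cell line; got "
            f"({a.factor}, {a.cell_line}) vs ({b.factor}, {b.cell_line})"
        )
    if keep not in ("intersection", "union"):
        raise ValidationError(f"keep must be 'intersection' or 'union', got {keep!r}")

    out: set[GenomicInterval] = set()
    ivs_b = sorted(b.intervals)
    # sorted sweep: for each a-interval, walk the b-intervals that can overlap
    import bisect

    starts_b = [(iv.chrom, iv.start) for iv in ivs_b]
    for iva in sorted(a.intervals):
        lo = bisect.bisect_left(starts_b, (iva.chrom, -1))
        for ivb in ivs_b[lo:]:
            if ivb.chrom != iva.chrom or ivb.start >= iva.end:
                break
            if iva.overlaps(ivb):
                if keep == "intersection":
                    out.add(
                        GenomicInterval(
                            iva.chrom, max(iva.start, ivb.start), min(iva.end, ivb.end)
                        )
                    )
                else:
                    out.add(
                        GenomicInterval(
                            iva.chrom, min(iva.start, ivb.start), max(iva.end, ivb.end)
                        )
                    )
    return PeakSet(sorted(out), factor=a.factor, cell_line=a.cell_line, replicate_id=None)


def intersect_replicate_series(replicates: Sequence[PeakSet], keep: str = "intersection") -> PeakSet:
    """Fold :func:`intersect_replicates` left over > 2 replicates."""
    if not replicates:
        raise ValidationError("need at least one replicate peak set")
    result = replicates[0].sorted()
    for other in replicates[1:]:
        result = intersect_replicates(result, other, keep=keep)
    return result


def union_peak_sets(sets: Iterable[PeakSet], factor: str | None = None) -> PeakSet:
    """Pool peak sets, merging overlapping/adjacent intervals into maximal spans.

    Used to pool independent experiments of one factor across cell lines
    (e.g. ERα from ECC-1 and T47-D).
    """
    sets = list(sets)
    if not sets:
        raise ValidationError("union of zero peak sets is undefined")
    factors = {s.factor for s in sets}
    if factor is None:
        if len(factors) > 1:
            raise ValidationError(
                f"sets carry different factors {sorted(factors)}; pass factor= explicitly"
            )
        factor = sets[0].factor
    cell_lines = {s.cell_line for s in sets}
    cell_line = sets[0].cell_line if len(cell_lines) == 1 else None
    all_ivs = sorted(iv for s in sets for iv in s.intervals)
    return PeakSet(_merge_sorted(all_ivs), factor=factor, cell_line=cell_line)


def combine_factors(foxa1: PeakSet, foxa2: PeakSet, factor: str = "FOXA") -> PeakSet:
    """Pool FOXA1 and FOXA2 peaks into one FOXA binding-site set."""
    return union_peak_sets([foxa1, foxa2], factor=factor)


def covered_bases(peaks: PeakSet) -> int:
    """Total bases covered by a peak set (overlaps counted once)."""
    return sum(len(iv) for iv in _merge_sorted(sorted(peaks.intervals)))
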