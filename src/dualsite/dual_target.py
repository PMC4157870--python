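"""FOXA/ERα dual-target regions and their intersection with gene promoters.

A dual-target region is the merged span of a FOXA peak and an ERα peak lying
strictly closer than ``max_distance`` bp (edge-to-edge; 0 when overlapping).
Promoters are the 5-kb windows strictly upstream of each TSS, strand-aware.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace

from .core_io import GeneModel, GenomicInterval, PeakSet, ValidationError

DEFAULT_MAX_DISTANCE = 250
DEFAULT_UPSTREAM = 5000


@dataclass
class DualTargetRegion:
    """One co-bound FOXA/ERα peak pair and the span covering both."""

    region: GenomicInterval
    foxa_peak: GenomicInterval
    era_peak: GenomicInterval
    distance: int
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValidationError("inter-peak distance cannot be negative")


def _midpoint(iv: GenomicInterval) -> int:
    return (iv.start + iv.end) // 2


def find_dual_targets(
    foxa: PeakSet,
    era: PeakSet,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    summit: bool = False,
    merge: bool = False,
) -> list[DualTargetRegion]:
    """All (FOXA peak, ERα peak) pairs on one chromosome with gap < max_distance.

    ``summit=True`` measures midpoint-to-midpoint distance instead of the
    edge-to-edge gap. Each qualifying pair yields its own region unless
    ``merge=True``, which collapses overlapping regions afterwards.
    """
    if max_distance < 0:
        raise ValidationError("max_distance must be non-negative")
    era_sorted = sorted(era.intervals)
    era_keys = [(iv.chrom, iv.start) for iv in era_sorted]
    out: list[DualTargetRegion] = []
    for f in sorted(foxa.intervals):
        # ERα peaks with start < f.end + max_distance can qualify; walk from
        # the first peak on this chromosome and stop past the horizon.
        lo = bisect.bisect_left(era_keys, (f.chrom, -1))
        for e in era_sorted[lo:]:
            if e.chrom != f.chrom or e.start >= f.end + max_distance:
                break
            if summit:
                dist = abs(_midpoint(f) - _midpoint(e))
            else:
                dist = f.gap_to(e)
            if dist < max_distance:
                region = GenomicInterval(
                    f.chrom, min(f.start, e.start), max(f.end, e.end)
                )
                out.append(DualTargetRegion(region, f, e, dist))
    out.sort(key=lambda d: d.region)
    if merge:
        out = _merge_regions(out)
    return out


def _merge_regions(duals: list[DualTargetRegion]) -> list[DualTargetRegion]:
    """Collapse dual regions whose spans overlap/abut, keeping min distance."""
    merged: list[DualTargetRegion] = []
    for d in duals:
        if (
            merged
            and merged[-1].region.chrom == d.region.chrom
            and d.region.start <= merged[-1].region.end
        ):
            prev = merged[-1]
            merged[-1] = replace(
                prev,
                region=replace(
                    prev.region, end=max(prev.region.end, d.region.end)
                ),
                distance=min(prev.distance, d.distance),
            )
        else:
            merged.append(d)
    return merged


def promoters_from_genes(
    genes: list[GeneModel], upstream: int = DEFAULT_UPSTREAM
) -> list[tuple[str, GenomicInterval]]:
    """Strand-aware upstream promoter window per gene, clipped at position 0.

    ``+`` strand: [max(0, tss - upstream), tss); ``-`` strand:
    [tss + 1, tss + 1 + upstream).
    """
    if upstream <= 0:
        raise ValidationError("upstream must be positive")
    out: list[tuple[str, GenomicInterval]] = []
    for g in genes:
        if g.strand == "+":
            start, end = max(0, g.tss - upstream), g.tss
        else:
            start, end = g.tss + 1, g.tss + 1 + upstream
        if end > start:
            out.append((g.gene_id, GenomicInterval(g.chrom, start, end, g.strand)))
    return out


def intersect_with_promoters(
    duals: list[DualTargetRegion],
    promoters: list[tuple[str, GenomicInterval]],
) -> list[DualTargetRegion]:
    """Keep dual regions overlapping >= 1 promoter by >= 1 bp; annotate genes.

    Full or partial overlap both qualify. The returned regions carry every
    overlapping gene id, sorted for determinism.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gid, iv in promoters:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, gid))
    for lst in by_chrom.values():
        lst.sort()
    out: list[DualTargetRegion] = []
    for d in duals:
        hits = [
            gid
            for (s, e, gid) in by_chrom.get(d.region.chrom, [])
            if s < d.region.end and d.region.start < e
        ]
        if hits:
            out.append(replace(d, genes=sorted(set(hits))))
    return out
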