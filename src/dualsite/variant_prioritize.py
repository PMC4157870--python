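"""SNP-in-binding-element prioritization and the end-to-end pipeline driver.

The pipeline chains peak integration -> dual-target detection -> promoter
intersection -> PWM scanning -> dbSNP intersection -> common-variant filter
and emits a stage-count report plus a candidate table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

from . import dual_target, peak_integration, pwm_scan
from .core_io import (
    ValidationError,
    Variant,
    load_genome,
    read_gene_annotation,
    read_peaks,
    read_pwm_transfac,
    read_snp_table,
)
from .pwm_scan import TFBEHit

log = logging.getLogger(__name__)

DEFAULT_MAF_THRESHOLD = 0.05


@dataclass(frozen=True)
class CandidateVariant:
    """A variant landing inside a predicted binding element."""

    variant: Variant
    tfbe: TFBEHit
    gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.tfbe.contains(self.variant.chrom, self.variant.pos):
            raise ValidationError(
                f"{self.variant.rsid} at {self.variant.chrom}:{self.variant.pos} "
                f"lies outside its binding element"
            )

    @property
    def is_common(self) -> bool:
        return self.variant.maf is not None and self.variant.maf > DEFAULT_MAF_THRESHOLD


@dataclass
class PipelineReport:
    n_foxa_peaks: int = 0
    n_era_peaks: int = 0
    n_dual: int = 0
    n_dual_promoter: int = 0
    n_tfbe: int = 0
    n_variants: int = 0
    n_common: int = 0
    parameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_common > self.n_variants or self.n_dual_promoter > self.n_dual:
            raise ValidationError("stage counts must be monotone non-increasing")


def variants_in_tfbes(
    catalog: Sequence[Variant], tfbes: Sequence[TFBEHit],
    genes_by_region: dict[str, Sequence[str]] | None = None,
) -> list[CandidateVariant]:
    """One candidate per (variant, binding element) containment pair.

    A variant inside two elements yields two candidates; downstream consumers
    deduplicate by rsid when needed.
    """
    genes_by_region = genes_by_region or {}
    by_chrom: dict[str, list[TFBEHit]] = {}
    for h in tfbes:
        by_chrom.setdefault(h.chrom, []).append(h)
    out: list[CandidateVariant] = []
    for v in catalog:
        for h in by_chrom.get(v.chrom, []):
            if h.start <= v.pos < h.end:
                out.append(
                    CandidateVariant(
                        v, h, tuple(genes_by_region.get(h.region_id, ()))
                    )
                )
    return out


def filter_common(
    cands: Sequence[CandidateVariant], maf_threshold: float = DEFAULT_MAF_THRESHOLD
) -> list[CandidateVariant]:
    """Keep candidates with known MAF strictly above the threshold.

    Unknown-MAF candidates are dropped; their count is logged.
    """
    if not 0.0 <= maf_threshold <= 0.5:
        raise ValidationError("maf_threshold must lie in [0, 0.5]")
    n_unknown = sum(1 for c in cands if c.variant.maf is None)
    if n_unknown:
        log.info("dropping %d candidates with unknown MAF", n_unknown)
    return [
        c for c in cands if c.variant.maf is not None and c.variant.maf > maf_threshold
    ]


def _load_factor(cfg: dict[str, Any], factor: str, dialect: str) -> "peak_integration.PeakSet":
    """Peaks for one factor: replicates intersected, cell lines pooled."""
    groups = cfg[factor]  # list of {cell_line, replicates: [paths]}
    per_cell = []
    for grp in groups:
        reps = [
            read_peaks(p, dialect=dialect, factor=factor, cell_line=grp.get("cell_line"))
            for p in grp["replicates"]
        ]
        per_cell.append(
            peak_integration.intersect_replicate_series(
                reps, keep=cfg.get("replicate_keep", "intersection")
            )
            if len(reps) > 1
            else reps[0].sorted()
        )
    return peak_integration.union_peak_sets(per_cell, factor=factor)


def run_pipeline(config: dict[str, Any], out_dir: str | Path | None = None):
    """Execute the full prioritization chain from a config mapping.

    Config keys: ``peaks`` ({FOXA1,FOXA2,ERA: [{cell_line, replicates}]}),
    ``genes``, ``genome``, ``pwms``, ``snps`` (paths), and optional parameters
    ``max_distance`` (250), ``upstream`` (5000), ``core_cutoff`` (0.75),
    ``matrix_cutoff`` (0.85), ``maf_threshold`` (0.05), ``dialect`` (bed3),
    ``merge_duals`` (False), ``summit`` (False).

    Returns ``(report, candidates)``; when ``out_dir`` is given also writes
    ``report.json`` and ``candidates.tsv``. Deterministic given inputs.
    """
    params = {
        "max_distance": config.get("max_distance", dual_target.DEFAULT_MAX_DISTANCE),
        "upstream": config.get("upstream", dual_target.DEFAULT_UPSTREAM),
        "core_cutoff": config.get("core_cutoff", pwm_scan.DEFAULT_CORE_CUTOFF),
        "matrix_cutoff": config.get("matrix_cutoff", pwm_scan.DEFAULT_MATRIX_CUTOFF),
        "maf_threshold": config.get("maf_threshold", DEFAULT_MAF_THRESHOLD),
        "dialect": config.get("dialect", "bed3"),
        "merge_duals": config.get("merge_duals", False),
        "summit": config.get("summit", False),
        "replicate_keep": config.get("replicate_keep", "intersection"),
        "pwm_pseudo": config.get("pwm_pseudo", 0.0),
    }

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    peaks_cfg = dict(config["peaks"])
    peaks_cfg["replicate_keep"] = params["replicate_keep"]
    foxa1 = stage("peaks/FOXA1", _load_factor, peaks_cfg, "FOXA1", params["dialect"])
    foxa2 = stage("peaks/FOXA2", _load_factor, peaks_cfg, "FOXA2", params["dialect"])
    era = stage("peaks/ERA", _load_factor, peaks_cfg, "ERA", params["dialect"])
    foxa = stage("combine_factors", peak_integration.combine_factors, foxa1, foxa2)

    duals = stage(
        "find_dual_targets",
        dual_target.find_dual_targets,
        foxa,
        era,
        max_distance=params["max_distance"],
        summit=params["summit"],
        merge=params["merge_duals"],
    )
    genes = stage("read_genes", read_gene_annotation, config["genes"])
    promoters = stage(
        "promoters", dual_target.promoters_from_genes, genes, params["upstream"]
    )
    dual_prom = stage(
        "intersect_with_promoters", dual_target.intersect_with_promoters, duals, promoters
    )

    genome = stage("load_genome", load_genome, config["genome"])
    pwms = stage("read_pwms", read_pwm_transfac, config["pwms"], params["pwm_pseudo"])
    tfbes: list[TFBEHit] = []
    genes_by_region: dict[str, list[str]] = {}
    for i, d in enumerate(dual_prom):
        rid = f"dual{i}:{d.region.chrom}:{d.region.start}-{d.region.end}"
        genes_by_region[rid] = d.genes
        for pwm in pwms:
            tfbes.extend(
                stage(
                    "scan",
                    pwm_scan.scan,
                    pwm,
                    d.region,
                    genome,
                    core_cutoff=params["core_cutoff"],
                    matrix_cutoff=params["matrix_cutoff"],
                    region_id=rid,
                )
            )

    catalog = stage("read_snps", read_snp_table, config["snps"])
    cands = stage("variants_in_tfbes", variants_in_tfbes, catalog, tfbes, genes_by_region)
    common = stage("filter_common", filter_common, cands, params["maf_threshold"])

    report = PipelineReport(
        n_foxa_peaks=len(foxa),
        n_era_peaks=len(era),
        n_dual=len(duals),
        n_dual_promoter=len(dual_prom),
        n_tfbe=len(tfbes),
        n_variants=len(cands),
        n_common=len(common),
        parameters=params,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(asdict(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
        write_candidates(cands, out / "candidates.tsv")
    return report, cands


def write_candidates(cands: Sequence[CandidateVariant], path: str | Path) -> None:
    cols = [
        "rsid", "chrom", "pos", "gene_ids", "matrix",
        "core_score", "matrix_score", "maf", "is_common",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in cands:
            v = c.variant
            fh.write(
                "\t".join(
                    [
                        v.rsid, v.chrom, str(v.pos), ",".join(c.gene_ids),
                        c.tfbe.matrix, f"{c.tfbe.core_score:.6f}",
                        f"{c.tfbe.matrix_score:.6f}",
                        "" if v.maf is None else f"{v.maf:g}",
                        str(int(c.is_common)),
                    ]
                )
                + "\n"
            )
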