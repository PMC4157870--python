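"""Seeded generators for every input the pipeline consumes, with planted truth.

Three generators emulate the external resources the analysis would otherwise
require: ENCODE-style ChIP-seq peak sets with planted FOXA/ERα co-bound
promoter regions carrying motif-consensus binding elements and SNPs
(``make_regulatory_fixture``); a case-control cohort with genotypes in
Hardy-Weinberg equilibrium among controls and configurable per-stratum
genotype odds ratios plus demographically imbalanced covariates
(``simulate_cohort``); and a genotype-stratified qPCR cycle-threshold table
with configurable expression shifts (``simulate_ct_table``).

Everything is driven by a :class:`numpy.random.Generator` (or integer seed),
and each generator returns/writes a truth record sufficient to score every
downstream stage without re-reading this module.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import (
    DictGenome,
    GenomicInterval,
    PWM,
    PeakSet,
    Variant,
    write_peaks,
    write_pwm_transfac,
    write_snp_table,
)

BASES = "ACGT"

# default cohort mirrors the study scale: 1,081 cases / 2,008 controls,
# ~80% male, G-allele control frequency ~0.48, smoking 59.9% vs 48.9% and
# drinking 52.9% vs 44.7% ever, with the female-only genotype effect as the
# headline structure.
DEFAULT_OR_BY_STRATUM: Mapping[str, tuple[float, float]] = {
    "male": (1.0, 1.0),
    "female": (1.4, 2.0),  # (het, hom-alt) vs hom-ref
}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# regulatory fixture
# ---------------------------------------------------------------------------


@dataclass
class RegulatoryFixtureSpec:
    seed: int = 0
    chrom: str = "chr1"
    slot_size: int = 10_000  # one gene per slot; genome length = n_genes * slot
    n_genes: int = 20
    n_planted_dual_promoter: int = 3
    n_planted_tfbe_variants: int = 3
    n_planted_common: int = 2  # of the planted variants, how many have MAF > 0.05
    n_decoy_foxa: int = 10
    n_decoy_era: int = 10
    n_decoy_snps: int = 30
    peak_length: int = 200
    era_peak_length: int = 150
    max_pair_gap: int = 200  # planted FOXA-ERα gap drawn in [0, this]; < 250
    motif_length: int = 12
    consensus_weight: float = 0.85  # per-position consensus base frequency

    def __post_init__(self) -> None:
        if self.n_planted_dual_promoter > self.n_genes:
            raise ValueError("cannot plant more dual-promoter sites than genes")
        if self.n_planted_tfbe_variants > self.n_planted_dual_promoter * self.motif_length:
            raise ValueError("too many planted variants for the planted motifs")
        if self.n_planted_common > self.n_planted_tfbe_variants:
            raise ValueError("n_planted_common exceeds n_planted_tfbe_variants")
        if self.slot_size < 2 * self.peak_length + 6000:
            raise ValueError("genome slots too small for promoters plus peaks")

    @property
    def genome_length(self) -> int:
        return self.n_genes * self.slot_size


def make_foxa_like_pwm(
    rng: np.random.Generator,
    length: int = 12,
    consensus_weight: float = 0.85,
    name: str = "V$FOXA_SYN",
) -> PWM:
    """A synthetic forkhead-like frequency matrix with a strong consensus.

    The consensus sequence is drawn at random; each position gives the
    consensus base weight ``consensus_weight`` and splits the rest evenly.
    """
    consensus = rng.integers(0, 4, size=length)
    freqs = np.full((length, 4), (1.0 - consensus_weight) / 3.0)
    freqs[np.arange(length), consensus] = consensus_weight
    return PWM(name, freqs)


def make_regulatory_fixture(
    spec: RegulatoryFixtureSpec, out_dir: str | Path
) -> dict:
    """Write genome/genes/peaks/PWM/SNP files plus truth.json; return truth.

    Layout: the genome is divided into one slot per gene. Even-indexed genes
    are on ``+`` (TSS at span start), odd on ``-``. Planted slots get a FOXA
    peak centred in the promoter with an embedded motif-consensus site, an
    ERα peak < 250 bp away, and optionally SNPs inside the motif. Decoy FOXA
    and ERα peaks live in slot tails, > 1 kb from any promoter and > 9 kb
    from each other, so they can never form promoter-proximal dual regions;
    decoy SNPs are placed outside any planted motif.

    The returned truth dict also carries a ready-to-use ``config`` mapping for
    :func:`dualsite.variant_prioritize.run_pipeline`.
    """
    rng = _rng(spec.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    L = spec.genome_length
    genome_arr = rng.integers(0, 4, size=L)

    pwm = make_foxa_like_pwm(rng, spec.motif_length, spec.consensus_weight)
    consensus_codes = pwm.freqs.argmax(axis=1)

    genes_rows = []
    promoters: list[tuple[str, int, int]] = []
    for i in range(spec.n_genes):
        slot = i * spec.slot_size
        if i % 2 == 0:
            span = (slot + 6000, slot + 8500)
            strand, tss = "+", slot + 6000
            prom = (tss - 5000, tss)
        else:
            span = (slot + 1000, slot + 3500)
            strand, tss = "-", slot + 3500 - 1
            prom = (tss + 1, tss + 1 + 5000)
        genes_rows.append((f"gene{i}", spec.chrom, span[0], span[1], strand))
        promoters.append((f"gene{i}", prom[0], prom[1]))

    planted_idx = rng.choice(spec.n_genes, size=spec.n_planted_dual_promoter, replace=False)
    planted_idx.sort()

    foxa_planted: list[tuple[GenomicInterval, int]] = []  # (peak, motif_start)
    era_planted: list[GenomicInterval] = []
    truth_sites = []
    for gi in planted_idx:
        _, ps, pe = promoters[gi]
        # FOXA peak centred in the promoter, motif at the peak centre
        centre = (ps + pe) // 2
        f_start = centre - spec.peak_length // 2
        f_peak = GenomicInterval(spec.chrom, f_start, f_start + spec.peak_length)
        m_start = centre - spec.motif_length // 2
        genome_arr[m_start : m_start + spec.motif_length] = consensus_codes
        gap = int(rng.integers(0, spec.max_pair_gap + 1))
        e_start = f_peak.end + gap
        e_peak = GenomicInterval(spec.chrom, e_start, e_start + spec.era_peak_length)
        foxa_planted.append((f_peak, m_start))
        era_planted.append(e_peak)
        truth_sites.append(
            {
                "gene_id": f"gene{gi}",
                "foxa_peak": [f_peak.start, f_peak.end],
                "era_peak": [e_peak.start, e_peak.end],
                "gap": gap,
                "motif_start": int(m_start),
                "motif_end": int(m_start + spec.motif_length),
            }
        )

    # planted SNPs inside motifs: spread across sites round-robin, distinct offsets
    variants: list[Variant] = []
    truth_variants = []
    offsets_used: dict[int, set[int]] = {}
    n_common_left = spec.n_planted_common
    for k in range(spec.n_planted_tfbe_variants):
        site = truth_sites[k % len(truth_sites)]
        used = offsets_used.setdefault(k % len(truth_sites), set())
        free = [o for o in range(spec.motif_length) if o not in used]
        off = int(rng.choice(free))
        used.add(off)
        pos = site["motif_start"] + off
        ref = BASES[genome_arr[pos]]
        alt = rng.choice([b for b in BASES if b != ref])
        if n_common_left > 0:
            maf = float(np.round(rng.uniform(0.10, 0.40), 3))
            n_common_left -= 1
        else:
            maf = float(np.round(rng.uniform(0.001, 0.04), 4))
        rsid = f"rs9{k:05d}"
        variants.append(Variant(rsid, spec.chrom, pos, ref, str(alt), maf))
        truth_variants.append(
            {
                "rsid": rsid, "pos": int(pos), "maf": maf,
                "is_common": maf > 0.05, "gene_id": site["gene_id"],
                "planted_in_tfbe": True,
            }
        )

    # decoy peaks in slot tails: FOXA in even slots, ERα in odd slots
    def tail_interval(slot_idx: int, length: int) -> GenomicInterval:
        base = slot_idx * spec.slot_size + spec.slot_size - 1000
        start = int(base + rng.integers(0, 1000 - length))
        return GenomicInterval(spec.chrom, start, start + length)

    even = [i for i in range(spec.n_genes) if i % 2 == 0]
    odd = [i for i in range(spec.n_genes) if i % 2 == 1]
    foxa_decoys = [
        tail_interval(int(even[j % len(even)]), spec.peak_length)
        for j in range(spec.n_decoy_foxa)
    ]
    era_decoys = [
        tail_interval(int(odd[j % len(odd)]), spec.era_peak_length)
        for j in range(spec.n_decoy_era)
    ]

    # decoy SNPs outside any planted motif
    motif_spans = [(s["motif_start"], s["motif_end"]) for s in truth_sites]
    n_placed = 0
    while n_placed < spec.n_decoy_snps:
        pos = int(rng.integers(0, L))
        if any(s <= pos < e for s, e in motif_spans):
            continue
        ref = BASES[genome_arr[pos]]
        alt = rng.choice([b for b in BASES if b != ref])
        maf = float(np.round(rng.uniform(0.001, 0.45), 4))
        rsid = f"rs1{n_placed:05d}"
        variants.append(Variant(rsid, spec.chrom, pos, ref, str(alt), min(maf, 0.5)))
        truth_variants.append(
            {"rsid": rsid, "pos": pos, "maf": maf, "is_common": maf > 0.05,
             "gene_id": None, "planted_in_tfbe": False}
        )
        n_placed += 1
    variants.sort(key=lambda v: v.pos)

    # replicate structure: planted FOXA peaks alternate between FOXA1/FOXA2,
    # each written as two jittered replicates whose intersection keeps the
    # motif; ERα peaks alternate between two cell lines (no replicates).
    def jitter(iv: GenomicInterval, d: int) -> GenomicInterval:
        return GenomicInterval(
            iv.chrom, max(0, iv.start + d), iv.end + d
        )

    foxa1_pool = [p for i, (p, _) in enumerate(foxa_planted) if i % 2 == 0]
    foxa2_pool = [p for i, (p, _) in enumerate(foxa_planted) if i % 2 == 1]
    foxa1_pool += foxa_decoys[::2]
    foxa2_pool += foxa_decoys[1::2]

    files: dict[str, str] = {}

    def dump(name: str, ivs: list[GenomicInterval], factor: str, cell: str, rep: str | None):
        path = out / f"{name}.bed"
        write_peaks(PeakSet(sorted(ivs), factor, cell, rep), path)
        files[name] = str(path)

    max_jit = spec.peak_length // 4  # intersection still covers the central motif
    for factor, pool in (("foxa1", foxa1_pool), ("foxa2", foxa2_pool)):
        for rep in ("rep1", "rep2"):
            d = [int(rng.integers(-max_jit, max_jit + 1)) for _ in pool]
            dump(f"{factor}_{rep}", [jitter(p, di) for p, di in zip(pool, d)],
                 factor.upper(), "HepG2", rep)
    era1 = era_planted[::2] + era_decoys[::2]
    era2 = era_planted[1::2] + era_decoys[1::2]
    dump("era_ecc1", era1, "ERA", "ECC-1", None)
    dump("era_t47d", era2, "ERA", "T47-D", None)

    genome = DictGenome({spec.chrom: "".join(BASES[i] for i in genome_arr)})
    genome.write_fasta(out / "genome.fa")
    with open(out / "genes.tsv", "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for row in genes_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    write_pwm_transfac([pwm], out / "pwm.transfac", scale=1000)
    write_snp_table(variants, out / "snps.tsv")

    config = {
        "peaks": {
            "FOXA1": [{"cell_line": "HepG2",
                       "replicates": [files["foxa1_rep1"], files["foxa1_rep2"]]}],
            "FOXA2": [{"cell_line": "HepG2",
                       "replicates": [files["foxa2_rep1"], files["foxa2_rep2"]]}],
            "ERA": [{"cell_line": "ECC-1", "replicates": [files["era_ecc1"]]},
                    {"cell_line": "T47-D", "replicates": [files["era_t47d"]]}],
        },
        "genes": str(out / "genes.tsv"),
        "genome": str(out / "genome.fa"),
        "pwms": str(out / "pwm.transfac"),
        "snps": str(out / "snps.tsv"),
    }
    truth = {
        "spec": asdict(spec),
        "pwm_consensus": pwm.consensus,
        "planted_sites": truth_sites,
        "variants": truth_variants,
        "n_planted_common": spec.n_planted_common,
        "config": config,
    }
    # the on-disk truth carries paths relative to the fixture directory so
    # identical seeds give byte-identical files wherever they are written
    rel = json.loads(json.dumps(truth).replace(str(out) + "/", ""))
    with open(out / "truth.json", "w") as fh:
        json.dump(rel, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth


# ---------------------------------------------------------------------------
# cohort simulator
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    n_case: int = 1081
    n_control: int = 2008
    maf: float = 0.48  # alt (risk) allele frequency among controls
    or_by_stratum: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OR_BY_STRATUM)
    )
    male_frac_case: float = 0.801
    male_frac_control: float = 0.802
    age_case: tuple[float, float] = (54.96, 11.37)  # mean, sd
    age_control: tuple[float, float] = (55.56, 10.28)
    smoking_ever: tuple[float, float] = (0.599, 0.489)  # case, control
    smoking_unknown: tuple[float, float] = (0.014, 0.007)
    drinking_ever: tuple[float, float] = (0.529, 0.447)
    drinking_unknown: tuple[float, float] = (0.021, 0.009)

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        for ors in self.or_by_stratum.values():
            if min(ors) <= 0:
                raise ValueError("genotype odds ratios must be positive")


def _control_genotype_probs(maf: float) -> np.ndarray:
    p, q = 1.0 - maf, maf
    return np.array([p * p, 2 * p * q, q * q])


def _case_genotype_probs(maf: float, ors: tuple[float, float]) -> np.ndarray:
    """Case genotype distribution giving the requested ORs vs controls.

    P(g | case) ∝ P(g | control) * OR_g makes the cross-product ratio of any
    genotype contrast equal the planted OR in expectation.
    """
    w = _control_genotype_probs(maf) * np.array([1.0, ors[0], ors[1]])
    return w / w.sum()


def simulate_cohort(spec: CohortSpec, seed=0) -> tuple[pd.DataFrame, dict]:
    """Simulate a case-control subject table; returns (subjects, truth).

    Controls' genotypes are in HWE at ``spec.maf``; cases follow the
    per-stratum genotype odds ratios. Covariates are drawn independently of
    genotype with the configured case-control imbalance.
    """
    rng = _rng(seed)
    labels = np.array(["CC", "CG", "GG"])
    rows = []
    for status, n, male_frac, age, smk_e, smk_u, drk_e, drk_u in (
        ("case", spec.n_case, spec.male_frac_case, spec.age_case,
         *[spec.smoking_ever[0], spec.smoking_unknown[0],
           spec.drinking_ever[0], spec.drinking_unknown[0]]),
        ("control", spec.n_control, spec.male_frac_control, spec.age_control,
         *[spec.smoking_ever[1], spec.smoking_unknown[1],
           spec.drinking_ever[1], spec.drinking_unknown[1]]),
    ):
        sex = np.where(rng.random(n) < male_frac, "male", "female")
        geno = np.empty(n, dtype=object)
        for stratum in ("male", "female"):
            mask = sex == stratum
            if status == "control":
                probs = _control_genotype_probs(spec.maf)
            else:
                probs = _case_genotype_probs(
                    spec.maf, tuple(spec.or_by_stratum.get(stratum, (1.0, 1.0)))
                )
            geno[mask] = labels[rng.choice(3, size=int(mask.sum()), p=probs)]
        ages = np.clip(rng.normal(age[0], age[1], n), 18, 95)
        u = rng.random(n)
        smoking = np.where(u < smk_u, "unknown", np.where(u < smk_u + smk_e, "ever", "never"))
        u = rng.random(n)
        drinking = np.where(u < drk_u, "unknown", np.where(u < drk_u + drk_e, "ever", "never"))
        for i in range(n):
            rows.append(
                {
                    "id": f"{status[0]}{i:05d}", "status": status, "sex": sex[i],
                    "age": float(np.round(ages[i], 1)), "smoking": smoking[i],
                    "drinking": drinking[i], "genotype": geno[i],
                }
            )
    subjects = pd.DataFrame(rows)
    truth = {"spec": {
        "n_case": spec.n_case, "n_control": spec.n_control, "maf": spec.maf,
        "or_by_stratum": {k: list(v) for k, v in spec.or_by_stratum.items()},
    }}
    return subjects, truth


def write_cohort(subjects: pd.DataFrame, truth: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# qPCR Ct simulator
# ---------------------------------------------------------------------------


@dataclass
class CtSpec:
    n_per_genotype: tuple[int, int, int] = (22, 38, 12)  # CC, CG, GG
    genotype_shift: Mapping[str, float] = field(
        default_factory=lambda: {"CC": 0.0, "CG": -0.75, "GG": -1.5}
    )
    ct_noise_sd: float = 1.0  # between-sample biological variability (cycles)
    tech_sd: float = 0.1  # between-duplicate technical noise (cycles)
    ref_baseline: float = 20.0
    delta_baseline: float = 5.0  # target minus reference at genotype CC
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if self.ct_noise_sd < 0 or self.tech_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def simulate_ct_table(spec: CtSpec, seed=0) -> tuple[pd.DataFrame, dict]:
    """Simulate a duplicate qPCR Ct table; returns (records, truth).

    Each sample's reference Ct is baseline plus biological noise; the target
    Ct adds the genotype-specific delta-Ct shift. Technical noise is added
    per replicate. A negative shift means higher expression.
    """
    rng = _rng(seed)
    rows = []
    truth_samples = []
    k = 0
    for genotype, n in zip(("CC", "CG", "GG"), spec.n_per_genotype):
        shift = float(spec.genotype_shift.get(genotype, 0.0))
        for _ in range(n):
            sid = f"s{k:03d}"
            k += 1
            ref_mean = spec.ref_baseline + rng.normal(0, spec.ct_noise_sd)
            delta = spec.delta_baseline + shift + rng.normal(0, spec.ct_noise_sd)
            for rep in range(1, spec.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": sid, "genotype": genotype, "replicate": rep,
                        "ct_target": float(ref_mean + delta + rng.normal(0, spec.tech_sd)),
                        "ct_reference": float(ref_mean + rng.normal(0, spec.tech_sd)),
                    }
                )
            truth_samples.append({"sample_id": sid, "genotype": genotype,
                                  "true_delta_ct": delta})
    records = pd.DataFrame(rows)
    truth = {
        "spec": {
            "n_per_genotype": list(spec.n_per_genotype),
            "genotype_shift": dict(spec.genotype_shift),
            "ct_noise_sd": spec.ct_noise_sd, "tech_sd": spec.tech_sd,
        },
        "samples": truth_samples,
    }
    return records, truth


def write_ct_table(records: pd.DataFrame, truth: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records.to_csv(out / "ct_table.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
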