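"""Truth-tagged two-population genotype/haplotype simulator.

The generator emulates the structure of a two-breed resequencing panel
(default 10 + 10 individuals, mirroring a typical breed-comparison
design) without any coalescent machinery: background loci are drawn
independently per haplotype from an allele frequency shared by both
populations (Hardy–Weinberg within each, hence label-independent), and
the discriminative structure is planted explicitly:

* **fixed differences** — population 1 homozygous REF, population 2
  homozygous ALT: a perfectly discriminating locus whose extractor
  score is exactly H(y) = ln 2 for a balanced panel;
* **breed-exclusive heterozygosity loci** — one population entirely
  homozygous REF while each individual of the other is heterozygous or
  homozygous ALT: still perfectly discriminating, but with breed-private
  heterozygosity (the pattern behind the conditional heterozygosity
  means);
* **a sweep** — a carrier fraction of one population's haplotypes share
  one donor haplotype over a window around a core position, producing
  the extended haplotype homozygosity that XP-EHH detects;
* **a mitochondrial contig** — haploid (written as homozygous diploid
  calls) with its fixed differences planted as one contiguous block
  from the first mito SNP, the way discriminative variants cluster on a
  non-recombining molecule.

Planted autosomal loci are separated by at least two background SNPs so
each planted locus's adjacent-pair partners are background.  Background
linkage disequilibrium is absent outside the injected sweep; see the
methods note for what that does and does not exercise.

Every random draw flows from the single configured seed; output files
are byte-identical across runs with the same config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .genotype_io import (
    CLASS_ORDER,
    GeneInterval,
    GeneIntervalSet,
    GenotypeMatrix,
    HaplotypeBlock,
    HaplotypeMatrix,
    SampleMap,
    Site,
    write_sample_map,
    write_vcf,
)

_BASES = np.array(list("ACGT"))

_HOM = {"A": "AA", "T": "TT", "G": "GG", "C": "CC"}


@dataclass(frozen=True)
class SweepSpec:
    chrom: str
    core_bp: int
    carrier_fraction: float = 0.9
    length_bp: int = 200_000

    def __post_init__(self) -> None:
        if not 0.0 < self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must be in (0, 1]")


@dataclass(frozen=True)
class MitoSpec:
    n_snps: int = 33
    n_fixed: int = 7
    contig: str = "MT"
    spacing_bp: int = 500


@dataclass(frozen=True)
class SimConfig:
    n_per_pop: int = 10
    pop_names: Tuple[str, str] = ("Angus", "Jersey")
    n_chromosomes: int = 2
    snps_per_chromosome: int = 200
    spacing_bp: int = 1_000
    freq_range: Tuple[float, float] = (0.05, 0.95)
    n_fixed_difference_loci: int = 5
    n_breed_exclusive_het_loci: int = 5
    het_prob: float = 0.5
    sweep: Optional[SweepSpec] = None
    mito: Optional[MitoSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.n_fixed_difference_loci + self.n_breed_exclusive_het_loci
        total = self.n_chromosomes * self.snps_per_chromosome
        if self.n_chromosomes and planted * 3 > total:
            raise ValueError("too many planted loci for the configured genome size")
        if not 0.0 <= self.het_prob <= 1.0:
            raise ValueError("het_prob must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sweep" in raw and raw["sweep"] is not None:
            raw["sweep"] = SweepSpec(**raw["sweep"])
        if "mito" in raw and raw["mito"] is not None:
            raw["mito"] = MitoSpec(**raw["mito"])
        if "pop_names" in raw:
            raw["pop_names"] = tuple(raw["pop_names"])
        if "freq_range" in raw:
            raw["freq_range"] = tuple(raw["freq_range"])
        return cls(**raw)


@dataclass
class SimResult:
    genotypes: GenotypeMatrix
    haplotypes: HaplotypeMatrix
    sample_map: SampleMap
    truth: pd.DataFrame
    genes: GeneIntervalSet
    config: SimConfig

    def write(self, out_prefix: str) -> Dict[str, str]:
        """Write VCF, sample map, truth table and synthetic-gene BED."""
        paths = {
            "vcf": f"{out_prefix}.vcf",
            "samples": f"{out_prefix}.samples.tsv",
            "truth": f"{out_prefix}.truth.tsv",
            "genes": f"{out_prefix}.genes.bed",
        }
        write_vcf(self.genotypes, paths["vcf"], haplotypes=self.haplotypes)
        write_sample_map(self.sample_map, paths["samples"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with open(paths["genes"], "w") as fh:
            for g in self.genes.records:
                fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")
        return paths


def _positions(rng: np.random.Generator, n: int, spacing: int) -> np.ndarray:
    gaps = rng.integers(max(1, spacing // 2), spacing + spacing // 2 + 1, size=n)
    return np.cumsum(gaps).astype(np.int64)


def _ref_alt(rng: np.random.Generator, n: int) -> Tuple[np.ndarray, np.ndarray]:
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_i], _BASES[alt_i]


def simulate(config: SimConfig) -> SimResult:
    """Generate a truth-tagged two-population dataset from `config`."""
    rng = np.random.default_rng(config.seed)
    n = config.n_per_pop
    pop_a, pop_b = config.pop_names
    samples = [f"{pop_a[0]}{i + 1:02d}" for i in range(n)] + [
        f"{pop_b[0]}{i + 1:02d}" for i in range(n)
    ]
    if len(set(samples)) != len(samples):
        samples = [f"A{i + 1:02d}" for i in range(n)] + [f"B{i + 1:02d}" for i in range(n)]
    sample_map = SampleMap.from_pairs(
        [(s, pop_a) for s in samples[:n]] + [(s, pop_b) for s in samples[n:]]
    )
    populations = np.array([pop_a] * n + [pop_b] * n, dtype=object)
    a_cols = np.arange(0, 2 * n)  # haplotype columns of population A
    b_cols = np.arange(2 * n, 4 * n)

    chrom_names = [str(c + 1) for c in range(config.n_chromosomes)]

    sites: List[Site] = []
    blocks: Dict[str, HaplotypeBlock] = {}
    site_chrom_index: List[Tuple[str, int]] = []  # (chrom, index within block)

    for chrom in chrom_names:
        m = config.snps_per_chromosome
        pos = _positions(rng, m, config.spacing_bp)
        if len(set(pos.tolist())) != len(pos):
            raise ValueError(f"position collision on chromosome {chrom}")
        ref, alt = _ref_alt(rng, m)
        freq = rng.uniform(*config.freq_range, size=m)
        alleles = (rng.random((m, 4 * n)) < freq[:, None]).astype(np.int8)
        blocks[chrom] = HaplotypeBlock(positions=pos, alleles=alleles)
        for k in range(m):
            sites.append(Site(chrom=chrom, pos=int(pos[k]), ref=str(ref[k]), alt=str(alt[k])))
            site_chrom_index.append((chrom, k))

    truth_rows: List[Dict[str, object]] = []

    # --- planted autosomal loci (fixed differences + breed-exclusive het) ---
    planted_chroms = [
        c for c in chrom_names if config.sweep is None or c != config.sweep.chrom
    ] or chrom_names
    candidates: List[int] = [
        i for i, (c, _) in enumerate(site_chrom_index) if c in planted_chroms
    ]
    n_planted = config.n_fixed_difference_loci + config.n_breed_exclusive_het_loci
    chosen: List[int] = []
    if n_planted:
        shuffled = rng.permutation(len(candidates))
        for j in shuffled:
            i = candidates[j]
            chrom_i, k_i = site_chrom_index[i]
            if all(
                site_chrom_index[p][0] != chrom_i or abs(site_chrom_index[p][1] - k_i) >= 3
                for p in chosen
            ):
                chosen.append(i)
            if len(chosen) == n_planted:
                break
        if len(chosen) < n_planted:
            raise ValueError("could not place planted loci with the required separation")
    fixed_idx = sorted(chosen[: config.n_fixed_difference_loci])
    het_idx = sorted(chosen[config.n_fixed_difference_loci :])

    for i in fixed_idx:
        chrom, k = site_chrom_index[i]
        site = sites[i]
        block = blocks[chrom]
        block.alleles[k, a_cols] = 0
        block.alleles[k, b_cols] = 1
        truth_rows.append(
            {
                "chrom": chrom,
                "pos": site.pos,
                "role": "fixed_difference",
                "population": "",
                "class_a": _HOM[site.ref],
                "class_b": _HOM[site.alt],
                "het_count_a": 0,
                "het_count_b": 0,
            }
        )

    for j, i in enumerate(het_idx):
        chrom, k = site_chrom_index[i]
        site = sites[i]
        block = blocks[chrom]
        carrier_is_a = j % 2 == 0  # alternate which breed carries the heterozygosity
        carrier_cols = a_cols if carrier_is_a else b_cols
        other_cols = b_cols if carrier_is_a else a_cols
        block.alleles[k, other_cols] = 0  # other breed entirely homozygous REF
        het_mask = rng.random(n) < config.het_prob
        if not het_mask.any():
            het_mask[0] = True  # the pattern requires at least one heterozygote
        for s in range(n):
            c0, c1 = carrier_cols[2 * s], carrier_cols[2 * s + 1]
            if het_mask[s]:
                if rng.random() < 0.5:
                    block.alleles[k, c0], block.alleles[k, c1] = 0, 1
                else:
                    block.alleles[k, c0], block.alleles[k, c1] = 1, 0
            else:
                block.alleles[k, c0] = block.alleles[k, c1] = 1  # homozygous ALT
        n_het = int(het_mask.sum())
        truth_rows.append(
            {
                "chrom": chrom,
                "pos": site.pos,
                "role": "exclusive_het",
                "population": pop_a if carrier_is_a else pop_b,
                "class_a": "" if carrier_is_a else _HOM[site.ref],
                "class_b": _HOM[site.ref] if carrier_is_a else "",
                "het_count_a": n_het if carrier_is_a else 0,
                "het_count_b": 0 if carrier_is_a else n_het,
            }
        )

    # --- sweep: one shared donor haplotype among population-A carriers ---
    if config.sweep is not None:
        spec = config.sweep
        if spec.chrom not in blocks:
            raise ValueError(f"sweep chromosome {spec.chrom!r} not simulated")
        block = blocks[spec.chrom]
        core_k = int(np.argmin(np.abs(block.positions - spec.core_bp)))
        core_pos = block.positions[core_k]
        half = spec.length_bp / 2.0
        n_carriers = max(2, int(round(spec.carrier_fraction * 2 * n)))
        carriers = rng.choice(a_cols, size=min(n_carriers, 2 * n), replace=False)
        donor = block.alleles[:, carriers[0]].copy()
        # Each carrier copies the donor haplotype outward from the core
        # until its own recombination breakpoints; one-sided extents are
        # uniform on [length/4, length/2], so every carrier shares at
        # least the central half-window and the shared haplotype frays
        # toward the window edges the way a sweep flank does.
        for col in carriers:
            ext_left = rng.uniform(spec.length_bp / 4.0, half)
            ext_right = rng.uniform(spec.length_bp / 4.0, half)
            covered = (block.positions >= core_pos - ext_left) & (
                block.positions <= core_pos + ext_right
            )
            block.alleles[covered, col] = donor[covered]
        seg_pos = block.positions[
            np.abs(block.positions - core_pos) <= half
        ]
        truth_rows.append(
            {
                "chrom": spec.chrom,
                "pos": int(block.positions[core_k]),
                "role": "sweep_core",
                "population": pop_a,
                "class_a": "",
                "class_b": "",
                "het_count_a": 0,
                "het_count_b": 0,
                "segment_start": int(seg_pos.min()),
                "segment_end": int(seg_pos.max()),
            }
        )

    # --- mitochondrial contig: haploid, fixed block at the start ---
    if config.mito is not None:
        spec = config.mito
        if spec.n_fixed > spec.n_snps:
            raise ValueError("mito n_fixed exceeds n_snps")
        m = spec.n_snps
        pos = _positions(rng, m, spec.spacing_bp)
        ref, alt = _ref_alt(rng, m)
        freq = rng.uniform(*config.freq_range, size=m)
        hap1 = (rng.random((m, 2 * n)) < freq[:, None]).astype(np.int8)  # one allele/sample
        hap1[:spec.n_fixed, :n] = 0
        hap1[:spec.n_fixed, n:] = 1
        alleles = np.repeat(hap1, 2, axis=1)  # haploid -> homozygous diploid calls
        blocks[spec.contig] = HaplotypeBlock(positions=pos, alleles=alleles)
        for k in range(m):
            sites.append(
                Site(chrom=spec.contig, pos=int(pos[k]), ref=str(ref[k]), alt=str(alt[k]))
            )
            site_chrom_index.append((spec.contig, k))
            if k < spec.n_fixed:
                truth_rows.append(
                    {
                        "chrom": spec.contig,
                        "pos": int(pos[k]),
                        "role": "mito_fixed_difference",
                        "population": "",
                        "class_a": _HOM[str(ref[k])],
                        "class_b": _HOM[str(alt[k])],
                        "het_count_a": 0,
                        "het_count_b": 0,
                    }
                )

    # --- assemble matrices ---
    calls_rows = []
    for chrom, k in site_chrom_index:
        row = blocks[chrom].alleles[k]
        calls_rows.append(row[0::2] + row[1::2])
    calls = np.vstack(calls_rows).astype(np.int8)
    matrix = GenotypeMatrix(sites=sites, calls=calls, samples=samples, populations=populations)
    haplotypes = HaplotypeMatrix(blocks=blocks, samples=samples, populations=populations)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom",
            "pos",
            "role",
            "population",
            "class_a",
            "class_b",
            "het_count_a",
            "het_count_b",
            "segment_start",
            "segment_end",
        ],
    )

    # Synthetic "genes" tiling the planted loci, for annotation tests.
    gene_records: List[GeneInterval] = []
    for g, row in enumerate(truth.itertuples()):
        start = max(0, int(row.pos) - 501)
        gene_records.append(
            GeneInterval(
                name=f"SIMGENE_{g + 1:03d}",
                chrom=str(row.chrom),
                start=start,
                end=int(row.pos) + 500,
                strand="+",
            )
        )
    genes = GeneIntervalSet(records=gene_records)
    truth = truth.assign(gene=[g.name for g in gene_records])

    return SimResult(
        genotypes=matrix,
        haplotypes=haplotypes,
        sample_map=sample_map,
        truth=truth,
        genes=genes,
        config=config,
    )


def null_config(seed: int, **overrides) -> SimConfig:
    """A config with no planted structure (label-independent genotypes)."""
    base = SimConfig(
        n_fixed_difference_loci=0,
        n_breed_exclusive_het_loci=0,
        sweep=None,
        mito=None,
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base
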