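"""Genotype, sample-map and gene-annotation I/O.

This module owns every coordinate convention in the package:

* VCF positions are kept 1-based internally (as in the file).
* Gene intervals are normalized to 0-based half-open ``[start, end)``
  on read (BED is native; GFF3 ``start..end`` 1-based closed becomes
  ``[start-1, end)``).
* SNP→gene distance is measured between the 1-based site position and
  the half-open interval bounds: ``0`` when ``start < pos <= end``,
  otherwise ``start - pos`` (gene downstream of the site) or
  ``pos - end`` (gene upstream).

Genotypes are stored as ALT-allele dosages (0/1/2) together with the
per-site REF/ALT bases, from which the ten unordered base-pair classes
(AA, TT, GG, CC, AT, AG, AC, TG, TC, GC — heterozygote orientation
collapsed) are derived on demand.  Missing genotypes are a hard error:
imputation is an upstream concern and entropy estimates on partial
count tables are ill-defined.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from cyvcf2 import VCF

#: Canonical order of the ten unordered genotype classes.  Homozygotes
#: first, then the six heterozygote pairs; ties in downstream majority
#: votes are broken by this order.
CLASS_ORDER: Tuple[str, ...] = ("AA", "TT", "GG", "CC", "AT", "AG", "AC", "TG", "TC", "GC")

CLASS_INDEX: Dict[str, int] = {c: i for i, c in enumerate(CLASS_ORDER)}

_BASES = frozenset("ACGT")

_HOM_CLASS = {"A": "AA", "T": "TT", "G": "GG", "C": "CC"}

# Unordered pair -> canonical heterozygote class name.
_HET_CLASS = {frozenset(c): c for c in ("AT", "AG", "AC", "TG", "TC", "GC")}


class GenotypeDataError(ValueError):
    """Raised when an input file violates a contract of this package."""


@dataclass(frozen=True)
class Site:
    """One biallelic SNP site (position is 1-based, as in VCF)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise GenotypeDataError(
                f"site {self.chrom}:{self.pos}: bases must be A/C/G/T, got REF={self.ref} ALT={self.alt}"
            )
        if self.ref == self.alt:
            raise GenotypeDataError(f"site {self.chrom}:{self.pos}: REF equals ALT")


@dataclass
class SampleMap:
    """Sample→population assignment for exactly two populations."""

    samples: List[str]
    population_of: Dict[str, str]
    populations: Tuple[str, str]

    @classmethod
    def from_pairs(cls, pairs: Sequence[Tuple[str, str]]) -> "SampleMap":
        samples = [s for s, _ in pairs]
        if len(set(samples)) != len(samples):
            raise GenotypeDataError("duplicate sample id in sample map")
        pop_of = dict(pairs)
        pops = sorted(set(pop_of.values()))
        if len(pops) != 2:
            raise GenotypeDataError(
                f"sample map must define exactly two populations, found {len(pops)}: {pops}"
            )
        return cls(samples=samples, population_of=pop_of, populations=(pops[0], pops[1]))

    @classmethod
    def read(cls, path: str) -> "SampleMap":
        """Read a two-column TSV ``sample_id<TAB>population`` (# comments allowed)."""
        pairs: List[Tuple[str, str]] = []
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2 or not fields[0] or not fields[1]:
                    raise GenotypeDataError(f"{path}:{lineno}: expected 'sample<TAB>population'")
                pairs.append((fields[0], fields[1]))
        if not pairs:
            raise GenotypeDataError(f"{path}: empty sample map")
        return cls.from_pairs(pairs)

    def labels_for(self, samples: Sequence[str]) -> np.ndarray:
        """Population label per sample, as an object array aligned with `samples`."""
        missing = [s for s in samples if s not in self.population_of]
        if missing:
            raise GenotypeDataError(f"samples absent from sample map: {missing}")
        return np.array([self.population_of[s] for s in samples], dtype=object)


@dataclass
class CategoricalSiteVector:
    """One site's genotypes mapped onto the ten unordered base-pair classes."""

    site: Site
    codes: np.ndarray  # int8 indices into CLASS_ORDER, one per sample

    @property
    def labels(self) -> np.ndarray:
        return np.array([CLASS_ORDER[c] for c in self.codes], dtype=object)


@dataclass
class GenotypeMatrix:
    """Complete biallelic genotype calls for two populations.

    `calls[i, j]` is the ALT dosage of sample j at site i.
    """

    sites: List[Site]
    calls: np.ndarray  # (n_sites, n_samples) int8 in {0,1,2}
    samples: List[str]
    populations: np.ndarray  # (n_samples,) population label per sample

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise GenotypeDataError("calls shape does not match sites × samples")
        if self.calls.size and not np.isin(self.calls, (0, 1, 2)).all():
            raise GenotypeDataError("genotype dosages must be 0, 1 or 2 (no missing calls)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def pop_names(self) -> Tuple[str, str]:
        pops = sorted(set(self.populations.tolist()))
        if len(pops) != 2:
            raise GenotypeDataError(f"expected two populations, found {pops}")
        return (pops[0], pops[1])

    def pop_mask(self, population: str) -> np.ndarray:
        mask = self.populations == population
        if not mask.any():
            raise GenotypeDataError(f"unknown population {population!r}")
        return mask

    def y_codes(self) -> np.ndarray:
        """0/1 per sample: 0 for the alphabetically first population."""
        return (self.populations == self.pop_names[1]).astype(np.int8)

    def chromosomes(self) -> List[str]:
        """Chromosome names in order of first appearance."""
        seen: Dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s.chrom, None)
        return list(seen)

    def chrom_site_indices(self, chrom: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.sites) if s.chrom == chrom], dtype=np.int64)

    def class_codes(self) -> np.ndarray:
        """(n_sites, n_samples) int8 matrix of genotype-class indices."""
        out = np.empty_like(self.calls)
        for i, site in enumerate(self.sites):
            out[i] = _class_lut(site)[self.calls[i]]
        return out

    def encode(self, i: int) -> CategoricalSiteVector:
        return encode_site(self.sites[i], self.calls[i])


@dataclass
class HaplotypeBlock:
    """Phased 0/1 alleles for one chromosome: sites × (2 × samples)."""

    positions: np.ndarray  # (n_sites,) 1-based bp
    alleles: np.ndarray  # (n_sites, 2*n_samples) int8 in {0,1}

    def __post_init__(self) -> None:
        if self.alleles.shape[0] != self.positions.shape[0]:
            raise GenotypeDataError("haplotype alleles do not match positions")


@dataclass
class HaplotypeMatrix:
    """Per-chromosome phased haplotypes; columns 2j, 2j+1 belong to sample j."""

    blocks: Dict[str, HaplotypeBlock]
    samples: List[str]
    populations: np.ndarray

    def hap_columns(self, population: str) -> np.ndarray:
        """Haplotype-column indices belonging to one population."""
        idx = np.flatnonzero(self.populations == population)
        if idx.size == 0:
            raise GenotypeDataError(f"unknown population {population!r}")
        return np.sort(np.concatenate([2 * idx, 2 * idx + 1]))


@dataclass(frozen=True)
class GeneInterval:
    """A gene as a 0-based half-open interval."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise GenotypeDataError(f"gene {self.name}: start {self.start} >= end {self.end}")


@dataclass
class GeneIntervalSet:
    records: List[GeneInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        # De-duplicate by (name, chrom), keeping the first occurrence.
        seen = set()
        unique: List[GeneInterval] = []
        for g in self.records:
            key = (g.name, g.chrom)
            if key not in seen:
                seen.add(key)
                unique.append(g)
        self.records = unique

    def __len__(self) -> int:
        return len(self.records)

    def by_chrom(self) -> Dict[str, List[GeneInterval]]:
        out: Dict[str, List[GeneInterval]] = {}
        for g in self.records:
            out.setdefault(g.chrom, []).append(g)
        for genes in out.values():
            genes.sort(key=lambda g: (g.start, g.end, g.name))
        return out

    def names(self) -> List[str]:
        return [g.name for g in self.records]


@dataclass
class VcfData:
    """Result of :func:`read_vcf`: genotypes, optional phased haplotypes, drop log."""

    genotypes: GenotypeMatrix
    haplotypes: Optional[HaplotypeMatrix]
    dropped: Dict[str, int]


def _class_lut(site: Site) -> np.ndarray:
    """Map dosage {0,1,2} -> class index for one site."""
    hom_ref = CLASS_INDEX[_HOM_CLASS[site.ref]]
    hom_alt = CLASS_INDEX[_HOM_CLASS[site.alt]]
    het = CLASS_INDEX[_HET_CLASS[frozenset((site.ref, site.alt))]]
    return np.array([hom_ref, het, hom_alt], dtype=np.int8)


def encode_site(site: Site, calls: np.ndarray) -> CategoricalSiteVector:
    """Map one site's dosages to the ten unordered base-pair classes.

    Heterozygote orientation is collapsed (REF=A/ALT=T and REF=T/ALT=A
    both yield class AT), so 0/1 and 1/0 calls are indistinguishable.
    """
    calls = np.asarray(calls)
    if calls.size and not np.isin(calls, (0, 1, 2)).all():
        raise GenotypeDataError(f"site {site.chrom}:{site.pos}: dosages must be in {{0,1,2}}")
    return CategoricalSiteVector(site=site, codes=_class_lut(site)[calls])


def read_vcf(path: str, sample_map: SampleMap) -> VcfData:
    """Read a biallelic-SNP genotype matrix (and haplotypes, if fully phased).

    Multiallelic and non-SNP records are dropped and counted in the drop
    log.  Missing genotypes, samples absent from the map, and duplicated
    positions on a chromosome are hard errors naming the offending record.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise GenotypeDataError(f"{path}: VCF has no sample columns / GT data")
    populations = sample_map.labels_for(samples)

    dropped = {"indel": 0, "multiallelic": 0, "non_acgt": 0}
    sites: List[Site] = []
    rows: List[np.ndarray] = []
    hap_rows: List[np.ndarray] = []
    all_phased = True
    seen_pos: Dict[str, set] = {}

    for var in vcf:
        alts = var.ALT
        if len(alts) != 1:
            dropped["multiallelic"] += 1
            continue
        ref, alt = var.REF, alts[0]
        if len(ref) != 1 or len(alt) != 1:
            dropped["indel"] += 1
            continue
        if ref not in _BASES or alt not in _BASES:
            dropped["non_acgt"] += 1
            continue
        chrom, pos = var.CHROM, var.POS
        positions = seen_pos.setdefault(chrom, set())
        if pos in positions:
            raise GenotypeDataError(f"duplicated position {chrom}:{pos}")
        positions.add(pos)

        gts = var.genotypes  # [allele0, allele1, phased] per sample
        dosages = np.empty(len(samples), dtype=np.int8)
        haps = np.empty(2 * len(samples), dtype=np.int8)
        for j, gt in enumerate(gts):
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0 or len(gt) < 3:
                raise GenotypeDataError(
                    f"missing genotype at {chrom}:{pos} (sample {samples[j]})"
                )
            dosages[j] = a0 + a1
            haps[2 * j], haps[2 * j + 1] = a0, a1
            if not gt[2]:
                all_phased = False
        sites.append(Site(chrom=chrom, pos=pos, ref=ref, alt=alt))
        rows.append(dosages)
        hap_rows.append(haps)

    if not sites:
        raise GenotypeDataError(f"{path}: no biallelic SNPs after filtering")

    # Sort within chromosome by position, preserving chromosome order of
    # first appearance.
    chrom_order: Dict[str, int] = {}
    for s in sites:
        chrom_order.setdefault(s.chrom, len(chrom_order))
    order = sorted(range(len(sites)), key=lambda i: (chrom_order[sites[i].chrom], sites[i].pos))
    sites = [sites[i] for i in order]
    calls = np.vstack([rows[i] for i in order])

    matrix = GenotypeMatrix(sites=sites, calls=calls, samples=samples, populations=populations)

    haplotypes: Optional[HaplotypeMatrix] = None
    if all_phased:
        hap_all = np.vstack([hap_rows[i] for i in order])
        blocks: Dict[str, HaplotypeBlock] = {}
        for chrom in matrix.chromosomes():
            idx = matrix.chrom_site_indices(chrom)
            blocks[chrom] = HaplotypeBlock(
                positions=np.array([sites[i].pos for i in idx], dtype=np.int64),
                alleles=hap_all[idx],
            )
        haplotypes = HaplotypeMatrix(blocks=blocks, samples=samples, populations=populations)

    return VcfData(genotypes=matrix, haplotypes=haplotypes, dropped=dropped)


def write_vcf(matrix: GenotypeMatrix, path: str, haplotypes: Optional[HaplotypeMatrix] = None) -> None:
    """Write a minimal GT-only VCF.

    Output is byte-deterministic (no date or version header lines).  When
    `haplotypes` is given, genotypes are written phased from the haplotype
    alleles; otherwise unphased from dosages.
    """
    hap_of_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    if haplotypes is not None:
        for chrom, block in haplotypes.blocks.items():
            hap_of_chrom[chrom] = (block.positions, block.alleles)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in matrix.chromosomes():
            idx = matrix.chrom_site_indices(chrom)
            length = matrix.sites[idx[-1]].pos + 1000
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.samples) + "\n")
        for i, site in enumerate(matrix.sites):
            if site.chrom in hap_of_chrom:
                positions, alleles = hap_of_chrom[site.chrom]
                k = int(np.searchsorted(positions, site.pos))
                row = alleles[k]
                gts = [f"{row[2 * j]}|{row[2 * j + 1]}" for j in range(matrix.n_samples)]
            else:
                lut = {0: "0/0", 1: "0/1", 2: "1/1"}
                gts = [lut[int(g)] for g in matrix.calls[i]]
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_sample_map(sample_map: SampleMap, path: str) -> None:
    with open(path, "w") as fh:
        for s in sample_map.samples:
            fh.write(f"{s}\t{sample_map.population_of[s]}\n")


def read_gene_annotation(path: str, format: str = "bed") -> GeneIntervalSet:
    """Read gene intervals from BED4+ (0-based half-open) or GFF3 (gene features).

    GFF3 gene names come from the ``Name=`` attribute, falling back to
    ``gene_id=``; coordinates are normalized to 0-based half-open.
    """
    fmt = format.lower()
    if fmt not in ("bed", "gff3"):
        raise GenotypeDataError(f"unknown annotation format {format!r} (expected bed or gff3)")
    records: List[GeneInterval] = []
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    if len(fields) < 4:
                        raise ValueError("BED needs at least 4 columns (chrom start end name)")
                    chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                    strand = fields[5] if len(fields) >= 6 else "."
                else:
                    if len(fields) < 9:
                        raise ValueError("GFF3 needs 9 columns")
                    if fields[2] != "gene":
                        continue
                    chrom, strand = fields[0], fields[6]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    attrs = dict(
                        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                    )
                    name = attrs.get("Name") or attrs.get("gene_id")
                    if not name:
                        raise ValueError("gene feature lacks Name= and gene_id= attributes")
                if start >= end:
                    raise ValueError(f"start {start} >= end {end}")
                records.append(GeneInterval(name=name, chrom=chrom, start=start, end=end, strand=strand))
            except (ValueError, GenotypeDataError) as exc:
                raise GenotypeDataError(f"{path}:{lineno}: {exc}") from None
    return GeneIntervalSet(records=records)


def _interval_distance(pos: int, gene: GeneInterval) -> int:
    """Distance between a 1-based site position and a half-open gene interval."""
    if gene.start < pos <= gene.end:
        return 0
    if pos <= gene.start:
        return gene.start - pos
    return pos - gene.end


def assign_snps_to_genes(
    sites: Sequence[Site], genes: GeneIntervalSet, max_distance_bp: int = 0
) -> List[Optional[str]]:
    """Nearest-gene assignment per site, up to `max_distance_bp`.

    A site inside a gene maps to it (distance 0); otherwise to the nearest
    gene on the same chromosome within the cap, ties broken by the smaller
    start coordinate.  Sites beyond the cap (or on gene-less chromosomes)
    come back as None.
    """
    if max_distance_bp < 0:
        raise GenotypeDataError("max_distance_bp must be >= 0")
    genes_of = genes.by_chrom()
    out: List[Optional[str]] = []
    for site in sites:
        candidates = genes_of.get(site.chrom, [])
        best: Optional[str] = None
        best_key: Optional[Tuple[int, int]] = None
        for g in candidates:
            d = _interval_distance(site.pos, g)
            if d > max_distance_bp:
                continue
            key = (d, g.start)
            if best_key is None or key < best_key:
                best_key, best = key, g.name
        out.append(best)
    return out
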