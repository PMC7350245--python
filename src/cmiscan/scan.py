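"""Genome-wide adjacent-pair extractor scan and descriptive summaries.

Adjacency means consecutive SNPs in coordinate order on the same
chromosome, with no physical-distance cap.  Each SNP participates in at
most two pairs; its reported score is the maximum over those pairs, with
the partner recorded.  Permutation p-values are computed lazily — only
for SNPs whose score reaches the flagging threshold θ, since sub-θ SNPs
can never be flagged regardless of p.  A SNP is flagged when its score
is ≥ θ (closed comparison: perfectly discriminating pairs sit exactly at
the H(y) = ln 2 ceiling) and its permutation p-value is below the
p-threshold.  No multiple-testing correction is applied by default,
mirroring the raw strict-p convention; a Bonferroni option is exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genotype_io import (
    CLASS_ORDER,
    GeneInterval,
    GeneIntervalSet,
    GenotypeMatrix,
    assign_snps_to_genes,
)
from .infotheory import extractor_from_vectors, permutation_pvalue

SCORE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "pair_partner_pos",
    "cmi_nats",
    "p_value",
    "flagged",
    "gene",
]


@dataclass
class ScanResult:
    """Per-SNP extractor scores; `table` columns follow SCORE_COLUMNS."""

    table: pd.DataFrame
    theta: float
    p_threshold: float
    n_perm: int
    warnings: Dict[str, int] = field(default_factory=dict)

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flagged"]]

    def flagged_indices(self) -> np.ndarray:
        return self.table.index[self.table["flagged"]].to_numpy()

    def write(self, path: str) -> None:
        out = self.table[SCORE_COLUMNS].copy()
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


def scan_genome(
    matrix: GenotypeMatrix,
    theta: float = 0.693,
    p_threshold: float = 1e-3,
    n_perm: int = 9_999,
    seed: Optional[int] = None,
    genes: Optional[GeneIntervalSet] = None,
    max_distance_bp: int = 0,
    bonferroni: bool = False,
) -> ScanResult:
    """Score every SNP by the best adjacent-pair extractor value.

    For each consecutive same-chromosome pair (i, i+1) the extractor
    I(y; class_i, class_{i+1}) is evaluated on the ten-class genotype
    codes; each SNP keeps the larger of its ≤2 pair scores.  Chromosome
    singletons cannot be paired and are reported unscored (NaN) with a
    warning count.
    """
    rng = np.random.default_rng(seed)
    y = matrix.y_codes()
    codes = matrix.class_codes()
    n_sites = matrix.n_sites

    score = np.full(n_sites, np.nan)
    partner = np.full(n_sites, -1, dtype=np.int64)
    singletons = 0
    n_pairs = 0

    for chrom in matrix.chromosomes():
        idx = matrix.chrom_site_indices(chrom)
        if idx.size < 2:
            singletons += idx.size
            continue
        for a, b in zip(idx[:-1], idx[1:]):
            val = extractor_from_vectors(y, codes[a], codes[b])
            n_pairs += 1
            for this, other in ((a, b), (b, a)):
                if np.isnan(score[this]) or val > score[this]:
                    score[this] = val
                    partner[this] = other

    effective_p = p_threshold / max(n_pairs, 1) if bonferroni else p_threshold

    p_value = np.where(np.isnan(score), np.nan, 1.0)
    candidates = np.flatnonzero(~np.isnan(score) & (score >= theta))
    for i in candidates:
        p, _ = permutation_pvalue(
            score[i], y, codes[i], codes[partner[i]], n_perm=n_perm, seed=rng
        )
        p_value[i] = p

    flagged = ~np.isnan(score) & (score >= theta) & (p_value < effective_p)

    gene_names: List[Optional[str]]
    if genes is not None:
        gene_names = assign_snps_to_genes(matrix.sites, genes, max_distance_bp)
    else:
        gene_names = [None] * n_sites

    table = pd.DataFrame(
        {
            "chrom": [s.chrom for s in matrix.sites],
            "pos": [s.pos for s in matrix.sites],
            "ref": [s.ref for s in matrix.sites],
            "alt": [s.alt for s in matrix.sites],
            "pair_partner_pos": [
                matrix.sites[p].pos if p >= 0 else -1 for p in partner
            ],
            "cmi_nats": score,
            "p_value": p_value,
            "flagged": flagged,
            "gene": gene_names,
        }
    )
    warnings = {"chromosome_singletons": singletons, "n_pairs": n_pairs}
    return ScanResult(
        table=table,
        theta=theta,
        p_threshold=effective_p,
        n_perm=n_perm,
        warnings=warnings,
    )


def _majority_class(codes_row: np.ndarray, mask: np.ndarray) -> int:
    """Majority genotype-class code within one population; ties broken by
    the canonical class order (lowest code wins)."""
    counts = np.bincount(codes_row[mask], minlength=len(CLASS_ORDER))
    return int(np.argmax(counts))  # argmax takes the first (canonical) maximum


def genotype_class_distribution(
    result: ScanResult,
    matrix: GenotypeMatrix,
    site_indices: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Per chromosome × population counts of flagged-SNP majority classes.

    Each flagged SNP contributes, for each population, that population's
    majority genotype class at the SNP.  Rows cover every chromosome in
    the matrix and both populations, with a count column per class (zero
    where nothing was flagged).  `site_indices` optionally restricts the
    tally to a subset of flagged sites.
    """
    codes = matrix.class_codes()
    pops = matrix.pop_names
    masks = {p: matrix.pop_mask(p) for p in pops}
    chroms = matrix.chromosomes()
    counts: Dict[Tuple[str, str], np.ndarray] = {
        (c, p): np.zeros(len(CLASS_ORDER), dtype=np.int64) for c in chroms for p in pops
    }
    flagged = set(result.flagged_indices().tolist())
    if site_indices is not None:
        flagged &= set(int(i) for i in site_indices)
    for i in sorted(flagged):
        chrom = matrix.sites[i].chrom
        for p in pops:
            counts[(chrom, p)][_majority_class(codes[i], masks[p])] += 1
    rows = []
    for (chrom, p), vec in counts.items():
        row = {"chrom": chrom, "population": p}
        row.update({cls: int(v) for cls, v in zip(CLASS_ORDER, vec)})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class HeterozygosityTable:
    """The three conditional mean heterozygote counts, per population.

    For each population: the mean per-locus heterozygote count over all
    loci; the mean restricted to loci where the *other* population is
    entirely homozygous; and the mean where the other population has at
    least one heterozygote.  Empty partitions are None (undefined), which
    is distinct from a mean of 0.
    """

    per_population: Dict[str, Dict[str, Optional[float]]]
    n_loci: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pop, entry in self.per_population.items():
            rows.append({"population": pop, **entry})
        return pd.DataFrame(rows)


def heterozygosity_table(
    result: ScanResult,
    matrix: GenotypeMatrix,
    gene_subset: Optional[Sequence[str]] = None,
) -> HeterozygosityTable:
    """Table of per-locus heterozygosity means over flagged SNPs.

    The locus set is the flagged SNPs, optionally restricted to those
    assigned to genes in `gene_subset`.  A sample is heterozygous at a
    locus when its two bases differ (dosage 1).
    """
    idx = result.flagged_indices()
    if gene_subset is not None:
        wanted = {g.strip().upper() for g in gene_subset}
        gene_col = result.table["gene"]
        idx = np.array(
            [
                i
                for i in idx
                if gene_col.iloc[i] is not None and str(gene_col.iloc[i]).upper() in wanted
            ],
            dtype=np.int64,
        )
    pops = matrix.pop_names
    het = {p: (matrix.calls[idx][:, matrix.pop_mask(p)] == 1).sum(axis=1) for p in pops}

    def _mean(values: np.ndarray) -> Optional[float]:
        return float(values.mean()) if values.size else None

    per_pop: Dict[str, Dict[str, Optional[float]]] = {}
    for p in pops:
        other = pops[1] if p == pops[0] else pops[0]
        other_all_hom = het[other] == 0
        per_pop[p] = {
            "total_mean_het_count": _mean(het[p]),
            "mean_het_given_other_all_homozygous": _mean(het[p][other_all_hom]),
            "mean_het_given_other_any_heterozygous": _mean(het[p][~other_all_hom]),
        }
    return HeterozygosityTable(per_population=per_pop, n_loci=int(idx.size))


def genotype_profile(
    matrix: GenotypeMatrix, gene: GeneInterval, population: str
) -> pd.DataFrame:
    """Sites × ten-class count matrix for one population inside a gene.

    Rows are the SNPs overlapping the gene interval (1-based position in
    the ``pos`` column); columns are the ten genotype classes; cells
    count individuals, so every row sums to the population size.  An
    empty frame (no overlapping SNPs) is a valid, warned-about outcome
    for the caller to handle.
    """
    mask = matrix.pop_mask(population)
    codes = matrix.class_codes()
    rows = []
    for i, site in enumerate(matrix.sites):
        if site.chrom == gene.chrom and gene.start < site.pos <= gene.end:
            counts = np.bincount(codes[i][mask], minlength=len(CLASS_ORDER))
            row = {"pos": site.pos}
            row.update({cls: int(v) for cls, v in zip(CLASS_ORDER, counts)})
            rows.append(row)
    return pd.DataFrame(rows, columns=["pos", *CLASS_ORDER])


@dataclass
class MitoSummary:
    n_total: int
    n_flagged: int
    percent_flagged: Optional[float]  # None when the contig is absent


def mito_summary(result: ScanResult, matrix: GenotypeMatrix, mito_name: str = "MT") -> MitoSummary:
    """Flagged fraction of mitochondrial SNPs, percent to one decimal."""
    mito_idx = matrix.chrom_site_indices(mito_name)
    if mito_idx.size == 0:
        return MitoSummary(n_total=0, n_flagged=0, percent_flagged=None)
    flagged = set(result.flagged_indices().tolist())
    n_flagged = sum(1 for i in mito_idx if int(i) in flagged)
    percent = round(100.0 * n_flagged / mito_idx.size, 1)
    return MitoSummary(n_total=int(mito_idx.size), n_flagged=n_flagged, percent_flagged=percent)
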