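"""Cross-population extended haplotype homozygosity (XP-EHH).

EHH here is flanking-haplotype homozygosity around a core SNP with both
core alleles pooled: walking outward from the core, haplotypes are
grouped by their allele vector over the sites strictly between the core
and the current site (inclusive of the current site), and

    EHH(d) = Σ_h C(c_h, 2) / C(n, 2)

over the group sizes c_h of the n population haplotypes.  The curve
starts at exactly 1 at the core and is non-increasing, since groups only
ever refine.  Distances are physical bp (no genetic map).

iHH integrates the EHH decay curve by the trapezoid rule, summed over
the two directions, truncating at the first sampled point whose EHH
falls below the truncation level (that final trapezoid is included; no
interpolation of the crossing).  The XP-EHH raw score for a core is
ln(iHH_A / iHH_B); raw scores are z-normalized genome-wide to mean 0,
variance 1, so positive extremes point to unusually long haplotype
homozygosity — a sweep signature — in population A and negative
extremes in population B.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .genotype_io import (
    GeneIntervalSet,
    HaplotypeBlock,
    HaplotypeMatrix,
    Site,
    assign_snps_to_genes,
)


@dataclass
class EhhCurve:
    """EHH values at successive flanking SNPs, from the core outward."""

    core_index: int
    direction: str  # "upstream" (decreasing pos) or "downstream"
    distances: np.ndarray  # bp from the core; first entry is 0
    values: np.ndarray  # EHH in [0, 1]; first entry is 1


def ehh(
    block: HaplotypeBlock,
    hap_columns: Sequence[int],
    core_index: int,
    direction: str,
) -> EhhCurve:
    """EHH decay curve for one population in one direction.

    A core on the chromosome edge yields a length-1 curve [(0, 1)].
    """
    if direction not in ("upstream", "downstream"):
        raise ValueError(f"direction must be upstream/downstream, got {direction!r}")
    cols = np.asarray(hap_columns, dtype=np.int64)
    n = cols.size
    if n < 2:
        raise ValueError("EHH needs at least 2 haplotypes")
    alleles = block.alleles[:, cols]
    n_sites = block.positions.size
    step = -1 if direction == "upstream" else 1
    pair_total = n * (n - 1) / 2.0

    distances = [0.0]
    values = [1.0]
    group = np.zeros(n, dtype=np.int64)  # all in one group over the empty interval
    n_groups = 1
    i = core_index + step
    while 0 <= i < n_sites:
        key = group * 2 + alleles[i]
        _, group = np.unique(key, return_inverse=True)
        n_groups = int(group.max()) + 1
        counts = np.bincount(group, minlength=n_groups)
        hom = float((counts * (counts - 1) / 2.0).sum() / pair_total)
        distances.append(float(abs(block.positions[i] - block.positions[core_index])))
        values.append(hom)
        if hom == 0.0:
            break  # groups can only refine; EHH stays 0 from here on
        i += step
    return EhhCurve(
        core_index=core_index,
        direction=direction,
        distances=np.asarray(distances),
        values=np.asarray(values),
    )


@dataclass
class IhhResult:
    area: float  # bp-weighted area under EHH, both directions
    edge_warning: bool  # some direction hit the chromosome end above truncation


def ihh(curves: Sequence[EhhCurve], truncation_ehh: float = 0.05) -> IhhResult:
    """Trapezoidal iHH over one or more directional curves.

    Integration stops at the first point with EHH below `truncation_ehh`,
    including the trapezoid that reaches it.  If a curve never falls
    below the truncation before the chromosome end, it is integrated to
    its end and the edge warning is set.
    """
    if not 0.0 < truncation_ehh < 1.0:
        raise ValueError("truncation_ehh must be in (0, 1)")
    area = 0.0
    edge = False
    for curve in curves:
        d, v = curve.distances, curve.values
        truncated = False
        for k in range(1, d.size):
            area += 0.5 * (v[k - 1] + v[k]) * (d[k] - d[k - 1])
            if v[k] < truncation_ehh:
                truncated = True
                break
        if not truncated:
            edge = True
    return IhhResult(area=area, edge_warning=edge)


def site_ihh(
    block: HaplotypeBlock,
    hap_columns: Sequence[int],
    core_index: int,
    truncation_ehh: float = 0.05,
) -> IhhResult:
    """iHH for one core: upstream plus downstream EHH areas."""
    return ihh(
        (
            ehh(block, hap_columns, core_index, "upstream"),
            ehh(block, hap_columns, core_index, "downstream"),
        ),
        truncation_ehh=truncation_ehh,
    )


@dataclass
class XpehhResult:
    """Per-site XP-EHH scores; z is normalized over all retained sites."""

    table: pd.DataFrame  # chrom pos ihh_a ihh_b raw z
    pop_a: str
    pop_b: str
    n_dropped: int
    edge_warnings: int

    def write(self, path: str, extremes: Optional[Tuple[pd.DataFrame, pd.DataFrame]] = None) -> None:
        out = self.table.copy()
        if extremes is not None:
            top, bottom = extremes
            out["extreme"] = ""
            out.loc[out.index.isin(top.index), "extreme"] = self.pop_a
            out.loc[out.index.isin(bottom.index), "extreme"] = self.pop_b
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


def xpehh_scan(
    haplotypes: HaplotypeMatrix,
    pop_a: str,
    pop_b: str,
    truncation_ehh: float = 0.05,
    min_ihh: float = 1e-3,
) -> XpehhResult:
    """Genome-wide XP-EHH: per-core ln(iHH_A/iHH_B), z-normalized.

    Cores where either population's iHH falls below `min_ihh` are
    dropped (the log-ratio of near-zero areas is unstable); at least two
    cores must survive for the normalization to be defined.
    """
    cols_a = haplotypes.hap_columns(pop_a)
    cols_b = haplotypes.hap_columns(pop_b)
    rows: List[Dict[str, object]] = []
    n_dropped = 0
    edge_warnings = 0
    for chrom, block in haplotypes.blocks.items():
        for core in range(block.positions.size):
            res_a = site_ihh(block, cols_a, core, truncation_ehh)
            res_b = site_ihh(block, cols_b, core, truncation_ehh)
            if res_a.edge_warning or res_b.edge_warning:
                edge_warnings += 1
            if res_a.area < min_ihh or res_b.area < min_ihh:
                n_dropped += 1
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(block.positions[core]),
                    "ihh_a": res_a.area,
                    "ihh_b": res_b.area,
                    "raw": float(np.log(res_a.area / res_b.area)),
                }
            )
    if len(rows) < 2:
        raise ValueError(f"only {len(rows)} sites retained; cannot normalize XP-EHH scores")
    table = pd.DataFrame(rows)
    raw = table["raw"].to_numpy()
    sd = raw.std()  # population SD: z has variance exactly 1
    if sd == 0:
        table["z"] = 0.0
    else:
        table["z"] = (raw - raw.mean()) / sd
    return XpehhResult(
        table=table, pop_a=pop_a, pop_b=pop_b, n_dropped=n_dropped, edge_warnings=edge_warnings
    )


def select_extremes(
    result: XpehhResult,
    quantile: float = 0.01,
    genes: Optional[GeneIntervalSet] = None,
    max_distance_bp: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Top/bottom `quantile` of z scores → (pop-A, pop-B) candidate sites.

    With n retained sites, each tail keeps int(n × quantile) sites; a
    degenerate all-equal z distribution yields empty tails.  When `genes`
    is given each candidate is annotated with its nearest gene.
    """
    if not 0.0 < quantile < 0.5:
        raise ValueError("quantile must be in (0, 0.5)")
    table = result.table
    z = table["z"].to_numpy()
    k = int(z.size * quantile)
    if k == 0 or np.ptp(z) == 0:
        empty = table.iloc[0:0].copy()
        return empty, empty
    order = np.argsort(z, kind="stable")
    top = table.iloc[order[-k:][::-1]].copy()
    bottom = table.iloc[order[:k]].copy()
    if genes is not None:
        for side in (top, bottom):
            sites = [
                Site(chrom=r.chrom, pos=int(r.pos), ref="A", alt="G")
                for r in side.itertuples()
            ]
            side["gene"] = assign_snps_to_genes(sites, genes, max_distance_bp)
    return top, bottom


#: Gene symbols matching this pattern are structural/small RNAs excluded
#: from overlap reports (rRNA, spliceosomal U RNAs, 7SK, snoRNAs, ...).
DEFAULT_RNA_EXCLUDE = r"(?i)^(5S_rRNA|7SK|U\d+|SNOR[AD]?\d*|.*_rRNA|.*_tRNA)$"


@dataclass
class OverlapReport:
    """Intersections between CMI-flagged genes and selection-scan candidates."""

    cmi: Set[str]
    xpehh_a: Set[str]
    xpehh_b: Set[str]
    xpclr_a: Optional[Set[str]] = None
    xpclr_b: Optional[Set[str]] = None
    pairwise: Dict[str, Set[str]] = field(default_factory=dict)
    three_way_a: Optional[Set[str]] = None
    three_way_b: Optional[Set[str]] = None
    n_excluded_rna: int = 0

    def counts(self) -> Dict[str, int]:
        out = {k: len(v) for k, v in self.pairwise.items()}
        if self.three_way_a is not None:
            out["cmi_xpehh_xpclr_a"] = len(self.three_way_a)
        if self.three_way_b is not None:
            out["cmi_xpehh_xpclr_b"] = len(self.three_way_b)
        return out


def overlap_sets(
    cmi_genes: Sequence[str],
    xpehh_genes_a: Sequence[str],
    xpehh_genes_b: Sequence[str],
    xpclr_genes_a: Optional[Sequence[str]] = None,
    xpclr_genes_b: Optional[Sequence[str]] = None,
    rna_exclude: str = DEFAULT_RNA_EXCLUDE,
) -> OverlapReport:
    """Pairwise and three-way candidate-gene intersections.

    Gene symbols are whitespace-stripped before matching; symbols whose
    name matches the RNA exclusion pattern are removed from every list
    before counting.
    """
    pattern = re.compile(rna_exclude) if rna_exclude else None
    excluded = 0

    def clean(names: Optional[Sequence[str]]) -> Optional[Set[str]]:
        nonlocal excluded
        if names is None:
            return None
        out = set()
        for raw in names:
            name = str(raw).strip()
            if not name:
                continue
            if pattern is not None and pattern.match(name):
                excluded += 1
                continue
            out.add(name)
        return out

    cmi = clean(cmi_genes) or set()
    xa = clean(xpehh_genes_a) or set()
    xb = clean(xpehh_genes_b) or set()
    ca = clean(xpclr_genes_a)
    cb = clean(xpclr_genes_b)

    pairwise = {
        "cmi_xpehh_a": cmi & xa,
        "cmi_xpehh_b": cmi & xb,
    }
    if ca is not None:
        pairwise["cmi_xpclr_a"] = cmi & ca
    if cb is not None:
        pairwise["cmi_xpclr_b"] = cmi & cb
    return OverlapReport(
        cmi=cmi,
        xpehh_a=xa,
        xpehh_b=xb,
        xpclr_a=ca,
        xpclr_b=cb,
        pairwise=pairwise,
        three_way_a=(cmi & xa & ca) if ca is not None else None,
        three_way_b=(cmi & xb & cb) if cb is not None else None,
        n_excluded_rna=excluded,
    )
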