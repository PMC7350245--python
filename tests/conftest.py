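import numpy as np
import pytest

from cmiscan.genotype_io import GenotypeMatrix, SampleMap, Site
from cmiscan.simulate import MitoSpec, SimConfig, simulate


@pytest.fixture(scope="session")
def balanced_labels():
    """0/1 population codes for a balanced 10 + 10 panel."""
    return np.array([0] * 10 + [1] * 10, dtype=np.int8)


@pytest.fixture(scope="session")
def planted_sim():
    """Small two-chromosome dataset with planted discriminative loci."""
    config = SimConfig(
        n_chromosomes=2,
        snps_per_chromosome=100,
        n_fixed_difference_loci=3,
        n_breed_exclusive_het_loci=3,
        mito=MitoSpec(n_snps=33, n_fixed=7),
        seed=42,
    )
    return simulate(config)


@pytest.fixture(scope="session")
def planted_scan(planted_sim):
    from cmiscan.scan import scan_genome

    return scan_genome(
        planted_sim.genotypes,
        seed=7,
        genes=planted_sim.genes,
        max_distance_bp=0,
    )


def make_matrix(sites, calls, n_per_pop=10, pops=("Angus", "Jersey")):
    """Assemble a GenotypeMatrix from site tuples and a dosage array."""
    site_objs = [Site(chrom=c, pos=p, ref=r, alt=a) for c, p, r, a in sites]
    n = n_per_pop
    samples = [f"A{i:02d}" for i in range(n)] + [f"B{i:02d}" for i in range(n)]
    populations = np.array([pops[0]] * n + [pops[1]] * n, dtype=object)
    return GenotypeMatrix(
        sites=site_objs,
        calls=np.asarray(calls, dtype=np.int8),
        samples=samples,
        populations=populations,
    )


def write_vcf_text(path, body, samples):
    """Write a minimal VCF file from raw record lines."""
    header = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n"
    )
    path.write_text(header + body)
    return str(path)


@pytest.fixture()
def sample_map_4():
    return SampleMap.from_pairs(
        [("s1", "Angus"), ("s2", "Angus"), ("s3", "Jersey"), ("s4", "Jersey")]
    )
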