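import numpy as np
import pandas as pd
import pytest

from cmiscan.genotype_io import HaplotypeBlock, HaplotypeMatrix
from cmiscan.simulate import SimConfig, SweepSpec, simulate
from cmiscan.xpehh import (
    EhhCurve,
    ehh,
    ihh,
    overlap_sets,
    select_extremes,
    site_ihh,
    xpehh_scan,
)


def block_from(positions, alleles):
    return HaplotypeBlock(
        positions=np.asarray(positions, dtype=np.int64),
        alleles=np.asarray(alleles, dtype=np.int8),
    )


def hap_matrix(blocks, n_per_pop=2, pops=("Angus", "Jersey")):
    n = n_per_pop
    samples = [f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)]
    populations = np.array([pops[0]] * n + [pops[1]] * n, dtype=object)
    return HaplotypeMatrix(blocks=blocks, samples=samples, populations=populations)


class TestEhh:
    def test_identical_haplotypes_stay_at_one(self):
        block = block_from([100, 200, 300, 400], np.tile([[1], [0], [1], [0]], (1, 4)))
        curve = ehh(block, [0, 1, 2, 3], core_index=0, direction="downstream")
        assert curve.values.tolist() == [1.0, 1.0, 1.0, 1.0]

    def test_all_distinct_at_first_flank_drops_to_zero(self):
        block = block_from([100, 200, 300], [[0, 0, 0, 0], [0, 1, 0, 1], [0, 0, 1, 1]])
        # four haplotypes over sites 2..3: 00,10,01,11 — all distinct at site 3
        curve = ehh(block, [0, 1, 2, 3], core_index=0, direction="downstream")
        assert curve.values[0] == 1.0
        assert curve.values[-1] == 0.0

    def test_hand_enumerated_group_refinement(self):
        """Four haplotypes split (2,2) then fully: EHH = [1, 2/6, 0]."""
        block = block_from(
            [100, 200, 300],
            [
                [0, 0, 0, 0],  # core site (pooled, does not split)
                [0, 0, 1, 1],  # groups of sizes (2, 2) -> (1+1)/C(4,2)
                [0, 1, 0, 1],  # all four distinct
            ],
        )
        curve = ehh(block, [0, 1, 2, 3], core_index=0, direction="downstream")
        assert curve.distances.tolist() == [0.0, 100.0, 200.0]
        assert curve.values == pytest.approx([1.0, 2.0 / 6.0, 0.0], abs=1e-12)

    def test_core_at_chromosome_edge_gives_length_one_curve(self):
        block = block_from([100, 200], [[0, 1, 0, 1], [0, 0, 1, 1]])
        curve = ehh(block, [0, 1, 2, 3], core_index=0, direction="upstream")
        assert curve.distances.tolist() == [0.0]
        assert curve.values.tolist() == [1.0]

    def test_monotone_nonincreasing_on_simulated_haplotypes(self):
        for seed in range(5):
            cfg = SimConfig(
                n_chromosomes=1,
                snps_per_chromosome=40,
                n_fixed_difference_loci=0,
                n_breed_exclusive_het_loci=0,
                seed=seed,
            )
            sim = simulate(cfg)
            block = sim.haplotypes.blocks["1"]
            cols = sim.haplotypes.hap_columns("Angus")
            for core in (0, 20, 39):
                for direction in ("upstream", "downstream"):
                    curve = ehh(block, cols, core, direction)
                    assert (np.diff(curve.values) <= 1e-12).all()


class TestIhh:
    def test_flat_curve_integrates_to_rectangle(self):
        curve = EhhCurve(0, "downstream", np.array([0.0, 500.0, 1000.0]), np.array([1.0, 1.0, 1.0]))
        result = ihh([curve], truncation_ehh=0.05)
        assert result.area == pytest.approx(1000.0)
        assert result.edge_warning  # never dropped below truncation

    def test_truncates_after_first_subthreshold_point(self):
        curve = EhhCurve(
            0, "downstream", np.array([0.0, 100.0, 200.0, 300.0]), np.array([1.0, 0.5, 0.04, 0.5])
        )
        result = ihh([curve], truncation_ehh=0.05)
        # 0.5·(1+0.5)·100 + 0.5·(0.5+0.04)·100; the rebound is never reached
        assert result.area == pytest.approx(102.0)
        assert not result.edge_warning

    def test_length_one_curve_has_zero_area(self):
        curve = EhhCurve(0, "upstream", np.array([0.0]), np.array([1.0]))
        assert ihh([curve]).area == 0.0

    def test_scale_covariance(self):
        rng = np.random.default_rng(4)
        values = np.sort(rng.random(6))[::-1]
        d = np.cumsum(rng.integers(50, 500, size=6)).astype(float)
        d[0] = 0.0
        base = ihh([EhhCurve(0, "downstream", d, values)]).area
        scaled = ihh([EhhCurve(0, "downstream", d * 7.0, values)]).area
        assert scaled == pytest.approx(7.0 * base, rel=1e-12)

    def test_invalid_truncation_rejected(self):
        curve = EhhCurve(0, "downstream", np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError):
            ihh([curve], truncation_ehh=1.5)


@pytest.fixture(scope="module")
def sweep_sim():
    cfg = SimConfig(
        n_chromosomes=2,
        snps_per_chromosome=150,
        spacing_bp=2_000,
        n_fixed_difference_loci=0,
        n_breed_exclusive_het_loci=0,
        sweep=SweepSpec(chrom="2", core_bp=150_000, carrier_fraction=0.9, length_bp=100_000),
        seed=77,
    )
    return simulate(cfg)


class TestXpehhScan:
    def test_identical_populations_have_zero_raw_scores(self):
        rng = np.random.default_rng(0)
        alleles_one_pop = rng.integers(0, 2, size=(30, 4)).astype(np.int8)
        block = block_from(
            np.cumsum(rng.integers(500, 1500, size=30)),
            np.hstack([alleles_one_pop, alleles_one_pop]),
        )
        result = xpehh_scan(hap_matrix({"1": block}), "Angus", "Jersey")
        assert result.table["raw"].abs().max() == pytest.approx(0.0, abs=1e-12)
        assert (result.table["z"] == 0.0).all()  # degenerate distribution guard

    def test_raw_antisymmetric_under_population_swap(self, sweep_sim):
        ab = xpehh_scan(sweep_sim.haplotypes, "Angus", "Jersey")
        ba = xpehh_scan(sweep_sim.haplotypes, "Jersey", "Angus")
        assert np.allclose(ab.table["raw"].to_numpy(), -ba.table["raw"].to_numpy(), atol=1e-12)
        assert np.allclose(ab.table["z"].to_numpy(), -ba.table["z"].to_numpy(), atol=1e-9)

    def test_z_normalization_moments(self, sweep_sim):
        z = xpehh_scan(sweep_sim.haplotypes, "Angus", "Jersey").table["z"].to_numpy()
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.var() == pytest.approx(1.0, abs=1e-9)

    def test_sweep_region_contains_max_z(self, sweep_sim):
        result = xpehh_scan(sweep_sim.haplotypes, "Angus", "Jersey")
        core_row = sweep_sim.truth[sweep_sim.truth.role == "sweep_core"].iloc[0]
        best = result.table.iloc[int(np.argmax(result.table["z"].to_numpy()))]
        assert best.chrom == "2"
        assert core_row.segment_start <= best.pos <= core_row.segment_end
        assert best.z > 0

    def test_too_few_retained_sites_errors(self):
        rng = np.random.default_rng(1)
        block = block_from([100, 200], rng.integers(0, 2, size=(2, 8)).astype(np.int8))
        with pytest.raises(ValueError, match="normalize"):
            xpehh_scan(hap_matrix({"1": block}), "Angus", "Jersey", min_ihh=1e12)


class TestSelectExtremes:
    def make_result(self, z):
        n = len(z)
        table = pd.DataFrame(
            {
                "chrom": ["1"] * n,
                "pos": np.arange(1, n + 1) * 100,
                "ihh_a": np.ones(n),
                "ihh_b": np.ones(n),
                "raw": z,
                "z": z,
            }
        )
        from cmiscan.xpehh import XpehhResult

        return XpehhResult(table=table, pop_a="Angus", pop_b="Jersey", n_dropped=0, edge_warnings=0)

    def test_one_percent_of_thousand_is_ten_per_tail(self):
        rng = np.random.default_rng(2)
        result = self.make_result(rng.normal(size=1000))
        top, bottom = select_extremes(result, quantile=0.01)
        assert (len(top), len(bottom)) == (10, 10)
        assert top["z"].min() > bottom["z"].max()

    def test_degenerate_all_equal_scores_give_empty_tails(self):
        result = self.make_result(np.zeros(1000))
        top, bottom = select_extremes(result, quantile=0.01)
        assert top.empty and bottom.empty

    def test_quantile_out_of_range_rejected(self):
        result = self.make_result(np.arange(100, dtype=float))
        with pytest.raises(ValueError):
            select_extremes(result, quantile=0.7)


class TestOverlapSets:
    def test_pairwise_intersection(self):
        report = overlap_sets(["A", "B", "C"], ["B", "C", "D"], ["X"])
        assert report.pairwise["cmi_xpehh_a"] == {"B", "C"}
        assert report.counts()["cmi_xpehh_a"] == 2

    def test_rna_genes_excluded_before_counting(self):
        report = overlap_sets(
            ["FASN", "5S_rRNA", "U6", "7SK"], ["FASN", "5S_rRNA"], []
        )
        assert report.pairwise["cmi_xpehh_a"] == {"FASN"}
        assert report.n_excluded_rna >= 3

    def test_empty_inputs_give_empty_intersections(self):
        report = overlap_sets([], ["A"], ["B"])
        assert report.pairwise["cmi_xpehh_a"] == set()
        assert report.pairwise["cmi_xpehh_b"] == set()

    def test_three_way_with_xpclr_lists(self):
        report = overlap_sets(
            ["A", "B", "C"], ["A", "B"], ["C"], xpclr_genes_a=["B", "Z"], xpclr_genes_b=["C"]
        )
        assert report.three_way_a == {"B"}
        assert report.three_way_b == {"C"}
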