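"""Generator checks: map structure, meiosis genetics, mating design, phenotypes."""

import numpy as np
import pandas as pd
import pytest

from hybridqtl import (
    FounderDivergence,
    MapSpec,
    QTLSpec,
    SimConfig,
    VarianceSpec,
    simulate_design,
    simulate_factorial,
    simulate_founders,
    simulate_map,
)
from hybridqtl._util import POP_PAIRS, haldane_r, ssd_effective_r
from hybridqtl.simdata import simulate_biparental_lines


class TestMap:
    @pytest.mark.parametrize(
        "n_chrom,length,n_markers,check",
        [
            (1, 100.0, 2, lambda t: list(t["pos_cM"]) == [0.0, 100.0]),
            (10, 160.0, 100, lambda t: len(t) == 1000),
            (1, 50.0, 11, lambda t: np.allclose(np.diff(t["pos_cM"]), 5.0)),
        ],
    )
    def test_regular_grids(self, n_chrom, length, n_markers, check):
        gmap = simulate_map(MapSpec(n_chrom, length, n_markers, "regular"), seed=1)
        assert check(gmap.table)

    def test_rejects_degenerate_specs(self):
        with pytest.raises(ValueError):
            simulate_map(MapSpec(1, -5.0, 10), seed=0)
        with pytest.raises(ValueError):
            simulate_map(MapSpec(1, 100.0, 1), seed=0)

    def test_uniform_spacing_sorted_and_deterministic(self):
        spec = MapSpec(3, 80.0, 40, "uniform")
        a = simulate_map(spec, seed=5)
        b = simulate_map(spec, seed=5)
        assert a.table.equals(b.table)
        for _, grp in a.table.groupby("chrom"):
            assert (np.diff(grp["pos_cM"]) >= 0).all()


class TestFounders:
    def _founders(self, p_poly, n_markers=2000, seed=2):
        cfg = SimConfig(
            map_spec=MapSpec(1, 100.0, n_markers),
            founder_divergence=FounderDivergence(p_polymorphic=p_poly),
        )
        gmap = simulate_map(cfg.map_spec, seed)
        return simulate_founders(gmap, cfg, seed)

    def test_degenerate_divergence(self):
        full = self._founders(1.0, n_markers=500)
        for g in ("D", "F"):
            a = full.alleles[full.group_rows(g)]
            assert (a.min(axis=0) != a.max(axis=0)).all()
        none = self._founders(0.0, n_markers=500)
        for g in ("D", "F"):
            a = none.alleles[none.group_rows(g)]
            assert (a.min(axis=0) == a.max(axis=0)).all()

    def test_polymorphism_rate_matches_config(self):
        p = 0.6
        n = 10_000
        f = self._founders(p, n_markers=n)
        frac = np.mean(
            [
                (f.alleles[f.group_rows(g)].min(axis=0) != f.alleles[f.group_rows(g)].max(axis=0))
                for g in ("D", "F")
            ]
        )
        se = np.sqrt(p * (1 - p) / (2 * n))
        assert abs(frac - p) < 3 * se

    def test_founders_homozygous(self):
        f = self._founders(0.5, 300)
        assert set(np.unique(f.alleles)) <= {0.0, 1.0}


class TestMeiosis:
    def test_dh_lines_have_no_heterozygotes(self, small_design):
        dent = small_design.lines.dosage[small_design.lines.group_mask("D")]
        assert not np.any(dent == 0.5)

    def test_dh_dosage_equals_transmitting_founder(self, small_design):
        d = small_design
        orig = d.truth.line_hap_origins["D"]
        info = d.truth.line_info["D"]
        for pop in range(2):
            rows = np.flatnonzero((info["population"] == pop).to_numpy())[:5]
            a0, a1 = d.founders.pair_alleles("D", pop)
            informative = a0 != a1
            dos = d.lines.dosage[rows][:, informative]
            expect = np.where(orig[rows, 0][:, informative] == 0, a0[informative], a1[informative])
            assert np.array_equal(dos, expect)

    def test_zero_distance_origins_identical(self, two_marker_map):
        gmap = two_marker_map(0.0)
        cfg = SimConfig(map_spec=MapSpec(1, 1.0, 2), founder_divergence=FounderDivergence(1.0))
        fnd = simulate_founders(simulate_map(cfg.map_spec, 1), cfg, 1)
        _, o = simulate_biparental_lines(fnd, "D", 0, 2000, "DH", gmap, 3)
        assert np.array_equal(o[:, 0, 0], o[:, 0, 1])

    def test_dh_recombination_matches_haldane(self, two_marker_map):
        gmap = two_marker_map(50.0)
        cfg = SimConfig(map_spec=MapSpec(1, 50.0, 2))
        fnd = simulate_founders(simulate_map(cfg.map_spec, 1), cfg, 1)
        n = 10_000
        _, o = simulate_biparental_lines(fnd, "D", 0, n, "DH", gmap, 7)
        rec = np.mean(o[:, 0, 0] != o[:, 0, 1])
        expected = haldane_r(50.0)  # (1 - e^-1)/2 ~ 0.316
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rec - expected) < 3 * se

    def test_ssd_recombination_matches_inflated_rate(self, two_marker_map):
        # after 5 generations of selfing the per-haplotype recombinant
        # fraction is close to the infinite-selfing limit r* = 2r/(1+2r)
        gmap = two_marker_map(20.0)
        cfg = SimConfig(map_spec=MapSpec(1, 20.0, 2))
        fnd = simulate_founders(simulate_map(cfg.map_spec, 1), cfg, 1)
        n = 20_000
        _, o = simulate_biparental_lines(fnd, "F", 0, n, "SSD", gmap, 7, n_selfing_generations=5)
        rec = np.mean(o[:, 0, 0] != o[:, 0, 1])
        expected = ssd_effective_r(haldane_r(20.0))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(rec - expected) < 4 * se

    def test_ssd_residual_heterozygosity_near_half_power(self, small_design):
        # ~ (1/2)^g at loci where the founders differ
        d = small_design
        orig = d.truth.line_hap_origins["F"]
        het = np.mean(orig[:, 0, :] != orig[:, 1, :])
        assert 0.5 * 0.5**5 < het < 2.5 * 0.5**5


class TestFactorial:
    def _lines(self, n_per_pop, group):
        return pd.DataFrame(
            {
                "line_id": [f"{group}{p}_{i}" for p in range(6) for i in range(n_per_pop)],
                "group": group,
                "population": np.repeat(np.arange(6), n_per_pop),
            }
        )

    def test_all_once_gives_min_count(self):
        ped = simulate_factorial(self._lines(30, "D"), self._lines(40, "F"), {1: 1.0}, 1)
        assert ped.n_hybrids == 6 * 30

    def test_all_combinations_covered(self):
        ped = simulate_factorial(self._lines(30, "D"), self._lines(30, "F"), {1: 1.0}, 2)
        combos = ped.table.groupby(["dent_pop", "flint_pop"]).size()
        assert len(combos) == 36

    def test_no_duplicate_parent_pairs(self):
        ped = simulate_factorial(
            self._lines(50, "D"), self._lines(50, "F"), {1: 0.6, 2: 0.3, 3: 0.1}, 3
        )
        assert not ped.table.duplicated(["dent_parent", "flint_parent"]).any()

    def test_mean_hybrids_per_line_matches_distribution(self):
        lines_D = self._lines(167, "D")  # 1002 lines
        # oversupply Flint slots so every Dent slot is used
        ped = simulate_factorial(lines_D, self._lines(400, "F"), {1: 0.8, 2: 0.2}, 4)
        mean = ped.n_hybrids / len(lines_D)
        se = np.sqrt(0.2 * 0.8 / len(lines_D))
        assert abs(mean - 1.2) < 3 * se + 0.01  # small slack for dropped duplicates

    def test_infeasible_demand_rejected(self):
        with pytest.raises(ValueError, match="parent pairs"):
            simulate_factorial(
                self._lines(1, "D").iloc[:2], self._lines(1, "F").iloc[:2], {4: 1.0}, 5
            )


class TestPhenotypes:
    def test_no_variance_no_qtl_gives_population_means(self):
        cfg = SimConfig(
            n_lines_per_population=5,
            map_spec=MapSpec(1, 50.0, 10),
            variance=VarianceSpec(0.0, 0.0, 0.0, 0.0),
            n_environments=3,
            seed=9,
        )
        cfg.population_means.mu = 10.0
        cfg.population_means.dent = np.arange(6.0)
        d = simulate_design(cfg)
        merged = d.plots.merge(
            d.pedigree.table[["hybrid_id", "dent_pop"]], left_on="hybrid", right_on="hybrid_id"
        )
        assert np.allclose(merged["value"], 10.0 + merged["dent_pop"].astype(float))

    def test_additive_qtl_minor_allele_contrast_is_2a(self):
        a = 1.5
        cfg = SimConfig(
            n_lines_per_population=40,
            map_spec=MapSpec(1, 60.0, 7),
            founder_divergence=FounderDivergence(1.0, 0.5),
            variance=VarianceSpec(0.0, 0.0, 0.0, 0.0),
            n_environments=1,
            seed=21,
        )
        gmap = simulate_map(cfg.map_spec, cfg.seed)
        fnd = simulate_founders(gmap, cfg, cfg.seed)
        m = 3  # QTL marker index
        gca_d = a * fnd.alleles[fnd.group_rows("D"), m]
        gca_f = a * fnd.alleles[fnd.group_rows("F"), m]
        cfg.qtl_spec = [QTLSpec(1, gmap.pos_cM[m], gca_d, gca_f, np.zeros((4, 4)))]
        d = simulate_design(cfg)
        pair = np.asarray(POP_PAIRS)
        fD = pair[d.pedigree.table["dent_pop"].to_numpy(), d.truth.transmitted["D"][:, m]]
        fF = pair[d.pedigree.table["flint_pop"].to_numpy(), d.truth.transmitted["F"][:, m]]
        dose = fnd.alleles[fnd.group_rows("D"), m][fD] + fnd.alleles[fnd.group_rows("F"), m][fF]
        g = d.truth.genetic_values
        hom_minor = g[dose == 2]
        hom_major = g[dose == 0]
        assert len(hom_minor) and len(hom_major)
        assert np.isclose(hom_minor.mean() - hom_major.mean(), 2 * a)

    def test_residual_variance_recovered(self):
        cfg = SimConfig(
            n_lines_per_population=900,
            map_spec=MapSpec(1, 50.0, 5),
            variance=VarianceSpec(0.0, 0.0, 2.5, 0.0),
            n_environments=1,
            hybrids_per_line_distribution={1: 0.8, 2: 0.2},
            seed=31,
        )
        d = simulate_design(cfg)
        assert d.pedigree.n_hybrids >= 5000
        v = d.truth.realized_variance["sigma2_e"]
        assert abs(v - 2.5) / 2.5 < 0.05

    def test_parental_variance_components_realized(self):
        cfg = SimConfig(
            n_lines_per_population=850,
            map_spec=MapSpec(1, 50.0, 5),
            variance=VarianceSpec(1.5, 0.8, 0.5, 0.0),
            n_environments=1,
            seed=33,
        )
        d = simulate_design(cfg)
        assert d.pedigree.n_hybrids >= 5000
        assert abs(np.var(d.truth.components["u_D"]) - 1.5) / 1.5 < 0.1
        assert abs(np.var(d.truth.components["u_F"]) - 0.8) / 0.8 < 0.1

    def test_truth_invariant_genetic_value_decomposition(self, small_design):
        c = small_design.truth.components
        recomputed = c["population"] + c["qtl"] + c["u_D"] + c["u_F"]
        assert np.allclose(recomputed, small_design.truth.genetic_values)

    def test_determinism(self):
        cfg = SimConfig(n_lines_per_population=10, map_spec=MapSpec(1, 40.0, 8), seed=77)
        d1 = simulate_design(cfg)
        d2 = simulate_design(cfg)
        assert np.array_equal(d1.lines.dosage, d2.lines.dosage, equal_nan=True)
        assert d1.plots.equals(d2.plots)
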