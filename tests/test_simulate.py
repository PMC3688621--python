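"""Generator tests: maps, RIL mosaics, architectures, plot phenotypes."""

import numpy as np
import pandas as pd
import pytest

from namqg.simulate import (GeneticMap, PlotTable, TraitArchitecture,
                            TraitSpec, _spatial_field, assign_architecture,
                            haldane_r, qtl_line_values,
                            ril_recombination_fraction, simulate_map,
                            simulate_plots, simulate_rils)


def _two_marker_map(d_cM: float) -> GeneticMap:
    return GeneticMap(pd.DataFrame({
        "marker": ["a", "b"], "chrom": [1, 1],
        "cM": [0.0, d_cM], "bp": [0, int(d_cM * 1e6) + 1]}))


class TestSimulateMap:
    def test_minimal_and_nam_scale(self):
        m = simulate_map(1, 2, 100.0, 1e8, seed=1)
        assert m.n_markers == 2
        assert (m.df["cM"] >= 0).all() and (m.df["cM"] <= 100).all()
        nam = simulate_map(10, 1106, 150.0, 2.3e8, seed=7)
        assert nam.n_markers == 1106
        assert len(nam.chromosomes()) == 10

    def test_positions_sorted_within_chromosome(self):
        m = simulate_map(4, 80, 90.0, 1e8, seed=3)
        for c in m.chromosomes():
            sub = m.chrom_slice(c)
            assert (np.diff(sub["cM"]) >= 0).all()
            assert (np.diff(sub["bp"]) >= 0).all()

    def test_deterministic_under_seed(self):
        a = simulate_map(3, 30, 100.0, 1e8, seed=5)
        b = simulate_map(3, 30, 100.0, 1e8, seed=5)
        pd.testing.assert_frame_equal(a.df, b.df)

    @pytest.mark.parametrize("cm,bp", [(-1.0, 1e8), (100.0, 0.0)])
    def test_rejects_nonpositive_lengths(self, cm, bp):
        with pytest.raises(ValueError):
            simulate_map(1, 5, cm, bp, seed=1)

    def test_map_invariants_enforced(self):
        with pytest.raises(ValueError, match="duplicate"):
            GeneticMap(pd.DataFrame({"marker": ["x", "x"], "chrom": [1, 1],
                                     "cM": [0.0, 1.0], "bp": [0, 10]}))
        with pytest.raises(ValueError, match="decrease"):
            GeneticMap(pd.DataFrame({"marker": ["x", "y"], "chrom": [1, 1],
                                     "cM": [2.0, 1.0], "bp": [0, 10]}))


class TestSimulateRils:
    def test_complete_linkage_identical_dosages(self):
        pop = simulate_rils(_two_marker_map(0.0), 2, 100, seed=4)
        G = pop.geno.to_numpy()
        assert np.array_equal(G[:, 0], G[:, 1])

    def test_unlinked_markers_uncorrelated(self):
        pop = simulate_rils(_two_marker_map(1000.0), 1, 500, seed=4)
        G = pop.geno.to_numpy()
        assert abs(np.corrcoef(G[:, 0], G[:, 1])[0, 1]) < 0.1

    def test_ril_recombinant_fraction_matches_closed_form(self):
        # Haldane r = 0.1 at d = -50 ln(0.8) cM; RIL fraction 2r/(1+2r)
        d = -50.0 * np.log(0.8)
        assert haldane_r(d) == pytest.approx(0.1, abs=1e-12)
        expect = 2 * 0.1 / 1.2
        pop = simulate_rils(_two_marker_map(d), 1, 2000, seed=8)
        G = pop.geno.to_numpy()
        obs = np.mean(G[:, 0] != G[:, 1])
        se = np.sqrt(expect * (1 - expect) / 2000)
        assert obs == pytest.approx(expect, abs=4 * se)

    def test_dosage_expectation_half(self, small_panel):
        means = small_panel.geno.groupby(small_panel.family).mean()
        # binomial se per family-marker is ~0.09 at n=30; check the grand mean
        assert small_panel.geno.to_numpy().mean() == pytest.approx(0.5,
                                                                   abs=0.02)
        assert means.to_numpy().min() >= 0.0
        assert means.to_numpy().max() <= 1.0

    def test_intermating_expands_map(self):
        d = 10.0
        tight = simulate_rils(_two_marker_map(d), 1, 3000, seed=9)
        ibm = simulate_rils(_two_marker_map(d), 1, 3000, seed=9,
                            intermating_expansion={"F01": 2.0})
        frac = lambda p: np.mean(p.geno.iloc[:, 0] != p.geno.iloc[:, 1])
        assert frac(ibm) > frac(tight)
        assert float(ril_recombination_fraction(d, 2.0)) > \
            float(ril_recombination_fraction(d, 1.0))

    def test_snp_mosaic_consistent_with_founders(self, snp_panel):
        pop = snp_panel
        # every SNP dosage equals the allele of the origin founder
        for fam in pop.families[:2]:
            rows = pop.family_of(fam)
            a0 = pop.founder_snps.loc["CP"].to_numpy()
            a1 = pop.founder_snps.loc[f"AP_{fam}"].to_numpy()
            o = pop.snp_origin.loc[rows].to_numpy()
            expect = np.where(o == 1, a1, a0)
            assert np.array_equal(pop.snp.loc[rows].to_numpy(), expect)

    def test_empty_map_rejected(self):
        empty = GeneticMap(pd.DataFrame(columns=["marker", "chrom", "cM",
                                                 "bp"]))
        with pytest.raises(ValueError):
            simulate_rils(empty, 1, 5, seed=1)


class TestArchitecture:
    def test_no_qtl_gives_pure_nongenetic_trait(self, small_panel):
        arch = assign_architecture(small_panel, 0, 0.2, 0.1, seed=1)
        spec = arch.traits["trait"]
        assert spec.qtl == {}
        g = qtl_line_values(small_panel, spec.qtl)
        assert np.allclose(g, 0.0)

    def test_zero_series_sd_identical_effects(self, small_panel):
        arch = assign_architecture(small_panel, 5, 0.3, 0.0, seed=2)
        for effects in arch.traits["trait"].qtl.values():
            vals = list(effects.values())
            assert np.ptp(vals) == pytest.approx(0.0, abs=1e-12)

    def test_variance_target_scaling_is_exact(self, small_panel):
        arch = assign_architecture(small_panel, 8, 0.2, 0.15, seed=3,
                                   qtl_variance_target=0.5)
        g = qtl_line_values(small_panel, arch.traits["trait"].qtl)
        within = g.groupby(small_panel.family).var(ddof=1).mean()
        assert within == pytest.approx(0.5, rel=1e-9)

    def test_invalid_architecture_rejected(self):
        with pytest.raises(ValueError):
            TraitSpec(family=-0.1).validate()
        with pytest.raises(ValueError):
            TraitSpec(rho_row=1.0).validate()
        with pytest.raises(ValueError):
            TraitArchitecture(traits={"t": TraitSpec()},
                              genetic_corr=pd.DataFrame(
                                  [[1.0, 2.0], [2.0, 1.0]],
                                  index=["a", "b"], columns=["a", "b"]))


class TestSimulatePlots:
    def test_all_zero_variance_gives_grand_mean(self, small_panel):
        spec = TraitSpec(family=0, ril=0, env=0, fam_env=0, ril_env=0,
                         plant=0, mean=7.5)
        plots = simulate_plots(small_panel, TraitArchitecture(
            traits={"t": spec}), 2, (15, 12), 1, seed=5)
        assert np.allclose(plots.df["value"], 7.5)

    def test_record_count_and_grid(self, small_panel):
        spec = TraitSpec(plant=1.0)
        plots = simulate_plots(small_panel, TraitArchitecture(
            traits={"a": spec, "b": TraitSpec(plant=1.0)}),
            3, (15, 12), 2, seed=6)
        n_lines = len(small_panel.lines)
        assert len(plots.df) == n_lines * 3 * 2
        cells = plots.df[["env", "trait", "row", "col"]]
        assert not cells.duplicated().any()

    def test_spatial_autocorrelation_matches_ar1(self):
        rng = np.random.default_rng(10)
        field = _spatial_field(rng, 50, 50, 1.0, 0.6, 0.6)
        lag = np.corrcoef(field[:-1].ravel(), field[1:].ravel())[0, 1]
        assert lag == pytest.approx(0.6, abs=0.05)

    def test_plant_noise_scales_with_plants_per_plot(self, small_panel):
        spec = TraitSpec(plant=4.0)
        arch = TraitArchitecture(traits={"t": spec})
        v1 = simulate_plots(small_panel, arch, 1, (15, 12), 1,
                            seed=7).df["value"].var()
        v4 = simulate_plots(small_panel, arch, 1, (15, 12), 4,
                            seed=7).df["value"].var()
        assert v4 == pytest.approx(v1 / 4, rel=0.2)

    def test_trait_correlation_recovered(self):
        gmap = simulate_map(3, 20, 100.0, 1e8, seed=41)
        pop = simulate_rils(gmap, 10, 200, seed=42)
        corr = pd.DataFrame([[1.0, 0.6], [0.6, 1.0]],
                            index=["A", "B"], columns=["A", "B"])
        arch = TraitArchitecture(
            traits={"A": TraitSpec(ril=1.0, plant=0.5),
                    "B": TraitSpec(ril=1.0, plant=0.5)},
            genetic_corr=corr)
        plots = simulate_plots(pop, arch, 1, (50, 40), 1, seed=43)
        gA = plots.truth["genetic"]["A"]
        gB = plots.truth["genetic"]["B"]
        assert np.corrcoef(gA, gB)[0, 1] == pytest.approx(0.6, abs=0.05)

    def test_deterministic_under_seed(self, small_panel):
        spec = TraitSpec(family=0.3, ril=0.5, plant=1.0)
        arch = TraitArchitecture(traits={"t": spec})
        a = simulate_plots(small_panel, arch, 2, (15, 12), 1, seed=13)
        b = simulate_plots(small_panel, arch, 2, (15, 12), 1, seed=13)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_grid_too_small_rejected(self, small_panel):
        with pytest.raises(ValueError, match="grid"):
            simulate_plots(small_panel, TraitArchitecture(
                traits={"t": TraitSpec()}), 1, (3, 3), 1, seed=1)

    def test_plot_table_rejects_duplicate_cells(self):
        df = pd.DataFrame({
            "line": ["a", "b"], "family": ["F", "F"], "env": ["e", "e"],
            "row": [0, 0], "col": [0, 0], "block": [0, 0],
            "trait": ["t", "t"], "value": [1.0, 2.0], "n_plants": [1, 1]})
        with pytest.raises(ValueError, match="duplicate"):
            PlotTable(df=df)
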