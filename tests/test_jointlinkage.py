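"""Family-nested stepwise mapping, RMIP and related tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from namqg.jointlinkage import (bootstrap_rmip, partition_variance,
                                permutation_threshold, pleiotropy_test,
                                stepwise_select, _stratified_resample)
from namqg.simulate import simulate_map, simulate_rils


def _panel(seed, n_fam=6, nf=40, n_markers=60, n_chrom=3):
    gmap = simulate_map(n_chrom, n_markers, 120.0, 1.5e8, seed=seed)
    pop = simulate_rils(gmap, n_fam, nf, seed=seed + 1)
    return gmap, pop


def _exhaustive_best(y, geno, families):
    """Brute-force single-term search: smallest family-nested marginal p."""
    famc = pd.Categorical(families).codes
    Xfam = np.eye(famc.max() + 1)[famc]
    yv = y.to_numpy(float)
    b0, *_ = np.linalg.lstsq(Xfam, yv, rcond=None)
    rss0 = float(((yv - Xfam @ b0) ** 2).sum())
    best = None
    for mk in geno.columns:
        x = geno[mk].to_numpy(float)
        seg = [f for f in range(famc.max() + 1)
               if x[famc == f].var() > 1e-9]
        if not seg:
            continue
        B = np.zeros((len(yv), len(seg)))
        for k, f in enumerate(seg):
            B[famc == f, k] = x[famc == f]
        X = np.hstack([Xfam, B])
        b, *_ = np.linalg.lstsq(X, yv, rcond=None)
        rss = float(((yv - X @ b) ** 2).sum())
        k, df2 = len(seg), len(yv) - X.shape[1]
        F = ((rss0 - rss) / k) / (rss / df2)
        p = stats.f.sf(F, k, df2)
        if best is None or p < best[1]:
            best = (mk, p)
    return best


class TestStepwise:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_first_step_equals_exhaustive_search(self, seed):
        gmap, pop = _panel(100 + seed, n_markers=50)
        rng = np.random.default_rng(seed)
        eff = {f: rng.normal(0.3, 0.15) for f in pop.families}
        y = pd.Series(pop.geno.iloc[:, 17] * pop.family.map(eff)
                      + rng.normal(0, 1, len(pop.lines)), index=pop.lines)
        model = stepwise_select(y, pop.geno, pop.family, p_entry=0.999999,
                                p_exit=1.0, max_terms=1, gmap=gmap)
        best_mk, _ = _exhaustive_best(y, pop.geno, pop.family)
        assert model.markers == [best_mk]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_large_qtl_found_first(self, seed):
        gmap, pop = _panel(200 + seed, n_fam=8, nf=50, n_markers=80)
        rng = np.random.default_rng(seed)
        eff = {f: rng.normal(0.8, 0.2) for f in pop.families}
        true_mk = pop.geno.columns[33]
        y = pd.Series(pop.geno[true_mk] * pop.family.map(eff)
                      + rng.normal(0, 1, len(pop.lines)), index=pop.lines)
        model = stepwise_select(y, pop.geno, pop.family, p_entry=5e-4,
                                gmap=gmap)
        assert model.terms
        mdf = gmap.df.set_index("marker")
        first = model.terms[0]
        assert first.chrom == int(mdf.loc[true_mk, "chrom"])
        assert abs(first.cM - float(mdf.loc[true_mk, "cM"])) <= 3.0

    def test_null_selects_almost_nothing(self):
        gmap, pop = _panel(300, n_fam=6, nf=50, n_markers=100)
        n_terms = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = pd.Series(rng.normal(0, 1, len(pop.lines)), index=pop.lines)
            m = stepwise_select(y, pop.geno, pop.family, p_entry=5e-4,
                                gmap=gmap)
            n_terms.append(len(m.terms))
        assert max(n_terms) <= 1

    def test_effects_absent_for_nonsegregating_family(self):
        gmap, pop = _panel(400)
        geno = pop.geno.copy()
        mono_fam = pop.families[0]
        rows = pop.family_of(mono_fam)
        geno.loc[rows, :] = 0.0  # F01 carries the common parent everywhere
        rng = np.random.default_rng(2)
        eff = {f: 0.9 for f in pop.families}
        mk = geno.columns[10]
        y = pd.Series(geno[mk] * pop.family.map(eff)
                      + rng.normal(0, 1, len(pop.lines)), index=pop.lines)
        model = stepwise_select(y, geno, pop.family, p_entry=5e-4, gmap=gmap)
        assert model.terms
        for term in model.terms:
            assert mono_fam not in term.effects

    def test_unit_weights_match_unweighted(self):
        gmap, pop = _panel(500)
        rng = np.random.default_rng(3)
        y = pd.Series(pop.geno.iloc[:, 5] * 0.8
                      + rng.normal(0, 1, len(pop.lines)), index=pop.lines)
        w = pd.Series(1.0, index=pop.lines)
        a = stepwise_select(y, pop.geno, pop.family, p_entry=0.01, gmap=gmap)
        b = stepwise_select(y, pop.geno, pop.family, p_entry=0.01, gmap=gmap,
                            weights=w)
        assert a.markers == b.markers
        assert a.rss == pytest.approx(b.rss, rel=1e-10)

    def test_invalid_thresholds_rejected(self):
        gmap, pop = _panel(600)
        y = pd.Series(np.zeros(len(pop.lines)), index=pop.lines)
        with pytest.raises(ValueError):
            stepwise_select(y, pop.geno, pop.family, p_entry=0.01,
                            p_exit=0.001)


class TestBootstrapRmip:
    def test_resample_preserves_family_sizes(self):
        rng = np.random.default_rng(0)
        fam_codes = np.repeat(np.arange(4), [10, 20, 8, 12])
        take = _stratified_resample(rng, fam_codes)
        sizes = pd.Series(fam_codes[take]).value_counts().sort_index()
        assert sizes.tolist() == [10, 20, 8, 12]
        # ~75% of each family's draw is unique lines
        fam0 = take[fam_codes[take] == 1]
        assert len(np.unique(fam0)) >= 15

    def test_small_family_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="fewer than 4"):
            _stratified_resample(rng, np.array([0, 0, 0, 1, 1, 1, 1]))

    def test_single_resample_counts_are_indicators(self):
        gmap, pop = _panel(700)
        rng = np.random.default_rng(4)
        y = pd.Series(pop.geno.iloc[:, 7] * 1.0
                      + rng.normal(0, 0.8, len(pop.lines)), index=pop.lines)
        tab = bootstrap_rmip(y, pop.geno, pop.family, B=1, p_entry=5e-4,
                             gmap=gmap, seed=5)
        assert set(tab.counts.unique()) <= {0, 1}
        assert tab.counts.sum() >= 1

    def test_rmip_grows_with_effect_size(self):
        gmap, pop = _panel(800, n_fam=6, nf=40, n_markers=40)
        rng = np.random.default_rng(6)
        noise = rng.normal(0, 1, len(pop.lines))
        mk = pop.geno.columns[20]
        rmips = []
        for eff in (0.3, 1.2):
            y = pd.Series(pop.geno[mk] * eff + noise, index=pop.lines)
            tab = bootstrap_rmip(y, pop.geno, pop.family, B=20,
                                 p_entry=5e-4, gmap=gmap, seed=7)
            rmips.append(int(tab.collapsed[mk]))
        assert rmips[1] > rmips[0]
        assert rmips[1] >= 15

    def test_invariant_to_marker_and_line_order(self):
        gmap, pop = _panel(900, n_fam=5, nf=30, n_markers=30)
        rng = np.random.default_rng(8)
        y = pd.Series(pop.geno.iloc[:, 12] * 0.9
                      + rng.normal(0, 1, len(pop.lines)), index=pop.lines)
        tab1 = bootstrap_rmip(y, pop.geno, pop.family, B=10, p_entry=5e-4,
                              gmap=gmap, seed=9)
        rng2 = np.random.default_rng(10)
        col_perm = rng2.permutation(pop.geno.columns)
        row_perm = rng2.permutation(pop.geno.index)
        tab2 = bootstrap_rmip(y.loc[row_perm], pop.geno.loc[row_perm,
                                                            col_perm],
                              pop.family.loc[row_perm], B=10, p_entry=5e-4,
                              gmap=gmap, seed=9)
        pd.testing.assert_series_equal(tab1.counts.sort_index(),
                                       tab2.counts.sort_index())

    def test_collapse_window_counts_linked_markers_once(self):
        gmap, pop = _panel(1000, n_markers=40)
        rng = np.random.default_rng(11)
        y = pd.Series(pop.geno.iloc[:, 4] * 1.5
                      + rng.normal(0, 0.5, len(pop.lines)), index=pop.lines)
        tab = bootstrap_rmip(y, pop.geno, pop.family, B=10, p_entry=5e-4,
                             collapse_cM=3.0, gmap=gmap, seed=12)
        assert (tab.collapsed >= tab.counts).all()
        assert tab.collapsed.max() <= tab.B


class TestPermutationThreshold:
    def test_alpha_one_returns_one(self, small_panel):
        y = pd.Series(np.zeros(len(small_panel.lines)),
                      index=small_panel.lines)
        thr = permutation_threshold(y, small_panel.geno, small_panel.family,
                                    n_perm=100, target_alpha=1.0)
        assert thr == 1.0

    def test_threshold_less_stringent_with_fewer_markers(self):
        gmap, pop = _panel(1100, n_fam=6, nf=40, n_markers=100)
        rng = np.random.default_rng(13)
        y = pd.Series(rng.normal(0, 1, len(pop.lines)), index=pop.lines)
        thr_many = permutation_threshold(y, pop.geno, pop.family,
                                         n_perm=300, seed=14)
        thr_few = permutation_threshold(y, pop.geno.iloc[:, :5], pop.family,
                                        n_perm=300, seed=14)
        assert thr_few > thr_many

    def test_minimum_permutations_enforced(self, small_panel):
        y = pd.Series(np.zeros(len(small_panel.lines)),
                      index=small_panel.lines)
        with pytest.raises(ValueError):
            permutation_threshold(y, small_panel.geno, small_panel.family,
                                  n_perm=10)


class TestPleiotropyAndPartition:
    def _model_and_traits(self):
        gmap, pop = _panel(1200, n_fam=8, nf=50, n_markers=50)
        rng = np.random.default_rng(15)
        mks = [pop.geno.columns[i] for i in (10, 30)]
        # wide allele series and modest noise so per-family effect
        # estimates are precise enough for the correlation test
        eff = {mk: {f: rng.normal(0.5, 0.8) for f in pop.families}
               for mk in mks}
        gA = sum(pop.geno[mk] * pop.family.map(eff[mk]) for mk in mks)
        yA = pd.Series(gA + rng.normal(0, 0.4, len(pop.lines)),
                       index=pop.lines)
        # trait B shares the QTL with proportional effects
        gB = sum(pop.geno[mk] * pop.family.map(
            {f: 0.7 * e for f, e in eff[mk].items()}) for mk in mks)
        yB = pd.Series(gB + rng.normal(0, 0.4, len(pop.lines)),
                       index=pop.lines)
        model = stepwise_select(yA, pop.geno, pop.family, p_entry=5e-4,
                                gmap=gmap)
        return gmap, pop, model, yA, yB

    def test_self_correlation_is_one(self):
        _, pop, model, yA, _ = self._model_and_traits()
        res = pleiotropy_test(model, yA, pop.geno, pop.family)
        assert (res["correlation"].dropna() > 0.999).all()

    def test_shared_qtl_recovered(self):
        _, pop, model, _, yB = self._model_and_traits()
        res = pleiotropy_test(model, yB, pop.geno, pop.family)
        assert res["correlation"].dropna().max() > 0.9

    def test_independent_trait_uncorrelated(self):
        # mean |r| over several independent noise traits stays near the
        # null expectation for 8 families, well below a shared-QTL signal
        _, pop, model, _, _ = self._model_and_traits()
        rng = np.random.default_rng(16)
        rs = []
        for _ in range(8):
            yC = pd.Series(rng.normal(0, 1, len(pop.lines)),
                           index=pop.lines)
            res = pleiotropy_test(model, yC, pop.geno, pop.family)
            rs.extend(res["correlation"].abs().dropna().tolist())
        assert np.mean(rs) < 0.5

    def test_partition_identities(self):
        gmap, pop, model, yA, _ = (lambda t: (t[0], t[1], t[2], t[3],
                                              t[4]))(self._model_and_traits())
        part = partition_variance(model, yA, pop.geno, pop.family)
        assert 0 <= part["family_r2"] <= part["family_qtl_r2"] <= 1
        total_delta = sum(part["per_term_delta_r2"].values())
        assert part["family_qtl_r2"] - part["family_r2"] == \
            pytest.approx(total_delta, abs=1e-10)

    def test_partition_zero_qtl_model(self):
        gmap, pop = _panel(1300)
        rng = np.random.default_rng(17)
        y = pd.Series(rng.normal(0, 1, len(pop.lines)), index=pop.lines)
        model = stepwise_select(y, pop.geno, pop.family, p_entry=1e-12,
                                gmap=gmap)
        assert not model.terms
        part = partition_variance(model, y, pop.geno, pop.family)
        assert part["family_qtl_r2"] == pytest.approx(part["family_r2"])

    def test_between_family_share_recovered(self):
        gmap, pop = _panel(1400, n_fam=10, nf=60)
        rng = np.random.default_rng(18)
        fam_eff = {f: e for f, e in zip(
            pop.families, rng.normal(0, 1, len(pop.families)))}
        fvals = pop.family.map(fam_eff).astype(float)
        fvals = (fvals - fvals.mean()) / fvals.std()
        noise = rng.normal(0, 1, len(pop.lines))
        noise = (noise - noise.mean()) / noise.std()
        # construct ~60% between-family share
        y = pd.Series(np.sqrt(0.6) * fvals + np.sqrt(0.4) * noise,
                      index=pop.lines)
        model = stepwise_select(y, pop.geno, pop.family, p_entry=1e-12,
                                gmap=gmap)
        part = partition_variance(model, y, pop.geno, pop.family)
        assert part["family_r2"] == pytest.approx(0.6, abs=0.1)
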