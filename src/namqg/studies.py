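"""Calibration and recovery studies run on synthetic panels.

These functions define the package's standard Monte-Carlo studies:
null-calibration of the bootstrapped joint-linkage RMIP rule and of the
subsampled forward-GWAS RMIP rule, parameter-recovery for line-means
heritability and AR1 spatial correlation, and the genomic-prediction
architecture contrast.  They are used both by the test suite and by the
reproduction script, so the study conditions live in one place.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gblup import crossval, vanraden
from .gwas import forward_gwas
from .jointlinkage import bootstrap_rmip
from .linemeans import ModelSpec, fit_multienv_model, heritability_line_means
from .reml import reml_ar1_grid
from .simulate import (TraitArchitecture, TraitSpec, _spatial_field,
                       assign_architecture, simulate_map, simulate_plots,
                       simulate_rils)

__all__ = ["jl_null_calibration", "gwas_null_calibration", "h2_recovery",
           "ar1_recovery", "architecture_contrast", "cv_monotonicity"]


def jl_null_calibration(n_reps: int = 120, n_families: int = 10,
                        rils_per_family: int = 60, n_markers: int = 200,
                        n_chromosomes: int = 10, B: int = 50,
                        p_entry: float = 5e-4, rmip_threshold: float = 0.10,
                        seed: int = 0) -> dict:
    """Family-wise type-I error of the bootstrapped joint-linkage RMIP rule.

    Each replicate simulates a NAM-like panel with a null trait (family
    means plus noise, zero QTL), runs the 75%-without/25%-with-replacement
    family-stratified bootstrap with stepwise entry/exit at ``p_entry``,
    and records whether any marker's (3 cM collapsed) RMIP exceeds
    ``rmip_threshold`` of the ``B`` models.  Returns the fraction of
    replicates with such a false QTL claim.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        rep_rng = np.random.default_rng(rng.integers(2 ** 31))
        gmap = simulate_map(n_chromosomes, n_markers, 150.0, 2e8, rep_rng)
        pop = simulate_rils(gmap, n_families, rils_per_family, rep_rng)
        fam_eff = {f: rep_rng.normal(0, 0.3) for f in pop.families}
        y = pd.Series(pop.family.map(fam_eff).astype(float)
                      + rep_rng.normal(0, 1, len(pop.lines)),
                      index=pop.lines)
        tab = bootstrap_rmip(y, pop.geno, pop.family, B=B, p_entry=p_entry,
                             collapse_cM=3.0, gmap=gmap,
                             seed=int(rep_rng.integers(2 ** 31)))
        if int(tab.collapsed.max()) > rmip_threshold * B:
            hits += 1
    return {"rate": hits / n_reps, "n_reps": n_reps, "hits": hits}


def gwas_null_calibration(n_reps: int = 100, n_lines: int = 3000,
                          n_snps: int = 10000, n_families: int = 25,
                          B: int = 50, p_entry: float = 5e-8,
                          rmip_threshold: float = 0.05,
                          seed: int = 0) -> dict:
    """Type-I error of the subsampled forward-GWAS RMIP rule.

    Each replicate draws iid-noise residual line means (the family term is
    fit before selection, so family structure is irrelevant under the
    null), simulates ``n_snps`` independent biallelic SNPs, runs forward
    selection at ``p_entry`` over ``B`` subsamples of 75% of the lines
    without replacement, and records whether any SNP's RMIP exceeds
    ``rmip_threshold`` of the models.
    """
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"L{i:05d}" for i in range(n_lines)])
    codes = np.repeat(np.arange(n_families),
                      int(np.ceil(n_lines / n_families)))[:n_lines]
    fam = pd.Series([f"F{c:02d}" for c in codes], index=idx)
    hits = 0
    for _ in range(n_reps):
        rep_rng = np.random.default_rng(rng.integers(2 ** 31))
        freqs = rep_rng.uniform(0.1, 0.9, n_snps)
        S = rep_rng.binomial(1, freqs, size=(n_lines, n_snps)).astype(float)
        snps = pd.DataFrame(S, index=idx)
        resid = pd.Series(rep_rng.normal(0, 1, n_lines), index=idx)
        res = forward_gwas(resid, snps, fam, p_entry=p_entry, B=B,
                           subsample_frac=0.75,
                           seed=int(rep_rng.integers(2 ** 31)))
        if int(res.table["rmip_count"].max()) > rmip_threshold * B:
            hits += 1
    return {"rate": hits / n_reps, "n_reps": n_reps, "hits": hits}


def _h2_panel(rep_rng: np.random.Generator, H2: float, n_families: int,
              rils_per_family: int, n_env: int = 3):
    """NAM-scale panel with a target across-panel line-means heritability.

    Genetic variance (family 0.35 + RIL-within-family 0.65) is fixed at 1;
    nuisance variance (family x env 30%, RIL x env 30%, plot error 40%)
    is scaled so that the line-means heritability over ``n_env``
    environments equals ``H2``.
    """
    gmap = simulate_map(5, 60, 150.0, 2e8, rep_rng)
    pop = simulate_rils(gmap, n_families, rils_per_family, rep_rng)
    nuis = n_env * (1.0 - H2) / H2
    spec = TraitSpec(family=0.35, ril=0.65, env=0.5,
                     fam_env=0.3 * nuis, ril_env=0.3 * nuis,
                     plant=0.4 * nuis, mean=5.0)
    n = len(pop.lines)
    side = int(np.ceil(np.sqrt(n * 1.15)))
    plots = simulate_plots(pop, TraitArchitecture(traits={"RPR": spec}),
                           n_env, (side, side), 1, rep_rng)
    return pop, plots


def h2_recovery(targets=(0.05, 0.2, 0.5, 0.9), n_reps: int = 50,
                n_families: int = 25, rils_per_family: int = 80,
                seed: int = 0) -> dict:
    """Mean estimated line-means heritability at each target value."""
    rng = np.random.default_rng(seed)
    out = {}
    for H2 in targets:
        ests = []
        for _ in range(n_reps):
            rep_rng = np.random.default_rng(rng.integers(2 ** 31))
            _, plots = _h2_panel(rep_rng, H2, n_families, rils_per_family)
            fit = fit_multienv_model(plots, ModelSpec(trait="RPR",
                                                      per_family_ril=False))
            ests.append(heritability_line_means(fit).H2)
        out[H2] = {"mean": float(np.mean(ests)), "sd": float(np.std(ests)),
                   "n_reps": n_reps}
    return out


def ar1_recovery(rho: float = 0.6, n_reps: int = 6, grid: int = 50,
                 spatial_var: float = 2.0, nugget_var: float = 0.5,
                 seed: int = 0) -> dict:
    """Mean REML estimates of the AR1 row/column parameters on a grid."""
    rng = np.random.default_rng(seed)
    rows, cols = [], []
    for _ in range(n_reps):
        rep_rng = np.random.default_rng(rng.integers(2 ** 31))
        Y = 3.0 + _spatial_field(rep_rng, grid, grid, spatial_var, rho, rho) \
            + rep_rng.normal(0, np.sqrt(nugget_var), (grid, grid))
        fit = reml_ar1_grid(Y)
        rows.append(fit.rho_row)
        cols.append(fit.rho_col)
    return {"rho_row_mean": float(np.mean(rows)),
            "rho_col_mean": float(np.mean(cols)), "n_reps": n_reps}


def _prediction_panel(rep_rng, n_families=10, rils_per_family=100,
                      n_markers=200, n_qtl=200, h2_line=0.7):
    """Panel with a many-small-QTL architecture and heritable line means."""
    gmap = simulate_map(5, n_markers, 150.0, 2e8, rep_rng)
    pop = simulate_rils(gmap, n_families, rils_per_family, rep_rng)
    arch = assign_architecture(pop, n_qtl, effect_scale=0.1,
                               allele_series_sd=0.05, seed=rep_rng,
                               qtl_variance_target=1.0)
    from .simulate import qtl_line_values
    g = qtl_line_values(pop, arch.traits["trait"].qtl)
    noise_sd = np.sqrt(g.var() * (1 - h2_line) / h2_line)
    y = g + rep_rng.normal(0, noise_sd, len(g))
    return gmap, pop, pd.Series(y, index=pop.lines)


def architecture_contrast(repeats: int = 20, seed: int = 0) -> dict:
    """GBLUP vs family-nested QTL prediction on a many-small-QTL panel.

    Both predictors are cross-validated with 20% calibration sets (one of
    five subsets) on the same partitions.  Returns mean accuracies and
    fold-to-fold accuracy standard deviations.
    """
    rng = np.random.default_rng(seed)
    gmap, pop, y = _prediction_panel(np.random.default_rng(
        rng.integers(2 ** 31)))
    K = vanraden(pop.geno)
    cv_seed = int(rng.integers(2 ** 31))
    cv_g = crossval(y, kinship=K, families=pop.family, fractions=(1,),
                    repeats=repeats, predictor="gblup", seed=cv_seed)
    cv_q = crossval(y, genotypes=pop.geno, families=pop.family,
                    fractions=(1,), repeats=repeats, predictor="qtl",
                    gmap=gmap, seed=cv_seed)
    return {
        "gblup_mean_r2": float(cv_g.summary["mean_r2"].iloc[0]),
        "qtl_mean_r2": float(cv_q.summary["mean_r2"].iloc[0]),
        "gblup_fold_sd": float(cv_g.folds["r2"].std()),
        "qtl_fold_sd": float(cv_q.folds["r2"].std()),
        "repeats": repeats,
    }


def cv_monotonicity(repeats: int = 20, seed: int = 0) -> pd.DataFrame:
    """Mean GBLUP accuracy by calibration fraction k = 1..4 of 5 subsets."""
    rng = np.random.default_rng(seed)
    _, pop, y = _prediction_panel(np.random.default_rng(
        rng.integers(2 ** 31)), n_families=8, rils_per_family=60,
        n_qtl=150, h2_line=0.8)
    K = vanraden(pop.geno)
    cv = crossval(y, kinship=K, families=pop.family, fractions=(1, 2, 3, 4),
                  repeats=repeats, predictor="gblup",
                  seed=int(rng.integers(2 ** 31)))
    return cv.summary
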