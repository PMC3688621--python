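"""Simulate a NAM-style RIL panel and a multi-environment field trial.

Builds a linkage map, 5 biparental families of 50 recombinant inbred
lines sharing one common parent, a trait with 10 QTL carrying
family-specific allele series, and plot phenotypes in 3 environments,
then prints what was generated.
"""

import numpy as np

from namqg import (TraitSpec, assign_architecture, simulate_map,
                   simulate_plots, simulate_rils)

gmap = simulate_map(n_chromosomes=5, n_markers=100, cM_length=150.0,
                    bp_length=2e8, seed=1)
pop = simulate_rils(gmap, n_families=5, rils_per_family=50, seed=2)

base = TraitSpec(family=0.35, ril=0.65, env=0.5, fam_env=0.9, ril_env=0.9,
                 plant=3.6, mean=5.0)
arch = assign_architecture(pop, n_qtl=10, effect_scale=0.15,
                           allele_series_sd=0.1, seed=3,
                           qtl_variance_target=0.4, base=base, trait="RPR")
plots = simulate_plots(pop, arch, environments=3, grid_shape=(18, 15),
                       plants_per_plot=3, seed=4)

print(f"map: {gmap.n_markers} markers on {len(gmap.chromosomes())} "
      "chromosomes")
print(f"panel: {len(pop.lines)} RILs in {len(pop.families)} families, "
      "all sharing the common parent")
qtl = arch.traits["RPR"].qtl
effects = np.array([list(e.values()) for e in qtl.values()])
print(f"architecture: {len(qtl)} QTL; {np.mean(effects > 0):.0%} of "
      "family effects increase the trait (allele series => both signs)")
print(f"trial: {len(plots.df)} plot records over 3 environments")
print(plots.df.head(3).to_string(index=False))
print("Each plot value = mean + family + RIL genetic value + environment"
      " + interactions + field effects + plant-sampling noise.")
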