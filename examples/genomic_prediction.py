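"""Cross-validated genomic prediction: GBLUP vs family-nested QTL models.

On a panel with many small QTL, whole-genome GBLUP outperforms selected
family-nested QTL models, and the QTL models' accuracy varies more from
calibration set to calibration set — the hallmark of a highly polygenic
trait.
"""

from namqg import crossval, vanraden
from namqg.studies import _prediction_panel

import numpy as np

gmap, pop, y = _prediction_panel(np.random.default_rng(40),
                                 n_families=8, rils_per_family=80,
                                 n_qtl=150)
K = vanraden(pop.geno)

cv_g = crossval(y, kinship=K, families=pop.family, fractions=(1, 4),
                repeats=5, predictor="gblup", seed=41)
cv_q = crossval(y, genotypes=pop.geno, families=pop.family,
                fractions=(1, 4), repeats=5, predictor="qtl", gmap=gmap,
                seed=41)

print(f"panel: {len(pop.lines)} RILs, 150 small QTL, line-mean h2 ~ 0.7")
print("calibration  GBLUP R2   QTL-model R2")
for k in (1, 4):
    rg = cv_g.summary.set_index("fraction").loc[k, "mean_r2"]
    rq = cv_q.summary.set_index("fraction").loc[k, "mean_r2"]
    print(f"   {k}/5 ({k * 20}%)   {rg:6.3f}     {rq:6.3f}")
sd_g = cv_g.folds["r2"].std()
sd_q = cv_q.folds["r2"].std()
print(f"fold-to-fold sd: GBLUP {sd_g:.3f}, QTL model {sd_q:.3f}")
print("R2 is the coefficient of determination of observed line means "
      "regressed on predictions, averaged over folds then repeats.")
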