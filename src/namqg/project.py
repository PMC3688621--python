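"""Linkage-marker imputation and SNP projection onto RILs.

Missing linkage-marker calls are imputed per line as the weighted average
of the nearest non-missing flanking markers on the same chromosome, with
weights proportional to one minus the relative genetic (cM) distance:
a missing call at position p between flanks a and b receives
``w_a g_a + w_b g_b`` with ``w_a = (cM_b - cM_p) / (cM_b - cM_a)``.
Terminal gaps copy the single available flank.

Dense SNPs are projected from founder haplotypes: the flanking linkage
markers' founder dosages give each RIL's probability of carrying the
alternate parent at the SNP, interpolated linearly in physical (bp)
distance, and the probability is mapped through the two parents' SNP
alleles.  For inbred founders interpolating origin probabilities and
interpolating final dosages coincide.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import COMMON_PARENT, GeneticMap

__all__ = ["impute_linkage", "project_snps"]


def _interp_row(vals: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Linear interpolation of NaNs in ``vals`` over positions ``pos``;
    terminal NaNs copy the nearest observed value.  All-NaN -> unchanged."""
    miss = np.isnan(vals)
    if not miss.any():
        return vals
    if miss.all():
        return vals
    out = vals.copy()
    out[miss] = np.interp(pos[miss], pos[~miss], vals[~miss])
    return out


def impute_linkage(genotypes: pd.DataFrame, gmap: GeneticMap,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute missing linkage genotypes by flanking-marker cM weighting.

    Returns the completed genotype table and a (line x chromosome) flag
    table marking chromosomes that were entirely missing for a line
    (left missing).
    """
    mdf = gmap.df
    missing_cols = [m for m in genotypes.columns if m not in set(mdf["marker"])]
    if missing_cols:
        raise ValueError(f"markers absent from map: {missing_cols[:3]}")
    out = genotypes.copy().astype(float)
    chroms = gmap.chromosomes()
    flags = pd.DataFrame(False, index=genotypes.index, columns=chroms)
    for c in chroms:
        sub = mdf[mdf["chrom"] == c]
        cols = [m for m in sub["marker"] if m in genotypes.columns]
        if not cols:
            continue
        pos = sub.set_index("marker").loc[cols, "cM"].to_numpy(float)
        block = out[cols].to_numpy(float)
        all_missing = np.isnan(block).all(axis=1)
        flags.loc[all_missing, c] = True
        for i in np.nonzero(np.isnan(block).any(axis=1) & ~all_missing)[0]:
            block[i] = _interp_row(block[i], pos)
        out[cols] = block
    return out, flags


def project_snps(founder_snps: pd.DataFrame,
                 ril_linkage_genotypes: pd.DataFrame,
                 snp_map: GeneticMap, linkage_map: GeneticMap,
                 families: pd.Series) -> pd.DataFrame:
    """Project founder SNPs onto RILs by physical-distance weighting.

    ``founder_snps`` rows are founders (the common parent plus one
    ``AP_<family>`` row per family); ``ril_linkage_genotypes`` holds the
    complete founder dosages (0 = common parent) at linkage markers.  The
    origin probability at each SNP is the bp-linear interpolation of the
    flanking linkage dosages; the returned dosage is the probability-
    weighted average of the two parents' SNP alleles.
    """
    if COMMON_PARENT not in founder_snps.index:
        raise ValueError(f"founder table lacks the common parent row "
                         f"{COMMON_PARENT!r}")
    link_chroms = set(linkage_map.chromosomes())
    bad = [c for c in snp_map.chromosomes() if c not in link_chroms]
    if bad:
        raise ValueError(f"SNP chromosomes absent from linkage map: {bad}")
    lines = ril_linkage_genotypes.index
    fam = families.loc[lines].astype(str)
    n = len(lines)
    out = np.empty((n, snp_map.n_markers))
    snp_cols = list(snp_map.markers)
    col_pos = {m: i for i, m in enumerate(snp_cols)}
    a_cp = founder_snps.loc[COMMON_PARENT]

    for c in sorted(link_chroms):
        lsub = linkage_map.chrom_slice(c)
        lcols = [m for m in lsub["marker"] if m in ril_linkage_genotypes.columns]
        if not lcols:
            continue
        lbp = lsub.set_index("marker").loc[lcols, "bp"].to_numpy(float)
        ssub = snp_map.chrom_slice(c)
        if ssub.empty:
            continue
        sbp = ssub["bp"].to_numpy(float)
        scols = [col_pos[m] for m in ssub["marker"]]
        G = ril_linkage_genotypes[lcols].to_numpy(float)
        # per line: origin probability at SNP bp via linear interpolation;
        # np.interp clamps beyond the outermost markers (nearest flank)
        P = np.empty((n, len(sbp)))
        for i in range(n):
            P[i] = np.interp(sbp, lbp, G[i])
        for f in fam.unique():
            ap = f"AP_{f}"
            if ap not in founder_snps.index:
                raise ValueError(f"founder table lacks {ap!r}")
            rows = np.nonzero((fam == f).to_numpy())[0]
            a0 = a_cp.iloc[scols].to_numpy(float)
            a1 = founder_snps.loc[ap].iloc[scols].to_numpy(float)
            out[np.ix_(rows, scols)] = (1 - P[rows]) * a0 + P[rows] * a1
    return pd.DataFrame(out, index=lines, columns=snp_cols)
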