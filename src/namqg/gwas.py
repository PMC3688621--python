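"""Genome-wide association: joint-linkage-assisted and mixed-model scans.

Two GWAS modes are provided.

RIL-panel mode ("joint-linkage assisted"): the fitted family-nested QTL
model is used to absorb background genetic variation.  For each
chromosome a residual trait is formed by refitting the QTL model without
the family term and without that chromosome's QTL, so the residual
carries the error plus the held-out chromosome's signal.  Residuals are
then regressed on that chromosome's SNPs by forward selection of
single-slope (non-nested) terms after a family term, repeated over
subsamples of 75% of the lines without replacement, and each SNP's RMIP
is the fraction of subsample models that selected it.

Diversity-panel mode: a single-SNP linear mixed model with a random
polygenic term whose covariance is the identity-by-state kinship matrix.
Variance components are estimated once on the null model and reused for
every SNP (the P3D/EMMAX approximation), the model is solved through one
eigendecomposition of the kinship, and Benjamini-Hochberg q-values are
reported across all SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .jointlinkage import QTLModel

__all__ = ["ChromosomeResiduals", "GwasResult", "chromosome_residuals",
           "forward_gwas", "mlm_gwas", "bh_qvalues"]


@dataclass
class ChromosomeResiduals:
    """Per-chromosome residual line means (family term excluded)."""

    residuals: dict[int, pd.Series]

    def __getitem__(self, chrom: int) -> pd.Series:
        return self.residuals[chrom]

    def chromosomes(self) -> list[int]:
        return sorted(self.residuals)


@dataclass
class GwasResult:
    """Per-SNP association results.

    ``table`` columns: snp, chrom (if known), effect, stat, p_value and
    either rmip (RIL mode) or q_value (diversity mode).
    """

    table: pd.DataFrame
    mode: str
    B: int | None = None


def chromosome_residuals(qtl_model: QTLModel,
                         line_means: pd.Series | pd.DataFrame,
                         genotypes: pd.DataFrame, families: pd.Series,
                         chromosomes: list[int] | None = None,
                         ) -> ChromosomeResiduals:
    """Residual line means per chromosome from the QTL model.

    For chromosome ``c`` the model keeps an intercept and every selected
    family-nested QTL except those mapped to ``c``; the family term is
    dropped, so between-family variation stays in the residuals.  With no
    QTL on a chromosome the residuals equal the intercept-plus-all-QTL
    model's residuals.
    """
    if isinstance(line_means, pd.DataFrame):
        line_means = line_means.set_index("line")["value"]
    lines = line_means.index.intersection(genotypes.index)
    y = line_means.loc[lines].to_numpy(float)
    fam = families.loc[lines].astype(str)
    if chromosomes is None:
        chroms = sorted({t.chrom for t in qtl_model.terms
                         if t.chrom is not None})
        if not chroms:
            chroms = [0]
    else:
        chroms = list(chromosomes)

    def nested_cols(term):
        x = genotypes[term.marker].loc[lines].to_numpy(float)
        cols = []
        for f in term.effects:
            c = np.where(fam.to_numpy() == f, x, 0.0)
            cols.append(c)
        return cols

    out = {}
    for c in chroms:
        cols = [np.ones(len(lines))]
        for t in qtl_model.terms:
            if t.chrom == c:
                continue
            cols.extend(nested_cols(t))
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        out[c] = pd.Series(y - X @ beta, index=lines)
    return ChromosomeResiduals(residuals=out)


class _FamilyProjector:
    """Orthonormal handling of the family term for fast forward scans.

    Rows must be sorted by family code; ``starts`` are the reduceat
    boundaries, which makes family sums a single memory pass.
    """

    def __init__(self, fam_codes_sorted: np.ndarray):
        self.codes = fam_codes_sorted
        change = np.nonzero(np.diff(fam_codes_sorted))[0] + 1
        self.starts = np.concatenate([[0], change])
        self.sizes = np.diff(np.concatenate(
            [self.starts, [len(fam_codes_sorted)]])).astype(float)
        self.n_groups = len(self.starts)

    def group_sums(self, M: np.ndarray) -> np.ndarray:
        return np.add.reduceat(M, self.starts, axis=0)

    def center(self, v: np.ndarray) -> np.ndarray:
        """Residual of v on the family indicators (within-family center)."""
        means = np.add.reduceat(v, self.starts) / self.sizes
        return v - np.repeat(means, self.sizes.astype(int))


def _forward_once(y: np.ndarray, S: np.ndarray, proj: _FamilyProjector,
                  p_entry: float, max_terms: int,
                  S2: np.ndarray | None = None) -> list[int]:
    """Forward selection of single-slope SNP terms after the family term.

    Rows of ``y``/``S`` must be sorted by family.  ``S2`` may carry the
    precomputed elementwise square of ``S``.
    """
    n, m = S.shape
    selected: list[int] = []
    qcols: list[np.ndarray] = []   # orthonormal, family-centered
    r = proj.center(y)
    if S2 is None:
        S2 = S * S
    fam_sums = proj.group_sums(S)
    colsum2 = proj.group_sums(S2).sum(axis=0)
    den = colsum2 - np.einsum(
        "fj,fj->j", fam_sums, fam_sums / proj.sizes[:, None])
    p_rank = proj.n_groups
    while len(selected) < max_terms:
        num = S.T @ r
        d = np.maximum(den, 0.0)
        rss = float(r @ r)
        df2 = n - p_rank - len(selected) - 1
        if df2 <= 0:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            ssr = np.where(d > 1e-10, num ** 2 / d, 0.0)
        ssr = np.minimum(ssr, rss * (1 - 1e-12))
        # screen on the best F before computing any p-value
        Fstat = ssr / ((rss - ssr) / df2)
        j = int(np.argmax(np.where(d > 1e-10, Fstat, -1.0)))
        if selected:
            Fstat[np.asarray(selected)] = -1.0
            j = int(np.argmax(Fstat))
        if stats.f.sf(Fstat[j], 1, df2) >= p_entry:
            break
        # orthonormalize the new column against family + previous
        q = proj.center(S[:, j].astype(float))
        for qq in qcols:
            q -= qq * (qq @ q)
        nq = np.linalg.norm(q)
        if nq <= 1e-10:
            den[j] = 0.0
            continue
        q /= nq
        qcols.append(q)
        selected.append(j)
        r = r - q * (q @ r)
        den = den - (q @ S) ** 2
    return selected


def _first_step_screen(y: np.ndarray, S: np.ndarray, codes: np.ndarray,
                       takes: list[np.ndarray], p_entry: float,
                       slack: float = 4.0) -> list[int]:
    """Subsamples whose best first-step p-value may cross ``p_entry``.

    First-step F statistics for every subsample are computed in one batch
    (numerators by a single matrix product, denominators from complement
    sums in float32); a subsample is flagged when its best statistic
    exceeds the entry threshold divided by ``slack``, after which the
    flagged subsamples are re-run exactly in float64.  Under a null trait
    almost nothing is flagged, which keeps large calibration studies fast.
    """
    n, m = S.shape
    S32 = S.astype(np.float32)
    S232 = S32 * S32
    change = np.nonzero(np.diff(codes))[0] + 1
    starts = np.concatenate([[0], change])
    sizes_full = np.diff(np.concatenate([starts, [n]])).astype(float)
    famsums_full = np.add.reduceat(S32, starts, axis=0).astype(np.float64)
    colsum2_full = np.add.reduceat(S232, starts, axis=0).sum(axis=0,
                                                             dtype=np.float64)
    F_crit = stats.f.isf(min(p_entry * slack, 0.5), 1,
                         max(n - len(starts) - 1, 2))
    Z = np.zeros((n, len(takes)))
    dens, df2s, rsss = [], [], []
    for b, take in enumerate(takes):
        mask = np.zeros(n, dtype=bool)
        mask[take] = True
        comp = np.nonzero(~mask)[0]
        famsums = famsums_full.copy()
        colsum2 = colsum2_full.copy()
        nsub_f = sizes_full.copy()
        if len(comp):
            cc = codes[comp]
            cchange = np.nonzero(np.diff(cc))[0] + 1
            cstarts = np.concatenate([[0], cchange])
            cfams = np.searchsorted(codes[starts], cc[cstarts])
            csizes = np.diff(np.concatenate([cstarts, [len(comp)]]))
            Scomp = S32[comp]
            famsums[cfams] -= np.add.reduceat(Scomp, cstarts, axis=0)
            colsum2 -= np.einsum("ij,ij->j", Scomp, Scomp,
                                 dtype=np.float64)
            nsub_f[cfams] -= csizes
        den = colsum2 - np.einsum("fj,fj->j", famsums,
                                  famsums / np.maximum(nsub_f, 1)[:, None])
        dens.append(np.maximum(den, 0.0))
        # centered y on the subsample, zero elsewhere
        ysub = np.where(mask, y, 0.0)
        ysums = np.add.reduceat(ysub, starts)
        ymeans = ysums / np.maximum(nsub_f, 1)
        r = np.where(mask, y - ymeans[codes], 0.0)
        Z[:, b] = r
        rsss.append(float(r @ r))
        df2s.append(len(take) - (nsub_f > 0).sum() - 1)
    num = S.T @ Z    # m x B in one pass
    flagged = []
    for b in range(len(takes)):
        den = dens[b]
        with np.errstate(divide="ignore", invalid="ignore"):
            ssr = np.where(den > 1e-6, num[:, b] ** 2 / den, 0.0)
        ssr = np.minimum(ssr, rsss[b] * (1 - 1e-9))
        F = ssr / ((rsss[b] - ssr) / max(df2s[b], 2))
        if np.nanmax(F) >= F_crit:
            flagged.append(b)
    return flagged


def forward_gwas(residuals: pd.Series | ChromosomeResiduals,
                 snps: pd.DataFrame, families: pd.Series,
                 snp_map: pd.DataFrame | None = None,
                 p_entry: float = 5e-8, B: int = 100,
                 subsample_frac: float = 0.75, max_terms: int = 50,
                 seed: int | np.random.Generator = 0) -> GwasResult:
    """Bootstrapped forward regression of residuals on SNPs with RMIP.

    ``snp_map`` (columns marker, chrom) routes each chromosome's residual
    vector to its own SNPs; without it all SNPs are scanned against the
    single residual vector given.  Each of ``B`` subsamples draws
    ``subsample_frac`` of the lines without replacement; a SNP's RMIP is
    the number of subsample models including it, out of ``B``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(residuals, ChromosomeResiduals):
        groups = [(c, residuals[c]) for c in residuals.chromosomes()]
    else:
        groups = [(None, residuals)]
    counts = pd.Series(0, index=snps.columns, dtype=int)
    keep_cols = {}
    for c, resid in groups:
        if snp_map is not None and c is not None:
            cols = snp_map.loc[snp_map["chrom"] == c, "marker"]
            cols = [m for m in cols if m in snps.columns]
        else:
            cols = list(snps.columns)
        keep_cols[c] = cols
        if not cols:
            continue
        lines = resid.index.intersection(snps.index)
        y = resid.loc[lines].to_numpy(float)
        S = snps.loc[lines, cols].to_numpy(float)
        const = S.std(axis=0) <= 1e-12
        if const.any():
            S = S[:, ~const]
            cols = [m for m, k in zip(cols, ~const) if k]
        fam = pd.Categorical(families.loc[lines].astype(str))
        codes = fam.codes.astype(int)
        # sort rows by family once so subsample group sums are reduceat
        order = np.argsort(codes, kind="stable")
        y, S, codes = y[order], np.ascontiguousarray(S[order]), codes[order]
        n = len(y)
        n_sub = int(round(subsample_frac * n))
        takes = [np.sort(rng.choice(n, n_sub, replace=False))
                 for _ in range(B)]
        flagged = _first_step_screen(y, S, codes, takes, p_entry)
        S2 = None
        for b in flagged:
            take = takes[b]
            if S2 is None:
                S2 = S * S
            proj = _FamilyProjector(codes[take])
            sel = _forward_once(y[take], S[take], proj, p_entry, max_terms,
                                S2=S2[take])
            for j in sel:
                counts[cols[j]] += 1
    table = pd.DataFrame({"snp": counts.index, "rmip_count": counts.values,
                          "rmip": counts.values / B})
    if snp_map is not None:
        table = table.merge(snp_map[["marker", "chrom"]], left_on="snp",
                            right_on="marker", how="left").drop(columns="marker")
    return GwasResult(table=table, mode="ril", B=B)


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p)."""
    from statsmodels.stats.multitest import multipletests
    p = np.asarray(pvals, float)
    return multipletests(p, method="fdr_bh")[1]


def mlm_gwas(line_means: pd.Series | pd.DataFrame, snps: pd.DataFrame,
             kinship: "pd.DataFrame | object") -> GwasResult:
    """Single-SNP mixed-model GWAS with a polygenic kinship term.

    Model: y = mu + x_j b_j + g + e with g ~ N(0, K sigma_g^2).  The two
    variance components are estimated once by REML on the null model
    through an eigendecomposition of K and reused for every SNP test
    (P3D-style), making each SNP a generalized-least-squares t-test in the
    rotated basis.  q-values are Benjamini-Hochberg across all SNPs.
    """
    if isinstance(line_means, pd.DataFrame):
        line_means = line_means.set_index("line")["value"]
    Kdf = kinship.matrix if hasattr(kinship, "matrix") else kinship
    lines = line_means.index.intersection(snps.index).intersection(Kdf.index)
    y = line_means.loc[lines].to_numpy(float)
    K = Kdf.loc[lines, lines].to_numpy(float)
    n = len(y)
    w = np.linalg.eigvalsh(K)
    if w.min() < -1e-8:
        warnings.warn("kinship not PSD; ridge-stabilized", stacklevel=2)
        K = K + (abs(w.min()) + 1e-8) * np.eye(n)
    lam, U = np.linalg.eigh(K)
    lam = np.maximum(lam, 0.0)
    yt = U.T @ y
    ones_t = U.T @ np.ones(n)

    def nll(log_ratio):
        # ratio = sigma_g^2 / sigma_e^2; profile sigma_e^2 and mu
        r = np.exp(log_ratio)
        d = r * lam + 1.0
        xtx = (ones_t ** 2 / d).sum()
        xty = (ones_t * yt / d).sum()
        mu = xty / xtx
        rss = ((yt - ones_t * mu) ** 2 / d).sum()
        df = n - 1
        s2 = rss / df
        return 0.5 * (np.log(d).sum() + np.log(xtx) + df * np.log(s2) + df)

    res = optimize.minimize_scalar(nll, bounds=(-10, 10), method="bounded",
                                   options={"xatol": 1e-8})
    ratio = float(np.exp(res.x))
    d = ratio * lam + 1.0
    Xt_all = U.T @ snps.loc[lines].to_numpy(float)   # n x m
    m = Xt_all.shape[1]
    # GLS per SNP with X = [1, x]
    iv = 1.0 / d
    a11 = (ones_t ** 2 * iv).sum()
    a1y = (ones_t * yt * iv).sum()
    a12 = np.einsum("i,i,ij->j", ones_t, iv, Xt_all)
    a22 = np.einsum("ij,i,ij->j", Xt_all, iv, Xt_all)
    a2y = np.einsum("ij,i,i->j", Xt_all, iv, yt)
    det = a11 * a22 - a12 ** 2
    yy = (yt ** 2 * iv).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (a11 * a2y - a12 * a1y) / det
        mu = (a22 * a1y - a12 * a2y) / det
        rss = yy - mu * a1y - beta * a2y
        df2 = n - 2
        s2 = rss / df2
        var_b = s2 * a11 / det
        tstat = beta / np.sqrt(var_b)
    bad = ~np.isfinite(tstat)
    tstat[bad] = 0.0
    pv = 2.0 * stats.t.sf(np.abs(tstat), df2)
    pv = np.clip(pv, np.finfo(float).tiny, 1.0)
    q = bh_qvalues(pv)
    table = pd.DataFrame({"snp": snps.columns, "effect": beta, "stat": tstat,
                          "p_value": pv, "q_value": q})
    table.attrs["variance_ratio"] = ratio
    return GwasResult(table=table, mode="diversity")
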