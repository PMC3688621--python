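"""Family-nested joint-linkage QTL mapping with bootstrap RMIP.

Line means from the multi-environment model are regressed on a family
term plus linkage markers nested within families: a selected marker
carries one regression slope per family in which it segregates, so allele
series (effects of opposite sign in different families, all relative to
the shared common parent) are representable.  Model building is stepwise:
forward steps add the marker whose family-nested group has the smallest
marginal-F p-value below the entry threshold, and after each addition any
term whose marginal p-value has risen above the exit threshold is
dropped.  Robustness is quantified by the resample model inclusion
probability (RMIP): the panel is resampled B times family-stratified
(75% of each family's lines without replacement plus 25% with
replacement), the model is rebuilt on each resample, and a marker's RMIP
is the fraction of resamples in which it (or, with map collapsing, any
marker within a window of a few cM) entered the model.

Entry/exit thresholds are calibrated by permutation: line means are
permuted within families, preserving family means, and the threshold is
the lower quantile of the distribution of the minimum marginal p-value
over markers under this null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GeneticMap

__all__ = ["QTLTerm", "QTLModel", "RMIPTable", "stepwise_select",
           "bootstrap_rmip", "permutation_threshold", "pleiotropy_test",
           "partition_variance"]

_SEG_EPS = 1e-9


@dataclass
class QTLTerm:
    marker: str
    index: int
    chrom: int | None
    cM: float | None
    p_value: float
    effects: dict[str, float] = field(default_factory=dict)


@dataclass
class QTLModel:
    """Ordered family-nested marker terms plus family intercepts."""

    terms: list[QTLTerm]
    family_intercepts: dict[str, float]
    families: list[str]
    n_lines: int
    rss: float
    tss: float

    @property
    def markers(self) -> list[str]:
        return [t.marker for t in self.terms]

    @property
    def r_squared(self) -> float:
        return 1.0 - self.rss / self.tss if self.tss > 0 else 0.0


@dataclass
class RMIPTable:
    """Marker inclusion counts out of ``B`` resampled model builds."""

    counts: pd.Series          # marker -> count, raw (exact marker identity)
    collapsed: pd.Series | None  # windowed counts (any marker within window)
    B: int
    collapse_cM: float | None = None

    def rmip(self, collapsed: bool = True) -> pd.Series:
        src = self.collapsed if (collapsed and self.collapsed is not None) \
            else self.counts
        return src / self.B


class _NestedScanner:
    """Shared machinery for family-nested stepwise regression.

    Supports frequency weights for bootstrap resamples in which lines are
    drawn with replacement: the resample is represented as unique lines
    with multiplicities, estimation uses weighted least squares, and all
    F-tests are line-clustered sandwich tests, which account for the fact
    that a line drawn twice carries one error draw, not two.  With unit
    weights the sandwich test reduces exactly to the classical marginal F.
    """

    def __init__(self, y: np.ndarray, G: np.ndarray, fam_codes: np.ndarray,
                 n_fam: int, weights: np.ndarray | None = None):
        self.y = np.asarray(y, float)
        self.G = np.asarray(G, float)
        self.fam = fam_codes
        self.n, self.m = self.G.shape
        self.n_fam = n_fam
        self.w = np.ones(self.n) if weights is None else \
            np.asarray(weights, float)
        if np.any(self.w <= 0):
            raise ValueError("weights must be positive")
        self.sw = np.sqrt(self.w)
        self.n_eff = float(self.w.sum())
        # Kish effective sample size: correct residual df under frequency
        # weighting; equals n for unit weights
        self.n_kish = float(self.w.sum() ** 2 / (self.w ** 2).sum())
        self.rows = [np.nonzero(fam_codes == f)[0] for f in range(n_fam)]
        # segregation: within-family variance of each marker
        self.seg = np.zeros((n_fam, self.m), dtype=bool)
        for f in range(n_fam):
            sub = self.G[self.rows[f]]
            if len(sub) > 1:
                self.seg[f] = sub.var(axis=0) > _SEG_EPS
        self.fam_design = np.zeros((self.n, n_fam))
        self.fam_design[np.arange(self.n), fam_codes] = 1.0

    def design(self, terms: list[tuple[int, np.ndarray]],
               weighted: bool = False) -> np.ndarray:
        """Family indicators plus nested columns for (marker, fams) terms."""
        cols = [self.fam_design]
        for j, fams in terms:
            block = np.zeros((self.n, len(fams)))
            for k, f in enumerate(fams):
                rr = self.rows[f]
                block[rr, k] = self.G[rr, j]
            cols.append(block)
        X = np.hstack(cols)
        return self.sw[:, None] * X if weighted else X

    def term_slices(self, terms: list[tuple[int, np.ndarray]]) -> list[slice]:
        """Coefficient index ranges of each nested term in ``design``."""
        out = []
        pos = self.n_fam
        for _, fams in terms:
            out.append(slice(pos, pos + len(fams)))
            pos += len(fams)
        return out

    def scan(self, Q: np.ndarray, resid: np.ndarray, rss: float,
             p_rank: int, exclude: set[int]) -> tuple[np.ndarray, np.ndarray]:
        """Marginal p-value of adding each marker's nested group.

        ``Q`` is an orthonormal basis of the current (weighted) design,
        ``resid`` the current weighted residual vector, ``rss`` its squared
        norm.  Tests are line-clustered sandwich F-tests, identical to the
        classical marginal F for unit weights.  Returns (p-values, df1)
        arrays over markers (excluded/singular -> 1).
        """
        m = self.m
        weighted = not np.all(self.w == 1.0)
        pvals = np.ones(m)
        df1s = np.zeros(m, dtype=int)
        U, Uw = [], []   # per family: (p_rank x m)
        d = np.zeros((self.n_fam, m))
        d2 = np.zeros((self.n_fam, m))
        v = np.zeros((self.n_fam, m))
        QwQ = (Q.T @ (self.w[:, None] * Q)) if weighted else None
        for f in range(self.n_fam):
            rr = self.rows[f]
            Cf = self.sw[rr, None] * self.G[rr]
            U.append(Q[rr].T @ Cf)
            d[f] = np.einsum("ij,ij->j", Cf, Cf)
            v[f] = Cf.T @ resid[rr]
            if weighted:
                WCf = self.w[rr, None] * Cf
                Uw.append(Q[rr].T @ WCf)
                d2[f] = np.einsum("ij,ij->j", Cf, WCf)
        for j in range(m):
            if j in exclude:
                continue
            S = np.nonzero(self.seg[:, j])[0]
            k = len(S)
            if k == 0:
                continue
            df2 = self.n_kish - p_rank - k
            if df2 <= 0:
                continue
            Uj = np.column_stack([U[f][:, j] for f in S])
            Gj = np.diag(d[S, j]) - Uj.T @ Uj
            vj = v[S, j]
            try:
                a = np.linalg.solve(Gj, vj)
            except np.linalg.LinAlgError:
                continue
            ssr = float(vj @ a)
            if not np.isfinite(ssr) or ssr < 0 or ssr >= rss:
                ssr = min(max(ssr, 0.0), rss * (1 - 1e-12))
            if weighted:
                Uwj = np.column_stack([Uw[f][:, j] for f in S])
                Mj = (np.diag(d2[S, j]) - Uwj.T @ Uj - Uj.T @ Uwj
                      + Uj.T @ QwQ @ Uj)
                try:
                    stat = float(vj @ np.linalg.solve(Mj, vj))
                except np.linalg.LinAlgError:
                    continue
                if not np.isfinite(stat) or stat < 0:
                    continue
            else:
                stat = ssr
            F = (stat / k) / ((rss - ssr) / df2)
            pvals[j] = stats.f.sf(F, k, df2)
            df1s[j] = k
        return pvals, df1s


def _align(line_means: pd.Series | pd.DataFrame, genotypes: pd.DataFrame,
           families: pd.Series):
    if isinstance(line_means, pd.DataFrame):
        line_means = line_means.set_index("line")["value"]
    lines = line_means.index.intersection(genotypes.index).sort_values()
    if len(lines) == 0:
        raise ValueError("line means and genotypes share no line ids")
    y = line_means.loc[lines].to_numpy(float)
    G = genotypes.loc[lines].to_numpy(float)
    fam = families.loc[lines].astype(str)
    fam_cat = pd.Categorical(fam)
    return y, G, fam_cat.codes.astype(int), list(fam_cat.categories), \
        genotypes.columns, lines


def _marker_order_key(gmap: GeneticMap | None, markers: pd.Index):
    """Deterministic tie-break order: (chrom, cM, name)."""
    if gmap is None:
        return {mk: (0, 0.0, str(mk)) for mk in markers}
    mdf = gmap.df.set_index("marker")
    out = {}
    for mk in markers:
        if mk in mdf.index:
            r = mdf.loc[mk]
            out[mk] = (int(r["chrom"]), float(r["cM"]), str(mk))
        else:
            out[mk] = (10 ** 6, 0.0, str(mk))
    return out


def stepwise_select(line_means: pd.Series | pd.DataFrame,
                    genotypes: pd.DataFrame, families: pd.Series,
                    p_entry: float = 5e-4, p_exit: float | None = None,
                    max_terms: int = 100,
                    gmap: GeneticMap | None = None,
                    weights: pd.Series | None = None) -> QTLModel:
    """Family-nested stepwise regression of line means on linkage markers.

    Family main effects are always in the model.  Ties among candidate
    markers with equal p-values break deterministically by chromosome,
    then cM, then marker name.  ``weights`` are frequency weights (line
    multiplicities in a bootstrap resample); estimation is then weighted
    least squares and all tests are line-clustered sandwich F-tests.
    """
    if p_exit is None:
        p_exit = p_entry
    if p_exit < p_entry:
        raise ValueError("p_exit must be >= p_entry")
    y, G, fam_codes, fams, markers, lines = _align(line_means, genotypes,
                                                   families)
    wvec = None if weights is None else weights.loc[lines].to_numpy(float)
    sc = _NestedScanner(y, G, fam_codes, len(fams), weights=wvec)
    order_key = _marker_order_key(gmap, markers)
    ybar = float(np.average(y, weights=sc.w))
    tss = float((sc.w * (y - ybar) ** 2).sum())

    terms: list[tuple[int, np.ndarray]] = []  # (marker idx, segregating fams)
    dropped_singular: set[int] = set()

    yw = sc.sw * y
    weighted = not np.all(sc.w == 1.0)

    def refit():
        """QR + coefficients + marginal p-value of every term in the model.

        Marginal (drop-one-term) tests come from the coefficient
        covariance; with unit weights F = b_I' [ (X'X)^-1_II ]^-1 b_I /
        (k s^2), identical to refitting without the term.  With frequency
        weights the line-clustered sandwich covariance is used instead.
        """
        from scipy.linalg import solve_triangular
        X = sc.design(terms, weighted=True)
        Q, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        if diag.min() <= 1e-8 * max(1.0, diag.max()):
            return None  # rank deficient
        Qty = Q.T @ yw
        resid = yw - Q @ Qty
        rss = float(resid @ resid)
        beta = solve_triangular(R, Qty)
        Rinv = solve_triangular(R, np.eye(R.shape[0]))
        XtX_inv = Rinv @ Rinv.T
        df2 = sc.n_kish - X.shape[1]
        if weighted:
            meat = X.T @ (sc.w[:, None] * X)
            S = XtX_inv @ meat @ XtX_inv
        else:
            S = XtX_inv
        pvals_t = []
        for sl in sc.term_slices(terms):
            bI = beta[sl]
            k = sl.stop - sl.start
            ssr = float(bI @ np.linalg.solve(S[sl, sl], bI))
            F = (ssr / k) / (rss / df2) if df2 > 0 else np.inf
            pvals_t.append(float(stats.f.sf(max(F, 0.0), k, max(df2, 1))))
        return Q, resid, rss, beta, pvals_t

    state = refit()
    Q, resid, rss, beta, term_ps = state
    while len(terms) < max_terms:
        in_model = {j for j, _ in terms}
        pvals, df1s = sc.scan(Q, resid, rss, Q.shape[1],
                              in_model | dropped_singular)
        best_p = pvals.min()
        if best_p >= p_entry:
            break
        cands = np.nonzero(pvals <= best_p * (1 + 1e-12))[0]
        j = min(cands, key=lambda jj: order_key[markers[jj]])
        terms.append((int(j), np.nonzero(sc.seg[:, j])[0]))
        state = refit()
        if state is None:
            terms.pop()
            dropped_singular.add(int(j))
            warnings.warn(f"marker {markers[j]} duplicates the current "
                          "model; dropped", stacklevel=2)
            continue
        Q, resid, rss, beta, term_ps = state
        # backward pass: drop the worst term while above the exit threshold
        while len(terms) > 1:
            worst_i = int(np.argmax(term_ps))
            if term_ps[worst_i] <= p_exit:
                break
            terms.pop(worst_i)
            Q, resid, rss, beta, term_ps = refit()

    fam_int = {fams[f]: float(beta[f]) for f in range(len(fams))}
    out_terms: list[QTLTerm] = []
    mdf = gmap.df.set_index("marker") if gmap is not None else None
    for (j, fams_j), sl, p_j in zip(terms, sc.term_slices(terms), term_ps):
        effs = {fams[f]: float(beta[sl][i]) for i, f in enumerate(fams_j)}
        mk = markers[j]
        chrom = int(mdf.loc[mk, "chrom"]) if mdf is not None and mk in mdf.index else None
        cM = float(mdf.loc[mk, "cM"]) if mdf is not None and mk in mdf.index else None
        out_terms.append(QTLTerm(marker=str(mk), index=int(j), chrom=chrom,
                                 cM=cM, p_value=p_j, effects=effs))
    return QTLModel(terms=out_terms, family_intercepts=fam_int,
                    families=fams, n_lines=sc.n, rss=rss, tss=tss)


def _stratified_resample(rng: np.random.Generator, fam_codes: np.ndarray,
                         frac_wo: float = 0.75) -> np.ndarray:
    """75% without + 25% with replacement per family; size preserved."""
    out = []
    for f in np.unique(fam_codes):
        rr = np.nonzero(fam_codes == f)[0]
        nf = len(rr)
        if nf < 4:
            raise ValueError(f"family {f} has fewer than 4 lines")
        n_wo = int(round(frac_wo * nf))
        n_wr = nf - n_wo
        keep = rng.choice(rr, n_wo, replace=False)
        extra = rng.choice(rr, n_wr, replace=True)
        out.append(np.concatenate([keep, extra]))
    return np.concatenate(out)


def bootstrap_rmip(line_means: pd.Series | pd.DataFrame,
                   genotypes: pd.DataFrame, families: pd.Series,
                   B: int = 100, p_entry: float = 5e-4,
                   p_exit: float | None = None, max_terms: int = 100,
                   collapse_cM: float | None = 3.0,
                   gmap: GeneticMap | None = None,
                   seed: int | np.random.Generator = 0) -> RMIPTable:
    """RMIP from family-stratified bootstrap of the stepwise QTL model.

    Each resample draws, within every family, 75% of its lines without
    replacement plus 25% with replacement (duplicates possible; family
    sizes preserved), then rebuilds the model with ``stepwise_select``.
    ``collapse_cM`` additionally reports windowed counts: the number of
    resamples in which one or more selected markers lie within the window
    of each map position (requires ``gmap``).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(line_means, pd.DataFrame):
        line_means = line_means.set_index("line")["value"]
    lines = line_means.index.intersection(genotypes.index).sort_values()
    lm = line_means.loc[lines]
    gn = genotypes.loc[lines]
    fm = families.loc[lines]
    fam_codes = pd.Categorical(fm.astype(str)).codes.astype(int)

    markers = genotypes.columns
    counts = pd.Series(0, index=markers, dtype=int)
    selected_sets: list[list[str]] = []
    for b in range(B):
        take = _stratified_resample(rng, fam_codes)
        # duplicates become frequency weights on unique lines
        uniq, cnt = np.unique(take, return_counts=True)
        sub = lines[uniq]
        model = stepwise_select(lm.loc[sub], gn.loc[sub], fm.loc[sub],
                                p_entry=p_entry, p_exit=p_exit,
                                max_terms=max_terms, gmap=gmap,
                                weights=pd.Series(cnt.astype(float),
                                                  index=sub))
        sel = model.markers
        selected_sets.append(sel)
        for mk in sel:
            counts[mk] += 1

    collapsed = None
    if collapse_cM is not None and gmap is not None:
        mdf = gmap.df.set_index("marker")
        chrom = mdf["chrom"]
        cM = mdf["cM"]
        collapsed = pd.Series(0, index=markers, dtype=int)
        for sel in selected_sets:
            if not sel:
                continue
            sel_chrom = chrom.loc[sel].to_numpy()
            sel_cM = cM.loc[sel].to_numpy()
            hit = np.zeros(len(markers), dtype=bool)
            mk_chrom = chrom.reindex(markers).to_numpy()
            mk_cM = cM.reindex(markers).to_numpy()
            for sc_, sm in zip(sel_chrom, sel_cM):
                hit |= (mk_chrom == sc_) & (np.abs(mk_cM - sm) <= collapse_cM)
            collapsed += hit
    return RMIPTable(counts=counts, collapsed=collapsed, B=B,
                     collapse_cM=collapse_cM)


def permutation_threshold(line_means: pd.Series | pd.DataFrame,
                          genotypes: pd.DataFrame, families: pd.Series,
                          n_perm: int = 1000, target_alpha: float = 0.05,
                          seed: int | np.random.Generator = 0) -> float:
    """Per-test entry threshold with family-wise error <= ``target_alpha``.

    Line means are permuted within families (family means preserved); the
    returned threshold is the ``target_alpha`` quantile of the minimum
    family-nested marginal p-value over markers across permutations, so
    selecting any marker at that threshold is a <= alpha-probability event
    under the no-QTL null.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if target_alpha >= 1.0:
        return 1.0
    rng = np.random.default_rng(seed)
    if isinstance(line_means, pd.DataFrame):
        line_means = line_means.set_index("line")["value"]
    lines = line_means.index.intersection(genotypes.index)
    y0 = line_means.loc[lines].to_numpy(float)
    G = genotypes.loc[lines].to_numpy(float)
    fam_codes = pd.Categorical(families.loc[lines].astype(str)).codes
    n_fam = fam_codes.max() + 1
    sc = _NestedScanner(y0, G, fam_codes.astype(int), n_fam)
    Q, _ = np.linalg.qr(sc.fam_design)
    rowsets = [np.nonzero(fam_codes == f)[0] for f in range(n_fam)]
    min_ps = np.empty(n_perm)
    for it in range(n_perm):
        y = y0.copy()
        for rr in rowsets:
            y[rr] = y[rr][rng.permutation(len(rr))]
        sc.y = y
        resid = y - Q @ (Q.T @ y)
        rss = float(resid @ resid)
        pv, _ = sc.scan(Q, resid, rss, Q.shape[1], set())
        min_ps[it] = pv.min()
    return float(np.quantile(min_ps, target_alpha))


def pleiotropy_test(model_A: QTLModel, trait_B_line_means: pd.Series | pd.DataFrame,
                    genotypes: pd.DataFrame, families: pd.Series,
                    min_families: int = 3) -> pd.DataFrame:
    """Correlation of per-family allele effects between two traits.

    Trait B is refit on model A's terms; for each QTL the Pearson
    correlation of the two traits' per-family effect vectors is computed
    with a t-test across families.  QTL segregating in fewer than
    ``min_families`` families are flagged (NaN correlation).
    """
    lm_B = trait_B_line_means
    if isinstance(lm_B, pd.DataFrame):
        lm_B = lm_B.set_index("line")["value"]
    lines = lm_B.index.intersection(genotypes.index)
    y, G, fam_codes, fams, markers, _ = _align(lm_B, genotypes, families)
    sc = _NestedScanner(y, G, fam_codes, len(fams))
    idx_of = {str(mk): i for i, mk in enumerate(markers)}
    terms = []
    for t in model_A.terms:
        j = idx_of[t.marker]
        terms.append((j, np.nonzero(sc.seg[:, j])[0]))
    X = sc.design(terms)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    pos = len(fams)
    rows = []
    for t, (j, fams_j) in zip(model_A.terms, terms):
        eff_B = {fams[f]: float(beta[pos + i]) for i, f in enumerate(fams_j)}
        pos += len(fams_j)
        shared = sorted(set(t.effects) & set(eff_B))
        if len(shared) < min_families:
            rows.append((t.marker, np.nan, np.nan, len(shared), True))
            continue
        a = np.array([t.effects[f] for f in shared])
        b = np.array([eff_B[f] for f in shared])
        if a.std() == 0 or b.std() == 0:
            rows.append((t.marker, np.nan, np.nan, len(shared), True))
            continue
        r, p = stats.pearsonr(a, b)
        rows.append((t.marker, float(r), float(p), len(shared), False))
    return pd.DataFrame(rows, columns=["marker", "correlation", "p_value",
                                       "n_families", "flagged"])


def partition_variance(model: QTLModel, line_means: pd.Series | pd.DataFrame,
                       genotypes: pd.DataFrame, families: pd.Series,
                       ) -> dict:
    """Sequential R^2 decomposition: family first, then each QTL in order."""
    y, G, fam_codes, fams, markers, _ = _align(line_means, genotypes,
                                               families)
    sc = _NestedScanner(y, G, fam_codes, len(fams))
    tss = float(((y - y.mean()) ** 2).sum())
    idx_of = {str(mk): i for i, mk in enumerate(markers)}

    def rss_of(terms):
        X = sc.design(terms)
        Q, _ = np.linalg.qr(X)
        r = y - Q @ (Q.T @ y)
        return float(r @ r)

    rss_fam = rss_of([])
    r2_family = 1.0 - rss_fam / tss
    terms = []
    delta = {}
    prev = rss_fam
    for t in model.terms:
        j = idx_of[t.marker]
        terms.append((j, np.nonzero(sc.seg[:, j])[0]))
        cur = rss_of(terms)
        delta[t.marker] = (prev - cur) / tss
        prev = cur
    return {"family_r2": r2_family,
            "family_qtl_r2": 1.0 - prev / tss,
            "per_term_delta_r2": delta}
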