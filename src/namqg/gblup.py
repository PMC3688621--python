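"""Genomic prediction: Van Raden kinship, GBLUP and cross-validation.

The identity-by-state genomic relationship matrix follows Van Raden:
``K = Z Z' / (2 sum_k p_k (1 - p_k))`` with ``Z`` the column-centered
allele-count matrix and ``p_k`` observed allele frequencies.  GBLUP fits
``y = 1 mu + g + e`` with ``g ~ N(0, K sigma_g^2)`` by REML on the
training lines (one eigendecomposition) and predicts held-out lines by
the conditional expectation through the cross-covariance blocks of the
full kinship — standard kriging, identical under the model to refitting
with missing records.

Cross-validation mirrors the combinatorial design used for NAM panels:
each repeat draws a fresh random partition of the panel into five
disjoint subsets (optionally stratified by family); for a calibration
fraction of k subsets all C(5, k) calibration sets are fit and the
complement predicted; accuracy is the coefficient of determination from
regressing observed line means on predictions, averaged over folds and
then repeats.  A family-nested QTL predictor (stepwise selection with
relaxed entry/exit p < 0.05 and at most 40 terms) is provided for
comparison with GBLUP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize

from .jointlinkage import stepwise_select

__all__ = ["KinshipMatrix", "CVResult", "vanraden", "gblup_fit_predict",
           "crossval", "qtl_predictor"]


@dataclass
class KinshipMatrix:
    """Line x line IBS relationship matrix with its allele frequencies."""

    matrix: pd.DataFrame
    freqs: pd.Series

    @property
    def lines(self) -> pd.Index:
        return self.matrix.index

    def to_numpy(self) -> np.ndarray:
        return self.matrix.to_numpy(float)


@dataclass
class CVResult:
    """Per-fold prediction accuracies and per-fraction summaries."""

    folds: pd.DataFrame          # fraction, repeat, fold, n_train, r2
    summary: pd.DataFrame        # fraction, mean_r2, sd_r2 (over repeats)
    predictor: str


def vanraden(snp_dosages: pd.DataFrame) -> KinshipMatrix:
    """Van Raden genomic relationship matrix from [0, 1] SNP dosages.

    Dosages are rescaled to allele counts in [0, 2]; monomorphic SNPs are
    excluded; ``K = Z Z' / (2 sum p(1-p))`` with Z column-centered counts.
    """
    D = snp_dosages.to_numpy(float)
    if np.nanmin(D) < 0 or np.nanmax(D) > 1:
        raise ValueError("dosages must lie in [0, 1]")
    X = 2.0 * D
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic")
    X = X[:, poly]
    p = p[poly]
    Z = X - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    K = Z @ Z.T / denom
    idx = snp_dosages.index
    return KinshipMatrix(
        matrix=pd.DataFrame(K, index=idx, columns=idx),
        freqs=pd.Series(p, index=snp_dosages.columns[poly]))


def _reml_ratio(yc: np.ndarray, lam: np.ndarray, ones_t: np.ndarray,
                yt: np.ndarray) -> tuple[float, float, float]:
    """Profile REML for y = 1 mu + g + e over the ratio sigma_g2/sigma_e2."""
    n = len(yt)

    def nll(log_ratio):
        r = np.exp(log_ratio)
        d = r * lam + 1.0
        xtx = (ones_t ** 2 / d).sum()
        mu = (ones_t * yt / d).sum() / xtx
        rss = ((yt - ones_t * mu) ** 2 / d).sum()
        s2 = rss / (n - 1)
        return 0.5 * (np.log(d).sum() + np.log(xtx) + (n - 1) * np.log(s2))

    res = optimize.minimize_scalar(nll, bounds=(-12, 12), method="bounded",
                                   options={"xatol": 1e-9})
    ratio = float(np.exp(res.x))
    d = ratio * lam + 1.0
    xtx = (ones_t ** 2 / d).sum()
    mu = float((ones_t * yt / d).sum() / xtx)
    s2e = float(((yt - ones_t * mu) ** 2 / d).sum() / (n - 1))
    return ratio, mu, s2e


def gblup_fit_predict(line_means_train: pd.Series, kinship: KinshipMatrix,
                      predict_ids: pd.Index | list) -> pd.Series:
    """GBLUP: REML on the training lines, kriging for held-out lines.

    Returns predicted line means (mu + predicted genetic value) for
    ``predict_ids``.  When the genetic variance is estimated at the zero
    boundary the predictions collapse to the training mean and the result
    is flagged via ``Series.attrs['boundary']``.
    """
    train = pd.Index(line_means_train.index)
    predict_ids = pd.Index(predict_ids)
    missing = train.difference(kinship.lines)
    if len(missing):
        raise ValueError(f"training ids absent from kinship: {missing[:3]}")
    y = line_means_train.to_numpy(float)
    Ktt = kinship.matrix.loc[train, train].to_numpy(float)
    lam, U = np.linalg.eigh(Ktt)
    lam = np.maximum(lam, 0.0)
    yt = U.T @ y
    ones_t = U.T @ np.ones(len(y))
    ratio, mu, s2e = _reml_ratio(y, lam, ones_t, yt)
    out_attrs = {"boundary": False, "ratio": ratio, "mu": mu}
    if ratio < 1e-8:
        warnings.warn("genetic variance at zero boundary; predicting mean",
                      stacklevel=2)
        out_attrs["boundary"] = True
        pred = pd.Series(mu, index=predict_ids)
        pred.attrs.update(out_attrs)
        return pred
    d = ratio * lam + 1.0
    # alpha = V^-1 (y - mu) with V = ratio*K + I (sigma_e^2 cancels)
    alpha = U @ ((yt - ones_t * mu) / d)
    Kpt = kinship.matrix.loc[predict_ids, train].to_numpy(float)
    g = ratio * (Kpt @ alpha)
    pred = pd.Series(mu + g, index=predict_ids)
    pred.attrs.update(out_attrs)
    return pred


def qtl_predictor(train_line_means: pd.Series, genotypes: pd.DataFrame,
                  families: pd.Series, predict_ids: pd.Index | list,
                  p: float = 0.05, max_qtl: int = 40,
                  gmap=None) -> pd.Series:
    """Family-nested QTL prediction: stepwise model on the training set.

    Entry/exit are relaxed to ``p`` and at most ``max_qtl`` family-nested
    terms are permitted; a family term is always included.  Held-out
    lines are predicted from their family intercept plus the selected
    nested effects; lines of families absent from training fall back to
    the training grand mean (flagged in ``attrs``).
    """
    with warnings.catch_warnings():
        # at relaxed thresholds, near-duplicate linked markers routinely
        # collide in the design; the drop-and-continue path is expected
        warnings.filterwarnings("ignore", message=".*duplicates the current")
        model = stepwise_select(train_line_means, genotypes, families,
                                p_entry=p, p_exit=p, max_terms=max_qtl,
                                gmap=gmap)
    predict_ids = pd.Index(predict_ids)
    fam = families.loc[predict_ids].astype(str)
    grand = float(train_line_means.mean())
    vals = np.array([model.family_intercepts.get(f, grand) for f in fam])
    unseen = [f for f in fam.unique() if f not in model.family_intercepts]
    for t in model.terms:
        x = genotypes.loc[predict_ids, t.marker].to_numpy(float)
        eff = np.array([t.effects.get(f, 0.0) for f in fam])
        vals = vals + x * eff
    pred = pd.Series(vals, index=predict_ids)
    pred.attrs["n_terms"] = len(model.terms)
    pred.attrs["unseen_families"] = unseen
    return pred


def _accuracy(observed: pd.Series, predicted: pd.Series) -> float:
    """Coefficient of determination of observed regressed on predicted.

    For a simple linear regression with intercept this equals the squared
    Pearson correlation; degenerate (constant) predictions score 0.
    """
    o = observed.to_numpy(float)
    p = predicted.loc[observed.index].to_numpy(float)
    if np.std(p) <= 1e-12 or np.std(o) <= 1e-12:
        return 0.0
    r = np.corrcoef(o, p)[0, 1]
    return float(r ** 2)


def _partition(rng: np.random.Generator, lines: pd.Index,
               families: pd.Series | None, n_subsets: int) -> list[np.ndarray]:
    """Random split into ``n_subsets`` disjoint, exhaustive subsets."""
    idx = np.arange(len(lines))
    assign = np.empty(len(lines), dtype=int)
    if families is None:
        perm = rng.permutation(idx)
        for s, chunk in enumerate(np.array_split(perm, n_subsets)):
            assign[chunk] = s
    else:
        fam = families.loc[lines].astype(str).to_numpy()
        pooled = []
        for f in np.unique(fam):
            rr = idx[fam == f]
            if len(rr) < n_subsets:
                warnings.warn(f"family {f} smaller than {n_subsets}; pooled",
                              stacklevel=2)
                pooled.extend(rr)
                continue
            perm = rng.permutation(rr)
            # rotate subset order per family so sizes balance
            off = rng.integers(n_subsets)
            for s, chunk in enumerate(np.array_split(perm, n_subsets)):
                assign[chunk] = (s + off) % n_subsets
        if pooled:
            perm = rng.permutation(np.array(pooled))
            for s, chunk in enumerate(np.array_split(perm, n_subsets)):
                assign[chunk] = s
    return [idx[assign == s] for s in range(n_subsets)]


def crossval(line_means: pd.Series, kinship: KinshipMatrix | None = None,
             genotypes: pd.DataFrame | None = None,
             families: pd.Series | None = None,
             n_subsets: int = 5, fractions: tuple[int, ...] = (1, 2, 3, 4),
             repeats: int = 20, stratify_by_family: bool = True,
             predictor: str = "gblup", qtl_p: float = 0.05,
             qtl_max: int = 40, gmap=None,
             seed: int | np.random.Generator = 0) -> CVResult:
    """Combinatorial cross-validated prediction accuracy.

    For every repeat a fresh ``n_subsets``-way partition is drawn; for
    each calibration fraction ``k`` all C(n_subsets, k) combinations of
    subsets calibrate the model and the complement is predicted.
    Accuracies (R^2 of observed-on-predicted regression) are averaged
    over folds within a repeat and then summarized over repeats.
    """
    if predictor not in ("gblup", "qtl"):
        raise ValueError("predictor must be 'gblup' or 'qtl'")
    if predictor == "gblup" and kinship is None:
        raise ValueError("gblup predictor needs a kinship matrix")
    if predictor == "qtl" and (genotypes is None or families is None):
        raise ValueError("qtl predictor needs genotypes and families")
    rng = np.random.default_rng(seed)
    lines = pd.Index(line_means.index)
    strat = families if (stratify_by_family and families is not None) else None
    rows = []
    for rep in range(repeats):
        subsets = _partition(rng, lines, strat, n_subsets)
        for k in fractions:
            for fold_i, combo in enumerate(combinations(range(n_subsets), k)):
                train_idx = np.concatenate([subsets[s] for s in combo])
                test_idx = np.concatenate(
                    [subsets[s] for s in range(n_subsets) if s not in combo])
                train, test = lines[train_idx], lines[test_idx]
                if predictor == "gblup":
                    pred = gblup_fit_predict(line_means.loc[train], kinship,
                                             test)
                else:
                    pred = qtl_predictor(line_means.loc[train], genotypes,
                                         families, test, p=qtl_p,
                                         max_qtl=qtl_max, gmap=gmap)
                r2 = _accuracy(line_means.loc[test], pred)
                rows.append((k, rep, fold_i, len(train), r2))
    folds = pd.DataFrame(rows, columns=["fraction", "repeat", "fold",
                                        "n_train", "r2"])
    per_rep = folds.groupby(["fraction", "repeat"])["r2"].mean().reset_index()
    summary = per_rep.groupby("fraction")["r2"].agg(["mean", "std"]) \
        .rename(columns={"mean": "mean_r2", "std": "sd_r2"}).reset_index()
    return CVResult(folds=folds, summary=summary, predictor=predictor)
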