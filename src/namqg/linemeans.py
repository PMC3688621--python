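"""Variance partitioning, line means and line-means heritability.

The workflow mirrors standard multi-environment field-trial analysis of
RIL panels: plot values are winsorized per environment, a mixed model is
fit by REML with genetic terms (family, RIL within family with per-family
variances), environmental terms (environment, family x environment,
RIL x environment, block/row/column) and optionally an AR1 x AR1 spatial
residual per environment, and shrunken (BLUP) or unshrunken (BLUE) line
means are predicted for downstream mapping and genomic prediction.

Broad-sense heritability on a line-means basis divides the genetic
variance between lines by the variance of a line mean, with interaction
components divided by the harmonic mean of the number of environments per
family/RIL and the average residual variance divided by the harmonic mean
of the number of plots per RIL.

Two model backends are used.  A complete line x environment layout with
one plot per cell and no requested field-design terms goes through the
fast rotated-likelihood fitter (``reml.reml_crossed``), which scales to
NAM-size panels.  Anything else (replicate plots, block/row/column terms,
spatial residuals, unbalanced layouts) goes through the general dense
engine (``reml.reml_dense``), intended for moderate problem sizes.  With a
single plot per line and environment the RIL x environment and residual
variances are confounded; the fast path reports their sum as the residual
and zero for RIL x environment, which leaves line-means heritability
unchanged because the two denominators coincide in that design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reml
from .simulate import PlotTable

__all__ = ["winsorize", "fit_multienv_model", "fit_single_env_model",
           "predict_line_means", "heritability_line_means",
           "VarianceComponents", "HeritabilityEstimate", "ModelSpec"]


@dataclass
class ModelSpec:
    """Which terms enter the multi-environment mixed model."""

    trait: str
    per_family_ril: bool = True
    env_terms: tuple[str, ...] = ()          # subset of ("block","row","col")
    spatial: bool = False                     # AR1 x AR1 residual per env
    covariate: str | None = None              # covariate trait (random reg.)
    backward: bool = False                    # LRT backward elimination
    backward_alpha: float = 0.05
    method: str = "auto"                      # auto | crossed | dense


@dataclass
class VarianceComponents:
    """REML variance-component estimates with design bookkeeping."""

    trait: str
    family: float
    ril: dict[str, float]                     # per family
    env: float
    fam_env: float
    ril_env: float
    block: dict[str, float] = field(default_factory=dict)   # per env
    row: dict[str, float] = field(default_factory=dict)
    col: dict[str, float] = field(default_factory=dict)
    resid: dict[str, float] = field(default_factory=dict)   # per env
    ar1: dict[str, tuple[float, float]] = field(default_factory=dict)
    covariate: float = 0.0
    loglik: float = float("nan")
    mu: float = 0.0
    converged: bool = True
    retained: list[str] = field(default_factory=list)
    # design bookkeeping for heritability and BLUP
    lines: pd.Index | None = None
    line_family: pd.Series | None = None
    n_env_per_line: pd.Series | None = None
    n_env_per_family: pd.Series | None = None
    n_plots_per_line: pd.Series | None = None
    _backend: object | None = None
    _backend_kind: str = ""

    @property
    def mean_ril(self) -> float:
        return float(np.mean(list(self.ril.values())))

    @property
    def mean_resid(self) -> float:
        return float(np.mean(list(self.resid.values())))


@dataclass
class HeritabilityEstimate:
    """Line-means broad-sense heritability and its ingredients."""

    numerator: float
    denominator: float
    h_env: float
    h_plots: float
    H2: float
    level: str = "panel"


def _harmonic(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    if np.any(x <= 0):
        raise ValueError("harmonic mean needs positive counts")
    return float(len(x) / np.sum(1.0 / x))


# ---------------------------------------------------------------------------
# winsorization
# ---------------------------------------------------------------------------


def winsorize(plots: PlotTable | pd.DataFrame, k_sd: float = 3.0,
              ) -> tuple[PlotTable, int]:
    """Clip plot values beyond ``mean +- k_sd * sd`` of their environment.

    Returns the winsorized table and the number of modified records.
    Limits are computed separately per (trait, environment).
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    df = (plots.df if isinstance(plots, PlotTable) else plots).copy()
    n_mod = 0
    for (trait, env), sub in df.groupby(["trait", "env"]):
        if len(sub) == 0:
            raise ValueError(f"empty environment {env} for {trait}")
        m, s = sub["value"].mean(), sub["value"].std(ddof=1)
        if not np.isfinite(s) or s == 0 or not np.isfinite(k_sd):
            continue
        lo, hi = m - k_sd * s, m + k_sd * s
        clipped = sub["value"].clip(lo, hi)
        n_mod += int((clipped != sub["value"]).sum())
        df.loc[sub.index, "value"] = clipped
    out = PlotTable(df=df, truth=plots.truth if isinstance(plots, PlotTable)
                    else None)
    return out, n_mod


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


def _pivot_complete(df: pd.DataFrame) -> tuple[pd.DataFrame, bool]:
    """Pivot plot records to a line x env table; flag completeness."""
    counts = df.groupby(["line", "env"]).size()
    if (counts != 1).any():
        return pd.DataFrame(), False
    wide = df.pivot(index="line", columns="env", values="value")
    return wide, not wide.isna().any().any()


def _indicator(codes: pd.Series) -> np.ndarray:
    cats = pd.Categorical(codes)
    Z = np.zeros((len(codes), len(cats.categories)))
    Z[np.arange(len(codes)), cats.codes] = 1.0
    return Z


def fit_multienv_model(plots: PlotTable | pd.DataFrame, spec: ModelSpec,
                       ) -> VarianceComponents:
    """REML fit of the multi-environment mixed model for one trait."""
    full_df = (plots.df if isinstance(plots, PlotTable) else plots)
    df = full_df[full_df["trait"] == spec.trait]
    if df.empty:
        raise ValueError(f"no records for trait {spec.trait!r}")
    envs = sorted(df["env"].unique())
    fam_of_line = (df.drop_duplicates("line").set_index("line")["family"]
                   .sort_index())
    if fam_of_line.nunique() < 1 or len(fam_of_line) < 2:
        raise ValueError("need at least 2 lines")

    n_env_line = df.groupby("line")["env"].nunique()
    n_env_fam = df.groupby("family")["env"].nunique()
    n_plots_line = df.groupby("line").size()

    wide, complete = _pivot_complete(df)
    use_crossed = (spec.method == "crossed"
                   or (spec.method == "auto" and complete
                       and not spec.env_terms and not spec.spatial))
    if spec.method == "crossed" and not complete:
        raise ValueError("crossed backend requires a complete line x env grid")

    if use_crossed:
        return _fit_crossed(df, full_df, wide, fam_of_line, spec, envs,
                            n_env_line, n_env_fam, n_plots_line)
    return _fit_dense(df, fam_of_line, spec, envs,
                      n_env_line, n_env_fam, n_plots_line,
                      plots.truth if isinstance(plots, PlotTable) else None)


def _covariate_line_means(plots_df: pd.DataFrame, covariate: str,
                          lines: pd.Index) -> np.ndarray:
    sub = plots_df[plots_df["trait"] == covariate]
    if sub.empty:
        raise ValueError(f"covariate trait {covariate!r} absent from plots")
    lm = sub.groupby("line")["value"].mean().reindex(lines)
    if lm.isna().any():
        raise ValueError("covariate line means missing for some lines")
    return lm.to_numpy()


def _fit_crossed(df, full_df, wide, fam_of_line, spec, envs,
                 n_env_line, n_env_fam, n_plots_line) -> VarianceComponents:
    fam_sorted = fam_of_line.sort_values(kind="stable")
    order = fam_sorted.index
    Y = wide.loc[order, envs].to_numpy(float)
    fams = list(pd.unique(fam_sorted))
    sizes = fam_sorted.value_counts().loc[fams].to_numpy()
    cov = None
    if spec.covariate is not None:
        cov = _covariate_line_means(full_df, spec.covariate, pd.Index(order))
    fit = reml.reml_crossed(Y, sizes, per_family_ril=spec.per_family_ril,
                            covariate=cov, families=fams)
    ril = {f: float(v) for f, v in zip(fams, fit.sigma_ril)}
    vc = VarianceComponents(
        trait=spec.trait, family=fit.sigma_fam, ril=ril, env=fit.sigma_env,
        fam_env=fit.sigma_fam_env, ril_env=0.0,
        resid={e: fit.sigma_resid for e in envs},
        covariate=fit.sigma_cov, loglik=fit.loglik, mu=fit.mu,
        converged=fit.converged,
        retained=["family", "ril", "env", "fam_env", "resid"],
        lines=pd.Index(order), line_family=fam_sorted,
        n_env_per_line=n_env_line, n_env_per_family=n_env_fam,
        n_plots_per_line=n_plots_line,
        _backend=fit, _backend_kind="crossed")
    return vc


def _dense_terms(df: pd.DataFrame, spec: ModelSpec, envs: list[str],
                 env_terms: tuple[str, ...], spatial: bool,
                 cov_vals: np.ndarray | None):
    """Design matrices for the dense backend."""
    terms: dict[str, np.ndarray] = {}
    fam = df["family"].astype(str)
    line = df["line"].astype(str)
    env = df["env"].astype(str)
    terms["family"] = _indicator(fam)
    if spec.per_family_ril:
        for f in sorted(fam.unique()):
            mask = (fam == f).to_numpy()
            sub_lines = line[mask]
            Z = np.zeros((len(df), sub_lines.nunique()))
            codes = pd.Categorical(line[mask]).codes
            Z[np.nonzero(mask)[0], codes] = 1.0
            terms[f"ril:{f}"] = Z
    else:
        terms["ril"] = _indicator(line)
    if len(envs) > 1:
        terms["env"] = _indicator(env)
        terms["fam_env"] = _indicator(fam.str.cat(env, sep=":"))
        terms["ril_env"] = _indicator(line.str.cat(env, sep=":"))
    for t in env_terms:
        for e in envs:
            mask = (env == e).to_numpy()
            Z = np.zeros((len(df), df.loc[mask, t].nunique()))
            codes = pd.Categorical(df.loc[mask, t]).codes
            Z[np.nonzero(mask)[0], codes] = 1.0
            terms[f"{t}:{e}"] = Z
    if cov_vals is not None:
        terms["covariate"] = cov_vals[:, None]
    groups = {}
    for e in envs:
        rows = np.nonzero((env == e).to_numpy())[0]
        if spatial:
            groups[e] = reml.ResidGroup(
                rows=rows, kind="ar1",
                grid_row=df.loc[env == e, "row"].to_numpy(),
                grid_col=df.loc[env == e, "col"].to_numpy())
        else:
            groups[e] = reml.ResidGroup(rows=rows, kind="iid")
    return terms, groups


def lrt_pvalue(ll_full: float, ll_reduced: float, df: int = 1,
               boundary: bool = True) -> float:
    """Likelihood-ratio p-value; boundary=True uses the 50:50 chi2 mixture
    appropriate for testing a variance component against zero."""
    from scipy import stats
    stat = max(0.0, 2.0 * (ll_full - ll_reduced))
    p = stats.chi2.sf(stat, df)
    if boundary and df == 1:
        p = 0.5 * p if stat > 0 else 1.0
    return float(p)


def _fit_dense(df, fam_of_line, spec, envs, n_env_line, n_env_fam,
               n_plots_line, truth) -> VarianceComponents:
    df = df.sort_values(["family", "line", "env"], kind="stable"
                        ).reset_index(drop=True)
    y = df["value"].to_numpy(float)
    X = np.ones((len(df), 1))
    cov_vals = None
    if spec.covariate is not None:
        raise ValueError("covariate adjustment requires the crossed backend")

    env_terms = tuple(spec.env_terms)
    spatial = spec.spatial

    def fit_with(et, sp):
        terms, groups = _dense_terms(df, spec, envs, et, sp, cov_vals)
        return reml.reml_dense(y, X, terms, groups), terms

    fit, terms = fit_with(env_terms, spatial)
    retained = list(env_terms) + (["spatial"] if spatial else [])
    if spec.backward:
        # drop non-significant environmental terms one at a time (LRT)
        changed = True
        while changed:
            changed = False
            candidates = list(env_terms) + (["spatial"] if spatial else [])
            worst, worst_p, worst_fit = None, -1.0, None
            for t in candidates:
                et = tuple(x for x in env_terms if x != t)
                sp = spatial and t != "spatial"
                f2, _ = fit_with(et, sp)
                p = lrt_pvalue(fit.loglik, f2.loglik)
                if p > worst_p:
                    worst, worst_p, worst_fit, worst_et, worst_sp = \
                        t, p, f2, et, sp
            if worst is not None and worst_p > spec.backward_alpha:
                env_terms, spatial, fit = worst_et, worst_sp, worst_fit
                changed = True
        retained = list(env_terms) + (["spatial"] if spatial else [])

    fams = sorted(fam_of_line.unique())
    if spec.per_family_ril:
        ril = {f: fit.variances.get(f"ril:{f}", 0.0) for f in fams}
    else:
        ril = {f: fit.variances.get("ril", 0.0) for f in fams}
    vc = VarianceComponents(
        trait=spec.trait, family=fit.variances.get("family", 0.0), ril=ril,
        env=fit.variances.get("env", 0.0),
        fam_env=fit.variances.get("fam_env", 0.0),
        ril_env=fit.variances.get("ril_env", 0.0),
        block={e: fit.variances.get(f"block:{e}", np.nan) for e in envs
               if f"block:{e}" in fit.variances},
        row={e: fit.variances.get(f"row:{e}", np.nan) for e in envs
             if f"row:{e}" in fit.variances},
        col={e: fit.variances.get(f"col:{e}", np.nan) for e in envs
             if f"col:{e}" in fit.variances},
        resid={e: fit.resid[e] for e in envs},
        ar1={e: fit.ar1.get(e, (0.0, 0.0)) for e in envs if e in fit.ar1},
        loglik=fit.loglik, mu=float(fit.beta[0]), converged=fit.converged,
        retained=["family", "ril", "env", "fam_env", "ril_env"] + retained,
        lines=pd.Index(sorted(df["line"].unique())),
        line_family=fam_of_line,
        n_env_per_line=n_env_line, n_env_per_family=n_env_fam,
        n_plots_per_line=n_plots_line,
        _backend=(fit, df), _backend_kind="dense")
    if not fit.converged:
        vc.retained.append("NONCONVERGED")
    return vc


def fit_single_env_model(plots: PlotTable | pd.DataFrame, env: str,
                         spec: ModelSpec) -> VarianceComponents:
    """Per-environment mixed model (bottom-up stage of model building)."""
    df = (plots.df if isinstance(plots, PlotTable) else plots)
    sub = df[df["env"] == env]
    if sub.empty:
        raise ValueError(f"no records for environment {env!r}")
    return fit_multienv_model(
        PlotTable(df=sub.copy()), ModelSpec(
            trait=spec.trait, per_family_ril=spec.per_family_ril,
            env_terms=spec.env_terms, spatial=spec.spatial,
            backward=spec.backward, backward_alpha=spec.backward_alpha,
            method="dense"))


# ---------------------------------------------------------------------------
# line means
# ---------------------------------------------------------------------------


def predict_line_means(fit: VarianceComponents,
                       plots: PlotTable | pd.DataFrame | None = None,
                       mode: str = "BLUP") -> pd.DataFrame:
    """Line means from the fitted model.

    BLUP: conditional expectation of each line's genetic value
    (family + RIL effect) added to the grand mean — shrunken toward family
    and grand means.  BLUE: unshrunken two-way (line, environment) fixed
    effect estimate; with a balanced single-environment design this is the
    arithmetic plot mean per line.
    """
    if mode not in ("BLUP", "BLUE"):
        raise ValueError("mode must be BLUP or BLUE")
    if mode == "BLUP":
        if fit._backend_kind == "crossed":
            u = reml.crossed_blup(fit._backend)
            vals = fit.mu + u
            out = pd.DataFrame({"line": fit.lines, "value": vals})
        elif fit._backend_kind == "dense":
            dense, df = fit._backend
            # generic BLUP: u = G Z' P y for the genetic terms
            fam = df["family"].astype(str)
            line = df["line"].astype(str)
            lines = pd.Index(sorted(line.unique()))
            Py = dense.Py
            Zl = _indicator(line)
            cats = pd.Categorical(line).categories
            fam_of = (df.drop_duplicates("line").set_index("line")["family"]
                      .reindex(cats))
            s_ril = np.array([fit.ril.get(f, 0.0) for f in fam_of])
            u_ril = s_ril * (Zl.T @ Py)
            Zf = _indicator(fam)
            fcats = pd.Categorical(fam).categories
            u_fam = fit.family * (Zf.T @ Py)
            fam_idx = pd.Index(fcats).get_indexer(fam_of)
            vals = fit.mu + u_fam[fam_idx] + u_ril
            out = pd.DataFrame({"line": cats, "value": vals})
        else:
            raise ValueError("fit carries no backend for BLUP")
        out["family"] = fit.line_family.reindex(out["line"]).to_numpy()
        out["trait"] = fit.trait
        return out[["line", "family", "trait", "value"]].reset_index(drop=True)

    # BLUE: two-way fixed-effects (line + env) by alternating demeaning
    if plots is None:
        raise ValueError("BLUE needs the plot table")
    df = (plots.df if isinstance(plots, PlotTable) else plots)
    df = df[df["trait"] == fit.trait]
    y = df["value"].to_numpy(float)
    line = pd.Categorical(df["line"])
    env = pd.Categorical(df["env"])
    a = np.zeros(len(line.categories))   # line effects
    b = np.zeros(len(env.categories))    # env effects
    mu = y.mean()
    for _ in range(200):
        resid = y - mu - b[env.codes]
        a_new = pd.Series(resid).groupby(line.codes).mean().to_numpy()
        resid = y - mu - a_new[line.codes]
        b_new = pd.Series(resid).groupby(env.codes).mean().to_numpy()
        b_new -= b_new.mean()
        if np.max(np.abs(a_new - a)) + np.max(np.abs(b_new - b)) < 1e-12:
            a, b = a_new, b_new
            break
        a, b = a_new, b_new
    vals = mu + a
    out = pd.DataFrame({"line": line.categories, "value": vals})
    out["family"] = fit.line_family.reindex(out["line"]).to_numpy()
    out["trait"] = fit.trait
    return out[["line", "family", "trait", "value"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------


def heritability_line_means(fit: VarianceComponents,
                            family: str | None = None) -> HeritabilityEstimate:
    """Broad-sense heritability on a line-means basis.

    Across the panel the numerator is the family variance plus the
    arithmetic mean of the per-family RIL variances; within a family it is
    that family's RIL variance.  The denominator adds family x environment
    and RIL x environment divided by the harmonic mean of the number of
    environments (per family and per RIL respectively) and the mean
    residual variance divided by the harmonic mean of plots per RIL.
    """
    h_env_fam = _harmonic(fit.n_env_per_family.to_numpy())
    h_env_ril = _harmonic(fit.n_env_per_line.to_numpy())
    h_plots = _harmonic(fit.n_plots_per_line.to_numpy())
    if family is None:
        num = fit.family + fit.mean_ril
        level = "panel"
    else:
        if family not in fit.ril:
            raise KeyError(f"family {family!r} not in fit")
        num = fit.ril[family]
        level = family
    den = (num + fit.fam_env / h_env_fam + fit.ril_env / h_env_ril
           + fit.mean_resid / h_plots)
    if den <= 0:
        raise ZeroDivisionError("nonpositive heritability denominator")
    return HeritabilityEstimate(numerator=num, denominator=den,
                                h_env=h_env_ril, h_plots=h_plots,
                                H2=num / den, level=level)
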