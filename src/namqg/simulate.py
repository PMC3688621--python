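"""Synthetic NAM-style populations and multi-environment field trials.

This module generates the inputs the rest of the pipeline consumes: a
genetic map, a panel of biparental RIL families sharing one common parent,
a trait architecture (QTL with family-specific allele series plus polygenic
and environmental variance components), and plot-level phenotypes laid out
on field grids with block/row/column effects and a separable AR1 x AR1
spatial residual.

RIL genomes are simulated directly at the inbred-line (F-infinity)
recombination fraction ``R = 2r / (1 + 2r)``, where ``r`` is the
single-meiosis recombination fraction obtained from the genetic distance
through the Haldane map function.  Each chromosome is a two-state Markov
walk over the marker positions, so every RIL is an exact mosaic of its two
parents.  Intermated (IBM-style) families are modelled by expanding the
genetic map by a configurable factor before computing ``R``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

COMMON_PARENT = "CP"

__all__ = [
    "GeneticMap",
    "Population",
    "TraitSpec",
    "TraitArchitecture",
    "PlotTable",
    "simulate_map",
    "simulate_rils",
    "assign_architecture",
    "simulate_plots",
    "haldane_r",
    "ril_recombination_fraction",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Marker map: one row per marker with chromosome, cM and bp position.

    ``df`` columns: ``marker`` (unique str), ``chrom`` (int), ``cM``
    (float, nondecreasing within chromosome), ``bp`` (int, nondecreasing
    within chromosome).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["marker", "chrom", "cM", "bp"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValueError(f"map missing columns: {missing}")
        if self.df["marker"].duplicated().any():
            dup = self.df["marker"][self.df["marker"].duplicated()].iloc[0]
            raise ValueError(f"duplicate marker name: {dup}")
        for chrom, sub in self.df.groupby("chrom"):
            if not (np.diff(sub["cM"].to_numpy()) >= 0).all():
                raise ValueError(f"cM positions decrease on chromosome {chrom}")
            if not (np.diff(sub["bp"].to_numpy()) >= 0).all():
                raise ValueError(f"bp positions decrease on chromosome {chrom}")

    @property
    def markers(self) -> pd.Index:
        return pd.Index(self.df["marker"])

    @property
    def n_markers(self) -> int:
        return len(self.df)

    def chromosomes(self) -> list[int]:
        return sorted(self.df["chrom"].unique())

    def chrom_slice(self, chrom: int) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]


@dataclass
class Population:
    """A panel of biparental RIL families sharing one common parent.

    ``geno`` holds founder dosages at linkage markers: 0 = common-parent
    allele, 1 = alternate-parent allele; fractional values may appear after
    imputation.  ``snp`` holds dosages of the "1" allele at dense SNPs.
    ``founder_snps`` gives each founder's SNP allele (rows indexed by
    founder name; the common parent plus one alternate parent per family).
    """

    family: pd.Series
    geno: pd.DataFrame
    linkage_map: GeneticMap
    snp: pd.DataFrame | None = None
    snp_map: GeneticMap | None = None
    founder_snps: pd.DataFrame | None = None
    snp_origin: pd.DataFrame | None = None  # true founder origin at SNPs

    @property
    def lines(self) -> pd.Index:
        return self.geno.index

    @property
    def families(self) -> list[str]:
        return sorted(self.family.unique())

    def family_of(self, fam: str) -> pd.Index:
        return self.family.index[self.family == fam]

    def alternate_parent(self, fam: str) -> str:
        return f"AP_{fam}"


@dataclass
class TraitSpec:
    """Architecture of one trait: QTL effects plus variance targets.

    ``qtl`` maps marker index (into the linkage map) to a per-family effect
    of the alternate-parent allele; a positive ``allele_series_sd`` at
    construction spreads effects around the shared mean, producing sign
    heterogeneity across families.  Variances are on the plot-measurement
    scale; ``plant`` is the per-plant error variance (a plot of ``n``
    plants contributes ``plant / n`` to the plot value).
    """

    qtl: dict[int, dict[str, float]] = field(default_factory=dict)
    family: float = 0.0
    ril: Mapping[str, float] | float = 0.0
    env: float = 0.0
    fam_env: float = 0.0
    ril_env: float = 0.0
    block: float = 0.0
    row: float = 0.0
    col: float = 0.0
    spatial: float = 0.0
    plant: float = 1.0
    rho_row: float = 0.0
    rho_col: float = 0.0
    mean: float = 0.0

    def ril_var(self, fam: str) -> float:
        if isinstance(self.ril, Mapping):
            return float(self.ril[fam])
        return float(self.ril)

    def validate(self) -> None:
        for name in ("family", "env", "fam_env", "ril_env", "block", "row",
                     "col", "spatial", "plant"):
            if getattr(self, name) < 0:
                raise ValueError(f"variance {name!r} must be >= 0")
        rils = (self.ril.values() if isinstance(self.ril, Mapping)
                else [self.ril])
        if any(v < 0 for v in rils):
            raise ValueError("RIL-within-family variances must be >= 0")
        for rho in (self.rho_row, self.rho_col):
            if not -1.0 < rho < 1.0:
                raise ValueError("AR1 parameters must lie in (-1, 1)")


@dataclass
class TraitArchitecture:
    """Trait specs plus the genetic correlation among the traits' line values."""

    traits: dict[str, TraitSpec]
    genetic_corr: pd.DataFrame | None = None  # trait x trait

    def __post_init__(self) -> None:
        for spec in self.traits.values():
            spec.validate()
        if self.genetic_corr is not None:
            C = self.genetic_corr.to_numpy(float)
            if not np.allclose(C, C.T):
                raise ValueError("genetic correlation matrix must be symmetric")
            w = np.linalg.eigvalsh(C)
            if w.min() < -1e-8:
                raise ValueError("genetic correlation matrix must be PSD")

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits)


@dataclass
class PlotTable:
    """Plot-level phenotype records plus (for simulations) the ground truth.

    ``df`` columns: line, family, env, row, col, block, trait, value,
    n_plants.  ``truth`` (optional) records the simulated effects: per-trait
    line genetic values, family effects, interaction draws and the target
    variance components, for method-of-moments checks.
    """

    df: pd.DataFrame
    truth: dict | None = None

    REQUIRED = ("line", "family", "env", "row", "col", "block", "trait",
                "value", "n_plants")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"plot table missing columns: {missing}")
        # no duplicate grid cells within an environment
        cells = self.df[["env", "trait", "row", "col"]]
        if cells.duplicated().any():
            raise ValueError("duplicate (env, row, col) plot cells")


# ---------------------------------------------------------------------------
# recombination helpers
# ---------------------------------------------------------------------------


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Single-meiosis recombination fraction from Haldane's map function."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, float) / 100.0))


def ril_recombination_fraction(d_cM: np.ndarray | float,
                               expansion: float = 1.0) -> np.ndarray | float:
    """Expected recombinant fraction between two loci in inbred RILs.

    ``R = 2r / (1 + 2r)`` with ``r`` from Haldane's function applied to the
    (optionally expanded, for intermated families) map distance.
    """
    r = haldane_r(np.asarray(d_cM, float) * expansion)
    return 2.0 * r / (1.0 + 2.0 * r)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def simulate_map(n_chromosomes: int, n_markers: int, cM_length: float,
                 bp_length: float, seed: int | np.random.Generator,
                 prefix: str = "m") -> GeneticMap:
    """Random marker map: markers spread uniformly with jitter, then sorted.

    ``n_markers`` is the total across chromosomes (split as evenly as
    possible); ``cM_length`` / ``bp_length`` apply per chromosome.
    """
    if cM_length <= 0 or bp_length <= 0:
        raise ValueError("map lengths must be positive")
    if n_markers < 2 * n_chromosomes:
        raise ValueError("need at least 2 markers per chromosome")
    rng = np.random.default_rng(seed)
    per = np.full(n_chromosomes, n_markers // n_chromosomes)
    per[: n_markers % n_chromosomes] += 1
    rows = []
    i = 0
    for c in range(1, n_chromosomes + 1):
        m = int(per[c - 1])
        # uniform spread + jitter, kept sorted
        cM = np.sort(rng.uniform(0, cM_length, m))
        frac = cM / cM_length
        bp = np.sort(np.round(frac * bp_length
                              + rng.normal(0, bp_length * 0.01, m)))
        bp = np.maximum.accumulate(np.clip(bp, 0, bp_length)).astype(np.int64)
        for j in range(m):
            rows.append((f"{prefix}{i + j + 1:05d}", c, float(cM[j]), int(bp[j])))
        i += m
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chrom", "cM", "bp"]))


def _mosaic(rng: np.random.Generator, n_lines: int, cM: np.ndarray,
            chrom: np.ndarray, expansion: float) -> np.ndarray:
    """Founder-origin mosaic (0/1) for ``n_lines`` RILs over ordered loci."""
    n_loci = len(cM)
    origin = np.empty((n_lines, n_loci), dtype=np.uint8)
    start = 0
    for c in np.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        m = len(idx)
        gaps = np.diff(cM[idx])
        R = np.asarray(ril_recombination_fraction(gaps, expansion), float)
        flips = np.empty((n_lines, m), dtype=np.uint8)
        flips[:, 0] = rng.random(n_lines) < 0.5
        flips[:, 1:] = rng.random((n_lines, m - 1)) < R[None, :]
        origin[:, idx] = np.bitwise_xor.accumulate(flips, axis=1)
        start += m
    return origin


def simulate_rils(linkage_map: GeneticMap, n_families: int,
                  rils_per_family: int, seed: int | np.random.Generator,
                  intermating_expansion: Mapping[str, float] | None = None,
                  snp_map: GeneticMap | None = None,
                  snp_maf_range: tuple[float, float] = (0.1, 0.9),
                  ) -> Population:
    """Simulate RIL families as two-founder mosaics of the common parent.

    Each family descends from the common parent (allele 0 everywhere on the
    linkage map) and one alternate parent (allele 1).  When ``snp_map`` is
    given, founder SNP haplotypes are drawn per founder and the true mosaic
    is sampled jointly at linkage-marker and SNP positions so RIL SNP
    dosages are exact; SNP cM positions are interpolated from the linkage
    map through physical position.
    """
    if linkage_map.n_markers == 0:
        raise ValueError("empty linkage map")
    if rils_per_family < 1:
        raise ValueError("rils_per_family must be >= 1")
    rng = np.random.default_rng(seed)
    intermating_expansion = intermating_expansion or {}

    fams = [f"F{i + 1:02d}" for i in range(n_families)]
    mdf = linkage_map.df
    # joint position list: linkage markers and (optionally) SNPs
    if snp_map is not None:
        sdf = snp_map.df.copy()
        if "cM" not in sdf.columns or sdf["cM"].isna().any():
            sdf["cM"] = np.nan
        cm = []
        for chrom, sub in sdf.groupby("chrom"):
            ref = mdf[mdf["chrom"] == chrom]
            if ref.empty:
                raise ValueError(f"SNP chromosome {chrom} absent from linkage map")
            cm.append(pd.Series(
                np.interp(sub["bp"], ref["bp"], ref["cM"]), index=sub.index))
        sdf["cM"] = pd.concat(cm).sort_index()
        joint = pd.concat([
            mdf.assign(_kind="L"), sdf.assign(_kind="S")
        ]).sort_values(["chrom", "cM", "bp"], kind="stable").reset_index(drop=True)
    else:
        joint = mdf.assign(_kind="L").reset_index(drop=True)

    cM = joint["cM"].to_numpy(float)
    chrom = joint["chrom"].to_numpy()
    is_link = (joint["_kind"] == "L").to_numpy()

    geno_blocks, snp_blocks, fam_labels, line_ids = [], [], [], []
    origin_blocks = []
    founder_rows = {}
    if snp_map is not None:
        n_snp = snp_map.n_markers
        freq = rng.uniform(*snp_maf_range, n_snp)
        founder_rows[COMMON_PARENT] = (rng.random(n_snp) < freq).astype(np.int8)

    for fam in fams:
        exp = float(intermating_expansion.get(fam, 1.0))
        origin = _mosaic(rng, rils_per_family, cM, chrom, exp)
        geno_blocks.append(origin[:, is_link])
        if snp_map is not None:
            founder_rows[f"AP_{fam}"] = (rng.random(n_snp) < freq).astype(np.int8)
            o = origin[:, ~is_link]
            origin_blocks.append(o)
            a0 = founder_rows[COMMON_PARENT]
            a1 = founder_rows[f"AP_{fam}"]
            snp_blocks.append(np.where(o == 1, a1[None, :], a0[None, :]))
        fam_labels += [fam] * rils_per_family
        line_ids += [f"{fam}_{j + 1:04d}" for j in range(rils_per_family)]

    idx = pd.Index(line_ids, name="line")
    geno = pd.DataFrame(np.vstack(geno_blocks).astype(float), index=idx,
                        columns=linkage_map.markers)
    family = pd.Series(fam_labels, index=idx, name="family")
    snp = snp_origin = founder_snps = None
    if snp_map is not None:
        snp = pd.DataFrame(np.vstack(snp_blocks).astype(float), index=idx,
                           columns=snp_map.markers)
        snp_origin = pd.DataFrame(np.vstack(origin_blocks).astype(float),
                                  index=idx, columns=snp_map.markers)
        founder_snps = pd.DataFrame(founder_rows, index=snp_map.markers).T
    return Population(family=family, geno=geno, linkage_map=linkage_map,
                      snp=snp, snp_map=snp_map, founder_snps=founder_snps,
                      snp_origin=snp_origin)


def qtl_line_values(population: Population, qtl: dict[int, dict[str, float]],
                    ) -> pd.Series:
    """True genetic value per line contributed by the QTL set."""
    g = np.zeros(len(population.lines))
    fam = population.family.to_numpy()
    G = population.geno.to_numpy()
    for j, effects in qtl.items():
        dose = G[:, j]
        eff = np.array([effects.get(f, 0.0) for f in fam])
        g += dose * eff
    return pd.Series(g, index=population.lines)


def assign_architecture(population: Population, n_qtl: int,
                        effect_scale: float, allele_series_sd: float,
                        seed: int | np.random.Generator,
                        qtl_variance_target: float | None = None,
                        base: TraitSpec | None = None,
                        trait: str = "trait") -> TraitArchitecture:
    """Place QTL with per-family allele series on a population.

    Each QTL draws a shared mean effect ``N(0, effect_scale^2)`` and then a
    per-family effect ``N(mean, allele_series_sd^2)``, giving sign
    heterogeneity across families when ``allele_series_sd > 0``.  When
    ``qtl_variance_target`` is set, effects are rescaled so the realized
    mean within-family genetic variance of the QTL term equals the target
    exactly on this population.
    """
    if n_qtl > population.linkage_map.n_markers:
        raise ValueError("more QTL than markers")
    rng = np.random.default_rng(seed)
    spec = TraitSpec(**{k: getattr(base, k) for k in (
        "family", "ril", "env", "fam_env", "ril_env", "block", "row", "col",
        "spatial", "plant", "rho_row", "rho_col", "mean")}) if base else TraitSpec()
    fams = population.families
    if n_qtl > 0:
        loci = np.sort(rng.choice(population.linkage_map.n_markers, n_qtl,
                                  replace=False))
        qtl: dict[int, dict[str, float]] = {}
        for j in loci:
            mu = rng.normal(0.0, effect_scale)
            qtl[int(j)] = {f: float(rng.normal(mu, allele_series_sd))
                           for f in fams}
        if qtl_variance_target is not None:
            g = qtl_line_values(population, qtl)
            within = g.groupby(population.family).var(ddof=1).mean()
            if within > 0:
                s = np.sqrt(qtl_variance_target / within)
                qtl = {j: {f: e * s for f, e in eff.items()}
                       for j, eff in qtl.items()}
        spec.qtl = qtl
    return TraitArchitecture(traits={trait: spec})


def _ar1_chol(n: int, rho: float) -> np.ndarray:
    """Cholesky factor of an AR1(rho) correlation matrix."""
    idx = np.arange(n)
    R = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(R)


def _spatial_field(rng: np.random.Generator, n_row: int, n_col: int,
                   var: float, rho_r: float, rho_c: float) -> np.ndarray:
    """AR1(row) x AR1(col) Gaussian field with marginal variance ``var``."""
    Lr = _ar1_chol(n_row, rho_r)
    Lc = _ar1_chol(n_col, rho_c)
    Z = rng.standard_normal((n_row, n_col))
    return np.sqrt(var) * (Lr @ Z @ Lc.T)


def simulate_plots(population: Population, architecture: TraitArchitecture,
                   environments: int | Sequence[str], grid_shape: tuple[int, int],
                   plants_per_plot: int, seed: int | np.random.Generator,
                   block_rows: int = 2) -> PlotTable:
    """Simulate plot phenotypes on an environment-specific field grid.

    Each line gets one plot per environment at a random grid cell; the plot
    value is the sum of the grand mean, family, RIL-within-family genetic
    value (QTL + polygenic), environment, family x env, RIL x env, block,
    row, column, AR1 x AR1 spatial residual and iid plant-sampling noise
    with variance ``plant / plants_per_plot``.  Traits are generated with
    the architecture's genetic correlation among true line values.
    """
    rng = np.random.default_rng(seed)
    envs = ([f"env{i + 1}" for i in range(environments)]
            if isinstance(environments, int) else list(environments))
    n_row, n_col = grid_shape
    lines = population.lines
    n_lines = len(lines)
    if n_row * n_col < n_lines:
        raise ValueError("grid too small for the panel")
    fams = population.families
    fam_arr = population.family.to_numpy()
    fam_pos = {f: np.nonzero(fam_arr == f)[0] for f in fams}

    names = architecture.trait_names
    # genetic line values, jointly correlated across traits
    C = (architecture.genetic_corr.loc[names, names].to_numpy(float)
         if architecture.genetic_corr is not None else np.eye(len(names)))
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(names)))
    Zstd = np.empty((n_lines, len(names)))
    gvals: dict[str, np.ndarray] = {}
    for t, name in enumerate(names):
        spec = architecture.traits[name]
        gq = qtl_line_values(population, spec.qtl).to_numpy() if spec.qtl \
            else np.zeros(n_lines)
        sd_r = np.array([np.sqrt(spec.ril_var(f)) for f in fam_arr])
        raw = gq + sd_r * rng.standard_normal(n_lines)
        sd = raw.std()
        Zstd[:, t] = (raw - raw.mean()) / sd if sd > 0 else \
            rng.standard_normal(n_lines)
    Zcorr = Zstd @ L.T
    for t, name in enumerate(names):
        spec = architecture.traits[name]
        # scale back to each trait's total within-panel genetic sd
        gq = qtl_line_values(population, spec.qtl).to_numpy() if spec.qtl \
            else np.zeros(n_lines)
        var_r = np.array([spec.ril_var(f) for f in fam_arr])
        tot = np.sqrt(max(np.var(gq) + var_r.mean(), 0.0))
        gvals[name] = Zcorr[:, t] * tot

    records = []
    truth: dict = {"genetic": {}, "family_eff": {}, "targets": {}}
    for name in names:
        spec = architecture.traits[name]
        spec.validate()
        fam_eff = {f: rng.normal(0, np.sqrt(spec.family)) for f in fams}
        env_eff = {e: rng.normal(0, np.sqrt(spec.env)) for e in envs}
        g = gvals[name]
        truth["genetic"][name] = pd.Series(g, index=lines)
        truth["family_eff"][name] = fam_eff
        truth["targets"][name] = spec
        for e in envs:
            perm = rng.permutation(n_row * n_col)[:n_lines]
            rows, cols = np.unravel_index(perm, (n_row, n_col))
            fe = {f: rng.normal(0, np.sqrt(spec.fam_env)) for f in fams}
            re = rng.normal(0, np.sqrt(spec.ril_env), n_lines)
            blk_of_row = np.arange(n_row) // block_rows
            n_blk = blk_of_row.max() + 1
            b_eff = rng.normal(0, np.sqrt(spec.block), n_blk)
            r_eff = rng.normal(0, np.sqrt(spec.row), n_row)
            c_eff = rng.normal(0, np.sqrt(spec.col), n_col)
            sp = (_spatial_field(rng, n_row, n_col, spec.spatial,
                                 spec.rho_row, spec.rho_col)
                  if spec.spatial > 0 else np.zeros((n_row, n_col)))
            noise = rng.normal(0, np.sqrt(spec.plant / plants_per_plot), n_lines)
            vals = (spec.mean
                    + np.array([fam_eff[f] for f in fam_arr])
                    + g + env_eff[e]
                    + np.array([fe[f] for f in fam_arr])
                    + re + b_eff[blk_of_row[rows]] + r_eff[rows] + c_eff[cols]
                    + sp[rows, cols] + noise)
            blocks = blk_of_row[rows]
            records.append(pd.DataFrame({
                "line": lines, "family": fam_arr, "env": e,
                "row": rows, "col": cols, "block": blocks,
                "trait": name, "value": vals, "n_plants": plants_per_plot,
            }))
    df = pd.concat(records, ignore_index=True)
    return PlotTable(df=df, truth=truth)
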