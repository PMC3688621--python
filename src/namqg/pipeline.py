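"""End-to-end pipeline driver: simulate -> line means -> mapping -> prediction.

A ``PipelineConfig`` (loadable from YAML) validates every enabled stage's
parameters before anything runs; ``run_pipeline`` then executes the
stages in order, writes each stage's tables to the output directory and
records a machine-readable manifest (seeds, parameters, row counts) so a
rerun with the same configuration reproduces every output.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .gblup import crossval, vanraden
from .jointlinkage import bootstrap_rmip
from .linemeans import (ModelSpec, fit_multienv_model,
                        heritability_line_means, predict_line_means,
                        winsorize)
from .simulate import (TraitArchitecture, TraitSpec, simulate_map,
                       simulate_plots, simulate_rils)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters; validated before any stage runs."""

    out_dir: str
    seed: int = 0
    trait: str = "RPR"
    # simulate
    n_chromosomes: int = 10
    n_markers: int = 200
    cM_length: float = 150.0
    bp_length: float = 2e8
    n_families: int = 5
    rils_per_family: int = 50
    n_snps: int = 0
    environments: int = 3
    grid_rows: int = 20
    grid_cols: int = 20
    plants_per_plot: int = 3
    variances: dict = field(default_factory=lambda: {
        "family": 0.35, "ril": 0.65, "env": 0.5, "fam_env": 0.9,
        "ril_env": 0.9, "plant": 3.6})
    n_qtl: int = 10
    effect_scale: float = 0.15
    allele_series_sd: float = 0.1
    # stages
    stages: tuple[str, ...] = ("simulate", "linemeans", "jointlinkage",
                               "gblup")
    winsor_k: float = 3.0
    # joint linkage
    boot: int = 20
    p_entry: float = 5e-4
    collapse_cM: float = 3.0
    # gblup
    cv_repeats: int = 5
    cv_fractions: tuple[int, ...] = (1, 4)

    def validate(self) -> None:
        if self.n_markers < 2 * self.n_chromosomes:
            raise ValueError("need >= 2 markers per chromosome")
        if self.grid_rows * self.grid_cols < \
                self.n_families * self.rils_per_family:
            raise ValueError("field grid too small for the panel")
        known = {"simulate", "linemeans", "jointlinkage", "gblup"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if any(v < 0 for v in self.variances.values()):
            raise ValueError("variance targets must be >= 0")
        if self.boot < 1 or self.cv_repeats < 1:
            raise ValueError("boot and cv_repeats must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for k in ("stages", "cv_fractions"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order; returns the manifest dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"seed": config.seed, "python": platform.python_version(),
                      "config": {k: (list(v) if isinstance(v, tuple) else v)
                                 for k, v in asdict(config).items()},
                      "stages": {}}
    pop = plots = fit = lm = None

    def fail(stage, exc):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if "simulate" in config.stages:
        try:
            gmap = simulate_map(config.n_chromosomes, config.n_markers,
                                config.cM_length, config.bp_length, rng)
            snp_map = None
            if config.n_snps > 0:
                snp_map = simulate_map(config.n_chromosomes, config.n_snps,
                                       config.cM_length, config.bp_length,
                                       rng, prefix="s")
            pop = simulate_rils(gmap, config.n_families,
                                config.rils_per_family, rng, snp_map=snp_map)
            spec = TraitSpec(**config.variances, mean=5.0)
            arch = TraitArchitecture(traits={config.trait: spec})
            if config.n_qtl > 0:
                arch = _with_qtl(pop, config, rng, spec)
            plots = simulate_plots(pop, arch, config.environments,
                                   (config.grid_rows, config.grid_cols),
                                   config.plants_per_plot, rng)
            nio.write_map(gmap, out / "linkage_map.tsv")
            nio.write_genotypes(pop.geno, out / "genotypes.tsv")
            if pop.snp is not None:
                nio.write_map(pop.snp_map, out / "snp_map.tsv")
                nio.write_genotypes(pop.snp, out / "snp_dosages.tsv")
            nio.write_plots(plots, out / "plots.tsv")
            manifest["stages"]["simulate"] = {
                "n_lines": len(pop.lines), "n_markers": gmap.n_markers,
                "n_plots": len(plots.df)}
        except Exception as e:        # noqa: BLE001
            fail("simulate", e)

    if "linemeans" in config.stages:
        try:
            plots_w, n_mod = winsorize(plots, config.winsor_k)
            fit = fit_multienv_model(plots_w, ModelSpec(trait=config.trait))
            lm = predict_line_means(fit, plots_w, mode="BLUP")
            blue = predict_line_means(fit, plots_w, mode="BLUE")
            lm2 = lm.rename(columns={"value": "blup"})
            lm2["blue"] = blue.set_index("line")["value"] \
                .reindex(lm2["line"]).to_numpy()
            nio.write_line_means(
                lm2.rename(columns={"blup": "value"})
                [["line", "family", "trait", "value", "blue"]],
                out / "line_means.tsv")
            h2 = heritability_line_means(fit)
            manifest["stages"]["linemeans"] = {
                "winsorized": n_mod, "H2": h2.H2,
                "loglik": fit.loglik, "converged": fit.converged}
        except Exception as e:        # noqa: BLE001
            fail("linemeans", e)

    if "jointlinkage" in config.stages:
        try:
            y = lm.set_index("line")["value"]
            tab = bootstrap_rmip(y, pop.geno, pop.family, B=config.boot,
                                 p_entry=config.p_entry,
                                 collapse_cM=config.collapse_cM,
                                 gmap=pop.linkage_map,
                                 seed=int(rng.integers(2 ** 31)))
            res = pd.DataFrame({"marker": tab.counts.index,
                                "count": tab.counts.values,
                                "rmip": tab.counts.values / tab.B})
            if tab.collapsed is not None:
                res["count_3cM"] = tab.collapsed.values
            res.to_csv(out / "rmip.tsv", sep="\t", index=False)
            manifest["stages"]["jointlinkage"] = {
                "B": tab.B, "max_rmip": float(res["rmip"].max())}
        except Exception as e:        # noqa: BLE001
            fail("jointlinkage", e)

    if "gblup" in config.stages:
        try:
            y = lm.set_index("line")["value"]
            geno_for_k = pop.snp if pop.snp is not None else pop.geno
            K = vanraden(geno_for_k)
            nio.write_kinship(K, out / "kinship.tsv")
            cv = crossval(y, kinship=K, families=pop.family,
                          repeats=config.cv_repeats,
                          fractions=config.cv_fractions,
                          seed=int(rng.integers(2 ** 31)))
            cv.summary.to_csv(out / "cv_summary.tsv", sep="\t", index=False)
            manifest["stages"]["gblup"] = {
                "fractions": list(config.cv_fractions),
                "mean_r2": cv.summary["mean_r2"].tolist()}
        except Exception as e:        # noqa: BLE001
            fail("gblup", e)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest


def _with_qtl(pop, config: PipelineConfig, rng, base: TraitSpec):
    from .simulate import assign_architecture
    arch = assign_architecture(pop, config.n_qtl, config.effect_scale,
                               config.allele_series_sd, rng,
                               base=base, trait=config.trait)
    return arch
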