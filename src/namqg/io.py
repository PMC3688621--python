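"""Tab-delimited readers/writers for the pipeline's tables.

All files are plain TSV with headers.  Conventions: genetic positions in
cM and physical positions in bp as given; genotypes are founder dosages
in [0, 1] with ``NA`` for missing; the first genotype column is the line
id.  Readers validate declared schemas and name the offending column on
mismatch; write->read round-trips are identity up to float formatting.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GeneticMap, PlotTable

__all__ = ["read_map", "write_map", "read_genotypes", "write_genotypes",
           "read_plots", "write_plots", "read_kinship", "write_kinship",
           "read_line_means", "write_line_means"]

_PLOT_COLS = ["line", "family", "env", "row", "col", "block", "trait",
              "value", "n_plants"]


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"{path}: missing required column {c!r}")


def write_map(gmap: GeneticMap, path) -> None:
    gmap.df.to_csv(path, sep="\t", index=False)


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["marker", "chrom", "cM", "bp"], path)
    return GeneticMap(df)


def write_genotypes(geno: pd.DataFrame, path) -> None:
    geno.to_csv(path, sep="\t", index_label="line", na_rep="NA")


def read_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    if df.columns[0] != "line":
        raise ValueError(f"{path}: first column must be 'line'")
    return df.set_index("line")


def write_plots(plots: PlotTable | pd.DataFrame, path) -> None:
    df = plots.df if isinstance(plots, PlotTable) else plots
    df.to_csv(path, sep="\t", index=False)


def read_plots(path, chunksize: int | None = None) -> PlotTable:
    """Read a plot table; ``chunksize`` streams large files."""
    if chunksize:
        parts = pd.read_csv(path, sep="\t", chunksize=chunksize)
        df = pd.concat(parts, ignore_index=True)
    else:
        df = pd.read_csv(path, sep="\t")
    _require(df, _PLOT_COLS, path)
    return PlotTable(df=df)


def write_kinship(kinship, path) -> None:
    K = kinship.matrix if hasattr(kinship, "matrix") else kinship
    K.to_csv(path, sep="\t", index_label="line")


def read_kinship(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").set_index("line")
    df.columns.name = None
    if not df.index.equals(pd.Index(df.columns)):
        raise ValueError(f"{path}: kinship rows and columns disagree")
    return df


def write_line_means(lm: pd.DataFrame, path) -> None:
    lm.to_csv(path, sep="\t", index=False)


def read_line_means(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["line", "family", "trait", "value"], path)
    return df


def write_founders(founders: pd.DataFrame, path) -> None:
    founders.to_csv(path, sep="\t", index_label="founder")


def read_founders(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "founder":
        raise ValueError(f"{path}: first column must be 'founder'")
    return df.set_index("founder")
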