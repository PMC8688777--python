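"""Tabular inputs: trait tables, copy-number matrices, run configuration.

Traits (carapace length in mm, maximum lifespan in years) are tip-indexed
scalars; copy numbers are a gene × species integer matrix with "NA" marking
unassessed cells (distinct from 0, which is biological absence).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trees import Phylogeny

logger = logging.getLogger("carapace")

__all__ = [
    "TraitTable",
    "read_trait_table",
    "read_copy_number_table",
    "write_copy_number_table",
    "RunConfig",
    "load_config",
]

MISSING = "NA"


@dataclasses.dataclass
class TraitTable:
    """Mapping species → trait value with scale/unit metadata."""

    values: dict[str, float]
    trait: str
    scale: str = "linear"  # "linear" | "log2"
    units: str = ""

    def __post_init__(self):
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if not self.values:
            raise ValueError("trait table is empty")
        for sp, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite value for species {sp!r}")
            if self.scale == "linear" and v <= 0:
                raise ValueError(
                    f"non-positive linear-scale value {v} for species {sp!r}"
                )

    @property
    def species(self) -> list[str]:
        return list(self.values)

    def to_log2(self) -> "TraitTable":
        if self.scale == "log2":
            return self
        return TraitTable(
            {sp: float(np.log2(v)) for sp, v in self.values.items()},
            trait=self.trait,
            scale="log2",
            units=f"log2({self.units})" if self.units else "log2",
        )

    def array_for(self, species: list[str]) -> np.ndarray:
        missing = [s for s in species if s not in self.values]
        if missing:
            raise KeyError(f"species missing trait {self.trait!r}: {', '.join(missing)}")
        return np.array([self.values[s] for s in species], dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def read_trait_table(
    path,
    trait: str,
    scale: str = "linear",
    species_col: str = "species",
    units: str = "",
    tree: Phylogeny | None = None,
) -> TraitTable:
    """Read one trait column from a tab-delimited table.

    Duplicate species rows are an error; species absent from ``tree`` (if
    given) trigger a warning listing them.
    """
    df = pd.read_csv(path, sep="\t")
    for col in (species_col, trait):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    dup = df[species_col][df[species_col].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate species in trait table: {', '.join(map(str, dup))}")
    table = TraitTable(
        dict(zip(df[species_col].astype(str), df[trait].astype(float))),
        trait=trait,
        scale=scale,
        units=units,
    )
    if tree is not None:
        extra = sorted(set(table.species) - set(tree.tip_labels))
        if extra:
            warnings.warn(
                f"species not in tree: {', '.join(extra)}", stacklevel=2
            )
    return table


class CopyNumberMatrix:
    """Gene × species table of non-negative integer copy counts.

    Missing cells (unassessed) are held as pandas NA; zero means the gene is
    absent from that genome.
    """

    def __init__(self, table: pd.DataFrame):
        if table.shape[0] < 1 or table.shape[1] < 2:
            raise ValueError("need at least one gene and two species")
        vals = table.to_numpy(dtype=object)
        for v in vals.ravel():
            if pd.isna(v):
                continue
            if float(v) != int(v) or int(v) < 0:
                raise TypeError(f"copy counts must be integers >= 0, got {v!r}")
        self.table = table.astype("Int64")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def species(self) -> list[str]:
        return list(self.table.columns)

    def __eq__(self, other) -> bool:
        return isinstance(other, CopyNumberMatrix) and self.table.equals(other.table)


def read_copy_number_table(path) -> CopyNumberMatrix:
    """Read a copy-number table, sniffing long (gene, species, copies) vs wide.

    Genes whose row is entirely missing are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", na_values=[MISSING], dtype=object)
    if df.empty:
        raise ValueError(f"empty copy-number file: {path}")
    cols = [c.lower() for c in df.columns]
    if cols[:3] == ["gene", "species", "copies"]:
        copies = pd.to_numeric(df.iloc[:, 2], errors="raise")
        wide = pd.DataFrame(
            {"gene": df.iloc[:, 0], "species": df.iloc[:, 1], "copies": copies}
        ).pivot(index="gene", columns="species", values="copies")
        wide.columns.name = None
        wide.index.name = "gene"
    else:
        wide = df.set_index(df.columns[0])
        wide = wide.apply(pd.to_numeric, errors="raise")
        wide.index.name = "gene"
    for col in wide.columns:
        bad = wide[col].dropna() % 1 != 0
        if bad.any():
            raise TypeError(
                f"non-integer copy count for gene {wide.index[bad.argmax()]!r}"
            )
    all_missing = wide.isna().all(axis=1)
    if all_missing.any():
        logger.info("dropping %d all-missing gene rows", int(all_missing.sum()))
        wide = wide[~all_missing]
    return CopyNumberMatrix(wide)


def write_copy_number_table(matrix: CopyNumberMatrix, path) -> None:
    out = matrix.table.copy()
    out.to_csv(path, sep="\t", na_rep=MISSING)


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration; the seed is echoed into every output."""

    tree_path: str = ""
    size_path: str = ""
    lifespan_path: str = ""
    copy_number_path: str = ""
    annotation_path: str = ""
    plate_path: str = ""
    model: str = "bm"  # "bm" | "jump"
    mcmc_iterations: int = 6000
    mcmc_burn_in: int = 2000
    seed: int = 0
    n_boot: int = 5000
    n_perm: int = 5000
    enrichment_alpha: float = 0.05
    out_dir: str = "carapace_out"

    def __post_init__(self):
        if self.model not in ("bm", "jump"):
            raise ValueError("model must be 'bm' or 'jump'")
        for name in ("mcmc_iterations", "mcmc_burn_in", "n_boot", "n_perm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mcmc_iterations <= self.mcmc_burn_in:
            raise ValueError("mcmc_iterations must exceed mcmc_burn_in")
        if not 0 < self.enrichment_alpha < 1:
            raise ValueError("enrichment_alpha must lie in (0, 1)")

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        from . import __version__

        d["version"] = __version__
        return d


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
    return RunConfig(**data)


def ensure_out_dir(config: RunConfig) -> Path:
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    logger.info("run seed=%d out_dir=%s", config.seed, p)
    return p
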