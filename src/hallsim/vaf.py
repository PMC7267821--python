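"""Variant allele frequencies of a simulated population.

A bulk-sequencing analogue of the final cell population: the VAF of gene g
is the mutated cell fraction divided by a ploidy factor,

    VAF_g = (# cells with x[g] = 1) / (ploidy_factor * N),

so a fully clonal heterozygous-diploid mutation maps to VAF = 0.5.  VAFs
can be resolved per compartment (primary, metastatic) or pooled (the bulk
analogue used as the ABC summary statistic).  An optional binomial read-
sampling layer adds sequencing-depth noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .driver import PopulationState
from .engine import METASTATIC, PRIMARY
from .genes import GenePanel

COMPARTMENTS = (PRIMARY, METASTATIC, "pooled")


class EmptyCompartmentError(ValueError):
    """Raised when a VAF is requested for a compartment with zero cells."""


@dataclass(frozen=True)
class VAFVector:
    """Per-gene VAFs for one compartment of one population state."""

    genes: tuple[str, ...]
    values: np.ndarray
    compartment: str
    n_cells_used: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.genes), name=self.compartment)


def compute_vaf(
    state: PopulationState,
    panel: GenePanel,
    compartment: str = "pooled",
    *,
    ploidy_factor: float = 2.0,
    depth: int | None = None,
    rng: np.random.Generator | None = None,
) -> VAFVector:
    """Per-gene VAF of a compartment; 'pooled' mixes both compartments.

    With `depth` given, each VAF is replaced by a binomial read draw
    (reads_alt / depth) to emulate finite sequencing coverage.
    """
    if compartment not in COMPARTMENTS:
        raise ValueError(f"compartment must be one of {COMPARTMENTS}")
    if ploidy_factor <= 0:
        raise ValueError("ploidy_factor must be > 0")
    mutated = np.zeros(panel.size, dtype=float)
    total = 0
    for clone in state.clones:
        if clone.n_cells == 0:
            continue
        if compartment != "pooled" and clone.compartment != compartment:
            continue
        total += clone.n_cells
        mutated += clone.n_cells * clone.genotype.astype(float)
    if total == 0:
        raise EmptyCompartmentError(
            f"no cells in compartment {compartment!r}; VAF undefined"
        )
    vaf = mutated / (ploidy_factor * total)
    if depth is not None:
        if rng is None:
            raise ValueError("read sampling (depth) requires an rng")
        vaf = rng.binomial(depth, np.clip(vaf, 0.0, 1.0)) / depth
    return VAFVector(tuple(panel.names), vaf, compartment, total)


def vaf_table(state: PopulationState, panel: GenePanel, **kwargs) -> pd.DataFrame:
    """TSV-ready table ``gene vaf_primary vaf_metastatic vaf_pooled``.

    Compartments with no cells get NaN columns rather than raising.
    """
    cols = {}
    for comp in COMPARTMENTS:
        try:
            cols[comp] = compute_vaf(state, panel, comp, **kwargs).values
        except EmptyCompartmentError:
            cols[comp] = np.full(panel.size, np.nan)
    return pd.DataFrame(
        {
            "gene": panel.names,
            "vaf_primary": cols[PRIMARY],
            "vaf_metastatic": cols[METASTATIC],
            "vaf_pooled": cols["pooled"],
        }
    )


def load_observed_vaf(path, panel: GenePanel) -> np.ndarray:
    """Read an observed-VAF TSV ``gene  vaf`` aligned to the panel order."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str}).set_index("gene")
    if "vaf" not in df.columns:
        raise ValueError(f"{path}: missing 'vaf' column")
    missing = set(panel.names) - set(df.index)
    if missing:
        raise ValueError(f"{path}: no VAF for genes {sorted(missing)}")
    values = df.loc[panel.names, "vaf"].to_numpy(dtype=float)
    if np.any((values < 0) | (values > 1)):
        raise ValueError(f"{path}: VAFs must lie in [0, 1]")
    return values


def write_observed_vaf(genes, values, path) -> None:
    pd.DataFrame({"gene": list(genes), "vaf": np.asarray(values, dtype=float)}).to_csv(
        path, sep="\t", index=False
    )
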