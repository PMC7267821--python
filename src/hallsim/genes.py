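"""Gene panel, gene-to-hallmark weight matrix, and hallmark variable algebra.

The model links the mutational state of a panel of tumor-related genes to
five cancer-hallmark variables through a non-negative weight matrix.  A
genotype is a binary indicator vector x over the panel (x[g] = 1 when gene
g's tumor-suppressive / growth-regulatory function is impaired by mutation).
Each hallmark variable is the linear combination

    H_h = sum_g w[g, h] * x[g]

with weights normalized per hallmark column so that H_h lies in [0, 1] and
can interfere directly with a per-cell trial probability.

Hallmark axis (fixed order):

    Ha   evading apoptosis
    Hd   sustained growth / insensitivity to anti-growth signals (division)
    Hi   limitless replicative potential (immortalization)
    Hb   sustained angiogenesis
    Him  tissue invasion and metastasis
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: Fixed hallmark axis; column order of every weight matrix.
HALLMARKS: tuple[str, ...] = ("Ha", "Hd", "Hi", "Hb", "Him")

N_HALLMARKS = len(HALLMARKS)

GENE_ROLES = ("oncogene", "suppressor", "unspecified")


class HallmarkValues(NamedTuple):
    """The five hallmark variables computed from one genotype; each in [0, 1]."""

    Ha: float
    Hd: float
    Hi: float
    Hb: float
    Him: float

    def as_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)


@dataclass(frozen=True)
class GeneRecord:
    """One gene of the panel.

    cds_length (bases) is optional and only used to length-weight the
    per-gene driver mutation probability; role is carried but inert.
    """

    name: str
    cds_length: int | None = None
    role: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene name must be non-empty")
        if self.cds_length is not None and self.cds_length <= 0:
            raise ValueError(f"cds_length of {self.name} must be > 0")
        if self.role not in GENE_ROLES:
            raise ValueError(f"unknown gene role {self.role!r}")


@dataclass(frozen=True)
class GenePanel:
    """Ordered panel of tumor-related genes; genotype/weight axes follow it."""

    genes: tuple[GeneRecord, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    @classmethod
    def from_names(cls, names: Sequence[str]) -> "GenePanel":
        return cls(tuple(GeneRecord(n) for n in names))

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.genes]

    @property
    def size(self) -> int:
        return len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"gene {name!r} not in panel {self.names}") from None

    def relative_lengths(self) -> np.ndarray:
        """Per-gene CDS length divided by the panel mean; 1.0 when absent.

        Genes without a recorded length get weight 1.0 (uniform); when all
        lengths are present the factors average to 1 so the panel-wide
        mutation burden is independent of the length annotation.
        """
        lengths = np.array(
            [g.cds_length if g.cds_length is not None else np.nan for g in self.genes],
            dtype=float,
        )
        if np.isnan(lengths).all():
            return np.ones(self.size)
        mean = np.nanmean(lengths)
        rel = lengths / mean
        return np.where(np.isnan(rel), 1.0, rel)


def empty_genotype(panel: GenePanel) -> np.ndarray:
    """All-wild-type indicator vector over the panel."""
    return np.zeros(panel.size, dtype=np.uint8)


def validate_genotype(genotype: np.ndarray, panel: GenePanel) -> np.ndarray:
    g = np.asarray(genotype, dtype=np.uint8)
    if g.shape != (panel.size,):
        raise ValueError(
            f"genotype length {g.shape} does not match panel size {panel.size}"
        )
    if np.any(g > 1):
        raise ValueError("genotype entries must be 0/1")
    return g


def normalize_weights(raw: np.ndarray) -> np.ndarray:
    """Normalize each hallmark column of a non-negative matrix to sum 1.

    All-zero columns are left as zeros (that hallmark is simply inactive).
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("weights must be non-negative")
    sums = raw.sum(axis=0)
    out = raw.copy()
    nz = sums > 0
    out[:, nz] = out[:, nz] / sums[nz]
    return out


class HallmarkWeights:
    """Gene x hallmark weight matrix, column-normalized.

    Rows follow the panel order, columns follow :data:`HALLMARKS`.  A gene
    may contribute to several hallmarks and a hallmark may draw from several
    genes (the many-to-many mapping is the point of the model).
    """

    def __init__(self, panel: GenePanel, matrix: np.ndarray, *, normalize: bool = True):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (panel.size, N_HALLMARKS):
            raise ValueError(
                f"weight matrix shape {matrix.shape} != ({panel.size}, {N_HALLMARKS})"
            )
        if np.any(matrix < 0):
            raise ValueError("weights must be non-negative")
        if normalize:
            normed = normalize_weights(matrix)
            if not np.allclose(normed, matrix):
                warnings.warn(
                    "hallmark weight columns renormalized to sum 1", stacklevel=2
                )
            matrix = normed
        self.panel = panel
        self.matrix = matrix
        self.matrix.setflags(write=False)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, HallmarkWeights)
            and self.panel == other.panel
            and np.array_equal(self.matrix, other.matrix)
        )

    def copy(self) -> "HallmarkWeights":
        return HallmarkWeights(self.panel, self.matrix.copy(), normalize=False)

    def column_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    def nullify_gene(self, gene: str) -> "HallmarkWeights":
        """Return a copy with every weight of `gene` set to zero.

        The remaining weights are deliberately NOT renormalized: the
        in-silico knockout removes one gene's contribution while keeping the
        other genes' calibrated weights untouched.
        """
        i = self.panel.index(gene)
        m = self.matrix.copy()
        m[i, :] = 0.0
        return HallmarkWeights(self.panel, m, normalize=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.panel.names, columns=list(HALLMARKS))


def compute_hallmarks(genotype: np.ndarray, weights: HallmarkWeights) -> HallmarkValues:
    """Hallmark variables for one genotype: H_h = sum_g w[g,h] * x[g]."""
    x = validate_genotype(genotype, weights.panel)
    values = x.astype(float) @ weights.matrix
    return HallmarkValues(*values)


def nullify_gene(weights: HallmarkWeights, gene: str) -> HallmarkWeights:
    """Functional alias of :meth:`HallmarkWeights.nullify_gene`."""
    return weights.nullify_gene(gene)


# ---------------------------------------------------------------------------
# TSV I/O


def load_gene_panel(path) -> GenePanel:
    """Read a gene-panel TSV with header ``gene  cds_length  role``.

    ``cds_length`` and ``role`` columns are optional; empty cells are allowed.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if "gene" not in df.columns:
        raise ValueError(f"{path}: missing required 'gene' column")
    records = []
    for _, row in df.iterrows():
        length = row.get("cds_length")
        length = None if length is None or pd.isna(length) else int(length)
        role = row.get("role")
        role = "unspecified" if role is None or pd.isna(role) else str(role)
        records.append(GeneRecord(str(row["gene"]), length, role))
    return GenePanel(tuple(records))


def write_gene_panel(panel: GenePanel, path) -> None:
    df = pd.DataFrame(
        {
            "gene": panel.names,
            "cds_length": [g.cds_length for g in panel.genes],
            "role": [g.role for g in panel.genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_weights(path, panel: GenePanel) -> HallmarkWeights:
    """Read a weight TSV ``gene  Ha  Hd  Hi  Hb  Him``; normalizes columns.

    Rows are reordered to the panel order and must cover the panel exactly.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str}).set_index("gene")
    missing = [h for h in HALLMARKS if h not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing hallmark columns {missing}")
    extra = set(df.index) - set(panel.names)
    absent = set(panel.names) - set(df.index)
    if extra or absent:
        raise ValueError(
            f"{path}: weight genes do not match panel (extra={sorted(extra)}, "
            f"missing={sorted(absent)})"
        )
    matrix = df.loc[panel.names, list(HALLMARKS)].to_numpy(dtype=float)
    return HallmarkWeights(panel, matrix)


def write_weights(weights: HallmarkWeights, path) -> None:
    df = weights.to_frame().rename_axis("gene").reset_index()
    df.to_csv(path, sep="\t", index=False)
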