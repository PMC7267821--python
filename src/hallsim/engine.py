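"""Per-step stochastic cell-fate trials for one clone.

Every time step each cell is put through a fixed sequence of Bernoulli
trials whose probabilities the hallmark variables interfere with:

1. apoptosis            p = clamp(a0 - Ha, 0, 1)
2. environmental death  p = k0
3. replicative limit    cells whose lineage has reached c_max divisions
                        survive the senescence check with p = Hi
4. division             p = clamp(d0 + Hd, 0, 1), damped for primary cells
                        by a logistic friction term (1 - E'·N_primary) with
                        E' = E0 / (1 + F·Hb)  (angiogenesis relieves the
                        resource limit)
5. invasion             surviving primary cells convert to the metastatic
                        compartment with p = Him

Cells of a clone are exchangeable, so the per-cell Bernoulli trials are
drawn as aggregated binomials over the clone's cell count — distributionally
identical and tractable at 1e5-1e6 cells.  Daughter cells acquire new driver
hits per gene with probability m0 (optionally CDS-length weighted); each
distinct mutant genotype founds a new clone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .genes import GenePanel, HallmarkValues

PRIMARY = "primary"
METASTATIC = "metastatic"


@dataclass(frozen=True)
class SimulationParameters:
    """Base trial probabilities and bookkeeping constants of one run.

    a0, d0, k0 : base per-step probabilities of apoptosis, division and
        environmental death before hallmark interference.
    m0 : driver hit probability per gene per daughter cell per division.
    E0 : friction coefficient (1/cells) of the logistic division damping.
    F : angiogenesis relief factor (dimensionless, >= 0).
    c_max : replicative (Hayflick) limit in lineage divisions.
    N0 : initial cell count; t_max : maximum steps; N_cap : hard stop.
    """

    a0: float = 0.0
    d0: float = 0.3
    k0: float = 0.0
    m0: float = 0.0
    E0: float = 0.0
    F: float = 0.0
    c_max: int = 50
    N0: int = 1000
    t_max: int = 100
    N_cap: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("a0", "d0", "k0", "m0"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be a probability in [0, 1]")
        if self.E0 < 0 or self.F < 0:
            raise ValueError("E0 and F must be >= 0")
        if self.c_max < 0:
            raise ValueError("c_max must be >= 0")
        if self.N0 < 1 or self.t_max < 1 or self.N_cap < 1:
            raise ValueError("N0, t_max and N_cap must be >= 1")


@dataclass
class Clone:
    """A group of identical cells: genotype, size, and lineage metadata.

    c is the division counter of the lineage (maximum divisions any cell of
    the clone has experienced); mutation_order records (gene, step) pairs in
    the order the lineage first impaired each gene.
    """

    clone_id: int
    parent_id: int | None
    genotype: np.ndarray
    n_cells: int
    c: int = 0
    compartment: str = PRIMARY
    birth_step: int = 0
    mutation_order: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        self.genotype = np.asarray(self.genotype, dtype=np.uint8)
        if self.n_cells < 0 or self.c < 0:
            raise ValueError("n_cells and c must be >= 0")
        if self.compartment not in (PRIMARY, METASTATIC):
            raise ValueError(f"unknown compartment {self.compartment!r}")

    @property
    def genotype_key(self) -> bytes:
        return self.genotype.tobytes()

    def genotype_bitstring(self) -> str:
        return "".join(map(str, self.genotype.tolist()))


class TrialProbabilities(NamedTuple):
    p_apoptosis: float
    p_env_death: float
    p_division: float
    p_immortal_survival: float
    p_invasion: float


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def trial_probabilities(
    clone: Clone,
    H: HallmarkValues,
    params: SimulationParameters,
    N_primary: int,
) -> TrialProbabilities:
    """Hallmark-interfered trial probabilities for one clone at one step.

    The apoptosis hallmark lowers the apoptosis probability to a0 - Ha; the
    division hallmark raises the division probability to d0 + Hd; primary
    cells additionally feel logistic friction 1 - E'·N_primary where the
    angiogenesis hallmark relieves E' = E0/(1 + F·Hb).  Metastatic cells are
    never friction-limited.  All results are clamped to [0, 1].
    """
    p_apop = _clamp01(params.a0 - H.Ha)
    p_env = params.k0
    p_immortal = _clamp01(H.Hi)
    p_invasion = _clamp01(H.Him) if clone.compartment == PRIMARY else 0.0
    base_div = params.d0 + H.Hd
    if clone.compartment == PRIMARY:
        e_prime = params.E0 / (1.0 + params.F * H.Hb)
        p_div = _clamp01(base_div * (1.0 - e_prime * N_primary))
    else:
        p_div = _clamp01(base_div)
    return TrialProbabilities(p_apop, p_env, p_div, p_immortal, p_invasion)


def step_clone(
    clone: Clone,
    probs: TrialProbabilities,
    params: SimulationParameters,
    rng: np.random.Generator,
) -> tuple[int, int, int]:
    """Run one step of fate trials over a clone's cells.

    Returns (survivors, dividers, invaders): cells alive after the death
    trials, the subset that divides this step, and the subset that will
    convert to the metastatic compartment.  Aggregated binomial draws are
    used in the fixed trial order apoptosis -> environmental death ->
    senescence check (only at the replicative limit) -> division ->
    invasion.
    """
    n = clone.n_cells
    if n < 1:
        raise ValueError("step_clone requires a non-empty clone")
    alive = n - rng.binomial(n, probs.p_apoptosis)
    alive -= rng.binomial(alive, probs.p_env_death) if alive else 0
    if clone.c >= params.c_max and alive:
        alive = rng.binomial(alive, probs.p_immortal_survival)
    survivors = int(alive)
    dividers = int(rng.binomial(survivors, probs.p_division)) if survivors else 0
    invaders = int(rng.binomial(survivors, probs.p_invasion)) if survivors else 0
    return survivors, dividers, invaders


def mutate_daughters(
    clone: Clone,
    dividers: int,
    panel: GenePanel,
    params: SimulationParameters,
    step: int,
    rng: np.random.Generator,
) -> tuple[int, list[tuple[np.ndarray, int, tuple[tuple[str, int], ...]]]]:
    """Draw driver hits for the 2·dividers daughter cells of a clone.

    Each daughter independently acquires, per still-unmutated gene g, a new
    hit with probability m0·L_g/L̄ (CDS-length weighted when lengths are
    annotated).  Daughters with identical mutant genotypes are grouped.

    Returns (n_mutant_daughters, groups) where each group is
    (new_genotype, cell_count, mutation_order_delta); unmutated daughters
    stay with the parent clone and are not listed.
    """
    if dividers < 0:
        raise ValueError("dividers must be >= 0")
    daughters = 2 * dividers
    if daughters == 0 or params.m0 == 0.0:
        return 0, []
    unmut = np.flatnonzero(clone.genotype == 0)
    if unmut.size == 0:
        return 0, []
    q = np.clip(params.m0 * panel.relative_lengths()[unmut], 0.0, 1.0)
    # Daughters with no hit are the overwhelming majority at realistic m0:
    # draw the number of mutant daughters first, then hit patterns only for
    # those, conditioned on at least one hit.
    p_any = 1.0 - np.prod(1.0 - q)
    n_mut = int(rng.binomial(daughters, p_any))
    if n_mut == 0:
        return 0, []
    # Exact sampling of hit patterns conditional on >= 1 hit: pick the first
    # hit gene (in panel order) with its conditional probability, then draw
    # later genes unconditionally.  Avoids rejection loops at small m0.
    k = unmut.size
    no_hit_before = np.concatenate(([1.0], np.cumprod(1.0 - q)[:-1]))
    first_probs = q * no_hit_before / p_any
    first_probs = first_probs / first_probs.sum()  # guard rounding
    first = rng.choice(k, size=n_mut, p=first_probs)
    hits = rng.random((n_mut, k)) < q
    cols = np.arange(k)
    hits &= cols[None, :] > first[:, None]
    hits[np.arange(n_mut), first] = True
    genotypes = np.broadcast_to(clone.genotype, (n_mut, panel.size)).copy()
    genotypes[:, unmut] |= hits.astype(np.uint8)
    uniq, counts = np.unique(genotypes, axis=0, return_counts=True)
    groups = []
    for row, count in zip(uniq, counts):
        new_genes = tuple(
            (panel.names[i], step)
            for i in np.flatnonzero((row == 1) & (clone.genotype == 0))
        )
        groups.append((row.copy(), int(count), new_genes))
    return n_mut, groups


def apply_invasion(
    clone: Clone,
    invaders: int,
    next_clone_id: int,
    step: int,
    existing_metastatic: Clone | None = None,
) -> Clone | None:
    """Move `invaders` cells of a primary clone to the metastatic compartment.

    Reuses `existing_metastatic` (same genotype and lineage) when given,
    otherwise founds a new metastatic clone descending from this one.
    Returns the metastatic clone touched, or None when invaders == 0.
    """
    if clone.compartment != PRIMARY:
        raise ValueError("apply_invasion requires a primary clone")
    if invaders > clone.n_cells:
        raise ValueError("invaders cannot exceed the clone's cell count")
    if invaders == 0:
        return None
    clone.n_cells -= invaders
    if existing_metastatic is not None:
        existing_metastatic.n_cells += invaders
        existing_metastatic.c = max(existing_metastatic.c, clone.c)
        return existing_metastatic
    return Clone(
        clone_id=next_clone_id,
        parent_id=clone.clone_id,
        genotype=clone.genotype.copy(),
        n_cells=invaders,
        c=clone.c,
        compartment=METASTATIC,
        birth_step=step,
        mutation_order=clone.mutation_order,
    )
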