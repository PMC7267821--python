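"""Full-run time loop: trials, mutation, invasion, logging, stopping rules.

The driver owns the single RNG stream, iterates the trial engine over all
live clones in clone_id order (reproducibility over parallel speed), caches
hallmark values per distinct genotype, and records the evolution log: one
row per (step, clone) plus per-step aggregate counts.  A run stops at
extinction, at t_max, or when the population reaches the hard cap N_cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import (
    METASTATIC,
    PRIMARY,
    Clone,
    SimulationParameters,
    apply_invasion,
    mutate_daughters,
    step_clone,
    trial_probabilities,
)
from .genes import (
    GenePanel,
    HallmarkValues,
    HallmarkWeights,
    compute_hallmarks,
    empty_genotype,
    validate_genotype,
)


@dataclass
class SimulationConfig:
    """Everything one run needs: parameters, panel, weights, start genotype."""

    params: SimulationParameters
    panel: GenePanel
    weights: HallmarkWeights
    initial_genotype: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.weights.panel is not self.panel and self.weights.panel != self.panel:
            raise ValueError("weights and config use different gene panels")
        if self.initial_genotype is not None:
            self.initial_genotype = validate_genotype(self.initial_genotype, self.panel)

    def with_weights(self, weights: HallmarkWeights) -> "SimulationConfig":
        return SimulationConfig(self.params, self.panel, weights, self.initial_genotype)

    def with_seed(self, seed: int) -> "SimulationConfig":
        from dataclasses import replace

        return SimulationConfig(
            replace(self.params, seed=int(seed)),
            self.panel,
            self.weights,
            self.initial_genotype,
        )


@dataclass
class PopulationState:
    """All live clones at one step plus aggregate counts."""

    step: int
    clones: list[Clone]

    @property
    def N_primary(self) -> int:
        return sum(c.n_cells for c in self.clones if c.compartment == PRIMARY)

    @property
    def N_metastatic(self) -> int:
        return sum(c.n_cells for c in self.clones if c.compartment == METASTATIC)

    @property
    def n_clones(self) -> int:
        return sum(1 for c in self.clones if c.n_cells > 0)


@dataclass
class EvolutionLog:
    """Per-step clone rows and summaries of one run.

    clone_rows: dicts with step, clone_id, parent_id, genotype (bitstring),
    n_cells, c, compartment — clones are logged with n_cells = 0 at the step
    they die and dropped thereafter.
    """

    clone_rows: list[dict] = field(default_factory=list)
    step_rows: list[dict] = field(default_factory=list)

    def clones_frame(self) -> pd.DataFrame:
        cols = ["step", "clone_id", "parent_id", "genotype", "n_cells", "c", "compartment"]
        return pd.DataFrame(self.clone_rows, columns=cols)

    def summary_frame(self) -> pd.DataFrame:
        cols = ["step", "n_clones", "N_primary", "N_metastatic"]
        return pd.DataFrame(self.step_rows, columns=cols)

    def write(self, clones_path, summary_path) -> None:
        self.clones_frame().to_csv(clones_path, sep="\t", index=False)
        self.summary_frame().to_csv(summary_path, sep="\t", index=False)


class _HallmarkCache:
    """Memoizes compute_hallmarks per distinct genotype of a run."""

    def __init__(self, weights: HallmarkWeights):
        self.weights = weights
        self._cache: dict[bytes, HallmarkValues] = {}

    def get(self, clone: Clone) -> HallmarkValues:
        key = clone.genotype_key
        try:
            return self._cache[key]
        except KeyError:
            H = compute_hallmarks(clone.genotype, self.weights)
            self._cache[key] = H
            return H

    def items(self):
        return self._cache.items()


def run_simulation(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    *,
    log_clones: bool = True,
) -> tuple[PopulationState, EvolutionLog]:
    """Run one full simulation; identical seed + config give identical logs.

    Set log_clones=False to skip per-clone log rows (per-step summaries are
    always kept) — the forward model inside ABC loops uses this.
    """
    params = config.params
    if rng is None:
        rng = np.random.default_rng(params.seed)
    genotype0 = (
        config.initial_genotype
        if config.initial_genotype is not None
        else empty_genotype(config.panel)
    )
    order0 = tuple(
        (config.panel.names[i], 0) for i in np.flatnonzero(genotype0 == 1)
    )
    clones: list[Clone] = [
        Clone(0, None, genotype0.copy(), params.N0, 0, PRIMARY, 0, order0)
    ]
    next_id = 1
    cache = _HallmarkCache(config.weights)
    log = EvolutionLog()
    # map primary clone_id -> its metastatic offshoot, to pool repeat invaders
    met_of: dict[int, int] = {}
    by_id: dict[int, Clone] = {0: clones[0]}

    state = PopulationState(0, clones)
    for step in range(1, params.t_max + 1):
        N_primary = state.N_primary
        new_clones: list[Clone] = []
        for clone in clones:
            if clone.n_cells == 0:
                continue
            H = cache.get(clone)
            probs = trial_probabilities(clone, H, params, N_primary)
            survivors, dividers, invaders = step_clone(clone, probs, params, rng)
            n_mut, groups = mutate_daughters(
                clone, dividers, config.panel, params, step, rng
            )
            clone.n_cells = survivors + dividers - n_mut
            if dividers > 0:
                clone.c += 1
            for genotype, count, new_genes in groups:
                key = genotype.tobytes()
                merged = False
                for sib in new_clones:
                    # merge equal genotypes from the same parent founded this step
                    if sib.parent_id == clone.clone_id and sib.genotype_key == key:
                        sib.n_cells += count
                        sib.c = max(sib.c, clone.c)
                        merged = True
                        break
                if not merged:
                    new_clones.append(
                        Clone(
                            next_id,
                            clone.clone_id,
                            genotype,
                            count,
                            clone.c,
                            clone.compartment,
                            step,
                            clone.mutation_order + new_genes,
                        )
                    )
                    next_id += 1
            if invaders > 0 and clone.compartment == PRIMARY:
                invaders = min(invaders, clone.n_cells)
                existing = by_id.get(met_of.get(clone.clone_id, -1))
                if existing is not None and existing.n_cells == 0:
                    existing = None  # died earlier; found a fresh one
                met = apply_invasion(clone, invaders, next_id, step, existing)
                if met is not None and met.clone_id == next_id:
                    new_clones.append(met)
                    met_of[clone.clone_id] = met.clone_id
                    next_id += 1
        clones.extend(new_clones)
        for c in new_clones:
            by_id[c.clone_id] = c

        state = PopulationState(step, clones)
        n_primary, n_met = state.N_primary, state.N_metastatic
        log.step_rows.append(
            {
                "step": step,
                "n_clones": state.n_clones,
                "N_primary": n_primary,
                "N_metastatic": n_met,
            }
        )
        if log_clones:
            for c in clones:
                log.clone_rows.append(
                    {
                        "step": step,
                        "clone_id": c.clone_id,
                        "parent_id": c.parent_id,
                        "genotype": c.genotype_bitstring(),
                        "n_cells": c.n_cells,
                        "c": c.c,
                        "compartment": c.compartment,
                    }
                )
        # dead clones are logged once (n_cells = 0 above) then dropped
        dead = [c for c in clones if c.n_cells == 0]
        if dead:
            clones = [c for c in clones if c.n_cells > 0]
            for c in dead:
                by_id.pop(c.clone_id, None)
            state = PopulationState(step, clones)
        total = n_primary + n_met
        if total == 0 or total >= params.N_cap:
            break
    return state, log


def summarize_final(state: PopulationState) -> tuple[int, int, int]:
    """(N_primary, N_metastatic, n_clones) of a state; empty clones excluded."""
    return state.N_primary, state.N_metastatic, state.n_clones


def order_of_dysfunction(state: PopulationState) -> list[dict]:
    """Per surviving clone: genes in first-hit order along its lineage.

    Returns dicts with clone_id, genotype, n_cells, compartment and the
    ordered (gene, step) list.
    """
    out = []
    for c in state.clones:
        if c.n_cells == 0:
            continue
        ordered = sorted(c.mutation_order, key=lambda gs: (gs[1],))
        out.append(
            {
                "clone_id": c.clone_id,
                "genotype": c.genotype_bitstring(),
                "n_cells": c.n_cells,
                "compartment": c.compartment,
                "order_of_dysfunction": ordered,
            }
        )
    return out


def final_state_frame(state: PopulationState) -> pd.DataFrame:
    """Final-state table; gene order encoded as semicolon-joined gene:step."""
    rows = []
    for rec in order_of_dysfunction(state):
        rows.append(
            {
                "clone_id": rec["clone_id"],
                "genotype": rec["genotype"],
                "n_cells": rec["n_cells"],
                "compartment": rec["compartment"],
                "order_of_dysfunction": ";".join(
                    f"{g}:{s}" for g, s in rec["order_of_dysfunction"]
                ),
            }
        )
    cols = ["clone_id", "genotype", "n_cells", "compartment", "order_of_dysfunction"]
    return pd.DataFrame(rows, columns=cols)
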