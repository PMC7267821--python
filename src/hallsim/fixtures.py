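"""Synthetic calibration scenarios: a self-consistent input set with a
known ground truth.

A scenario fabricates every input the pipeline needs — gene panel, weight
matrix, simulation parameters, and an "observed" VAF vector produced by
actually running the simulator at the true weights — plus a truth record,
so parameter-recovery experiments can grade the ABC against a known answer.

The default scenario is a colorectal-style caricature over APC, KRAS, TP53
and PIK3CA.  Each hallmark draws on two genes, one designated dominant
(weight share drawn from U(0.65, 0.9)); TP53 participates in three
hallmarks, exercising the many-to-many gene-hallmark mapping.  The weight
values are illustrative, not biological claims.  CDS-length weighting of
the mutation rate is off by default here so that selection, not mutational
target size, drives the VAF differences the ABC inverts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .configio import write_params
from .driver import SimulationConfig, run_simulation
from .engine import SimulationParameters
from .genes import (
    HALLMARKS,
    GenePanel,
    GeneRecord,
    HallmarkWeights,
    write_gene_panel,
    write_weights,
)
from .vaf import EmptyCompartmentError, compute_vaf, write_observed_vaf

_SEED_MOD = 2**31

#: Reference CDS lengths (bases) of the example panel; annotation only in
#: the default scenario (mutation stays uniform unless use_cds_lengths=True).
_CDS_LENGTHS = {"APC": 8532, "KRAS": 570, "TP53": 1182, "PIK3CA": 3207}
_ROLES = {
    "APC": "suppressor",
    "KRAS": "oncogene",
    "TP53": "suppressor",
    "PIK3CA": "oncogene",
}

#: hallmark -> (dominant gene, minor gene) of the default scenario.  The
#: assignment balances total selective advantage across the four genes so
#: every gene reaches a macroscopic frequency and its hallmark allocation
#: leaves a footprint in the VAF vector.
DEFAULT_DOMINANCE: dict[str, tuple[str, str]] = {
    "Ha": ("TP53", "PIK3CA"),
    "Hd": ("APC", "KRAS"),
    "Hi": ("KRAS", "TP53"),
    "Hb": ("KRAS", "APC"),
    "Him": ("PIK3CA", "TP53"),
}

DEFAULT_PARAMS = SimulationParameters(
    a0=0.3,
    d0=0.4,
    k0=0.05,
    m0=1e-3,
    E0=2e-4,
    F=2.0,
    c_max=15,
    N0=1500,
    t_max=60,
    N_cap=20000,
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything needed to fabricate a scenario deterministically."""

    gene_names: tuple[str, ...] = ("APC", "KRAS", "TP53", "PIK3CA")
    dominance: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_DOMINANCE)
    )
    params: SimulationParameters = DEFAULT_PARAMS
    dominant_share_range: tuple[float, float] = (0.65, 0.9)
    use_cds_lengths: bool = False
    observed_replicates: int = 3
    max_extinction_retries: int = 20
    seed: int = 0


@dataclass(frozen=True)
class Scenario:
    """In-memory realization of a ScenarioSpec."""

    spec: ScenarioSpec
    panel: GenePanel
    true_weights: HallmarkWeights
    config: SimulationConfig
    observed_vaf: np.ndarray
    observed_seeds: tuple[int, ...]


def make_panel(spec: ScenarioSpec) -> GenePanel:
    records = []
    for name in spec.gene_names:
        length = _CDS_LENGTHS.get(name) if spec.use_cds_lengths else None
        records.append(GeneRecord(name, length, _ROLES.get(name, "unspecified")))
    return GenePanel(tuple(records))


def draw_true_weights(
    spec: ScenarioSpec, panel: GenePanel, rng: np.random.Generator
) -> HallmarkWeights:
    """Truth matrix: per hallmark, dominant share u ~ U(lo, hi), minor 1-u."""
    lo, hi = spec.dominant_share_range
    m = np.zeros((panel.size, len(HALLMARKS)))
    for h, hallmark in enumerate(HALLMARKS):
        if hallmark not in spec.dominance:
            continue
        dom, minor = spec.dominance[hallmark]
        u = rng.uniform(lo, hi)
        m[panel.index(dom), h] = u
        m[panel.index(minor), h] = 1.0 - u
    return HallmarkWeights(panel, m, normalize=False)


def build_scenario(spec: ScenarioSpec) -> Scenario:
    """Realize a scenario: draw the truth, simulate the observed VAFs.

    The observed vector is the pooled VAF averaged over
    spec.observed_replicates independent runs at the true weights; runs
    that go extinct are redrawn with fresh seeds up to
    spec.max_extinction_retries times.
    """
    rng = np.random.default_rng(spec.seed)
    panel = make_panel(spec)
    weights = draw_true_weights(spec, panel, rng)
    config = SimulationConfig(replace(spec.params, seed=spec.seed), panel, weights)
    vafs, seeds = [], []
    attempts = 0
    while len(vafs) < spec.observed_replicates:
        if attempts >= spec.observed_replicates + spec.max_extinction_retries:
            raise RuntimeError(
                "simulator went extinct at the true weights too often; "
                "scenario parameters do not sustain a tumor"
            )
        attempts += 1
        seed = int(rng.integers(_SEED_MOD))
        state, _ = run_simulation(
            config.with_seed(seed), np.random.default_rng(seed), log_clones=False
        )
        try:
            vafs.append(compute_vaf(state, panel, "pooled").values)
        except EmptyCompartmentError:
            continue
        seeds.append(seed)
    observed = np.mean(vafs, axis=0)
    return Scenario(spec, panel, weights, config, observed, tuple(seeds))


def generate_scenario(spec: ScenarioSpec, out_dir) -> dict[str, Path]:
    """Write the four input files plus the truth record; returns the paths.

    Files: genes.tsv, weights.tsv (the true weights — they double as the
    ABC participation mask), config.yaml, observed_vaf.tsv, truth.json.
    Same spec + seed always produce identical files.
    """
    scenario = build_scenario(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out / "genes.tsv",
        "weights": out / "weights.tsv",
        "config": out / "config.yaml",
        "observed": out / "observed_vaf.tsv",
        "truth": out / "truth.json",
    }
    write_gene_panel(scenario.panel, paths["genes"])
    write_weights(scenario.true_weights, paths["weights"])
    write_params(scenario.config.params, paths["config"])
    write_observed_vaf(scenario.panel.names, scenario.observed_vaf, paths["observed"])
    truth = {
        "seed": spec.seed,
        "observed_seeds": list(scenario.observed_seeds),
        "true_weights": {
            g: {h: scenario.true_weights.matrix[i, j] for j, h in enumerate(HALLMARKS)}
            for i, g in enumerate(scenario.panel.names)
        },
        "dominance": {h: list(v) for h, v in spec.dominance.items()},
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths
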