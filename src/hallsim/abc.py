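"""Rejection ABC over the gene-to-hallmark weights, MAP extraction, and
in-silico gene-nullification experiments.

The weights are calibrated against an observed per-gene VAF vector: draw a
weight matrix from the prior, run the forward simulator, compute pooled
VAFs, accept the draws whose Euclidean distance to the observed vector
falls below a tolerance (an absolute cutoff or a quantile of all proposal
distances).  Runs that go extinct score distance +inf — an observed tumor
implies survival.  The prior is flat (symmetric Dirichlet, concentration 1)
over each hallmark's simplex of participating genes; the participation mask
fixes which gene-hallmark weights are free versus pinned at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .driver import SimulationConfig, run_simulation, summarize_final
from .genes import HALLMARKS, GenePanel, HallmarkWeights, N_HALLMARKS
from .vaf import EmptyCompartmentError, compute_vaf

_SEED_MOD = 2**31


class EmptyPosteriorError(RuntimeError):
    """No proposal fell within the tolerance; carries the distances seen."""

    def __init__(self, distances: np.ndarray):
        super().__init__(
            f"rejection ABC accepted 0 of {distances.size} proposals "
            f"(min distance {np.nanmin(distances):.4g})"
        )
        self.distances = distances


@dataclass(frozen=True)
class WeightPrior:
    """Flat prior over each hallmark's participating-gene weight simplex.

    mask[g, h] = True marks a free weight; each hallmark column with k >= 1
    participating genes gets a symmetric Dirichlet(1, ..., 1) draw over
    those k weights (uniform on the simplex), so every draw satisfies the
    column-normalization invariant by construction.
    """

    panel: GenePanel
    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != (self.panel.size, N_HALLMARKS):
            raise ValueError("participation mask must be genes x hallmarks")
        object.__setattr__(self, "mask", mask)

    @classmethod
    def from_weights(cls, weights: HallmarkWeights) -> "WeightPrior":
        """Free exactly the weights that are nonzero in an initial matrix."""
        return cls(weights.panel, weights.matrix > 0)

    @property
    def free_parameters(self) -> list[tuple[str, str]]:
        """(gene, hallmark) labels of the free weights, column-major."""
        out = []
        for h, hallmark in enumerate(HALLMARKS):
            for g in np.flatnonzero(self.mask[:, h]):
                out.append((self.panel.names[g], hallmark))
        return out

    def sample(self, rng: np.random.Generator) -> HallmarkWeights:
        m = np.zeros((self.panel.size, N_HALLMARKS))
        for h in range(N_HALLMARKS):
            idx = np.flatnonzero(self.mask[:, h])
            if idx.size:
                m[idx, h] = rng.dirichlet(np.ones(idx.size))
        return HallmarkWeights(self.panel, m, normalize=False)

    def flatten(self, weights: HallmarkWeights) -> np.ndarray:
        return weights.matrix.T[self.mask.T]

    def unflatten(self, values: np.ndarray) -> HallmarkWeights:
        m = np.zeros((self.panel.size, N_HALLMARKS))
        m.T[self.mask.T] = values
        return HallmarkWeights(self.panel, m, normalize=False)


@dataclass
class ABCResult:
    """Accepted draws of a rejection-ABC run plus the distance bookkeeping."""

    prior: WeightPrior | None
    accepted: np.ndarray  # (n_accepted, n_free) flattened draws
    distances: np.ndarray  # accepted distances
    all_distances: np.ndarray
    tolerance: float
    n_proposals: int
    map_is_fallback: bool = field(default=False)

    @property
    def n_accepted(self) -> int:
        return self.accepted.shape[0]

    def posterior_summary(self) -> pd.DataFrame:
        names = (
            [f"{g}.{h}" for g, h in self.prior.free_parameters]
            if self.prior is not None
            else [f"param{i}" for i in range(self.accepted.shape[1])]
        )
        q = np.quantile(self.accepted, [0.025, 0.5, 0.975], axis=0)
        return pd.DataFrame(
            {
                "parameter": names,
                "mean": self.accepted.mean(axis=0),
                "q025": q[0],
                "median": q[1],
                "q975": q[2],
            }
        )

    def accepted_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.accepted,
            columns=(
                [f"{g}.{h}" for g, h in self.prior.free_parameters]
                if self.prior is not None
                else None
            ),
        )
        df["distance"] = self.distances
        return df


def rejection_sample(
    observed: np.ndarray,
    draw: Callable[[np.random.Generator], np.ndarray],
    simulate: Callable[[np.ndarray, np.random.Generator], np.ndarray | None],
    n_proposals: int,
    rng: np.random.Generator,
    *,
    quantile: float | None = None,
    tolerance: float | None = None,
) -> ABCResult:
    """Generic rejection-ABC core over an arbitrary forward model.

    `draw` proposes a flat parameter vector from the prior; `simulate`
    returns a summary-statistic vector or None (scored +inf, e.g. extinct
    runs).  Exactly one of `quantile` (accept that fraction of proposals by
    distance) or `tolerance` (absolute cutoff) must be given.
    """
    if (quantile is None) == (tolerance is None):
        raise ValueError("give exactly one of quantile= or tolerance=")
    if n_proposals < 1:
        raise ValueError("n_proposals must be >= 1")
    observed = np.asarray(observed, dtype=float)
    draws = []
    distances = np.empty(n_proposals)
    for i in range(n_proposals):
        theta = draw(rng)
        summary = simulate(theta, rng)
        if summary is None:
            distances[i] = np.inf
        else:
            distances[i] = float(np.linalg.norm(np.asarray(summary) - observed))
        draws.append(theta)
    draws_arr = np.asarray(draws)
    if quantile is not None:
        finite = distances[np.isfinite(distances)]
        if finite.size == 0:
            raise EmptyPosteriorError(distances)
        cutoff = float(np.quantile(finite, quantile))
    else:
        cutoff = float(tolerance)
    keep = distances <= cutoff
    if not keep.any():
        raise EmptyPosteriorError(distances)
    return ABCResult(
        prior=None,
        accepted=draws_arr[keep],
        distances=distances[keep],
        all_distances=distances,
        tolerance=cutoff,
        n_proposals=n_proposals,
    )


def _vaf_forward(
    config: SimulationConfig,
    weights: HallmarkWeights,
    replicates: int,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Pooled VAFs at the run's end, averaged over replicate seeds.

    Returns None when every replicate goes extinct.
    """
    sims = []
    cfg = config.with_weights(weights)
    for _ in range(replicates):
        seed = int(rng.integers(_SEED_MOD))
        state, _ = run_simulation(
            cfg.with_seed(seed), np.random.default_rng(seed), log_clones=False
        )
        try:
            sims.append(compute_vaf(state, config.panel, "pooled").values)
        except EmptyCompartmentError:
            continue
    if not sims:
        return None
    return np.mean(sims, axis=0)


def abc_rejection(
    observed: np.ndarray,
    prior: WeightPrior,
    config: SimulationConfig,
    n_proposals: int,
    *,
    quantile: float | None = None,
    tolerance: float | None = None,
    replicates_per_proposal: int = 3,
    rng: np.random.Generator | None = None,
) -> ABCResult:
    """Rejection ABC of the hallmark weights against observed per-gene VAFs.

    For each proposal the forward simulator is run replicates_per_proposal
    times with fresh seeds and the pooled VAF vectors are averaged before
    the Euclidean distance to `observed` is taken.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (config.panel.size,):
        raise ValueError("observed VAF vector must cover the whole panel")
    if rng is None:
        rng = np.random.default_rng(config.params.seed)

    def draw(r: np.random.Generator) -> np.ndarray:
        return prior.flatten(prior.sample(r))

    def simulate(theta: np.ndarray, r: np.random.Generator) -> np.ndarray | None:
        return _vaf_forward(config, prior.unflatten(theta), replicates_per_proposal, r)

    result = rejection_sample(
        observed, draw, simulate, n_proposals, rng, quantile=quantile, tolerance=tolerance
    )
    result.prior = prior
    return result


def map_estimate(result: ABCResult) -> HallmarkWeights | np.ndarray:
    """MAP weights: per-parameter KDE mode, projected back to the simplexes.

    Each free parameter's accepted sample gets a 1-D Gaussian KDE whose mode
    is located on a [0, 1] grid (product approximation across parameters —
    accepted samples are too small for stable multivariate KDE).  The mode
    vector is then re-normalized per hallmark column.  With fewer than 20
    accepted draws (or a degenerate sample) the minimum-distance draw is
    returned instead and result.map_is_fallback is set.
    """
    if result.n_accepted == 0:
        raise ValueError("cannot take a MAP of an empty posterior")
    grid = np.linspace(0.0, 1.0, 201)
    modes = np.empty(result.accepted.shape[1])
    fallback = result.n_accepted < 20
    if not fallback:
        for j in range(result.accepted.shape[1]):
            sample = result.accepted[:, j]
            if np.ptp(sample) < 1e-12:
                modes[j] = sample[0]
                continue
            try:
                kde = stats.gaussian_kde(sample)
                modes[j] = grid[np.argmax(kde(grid))]
            except np.linalg.LinAlgError:
                fallback = True
                break
    if fallback:
        result.map_is_fallback = True
        best = result.accepted[int(np.argmin(result.distances))]
        return result.prior.unflatten(best) if result.prior is not None else best
    if result.prior is None:
        return modes
    weights = result.prior.unflatten(modes)
    m = weights.matrix.copy()
    sums = m.sum(axis=0)
    nz = sums > 0
    m[:, nz] /= sums[nz]
    return HallmarkWeights(result.prior.panel, m, normalize=False)


def nullification_battery(
    map_weights: HallmarkWeights,
    genes: Sequence[str],
    config: SimulationConfig,
    n_runs: int,
    master_seed: int,
) -> pd.DataFrame:
    """Baseline vs per-gene knockout simulations under shared seeds.

    Runs n_runs simulations for the baseline (MAP weights) and for each
    gene with its weights set to zero while the others keep their MAP
    values.  Run i of every condition uses the same derived seed, so a
    knockout of a zero-weight gene reproduces the baseline exactly.
    Returns a tidy frame: condition, run, N_primary, N_metastatic, n_clones.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    conditions = [("baseline", map_weights)]
    for gene in genes:
        conditions.append((f"-{gene}", map_weights.nullify_gene(gene)))
    rows = []
    for name, weights in conditions:
        cfg = config.with_weights(weights)
        for run in range(n_runs):
            seed = int(
                np.random.default_rng([master_seed % _SEED_MOD, run]).integers(_SEED_MOD)
            )
            state, _ = run_simulation(
                cfg.with_seed(seed), np.random.default_rng(seed), log_clones=False
            )
            n_p, n_m, n_c = summarize_final(state)
            rows.append(
                {
                    "condition": name,
                    "run": run,
                    "N_primary": n_p,
                    "N_metastatic": n_m,
                    "n_clones": n_c,
                }
            )
    return pd.DataFrame(rows)


def battery_summary(battery: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of the three final counts per condition."""
    return (
        battery.groupby("condition")[["N_primary", "N_metastatic", "n_clones"]]
        .quantile([0.25, 0.5, 0.75])
        .unstack(level=-1)
    )
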