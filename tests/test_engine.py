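"""Per-step fate trials: probability algebra, sampling, mutation, invasion."""

import numpy as np
import pytest
from scipy import stats

from hallsim import (
    Clone,
    HallmarkValues,
    SimulationParameters,
    apply_invasion,
    mutate_daughters,
    step_clone,
    trial_probabilities,
)
from hallsim.engine import METASTATIC, PRIMARY


def H(Ha=0.0, Hd=0.0, Hi=0.0, Hb=0.0, Him=0.0) -> HallmarkValues:
    return HallmarkValues(Ha, Hd, Hi, Hb, Him)


def clone(n=100, c=0, compartment=PRIMARY, genes=2) -> Clone:
    return Clone(0, None, np.zeros(genes, dtype=np.uint8), n, c, compartment)


class TestTrialProbabilities:
    def test_apoptosis_interference(self):
        p = trial_probabilities(clone(), H(Ha=0.2), SimulationParameters(a0=0.5), 0)
        assert p.p_apoptosis == pytest.approx(0.3)

    def test_apoptosis_clamped_at_zero(self):
        p = trial_probabilities(clone(), H(Ha=0.9), SimulationParameters(a0=0.5), 0)
        assert p.p_apoptosis == 0.0

    def test_friction_zeroes_division_at_capacity(self):
        params = SimulationParameters(d0=0.35, E0=1e-3)
        p = trial_probabilities(clone(), H(), params, 1000)
        assert p.p_division == 0.0

    def test_division_with_angiogenesis_relief(self):
        # (0.3 + 0.1) * (1 - (1e-3 / (1 + 1*1)) * 500) = 0.4 * 0.75 = 0.3
        params = SimulationParameters(d0=0.3, E0=1e-3, F=1.0)
        p = trial_probabilities(clone(), H(Hd=0.1, Hb=1.0), params, 500)
        assert p.p_division == pytest.approx(0.3)

    def test_metastatic_clone_feels_no_friction(self):
        params = SimulationParameters(d0=0.3, E0=1e-3)
        p = trial_probabilities(clone(compartment=METASTATIC), H(Hd=0.1), params, 10**6)
        assert p.p_division == pytest.approx(0.4)
        assert p.p_invasion == 0.0

    def test_direct_hallmark_probabilities(self):
        p = trial_probabilities(clone(), H(Hi=0.4, Him=0.7), SimulationParameters(k0=0.2), 0)
        assert p.p_immortal_survival == pytest.approx(0.4)
        assert p.p_invasion == pytest.approx(0.7)
        assert p.p_env_death == pytest.approx(0.2)

    def test_all_probabilities_clamped_for_adversarial_inputs(self):
        params = SimulationParameters(a0=1.0, d0=1.0, k0=1.0)
        p = trial_probabilities(clone(), H(1.0, 1.0, 1.0, 1.0, 1.0), params, 10**7)
        assert all(0.0 <= v <= 1.0 for v in p)


class TestStepClone:
    def test_noop_when_all_probabilities_zero(self):
        probs = trial_probabilities(clone(), H(), SimulationParameters(d0=0.0), 0)
        s, d, i = step_clone(clone(50), probs, SimulationParameters(d0=0.0), np.random.default_rng(0))
        assert (s, d, i) == (50, 0, 0)

    def test_certain_apoptosis_kills_all(self):
        params = SimulationParameters(a0=1.0)
        probs = trial_probabilities(clone(), H(), params, 0)
        s, d, i = step_clone(clone(50), probs, params, np.random.default_rng(0))
        assert (s, d, i) == (0, 0, 0)

    def test_empty_clone_rejected(self):
        params = SimulationParameters()
        probs = trial_probabilities(clone(), H(), params, 0)
        with pytest.raises(ValueError, match="non-empty"):
            step_clone(clone(0), probs, params, np.random.default_rng(0))

    def test_survivor_fraction_matches_binomial_moments(self):
        n = 10**5
        params = SimulationParameters(a0=0.3, d0=0.0)
        probs = trial_probabilities(clone(), H(), params, 0)
        s, _, _ = step_clone(clone(n), probs, params, np.random.default_rng(1))
        sd = np.sqrt(n * 0.3 * 0.7)
        assert abs(s - 0.7 * n) < 4 * sd

    def test_counts_nested_and_conserved(self):
        params = SimulationParameters(a0=0.2, d0=0.5, k0=0.1)
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(1, 500))
            probs = trial_probabilities(clone(), H(Him=0.3), params, 10)
            s, d, i = step_clone(clone(n), probs, params, rng)
            assert 0 <= d <= s <= n
            assert 0 <= i <= s

    def test_senescence_trial_applies_only_at_limit(self):
        params = SimulationParameters(c_max=10)
        probs = trial_probabilities(clone(), H(Hi=0.0), params, 0)
        rng = np.random.default_rng(3)
        s, _, _ = step_clone(clone(100, c=9), probs, params, rng)
        assert s == 100  # below the limit: no senescence death
        s, _, _ = step_clone(clone(100, c=10), probs, params, rng)
        assert s == 0  # at the limit with Hi = 0: nobody survives

    def test_aggregated_binomials_match_per_cell_bernoulli(self):
        """Clone-level binomial draws are distributionally identical to
        per-cell sequential Bernoulli trials (chi-square on small n)."""
        params = SimulationParameters(a0=0.3, d0=0.5, k0=0.1)
        probs = trial_probabilities(clone(), H(), params, 0)
        rng = np.random.default_rng(4)
        reps, n = 4000, 3
        agg, cell = [], []
        for _ in range(reps):
            s, d, _ = step_clone(clone(n), probs, params, rng)
            agg.append((s, d))
            surv = div = 0
            for _cell in range(n):
                if rng.random() < probs.p_apoptosis:
                    continue
                if rng.random() < probs.p_env_death:
                    continue
                surv += 1
                if rng.random() < probs.p_division:
                    div += 1
            cell.append((surv, div))
        outcomes = sorted({*agg, *cell})
        table = np.array(
            [
                [sum(1 for x in agg if x == o) for o in outcomes],
                [sum(1 for x in cell if x == o) for o in outcomes],
            ]
        )
        table = table[:, table.sum(axis=0) >= 10]
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.001


class TestMutateDaughters:
    params4 = SimulationParameters(m0=0.01)

    def test_zero_rate_yields_no_mutants(self, panel4):
        c = clone(genes=4)
        n_mut, groups = mutate_daughters(
            c, 50, panel4, SimulationParameters(m0=0.0), 1, np.random.default_rng(0)
        )
        assert n_mut == 0 and groups == []

    def test_certain_mutation_single_gene(self):
        from hallsim import GenePanel

        panel = GenePanel.from_names(["APC"])
        c = clone(genes=1)
        n_mut, groups = mutate_daughters(
            c, 10, panel, SimulationParameters(m0=1.0), 3, np.random.default_rng(0)
        )
        assert n_mut == 20  # both daughters of every division mutate
        assert len(groups) == 1
        genotype, count, order = groups[0]
        assert count == 20 and genotype.tolist() == [1] and order == (("APC", 3),)

    def test_fully_mutated_clone_cannot_mutate_further(self, panel4):
        c = Clone(0, None, np.ones(4, dtype=np.uint8), 100)
        n_mut, groups = mutate_daughters(
            c, 50, panel4, SimulationParameters(m0=1.0), 1, np.random.default_rng(0)
        )
        assert n_mut == 0 and groups == []

    def test_mutant_fraction_matches_complement_oracle(self):
        from hallsim import GenePanel

        panel = GenePanel.from_names(["A", "B", "C", "D"])  # uniform lengths
        c = clone(genes=4)
        dividers = 5000  # 10^4 daughters
        p_any = 1 - (1 - 0.01) ** 4
        n_mut, groups = mutate_daughters(
            c, dividers, panel, self.params4, 1, np.random.default_rng(5)
        )
        daughters = 2 * dividers
        sd = np.sqrt(daughters * p_any * (1 - p_any))
        assert abs(n_mut - daughters * p_any) < 4 * sd
        assert sum(count for _, count, _ in groups) == n_mut

    def test_length_weighting_shifts_hits_to_long_genes(self, panel4):
        c = clone(genes=4)
        rng = np.random.default_rng(6)
        hits = np.zeros(4)
        for _ in range(200):
            _, groups = mutate_daughters(
                c, 500, panel4, SimulationParameters(m0=0.005), 1, rng
            )
            for genotype, count, _ in groups:
                hits += count * genotype
        rel = panel4.relative_lengths()
        # APC (longest CDS) must collect more hits than KRAS (shortest)
        assert rel[0] > rel[1]
        assert hits[0] > hits[1]


class TestApplyInvasion:
    def test_zero_invaders_is_noop(self):
        c = clone(10)
        assert apply_invasion(c, 0, 1, 2) is None
        assert c.n_cells == 10

    def test_total_conversion_empties_primary(self):
        c = clone(10)
        met = apply_invasion(c, 10, 7, 4)
        assert c.n_cells == 0
        assert met.compartment == METASTATIC
        assert met.n_cells == 10 and met.clone_id == 7 and met.birth_step == 4
        assert np.array_equal(met.genotype, c.genotype)

    def test_reuses_existing_metastatic_clone(self):
        c = clone(10)
        met = Clone(3, 0, c.genotype.copy(), 5, compartment=METASTATIC)
        out = apply_invasion(c, 4, 99, 4, existing_metastatic=met)
        assert out is met and met.n_cells == 9 and c.n_cells == 6

    def test_overdraw_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            apply_invasion(clone(3), 4, 1, 1)

    def test_metastatic_source_rejected(self):
        with pytest.raises(ValueError, match="primary"):
            apply_invasion(clone(3, compartment=METASTATIC), 1, 1, 1)
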