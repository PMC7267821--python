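# Model and methods

## The model

`hallsim` simulates the clonal evolution of a tumor cell population as a
discrete-time, agent-based branching process in which the agents are
*clones* — groups of cells sharing an identical genotype over a panel of
tumor-related genes — rather than individual cells.

Each gene g of the panel carries a binary indicator x[g]: 1 when the gene's
tumor-suppressive or growth-regulatory function has been impaired by a
driver mutation. Five hallmark variables summarize what a genotype can do:

    H_h = Σ_g w[g, h] · x[g],   h ∈ {Ha, Hd, Hi, Hb, Him}

with a non-negative weight matrix w whose columns are normalized to sum
to 1, so every H_h lies in [0, 1]. The hallmark axis is: evading apoptosis
(Ha), sustained proliferation / insensitivity to anti-growth signals (Hd),
limitless replicative potential (Hi), sustained angiogenesis (Hb), and
tissue invasion / metastasis (Him). The two classical growth-signal
capabilities are merged into the single division hallmark Hd because both
act on the same trial; this keeps one variable per trial. The mapping is
deliberately many-to-many: one gene may feed several hallmarks (TP53
famously contributes to both apoptosis control and tumor suppression) and
one hallmark may draw on several genes.

### Fate trials

Every step, each cell is put through a fixed sequence of Bernoulli trials
whose probabilities the hallmarks interfere with:

1. **apoptosis** `p = clamp(a0 − Ha, 0, 1)` — the apoptosis hallmark
   directly lowers the base apoptosis probability;
2. **environmental death** `p = k0`, hallmark-independent;
3. **senescence check** — only for cells whose lineage has reached the
   replicative (Hayflick) limit `c_max`; they survive with `p = Hi`;
4. **division** `p = clamp((d0 + Hd)·(1 − E′·N_primary), 0, 1)` for primary
   cells, with `E′ = E0 / (1 + F·Hb)`: a logistic friction term models
   resource limitation, and the angiogenesis hallmark relieves it.
   Metastatic cells divide with `clamp(d0 + Hd, 0, 1)` — no friction;
5. **invasion** — surviving primary cells convert to the metastatic
   compartment with `p = Him`.

The apoptosis form is the canonical hallmark-interference example; the
remaining forms follow the same additive/relief pattern and are isolated in
a single function (`engine.trial_probabilities`) so alternative functional
forms can be substituted in one place. All probabilities are clamped to
[0, 1] after interference because user-supplied weights can push them out.

Cells within a clone are exchangeable, so the per-cell trials are drawn as
*aggregated binomials* over the clone's cell count — distributionally
identical to per-cell Bernoulli draws (verified by a chi-square test in the
suite) and tractable at 10^5–10^6 cells.

### Mutation and clone bookkeeping

Each daughter cell of a division independently acquires, per still-intact
gene, a driver hit with probability `m0` (multiplied by `L_g/L̄` when CDS
lengths are annotated, so long genes are bigger targets; the factors
average to 1 over the panel). Mutation is modeled at the gene level — one
hit impairs the gene regardless of its oncogene/suppressor label; the label
is carried in the panel format but currently inert. Each distinct mutant
genotype founds a new clone recording its parent, birth step and the
(gene, step) order in which its lineage first impaired each gene; equal
genotypes reached through different parents stay distinct clones, which
keeps clone counts and dysfunction orders lineage-true.

The division counter `c` is tracked per clone as the lineage maximum and
incremented whenever the clone divides; daughters inherit the incremented
counter. This is the conservative (earliest-limit) reading — clone-level
bookkeeping cannot carry per-cell counters — and means the limit binds for
a whole clone at once.

### Driver loop and stopping

One global RNG stream; clones are processed in clone-id order; hallmark
values are cached per distinct genotype. Trial probabilities use the
primary population size from the start of the step (synchronous update).
A run stops at extinction, at `t_max`, or when the total population reaches
the hard cap `N_cap` (runaway exponential phases otherwise never end).
Dying clones are logged once with zero cells and then dropped. Identical
seed and configuration reproduce the logs byte-for-byte.

## VAF summaries

The bulk-sequencing analogue of a final state reports, per gene,

    VAF_g = (# cells with x[g] = 1) / (2 · N)

under a heterozygous-diploid convention (a clonal mutation has VAF 0.5),
resolved per compartment or pooled. The map is deterministic — no purity
or coverage noise — because it is the ABC summary statistic; an optional
binomial read-sampling layer (`depth=`) is available but off by default.
The VAF depends only on per-gene mutated-cell totals, never on how cells
are partitioned into clones.

## Rejection ABC and knockouts

The weight matrix is calibrated against an observed per-gene VAF vector by
plain rejection ABC: draw weights from the prior, run the forward
simulator (`replicates_per_proposal` independent seeds, default 3, VAFs
averaged), and accept draws whose Euclidean distance to the observed
pooled-VAF vector falls inside the tolerance (absolute, or a quantile of
the proposal distances). Extinct runs score +∞ — an observed tumor implies
survival. The prior is flat on each hallmark's simplex of participating
genes (symmetric Dirichlet, concentration 1), the participation mask taken
from the nonzero entries of the initial weight file; draws therefore
satisfy the normalization invariant by construction. The MAP estimate is
the per-parameter Gaussian-KDE mode on a 201-point grid, projected back
onto the column simplexes (a product approximation — accepted samples at
desk scale are too small for stable multivariate KDE); below 20 accepted
draws the minimum-distance draw is returned and flagged.

In-silico knockouts re-run the simulator with one gene's weights set to
zero while the others keep their calibrated values (no renormalization —
the experiment measures removal of one gene's contribution). Run i of
every condition shares a seed derived from the master seed, so knocking
out a zero-weight gene reproduces the baseline bit-identically and
between-condition contrasts are paired.

## The synthetic scenario generator

`fixtures.ScenarioSpec` fabricates a complete, self-consistent input set:
gene panel, true weight matrix, parameter file, and an "observed" VAF
vector produced by actually running the simulator at the true weights
(averaged over 3 replicate runs; extinct runs redrawn up to a bound). The
default scenario is a colorectal-style caricature over APC, KRAS, TP53 and
PIK3CA in which each hallmark draws on two genes with a designated dominant
one (share ~ U(0.65, 0.9)):

    Ha: TP53 > PIK3CA    Hd: APC > KRAS    Hi: KRAS > TP53
    Hb: KRAS > APC       Him: PIK3CA > TP53

The assignment balances total selective advantage across the four genes so
that every gene reaches macroscopic frequency and its allocation leaves a
footprint in the VAF vector. The weights are illustrative, not biological
claims. CDS lengths are annotated in the example panel but length
weighting is disabled in the generated scenario, so selection rather than
mutational target size drives the VAF differences the ABC inverts.

Default scenario parameters (chosen as a desk-scale regime in which the
wild-type population declines slowly, drivers establish and sweep
partially, friction and the replicative limit both engage, and runs finish
in ~10 ms): a0 = 0.3, d0 = 0.4, k0 = 0.05, m0 = 10⁻³ per gene per daughter,
E0 = 2·10⁻⁴, F = 2, c_max = 15, N0 = 1500, t_max = 60, N_cap = 20 000.

### What the generator does and does not emulate

It emulates the shape of a bulk-sequenced tumor profile: a handful of
driver genes at clonal/subclonal cell fractions under a diploid
heterozygous VAF convention. It does **not** emulate sequencing noise,
purity, copy number, mutation calling, neutral passenger load, or spatial
sampling. Passing recovery tests therefore show that the inference
machinery can invert the simulator's own forward map at these problem
sizes — not that the weights of a real patient are identifiable from four
VAFs.

### Identifiability limits

Endpoint pooled VAFs are 4 numbers; the free weights form 5 two-gene
simplexes. Apoptosis (Ha) and division (Hd) allocations recover reliably
because they set the relative sweep speeds of clones carrying the
respective genes. Hi, Hb and Him allocations are only weakly identified:
once a sweeping clone carries *both* participating genes of a hallmark,
column normalization plus clamping make the within-hallmark split
epistatically invisible in the endpoint VAF vector, and the posterior for
that simplex stays near the prior. This is a property of the summary
statistic, not a bug in the inference; richer summaries (time courses,
compartment-resolved VAFs) would be needed to break it.

## Numerical choices

- Probabilities are clamped after every interference; hallmark values are
  exact dot products (no tolerance needed).
- Mutant daughters' hit patterns are sampled exactly, conditional on at
  least one hit, via a first-hit decomposition — no rejection loops at
  small m0.
- The quantile tolerance in ABC is taken over *finite* distances, so the
  acceptance rate refers to surviving proposals.
- KDE mode search uses a fixed 201-point grid on [0, 1]; degenerate
  (zero-variance) samples short-circuit to the sample value.
- Seeds derived internally are kept below 2³¹.

## Problem sizes used in the acceptance script

Branching-mean check: 3 parameter settings × 500 replicates, 10 steps.
Plateau check: 3 runs × 400 steps around N* ≈ 222. Replicative-limit
check: 100 seeded runs. ABC toy: 50 000 proposals, 1% quantile. Recovery:
5 synthetic truths × 2000 proposals × 3 replicates at the default scenario
size. These sizes give Monte-Carlo errors comfortably inside the documented
tolerances while keeping a full acceptance run in the minutes range.

## Known limitations

- No spatial structure, micro-environment, copy-number events or
  sequence-level mutation; gene-level indicators only.
- Clone-level division counters make the replicative limit bind earlier
  than per-cell counters would.
- Rejection ABC only (no SMC/MCMC/regression adjustment); the posterior is
  conditioned on non-extinction.
- The two later "emerging" hallmarks and enabling characteristics are not
  modeled; the role column (oncogene/suppressor) is carried but inert.
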