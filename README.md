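# hallsim

A stochastic simulator of cancer clonal evolution in which the mutational
states of named tumor-related genes — not abstract fitness coefficients —
drive cell behavior through the hallmarks of cancer, plus the machinery to
calibrate that link against observed variant allele frequencies (VAFs) and
to ask which gene matters for which outcome by in-silico knockout.

**Who it is for.** Computational cancer biologists who want to reason about
intra-tumor heterogeneity, driver-gene order, and metastasis in terms of
real gene panels (APC, KRAS, TP53, PIK3CA, ...) and to test gene-level
hypotheses that models with one abstract "driver mutation" parameter cannot
express.

## The model in brief

A clone is a group of cells with identical genotype x ∈ {0,1}^G over a
gene panel (x[g] = 1: gene g impaired by a driver mutation). Five hallmark
variables are weighted sums of the indicators,

    H_h = Σ_g w[g,h] · x[g],  h ∈ {Ha, Hd, Hi, Hb, Him},  Σ_g w[g,h] = 1,

and interfere with per-cell, per-step Bernoulli fate trials:

| trial | probability |
|---|---|
| apoptosis | clamp(a₀ − Ha, 0, 1) |
| environmental death | k₀ |
| senescence at the replicative limit c ≥ c_max | survives w.p. Hi |
| division (primary) | clamp((d₀ + Hd)·(1 − E′·N_primary), 0, 1), E′ = E₀/(1 + F·Hb) |
| division (metastatic) | clamp(d₀ + Hd, 0, 1) |
| invasion → metastatic compartment | Him |

Daughter cells mutate per gene with probability m₀ (optionally CDS-length
weighted); every new genotype founds a clone that remembers its parent and
the order in which its lineage impaired each gene. The weight matrix w is
the inference target: rejection ABC accepts weight draws whose simulated
pooled VAF vector lands near the observed one, a MAP matrix is extracted by
per-parameter KDE, and knockout batteries re-run the simulator with one
gene's weights zeroed while the rest keep their MAP values.

See `docs/methods.md` for assumptions, parameter meanings and limits.

## Worked example

Everything below is driven by plain TSV/YAML files; `make-fixtures` writes
a self-consistent synthetic input set (4-gene colorectal-style panel,
known true weights, and an "observed" VAF vector produced by running the
simulator at those weights):

```bash
hallsim make-fixtures --out demo --seed 7
hallsim simulate --config demo/config.yaml --genes demo/genes.tsv \
                 --weights demo/weights.tsv --out sim --seed 1
# simulate: stopped at step 47 with N_primary=0 N_metastatic=26975 n_clones=27
```

This run's tumor metastasized and the metastatic compartment, free of the
logistic resource friction, overran the population cap at step 47 while the
primary compartment collapsed. `sim/final_state.tsv` lists the surviving
clones with the order in which their lineages lost each gene:

```
clone_id  genotype  n_cells  compartment  order_of_dysfunction
37        0110      24815    metastatic   TP53:1;KRAS:19
38        0111      146      metastatic   TP53:1;KRAS:19;PIK3CA:34
40        1110      755      metastatic   TP53:1;KRAS:19;APC:37
```

— the dominant clone lost TP53 at step 1 and KRAS at step 19; later
subclones added PIK3CA and APC. `sim/vaf.tsv` gives per-gene VAFs under
the heterozygous-diploid convention (clonal mutation → 0.5): here KRAS and
TP53 are clonal (0.5), APC subclonal (0.033).

Calibrate weights against the observed VAFs and run the knockout battery
at the MAP estimate:

```bash
hallsim abc --observed demo/observed_vaf.tsv --config demo/config.yaml \
            --genes demo/genes.tsv --weights demo/weights.tsv \
            --proposals 200 --quantile 0.1 --replicates 1 --seed 2 --out abc_out
# abc: accepted 15/200 (tolerance 0.3799, MAP from min-distance fallback)
hallsim nullify --config demo/config.yaml --genes demo/genes.tsv \
                --map abc_out/map_weights.tsv --runs 30 --seed 3 --out null_out
# nullify: per-condition medians
#            N_primary  N_metastatic  n_clones
# -APC          4072.0       21516.5      56.5
# -KRAS            0.0           0.0       0.0
# -PIK3CA       3323.5       20915.0      52.5
# -TP53         6495.0       17865.5      69.0
# baseline      4004.5       21804.0      52.5
```

The battery shares seeds across conditions, so differences are paired: in
this calibration KRAS ended up carrying the immortalization weight, and
knocking it out lets the replicative limit extinguish every run (medians
0), while the other knockouts shift tumor burden and clone counts more
mildly. (With 200 proposals the accepted sample is below the KDE
threshold, so the MAP falls back to the minimum-distance draw — the log
says so; use a few thousand proposals for a smooth posterior.)

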