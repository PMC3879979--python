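# strandbalance

Why do bacterial genomes keep genes on the lagging strand at all?
Lagging-strand genes suffer head-on collisions between the replication and
transcription machineries — mutagenic and deleterious — so genes should,
and mostly do, accumulate on the leading strand. One proposal holds that
the remaining lagging-strand genes are there *adaptively*, exploiting the
extra mutagenesis. `strandbalance` implements the neutral counter-argument
for anyone analysing strand asymmetries in closely related bacterial
strains:

1. **Mutation–selection balance.** With inversion mutations moving a gene
   leading→lagging at rate *u*, back at rate *v*, and a selective
   disadvantage *s* of lagging encoding, the lagging probability
   equilibrates at (1 − q)u = q(v + s), i.e. **q\* = u/(u + v + s)** —
   positive whenever u > 0, and decreasing in *s*. No benefit is needed to
   maintain lagging-strand genes.
2. **A conditional resampling test.** Sites hit by more than one amino
   acid change ("multihit" sites) are not evidence of diversifying
   selection if lagging-strand genes simply evolve faster. Holding each
   gene's variable-site count V and change count C fixed, the C changes
   are redrawn uniformly over the V sites (10,000 replicates) to get null
   distributions of **R_N** (lagging/leading multihit-site ratio) and
   **R_G** (ditto for multihit-containing genes), with two-tailed
   empirical P-values. Changes themselves are mapped by small parsimony on
   the strain tree, with full MPR enumeration so genuinely parallel or
   convergent changes (same descendant residue in independent lineages)
   can be separated from mere multihit sites, and gene-level parallel
   fractions compared between strands by Fisher's exact test.

A seeded synthetic-data generator (strand-labeled gene alignments evolved
on a known tree, with ground-truth change events) makes the whole pipeline
testable without any external genome download.

## Worked example

Balance model — equal inversion rates and s/u = 2 put a quarter of genes
on the lagging strand at equilibrium:

```console
$ strandbalance model --u 1e-4 --v 1e-4 --s 2e-4
{
  "equilibrium_q": 0.25,
  "iterated_fixed_point": 0.24997499999811812,
  "converged": true,
  "generations_run": 46049
}
```

The analytic equilibrium is exactly 1/(2 + s/u) = 0.25; the iterated
per-generation dynamics converge to within 0.01% of it.

Resampling test on a synthetic dataset of 200 leading + 30 lagging genes
in which lagging genes evolve twice as fast but changes land independently
across sites (the neutral world):

```python
from strandbalance import SimulationConfig, generate_dataset, null_distribution
from strandbalance.stats_pipeline import summaries_for_dataset

ds = generate_dataset(SimulationConfig(n_leading=200, n_lagging=30, seed=1))
summaries = summaries_for_dataset(ds.alignments, ds.tree, seed=1)
res = null_distribution(summaries, n_replicates=10_000, seed=1)
print(f"R_N observed = {res.r_n_obs:.3f}  (two-tail P = {res.p_n:.3f})")
print(f"R_G observed = {res.r_g_obs:.3f}  (two-tail P = {res.p_g:.3f})")
print("inside central 90% band:", res.central_band(0.90))
```

```text
R_N observed = 0.538  (two-tail P = 0.557)
R_G observed = 0.338  (two-tail P = 0.471)
inside central 90% band: {'r_n': True, 'r_g': True}
```

Both observed ratios sit well inside their null distributions: the
two-fold rate excess alone produces exactly as many multihit sites on the
lagging strand as conditional chance predicts, so nothing is left for an
adaptive explanation to explain. `strandbalance run --config <yaml>`
chains the same stages (filtering, change mapping, classification,
resampling in several variable-site modes, Fisher contrast) into a single
report directory; `strandbalance simulate`, `filter`, `resample` and
`model` expose the individual stages.

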