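# Methods

## The question

Most bacterial genes sit on the leading strand, where RNA polymerase moves
with the replication fork; genes on the lagging strand face head-on
collisions between the replication and transcription machineries, which
are both mutagenic and disruptive. Two explanations have been offered for
why lagging-strand genes persist at all: an adaptive one (those genes
profit from the extra mutagenesis, e.g. through diversifying selection
visible as an excess of repeatedly substituted sites) and a neutral one
(they are simply deleterious variants maintained at mutation–selection
balance). This package implements both prongs of the neutral argument: the
balance model itself, and a resampling re-analysis showing that "multihit"
amino acid sites need no adaptive explanation once the elevated
substitution rate of lagging-strand genes is conditioned on.

## Mutation–selection balance of strand orientation

Each gene is modelled as an independent two-state lineage: leading- or
lagging-strand encoded. Inversion mutations move it from leading to
lagging at rate *u* per gene per generation, back at rate *v*, and
lagging-strand encoding carries a selective disadvantage *s* (0 ≤ *s* < 1,
derived under *s* ≪ 1). Writing *q* for the probability of lagging
encoding, influx and removal balance when (1 − *q*)*u* = *q*(*v* + *s*),
giving the equilibrium

    q* = u / (u + v + s),

which reduces to 1/(2 + s/u) when u = v. q* is positive whenever u > 0 —
lagging-strand genes persist without any benefit — and decreases in *s*,
matching the observed deficit of highly expressed and essential genes on
the lagging strand.

`iterate_deterministic` realises the balance as a discrete-generation
chain: mutation q′ = q(1 − v) + (1 − q)u, then purifying removal
q″ = q′(1 − s). Selection is deliberately *not* implemented as
mean-fitness-normalised frequency change: the balance equation above
treats selection as a per-lineage removal probability (a purged lagging
variant is replaced by the leading allele of the same gene), and the
normalised map q″ = q′(1 − s)/(1 − sq′) instead equilibrates where
u(1 − q) = vq + sq(1 − q)/(1 − sq), which sits ~15% away from q* whenever
u ≈ v ≈ s, at any scale. With the removal form, the exact fixed point is
(1 − s)u / (s + (1 − s)(u + v)); its relative deviation from q* is of
order s²/(u + v + s) and stays below 1% over the whole
{10⁻², 10⁻³, 10⁻⁴}³ rate grid (worst corner: u = v = 10⁻⁴, s = 10⁻²,
0.98%). `simulate_wright_fisher` is the finite-population counterpart —
n_genes independent lineages with binomial mutation gains/losses and
binomial thinning of lagging lineages by *s* — and fluctuates around the
same fixed point. Iteration defaults: tolerance 10⁻¹² on the
per-generation movement, at most 10⁷ generations; with rates of order
10⁻⁴ convergence takes ~10⁵ generations.

## Substitution mapping

Amino acid changes among the focal strains are counted by small parsimony
(unit cost between any two residues) on a user-supplied rooted strain
tree; the tree is a required input because the strains' relationships are
not derivable from the alignments at these divergences. Minimum change
counts come from dynamic programming over the states observed at the
column (a restriction that provably contains a parsimony optimum), exact
on arbitrary rooted trees. All most-parsimonious reconstructions (MPRs)
are then recovered by exhaustive enumeration over internal-node
assignments — at most kⁿ combinations for k ≤ 5 observed states and n ≤ 4
internal nodes on a five-strain tree, so this is cheap; a seeded sampling
fallback guards the (unreachable) case of more than six observed states.
`X` and focal gaps are treated as missing: unconstrained leaves that
contribute no events. A `distinct` counting mode (changes = distinct
residues − 1) is provided for comparison with naive counting; parsimony is
the default. The root of the input tree is trusted; no outgroup residue is
used to break root-state ties by default.

## Site and gene classification

* **variable** (observed rule): the column shows more than one distinct
  non-missing residue across focal and outgroup rows, or a gap in any
  outgroup row. The all-variable mode declares every column variable; the
  interpolated mode promotes a seeded random draw of invariant columns
  until a target fraction is variable, sweeping between the two.
* **multihit**: minimum change count ≥ 2 among focal strains.
* **parallel / convergent**: within an MPR, a pair of events on branches
  with no ancestor–descendant relation (independent lineages) reaching the
  same descendant residue; parallel if the ancestral residues match,
  convergent otherwise. The default `all_mprs` policy flags a site only
  when *every* MPR exhibits the pattern — conservative under
  reconstruction ambiguity; `any_mpr` is available and is always a
  superset.

Columns with a gap in any focal row are removed before analysis; columns
whose only gaps are in outgroups are kept, because outgroup gaps feed the
variable-site rule. Ortholog-quality filters mirror standard core-gene
criteria: focal ungapped length strictly greater than 200 residues keeps a
gene; an outgroup row is dropped (not the gene) when its identity to the
first focal row (matches / mutually ungapped columns) or its mutual
coverage (ungapped overlap / shorter ungapped length) falls below 0.70.
Whether coverage should be of the query, the hit, or mutual is a genuinely
open convention; mutual-of-shorter is used as the symmetric choice.

## The resampling null

For each gene the observed totals are held fixed: V variable sites and C
amino acid changes. A null replicate redraws the C changes uniformly with
replacement over the V sites; sites drawn ≥ 2 times are the randomly
expected multihit sites (E[count] = V·[1 − (1 − 1/V)^C − (C/V)(1 −
1/V)^(C−1)], used as an oracle in tests). Aggregating over genes by strand
gives one replicate of R_N (lagging/leading multihit-site totals) and R_G
(lagging/leading counts of genes with ≥ 1 multihit site); 10,000
replicates (the default) form the null distributions. Observed ratios use
the parsimony multihit counts, each multihit site counted once regardless
of how many changes it carries.

Conventions: a ratio with zero denominator and positive numerator is +∞
(sorts above all finite values); 0/0 is neutral (1.0) — both preserve all
replicates without pseudocounts. The two-tailed P doubles the smaller tail
with ties counted in both, capped at 1; an observation beyond every
replicate is reported with the add-one estimate 2(k+1)/(n+1) rather than
0. The central-90% check uses inclusive empirical order statistics (no
interpolation, so infinite ratios are handled exactly). Per-gene RNG
streams are keyed by a hash of the gene id under one master seed, so
results are independent of gene order. Genes with C ≥ 1 but V = 0
(possible only through reversion-style corner cases) cannot be resampled
and are excluded with a logged warning.

## The strand contrast

Gene-level parallel-change flags feed a 2×2 table (strand × has-parallel)
scored with Fisher's exact test. The primary two-sided convention sums
hypergeometric probabilities of margin-preserving tables no more likely
than the observed one (the convention of standard statistical software,
relative tie tolerance 10⁻⁷ via scipy); the doubled-one-tail value is
reported alongside because the two can differ at the second decimal. A
zero margin yields P = 1 by convention.

## The synthetic generator

`generate_dataset` emulates the target study design: five focal strains on
a pectinate tree with equal branches of 0.01 expected substitutions per
site (closely related conspecific strains: a few changes per 250-residue
gene), 200 leading- and 30 lagging-strand genes, a two-fold lagging-strand
rate multiplier applied to branch lengths (the magnitude of the real rate
excess is not pinned down; 2× is a moderate, configurable choice), ten
star-like outgroup rows at divergence 0.3 (≈ 74% expected identity,
comfortably above the 70% filters, and enough to mark most eligible sites
variable), and half of all sites eligible to vary (the rest absolutely
constrained; the true constrained fraction is unknown and 0.5 keeps both
site classes well represented). Per branch, each eligible site mutates
with probability 1 − exp(−b·m) to a uniformly chosen different residue, at
most once per site per branch — a Jukes–Cantor-like scheme chosen so that
change counts have closed-form expectations for oracle tests. The root
sequence is uniform over the 20 residues. Every focal-branch event is
recorded as ground truth.

What the generator does *not* emulate: codon structure and d_N/d_S,
among-site rate variation beyond the eligible/ineligible dichotomy,
realistic amino acid composition and exchangeabilities, indels in focal
strains (outgroup gaps only, off by default), and site-level clustering of
substitutions. Passing calibration therefore shows the pipeline is honest
under a rate-biased but site-homogeneous world — exactly the null the
resampling test conditions on — not that real genomes lack diversifying
selection.

## Calibration, problem sizes, determinism

Because the pipeline's target datasets come from external genome
databases, the core claim is checked as a property: on synthetic data with
a strand rate bias but no site clustering, the observed R_N and R_G should
fall inside the central 90% of their conditional nulls about 90% of the
time. The shipped check uses 100 datasets (seeds 1–100, 200 + 30 genes)
with 2,000-replicate nulls — sizes chosen to make the whole suite
comfortably runnable on a laptop while keeping the binomial 95% band
[0.83, 0.95] informative — and measures coverage 0.87 (R_N) and 0.83
(R_G). Two caveats bound what this shows: parsimony undercounts true
changes (multiple hits on one branch collapse; reversion-only multihit
sites are invisible), and the observed-variable-site set conditions on
variation having occurred, so observed and null quantities are not drawn
from identical processes — the slight conservativeness of R_G reflects its
strong discreteness (small integer counts of multihit-containing genes).

All randomness flows from explicit seeds through `numpy` generators;
identical configuration plus seed reproduces every dataset, null
distribution, trajectory, and report bit for bit.

## Known limitations

* Inversions move one gene at a time in the model; real inversions
  relocate many genes jointly, so u and v are effective per-gene rates.
* No probabilistic (ML/Bayesian) ancestral reconstruction; branch lengths
  do not inform the mapping.
* The parallel/convergent contrast inherits parsimony's blindness to
  homoplasy on nested branches.
* d_N, d_S and expression/essentiality covariates are out of scope; the
  strand rate difference enters only through the generator's multiplier.
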