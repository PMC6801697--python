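# Methods

`flavopan` re-implements, as a reusable and fully tested library, the
comparative-genomics workflow used to place a newly sequenced bacterial
genome among its relatives: ortholog clustering from filtered all-vs-all
protein similarity, pan-genome openness via Heaps' law, presence/absence
and feature-count ordination, neighbor joining, Nei–Gojobori Ka/Ks with
mixture analysis of the Ks distribution, synteny-block detection, and a
secretome-size regression. This note records the models, the defaults
and their rationale, the numerical choices, and the known limitations.

## Hit filtering and ortholog clustering

Orthologous groups are inferred from all-vs-all protein similarity hits
(standard 12-column tabular format; the pipeline consumes hits, it never
runs an aligner). A hit between proteins of lengths `lq`, `ls` with
alignment length `L` (amino acids) and percent identity `pid` survives
iff

* `L >= 0.8 * max(lq, ls)` (coverage of the longer protein), and
* `pid >= 30` when `L >= 150`, or
  `pid >= 100 * (0.06 + 4.8 * L^(-0.32 * (1 + exp(-L/1000))))` when
  `L < 150`.

The short-alignment curve is strictly decreasing in `L` and meets the
flat 30% floor near `L = 150` (30.3% at 150), so the rule is continuous
in practice. Self-hits are always removed, and the filter is applied per
hit, so a surviving A→B hit never resurrects a filtered B→A hit.

Surviving hits form a weighted undirected graph: each directed hit
contributes `-log10(e-value)` (e-values floored at 1e-300), and the edge
weight is the average of the two directions, a missing direction
counting as 0. The graph is partitioned by Markov clustering (MCL):
self-loops at each node's maximum incident weight are added for
stability, columns are normalized to a stochastic matrix, and expansion
(matrix squaring) alternates with inflation (entrywise power, default
1.5 — OrthoMCL's published default — followed by column renormalization)
until the matrix is idempotent (residual < 1e-8; non-convergence after
200 iterations is an error reporting the residual). Clusters are read
off the attractor structure; a node supported by several attractor
systems joins the one whose smallest member sorts first (deterministic).
Entries below 1e-9 are pruned each iteration to keep the matrix sparse.

Genes in no multi-gene cluster are *singletons*. Core groups at
threshold `t` are groups with members from at least `t` distinct
genomes. Pairwise 1:1 orthologs come from groups holding exactly one
member of each of the two genomes; groups with in-genome paralogs are
skipped, because a pairwise Ka/Ks between ambiguous paralogs is not
interpretable.

## Pan-genome openness

Gene accumulation is computed over random genome orderings (default 100
permutations; medians, not means, summarize each N). Heaps' law is fit
on the median number of *new* families contributed by the N-th genome,

    n(N) = kappa * N^(-alpha),

by least squares of `log n` on `log N` for `N >= 2` (zero medians are
dropped with a warning; fewer than three surviving points is an error).
`alpha < 1` reads as an open pan-genome. The alternative fit of the pan
size itself, `P(N) = kappa * N^gamma`, is available behind a flag
(`mode="pan"`, reported as `alpha = -gamma`) but is not the default,
because the new-gene form is the one whose exponent carries the
open/closed interpretation directly.

## The synthetic family-matrix generator

The generator must produce matrices whose permuted accumulation curve
actually follows the requested power law — otherwise Heaps-fit recovery
tests measure nothing. Under random genome orderings the expected number
of new families at position N depends only on the family-frequency
spectrum: a family carried by `m` of `n` genomes first appears at
position N with probability `C(n-N, m-1) / C(n, m)`. The generator
therefore solves (non-negative least squares) for the integer spectrum
`G(m)` whose expected first-appearance curve equals
`kappa * N^(-alpha)`, rounds it, pins the total accessory-family count
to `sum_k round(kappa * k^(-alpha))` exactly, and assigns each family a
uniformly random carrier set of its multiplicity. Because the
construction is exchangeable, the generator's own genome numbering also
introduces `~round(kappa * k^(-alpha))` unseen families at genome `k`,
with later genomes re-carrying part of the earlier accessory repertoire.
Planting is deterministic given the spectrum; randomness only decides
which genomes carry each family.

Very large `alpha` (the closed-pan-genome limit) degenerates to
accessory families carried by every genome, so the pan size is constant
after the first genome. For `alpha <= 5`, parameters that would plant
zero new families at the second genome are rejected as degenerate.

What this generator does **not** emulate: paralogy (one copy per
carrier), gene-length and genome-size variation, annotation error, and
any correlation between family content and phylogeny. Tests passing on
it show the estimators recover planted structure under the model's own
assumptions, not that real annotation pipelines are error-free.

## Ordination and trees

PCA is a singular value decomposition of the genomes × families matrix;
explained percentages are squared singular values normalized to 100.
Binary presence/absence matrices are centered but not scaled (scaling
near-constant 0/1 columns amplifies noise); count matrices (e.g. CAZy
family counts) are centered and unit-variance scaled. Both behaviours
are flags. Clade labels riding along with feature matrices are metadata
only and never enter the computation.

Neighbor joining is the classical Saitou–Nei algorithm on any symmetric
zero-diagonal distance matrix (the package supplies Jaccard and Hamming
distances on presence/absence rows). Q-criterion ties are broken by the
smallest (row, column) index pair and counted; negative branch lengths
are clamped to zero with the deficit moved to the sister branch, and the
repair count is reported. On additive matrices the algorithm recovers
the generating topology exactly (property-tested against an independent
random-additive-tree construction, and cross-checked against dendropy's
NJ on a fixture).

## Ka/Ks by Nei–Gojobori (NG86)

Codon alignments are built by back-translating aligned protein pairs
(each residue replaced by its source codon, protein gaps by `---`;
translation mismatches and internal stops are hard errors naming the
codon). Codons with a gap or ambiguous base in either sequence are
dropped pairwise before any counting.

Per codon, the synonymous site count is the mean over the three
positions of (synonymous one-step changes)/3, changes to stop codons
counting as nonsynonymous; `S + N = 3 *` (compared codons) always.
Differences between a codon pair are averaged over all minimal
mutational pathways, excluding pathways through stop codons (if every
pathway passes through a stop — possible only for some multi-position
differences — all pathways are used). Proportions `ps = Sd/S`,
`pn = Nd/N` are corrected with Jukes–Cantor,
`d = -(3/4) ln(1 - (4/3) p)`; at `p >= 3/4` the estimate is flagged
saturated and reported as NaN, and saturated pairs are excluded from
density and mixture fitting. The implementation agrees with an
exhaustive rational-arithmetic oracle to 1e-9 on random codon pairs.

NG86 was chosen over transition/transversion-corrected (YN00) or
maximum-likelihood (GY94) variants because it is fully specifiable and
oracle-checkable; the trade is model sophistication for testability.

The companion codon simulator evolves a random stop-free sequence under
a Gillespie process with NG86's own assumptions (equal codon
frequencies, uniform rates, rate `omega` for amino-acid-changing moves,
stops forbidden). Every sense codon accrues synonymous changes at
exactly 3 per NG86 synonymous site per unit time, so evolving for time
`Ks/3` plants the requested synonymous divergence.

**Limitation (known, intended):** NG86's Jukes–Cantor correction
assumes each synonymous site is a 4-state symmetric site, but real (and
simulated) synonymous changes concentrate on positions of heterogeneous
degeneracy — a 2-fold site can hold a whole observed difference while
counting as only 1/3 synonymous site. The estimator is therefore
accurate at low divergence (about +5% at Ks = 0.3–0.5) but overestimates
substantially beyond Ks ≈ 1 (+16% at 1.0, +41% at 1.5, measured on the
simulator). This is the documented high-divergence behaviour of the
method, not an implementation defect; the unbiasedness tests cover the
validity range Ks ≤ 0.5, and downstream interpretation of large fitted
Ks component means should treat them as qualitative.

## Ks distribution analysis

Kernel densities use a Gaussian kernel with Silverman's bandwidth
(overridable); modes are local maxima with prominence above 5% of the
density maximum. One- and two-component normal and gamma mixtures are
fit by EM on the raw values: the gamma M-step solves
`log(a) - digamma(a) = log(mean) - mean(log)` for the shape by Brent
root-finding; two-component fits take the best of 20 random
quantile-split initializations (tolerance 1e-8 on the log-likelihood,
at most 2000 iterations; monotonicity of the likelihood is asserted
every iteration). A component collapsing below weight 1e-3 aborts that
restart; if all restarts collapse the fit falls back to one component
with a flag. AIC counts 2 parameters for `k=1` and 5 for `k=2`.

The distribution is called *bimodal* when the two-component AIC beats
the one-component AIC by more than 2 (the standard
information-criterion convention; the choice of 2 is a convention, not
a significance test) **and** the component means are separated by more
than twice the larger component standard deviation — the separation
guard keeps two heavily overlapping components from being called two
peaks. A binned least-squares mode (`method="binned"`) exists for
cross-checking the EM fit against the histogram.

## Synteny blocks

Anchors are 1:1 ortholog pairs placed at their ordinal gene ranks;
chaining runs in rank space (robust to gene-length variation), base
pairs are used only for block spans and coverage. Forward blocks are
chains strictly increasing in both genomes, reverse blocks strictly
decreasing on the second; consecutive anchors may be separated by at
most `max_gap` intervening genes on either genome. Chains are found by
longest-chain dynamic programming per orientation and extracted
greedily, longest first (forward wins ties; among equal-length chains
the lexicographically smallest in anchor order is taken), so each anchor
belongs to at most one block; blocks below `min_anchors` are discarded.
The extraction equals an exhaustive chain-enumeration oracle on small
anchor sets.

Defaults are `min_anchors = 5`, `max_gap = 25` genes, a SyMAP-like scale
for real, noisy anchor sets where many genes lack 1:1 orthologs. With a
*complete* anchor set (every gene anchored, as the rearrangement
simulator produces), the faithful setting is `max_gap = 0`: any positive
gap tolerance lets the longest chain bridge across a rearrangement
breakpoint and steal a boundary anchor from a short inversion, which is
why the exact-boundary recovery tests run at `max_gap = 0`.

Coverage is the union of block spans (overlaps counted once) divided by
the genome length, as a percentage.

## Secretome regression and predictor consensus

The expected type-2 secretome fraction of a Gram-negative proteome is
estimated from proteome size alone:

    percent = 0.0017 * proteome_size + 23.8

with the protein count rounded half away from zero from
`percent/100 * proteome_size`. For a 4067-protein proteome this gives
30.7% — about 1249 proteins. Signal-peptide call sets from two
independent predictors are hardened by intersection (`consensus_calls`).

## Reproducibility and problem sizes

`PipelineConfig` holds one global seed; every stochastic stage derives
its own stream from it (`config.rng(stage)`), so whole-pipeline runs are
bit-reproducible. The test suite's simulation sizes — 40 genomes / 100
permutations for Heaps recovery, 2000 draws for mixture recovery, 120
codon pairs of 300 codons for the selection signature, 200-gene toy
genomes for synteny — are chosen so each recovery test has comfortable
statistical margin while the whole suite runs in well under a minute.
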