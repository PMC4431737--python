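# Methods

## The Functional Tree

The tree has five fixed layers below the root: biological category,
biological process, pathway, module, KO. The upper skeleton
(pathway → process → category) is taken as given input; only module
placement is inferred, from the KO inclusion relationship between module
and pathway KO sets. Two policies are exposed:

* `subset` (default): module `M` is a child of pathway `P` iff
  `KO(M) ⊆ KO(P)`. This matches the reading of a pathway as a collection
  of complete modules.
* `overlap`: one shared KO suffices. This duplicates modules whose KO sets
  straddle pathways, reproducing the multi-placement behavior in which one
  function is visible under every pathway it touches.

A function id may therefore occur at several *placements*. Statistics are
always computed once per function id (over the union of its subtree KO
sets); rendering draws once per placement. Children are ordered
lexicographically by function id, which makes construction, serialization
and layout fully deterministic.

KOs attached to a pathway but to none of that pathway's placed modules
become direct pathway children. KOs in no module and no pathway are kept
under a hidden chain — Undefined Biological Category → Undefined Biological
Process → Undefined Pathway — rather than under a bare category node, so
the layer-order invariant (KO only under module or pathway) holds
uniformly; the same chain receives modules that no pathway contains under
the chosen policy. Hidden KOs are excluded from layout only: they count in
aggregation denominators, coverage totals and the Fisher universe.

Degenerate inputs are rejected rather than repaired: empty tables, ids
used in two layer roles (a self-referential membership), pathways missing
from the skeleton, and non-finite values all raise typed errors naming the
offending ids or line numbers.

## Aggregation (internal node calculation)

For a non-KO function `f` with subtree KO set `S(f)` and input values
`x_k`:

* sum mode: `v(f) = Σ_{k ∈ S(f)} x_k`, missing KOs contributing 0;
* mean mode: `v(f) = Σ x_k / |S(f)|` by default — the denominator counts
  *all* KOs assigned under the function, consistent with the coverage
  definition below, so sparsely covered functions are penalized;
  `observed_denominator=True` divides by the number of KOs present in the
  input instead.

Aggregation is over distinct KO function ids, so a KO under two modules of
one pathway is counted once for that pathway. A function placed under two
pathways contributes its full value to both parents; sum-mode conservation
(root value = input total) therefore holds exactly on trees without
multi-placement, and is tested in that regime.

## Statistics

**Coverage.** `cov_j = KO_exp,j / KO_total,j`, where `KO_total,j` is the
number of KOs assigned under function `j` and `KO_exp,j` the number of
those associated with the query (one observation — one gene, one non-zero
sample — suffices). Coverage down-weights functions whose support in the
data is thin.

**Rank-sum test.** Two independent groups are compared with the Wilcoxon
rank-sum (Mann–Whitney) test using midranks for ties. When both groups
have ≤ 8 observations the p-value is exact: an integer dynamic program
over doubled midranks counts, for every subset size, how many of the
C(n, n₁) rank splits reach each rank sum — equivalent to full enumeration,
with the observed split included in the tail. Above that size, the normal
approximation with tie-corrected variance and continuity correction is
used (via scipy). If all pooled values are identical the test returns
p = 1. Sidedness defaults to one-sided "greater" (is the query larger than
the background?); two-sided is available.

**Fisher's exact test.** One-sided (greater) p-value of a 2×2 table as the
hypergeometric tail: the sum over all margin-preserving tables with
`a' ≥ a` of the factorial point probability, accumulated in log-factorial
space (`lgamma`) for stability. The test suite checks equivalence with an
exact-rational brute-force enumeration for every table with total ≤ 30
(46,375 tables, max relative error ~4e-14) and with scipy's
implementation.

**Multiple testing.** Bonferroni: `p_corr = min(1, m·p)` with `m` the
number of functions actually tested in the family. Families are per
pipeline stage: the metagenome flow corrects its KO-layer tests separately
from its upper-layer Fisher tests; the pan-genomic and gene-list flows
each form one family.

**Display value.** For a significant function (`p_corr < α`, default
α = 0.05), `val = log10(1/p_corr) · cov`; otherwise `val = 0`. The log
base is 10 so that `val` reads as orders of magnitude of significance (a
base flag is exposed; the choice only rescales circle sizes
monotonically). p-values are floored at 1e-300 before the transform, and
p ≤ 0 is an error. In the metagenome pipeline the upper-layer display
value carries *no* coverage factor by default (a `coverage_weight` flag
restores it); the pan-genomic and gene-list pipelines are
coverage-weighted.

**Variability.** `val_j = σ_j · cov_j`, with `σ_j` the standard deviation
across samples of the per-sample summed relative abundance of `S(j)`.
Population σ (ddof 0) by default, sample σ via a flag. Requires ≥ 2
samples and rows summing to 1 (tolerance 1e-6).

**Pipelines.**

* *Pan-genomic* (`enrich_genus`): per function, per-organism gene counts
  summed over `S(f)` are rank-tested, focal organisms vs all others;
  `KO_exp` counts KOs with at least one gene in any focal organism.
  Functions absent from every organism are reported untested (p = 1,
  val = 0).
* *Metagenome* (`enrich_metagenome`): stage 1 rank-tests each KO's
  relative abundance, query vs background, and flags KOs with corrected
  p < α as enriched (a raw-p option exists). Stage 2 builds, for each
  non-KO function, the 2×2 table enriched×assigned over the **full** KO
  universe including hidden KOs, and applies Fisher's exact test.
* *Gene list* (`enrich_genelist`): a gene associates with a function iff
  it maps to a KO under it; Fisher on (in-list × associated) over the
  genome-wide gene universe; `KO_exp` counts KOs hit by at least one
  input gene. An empty gene list, or genes outside the universe, are
  errors.

## Rendering

Visible leaves are evenly spaced on the circle in child order, angular
origin at 12 o'clock, clockwise (both configurable); each internal node
sits on its layer ring at the mean of its children's angles. `center_on`
restricts layout to one placement's subtree spanning the full circle.
Value scaling maps the positive values' range [v_min, v_max] onto
[r_min, r_max] (defaults 2–14 px), linearly in the radius or in the circle
area; non-positive values draw nothing. Edges are drawn as
arc-then-radial paths (a straight-line flag exists); multi-placement
functions are drawn at every placement with identical styling. Output is
SVG 1.1 with deterministic element and attribute order — identical
invocations produce identical bytes.

## Synthetic data

The generators produce exchangeable null data at effect size 1 and a
controllable multiplicative planted signal otherwise; they do not attempt
to emulate real ontology topology, compositional correlation structure,
phylogenetic dependence between organisms, or realistic abundance tails.
Passing tests therefore demonstrate correctness of the machinery and
calibration under the generating model, not performance on real survey
data.

The named **standard scenario**: 2 categories, 4 processes, 12 pathways,
30 modules, 300 KOs, 10% unassigned KOs, 20 query + 20 background samples,
one planted pathway (`P0001`) at effect 3×. Each pathway receives at least
one KO; each module samples a subset of one host pathway's KOs (so subset
attachment always succeeds); 10% of assigned KOs join a second pathway to
exercise multi-placement.

Abundances are i.i.d. log-normal per sample and KO with σ = 0.5, planted
KOs multiplied by the effect in query samples, rows renormalized to sum
to 1. σ = 0.5 places the standard scenario's 3× effect in a regime where
stage-1 KO tests have substantial but not saturating power under
Bonferroni over 300 KOs — the regime the planted-recovery property of the
scenario presumes.

Gene counts are Poisson with rate 2 per organism and KO over 16 organisms
of which 8 are focal; focal rates on planted KOs are multiplied by the
effect. Both rank-test groups thus stay within the exact-enumeration
limit, so saturated tests have an exact, identical floor p = 1/C(16,8)
rather than approximation-noise-ordered values — with the consequence that
a fully planted pathway and its fully planted modules can tie at the
maximum display value, which is how recovery is scored. The gene universe
has 2 genes per KO plus 60 unmapped genes; the query list samples 30
genes from planted-KO genes and 20 uniformly elsewhere — except at effect
≤ 1, where the whole list is drawn uniformly (the exchangeable null).

All generators draw from `numpy` Generators seeded by (config seed,
stream id) and are bit-reproducible.

## Numerical choices and limitations

* Exact rank-sum enumeration bound: 8 per group (C(16,8) = 12,870 splits);
  beyond it the tie-corrected normal approximation can be slightly
  conservative or liberal at very small sizes, as usual.
* Two-sided exact p is 2·min(lower tail, upper tail), capped at 1.
* Fisher p-values are clipped into [0, 1] after summation; contingency
  cells must be non-negative with positive total.
* Scaling with a single distinct positive value maps it to r_max.
* Aggregation/coverage are undefined for functions with zero assigned
  KOs (possible only for empty input pathways); such functions are
  skipped or rejected, never silently zeroed.
* Bonferroni is deliberately the only correction offered; FDR control is
  out of scope.
* The circular layout assigns angles by leaf count, not subtree size; a
  pathway with many KOs occupies proportionally more arc, which matches
  the dendrogram aesthetic but is not an information-preserving area
  encoding.
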