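# Methods

## Model and procedure

`bgcrank` treats a comparative genome-mining screen as a two-layer
object: a species → section taxonomy, and per-species feature
observations (counts of BGC backbone-enzyme classes, or individual
metabolite/AMP hits carrying a % sequence match and a free-text
annotation). Analysis proceeds in four stages.

**1. Reduction to counts.** Hits are reduced to per-(species, feature)
counts by one of three rules: a similarity-threshold split (≥ 75 % vs
< 75 % match, the bound inclusive on the high side), six-way %-match
binning with an exclusion floor, or keyword categorization of
annotations. The AMP bins are {100}, [95, 100), [90, 95), [80, 90),
[70, 80) and [51, 70), labelled with their printed forms (100,
99.9–95.0, …, 69.9–51.0); anything below 51.0 — i.e. 50.9 and under,
given one-decimal recording — is excluded, and the exclusion count is
always reported. The exact-100 bin plus half-open intervals make every
one-decimal value decidable, including awkward cases like 89.95 (which
lands in 89.9–80.0). Keyword matching is ordered, first-match-wins,
case-insensitive substring; unmatched or empty annotations fall to a
fallback label. Both schemes are configurable via YAML; the shipped
defaults encode the bins above and the seven annotation categories
commonly surfaced by NCBI keyword summaries (hypothetical protein,
glycoside hydrolase family, cytochrome P450 family, non-ribosomal
peptide synthetase, ABC transporter, glycosyltransferase, peptidase).

**2. Section averaging.** For section s and category c,
w(s, c) = Σ_{i ∈ s} x(i, c) / n_s, where n_s counts *all* species
assigned to the section — a species with no recorded observation
contributes zero to the numerator but still sits in the denominator.
The alternative (observed-species-only denominators) would inflate
sparse sections; the inclusive convention reads "average over all the
species in a section" literally and keeps the identity
w(s, c) · n_s = section sum exact, which the tests verify directly.
Averaging is linear, so doubling every count doubles every cell.

**3. Graph construction.** Each section and each category with at least
one positive average becomes a node; every positive cell becomes a
directed edge section → category with weight w(s, c). Zero cells
produce no edge; all-zero categories are dropped by default (a flag
retains them as isolated nodes). An optional `binarize` flag sets all
weights to 1, for comparison with an unweighted reading of the graph.

**4. Centrality.** Strength is the weighted degree (out for sections,
in for features). Receiving PageRank is the stationary vector of the
damped random walk: from a node with out-edges, follow edge (v, u) with
probability w(v, u)/k_out(v); from a dangling node (every feature node
in this bipartite layout), jump uniformly over all nodes; with
probability 1 − α teleport uniformly. Broadcasting PageRank is the same
computation on the edge-reversed graph — the two are exact duals, and
the test suite asserts `broadcast(G) == receive(reverse(G))` node-wise
with no tolerance because they share one code path. Broadcasting via
edge reversal is this package's operationalization of
broadcasting/receiving centrality for a static weighted digraph: a
section is influential when it points, heavily, at categories that
themselves rank highly. Scores are min-max normalized separately within
the section and the feature node class, mirroring paired bar panels
that each span [0, 1]; a degenerate range (all scores equal, which is
structural for the receive scores of sections and the broadcast scores
of features in a purely bipartite graph — uniform teleport and dangling
redistribution treat them identically) maps to all-zeros with a logged
warning, since no variation carries no ranking signal. Ranking is
dense, per (node class, measure), descending raw score with ties broken
by ascending label.

## Numerical choices

* **Damping α = 0.85**, the canonical choice; configurable in (0, 1).
* **Power iteration**, L1 stopping tolerance 1e-10 (default), cap 1000
  iterations; non-convergence raises an error carrying the last
  residual rather than returning a partial vector. On every graph the
  acceptance machinery checks the iterate against a dense
  (I − αMᵀ)π = (1−α)/n · 1 solve; agreement is ~1e-14 at a 1e-13
  tolerance, far inside the 1e-8 bound asserted.
* **Worked closed form.** For the single-edge graph S1 → C1 at α = 0.85
  the 2×2 solve gives π(S1) = 0.350877…, π(C1) = 0.649123…; this pair
  is frozen in the tests and recomputed by the acceptance script.
* PageRank is invariant to uniform rescaling of weights (transitions
  are weight ratios); strengths scale linearly. Both are asserted.

## Synthetic data: what it emulates and what it does not

The generator emulates the *statistical shape* of predictor outputs,
not the predictors: per-(species, category) counts are independent
Poisson(λ) draws with λ = `base_rate`, multiplied by
`effect_multiplier` (≥ 1) for species of one planted section; each
counted event becomes a hit whose % match is drawn from a named
distribution (uniform over [0, 100] by default, or a Beta(5, 1)
high-skew variant mimicking screens dominated by close homologs) and
rounded to one decimal, with annotations drawn from a weighted keyword
mixture. Defaults — 5 sections × 5 species, base rate 4, five
backbone-class labels — match the scale of a mid-sized fungal genus
screen (tens of genomes, a handful of sections). Poisson was chosen as
the simplest model for "number of times a category is observed"; real
per-genome BGC counts are plausibly overdispersed, and a
negative-binomial option would be the natural extension for power
studies. The generator does not simulate genome sequences, cluster
boundaries, predictor error modes, or phylogenetic correlation between
related species — so passing the planted-recovery test shows the
pipeline detects a genuine multiplicative section effect under clean
sampling noise, not that it is robust to annotation bias or taxon
misassignment in real screens.

Each of the three tables draws from its own RNG stream spawned from the
master seed (numpy `SeedSequence(seed, spawn_key=(k,))`, k fixed per
table), so regenerating or adding one table never perturbs another's
draws, and identical configurations are byte-identical after writing.

The planted-recovery study condition used by the tests and the
acceptance script is 4 sections × 5 species, 10 categories, λ = 2,
effect ×5, 100 seeds; the planted section must top the broadcast
ranking in at least 95 runs (observed: 100).

## Degenerate inputs and edge cases

* Header-only TSVs load as empty tables; empty tables round-trip.
* A hit table whose every hit falls below the metabolite threshold (or
  the AMP floor) yields an empty graph; the pipeline raises a staged
  error naming `graph` rather than emitting empty rankings.
* Species with zero totals are *absent* from the hypothetical-protein
  fraction (0/0 is undefined, not zero) but present, with total 0, in
  genome totals and section denominators.
* Validation is total: duplicate species ids, negative or non-integer
  counts, out-of-range or unparseable match percentages each raise a
  typed error citing the offending row or id; nothing loads partially.

## Open design choices taken

* **Keyword restriction for the AMP keyword analysis**: annotation
  categories are counted over hits in the ≥ 95 % match bins by default
  (matching how top-annotation summaries are usually restricted to
  high-confidence hits); `restrict_keywords_to_high_match=False` counts
  all retained hits instead.
* **Top-k annotation lists** exclude the fallback category by default
  (hypothetical/unannotated mass otherwise swamps the list); pass
  `exclude=()` to rank everything.
* **Per-class normalization** (sections among sections, features among
  features) rather than joint: each reported panel spans one node class.
* **Run manifests carry no timestamps**, so identical runs are
  byte-identical — determinism is treated as part of the output
  contract, not a convenience.

## Limitations

* Broadcasting/receiving via edge reversal is an interpretation; other
  operationalizations (e.g. dynamic communicability on temporal
  networks) answer different questions and are out of scope.
* The pipeline starts from prediction tables in the canonical TSV
  dialects; converters from native predictor output formats are thin
  adapters left to the caller.
* Row order of heatmap-style outputs follows the taxonomy file; no
  phylogeny is constructed or used for ordering.
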