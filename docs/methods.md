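# Methods

`crowdval` implements the analysis pipeline used to validate a distantly
supervised biomedical relation corpus by crowdsourcing: a silver-standard
corpus of phenotype–gene relation candidates is partitioned into annotation
tasks, each sentence is shown to one or more paid raters as a three-option
classification micro-task, the resulting votes are adjudicated into a single
label per relation, the raters' reliability is summarised by chance-corrected
agreement coefficients, and the kept relations are merged into a revised
corpus release for downstream relation-extraction training.

## Data model

A relation instance is one sentence with a phenotype mention and a gene
mention (0-based half-open character offsets that must reproduce the surface
text, non-overlapping spans) plus two label layers:

* the **original label** from distant supervision — `KNOWN` if the pair is in
  the phenotype-ontology knowledge base, `UNKNOWN` otherwise; mapped to a
  baseline `TRUE` / `FALSE` when a revision starts;
* the **revised label** — `TRUE`, `FALSE`, or `EXCLUDE` (a pre-annotation
  error: wrong entity recognition or broken sentence), assigned by raters and
  adjudication.

The on-disk corpus format is a fixed-schema UTF-8 TSV, one relation per line;
literal tabs and newlines inside sentences are rejected on write and read so
the file stays diff-able. The corpus file schema is this package's own
convention: it carries exactly the fields the pipeline needs and nothing else.

## Task partition

`partition_corpus` shuffles uniformly under a stated seed and assigns the
first `floor(fraction * N)` instances to the first task. A 70/30 split of a
7963-relation corpus therefore yields tasks of 5574 and 2389 relations. An
optional stratified mode preserves original-label proportions within one
instance per stratum by largest-remainder apportionment; the default is
non-stratified, consistent with the small drift between the two partitions'
label shares that a uniform shuffle produces.

## Adjudication rule

Given a relation's multiset of `m` votes, with counts
`(n_true, n_false, n_exclude)`:

1. **exclude** if `n_exclude >= m / 2` ("at least half"), compared in exact
   arithmetic so 4-of-8 and 4-of-7 exclude while 3-of-7 does not;
2. else **true** if `n_true > m / 2` — an absolute majority of all votes
   agrees the relation holds (the default `ABSOLUTE_MAJORITY` rule);
3. else **false** — the default label for a kept relation with no agreement,
   on the argument that false relations are the harder call and a false
   positive harms downstream training more than a false negative.

With one vote the rule degenerates to a passthrough, so the same operation
serves a single-assignment task and a seven-assignment task. A
`PLURALITY_OVER_FALSE` variant (true merely needs `n_true > n_false`) is kept
as a policy switch; the two rules coincide for binary votes with an odd
assignment count. Absolute majority is the default because it is the only
reading under which every worked example of the consensus flowchart holds
simultaneously — in particular an 8-vote `(3 true, 2 false, 3 exclude)` split
is kept-but-false (no agreement on true), while a 7-vote `(4, 2, 1)` split is
true.

The exclusion threshold (default 1/2) and the default label are policy
parameters; thresholds are fractions of the total vote count, not of the
true/false subset.

## Agreement coefficients

Both coefficients are computed over the items-by-categories count table of a
rater group (crowd only; crowd plus the on-site extra rater; extra rater plus
domain expert).

* **Fleiss' kappa** `(P̄ − P̄ₑ)/(1 − P̄ₑ)` for complete designs (every item
  rated by the same number n ≥ 2 of raters). The implementation is the
  textbook formulation; the test suite cross-checks it against
  `statsmodels.stats.inter_rater.fleiss_kappa` on random tables and against a
  hand-evaluated two-item micro-example (κ = −1/3).
* **Krippendorff's alpha**, nominal difference function, from the coincidence
  matrix `o_ck = Σ_u n_uc (n_uk − δ_ck) / (m_u − 1)` with `α = 1 − D_o/D_e`.
  Items with fewer than two ratings contribute no pairable values and are
  ignored. The hand-computed oracle `{a,a}, {a,b} → α = 0` is frozen in the
  tests. No third-party alpha implementation is used; this one is validated
  against the micro-oracles and against kappa's large-N limit.

When all ratings fall in one category the chance-corrected denominator is
zero; both functions raise an explicit undefined-agreement error instead of
returning NaN. On complete designs the two coefficients differ only by
alpha's finite-sample correction, so `|α − κ| → 0` as the item count grows;
the suite asserts `|α − κ| ≤ 0.01` at N = 1000 simulated items and that both
coefficients sit within ±0.02 of zero for uniform-random raters at N = 5000.

Qualitative banding follows the Landis–Koch scale (`<0` poor, `[0, 0.20]`
slight, `(0.20, 0.40]` fair, `(0.40, 0.60]` moderate, `(0.60, 0.80]`
substantial, `>0.80` almost perfect). Because values a few thousandths above
0.20 are qualitatively borderline, the report hedges with the adjacent band
whenever a value is within 0.005 of a boundary ("slight to fair"). Neither
coefficient's design assumptions exactly match a marketplace campaign (raters
are neither fixed nor missing-at-random), so the report also carries
rater-overlap diagnostics — distinct raters and mean ratings per rater —
rather than attempting a corrected estimator.

## Costs, worker statistics, class weights

The cost model is `n_tasks × assignments × (reward + fee)` in exact cent
arithmetic (`decimal.Decimal`). The platform rounds the per-assignment fee up
to the cent, so a sub-cent surcharge for requiring high-performing workers is
absorbed whenever the base fee already sits at a cent boundary — the modelled
behaviour is the observed one (totals unchanged), not a reconstruction of the
platform's internal fee formula.

Work-time statistics use a cutoff (default 50 s, i.e. keep times ≤ 50, the
assignments completed in under 51 s): anything longer is treated as a
mid-task break, not rating effort. The cutoff applies to *statistics only* —
adjudication always uses the unfiltered votes. Histogram bins are 1 s wide on
`[0, cutoff]`. Assignments-per-worker is rounded half-up (22,255/64 → 348).
Printed percentages are rounded half-up to two decimals; half-up (not
banker's) rounding is required to reproduce the published aggregates
(0.81785 → 0.8179, 347.73 → 348).

The class-imbalance "full multiplier" is the majority/minority count ratio of
the training labels (equal to the ratio of their percentages); the weight
actually exported defaults to 5, a value between 1 and the full multiplier,
which keeps some of the natural imbalance visible to the model.

## Release building

A release merges two disjoint adjudicated partitions, drops `EXCLUDE`
instances, and recounts everything from the merged corpus: abstracts as
distinct PMIDs among kept relations, annotations as distinct kept mentions
(PMID + span + identifier) — mentions not participating in kept relations do
not count. The manifest also reports the recomputed exclusion rate over the
combined original totals; with the published per-task counts this is 23.06%,
and the manifest flags that recomputed value as the authoritative one. Export
writes one-row-per-relation TSVs with the two mentions replaced by typed
placeholders (`@PHENOTYPE$`, `@GENE$`), the common input convention of
sentence-level relation-extraction systems.

## Synthetic campaigns

The simulator generates what the real campaign would have produced, with
known ground truth:

* **latent labels** drawn i.i.d. from a three-way distribution; the default
  (0.5362, 0.1436, 0.3202) is the expert-reviewed composition of such a
  corpus, making "exclude-worthy" items roughly a third of the stream;
* **worker pool**: each item is assigned to `a` distinct workers sampled
  uniformly without replacement from a pool of `W` (default 33 workers, 7
  assignments — the redundant-annotation task design); no workload cap, so
  heavy-tailed per-worker HIT counts emerge rather than being imposed;
* **answers** drawn from the worker's 3×3 row-stochastic confusion matrix for
  the latent label; a malicious worker answers uniformly at random. The
  default pool cycles accuracy tiers θ ∈ {0.6, 0.8, 0.95} with 5% malicious
  workers — plausible placeholders, not estimates fitted to any campaign;
* **work times**: lognormal(μ = 2.4, σ = 0.6) "genuine effort" (mean ≈ 13 s)
  plus a rare break component (probability 0.005, exponential mean 3000 s)
  that reproduces occasional multi-hour completion times;
* **seeding**: one master `SeedSequence` spawns a substream per item, so any
  prefix of a campaign is reproducible in isolation.

The exact consensus-accuracy oracle enumerates binomial vote outcomes for
homogeneous binary workers (accuracy θ, odd assignment count a) and applies
the adjudication policy: at θ = 0.8, a = 7 the consensus recovers the latent
label with probability 0.9667. This quantifies why seven assignments beat
fewer: accuracy is non-decreasing in a for θ > 0.5, and consensus beats a
single worker throughout (0.5, 1). Even assignment counts are refused because
ties change the rule's semantics. `recover_parameters_check` runs the full
loop — simulate, adjudicate, compare to the oracle within a 95% binomial
interval, and compare empirical κ/α against a 10× re-simulation.

### What the simulator does not emulate

Real campaigns have item-difficulty heterogeneity (sentence complexity),
worker learning and fatigue, label-dependent error structure beyond the
confusion matrix, and non-random worker/item assignment (fast workers grab
more HITs). Passing tests therefore demonstrate that the pipeline's
*computations* are correct under a known generative model, not that any
particular agreement value or accuracy would be observed on real annotation
data.

## Problem sizes and numerical choices

The simulation-backed tests use 1000 items for the α/κ convergence check,
5000 for the chance-agreement check, and 2000 for the consensus-accuracy
check — sizes at which the Monte-Carlo noise is comfortably inside the
asserted tolerances (binomial s.e. ≈ 0.004 at n = 2000). Exclusion-threshold
comparisons use exact rational arithmetic in the test oracle and plain float
arithmetic (threshold 0.5 is exactly representable) in the implementation.
Degenerate inputs are errors, not silent results: empty vote sets, unvoted
relations, single-category agreement tables, zero false counts in the
multiplier, empty test sets on export.

## Known limitations

* Fleiss' kappa requires a complete design; campaigns with ragged per-item
  rater counts get alpha only.
* The published abstract/annotation counts of a real release cannot be
  reproduced from count triples alone (they need the actual corpus); the
  counting *rules* are implemented and tested on fixtures.
* No probabilistic label aggregation (Dawid–Skene style) and no worker
  confusion-matrix estimation from data; adjudication is the deterministic
  voting rule by design.
* Agreement confidence intervals are not computed; the pipeline reports point
  values, matching its reporting conventions.
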