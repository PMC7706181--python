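# crowdval

Crowdsourcing validation of distantly supervised relation corpora.

Silver-standard corpora — e.g. phenotype–gene relation candidates labeled
`Known`/`Unknown` by aligning PubMed sentences with an ontology's knowledge
base — are cheap but noisy: wrong entity annotations, broken sentences, and
`Unknown` pairs that are in fact true relations. `crowdval` is for corpus
curators who want to clean such a corpus with a paid micro-task platform
instead of (or alongside) domain experts. It implements the full validation
pipeline as a library plus a thin CLI:

* **corpus I/O and partitioning** — a fixed-schema TSV corpus, original→baseline
  label mapping, and a seeded 70/30 (or any-fraction) task split;
* **HIT management** — render each relation as a three-option classification
  task (true relation / false relation / wrongly labeled), write batch input
  CSVs, and ingest marketplace batch-result CSVs into a vote ledger with an
  anomaly report (unattributed rows, duplicate votes);
* **consensus adjudication** — per relation with `m` votes and counts
  `(n_true, n_false, n_exclude)`: EXCLUDE if `n_exclude ≥ m/2`, else TRUE if
  `n_true > m/2`, else FALSE (the default for a kept relation with no
  agreement); single-vote relations pass through;
* **inter-rater agreement** — Fleiss' κ = (P̄ − P̄ₑ)/(1 − P̄ₑ) for complete
  designs and Krippendorff's α = 1 − D_o/D_e (nominal, coincidence-matrix
  form) for ragged ones, per rater group, with Landis–Koch qualitative bands;
* **statistics** — campaign cost model in exact cents, work-time summaries
  under a break cutoff, label distributions, class-imbalance multipliers, and
  benchmark F-measure aggregation;
* **release building** — merge adjudicated partitions, drop excluded
  relations, recount abstracts/annotations, export placeholder-TSV train/test
  splits with class-weight metadata;
* **campaign simulation** — synthetic campaigns with latent labels, per-worker
  confusion-matrix reliability (including uniform-random "malicious" workers),
  unique workers per item, and heavy-tailed work times, so every stage is
  testable end to end with known ground truth.

See `docs/methods.md` for the underlying models and design choices.

## Worked example

Simulate a 500-item campaign with the default heterogeneous worker pool
(accuracy tiers 0.6/0.8/0.95, 5% malicious, 33 workers, 7 distinct workers
per item), adjudicate it, and measure agreement:

```python
from crowdval import (AdjudicationPolicy, CampaignConfig, RaterSource,
                      adjudicate_corpus, agreement_report, default_worker_pool,
                      label_distribution, sample_campaign)

config = CampaignConfig(n_items=500, n_workers=33, assignments_per_item=7, seed=7)
truth, votes = sample_campaign(config, default_worker_pool(33))

labeled, exclusions = adjudicate_corpus(corpus, votes, AdjudicationPolicy())
dist = label_distribution(labeled)
print(f"true {dist.n_true} ({dist.pct_true}%) / false {dist.n_false} "
      f"({dist.pct_false}%) / excluded {dist.n_excluded} ({dist.pct_excluded}%)")

(report,) = agreement_report(votes, {"workers": (RaterSource.CROWD,)})
print(f"Fleiss' kappa = {report.fleiss_kappa:.4f}, Krippendorff's alpha = "
      f"{report.krippendorff_alpha:.4f} ({report.qualitative}), "
      f"deviation = {report.deviation:.4f}")

acc = sum(inst.revised_label is truth[inst.relation_id] for inst in labeled) / 500
print(f"consensus recovered the latent label on {acc:.1%} of items")
```

(`corpus` is any `Corpus` whose relation ids match the simulated items — see
`tests/test_cli.py` for a complete script.) Output:

```
true 238 (47.6%) / false 105 (21.0%) / excluded 157 (31.4%)
Fleiss' kappa = 0.3888, Krippendorff's alpha = 0.3890 (fair), deviation = 0.0002
consensus recovered the latent label on 95.6% of items
```

The adjudicated label mix tracks the latent mix (≈54/14/32) with the usual
consensus compression; κ and α nearly coincide because the design is complete
(7 ratings per item), and their "fair" band reflects the mixed-reliability
pool, not the pipeline's accuracy — seven-way consensus still recovers over
95% of latent labels.

The same flow from a shell:

```sh
crowdval simulate --items 500 --seed 7 --out votes.csv --truth truth.tsv
crowdval ingest votes.csv --anomalies anomalies.json
crowdval adjudicate corpus.tsv votes.csv --out adjudicated.tsv
crowdval agree votes.csv
crowdval stats cost --tasks 5574 --assignments 1    # -> 167.22
```

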