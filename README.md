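# viropop

Viral population ecology from depth-stratified metagenomes.

Oxygen-deficient water columns — and permanently euxinic basins in
particular — harbor viral communities that are hard to study with
culture-based methods: most of what we know comes from viromes, i.e.
shotgun-sequenced viral particle concentrates. `viropop` implements the
standard inference chain such a study needs once assembly and tool runs
are done, as a tested, reusable Python library with a CLI:

* **Viral identification** — integrates VirSorter categories, VirFinder
  scores, CAT and PHASTER calls into high/medium/none confidence tiers
  with a fixed, auditable rule order.
* **Population clustering** — groups contigs > 5 kbp into species-level
  *viral populations* at ≥ 95% average nucleotide identity (ANI) over
  ≥ 80% of the shorter sequence, longest member as representative. ANI is
  computed by an anchored seeded-chain aligner, with an exact
  dynamic-programming route for short sequences that doubles as the test
  oracle.
* **Recruitment abundance** — applies read-retention filters (identity
  ≥ 95% over ≥ 90% of the read), the strict 75% contig-breadth rule, and
  normalizes mean depth per Gbp of library into a relative-abundance
  proxy.
* **Ecology** — Shannon/Pielou evenness, second-order jackknife richness,
  permutation accumulation curves, Bray–Curtis dissimilarities,
  Manhattan-distance dendrograms, and endemism/habitat-exclusivity
  classes (euxinic-only, redoxcline-only, …, cosmopolitan).
* **Gene-sharing genera** — hypergeometric significance of shared
  protein-cluster counts between populations, thresholded into a network
  whose dense components approximate genera (clustered / outlier /
  singleton statuses).
* **AMG context** — adjudicates putative auxiliary metabolic genes by
  genomic context: interior vs edge placement, virus-like flanking genes,
  and genome-boundary evidence (attL/attR, termini, prophage spans).
* **Synthetic viromes** — a ground-truthed generator (populations with
  controlled intra/inter divergence, zone-structured log-normal
  abundances, planted tiers and exclusivity classes, configurable
  evidence confusion and read error) so the whole chain is testable
  without any external data.

See `docs/methods.md` for the models, parameter defaults and their
rationale, and known limitations.

## Worked example

```python
from viropop import SimulationPlan, simulate_virome, cluster_populations
from viropop.recruitment_abundance import (
    filter_alignments, contig_coverage, build_abundance_matrix,
)
from viropop.ecology import diversity_report, classify_distribution

plan = SimulationPlan(n_populations=8, members_per_population=2,
                      target_depth=30, seed=4)
contigs, alignments, evidence, truth = simulate_virome(plan)

populations = cluster_populations(contigs)
print(f"{len(populations)} viral populations from {len(contigs)} contigs")

by_id = {c.contig_id: c for c in contigs}
coverages = []
for sample in plan.zones:
    kept = filter_alignments(alignments[sample.sample_id])
    per_contig = {}
    for a in kept:
        per_contig.setdefault(a.contig_id, []).append(a)
    coverages += [contig_coverage(rows, by_id[cid], sample)
                  for cid, rows in per_contig.items()]
matrix = build_abundance_matrix(coverages, populations, list(plan.zones))

for r in diversity_report(matrix):
    print(f"{r.sample_id}: S={r.observed_richness}  H'={r.shannon:.3f}  "
          f"J={r.pielou_j:.3f}  jack2={r.jackknife2:.1f}")

zone_of = {s.sample_id: s.zone for s in plan.zones}
for c in classify_distribution(matrix, zone_of):
    print(c.population_id, c.exclusivity)
```

Output:

```
8 viral populations from 16 contigs
s148: S=4  H'=0.566  J=0.409  jack2=10.0
s200: S=4  H'=1.119  J=0.807  jack2=10.0
s237: S=5  H'=1.481  J=0.920  jack2=10.0
s247: S=5  H'=1.098  J=0.682  jack2=10.0
s267: S=5  H'=1.417  J=0.881  jack2=10.0
s900: S=6  H'=1.566  J=0.874  jack2=10.0
P000_c00 oxygenated_only
...
P004_c00 euxinic_only
P006_c00 redoxcline_only
P007_c00 indeterminate
```

The clustering recovers the 8 planted populations exactly. Per sample you
get observed richness S, Shannon H′ (natural log), Pielou's evenness
J = H′/ln S, and the dataset-wide jackknife-2 richness estimate (10.0
here: 8 observed plus a correction for the populations seen in only one
or two samples). The distribution classes reflect the planted habitat
structure: populations detected only in the 900 m euxinic sample are
`euxinic_only`, the near-undetectable population (planted at 0.05×
coverage, below the 75% breadth rule) is `indeterminate`.

The same pipeline is available as shell subcommands
(`viropop simulate | classify | cluster | recruit | ecology | genera |
amg`); run any of them with `--help`.

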