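# Methods

`viropop` implements the desk half of a water-column virome study: it takes
assembled contigs, the outputs of virus-detection tools, and read-to-contig
alignment summaries, and turns them into viral populations, abundance
profiles, community-ecology statistics, genus-scale gene-sharing clusters,
and context-adjudicated AMG calls. The package ships its own synthetic
virome generator with planted ground truth, so every stage is validated
against known answers rather than against external downloads.

## Viral identification tiers

Four evidence sources per contig — a VirSorter category (1–6), a VirFinder
score, a CAT viral call, a PHASTER prophage call — are folded into
high/medium/none confidence tiers with a fixed rule order:

* high: VirSorter ∈ {1,2}, or VirFinder > 0.9 (strict);
* medium: VirSorter ∈ {4,5,6} confirmed by PHASTER; or VirSorter 3 with
  VirFinder ∈ [0.7, 0.9] (inclusive) confirmed by CAT; or exactly one of
  the two detectors identifies the contig (VirSorter 1–3, VirFinder ≥ 0.7);
* none otherwise. Contigs shorter than 1.5 kbp are dropped before
  classification.

"Identified by only one detector" needed a precise reading: we count a
detector as identifying a contig when it makes a positive non-prophage
call (VirSorter categories 1–3; VirFinder ≥ 0.7, the lower bound of the
medium band). A consequence worth knowing: with VirSorter 3 and no CAT
validation, raising VirFinder from below 0.7 (single-detector medium) to
0.7–0.9 (two detectors, CAT rule unmet) demotes the tier to none. This
non-monotone boundary follows directly from the rule list; the engine
pins it in a test rather than smoothing it away. Missing evidence (`"."`)
is distinct from a zero score and from a negative call.

## ANI and population clustering

Populations are species-level clusters: contigs > 5 kbp joined at
ANI ≥ 95% over ≥ 80% of the shorter sequence, longest member as
representative.

Two ANI routes share one interface:

* **Seeded chain** (default for sequences > 2 kb): exact-match 15-mer
  seeds on both strands, grouped into gap-free diagonal blocks, best
  colinear chain by match count, terminal blocks extended gap-free to the
  overlap ends. ANI is matches over chained columns; aligned fraction is
  chained columns over the shorter length. K-mers occurring more than 8
  times in the indexed sequence are skipped to avoid repeat-induced junk
  diagonals; a perfectly periodic sequence therefore needs the DP route.
  N never matches anything (distinct sentinel codes on each side).
* **Dynamic programming** (exact; mandatory ≤ 2 kb): unit-cost semi-global
  alignment of the shorter sequence within the longer (edlib), ANI read
  off the extended CIGAR. This is also the independent oracle: on random
  substitution-divergent pairs in the 0–10% divergence band — the regime
  in which the 95% threshold decides anything — the two routes agree
  within 0.5 percentage points (measured max ≈ 0.2–0.4). At divergences
  beyond ~15% the routes drift apart by up to ~1 point because edit-based
  alignment can trade substitution runs for indels; both report ANI far
  below 95 there, so clustering decisions are unaffected.

Clustering is greedy longest-first (dereplication style): scan contigs by
descending length (ties by id), join the first population whose
representative matches at both thresholds (inclusive), else found a new
population. The explicit sort makes the partition invariant to input
order; member-to-representative identity is what is enforced, matching
common dereplication practice, not member-to-member.

## Recruitment abundance

Alignment summaries (PAF) are filtered at read identity ≥ 95%
(100·matches/aligned-span, so gap columns count against identity) over
≥ 90% of the read; both inclusive. Per contig and sample, breadth is the
interval union of retained alignments over the contig length, and
coverage is retained only when breadth exceeds 75% strictly. The
abundance proxy is

    normalized_abundance = mean_depth / metagenome_size_Gbp,

mean depth already normalizing by contig length and the Gbp divisor by
library size; any fixed monotone variant would do for the downstream
comparative analyses, and this one keeps the units legible (depth per Gbp
sequenced). Detection, for ecology, means a non-zero normalized
abundance, i.e. the breadth rule passed.

## Ecology

Shannon entropy is natural-log; Pielou's J = H′/ln S is undefined (None,
never 0) below two populations. Richness uses the Burnham–Overton
second-order jackknife, S_obs + Q1(2n−3)/n − Q2(n−2)²/(n(n−1)).
Accumulation curves average cumulative richness over 100 random sample
orderings, and the final-step detection rate is the mean fraction of
observed populations first seen when the last sample is added.
Bray–Curtis dissimilarity is computed on abundance columns (NaN flag for
pairs of empty samples). The dendrogram is agglomerative clustering on
Manhattan distances; average linkage (UPGMA) is used because the upstream
tool's default is average and nothing in the analysis depends on linkage
beyond reproducibility. Equal-height merges break toward the
earliest-created cluster pair, making the Newick output deterministic;
support values (bootstrap/AU) are out of scope.

Habitat classes come from the set of zones in which a population's
abundance exceeds `epsilon` (default 0: any passed-breadth detection):
euxinic-only, redoxcline-only, both anoxic zones, any oxic-containing set
(cosmopolitan when also found in the reference virome set, otherwise
oxygenated-only endemic), or indeterminate when never detected —
the "near undetectable" case. `epsilon` is configurable because the
underlying studies imply, but never state, a small positive cutoff.

## Gene-sharing genera

Populations are nodes; the edge weight between two PC profiles is
−log10 of the hypergeometric upper-tail probability of their shared PC
count given the global PC universe, computed with log-gamma and
log-sum-exp. Edges at score ≥ 1.0 (P ≤ 0.1, configurable) are kept.
Genus calling is intentionally simple: connected components of size ≥ 2
with internal density ≥ 0.5 become genera; members with at least one
internal edge are clustered, weakly attached nodes and members of
rejected components are outliers, isolated nodes singletons. This is
comparable in kind (genera/outliers/singletons), not in exact membership,
to ClusterONE/MCL-based tools. Note the score scale is universe-dependent:
in small planted universes (tens of PCs) even a fully shared genus core
scores ~3–5, so thresholds in the tens only make sense for large
catalogues.

## AMG adjudication

An AMG candidate is judged by where it sits and what surrounds it:
interior placement requires ≥ `edge_margin` (default 3) genes to both
contig ends and containment in any predicted prophage span; flank support
counts virus-like genes within `window` (default 5) genes per side;
boundary status is genome-bounded (attL+attR or predicted termini),
partial (one att), or unbounded. Confidence: high = interior with both
flanks supported; medium = interior with one flank, or edge but
genome-bounded; low otherwise — an edge AMG without boundary evidence may
simply be packaged host DNA. The defaults formalize qualitative
"interior"/"edge" reasoning; both are configuration parameters. Coverage
consistency across the AMG region is reported (mean depth) but never
auto-adjudicated.

## Synthetic data: what it emulates and what it does not

The generator plants: six samples spanning oxic (148, 200 m), redoxcline
(237, 247, 267 m) and euxinic (900 m) depths with 1 Gbp libraries; 20
populations of 20 kb genomes (3 members by default in recovery runs, the
representative full-length and other members truncated to 90–99% so the
longest-member rule is exercised); intra-population divergence 2% and
inter-population divergence ≥ 15% (each representative mutated from a
shared ancestor at rate 0.15, giving pairwise divergence ≈ 26%);
log-normal (μ=0, σ=1) per-sample fold-coverage scaled by a target depth;
an exclusivity plan (30% cosmopolitan, 25% basin-endemic generalist, 20%
euxinic-only, 10% redoxcline-only, 5% both anoxic zones, 10%
near-undetectable); uniformly placed full-length 150 bp reads with 1%
error; and tool-evidence rows drawn from tier-faithful generators with a
5% per-tier confusion rate. The "undetectable" class is realized as an
absolute 0.05× fold coverage, which keeps expected breadth ≈ 5%, far
below the 75% retention rule at any target depth. All outputs are pure
functions of (plan, seed), with per-operation derived RNG streams.

Deliberately not emulated: indels (so planted ANI is analytically
100·(1−divergence)), chimeric contigs, platform error profiles, real read
sequences, and mapping ambiguity (reads are emitted directly as alignment
records against population representatives, bypassing a mapper). Passing
tests therefore demonstrate the correctness of the filtering, clustering
and statistical logic under a substitution-only, uniquely-mapping model —
not robustness to assembler or mapper artifacts.

## Problem sizes and numerical choices

Test and acceptance runs use 20 populations × 2–3 members of 20 kb with
six samples at 20–50× target depth — large enough that every decision
rule and estimator operates in its intended regime, small enough for a
laptop CPU. Thresholds are compared inclusively except where the source
wording is strict ("larger than 5 kbp", "over 75%", "greater than 0.9").
Hypergeometric tails are computed in log space; Bray–Curtis returns NaN
(flagged, not zero) for undefined pairs; Pielou returns None rather than
0 when undefined; ANI on a pair with no shared seed is 0 with aligned
fraction 0, which can never join a cluster.

## Known limitations

* The seeded-chain ANI is tuned for substitution-divergent viral contigs
  at desk scale; very repetitive sequences defeat the k-mer-occurrence
  cap and should use (and automatically get, below 2 kb) the DP route.
* Genus assignment approximates, but does not reproduce, ClusterONE/MCL
  behaviour; outlier/singleton counts are not comparable across tools.
* The abundance proxy is comparative, not absolute; cross-study
  comparisons require identical normalization choices.
* The non-monotone medium/none boundary of the tier engine (above) is
  inherent to the published rule set as written.
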