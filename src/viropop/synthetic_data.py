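"""Ground-truthed synthetic viromes.

Emulates the sampling design of a depth-stratified, permanently euxinic
basin: a handful of virome samples spanning oxic, redoxcline and euxinic
zones; viral populations with controlled intra- and inter-population
divergence; log-normal per-sample abundances with planted habitat
exclusivity (cosmopolitan, basin-endemic, euxinic-only, redoxcline-only,
redoxcline-and-euxinic, near-undetectable); read alignments with a
configurable per-base error rate; and tool-evidence tables with
configurable tier-confusion rates.  Every output is a pure function of
``(plan, seed)``.

Model choices
-------------
* Substitution-only mutation (no indels), so planted ANI between a member
  and its representative is analytically ~ ``100 * (1 - intra_divergence)``.
* Population representatives derive from one shared random ancestor, each
  mutated independently at per-site rate ``inter_divergence``; pairwise
  representative divergence is therefore at least the planted
  ``inter_divergence`` (approximately ``2 d (1 - 4d/3)`` in expectation).
* Reads are emitted directly as alignment summaries (PAF records),
  bypassing a mapper, which isolates the retention/normalization logic
  from mapping-software behaviour.  Reads are placed uniformly and recruit
  to the population *representative* contig, mirroring recruitment against
  a dereplicated reference set.
* The ``undetectable`` exclusivity class is realized as an absolute fold
  coverage of 0.05x in every sample, far below the breadth the 75%
  retention rule requires, regardless of ``target_depth``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from viropop.io_formats import ContigRecord, ReadAlignment, SampleMetadata
from viropop.viral_id import ToolEvidence

__all__ = [
    "SimulationPlan",
    "GroundTruth",
    "default_zones",
    "default_exclusivity_plan",
    "mutate_sequence",
    "simulate_genomes",
    "simulate_abundances",
    "simulate_alignments",
    "simulate_evidence",
    "simulate_pc_profiles",
    "simulate_virome",
]

EXCLUSIVITY_CLASSES = (
    "cosmopolitan",
    "cariaco_only",
    "euxinic_only",
    "redoxcline_only",
    "redoxcline_and_euxinic",
    "undetectable",
)

#: zones in which each exclusivity class has non-zero planted abundance
_ALLOWED_ZONES = {
    "cosmopolitan": {"oxic", "redoxcline", "euxinic"},
    "cariaco_only": {"oxic", "redoxcline", "euxinic"},
    "euxinic_only": {"euxinic"},
    "redoxcline_only": {"redoxcline"},
    "redoxcline_and_euxinic": {"redoxcline", "euxinic"},
    "undetectable": {"oxic", "redoxcline", "euxinic"},
}

#: absolute fold-coverage of the "undetectable" class (breadth << 75%)
UNDETECTABLE_DEPTH = 0.05

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_zones() -> list[SampleMetadata]:
    """Six samples spanning the water column of a stratified euxinic basin:
    two oxic, three redoxcline, one deep euxinic."""
    spec = [
        ("s148", 148.0, "oxic"),
        ("s200", 200.0, "oxic"),
        ("s237", 237.0, "redoxcline"),
        ("s247", 247.0, "redoxcline"),
        ("s267", 267.0, "redoxcline"),
        ("s900", 900.0, "euxinic"),
    ]
    return [
        SampleMetadata(sample_id=s, depth_m=d, zone=z, metagenome_size_bp=1_000_000_000)
        for s, d, z in spec
    ]


def default_exclusivity_plan(n_populations: int) -> dict[str, str]:
    """Assign exclusivity classes in proportions echoing a strongly endemic
    community: ~30% cosmopolitan, ~25% basin-endemic but zone-generalist,
    ~20% euxinic-only, ~10% redoxcline-only, ~5% both anoxic zones, ~10%
    near-undetectable."""
    weights = {
        "cosmopolitan": 0.30,
        "cariaco_only": 0.25,
        "euxinic_only": 0.20,
        "redoxcline_only": 0.10,
        "redoxcline_and_euxinic": 0.05,
        "undetectable": 0.10,
    }
    counts = {cls: int(round(w * n_populations)) for cls, w in weights.items()}
    # fix rounding drift on the largest class
    drift = n_populations - sum(counts.values())
    counts["cosmopolitan"] += drift
    plan: dict[str, str] = {}
    i = 0
    for cls in EXCLUSIVITY_CLASSES:
        for _ in range(max(0, counts[cls])):
            if i >= n_populations:
                break
            plan[f"P{i:03d}"] = cls
            i += 1
    while i < n_populations:
        plan[f"P{i:03d}"] = "cosmopolitan"
        i += 1
    return plan


@dataclass(frozen=True)
class SimulationPlan:
    """All knobs of a synthetic virome run; defaults are the package's
    standard study conditions (see docs/methods.md)."""

    n_populations: int = 20
    genome_length_bp: int = 20_000
    intra_divergence: float = 0.02
    inter_divergence: float = 0.15
    members_per_population: int = 3
    zones: tuple[SampleMetadata, ...] = field(default_factory=lambda: tuple(default_zones()))
    abundance_lognormal_mu: float = 0.0
    abundance_lognormal_sigma: float = 1.0
    exclusivity_plan: dict[str, str] | None = None
    read_length: int = 150
    read_error: float = 0.01
    target_depth: float = 20.0
    tier_fractions: tuple[float, float, float] = (0.6, 0.3, 0.1)  # high, medium, none
    evidence_confusion: dict[str, float] = field(
        default_factory=lambda: {"high": 0.05, "medium": 0.05, "none": 0.05}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.intra_divergence < self.inter_divergence <= 1):
            raise ValueError("require 0 <= intra_divergence < inter_divergence <= 1")
        for name in ("read_error",):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0,1]")
        for tier, p in self.evidence_confusion.items():
            if not (0 <= p <= 1):
                raise ValueError(f"evidence_confusion[{tier!r}] must be in [0,1]")
        if self.target_depth < 0:
            raise ValueError("target_depth must be >= 0")
        if self.inter_divergence <= 2 * self.intra_divergence:
            import warnings

            warnings.warn(
                "inter_divergence <= 2*intra_divergence: cluster separability "
                "is not guaranteed",
                stacklevel=2,
            )

    def resolved_exclusivity(self) -> dict[str, str]:
        if self.exclusivity_plan is not None:
            return dict(self.exclusivity_plan)
        return default_exclusivity_plan(self.n_populations)


@dataclass
class GroundTruth:
    """Planted truth tables used as oracles by tests and acceptance runs."""

    population_of_contig: dict[str, str]
    representative_of_population: dict[str, str]
    abundance: dict[tuple[str, str], float]  # (population_id, sample_id) -> fold-coverage
    tier_of_contig: dict[str, str]
    exclusivity_of_population: dict[str, str]

    def members(self, population_id: str) -> list[str]:
        return sorted(c for c, p in self.population_of_contig.items() if p == population_id)


# sub-streams per operation so module-level reruns are reproducible
_STREAM_OFFSETS = {"genomes": 1, "abundance": 2, "alignments": 3, "evidence": 4, "pcs": 5}


def _rng(plan: SimulationPlan, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([plan.seed, _STREAM_OFFSETS[stream]]))


def mutate_sequence(seq_codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply i.i.d. substitutions at the given per-site rate; each mutated
    site becomes one of the three other bases, uniformly."""
    if rate <= 0:
        return seq_codes.copy()
    out = seq_codes.copy()
    hits = np.nonzero(rng.random(out.size) < rate)[0]
    if hits.size:
        out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def simulate_genomes(plan: SimulationPlan) -> tuple[list[ContigRecord], GroundTruth]:
    """Generate population representatives and divergent member contigs.

    The representative (member 00) is the full genome; other members are
    mutated at ``intra_divergence`` and truncated to 90–100% of the genome
    so the representative is strictly the longest member.  Pairwise
    representative divergence is checked to be >= ``inter_divergence``.
    """
    rng = _rng(plan, "genomes")
    excl = plan.resolved_exclusivity()
    ancestor = rng.integers(0, 4, size=plan.genome_length_bp, dtype=np.uint8)

    contigs: list[ContigRecord] = []
    membership: dict[str, str] = {}
    representatives: dict[str, str] = {}
    rep_codes = []
    for p in range(plan.n_populations):
        pop_id = f"P{p:03d}"
        rep = mutate_sequence(ancestor, plan.inter_divergence, rng)
        rep_codes.append(rep)
        for m in range(plan.members_per_population):
            contig_id = f"{pop_id}_c{m:02d}"
            codes = mutate_sequence(rep, plan.intra_divergence, rng) if m else rep
            if m:
                keep = int(round(codes.size * rng.uniform(0.90, 0.99)))
                codes = codes[:keep]
            contigs.append(ContigRecord(contig_id=contig_id, sequence=_decode(codes)))
            membership[contig_id] = pop_id
            if m == 0:
                representatives[pop_id] = contig_id

    # planted separability floor: every representative pair diverges at
    # least as much as the planted inter_divergence
    for i in range(len(rep_codes)):
        for j in range(i + 1, len(rep_codes)):
            div = float(np.mean(rep_codes[i] != rep_codes[j]))
            if div < plan.inter_divergence:
                import warnings

                warnings.warn(
                    f"representative pair P{i:03d}/P{j:03d} divergence {div:.3f} "
                    f"below planted inter_divergence",
                    stacklevel=2,
                )

    truth = GroundTruth(
        population_of_contig=membership,
        representative_of_population=representatives,
        abundance={},
        tier_of_contig={},
        exclusivity_of_population={f"P{p:03d}": excl[f"P{p:03d}"] for p in range(plan.n_populations)},
    )
    return contigs, truth


def simulate_abundances(truth: GroundTruth, plan: SimulationPlan) -> GroundTruth:
    """Plant per-(population, sample) fold-coverages.

    Within a population's allowed zones the fold-coverage is
    ``target_depth * LogNormal(mu, sigma)``; outside them it is zero; the
    ``undetectable`` class gets a flat 0.05x everywhere.
    """
    rng = _rng(plan, "abundance")
    abundance: dict[tuple[str, str], float] = {}
    for pop_id, cls in truth.exclusivity_of_population.items():
        allowed = _ALLOWED_ZONES[cls]
        for sample in plan.zones:
            if cls == "undetectable":
                depth = UNDETECTABLE_DEPTH
            elif sample.zone in allowed:
                depth = plan.target_depth * rng.lognormal(
                    plan.abundance_lognormal_mu, plan.abundance_lognormal_sigma
                )
            else:
                depth = 0.0
            abundance[(pop_id, sample.sample_id)] = depth
    truth.abundance = abundance
    return truth


def simulate_alignments(
    contigs: list[ContigRecord], truth: GroundTruth, plan: SimulationPlan
) -> dict[str, list[ReadAlignment]]:
    """Emit read-alignment summaries per sample against representatives.

    Read count per (population, sample) is Poisson with mean
    ``depth * L / read_length``; reads are placed uniformly along the
    representative, align full length, and carry Binomial(read_length,
    1 - read_error) matching bases.
    """
    if plan.target_depth < 0:
        raise ValueError("target_depth must be >= 0")
    if not truth.abundance:
        raise ValueError("truth has no planted abundances; run simulate_abundances first")
    rng = _rng(plan, "alignments")
    length_of = {c.contig_id: c.length for c in contigs}
    out: dict[str, list[ReadAlignment]] = {s.sample_id: [] for s in plan.zones}
    rl = plan.read_length
    for pop_id, rep_id in sorted(truth.representative_of_population.items()):
        L = length_of[rep_id]
        for sample in plan.zones:
            depth = truth.abundance[(pop_id, sample.sample_id)]
            n_reads = int(rng.poisson(depth * L / rl)) if depth > 0 else 0
            if n_reads == 0:
                continue
            starts = rng.integers(0, L - rl + 1, size=n_reads)
            matches = rng.binomial(rl, 1.0 - plan.read_error, size=n_reads)
            matches = np.maximum(matches, 1)
            out[sample.sample_id].extend(
                ReadAlignment(
                    read_id=f"{sample.sample_id}_{pop_id}_r{i}",
                    read_length=rl,
                    contig_id=rep_id,
                    contig_start=int(s),
                    contig_end=int(s) + rl,
                    aligned_read_bases=rl,
                    matches=int(m),
                    sample_id=sample.sample_id,
                )
                for i, (s, m) in enumerate(zip(starts, matches))
            )
    return out


# --- evidence ---------------------------------------------------------------

_TIERS = ("high", "medium", "none")


def _evidence_for_tier(contig_id: str, length: int, tier: str, rng: np.random.Generator) -> ToolEvidence:
    """Draw an evidence row whose classification under the tier rules is
    exactly ``tier``."""
    u = rng.integers(0, 3)
    if tier == "high":
        if u == 0:
            return ToolEvidence(contig_id, virsorter_category=int(rng.integers(1, 3)), contig_length=length)
        if u == 1:
            return ToolEvidence(contig_id, virfinder_score=float(rng.uniform(0.905, 1.0)), contig_length=length)
        return ToolEvidence(
            contig_id,
            virsorter_category=int(rng.integers(1, 3)),
            virfinder_score=float(rng.uniform(0.905, 1.0)),
            contig_length=length,
        )
    if tier == "medium":
        if u == 0:  # prophage validated by PHASTER
            return ToolEvidence(
                contig_id,
                virsorter_category=int(rng.integers(4, 7)),
                phaster_prophage=True,
                contig_length=length,
            )
        if u == 1:  # category 3 + mid VirFinder + CAT validation
            return ToolEvidence(
                contig_id,
                virsorter_category=3,
                virfinder_score=float(rng.uniform(0.7, 0.9)),
                cat_viral=True,
                contig_length=length,
            )
        # single-detector: VirSorter category 3 alone or mid VirFinder alone
        if rng.integers(0, 2) == 0:
            return ToolEvidence(contig_id, virsorter_category=3, contig_length=length)
        return ToolEvidence(
            contig_id, virfinder_score=float(rng.uniform(0.7, 0.9)), contig_length=length
        )
    # none
    if u == 0:
        return ToolEvidence(contig_id, contig_length=length)
    if u == 1:
        return ToolEvidence(contig_id, virfinder_score=float(rng.uniform(0.0, 0.69)), contig_length=length)
    return ToolEvidence(
        contig_id,
        virsorter_category=int(rng.integers(4, 7)),
        phaster_prophage=False,
        contig_length=length,
    )


def simulate_evidence(
    contigs: list[ContigRecord], truth: GroundTruth, plan: SimulationPlan
) -> list[ToolEvidence]:
    """Assign planted tiers and emit tool-evidence rows.

    With probability ``1 - evidence_confusion[tier]`` the row classifies to
    the planted tier; otherwise it is drawn from one of the other two
    tiers' generators, uniformly.
    """
    rng = _rng(plan, "evidence")
    fractions = np.asarray(plan.tier_fractions, dtype=float)
    fractions = fractions / fractions.sum()
    rows: list[ToolEvidence] = []
    for contig in contigs:
        tier = _TIERS[int(rng.choice(3, p=fractions))]
        truth.tier_of_contig[contig.contig_id] = tier
        confusion = plan.evidence_confusion.get(tier, 0.0)
        emit_tier = tier
        if confusion > 0 and rng.random() < confusion:
            emit_tier = _TIERS[(int(_TIERS.index(tier)) + int(rng.integers(1, 3))) % 3]
        rows.append(_evidence_for_tier(contig.contig_id, contig.length, emit_tier, rng))
    return rows


def simulate_pc_profiles(
    truth: GroundTruth,
    plan: SimulationPlan,
    populations_per_genus: int = 4,
    pcs_per_population: int = 20,
    within_genus_shared: float = 0.6,
    background_pcs: int = 200,
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Plant protein-cluster profiles with genus structure.

    Populations are grouped into genera of ``populations_per_genus``;
    members of a genus share ``within_genus_shared`` of their PCs (a
    genus-private core) and draw the rest from a large background pool, so
    between-genus overlap is negligible.  Returns (profiles, genus truth).
    """
    rng = _rng(plan, "pcs")
    pops = sorted(truth.exclusivity_of_population)
    profiles: dict[str, set[str]] = {}
    genus_of: dict[str, str] = {}
    n_core = int(round(pcs_per_population * within_genus_shared))
    for g, start in enumerate(range(0, len(pops), populations_per_genus)):
        genus_id = f"G{g:02d}"
        core = {f"{genus_id}_core{i:02d}" for i in range(n_core)}
        for pop_id in pops[start : start + populations_per_genus]:
            genus_of[pop_id] = genus_id
            accessory = {
                f"bg{int(i):04d}"
                for i in rng.choice(background_pcs, size=pcs_per_population - n_core, replace=False)
            }
            profiles[pop_id] = core | accessory
    return profiles, genus_of


def simulate_virome(plan: SimulationPlan):
    """Run the full generator: genomes, abundances, alignments, evidence.

    Returns ``(contigs, alignments_by_sample, evidence_rows, truth)``.
    """
    contigs, truth = simulate_genomes(plan)
    truth = simulate_abundances(truth, plan)
    alignments = simulate_alignments(contigs, truth, plan)
    evidence = simulate_evidence(contigs, truth, plan)
    return contigs, alignments, evidence, truth
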