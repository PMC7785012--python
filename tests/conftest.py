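import numpy as np
import pytest

from viropop.population_cluster import Population
from viropop.recruitment_abundance import (
    build_abundance_matrix,
    contig_coverage,
    filter_alignments,
)
from viropop.synthetic_data import SimulationPlan, simulate_virome


def make_random_contig(rng, length, contig_id="c"):
    from viropop.io_formats import ContigRecord

    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    return ContigRecord(contig_id=contig_id, sequence=seq)


@pytest.fixture(scope="session")
def small_virome():
    """A small but complete synthetic virome shared across test modules."""
    plan = SimulationPlan(
        n_populations=6,
        genome_length_bp=6000,
        members_per_population=2,
        target_depth=20,
        seed=11,
    )
    contigs, alignments, evidence, truth = simulate_virome(plan)
    return plan, contigs, alignments, evidence, truth


def truth_populations(contigs, truth):
    """Build Population objects straight from the ground truth."""
    by_id = {c.contig_id: c for c in contigs}
    pops = []
    for pop_id, rep in sorted(truth.representative_of_population.items()):
        members = truth.members(pop_id)
        members.sort(key=lambda m: (m != rep, m))
        pops.append(Population(rep, tuple(members), by_id[rep].length))
    return pops


def abundance_from_virome(plan, contigs, alignments, truth):
    """Recruitment pipeline on simulator output: filter, coverage, matrix."""
    by_id = {c.contig_id: c for c in contigs}
    pops = truth_populations(contigs, truth)
    coverages = []
    for sample in plan.zones:
        retained = filter_alignments(alignments[sample.sample_id])
        per_contig = {}
        for a in retained:
            per_contig.setdefault(a.contig_id, []).append(a)
        for contig_id, rows in per_contig.items():
            coverages.append(contig_coverage(rows, by_id[contig_id], sample))
    return build_abundance_matrix(coverages, pops, list(plan.zones))
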