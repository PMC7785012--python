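"""The synthetic virome generator: determinism, planted structure,
coverage expectations, and evidence confusion."""

from dataclasses import replace

import numpy as np
import pytest

from viropop.io_formats import ContigRecord, SampleMetadata
from viropop.synthetic_data import (
    SimulationPlan,
    default_exclusivity_plan,
    mutate_sequence,
    simulate_abundances,
    simulate_alignments,
    simulate_evidence,
    simulate_genomes,
    simulate_virome,
)
from viropop.viral_id import classify_contig

SMALL = dict(n_populations=4, genome_length_bp=3000, members_per_population=2)


class TestPlan:
    def test_divergence_ordering_enforced(self):
        with pytest.raises(ValueError):
            SimulationPlan(intra_divergence=0.2, inter_divergence=0.1)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            SimulationPlan(target_depth=-1)

    def test_separability_warning(self):
        with pytest.warns(UserWarning, match="separability"):
            SimulationPlan(intra_divergence=0.08, inter_divergence=0.15)

    def test_default_exclusivity_covers_all_populations(self):
        plan = default_exclusivity_plan(17)
        assert len(plan) == 17
        assert set(plan) == {f"P{i:03d}" for i in range(17)}


class TestGenomes:
    def test_deterministic_for_fixed_seed(self):
        plan = SimulationPlan(**SMALL, seed=5)
        c1, _ = simulate_genomes(plan)
        c2, _ = simulate_genomes(plan)
        assert [(c.contig_id, c.sequence) for c in c1] == [(c.contig_id, c.sequence) for c in c2]

    def test_zero_intra_divergence_members_identical_to_representative(self):
        plan = SimulationPlan(**SMALL, intra_divergence=0.0, inter_divergence=0.15, seed=6)
        contigs, truth = simulate_genomes(plan)
        by_id = {c.contig_id: c for c in contigs}
        for pop, rep in truth.representative_of_population.items():
            for member in truth.members(pop):
                # members are prefixes of the representative (truncation only)
                assert by_id[rep].sequence.startswith(by_id[member].sequence)

    def test_each_contig_in_exactly_one_population(self):
        plan = SimulationPlan(**SMALL, seed=7)
        contigs, truth = simulate_genomes(plan)
        assert sorted(truth.population_of_contig) == sorted(c.contig_id for c in contigs)

    def test_representative_is_longest_member(self):
        plan = SimulationPlan(**SMALL, seed=8)
        contigs, truth = simulate_genomes(plan)
        by_id = {c.contig_id: c for c in contigs}
        for pop, rep in truth.representative_of_population.items():
            assert by_id[rep].length == max(by_id[m].length for m in truth.members(pop))

    def test_planted_divergences_separate_at_95_ani(self):
        """Empirical separability: member-to-representative identity is above
        95%, representative-to-representative identity far below."""
        plan = SimulationPlan(**SMALL, seed=9)
        contigs, truth = simulate_genomes(plan)
        by_id = {c.contig_id: np.frombuffer(c.sequence.encode(), dtype=np.uint8) for c in contigs}
        reps = list(truth.representative_of_population.values())
        for pop, rep in truth.representative_of_population.items():
            for m in truth.members(pop):
                if m == rep:
                    continue
                s1, s2 = by_id[rep], by_id[m]
                n = min(s1.size, s2.size)
                ident = 100 * np.mean(s1[:n] == s2[:n])
                assert ident > 95.0
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                s1, s2 = by_id[reps[i]], by_id[reps[j]]
                n = min(s1.size, s2.size)
                assert 100 * np.mean(s1[:n] == s2[:n]) < 95.0


class TestAlignments:
    def plan(self, **kw):
        zones = (SampleMetadata("s1", 100.0, "oxic", 10**9),)
        base = dict(
            n_populations=1,
            genome_length_bp=10_000,
            members_per_population=1,
            zones=zones,
            exclusivity_plan={"P000": "cosmopolitan"},
            seed=10,
        )
        base.update(kw)
        return SimulationPlan(**base)

    def test_zero_depth_empty(self):
        plan = self.plan(target_depth=0.0)
        contigs, truth = simulate_genomes(plan)
        truth.abundance = {("P000", "s1"): 0.0}
        aln = simulate_alignments(contigs, truth, plan)
        assert aln["s1"] == []

    def test_total_aligned_bases_near_expectation(self):
        """Depth 50 on a 10-kb contig: 500 kb aligned +- 3 SD of the Poisson
        read count."""
        plan = self.plan(target_depth=50.0)
        contigs, truth = simulate_genomes(plan)
        truth.abundance = {("P000", "s1"): 50.0}
        aln = simulate_alignments(contigs, truth, plan)["s1"]
        total = sum(a.aligned_read_bases for a in aln)
        mean_reads = 50.0 * 10_000 / plan.read_length
        sd_bases = np.sqrt(mean_reads) * plan.read_length
        assert abs(total - 500_000) < 3 * sd_bases

    def test_zero_read_error_all_matches(self):
        plan = self.plan(read_error=0.0)
        contigs, truth = simulate_genomes(plan)
        truth.abundance = {("P000", "s1"): 5.0}
        for a in simulate_alignments(contigs, truth, plan)["s1"]:
            assert a.matches == a.aligned_read_bases

    def test_requires_abundances(self):
        plan = self.plan()
        contigs, truth = simulate_genomes(plan)
        with pytest.raises(ValueError, match="abundance"):
            simulate_alignments(contigs, truth, plan)

    def test_abundance_zero_outside_allowed_zones(self):
        plan = SimulationPlan(**SMALL, seed=12, exclusivity_plan={
            "P000": "euxinic_only", "P001": "redoxcline_only",
            "P002": "cosmopolitan", "P003": "undetectable"})
        _, truth = simulate_genomes(plan)
        truth = simulate_abundances(truth, plan)
        zone_of = {s.sample_id: s.zone for s in plan.zones}
        for (pop, sample), depth in truth.abundance.items():
            cls = truth.exclusivity_of_population[pop]
            if cls == "euxinic_only" and zone_of[sample] != "euxinic":
                assert depth == 0.0
            if cls == "undetectable":
                assert depth == pytest.approx(0.05)


class TestEvidence:
    def test_zero_confusion_perfect_recovery(self):
        plan = SimulationPlan(
            **SMALL, seed=13, evidence_confusion={"high": 0.0, "medium": 0.0, "none": 0.0}
        )
        contigs, truth = simulate_genomes(plan)
        rows = simulate_evidence(contigs, truth, plan)
        for row in rows:
            assert classify_contig(row).tier == truth.tier_of_contig[row.contig_id]

    def test_confusion_rate_matches_binomial_expectation(self):
        """10% confusion on 1000 contigs: recovered-tier accuracy 0.9 within
        binomial sampling error (+-0.03)."""
        contigs = [ContigRecord(f"c{i:04d}", "ACGT" * 10) for i in range(1000)]
        plan = SimulationPlan(
            seed=14, evidence_confusion={"high": 0.1, "medium": 0.1, "none": 0.1}
        )
        from viropop.synthetic_data import GroundTruth

        truth = GroundTruth({}, {}, {}, {}, {})
        rows = simulate_evidence(contigs, truth, plan)
        hits = sum(
            classify_contig(row).tier == truth.tier_of_contig[row.contig_id] for row in rows
        )
        assert abs(hits / 1000 - 0.9) <= 0.03

    def test_tables_identical_across_runs(self):
        plan = SimulationPlan(**SMALL, seed=15)
        contigs, truth = simulate_genomes(plan)
        r1 = simulate_evidence(contigs, truth, plan)
        r2 = simulate_evidence(contigs, truth, plan)
        assert r1 == r2


def test_full_virome_deterministic(small_virome):
    plan, contigs, alignments, evidence, truth = small_virome
    c2, a2, e2, t2 = simulate_virome(plan)
    assert [(c.contig_id, c.sequence) for c in contigs] == [(c.contig_id, c.sequence) for c in c2]
    assert {s: len(v) for s, v in alignments.items()} == {s: len(v) for s, v in a2.items()}
    assert evidence == e2
    assert truth.abundance == t2.abundance
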