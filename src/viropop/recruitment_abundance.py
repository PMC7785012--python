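"""Read-retention filters, contig coverage, and the abundance matrix.

Retention rules: a read alignment is kept iff its identity
(100 * matches / aligned_read_bases) is >= 95% and it spans >= 90% of the
read; a contig's coverage is kept iff retained reads cover strictly more
than 75% of its positions.  Retained mean depth is normalized by library
size to a per-Gbp rate, the pipeline's proxy for relative abundance:

    normalized_abundance = mean_depth / (metagenome_size_bp / 1e9)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from viropop.io_formats import ContigRecord, ReadAlignment, SampleMetadata
from viropop.population_cluster import Population

__all__ = [
    "ContigCoverage",
    "AbundanceMatrix",
    "filter_alignments",
    "contig_coverage",
    "build_abundance_matrix",
]

DEFAULT_MIN_IDENTITY_PCT = 95.0
DEFAULT_MIN_READ_FRACTION = 0.90
#: breadth must strictly exceed this for coverage to be retained
BREADTH_THRESHOLD = 0.75


@dataclass(frozen=True)
class ContigCoverage:
    contig_id: str
    sample_id: str
    breadth: float
    total_aligned_bases: int
    mean_depth: float
    normalized_abundance: float


class AbundanceMatrix:
    """Populations x samples matrix of normalized recruitment abundance.

    Thin wrapper over a :class:`pandas.DataFrame` (rows = populations,
    columns = samples) adding per-sample relative abundances.
    """

    def __init__(self, values: pd.DataFrame):
        if (values.values < 0).any():
            raise ValueError("abundance values must be >= 0")
        self.values = values

    @property
    def populations(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def relative(self) -> pd.DataFrame:
        """Per-sample relative abundances; all-zero columns stay all-zero."""
        sums = self.values.sum(axis=0)
        safe = sums.replace(0, np.nan)
        return self.values.div(safe, axis=1).fillna(0.0)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "population_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("population_id")
        df.index.name = None
        return cls(df.astype(float))


def filter_alignments(
    alignments: list[ReadAlignment],
    min_identity_pct: float = DEFAULT_MIN_IDENTITY_PCT,
    min_read_fraction: float = DEFAULT_MIN_READ_FRACTION,
) -> list[ReadAlignment]:
    """Retain alignments meeting both thresholds (inclusively).

    Idempotent: filtering a filtered list is a no-op.
    """
    out = []
    for a in alignments:
        if a.read_length <= 0:
            raise ValueError(f"read {a.read_id!r}: read_length must be > 0")
        if (
            100.0 * a.matches / a.aligned_read_bases >= min_identity_pct
            and a.aligned_read_bases / a.read_length >= min_read_fraction
        ):
            out.append(a)
    return out


def _union_covered(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total bases in the union of [start, end) intervals (sweep over
    sorted intervals)."""
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    covered = 0
    cur_start, cur_end = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s > cur_end:
            covered += cur_end - cur_start
            cur_start, cur_end = int(s), int(e)
        else:
            cur_end = max(cur_end, int(e))
    covered += cur_end - cur_start
    return covered


def contig_coverage(
    retained: list[ReadAlignment],
    contig: ContigRecord,
    sample: SampleMetadata,
) -> ContigCoverage:
    """Breadth, depth, and normalized abundance of one contig in one sample.

    Breadth is the union of alignment intervals over the contig length;
    mean depth is total aligned contig bases over the contig length;
    normalized abundance is mean depth per Gbp of library, zeroed when
    breadth fails the strict 75% rule.
    """
    rows = [a for a in retained if a.contig_id == contig.contig_id
            and (not a.sample_id or not sample.sample_id or a.sample_id == sample.sample_id)]
    L = contig.length
    if not rows:
        return ContigCoverage(contig.contig_id, sample.sample_id, 0.0, 0, 0.0, 0.0)
    starts = np.array([a.contig_start for a in rows])
    ends = np.array([a.contig_end for a in rows])
    if (ends > L).any() or (starts < 0).any():
        raise ValueError(f"contig {contig.contig_id!r}: alignment interval exceeds contig length")
    breadth = _union_covered(starts, ends) / L
    total = int((ends - starts).sum())
    mean_depth = total / L
    if breadth > BREADTH_THRESHOLD:
        normalized = mean_depth / (sample.metagenome_size_bp / 1e9)
    else:
        normalized = 0.0
    return ContigCoverage(contig.contig_id, sample.sample_id, breadth, total, mean_depth, normalized)


def build_abundance_matrix(
    coverages: list[ContigCoverage],
    populations: list[Population],
    samples: list[SampleMetadata] | None = None,
) -> AbundanceMatrix:
    """Aggregate per-contig coverage into a populations x samples matrix.

    Each coverage row maps to a population through its contig's membership
    (summed within a (population, sample) cell, which matters only if
    multiple members of one population were recruited against).  Coverage
    rows for contigs outside every population are skipped with a warning.
    All-zero rows are retained: "not detected" is information.
    """
    pop_of: dict[str, str] = {}
    for pop in populations:
        for member in pop.member_ids:
            pop_of[member] = pop.representative_id
    pop_ids = [p.representative_id for p in populations]
    sample_ids = [s.sample_id for s in samples] if samples is not None else sorted(
        {c.sample_id for c in coverages}
    )
    values = pd.DataFrame(0.0, index=pop_ids, columns=sample_ids)
    for cov in coverages:
        pop = pop_of.get(cov.contig_id)
        if pop is None:
            import warnings

            warnings.warn(
                f"coverage for contig {cov.contig_id!r} not assigned to any population; skipped",
                stacklevel=2,
            )
            continue
        if cov.sample_id not in values.columns:
            continue
        values.loc[pop, cov.sample_id] += cov.normalized_abundance
    return AbundanceMatrix(values)
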