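"""Genomic-context adjudication of putative auxiliary metabolic genes.

A host-derived metabolic gene on a viral contig (an AMG candidate) is only
credible as part of the viral genome if its context supports it: interior
placement (not within a few genes of a contig end, and inside any
predicted prophage span), virus-like genes on its flanks, and — for edge
cases — genome-boundary evidence (attL/attR attachment sites or predicted
packaging termini).  The adjudicator formalizes that reasoning as a
deterministic rule set:

* ``placement``: interior iff the AMG is at least ``edge_margin`` genes
  from both contig ends and, when a prophage span is predicted, inside it.
* ``boundary_status``: genome_bounded when both att sites or termini are
  present; partial when exactly one att site is; else unbounded.
* ``confidence``: high iff interior with virus-like genes on *both*
  flanks; medium iff interior with one supported flank, or edge but
  genome-bounded; low otherwise.  An edge AMG can never be high
  confidence — it may sit in packaged host DNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from viropop.io_formats import GeneAnnotationRow
from viropop.recruitment_abundance import AbundanceMatrix

__all__ = [
    "BoundaryEvidence",
    "AMGAssessment",
    "assess_amg",
    "assess_contig",
    "summarize_amg_abundance",
]

DEFAULT_WINDOW = 5
DEFAULT_EDGE_MARGIN = 3

VIRAL_CATEGORIES = {"viral_hallmark", "viral_like"}


@dataclass(frozen=True)
class BoundaryEvidence:
    """Evidence about viral genome boundaries on a contig."""

    attL_coord: int | None = None
    attR_coord: int | None = None
    termini_predicted: bool = False
    phaster_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if (
            self.attL_coord is not None
            and self.attR_coord is not None
            and not self.attL_coord < self.attR_coord
        ):
            raise ValueError("attL_coord must be < attR_coord")


@dataclass(frozen=True)
class AMGAssessment:
    contig_id: str
    gene_index: int
    amg_name: str | None
    placement: str  # interior | edge
    viral_flank_left: int
    viral_flank_right: int
    boundary_status: str  # genome_bounded | partial | unbounded
    confidence: str  # high | medium | low


def _boundary_status(boundary: BoundaryEvidence) -> str:
    has_l = boundary.attL_coord is not None
    has_r = boundary.attR_coord is not None
    if (has_l and has_r) or boundary.termini_predicted:
        return "genome_bounded"
    if has_l != has_r:
        return "partial"
    return "unbounded"


def assess_amg(
    genes: list[GeneAnnotationRow],
    amg_index: int,
    boundary: BoundaryEvidence | None = None,
    window: int = DEFAULT_WINDOW,
    edge_margin: int = DEFAULT_EDGE_MARGIN,
) -> AMGAssessment:
    """Adjudicate one AMG candidate on an ordered gene list.

    ``genes`` must be the full, start-sorted gene complement of one
    contig; ``amg_index`` indexes into it and must point at a gene with
    ``category == "amg"``.
    """
    if not genes:
        raise ValueError("empty gene list")
    if sorted(g.start for g in genes) != [g.start for g in genes]:
        raise ValueError("genes must be sorted by start coordinate")
    if not (0 <= amg_index < len(genes)):
        raise ValueError(f"amg_index {amg_index} out of range for {len(genes)} genes")
    amg = genes[amg_index]
    if amg.category != "amg":
        raise ValueError(f"gene {amg_index} has category {amg.category!r}, not 'amg'")
    boundary = boundary or BoundaryEvidence()

    n = len(genes)
    interior = amg_index >= edge_margin and (n - 1 - amg_index) >= edge_margin
    if interior and boundary.phaster_span is not None:
        span_start, span_end = boundary.phaster_span
        interior = span_start <= amg.start and amg.end <= span_end
    placement = "interior" if interior else "edge"

    left = genes[max(0, amg_index - window) : amg_index]
    right = genes[amg_index + 1 : amg_index + 1 + window]
    flank_left = sum(1 for g in left if g.category in VIRAL_CATEGORIES)
    flank_right = sum(1 for g in right if g.category in VIRAL_CATEGORIES)

    status = _boundary_status(boundary)

    if placement == "interior" and flank_left >= 1 and flank_right >= 1:
        confidence = "high"
    elif placement == "interior" and (flank_left >= 1) != (flank_right >= 1):
        confidence = "medium"
    elif placement == "edge" and status == "genome_bounded":
        confidence = "medium"
    else:
        confidence = "low"

    return AMGAssessment(
        contig_id=amg.contig_id,
        gene_index=amg_index,
        amg_name=amg.amg_name,
        placement=placement,
        viral_flank_left=flank_left,
        viral_flank_right=flank_right,
        boundary_status=status,
        confidence=confidence,
    )


def assess_contig(
    genes: list[GeneAnnotationRow],
    boundary: BoundaryEvidence | None = None,
    window: int = DEFAULT_WINDOW,
    edge_margin: int = DEFAULT_EDGE_MARGIN,
) -> list[AMGAssessment]:
    """Assess every AMG candidate on one contig's gene list."""
    return [
        assess_amg(genes, i, boundary, window=window, edge_margin=edge_margin)
        for i, g in enumerate(genes)
        if g.category == "amg"
    ]


def summarize_amg_abundance(
    assessments: list[AMGAssessment],
    abundance: AbundanceMatrix,
    population_of_contig: dict[str, str],
) -> pd.DataFrame:
    """Per-sample relative abundance of AMG-encoding populations.

    Rows are AMG names, columns samples; each cell sums the relative
    abundances of populations whose contigs carry that AMG (a population
    counted once per AMG name even if several of its genes carry it).
    Zero rows are retained.  Contigs outside every population are skipped
    with a warning.
    """
    rel = abundance.relative()
    carriers: dict[str, set[str]] = {}
    for a in assessments:
        pop = population_of_contig.get(a.contig_id)
        if pop is None:
            import warnings

            warnings.warn(
                f"AMG contig {a.contig_id!r} not assigned to any population; skipped",
                stacklevel=2,
            )
            continue
        if pop not in rel.index:
            continue
        carriers.setdefault(a.amg_name or "unnamed", set()).add(pop)
    table = pd.DataFrame(0.0, index=sorted(carriers), columns=abundance.samples)
    for amg_name, pops in carriers.items():
        table.loc[amg_name] = rel.loc[sorted(pops)].sum(axis=0)
    return table
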