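"""Evidence-integrated viral identification tiers.

Four virus-detection evidence sources per contig — a VirSorter category
(1–6), a VirFinder score (0–1), a CAT viral/non-viral call and a PHASTER
prophage call — are integrated into ``high`` / ``medium`` / ``none``
confidence tiers:

* **high** — VirSorter category 1 or 2, or VirFinder score strictly
  greater than 0.9.
* **medium** — prophage prediction (VirSorter category 4–6) validated by
  PHASTER; or VirSorter category 3 with a VirFinder score in [0.7, 0.9]
  further validated as viral by CAT; or the contig is identified by exactly
  one of the two detectors (VirSorter categories 1–3, or VirFinder ≥ 0.7)
  and no high rule fired.
* **none** — everything else.

Rules are evaluated high → medium in a fixed order; ``rule_fired`` records
the first match, so the assignment is total and deterministic.  Boundary
readings: "greater than 0.9" is strict, "between 0.7 and 0.9" is inclusive
at both ends.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["ToolEvidence", "ViralCall", "classify_contig", "classify_all"]

#: minimum contig length retained before classification (bp)
DEFAULT_MIN_LENGTH_BP = 1500


@dataclass(frozen=True)
class ToolEvidence:
    """Per-contig scores/categories from the four detection tools.

    ``None`` means the tool produced no call for this contig, which is
    distinct from a score of zero or a negative call.
    """

    contig_id: str
    virsorter_category: int | None = None
    virfinder_score: float | None = None
    cat_viral: bool | None = None
    phaster_prophage: bool | None = None
    contig_length: int | None = None

    def __post_init__(self) -> None:
        if self.virsorter_category is not None and self.virsorter_category not in range(1, 7):
            raise ValueError(
                f"contig {self.contig_id!r}: virsorter_category must be 1..6, "
                f"got {self.virsorter_category}"
            )
        if self.virfinder_score is not None and not (0.0 <= self.virfinder_score <= 1.0):
            raise ValueError(
                f"contig {self.contig_id!r}: virfinder_score must be in [0,1], "
                f"got {self.virfinder_score}"
            )


@dataclass(frozen=True)
class ViralCall:
    contig_id: str
    tier: str  # high | medium | none
    rule_fired: str


def _identified_by_virsorter(ev: ToolEvidence) -> bool:
    # categories 4-6 are prophage predictions with their own rule
    return ev.virsorter_category in (1, 2, 3)


def _identified_by_virfinder(ev: ToolEvidence) -> bool:
    return ev.virfinder_score is not None and ev.virfinder_score >= 0.7


def classify_contig(ev: ToolEvidence) -> ViralCall:
    """Assign a confidence tier to one contig's evidence row.

    Returns tier ``none`` with ``rule_fired="no_evidence"`` when all four
    evidence fields are missing.
    """
    if (
        ev.virsorter_category is None
        and ev.virfinder_score is None
        and ev.cat_viral is None
        and ev.phaster_prophage is None
    ):
        return ViralCall(ev.contig_id, "none", "no_evidence")

    if ev.virsorter_category in (1, 2):
        return ViralCall(ev.contig_id, "high", "high_virsorter_1_2")
    if ev.virfinder_score is not None and ev.virfinder_score > 0.9:
        return ViralCall(ev.contig_id, "high", "high_virfinder_gt_0.9")

    if ev.virsorter_category in (4, 5, 6) and ev.phaster_prophage is True:
        return ViralCall(ev.contig_id, "medium", "medium_prophage_phaster")
    if (
        ev.virsorter_category == 3
        and ev.virfinder_score is not None
        and 0.7 <= ev.virfinder_score <= 0.9
        and ev.cat_viral is True
    ):
        return ViralCall(ev.contig_id, "medium", "medium_cat3_virfinder_cat")
    if _identified_by_virsorter(ev) != _identified_by_virfinder(ev):
        return ViralCall(ev.contig_id, "medium", "medium_single_detector")

    return ViralCall(ev.contig_id, "none", "no_rule")


def classify_all(
    evidence: Iterable[ToolEvidence],
    min_length_bp: int = DEFAULT_MIN_LENGTH_BP,
) -> tuple[list[ViralCall], Counter]:
    """Classify a table of evidence rows, dropping short contigs first.

    Contigs with ``contig_length`` below ``min_length_bp`` are excluded
    before classification (rows with no recorded length are kept).
    Returns the calls and a Counter of per-tier counts; the counts
    partition the retained contigs.  Raises on duplicate contig ids.
    """
    evidence = list(evidence)
    ids = [ev.contig_id for ev in evidence]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate contig ids in evidence table: {dupes}")
    calls = [
        classify_contig(ev)
        for ev in evidence
        if ev.contig_length is None or ev.contig_length >= min_length_bp
    ]
    counts = Counter(call.tier for call in calls)
    return calls, counts
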