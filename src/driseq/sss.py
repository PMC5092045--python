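"""Species-specific sorting (SSS) of reads aligned to two genomes.

Each read, given its maximum-score alignments to genome A and genome B,
is assigned to one species or rejected.  The procedure is conservative:
it aims foremost to keep misassignments at zero, at the cost of
discarding reads it cannot place with confidence.

Decision procedure (per read):

1. no alignments anywhere -> ``UNALIGNED``.
2. alignments to exactly one genome -> provisional assignment to it.
3. alignments to both genomes: a read aligning more than once to either
   genome is discarded (``REJECTED_MULTIMAP``); otherwise the single
   alignments are compared by mismatch count, fewer wins provisionally;
   on a tie a structural check is applied (full-length, unclipped, and
   every intron-adjacent block at least 5 bases).  Structure satisfied
   for exactly one genome -> provisional to it; for both -> the read is
   ``AMBIGUOUS`` (it cannot be attributed with confidence); for neither
   -> ``REJECTED_STRUCTURE``.
4. final check on any provisional assignment: the read must have a
   single alignment to that genome, with zero mismatches, satisfying
   the structural criteria — otherwise it is rejected with the
   corresponding cause.

Every read that survives therefore has a single, full-length,
zero-mismatch, well-anchored alignment to exactly one genome.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from math import nan

import pandas as pd

from .toyalign import AlignmentRecord

MIN_ANCHOR = 5  # minimum bases aligned to the exons on either side of an intron


class Verdict(str, enum.Enum):
    SPECIES_A = "SPECIES_A"
    SPECIES_B = "SPECIES_B"
    AMBIGUOUS = "AMBIGUOUS"
    REJECTED_MULTIMAP = "REJECTED_MULTIMAP"
    REJECTED_STRUCTURE = "REJECTED_STRUCTURE"
    REJECTED_MISMATCH = "REJECTED_MISMATCH"
    UNALIGNED = "UNALIGNED"


REJECTED = {
    Verdict.AMBIGUOUS,
    Verdict.REJECTED_MULTIMAP,
    Verdict.REJECTED_STRUCTURE,
    Verdict.REJECTED_MISMATCH,
}


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    verdict: Verdict
    chosen_alignment: AlignmentRecord | None = None
    perfect_tie: bool = False  # AMBIGUOUS with a zero-mismatch tie to both genomes


def structure_ok(al: AlignmentRecord) -> bool:
    """Full-length (unclipped) and, if spliced, >=5-base exon anchors."""
    if al.clipped != 0:
        return False
    if len(al.blocks) > 1 and min(e - s for s, e in al.blocks) < MIN_ANCHOR:
        return False
    return True


def classify_read(
    read_id: str,
    aln_a: list[AlignmentRecord],
    aln_b: list[AlignmentRecord],
) -> ReadAssignment:
    """Assign one read to species A, species B, or reject it."""
    for al in list(aln_a) + list(aln_b):
        if al.read_id != read_id:
            raise ValueError(f"alignment for {al.read_id!r} in record for {read_id!r}")
    if not aln_a and not aln_b:
        return ReadAssignment(read_id, Verdict.UNALIGNED)

    provisional: str | None = None
    if aln_a and not aln_b:
        provisional = "A"
    elif aln_b and not aln_a:
        provisional = "B"
    else:
        if len(aln_a) > 1 or len(aln_b) > 1:
            return ReadAssignment(read_id, Verdict.REJECTED_MULTIMAP)
        a, b = aln_a[0], aln_b[0]
        if a.mismatches < b.mismatches:
            provisional = "A"
        elif b.mismatches < a.mismatches:
            provisional = "B"
        else:
            ok_a, ok_b = structure_ok(a), structure_ok(b)
            if ok_a and ok_b:
                return ReadAssignment(
                    read_id, Verdict.AMBIGUOUS, perfect_tie=a.mismatches == 0
                )
            if not ok_a and not ok_b:
                return ReadAssignment(read_id, Verdict.REJECTED_STRUCTURE)
            provisional = "A" if ok_a else "B"

    alns = aln_a if provisional == "A" else aln_b
    if len(alns) != 1:
        return ReadAssignment(read_id, Verdict.REJECTED_MULTIMAP)
    al = alns[0]
    if al.mismatches != 0:
        return ReadAssignment(read_id, Verdict.REJECTED_MISMATCH)
    if not structure_ok(al):
        return ReadAssignment(read_id, Verdict.REJECTED_STRUCTURE)
    verdict = Verdict.SPECIES_A if provisional == "A" else Verdict.SPECIES_B
    return ReadAssignment(read_id, verdict, chosen_alignment=al)


@dataclass
class SortSummary:
    counts: dict[str, int]
    n_reads: int
    n_assigned: int
    n_rejected: int
    conserved_fraction: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "counts": self.counts,
                "n_reads": self.n_reads,
                "n_assigned": self.n_assigned,
                "n_rejected": self.n_rejected,
                "conserved_fraction": self.conserved_fraction,
            },
            indent=2,
            sort_keys=True,
        )


def sort_sample(records) -> tuple[pd.DataFrame, SortSummary, list[ReadAssignment]]:
    """Classify a stream of ``(read_id, aln_a, aln_b)`` records.

    Returns the per-read verdict table, a :class:`SortSummary`, and the
    raw assignments.  ``conserved_fraction`` is the fraction of reads
    lost to complete sequence identity between the genomes: among reads
    meeting the initial criterion of a perfect full-length match
    (assigned reads plus perfect-tie ambiguous reads), the share that
    was ambiguous.  Duplicate read ids are an error.
    """
    assignments: list[ReadAssignment] = []
    seen: set[str] = set()
    for read_id, aln_a, aln_b in records:
        if read_id in seen:
            raise ValueError(f"duplicate read id {read_id!r}")
        seen.add(read_id)
        assignments.append(classify_read(read_id, aln_a, aln_b))

    counts = {v.value: 0 for v in Verdict}
    amb_perfect = 0
    rows = []
    for a in assignments:
        counts[a.verdict.value] += 1
        if a.verdict is Verdict.AMBIGUOUS and a.perfect_tie:
            amb_perfect += 1
        al = a.chosen_alignment
        rows.append(
            {
                "read": a.read_id,
                "verdict": a.verdict.value,
                "genome": al.genome_id if al else "",
                "strand": al.strand if al else "",
                "blocks": ";".join(f"{s}-{e}" for s, e in al.blocks) if al else "",
                "mismatches": al.mismatches if al else -1,
            }
        )
    n_assigned = counts[Verdict.SPECIES_A.value] + counts[Verdict.SPECIES_B.value]
    n_rejected = sum(counts[v.value] for v in REJECTED)
    denom = n_assigned + amb_perfect
    conserved = amb_perfect / denom if denom else nan
    table = pd.DataFrame(
        rows, columns=["read", "verdict", "genome", "strand", "blocks", "mismatches"]
    )
    summary = SortSummary(
        counts=counts,
        n_reads=len(assignments),
        n_assigned=n_assigned,
        n_rejected=n_rejected,
        conserved_fraction=conserved,
    )
    return table, summary, assignments
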