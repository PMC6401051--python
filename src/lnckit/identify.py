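"""The candidate-identification funnel.

Length filter → six-frame ORF filter → ingested coding-potential score
filter → ingested protein-homology filter, with a telescoping per-stage
report.  The two ingested stages are optional: without tables the funnel
degrades to the two sequence-intrinsic filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import SeqRecord, TabularHit

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Orf:
    """An ATG-initiated open reading frame in one of six frames.

    ``start``/``end`` are 0-based half-open on the scanned strand (the
    reverse complement for minus frames); ``end`` includes the stop
    codon when ``complete``.  ``aa_length`` counts codons from the start
    codon up to but excluding the stop.
    """

    frame: int
    start: int
    end: int
    aa_length: int
    complete: bool


def _scan_frame(seq: str, offset: int, frame: int) -> list[Orf]:
    orfs: list[Orf] = []
    open_starts: list[int] = []
    n = len(seq)
    pos = offset
    while pos + 3 <= n:
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            for s in open_starts:
                aa = (pos - s) // 3
                orfs.append(Orf(frame, s, pos + 3, aa, True))
            open_starts = []
        elif codon == "ATG":
            open_starts.append(pos)
        pos += 3
    for s in open_starts:
        aa = (pos - s) // 3
        orfs.append(Orf(frame, s, s + 3 * aa, aa, False))
    return orfs


def scan_orfs(seq: str) -> list[Orf]:
    """Report every ATG-initiated ORF in all six frames.

    Each ATG opens exactly one ORF, running to the first in-frame stop;
    ORFs truncated by the sequence end are reported with
    ``complete=False``.  Codons containing N never match ATG or a stop.
    Minus-frame coordinates refer to the reverse complement.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    seq = seq.upper().replace("U", "T")
    orfs: list[Orf] = []
    rc = reverse_complement(seq)
    for offset in range(3):
        orfs.extend(_scan_frame(seq, offset, offset + 1))
        orfs.extend(_scan_frame(rc, offset, -(offset + 1)))
    return orfs


def max_orf_aa(seq: str, require_complete: bool = False) -> int:
    """Longest ORF (in amino acids) over all six frames; 0 if none."""
    if len(seq) < 3:
        return 0
    best = 0
    for orf in scan_orfs(seq):
        if require_complete and not orf.complete:
            continue
        best = max(best, orf.aa_length)
    return best


@dataclass
class FilterReport:
    """Telescoping per-stage record of the identification funnel."""

    stages: list[tuple[str, int, int, int]] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_removed: int) -> None:
        self.stages.append((name, n_in, n_removed, n_in - n_removed))

    @property
    def final_retained(self) -> int:
        return self.stages[-1][3] if self.stages else 0

    def to_rows(self) -> list[dict]:
        return [
            {"stage": s, "input": i, "removed": r, "retained": k}
            for s, i, r, k in self.stages
        ]


def filter_by_length(
    records: Sequence[SeqRecord], min_len: int = 201
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Partition records into (kept, removed) by ``len >= min_len``."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [r for r in records if len(r.seq) >= min_len]
    removed = [r for r in records if len(r.seq) < min_len]
    return kept, removed


def filter_by_orf(
    records: Sequence[SeqRecord],
    max_aa: int = 100,
    require_complete: bool = False,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Remove records whose longest six-frame ORF exceeds *max_aa* codons.

    By default incomplete (stop-less) ORFs count toward the exclusion,
    the conservative choice for assembled fragments; pass
    ``require_complete=True`` to count only stop-terminated ORFs.
    """
    if max_aa < 1:
        raise ValueError("max_aa must be >= 1")
    kept, removed = [], []
    for r in records:
        if max_orf_aa(r.seq, require_complete=require_complete) > max_aa:
            removed.append(r)
        else:
            kept.append(r)
    return kept, removed


def apply_score_filter(
    records: Sequence[SeqRecord],
    score_table: Mapping[str, float],
    keep_below: float = 0.0,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Keep records whose ingested coding-potential score is < *keep_below*.

    Records absent from the table are kept and logged: the funnel removes
    only on positive evidence of coding capacity.
    """
    kept, removed = [], []
    missing = 0
    for r in records:
        if r.id not in score_table:
            missing += 1
            kept.append(r)
        elif score_table[r.id] < keep_below:
            kept.append(r)
        else:
            removed.append(r)
    if missing:
        logger.warning(
            "%d transcript(s) missing from the score table were kept", missing
        )
    return kept, removed


def apply_homology_filter(
    records: Sequence[SeqRecord], hit_table: Iterable[TabularHit]
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Remove records that appear as a query in at least one protein hit."""
    with_hits = {h.query_id for h in hit_table}
    kept = [r for r in records if r.id not in with_hits]
    removed = [r for r in records if r.id in with_hits]
    return kept, removed


def run_identification(
    records: Sequence[SeqRecord],
    min_len: int = 201,
    max_aa: int = 100,
    scores: Mapping[str, float] | None = None,
    protein_hits: Iterable[TabularHit] | None = None,
    require_complete_orfs: bool = False,
) -> tuple[list[SeqRecord], FilterReport]:
    """Run the full funnel: length, ORF, then optional score and homology.

    Returns the surviving candidate records and a telescoping report.
    """
    report = FilterReport()
    current = list(records)

    kept, removed = filter_by_length(current, min_len)
    report.add("length", len(current), len(removed))
    current = kept

    kept, removed = filter_by_orf(current, max_aa, require_complete_orfs)
    report.add("orf", len(current), len(removed))
    current = kept

    if scores is not None:
        kept, removed = apply_score_filter(current, scores)
        report.add("coding_score", len(current), len(removed))
        current = kept

    if protein_hits is not None:
        kept, removed = apply_homology_filter(current, protein_hits)
        report.add("protein_homology", len(current), len(removed))
        current = kept

    return current, report
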