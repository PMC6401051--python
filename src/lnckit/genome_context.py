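"""Genomic placement and classification of transcripts.

Places candidate transcripts on chromosomes from tabular alignment hits,
summarises their distribution (per-chromosome counts, densities per Mbp,
length histograms) and assigns each transcript a single-character class
code describing its relation to reference gene models (intergenic,
intronic, antisense, ...).

All coordinates are 0-based half-open; conversion from 1-based file
formats happens in :mod:`lnckit.io_formats`.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

#: Precedence of class codes: the first applicable code wins.
CLASS_CODE_ORDER = ("=", "c", "j", "e", "o", "i", "x", "s", "p", "u")

#: Maximum distance (nt) from a reference 3' end for the run-on code 'p'.
RUNON_WINDOW = 2000


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded chain of exons on one chromosome.

    Exons are 0-based half-open intervals, sorted and non-overlapping.
    Introns are derived as the gaps between consecutive exons.
    """

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ValueError(f"transcript {self.id!r}: at least one exon required")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for start, end in exons:
            if end - start < 1:
                raise ValueError(
                    f"transcript {self.id!r}: exon [{start}, {end}) has length < 1"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"transcript {self.id!r}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class ClassCodeResult:
    transcript_id: str
    code: str
    reference_id: str = ""


class Locus(NamedTuple):
    """Genomic placement of one transcript (0-based half-open)."""

    chrom: str
    strand: str
    start: int
    end: int


@dataclass
class DensityTable:
    """Per-chromosome placement summary."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _within(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return b[0] <= a[0] and a[1] <= b[1]


# ---------------------------------------------------------------------------
# placement


def assign_chromosome(
    hits: Iterable,
    min_identity: float = 90.0,
    max_evalue: float = 1e-10,
) -> tuple[dict[str, Locus], list[str]]:
    """Pick one genomic locus per query from genome-alignment hits.

    Hits with ``percent_identity`` not strictly above *min_identity* or
    ``evalue`` not strictly below *max_evalue* are discarded.  Among the
    survivors the best hit per query is chosen by descending bit score,
    then ascending e-value, subject id and subject start.  Queries whose
    hits all fail the thresholds are returned in the *unplaced* list.
    """
    best: dict[str, tuple] = {}
    seen: set[str] = set()
    for h in hits:
        seen.add(h.query_id)
        if not (h.percent_identity > min_identity and h.evalue < max_evalue):
            continue
        s_lo = min(h.s_start, h.s_end)
        key = (-h.bit_score, h.evalue, h.subject_id, h.s_start)
        if h.query_id not in best or key < best[h.query_id][0]:
            strand = "+" if h.s_start <= h.s_end else "-"
            locus = Locus(h.subject_id, strand, s_lo - 1, max(h.s_start, h.s_end))
            best[h.query_id] = (key, locus)
    placed = {q: v[1] for q, v in sorted(best.items())}
    unplaced = sorted(seen - set(placed))
    return placed, unplaced


def density_and_distribution(
    loci: Mapping[str, Locus], chrom_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Per-chromosome count, density per Mbp and share of placed transcripts.

    Raises ``ValueError`` for a locus on a chromosome absent from
    *chrom_lengths*.  Shares sum to 100 over chromosomes with ≥1 locus.
    """
    counts: dict[str, int] = {c: 0 for c in chrom_lengths}
    for tid, locus in loci.items():
        if locus.chrom not in chrom_lengths:
            raise ValueError(
                f"transcript {tid!r} placed on unknown chromosome {locus.chrom!r}"
            )
        counts[locus.chrom] += 1
    total = sum(counts.values())
    rows = []
    for chrom in sorted(chrom_lengths):
        n = counts[chrom]
        length = chrom_lengths[chrom]
        rows.append(
            {
                "chrom": chrom,
                "count": n,
                "chrom_length": length,
                "density_per_mbp": n / (length / 1e6),
                "share_percent": (100.0 * n / total) if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


DEFAULT_LENGTH_EDGES = (250, 500, 1000, 2000, 4000)


def length_histogram(
    lengths: Iterable[int], bin_edges: Sequence[int] = DEFAULT_LENGTH_EDGES
) -> list[tuple[tuple[int, int], int]]:
    """Count lengths into left-open right-closed bins between the edges.

    With edges ``(250, 500, 1000)`` the bins are ``(250, 500]`` and
    ``(500, 1000]``; values outside every bin are ignored.
    """
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    bins = list(zip(edges, edges[1:]))
    counts = [0] * len(bins)
    for length in lengths:
        for i, (lo, hi) in enumerate(bins):
            if lo < length <= hi:
                counts[i] += 1
                break
    return [(b, c) for b, c in zip(bins, counts)]


# ---------------------------------------------------------------------------
# class codes


def _code_against_reference(q: TranscriptModel, r: TranscriptModel) -> str | None:
    """First class code in precedence order that holds for q against r."""
    if q.chrom != r.chrom:
        return None
    same = q.strand == r.strand
    q_multi = len(q.exons) > 1
    r_multi = len(r.exons) > 1
    exonic = any(_overlap(qe, re) for qe in q.exons for re in r.exons)
    span_overlap = _overlap(q.span, r.span)

    if same:
        # '=': identical intron chain (multi-exon) or identical coords.
        if q_multi and r_multi and q.introns == r.introns:
            return "="
        if not q_multi and not r_multi and q.exons == r.exons:
            return "="
        # 'c': contained — every exon inside a reference exon and the
        # intron chain a contiguous sub-chain of the reference's.
        if all(any(_within(qe, re) for re in r.exons) for qe in q.exons):
            qi, ri = q.introns, r.introns
            contiguous = not qi or any(
                ri[k : k + len(qi)] == qi for k in range(len(ri) - len(qi) + 1)
            )
            if contiguous:
                return "c"
        # 'j': shares at least one splice junction.
        if q_multi and r_multi and set(q.introns) & set(r.introns):
            return "j"
        # 'e': single exon overlapping both a reference exon and intron.
        if (
            not q_multi
            and exonic
            and any(_overlap(q.exons[0], ri) for ri in r.introns)
        ):
            return "e"
        if exonic:
            return "o"
        # 'i': all exons inside one reference intron.
        if any(_within(q.span, ri) for ri in r.introns):
            return "i"
        # 'p': run-on fragment just downstream of the reference 3' end.
        if not span_overlap:
            if r.strand == "+" and 0 <= q.start - r.end <= RUNON_WINDOW:
                return "p"
            if r.strand == "-" and 0 <= r.start - q.end <= RUNON_WINDOW:
                return "p"
    else:
        if exonic:
            return "x"
        # 's': opposite-strand overlap confined to reference introns.
        if span_overlap and all(
            any(_within(qe, ri) for ri in r.introns) for qe in q.exons
        ):
            return "s"
    return None


def classify_transcript(
    model: TranscriptModel,
    references: Iterable[TranscriptModel] | Mapping[str, Sequence[TranscriptModel]],
) -> ClassCodeResult:
    """Assign a single class code to *model* against the reference models.

    Every reference is scored independently; the code earliest in
    :data:`CLASS_CODE_ORDER` wins, with ties broken by reference id.
    A transcript matching nothing (including one on a chromosome with no
    references) is 'u' with an empty witness.
    """
    if isinstance(references, Mapping):
        refs = references.get(model.chrom, ())
    else:
        refs = [r for r in references if r.chrom == model.chrom]
    rank = {c: i for i, c in enumerate(CLASS_CODE_ORDER)}
    best: tuple[int, str, str] | None = None
    for r in refs:
        code = _code_against_reference(model, r)
        if code is None:
            continue
        cand = (rank[code], r.id, code)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        return ClassCodeResult(model.id, "u", "")
    return ClassCodeResult(model.id, best[2], best[1])


def index_references(
    references: Iterable[TranscriptModel],
) -> dict[str, list[TranscriptModel]]:
    by_chrom: dict[str, list[TranscriptModel]] = defaultdict(list)
    for r in references:
        by_chrom[r.chrom].append(r)
    return dict(by_chrom)


def classify_transcripts(
    models: Iterable[TranscriptModel], references: Iterable[TranscriptModel]
) -> list[ClassCodeResult]:
    idx = index_references(references)
    return [classify_transcript(m, idx) for m in models]


def class_code_summary(results: Iterable[ClassCodeResult]) -> dict[str, float]:
    """Percentage of transcripts per class code (sums to 100 when non-empty)."""
    counts: dict[str, int] = defaultdict(int)
    for res in results:
        counts[res.code] += 1
    total = sum(counts.values())
    if not total:
        return {}
    return {code: 100.0 * n / total for code, n in sorted(counts.items())}


def loci_to_models(loci: Mapping[str, Locus]) -> list[TranscriptModel]:
    """Turn genome placements into single-exon transcript models."""
    return [
        TranscriptModel(tid, loc.chrom, loc.strand, ((loc.start, loc.end),))
        for tid, loc in loci.items()
    ]
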