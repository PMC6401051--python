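"""Readers and writers for the plain-text formats the pipeline touches.

FASTA, GTF exon features, 12-column tabular alignment hits (the classic
``outfmt 6`` dialect), score tables and annotation-term tables.  All
readers validate strictly and raise ``ValueError`` with the offending id
or line number; all writers round-trip through their reader.

Internal coordinates are 0-based half-open; 1-based inclusive GTF
coordinates are converted at the file boundary only.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .genome_context import TranscriptModel

_VALID_BASES = frozenset("ACGTN")
_TERM_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*:\d+$")


@dataclass(frozen=True)
class SeqRecord:
    """A nucleotide sequence record.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    the full header is kept in ``description``.  Sequences are stored
    upper-case with U normalized to T so miRNA and transcript alphabets
    unify.
    """

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TabularHit:
    """One row of a 12-column tabular alignment report.

    Subject coordinates are kept 1-based inclusive as printed;
    ``s_start > s_end`` encodes a minus-strand subject orientation.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    @property
    def subject_strand(self) -> str:
        return "+" if self.s_start <= self.s_end else "-"


class TermTable:
    """Transcript → annotation-term mapping with term labels."""

    def __init__(self) -> None:
        self.terms: dict[str, set[str]] = defaultdict(set)
        self.labels: dict[str, str] = {}

    def add(self, transcript_id: str, accession: str, label: str = "") -> None:
        if not _TERM_RE.match(accession):
            raise ValueError(f"malformed term accession {accession!r}")
        if accession in self.terms[transcript_id]:
            raise ValueError(
                f"duplicate (transcript, term) pair: ({transcript_id!r}, {accession!r})"
            )
        self.terms[transcript_id].add(accession)
        if label:
            self.labels[accession] = label

    def get(self, transcript_id: str) -> set[str]:
        return set(self.terms.get(transcript_id, ()))

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.terms

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for terms in self.terms.values():
            out |= terms
        return out


# ---------------------------------------------------------------------------
# FASTA


def _normalize_seq(raw: str, line_no: int) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(
            f"line {line_no}: non-IUPAC nucleotide character(s) {sorted(bad)!r}"
        )
    return seq


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Parse a (possibly multi-line) FASTA file into ordered records.

    Duplicate ids and characters outside {A,C,G,T,N,U} are hard errors.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        rec_id = header.split()[0] if header.split() else ""
        if not rec_id:
            raise ValueError(f"line {header_line}: empty FASTA header")
        if rec_id in seen:
            raise ValueError(f"duplicate FASTA id {rec_id!r}")
        seq = "".join(chunks)
        if not seq:
            raise ValueError(f"FASTA record {rec_id!r} has an empty sequence")
        seen.add(rec_id)
        records.append(SeqRecord(rec_id, seq, header))

    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = line_no
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"line {line_no}: sequence before first '>'")
                chunks.append(_normalize_seq(line.strip(), line_no))
    flush()
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    Exons are grouped by ``transcript_id``, sorted by start, and the
    1-based inclusive coordinates converted to 0-based half-open.
    Missing transcript_id attributes, '.' strands and overlapping exons
    within one transcript are hard errors.
    """
    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"line {line_no}: expected 9 tab-separated columns")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            if strand not in ("+", "-"):
                raise ValueError(
                    f"line {line_no}: exon strand must be '+' or '-', got {strand!r}"
                )
            attr_map = dict(_ATTR_RE.findall(attrs))
            tid = attr_map.get("transcript_id")
            if not tid:
                raise ValueError(f"line {line_no}: exon without transcript_id")
            interval = (int(start) - 1, int(end))
            if tid not in meta:
                meta[tid] = (chrom, strand)
                order.append(tid)
            elif meta[tid] != (chrom, strand):
                raise ValueError(
                    f"line {line_no}: transcript {tid!r} spans chromosomes or strands"
                )
            exons[tid].append(interval)
    models = []
    for tid in order:
        chrom, strand = meta[tid]
        ivs = sorted(exons[tid])
        for (s1, e1), (s2, _e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"transcript {tid!r}: overlapping exons in GTF")
        models.append(TranscriptModel(tid, chrom, strand, tuple(ivs)))
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str | Path, source: str = "lnckit") -> None:
    with open(path, "w") as fh:
        for m in models:
            for start, end in m.exons:
                attrs = f'gene_id "{m.id}"; transcript_id "{m.id}";'
                fh.write(
                    "\t".join(
                        [m.chrom, source, "exon", str(start + 1), str(end), ".",
                         m.strand, ".", attrs]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# tabular alignment hits


def read_blast_tab(path: str | Path) -> list[TabularHit]:
    """Read a 12-column tabular hit file; '#' comment lines are skipped."""
    hits: list[TabularHit] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"line {line_no}: expected 12 columns, got {len(fields)}"
                )
            try:
                hit = TabularHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    align_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"line {line_no}: {exc}") from None
            if hit.q_start > hit.q_end:
                raise ValueError(f"line {line_no}: q_start > q_end")
            hits.append(hit)
    return hits


def write_blast_tab(hits: Iterable[TabularHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
                        str(h.align_length), str(h.mismatches), str(h.gap_opens),
                        str(h.q_start), str(h.q_end), str(h.s_start), str(h.s_end),
                        f"{h.evalue:.2e}", f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# small TSV tables


def read_score_table(path: str | Path) -> dict[str, float]:
    """Read a two-column ``transcript_id<TAB>score`` table (header optional)."""
    scores: dict[str, float] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"line {line_no}: expected 2 columns")
            if line_no == 1 and fields[1].lower() in ("score", "coding_score"):
                continue
            try:
                scores[fields[0]] = float(fields[1])
            except ValueError:
                raise ValueError(
                    f"line {line_no}: malformed score {fields[1]!r}"
                ) from None
    return scores


def write_score_table(scores: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tscore\n")
        for tid, score in scores.items():
            fh.write(f"{tid}\t{score:.4f}\n")


def read_term_table(path: str | Path) -> TermTable:
    """Read ``transcript_id<TAB>term<TAB>label`` rows (label optional)."""
    table = TermTable()
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (2, 3):
                raise ValueError(f"line {line_no}: expected 2 or 3 columns")
            if line_no == 1 and fields[1].lower() in ("term", "accession"):
                continue
            label = fields[2] if len(fields) == 3 else ""
            try:
                table.add(fields[0], fields[1], label)
            except ValueError as exc:
                raise ValueError(f"line {line_no}: {exc}") from None
    return table


def write_term_table(table: TermTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tterm\tlabel\n")
        for tid in sorted(table.terms):
            for term in sorted(table.terms[tid]):
                fh.write(f"{tid}\t{term}\t{table.labels.get(term, '')}\n")


def read_id_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]
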