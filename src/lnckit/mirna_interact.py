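"""miRNA interaction calling for lncRNA candidates.

Three interaction kinds are called: penalty-scored target sites, hairpin
(precursor) embeddings, and target mimics whose duplex carries a short
transcript-side bulge between miRNA positions 10 and 11.  A typed
tripartite network export assembles the calls together with
co-expression edges.

Scoring follows the plant-target penalty family: Watson–Crick pair 0,
G:U wobble 0.5, mismatch 1.0, all doubled over miRNA positions 2–13,
with a total-penalty cutoff.  Mimic acceptance replaces thermodynamic
folding by a pairing-score ratio (G:C = 3, A:T = 2, G:U = 1) against the
perfect duplex; hairpin foldback is characterised by base-pair
maximization with a minimum loop of 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .coexpress import CoexpressionEdge, local_align
from .identify import reverse_complement
from .io_formats import SeqRecord

SEED_START, SEED_END = 2, 13  # doubled-penalty positions, 1-based inclusive

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# penalty per (mirna base, transcript base): WC 0, G:U 0.5, mismatch 1
_PENALTY = np.ones((5, 5))
for _m, _t in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
    _PENALTY[_CODE[_m], _CODE[_t]] = 0.0
for _m, _t in (("G", "T"), ("T", "G")):
    _PENALTY[_CODE[_m], _CODE[_t]] = 0.5

# pairing score per (mirna base, transcript base): G:C 3, A:T 2, G:U 1
_PAIR_SCORE = np.zeros((5, 5))
for _m, _t in (("G", "C"), ("C", "G")):
    _PAIR_SCORE[_CODE[_m], _CODE[_t]] = 3.0
for _m, _t in (("A", "T"), ("T", "A")):
    _PAIR_SCORE[_CODE[_m], _CODE[_t]] = 2.0
for _m, _t in (("G", "T"), ("T", "G")):
    _PAIR_SCORE[_CODE[_m], _CODE[_t]] = 1.0

_CAN_PAIR = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[b] for b in seq), dtype=np.int8, count=len(seq))


def _state(m: str, t: str) -> str:
    if (m, t) in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
        return "M"  # Watson-Crick
    if (m, t) in (("G", "T"), ("T", "G")):
        return "W"  # G:U wobble
    return "X"


@dataclass(frozen=True)
class DuplexAlignment:
    """A scored miRNA/transcript pairing at one transcript window.

    States run 5'→3' along the miRNA ('M' Watson–Crick, 'W' G:U wobble,
    'X' mismatch).  ``bulge`` is ``(miRNA position before the bulge,
    inserted transcript nt)`` for mimics, ``None`` for plain targets.
    """

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    states: str
    kind: str
    penalty_score: float | None = None
    pairing_score: float | None = None
    pairing_ratio: float | None = None
    bulge: tuple[int, int] | None = None


@dataclass(frozen=True)
class HairpinMatch:
    hairpin_id: str
    lncrna_id: str
    start: int
    end: int
    identity: float
    coverage: float
    foldback_paired_fraction: float


def _seed_weights(length: int) -> np.ndarray:
    w = np.ones(length)
    w[SEED_START - 1 : SEED_END] = 2.0
    return w


def score_duplex(mirna_seq: str, window_seq: str) -> tuple[float, str]:
    """Penalty and per-position states for an ungapped duplex.

    miRNA position 1 (5' end) pairs the window's 3'-most base.  The
    window must match the miRNA length exactly.
    """
    if len(window_seq) != len(mirna_seq):
        raise ValueError("window length must equal miRNA length in ungapped mode")
    m = mirna_seq.upper().replace("U", "T")
    w = window_seq.upper().replace("U", "T")
    length = len(m)
    weights = _seed_weights(length)
    penalty = 0.0
    states = []
    for i in range(1, length + 1):
        mb, tb = m[i - 1], w[length - i]
        states.append(_state(mb, tb))
        penalty += weights[i - 1] * _PENALTY[_CODE[mb], _CODE[tb]]
    return penalty, "".join(states)


def _collapse(sites: list, key) -> list:
    """Greedy best-first collapse of overlapping sites (tie → leftmost)."""
    chosen: list = []
    for site in sorted(sites, key=key):
        if all(site.end <= c.start or site.start >= c.end for c in chosen):
            chosen.append(site)
    return sorted(chosen, key=lambda s: s.start)


def find_target_sites(
    mirna: SeqRecord,
    transcript: SeqRecord,
    max_score: float = 3.0,
) -> list[DuplexAlignment]:
    """Scan every window of the transcript for target sites of one miRNA.

    Windows scoring at most *max_score* are reported; overlapping sites
    are collapsed to the best-scoring (leftmost on ties).
    """
    m = _encode(mirna.seq)
    t = _encode(transcript.seq)
    length = m.size
    if t.size < length:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(t, length)
    # column i-1 pairs miRNA position i after reversing the window
    rev = windows[:, ::-1]
    penalties = (_PENALTY[m[None, :], rev] * _seed_weights(length)).sum(axis=1)
    hits = []
    for start in np.nonzero(penalties <= max_score)[0]:
        score, states = score_duplex(mirna.seq, transcript.seq[start : start + length])
        hits.append(
            DuplexAlignment(
                mirna.id, transcript.id, int(start), int(start + length),
                states, "target", penalty_score=score,
            )
        )
    return _collapse(hits, key=lambda s: (s.penalty_score, s.start))


def find_etm_sites(
    mirna: SeqRecord,
    transcript: SeqRecord,
    min_pairing_ratio: float = 0.7,
    bulge_len: int = 3,
    paired_span: tuple[int, int] = (2, 13),
    max_unpaired: int = 1,
) -> list[DuplexAlignment]:
    """Scan for target-mimic sites with a transcript-side central bulge.

    Windows of miRNA length + *bulge_len* are tested with the inserted
    nucleotides placed between the bases pairing miRNA positions 10 and
    11; both flanks align without gaps.  A window qualifies when
    positions 10 and 11 both pair and the pairing-score ratio against
    the perfect full-length duplex reaches *min_pairing_ratio*.

    Two geometric side conditions keep the call specific on random
    sequence (a mimic sequesters the miRNA, so its duplex must be nearly
    fully engaged): every miRNA position across *paired_span* (1-based,
    inclusive — by default the central/seed block whose penalties the
    target scorer doubles) must pair (Watson–Crick or G:U), and at most
    *max_unpaired* positions of the whole miRNA may be unpaired.
    """
    if not 2 <= bulge_len <= 4:
        raise ValueError("bulge length must be between 2 and 4")
    m = _encode(mirna.seq)
    t = _encode(transcript.seq)
    length = m.size
    wlen = length + bulge_len
    if t.size < wlen:
        return []
    perfect = float(np.where((m == _CODE["G"]) | (m == _CODE["C"]), 3.0, 2.0).sum())
    windows = np.lib.stride_tricks.sliding_window_view(t, wlen)
    # partner column per miRNA position: i<=10 -> L+bulge-i, i>=11 -> L-i
    partner = np.array(
        [wlen - i if i <= 10 else length - i for i in range(1, length + 1)]
    )
    paired = windows[:, partner]
    scores = _PAIR_SCORE[m[None, :], paired]
    ratio = scores.sum(axis=1) / perfect
    engaged = scores > 0
    anchored = engaged[:, 9] & engaged[:, 10]
    lo, hi = paired_span
    span_ok = engaged[:, lo - 1 : hi].all(axis=1)
    few_gaps = (~engaged).sum(axis=1) <= max_unpaired
    hits = []
    for start in np.nonzero(
        (ratio >= min_pairing_ratio) & anchored & span_ok & few_gaps
    )[0]:
        window = transcript.seq[start : start + wlen]
        states = "".join(
            _state(mirna.seq[i - 1], window[partner[i - 1]])
            for i in range(1, length + 1)
        )
        hits.append(
            DuplexAlignment(
                mirna.id, transcript.id, int(start), int(start + wlen),
                states, "eTM",
                pairing_score=float(scores[start].sum()),
                pairing_ratio=float(ratio[start]),
                bulge=(10, bulge_len),
            )
        )
    return _collapse(hits, key=lambda s: (-s.pairing_ratio, s.start))


# ---------------------------------------------------------------------------
# precursors


def nussinov_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum number of nested base pairs (WC + G:U) with a minimum loop.

    Positions i and j may pair only when ``j - i > min_loop``.
    """
    n = len(seq)
    if n < 2:
        return 0
    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - min_loop):
                if (seq[k], seq[j]) in _CAN_PAIR:
                    left = dp[i][k - 1] if k > i else 0
                    inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    best = max(best, 1 + left + inner)
            dp[i][j] = best
    return dp[0][n - 1]


def foldback_paired_fraction(seq: str, min_loop: int = 3) -> float:
    """Fraction of bases engaged in the maximal nested pairing."""
    if not seq:
        return 0.0
    return 2.0 * nussinov_max_pairs(seq, min_loop) / len(seq)


def find_precursors(
    lncrnas: Sequence[SeqRecord],
    hairpins: Sequence[SeqRecord],
    min_identity: float = 0.95,
    min_coverage: float = 0.95,
) -> list[HairpinMatch]:
    """Match hairpin sequences inside lncRNAs by local alignment.

    A match must reach *min_identity* over its columns and cover at
    least *min_coverage* of the hairpin; the foldback pairing fraction
    of the matched lncRNA segment is reported (not filtered on).  Both
    lncRNA strands are searched.
    """
    if not hairpins:
        raise ValueError("hairpin set must be non-empty")
    matches = []
    for lnc in lncrnas:
        for hp in hairpins:
            best = None
            for strand, seq in (("+", lnc.seq), ("-", reverse_complement(lnc.seq))):
                aln = local_align(hp.seq, seq)
                if aln is None:
                    continue
                coverage = (aln.q_end - aln.q_start) / len(hp.seq)
                if aln.identity >= min_identity and coverage >= min_coverage:
                    if best is None or aln.score > best[0].score:
                        best = (aln, strand)
            if best is None:
                continue
            aln, strand = best
            if strand == "+":
                start, end = aln.s_start, aln.s_end
            else:
                start, end = len(lnc.seq) - aln.s_end, len(lnc.seq) - aln.s_start
            segment = lnc.seq[start:end]
            matches.append(
                HairpinMatch(
                    hp.id, lnc.id, start, end, aln.identity,
                    (aln.q_end - aln.q_start) / len(hp.seq),
                    foldback_paired_fraction(segment),
                )
            )
    return matches


# ---------------------------------------------------------------------------
# roles and network


def classify_interactions(
    targets: Iterable[DuplexAlignment],
    etms: Iterable[DuplexAlignment],
    precursors: Iterable[HairpinMatch],
    suppress_overlapping_etms: bool = True,
) -> tuple[dict[str, set[str]], dict[tuple[str, str], int], list[DuplexAlignment]]:
    """Role sets per lncRNA plus pairwise overlap counts.

    A mimic call overlapping a target call of the same miRNA on the same
    transcript is suppressed by default: bulge presence partitions the
    two kinds, so one locus never carries both.  Returns (roles,
    overlap_counts, retained_etms).
    """
    targets = list(targets)
    kept_etms = []
    for e in etms:
        clash = suppress_overlapping_etms and any(
            t.transcript_id == e.transcript_id
            and t.mirna_id == e.mirna_id
            and t.start < e.end
            and e.start < t.end
            for t in targets
        )
        if not clash:
            kept_etms.append(e)
    roles: dict[str, set[str]] = {}
    for t in targets:
        roles.setdefault(t.transcript_id, set()).add("target")
    for e in kept_etms:
        roles.setdefault(e.transcript_id, set()).add("eTM")
    for p in precursors:
        roles.setdefault(p.lncrna_id, set()).add("precursor")
    pairs = [("target", "precursor"), ("target", "eTM"), ("precursor", "eTM")]
    overlaps = {
        pair: sum(1 for r in roles.values() if pair[0] in r and pair[1] in r)
        for pair in pairs
    }
    return roles, overlaps, kept_etms


def build_network(
    coexpr_edges: Iterable[CoexpressionEdge] = (),
    targets: Iterable[DuplexAlignment] = (),
    etms: Iterable[DuplexAlignment] = (),
    precursors: Iterable[HairpinMatch] = (),
    hairpin_to_mirna: Mapping[str, str] | None = None,
    known_ids: Iterable[str] | None = None,
) -> nx.MultiGraph:
    """Assemble the typed interaction graph.

    Nodes carry a ``kind`` attribute (lncRNA / miRNA / mRNA / ...),
    edges a ``kind`` of coexpression / target / eTM / precursor.  With
    *known_ids* given, an edge endpoint outside the universe is an
    error.
    """
    known = set(known_ids) if known_ids is not None else None
    g = nx.MultiGraph()

    def add_node(node: str, kind: str) -> None:
        if known is not None and node not in known:
            raise ValueError(f"dangling edge endpoint {node!r}")
        if node not in g or g.nodes[node].get("kind") == "":
            g.add_node(node, kind=kind)

    kind_map = {
        "mRNA": "mRNA",
        "TF": "TF",
        "chloroplast_CDS": "organelle_CDS",
        "mitochondrial_CDS": "organelle_CDS",
    }
    for e in coexpr_edges:
        add_node(e.lncrna_id, "lncRNA")
        add_node(e.partner_id, kind_map.get(e.partner_kind, e.partner_kind))
        g.add_edge(e.lncrna_id, e.partner_id, kind="coexpression", r=e.r)
    for d in targets:
        add_node(d.mirna_id, "miRNA")
        add_node(d.transcript_id, "lncRNA")
        g.add_edge(d.mirna_id, d.transcript_id, kind="target", score=d.penalty_score)
    for d in etms:
        add_node(d.mirna_id, "miRNA")
        add_node(d.transcript_id, "lncRNA")
        g.add_edge(d.mirna_id, d.transcript_id, kind="eTM", ratio=d.pairing_ratio)
    for p in precursors:
        partner = (hairpin_to_mirna or {}).get(p.hairpin_id, p.hairpin_id)
        add_node(partner, "miRNA")
        add_node(p.lncrna_id, "lncRNA")
        g.add_edge(partner, p.lncrna_id, kind="precursor", identity=p.identity)
    return g


def write_network(graph: nx.MultiGraph, edge_tsv: str, graphml: str | None = None) -> None:
    with open(edge_tsv, "w") as fh:
        fh.write("source\tsource_kind\ttarget\ttarget_kind\tedge_kind\n")
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1], e[2]["kind"])):
            fh.write(
                f"{u}\t{graph.nodes[u]['kind']}\t{v}\t{graph.nodes[v]['kind']}\t{data['kind']}\n"
            )
    if graphml:
        clean = nx.MultiGraph()
        for n, d in graph.nodes(data=True):
            clean.add_node(n, **d)
        for u, v, d in graph.edges(data=True):
            clean.add_edge(u, v, **{k: v2 for k, v2 in d.items() if v2 is not None})
        nx.write_graphml(clean, graphml)
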