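"""Co-expression edges, annotation transfer, enrichment and organelle
homology screening.

Edges connect candidate lncRNAs to partner transcripts (mRNA, TF,
chloroplast or mitochondrial CDS) whose condition-consensus profiles
correlate with squared Pearson r at or above a threshold; support is
estimated by resampling condition columns.  Organelle homology uses
ingested tabular hits or a small seeded Smith–Waterman aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust
from .io_formats import SeqRecord, TabularHit, TermTable

PARTNER_KINDS = ("mRNA", "TF", "chloroplast_CDS", "mitochondrial_CDS")


@dataclass
class CoexpressionEdge:
    lncrna_id: str
    partner_id: str
    partner_kind: str
    r: float
    bootstrap_support: float | None = None

    @property
    def r2(self) -> float:
        return self.r * self.r

    @property
    def sign(self) -> int:
        return 1 if self.r >= 0 else -1


def mean_filter(consensus: pd.DataFrame, min_mean: float = 30.0) -> list[str]:
    """Ids whose mean consensus over conditions is at least *min_mean*.

    Removal is strict: a transcript averaging exactly the threshold stays.
    """
    means = consensus.mean(axis=1)
    return [str(i) for i in consensus.index[means >= min_mean]]


def pearson_edges(
    set_a: Sequence[str],
    set_b: Sequence[str],
    consensus: pd.DataFrame,
    r2_threshold: float = 0.9,
    partner_kind: str = "mRNA",
    use_abs_r: bool = False,
) -> list[CoexpressionEdge]:
    """All (a, b) pairs whose consensus profiles satisfy the correlation rule.

    By default an edge requires r² ≥ *r2_threshold*; with ``use_abs_r``
    the rule is |r| ≥ threshold instead.  Zero-variance profiles yield no
    edges (r is undefined there).  Self-pairs and duplicate unordered
    pairs are skipped.
    """
    if consensus.shape[1] < 3:
        raise ValueError("need at least 3 conditions for correlation edges")
    if partner_kind not in PARTNER_KINDS:
        raise ValueError(f"partner_kind must be one of {PARTNER_KINDS}")
    a_ids = [i for i in set_a if i in consensus.index]
    b_ids = [i for i in set_b if i in consensus.index]
    if not a_ids or not b_ids:
        return []

    def zscores(ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        x = consensus.loc[ids].to_numpy(dtype=float)
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        ok = sd[:, 0] > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (x - mu) / sd
        return z, ok

    za, ok_a = zscores(a_ids)
    zb, ok_b = zscores(b_ids)
    n = consensus.shape[1]
    r_mat = za @ zb.T / (n - 1)

    edges = []
    seen: set[frozenset[str]] = set()
    for i, a in enumerate(a_ids):
        if not ok_a[i]:
            continue
        for j, b in enumerate(b_ids):
            if not ok_b[j] or a == b:
                continue
            pair = frozenset((a, b))
            if pair in seen:
                continue
            r = float(np.clip(r_mat[i, j], -1.0, 1.0))
            stat = abs(r) if use_abs_r else r * r
            if stat >= r2_threshold:
                seen.add(pair)
                edges.append(CoexpressionEdge(a, b, partner_kind, r))
    return edges


def bootstrap_support(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    r2_threshold: float = 0.9,
    n_runs: int = 100,
    seed: int = 0,
    use_abs_r: bool = False,
) -> float:
    """Fraction of condition-column resamples that keep the edge.

    Resamples (with replacement) the condition axis *n_runs* times;
    resamples in which either profile loses all variance are skipped.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    n = a.size
    kept = 0
    valid = 0
    for _ in range(n_runs):
        idx = rng.integers(0, n, size=n)
        ra, rb = a[idx], b[idx]
        if ra.std() == 0 or rb.std() == 0:
            continue
        valid += 1
        r = float(np.corrcoef(ra, rb)[0, 1])
        stat = abs(r) if use_abs_r else r * r
        if stat >= r2_threshold:
            kept += 1
    return kept / valid if valid else 0.0


def attach_bootstrap(
    edges: Iterable[CoexpressionEdge],
    consensus: pd.DataFrame,
    r2_threshold: float = 0.9,
    n_runs: int = 100,
    seed: int = 0,
) -> list[CoexpressionEdge]:
    """Compute support for every edge, deterministically ordered by ids."""
    out = sorted(edges, key=lambda e: (e.lncrna_id, e.partner_id))
    for k, edge in enumerate(out):
        edge.bootstrap_support = bootstrap_support(
            consensus.loc[edge.lncrna_id].to_numpy(),
            consensus.loc[edge.partner_id].to_numpy(),
            r2_threshold=r2_threshold,
            n_runs=n_runs,
            seed=seed + k,
        )
    return out


def transfer_annotations(
    edges: Iterable[CoexpressionEdge], term_table: TermTable
) -> dict[str, dict[str, list[str]]]:
    """Each lncRNA inherits the union of its partners' terms with witnesses."""
    inherited: dict[str, dict[str, list[str]]] = {}
    for edge in edges:
        for term in sorted(term_table.get(edge.partner_id)):
            by_term = inherited.setdefault(edge.lncrna_id, {})
            witnesses = by_term.setdefault(term, [])
            if edge.partner_id not in witnesses:
                witnesses.append(edge.partner_id)
    return inherited


def enrichment(
    selected_ids: Iterable[str],
    term_table: TermTable,
    background_ids: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of terms in the selected set.

    For each term: p = P(X ≥ hits_selected) drawing |selected| items
    from a background of size |background| containing hits_background
    term carriers; BH-adjusted across terms.
    """
    selected = set(selected_ids)
    background = set(background_ids)
    if not selected <= background:
        raise ValueError("selected ids must be a subset of the background")
    rows = []
    term_universe: set[str] = set()
    for tid in background:
        term_universe |= term_table.get(tid)
    for term in sorted(term_universe):
        carriers = {tid for tid in background if term in term_table.get(tid)}
        k = len(carriers & selected)
        big_k = len(carriers)
        p = float(stats.hypergeom.sf(k - 1, len(background), big_k, len(selected)))
        rows.append(
            {
                "term": term,
                "label": term_table.labels.get(term, ""),
                "hits_selected": k,
                "hits_background": big_k,
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    else:
        df["fdr"] = pd.Series(dtype=float)
    return df


# ---------------------------------------------------------------------------
# local alignment (used when tabular hits are not ingested)


@dataclass(frozen=True)
class LocalAlignment:
    """A local alignment between a query and a subject sequence.

    ``align_length`` counts alignment columns including gaps; intervals
    are 0-based half-open on each sequence.
    """

    score: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    matches: int
    align_length: int

    @property
    def identity(self) -> float:
        return self.matches / self.align_length if self.align_length else 0.0


def _sw_align(
    a: str, b: str, match: float, mismatch: float, gap: float
) -> LocalAlignment | None:
    """Full Smith–Waterman with linear gaps and traceback (quadratic)."""
    n, m = len(a), len(b)
    h = [[0.0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        row, prev = h[i], h[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            score = max(0.0, diag, prev[j] + gap, row[j - 1] + gap)
            row[j] = score
            if score > best:
                best, bi, bj = score, i, j
    if best <= 0:
        return None
    i, j = bi, bj
    matches = cols = 0
    while i > 0 and j > 0 and h[i][j] > 0:
        cur = h[i][j]
        sub = match if a[i - 1] == b[j - 1] else mismatch
        if cur == h[i - 1][j - 1] + sub:
            matches += a[i - 1] == b[j - 1]
            cols += 1
            i, j = i - 1, j - 1
        elif cur == h[i - 1][j] + gap:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return LocalAlignment(best, i, bi, j, bj, matches, cols)


def _seed_windows(a: str, b: str, k: int = 13, pad: int = 60) -> list[tuple[int, int, int, int]]:
    """Candidate (a_lo, a_hi, b_lo, b_hi) windows from shared k-mers."""
    index: dict[str, list[int]] = {}
    for j in range(len(b) - k + 1):
        index.setdefault(b[j : j + k], []).append(j)
    seeds: list[tuple[int, int]] = []
    for i in range(len(a) - k + 1):
        for j in index.get(a[i : i + k], ()):
            seeds.append((i - j, i))
    if not seeds:
        return []
    seeds.sort()
    windows = []
    group: list[tuple[int, int]] = [seeds[0]]
    for d, i in seeds[1:]:
        if d - group[-1][0] <= 30:
            group.append((d, i))
        else:
            windows.append(group)
            group = [(d, i)]
    windows.append(group)
    out = []
    for grp in windows:
        a_lo = max(0, min(i for _, i in grp) - pad)
        a_hi = min(len(a), max(i for _, i in grp) + k + pad)
        d_lo, d_hi = min(d for d, _ in grp), max(d for d, _ in grp)
        b_lo = max(0, a_lo - d_hi - pad)
        b_hi = min(len(b), a_hi - d_lo + pad)
        out.append((a_lo, a_hi, b_lo, b_hi))
    return out


def local_align(
    query: str,
    subject: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap: float = -2.5,
    full_dp_cells: int = 4_000,
) -> LocalAlignment | None:
    """Best local alignment of *query* against *subject*.

    Small problems get the exact quadratic dynamic program; larger ones
    are k-mer seeded and the DP restricted to windows around seed
    diagonals (a pair sharing no 13-mer yields no alignment), which is
    the usual seed-and-extend trade-off: high-identity matches are found
    exactly, faint diffuse similarity is not reported.
    """
    if not query or not subject:
        return None
    if len(query) * len(subject) <= full_dp_cells:
        return _sw_align(query, subject, match, mismatch, gap)
    best: LocalAlignment | None = None
    for a_lo, a_hi, b_lo, b_hi in _seed_windows(query, subject):
        sub = _sw_align(query[a_lo:a_hi], subject[b_lo:b_hi], match, mismatch, gap)
        if sub is None:
            continue
        shifted = LocalAlignment(
            sub.score, sub.q_start + a_lo, sub.q_end + a_lo,
            sub.s_start + b_lo, sub.s_end + b_lo, sub.matches, sub.align_length,
        )
        if best is None or shifted.score > best.score:
            best = shifted
    return best


def organelle_homology(
    lncrnas: Sequence[SeqRecord],
    organelle_seqs: Sequence[SeqRecord],
    min_align_len: int = 200,
    ingested_hits: Iterable[TabularHit] | None = None,
) -> pd.DataFrame:
    """Homology hits between lncRNAs and organelle sequences.

    Only alignments strictly longer than *min_align_len* columns are
    retained.  With ingested tabular hits the aligner is bypassed; both
    strands are searched otherwise.
    """
    rows = []
    if ingested_hits is not None:
        for h in ingested_hits:
            if h.align_length > min_align_len:
                rows.append(
                    {
                        "lncrna_id": h.query_id,
                        "organelle_id": h.subject_id,
                        "align_length": h.align_length,
                        "identity": h.percent_identity / 100.0,
                        "score": h.bit_score,
                    }
                )
        return pd.DataFrame(rows)

    from .identify import reverse_complement

    for lnc in lncrnas:
        for org in organelle_seqs:
            for strand, seq in (("+", lnc.seq), ("-", reverse_complement(lnc.seq))):
                aln = local_align(seq, org.seq)
                if aln is not None and aln.align_length > min_align_len:
                    rows.append(
                        {
                            "lncrna_id": lnc.id,
                            "organelle_id": org.id,
                            "align_length": aln.align_length,
                            "identity": aln.identity,
                            "score": aln.score,
                            "strand": strand,
                        }
                    )
    return pd.DataFrame(rows)


def edges_to_frame(edges: Iterable[CoexpressionEdge]) -> pd.DataFrame:
    rows = [
        {
            "lncrna_id": e.lncrna_id,
            "partner_id": e.partner_id,
            "partner_kind": e.partner_kind,
            "r": e.r,
            "r2": e.r2,
            "sign": e.sign,
            "bootstrap_support": e.bootstrap_support,
        }
        for e in edges
    ]
    return pd.DataFrame(rows)
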