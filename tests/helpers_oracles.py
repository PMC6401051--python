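"""Independent brute-force oracles used by the test suite.

Everything here is implemented naively and separately from the package:
codon walks, base-position set enumeration, exhaustive tail sums,
textbook formulas and exhaustive structure enumeration.  The point is
that these stay independent of the code paths they check.
"""

from __future__ import annotations

from math import comb, sqrt

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_STOPS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_max_orf(seq: str, require_complete: bool = False) -> int:
    """Max ORF length (aa) over six frames by walking every codon position."""
    best = 0
    for strand_seq in (seq, revcomp(seq)):
        n = len(strand_seq)
        for offset in range(3):
            for start in range(offset, n - 2, 3):
                if strand_seq[start : start + 3] != "ATG":
                    continue
                aa = 0
                complete = False
                pos = start
                while pos + 3 <= n:
                    codon = strand_seq[pos : pos + 3]
                    if pos > start and codon in _STOPS:
                        complete = True
                        break
                    aa += 1
                    pos += 3
                if complete or not require_complete:
                    best = max(best, aa)
    return best


# ---------------------------------------------------------------------------
# class codes by base-position enumeration


def _exon_bases(exons) -> set[int]:
    out: set[int] = set()
    for a, b in exons:
        out.update(range(a, b))
    return out


def _introns(exons):
    return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


def oracle_code_vs_ref(q, r) -> str | None:
    """Same rule set as the implementation, evaluated by enumerating bases."""
    if q.chrom != r.chrom:
        return None
    same = q.strand == r.strand
    qb = _exon_bases(q.exons)
    rb = _exon_bases(r.exons)
    q_in = _introns(q.exons)
    r_in = _introns(r.exons)
    r_in_bases = _exon_bases(r_in)
    q_span = set(range(q.exons[0][0], q.exons[-1][1]))
    r_span = set(range(r.exons[0][0], r.exons[-1][1]))

    checks = []
    if same:
        if len(q.exons) > 1 and len(r.exons) > 1:
            checks.append(("=", q_in == r_in))
        else:
            checks.append(
                ("=", len(q.exons) == 1 == len(r.exons) and tuple(q.exons) == tuple(r.exons))
            )
        contained = all(
            any(set(range(a, b)) <= set(range(c, d)) for c, d in r.exons)
            for a, b in q.exons
        )
        sub = False
        if not q_in:
            sub = True
        else:
            for k in range(len(r_in) - len(q_in) + 1):
                if r_in[k : k + len(q_in)] == q_in:
                    sub = True
        checks.append(("c", contained and sub))
        checks.append(
            ("j", len(q_in) >= 1 and len(r_in) >= 1 and bool(set(q_in) & set(r_in)))
        )
        checks.append(
            ("e", len(q.exons) == 1 and bool(qb & rb) and bool(qb & r_in_bases))
        )
        checks.append(("o", bool(qb & rb)))
        checks.append(
            ("i", any(qb <= set(range(a, b)) for a, b in r_in))
        )
        if not (q_span & r_span):
            if r.strand == "+":
                p_ok = 0 <= q.exons[0][0] - r.exons[-1][1] <= 2000
            else:
                p_ok = 0 <= r.exons[0][0] - q.exons[-1][1] <= 2000
            checks.append(("p", p_ok))
    else:
        checks.append(("x", bool(qb & rb)))
        checks.append(
            ("s", bool(q_span & r_span) and bool(qb) and qb <= r_in_bases)
        )
    order = ["=", "c", "j", "e", "o", "i", "x", "s", "p"]
    found = {c for c, ok in checks if ok}
    for code in order:
        if code in found:
            return code
    return None


def oracle_classify(q, refs) -> tuple[str, str]:
    order = ["=", "c", "j", "e", "o", "i", "x", "s", "p", "u"]
    best = None
    for r in refs:
        code = oracle_code_vs_ref(q, r)
        if code is None:
            continue
        key = (order.index(code), r.id)
        if best is None or key < best[0]:
            best = (key, code, r.id)
    if best is None:
        return "u", ""
    return best[1], best[2]


# ---------------------------------------------------------------------------
# statistics


def hypergeom_upper_tail(k: int, M: int, K: int, n: int) -> float:
    """P(X >= k) for a hypergeometric draw, by exhaustive summation."""
    total = comb(M, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += comb(K, j) * comb(M - K, n - j)
    return acc / total


def pearson_formula(x, y) -> float:
    """Textbook Pearson correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / sqrt(sxx * syy)


def bh_by_hand(pvals):
    """BH step-up computed literally from the definition."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    adj = [None] * m
    prev = 1.0
    for rank_pos in range(m - 1, -1, -1):
        i = indexed[rank_pos]
        value = min(prev, pvals[i] * m / (rank_pos + 1), 1.0)
        adj[i] = value
        prev = value
    return adj


# ---------------------------------------------------------------------------
# alignment and folding


def sw_score_oracle(a: str, b: str, match=1.0, mismatch=-2.0, gap=-2.5) -> float:
    """Best local alignment score by the full quadratic recurrence."""
    n, m = len(a), len(b)
    h = [[0.0] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            h[i][j] = max(
                0.0, h[i - 1][j - 1] + sub, h[i - 1][j] + gap, h[i][j - 1] + gap
            )
            best = max(best, h[i][j])
    return best


_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def nussinov_enumerate(seq: str, min_loop: int = 3) -> int:
    """Max nested pairs by exhaustive enumeration of pairings (n <= ~15)."""

    def go(positions: tuple[int, ...]) -> int:
        if not positions:
            return 0
        i, rest = positions[0], positions[1:]
        best = go(rest)  # i unpaired
        for idx, j in enumerate(rest):
            if j - i > min_loop and (seq[i], seq[j]) in _PAIRS:
                inner = tuple(p for p in rest[:idx] if p < j)
                outer = tuple(p for p in rest[idx + 1 :])
                # nested structures only: partners of inner stay inside (i, j)
                best = max(best, 1 + go(inner) + go(outer))
        return best

    return go(tuple(range(len(seq))))


# ---------------------------------------------------------------------------
# miRNA windows


def duplex_penalty_oracle(mirna: str, window: str) -> float:
    total = 0.0
    L = len(mirna)
    for i in range(1, L + 1):
        m, t = mirna[i - 1], window[L - i]
        if (m, t) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}:
            p = 0.0
        elif (m, t) in {("G", "T"), ("T", "G")}:
            p = 0.5
        else:
            p = 1.0
        if 2 <= i <= 13:
            p *= 2.0
        total += p
    return total


def target_windows_oracle(mirna: str, transcript: str, max_score: float):
    """(start, score) of every qualifying window, then greedy collapse."""
    L = len(mirna)
    qualifying = []
    for start in range(len(transcript) - L + 1):
        s = duplex_penalty_oracle(mirna, transcript[start : start + L])
        if s <= max_score:
            qualifying.append((start, s))
    chosen = []
    for start, s in sorted(qualifying, key=lambda t: (t[1], t[0])):
        if all(start + L <= c or start >= c + L for c, _ in chosen):
            chosen.append((start, s))
    return sorted(chosen)
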