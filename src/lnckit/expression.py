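"""Consensus expression, differential expression, abundance bins and the
tissue/developmental-stage specificity index.

The matrix holds per-sample FPKM values; samples map to conditions
(tissue, stage) with replicates.  Consensus is the per-condition
replicate mean (median by flag).  The built-in differential test is
Welch's t on log2(FPKM + 1) with Benjamini–Hochberg adjustment per
pairwise comparison; a transcript is differential when any comparison
shows at least *min_fold* consensus fold change at FDR ≤ *max_fdr*.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXPRESSION_BINS: tuple[tuple[float, float, str], ...] = (
    (0.0, 5.0, "extremely low"),
    (5.0, 20.0, "very low"),
    (20.0, 50.0, "low"),
    (50.0, 100.0, "moderate"),
    (100.0, 500.0, "high"),
    (500.0, 1000.0, "very high"),
    (1000.0, float("inf"), "extremely high"),
)


class ExpressionMatrix:
    """Transcripts × samples FPKM matrix with (tissue, stage, replicate) metadata."""

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame):
        if (values.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        required = {"tissue", "stage", "replicate"}
        if not required.issubset(samples.columns):
            raise ValueError(f"sample sheet needs columns {sorted(required)}")
        missing = set(values.columns) - set(samples.index)
        if missing:
            raise ValueError(f"samples missing from sheet: {sorted(missing)}")
        self.values = values
        self.samples = samples.loc[list(values.columns)].copy()
        self.samples["condition"] = (
            self.samples["tissue"].astype(str) + ":" + self.samples["stage"].astype(str)
        )

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.samples["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def condition_samples(self, condition: str) -> list[str]:
        mask = self.samples["condition"] == condition
        return list(self.samples.index[mask])

    @classmethod
    def from_tsv(cls, expr_path: str | Path, samples_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0, dtype=str)
        return cls(values, samples)

    def to_tsv(self, expr_path: str | Path, samples_path: str | Path) -> None:
        self.values.to_csv(expr_path, sep="\t", index_label="transcript_id")
        self.samples.drop(columns=["condition"]).to_csv(
            samples_path, sep="\t", index_label="sample"
        )


def consensus_expression(
    matrix: ExpressionMatrix, method: str = "mean"
) -> pd.DataFrame:
    """Collapse replicates into one value per condition (mean or median)."""
    if method not in ("mean", "median"):
        raise ValueError("method must be 'mean' or 'median'")
    cols = {}
    for cond in matrix.conditions:
        samp = matrix.condition_samples(cond)
        if not samp:
            raise ValueError(f"condition {cond!r} has no samples")
        block = matrix.values[samp]
        cols[cond] = block.mean(axis=1) if method == "mean" else block.median(axis=1)
    return pd.DataFrame(cols)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _ttest_pvalues(a: np.ndarray, b: np.ndarray, equal_var: bool = True) -> np.ndarray:
    """Vectorized two-sided two-sample t-test along axis 1.

    The default pools the variance (Student's t, df = na + nb − 2):
    replicates come from one protocol, and with 2–3 replicates the
    Welch–Satterthwaite df estimate collapses toward its minimum
    whenever one sample variance dominates, destroying power.  Welch's
    unpooled form is available with ``equal_var=False``.

    Rows where both groups have zero variance get p = 0 if the means
    differ and 1 otherwise, so the noiseless limit stays well defined.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se2 = pooled * (1.0 / na + 1.0 / nb)
            df = np.full(va.shape, float(na + nb - 2))
        else:
            se2 = va / na + vb / nb
            df = se2**2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        zero = se2 == 0
        t = (ma - mb) / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p[zero] = np.where(ma[zero] != mb[zero], 0.0, 1.0)
    return p


@dataclass(frozen=True)
class DEResult:
    transcript_id: str
    condition_a: str
    condition_b: str
    log2fc: float
    p_value: float
    fdr: float
    is_de: bool


def de_filter(
    matrix: ExpressionMatrix,
    min_fold: float = 4.0,
    max_fdr: float = 0.001,
    pseudocount: float = 1.0,
    equal_var: bool = True,
    ingested_pvalues: Mapping[tuple[str, str], pd.Series] | None = None,
) -> pd.DataFrame:
    """Pairwise differential-expression filter over all condition pairs.

    Returns a long-format frame with one row per (transcript, comparison)
    carrying log2 fold change (consensus + pseudocount), p, BH-FDR and
    the ``is_de`` flag.  Requires ≥2 replicates per condition unless
    p-values are ingested per comparison.  The built-in test is a
    two-sample t on log2(FPKM + 1), pooled-variance by default (see
    :func:`_ttest_pvalues`).
    """
    cons = consensus_expression(matrix)
    conds = matrix.conditions
    if len(conds) < 2:
        raise ValueError("need at least two conditions")
    log_blocks = {
        c: np.log2(matrix.values[matrix.condition_samples(c)].to_numpy() + 1.0)
        for c in conds
    }
    if ingested_pvalues is None:
        for c, block in log_blocks.items():
            if block.shape[1] < 2:
                raise ValueError(
                    f"condition {c!r} has <2 replicates and no ingested p-values"
                )
    min_lfc = np.log2(min_fold)
    frames = []
    index = cons.index
    for a, b in combinations(conds, 2):
        lfc = np.log2(
            (cons[a].to_numpy() + pseudocount) / (cons[b].to_numpy() + pseudocount)
        )
        if ingested_pvalues is not None:
            key = (a, b) if (a, b) in ingested_pvalues else (b, a)
            p = ingested_pvalues[key].reindex(index).to_numpy()
        else:
            p = _ttest_pvalues(log_blocks[a], log_blocks[b], equal_var=equal_var)
        fdr = bh_adjust(p)
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": index,
                    "condition_a": a,
                    "condition_b": b,
                    "log2fc": lfc,
                    "p_value": p,
                    "fdr": fdr,
                    "is_de": (np.abs(lfc) >= min_lfc) & (fdr <= max_fdr),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def de_transcripts(de_table: pd.DataFrame) -> set[str]:
    """Transcripts flagged differential in at least one comparison."""
    flagged = de_table.loc[de_table["is_de"], "transcript_id"]
    return set(flagged)


def bin_expression(fpkm: float) -> str:
    """Label an FPKM value with its abundance category.

    Bins are half-open ``(lo, hi]``; zero is 'not expressed'.
    """
    if fpkm < 0:
        raise ValueError("FPKM must be non-negative")
    if fpkm == 0:
        return "not expressed"
    for lo, hi, label in EXPRESSION_BINS:
        if lo < fpkm <= hi:
            return label
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class SpecificityResult:
    transcript_id: str
    indices: tuple[float, ...]
    max_index: float
    argmax_condition: str
    is_specific: bool
    defined: bool = True


def specificity_index(
    consensus_row: pd.Series,
    threshold: float = 0.7,
    transcript_id: str = "",
) -> SpecificityResult:
    """Per-condition specificity quotient for one transcript.

    Each index is the condition's consensus value divided by the sum over
    all conditions; the transcript is specific when the maximum index
    reaches *threshold*.  All-zero rows are flagged undefined and never
    specific.
    """
    values = consensus_row.to_numpy(dtype=float)
    if values.size < 2:
        raise ValueError("need at least two conditions")
    if (values < 0).any():
        raise ValueError("negative consensus values")
    total = values.sum()
    tid = transcript_id or str(consensus_row.name)
    if total == 0:
        return SpecificityResult(tid, (), float("nan"), "", False, defined=False)
    idx = values / total
    k = int(np.argmax(idx))
    return SpecificityResult(
        tid, tuple(idx), float(idx[k]), str(consensus_row.index[k]),
        bool(idx[k] >= threshold),
    )


def specificity_table(consensus: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    rows = []
    for tid, row in consensus.iterrows():
        res = specificity_index(row, threshold, transcript_id=str(tid))
        rows.append(
            {
                "transcript_id": res.transcript_id,
                "max_index": res.max_index,
                "condition": res.argmax_condition,
                "is_specific": res.is_specific,
                "defined": res.defined,
            }
        )
    return pd.DataFrame(rows)
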