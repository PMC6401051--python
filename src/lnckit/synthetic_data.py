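"""Fully self-consistent synthetic study generator.

Emits a genome, reference gene annotation, a transcript pool mixing
long-ORF coding and non-coding sequences, a replicated FPKM matrix over
3 tissues × 10 developmental stages, mature miRNAs with hairpins,
organelle coding sequences, stub tables standing in for external
coding-potential and homology tools, and a ground-truth manifest whose
every claim is re-derivable from the emitted files by the analysis
modules.

Planted structure: condition-specific profiles with an exact target
specificity index, ≥8-fold differential transcripts, noiseless shared
co-expression profiles (lncRNA–mRNA, lncRNA–TF, lncRNA–organelle),
perfect-complement miRNA target sites, verbatim hairpin embeddings,
mimic sites with a 3-nt bulge, shared organelle segments, and genomic
placements realising the intergenic / intronic / antisense / run-on
class codes.  Identical configs produce byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as expr_mod
from .identify import max_orf_aa, reverse_complement
from .io_formats import (
    SeqRecord,
    TabularHit,
    TermTable,
    write_blast_tab,
    write_fasta,
    write_gtf,
    write_score_table,
    write_term_table,
)
from .genome_context import TranscriptModel

#: 3 tissues × 10 developmental stages (4 leaf, 3 inflorescence, 3 berry).
TISSUE_STAGES: tuple[tuple[str, str], ...] = (
    ("leaf", "young"),
    ("leaf", "medium"),
    ("leaf", "large"),
    ("leaf", "mature"),
    ("inflorescence", "3d_post_capfall"),
    ("inflorescence", "5d_post_capfall"),
    ("inflorescence", "7d_post_capfall"),
    ("berry", "veraison"),
    ("berry", "intermediate"),
    ("berry", "mature"),
)

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_GO_TERMS = (
    ("GO:0015979", "photosynthesis"),
    ("GO:0006412", "translation"),
    ("GO:0005634", "nucleus"),
    ("GO:0003824", "catalytic activity"),
    ("GO:0050896", "response to stimulus"),
    ("GO:0044237", "cellular metabolic process"),
)

N_CP_CDS = 8
N_MT_CDS = 6


@dataclass
class SimConfig:
    """Knobs of the synthetic study; the seed fixes every output byte."""

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 600_000
    n_coding: int = 100
    n_noncoding: int = 100
    n_conditions: int = 10
    n_replicates: int = 3
    n_specific: int = 8
    n_de_pairs: int = 8
    n_coexpr_pairs: int = 8
    n_tf_pairs: int = 3
    n_organelle_pairs: int = 4
    n_organelle_homology: int = 2
    n_mirnas: int = 6
    n_target_sites: int = 5
    n_precursor_embeddings: int = 3
    n_etm_sites: int = 3
    fpkm_noise_cv: float = 0.02
    specificity_target: float = 0.85

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if name in ("fpkm_noise_cv", "specificity_target"):
                continue
            if value < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_conditions < 2:
            raise ValueError("need at least 2 conditions")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.fpkm_noise_cv < 0:
            raise ValueError("fpkm_noise_cv must be >= 0")
        if not (1.0 / self.n_conditions < self.specificity_target <= 1.0):
            raise ValueError("specificity_target must be in (1/n_conditions, 1]")
        expr_roles = (
            self.n_specific + self.n_de_pairs + self.n_coexpr_pairs
            + self.n_tf_pairs + self.n_organelle_pairs
        )
        seq_roles = (
            self.n_target_sites + self.n_precursor_embeddings
            + self.n_etm_sites + self.n_organelle_homology
        )
        if expr_roles + seq_roles > self.n_noncoding:
            raise ValueError(
                "planted features exceed the number of non-coding transcripts"
            )
        # intronic/antisense/run-on lncRNAs each need their own host gene
        non_hosts = self.n_noncoding - seq_roles
        placed = non_hosts - (non_hosts + 3) // 4
        if placed > self.n_coding:
            raise ValueError(
                "not enough coding genes to host intronic/antisense/run-on lncRNAs"
            )
        if self.n_coexpr_pairs + self.n_tf_pairs > self.n_coding:
            raise ValueError("not enough coding transcripts for planted partners")
        if self.n_organelle_pairs > N_CP_CDS + N_MT_CDS:
            raise ValueError("not enough organelle CDS for planted pairs")
        n_profiles = self.n_coexpr_pairs + self.n_tf_pairs + self.n_organelle_pairs
        if n_profiles > 17:
            raise ValueError("at most 17 distinct co-expression profiles supported")
        if (self.n_target_sites or self.n_precursor_embeddings or self.n_etm_sites) \
                and self.n_mirnas == 0:
            raise ValueError("interaction plants require at least one miRNA")


@dataclass
class GroundTruthManifest:
    """Planted labels, cross-referencing every emitted file."""

    config: dict = field(default_factory=dict)
    condition_labels: list = field(default_factory=list)
    transcripts: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)

    def save(self, json_path: str | Path, tsv_path: str | Path | None = None) -> None:
        payload = {
            "config": self.config,
            "condition_labels": self.condition_labels,
            "transcripts": self.transcripts,
            "expected": self.expected,
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        if tsv_path is not None:
            rows = []
            for tid in sorted(self.transcripts):
                info = self.transcripts[tid]
                rows.append({"transcript_id": tid, **{
                    k: (";".join(map(str, v)) if isinstance(v, list) else v)
                    for k, v in info.items()
                }})
            pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)

    @classmethod
    def load(cls, json_path: str | Path) -> "GroundTruthManifest":
        with open(json_path) as fh:
            payload = json.load(fh)
        return cls(**payload)


# ---------------------------------------------------------------------------
# helpers


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _random_noncoding(rng: np.random.Generator, length: int, max_aa: int = 100) -> str:
    for _ in range(200):
        seq = _random_seq(rng, length)
        if max_orf_aa(seq) <= max_aa:
            return seq
    raise RuntimeError("failed to sample a non-coding sequence")


_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


def _coding_seq(rng: np.random.Generator, n_codons: int) -> tuple[str, int, int]:
    """UTR + ATG…stop ORF + UTR; returns (seq, orf_start, orf_end)."""
    utr5 = _random_seq(rng, int(rng.integers(80, 121)))
    body = "".join(
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), size=n_codons - 1)
    )
    orf = "ATG" + body + _STOPS[rng.integers(0, 3)]
    utr3 = _random_seq(rng, int(rng.integers(80, 121)))
    return utr5 + orf + utr3, len(utr5), len(utr5) + len(orf)


def _embed(seq: str, insert: str, pos: int) -> str:
    """Overwrite seq[pos:pos+len(insert)] with *insert* (length preserved)."""
    if pos < 0 or pos + len(insert) > len(seq):
        raise ValueError("planted site does not fit inside the host transcript")
    return seq[:pos] + insert + seq[pos + len(insert):]


def _plant_in_host(
    rng: np.random.Generator, length: int, insert: str, max_aa: int = 100
) -> tuple[str, int]:
    """Random host of *length* carrying *insert*, max six-frame ORF ≤ max_aa."""
    if len(insert) + 40 > length:
        raise ValueError("planted site does not fit inside the host transcript")
    for _ in range(200):
        pos = int(rng.integers(20, length - len(insert) - 20))
        seq = _embed(_random_seq(rng, length), insert, pos)
        if max_orf_aa(seq) <= max_aa:
            return seq, pos
    raise RuntimeError("failed to plant site without creating a long ORF")


def _coexpression_profiles(n_conditions: int) -> np.ndarray:
    """Deterministic profile shapes with pairwise |r| ≤ 1/√2.

    Discrete Fourier harmonics over the condition axis (mutually
    orthogonal) extended with sum/difference combinations.
    """
    c = np.arange(n_conditions)
    vectors = []
    max_m = (n_conditions - 1) // 2
    for m in range(1, max_m + 1):
        vectors.append(np.sin(2 * np.pi * m * c / n_conditions))
        vectors.append(np.cos(2 * np.pi * m * c / n_conditions))
    if n_conditions % 2 == 0:
        vectors.append((-1.0) ** c)
    base = [v / np.abs(v).max() for v in vectors]
    combos = []
    for i in range(0, len(base) - 1, 2):
        s = base[i] + base[i + 1]
        d = base[i] - base[i + 1]
        combos.append(s / np.abs(s).max())
        combos.append(d / np.abs(d).max())
    return np.array(base + combos)


def plant_specific_profile(
    base_matrix: pd.DataFrame,
    transcript: str,
    condition: str,
    index_target: float,
) -> pd.Series:
    """Rescale one consensus row to an exact specificity index.

    The row total is preserved: the focal condition receives
    ``index_target`` of it and the remainder is split evenly, so the
    specificity quotient of the returned row equals the target exactly.
    """
    row = base_matrix.loc[transcript]
    n = len(row)
    if not 1.0 / n < index_target <= 1.0:
        raise ValueError(
            f"index_target must be in (1/{n}, 1], got {index_target}"
        )
    if condition not in row.index:
        raise ValueError(f"unknown condition {condition!r}")
    total = float(row.sum())
    if total <= 0:
        raise ValueError("cannot plant a profile on an all-zero row")
    rest = (1.0 - index_target) * total / (n - 1)
    out = pd.Series(rest, index=row.index, name=row.name, dtype=float)
    out[condition] = index_target * total
    return out


# ---------------------------------------------------------------------------
# the generator


def simulate_study(config: SimConfig, outdir: str | Path) -> GroundTruthManifest:
    """Generate the full study bundle under *outdir* and return the manifest.

    All outputs are plain text; re-running with an identical config is
    byte-identical.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.n_conditions == 10:
        conditions = list(TISSUE_STAGES)
    else:
        conditions = [("tissue1", f"stage{i + 1}") for i in range(config.n_conditions)]
    cond_labels = [f"{t}:{s}" for t, s in conditions]
    n_cond = len(conditions)

    # --- miRNAs and hairpins -------------------------------------------------
    mirnas: list[SeqRecord] = []
    hairpins: list[SeqRecord] = []
    for k in range(config.n_mirnas):
        mature = _random_seq(rng, 21)
        arm = mature + _random_seq(rng, 9)
        hairpin = arm + _random_seq(rng, 8) + reverse_complement(arm)
        mirnas.append(SeqRecord(f"mir-{k + 1:03d}", mature))
        hairpins.append(SeqRecord(f"mir-{k + 1:03d}-hp", hairpin))

    # --- organelle CDS -------------------------------------------------------
    organelle: list[SeqRecord] = []
    for j in range(N_CP_CDS):
        organelle.append(SeqRecord(f"cp_CDS_{j + 1:02d}", _random_seq(rng, int(rng.integers(400, 901)))))
    for j in range(N_MT_CDS):
        organelle.append(SeqRecord(f"mt_CDS_{j + 1:02d}", _random_seq(rng, int(rng.integers(400, 901)))))
    organelle_by_id = {r.id: r for r in organelle}

    # --- coding transcripts --------------------------------------------------
    coding: list[SeqRecord] = []
    orf_codons: dict[str, int] = {}
    for i in range(config.n_coding):
        n_codons = int(rng.integers(150, 251))
        seq, _, _ = _coding_seq(rng, n_codons)
        rec = SeqRecord(f"MRNA_{i + 1:04d}", seq)
        coding.append(rec)
        orf_codons[rec.id] = n_codons

    # --- non-coding role assignment -----------------------------------------
    lnc_ids = [f"LNC_{i + 1:04d}" for i in range(config.n_noncoding)]
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = lnc_ids[cursor:cursor + n]
        cursor += n
        return out

    specific_ids = take(config.n_specific)
    de_ids = take(config.n_de_pairs)
    coexpr_lnc = take(config.n_coexpr_pairs)
    tf_lnc = take(config.n_tf_pairs)
    org_lnc = take(config.n_organelle_pairs)
    target_hosts = take(config.n_target_sites)
    precursor_hosts = take(config.n_precursor_embeddings)
    etm_hosts = take(config.n_etm_sites)
    homology_hosts = take(config.n_organelle_homology)
    seq_hosts = set(target_hosts + precursor_hosts + etm_hosts + homology_hosts)

    # class codes: sequence-planted hosts need a free intergenic locus ('u');
    # the rest cycle through intergenic / intronic / antisense / run-on.
    planted_code: dict[str, str] = {}
    cycle = ("u", "i", "x", "p")
    k = 0
    for tid in lnc_ids:
        if tid in seq_hosts:
            planted_code[tid] = "u"
        else:
            planted_code[tid] = cycle[k % 4]
            k += 1

    # --- non-coding sequences ------------------------------------------------
    lnc_seqs: dict[str, str] = {}
    interaction_sites: list[dict] = []
    homology_plants: list[dict] = []

    for idx, tid in enumerate(target_hosts):
        mir = mirnas[idx % config.n_mirnas]
        site = reverse_complement(mir.seq)
        seq, pos = _plant_in_host(rng, int(rng.integers(450, 701)), site)
        lnc_seqs[tid] = seq
        interaction_sites.append(
            {"mirna": mir.id, "transcript": tid, "start": pos,
             "end": pos + len(site), "kind": "target"}
        )
    for idx, tid in enumerate(precursor_hosts):
        mir = mirnas[idx % config.n_mirnas]
        hp = hairpins[idx % config.n_mirnas]
        seq, pos = _plant_in_host(rng, int(rng.integers(500, 701)), hp.seq)
        lnc_seqs[tid] = seq
        interaction_sites.append(
            {"mirna": mir.id, "transcript": tid, "start": pos,
             "end": pos + len(hp.seq), "kind": "precursor", "hairpin": hp.id}
        )
        # the 3' hairpin arm carries the reverse complement of the mature
        # miRNA, i.e. a perfect target site, at a known offset
        arm_len, loop_len = 30, 8
        t_start = pos + arm_len + loop_len + (arm_len - 21)
        interaction_sites.append(
            {"mirna": mir.id, "transcript": tid, "start": t_start,
             "end": t_start + 21, "kind": "target", "via": "precursor_arm"}
        )
    for idx, tid in enumerate(etm_hosts):
        mir = mirnas[idx % config.n_mirnas]
        site = (
            reverse_complement(mir.seq[10:])
            + _random_seq(rng, 3)
            + reverse_complement(mir.seq[:10])
        )
        seq, pos = _plant_in_host(rng, int(rng.integers(450, 701)), site)
        lnc_seqs[tid] = seq
        interaction_sites.append(
            {"mirna": mir.id, "transcript": tid, "start": pos,
             "end": pos + len(site), "kind": "eTM"}
        )
    for idx, tid in enumerate(homology_hosts):
        org = organelle[idx % len(organelle)]
        seg_len = 300
        off = int(rng.integers(0, len(org.seq) - seg_len + 1))
        segment = org.seq[off:off + seg_len]
        seq, pos = _plant_in_host(rng, int(rng.integers(550, 701)), segment)
        lnc_seqs[tid] = seq
        homology_plants.append(
            {"lncrna": tid, "organelle": org.id, "lnc_start": pos,
             "organelle_start": off, "length": seg_len}
        )
    for tid in lnc_ids:
        if tid not in lnc_seqs and planted_code[tid] == "u":
            lnc_seqs[tid] = _random_noncoding(rng, int(rng.integers(300, 701)))

    # --- genome layout -------------------------------------------------------
    gap_len = 2500
    derived_lncs = [t for t in lnc_ids if planted_code[t] in ("i", "x", "p")]
    lnc_strand: dict[str, str] = {}
    gene_host: dict[str, str] = {}  # gene id -> hosted derived lnc
    host_of: dict[str, str] = {}
    for j, tid in enumerate(derived_lncs):
        gene = coding[j % config.n_coding].id
        if gene in gene_host.values():
            raise ValueError("not enough genes to host placed lncRNAs")
        gene_host[gene] = tid
        host_of[tid] = gene
    # antisense lncRNAs stay short so the exonic part of their sequence
    # (reverse complement of a coding exon) cannot itself carry a >100 aa ORF
    derived_len = {
        t: int(rng.integers(300, 501 if planted_code[t] == "x" else 701))
        for t in derived_lncs
    }

    gene_strand = {}
    for rec in coding:
        hosted = gene_host.get(rec.id)
        if hosted is not None and planted_code[hosted] == "p":
            gene_strand[rec.id] = "+"  # keep the run-on fragment downstream
        else:
            gene_strand[rec.id] = "+" if rng.integers(0, 2) else "-"

    chrom_names = [f"chr{c + 1}" for c in range(config.n_chromosomes)]
    parts: dict[str, list[str]] = {c: [] for c in chrom_names}
    cursors: dict[str, int] = {c: 0 for c in chrom_names}
    gene_models: list[TranscriptModel] = []
    loci: dict[str, dict] = {}
    pending_p: dict[str, tuple[str, str]] = {}  # chrom -> (lnc, strand)

    def append(chrom: str, seq: str) -> int:
        start = cursors[chrom]
        parts[chrom].append(seq)
        cursors[chrom] += len(seq)
        return start

    def make_gap(chrom: str, gene_block: str | None, x_lnc: str | None) -> None:
        """Intergenic gap, hosting a pending run-on lnc and/or the random
        flank of an antisense lnc overlapping the next gene block."""
        p_entry = pending_p.pop(chrom, None)
        for _ in range(100):
            gap = _random_seq(rng, gap_len)
            ok = True
            p_seq = x_seq = None
            if p_entry is not None:
                tid = p_entry[0]
                length = derived_len[tid]
                raw = gap[300:300 + length]
                p_seq = raw if p_entry[1] == "+" else reverse_complement(raw)
                ok = ok and max_orf_aa(p_seq) <= 100
            if x_lnc is not None:
                length = derived_len[x_lnc]
                flank = gap[gap_len - 250:]
                raw = flank + gene_block[: length - 250]
                x_seq = raw if lnc_strand[x_lnc] == "+" else reverse_complement(raw)
                ok = ok and max_orf_aa(x_seq) <= 100
            if ok:
                break
        else:
            raise RuntimeError("failed to lay out an intergenic gap")
        start = append(chrom, gap)
        if p_entry is not None:
            tid = p_entry[0]
            lnc_seqs[tid] = p_seq
            loci[tid] = {"chrom": chrom, "strand": p_entry[1],
                         "start": start + 300, "end": start + 300 + derived_len[tid]}
        if x_lnc is not None:
            lnc_seqs[x_lnc] = x_seq
            loci[x_lnc] = {"chrom": chrom, "strand": lnc_strand[x_lnc],
                           "start": start + gap_len - 250,
                           "end": start + gap_len - 250 + derived_len[x_lnc]}

    for gi, rec in enumerate(coding):
        chrom = chrom_names[gi % config.n_chromosomes]
        strand = gene_strand[rec.id]
        hosted = gene_host.get(rec.id)
        code = planted_code[hosted] if hosted else None
        e1 = int(rng.integers(200, 301))
        exon1, exon2 = rec.seq[:e1], rec.seq[e1:]

        # intron, redrawn until an intronic lnc derived from it is non-coding
        ilen = int(rng.integers(1600, 2001))
        i_seq = None
        for _ in range(100):
            intron = _random_seq(rng, ilen)
            if code != "i":
                break
            length = derived_len[hosted]
            raw = intron[100:100 + length]
            cand = raw if strand == "+" else reverse_complement(raw)
            if max_orf_aa(cand) <= 100:
                i_seq = cand
                break
        else:
            raise RuntimeError("failed to lay out an intron")

        if strand == "+":
            block = exon1 + intron + exon2
            ex_iv = [(0, e1), (e1 + ilen, e1 + ilen + len(exon2))]
        else:
            block = (
                reverse_complement(exon2) + intron + reverse_complement(exon1)
            )
            ex_iv = [(0, len(exon2)), (len(exon2) + ilen, len(exon2) + ilen + e1)]

        if code == "x":
            lnc_strand[hosted] = "-" if strand == "+" else "+"
        make_gap(chrom, gene_block=block, x_lnc=hosted if code == "x" else None)
        gstart = append(chrom, block)
        exons = tuple((gstart + a, gstart + b) for a, b in ex_iv)
        gene_models.append(TranscriptModel(rec.id, chrom, strand, exons))
        loci[rec.id] = {"chrom": chrom, "strand": strand,
                        "start": exons[0][0], "end": exons[-1][1],
                        "exons": [list(e) for e in exons]}

        if code == "i":
            intron_start = gstart + ex_iv[0][1]
            lnc_seqs[hosted] = i_seq
            lnc_strand[hosted] = strand
            loci[hosted] = {"chrom": chrom, "strand": strand,
                            "start": intron_start + 100,
                            "end": intron_start + 100 + derived_len[hosted]}
        elif code == "p":
            lnc_strand[hosted] = strand
            pending_p[chrom] = (hosted, strand)

    # flush trailing run-on lncs, then intergenic ('u') lncRNAs
    u_lncs = [t for t in lnc_ids if planted_code[t] == "u"]
    for j, tid in enumerate(u_lncs):
        chrom = chrom_names[j % config.n_chromosomes]
        make_gap(chrom, gene_block=None, x_lnc=None)
        strand = "+" if rng.integers(0, 2) else "-"
        seq = lnc_seqs[tid]
        block = seq if strand == "+" else reverse_complement(seq)
        start = append(chrom, block)
        lnc_strand[tid] = strand
        loci[tid] = {"chrom": chrom, "strand": strand,
                     "start": start, "end": start + len(seq)}
    for chrom in chrom_names:
        make_gap(chrom, gene_block=None, x_lnc=None)  # clears pending run-ons

    genome: list[SeqRecord] = []
    for chrom in chrom_names:
        seq = "".join(parts[chrom])
        if len(seq) > config.chrom_length:
            raise ValueError(
                f"chrom_length {config.chrom_length} too small: {chrom} needs {len(seq)}"
            )
        seq += _random_seq(rng, config.chrom_length - len(seq))
        genome.append(SeqRecord(chrom, seq))

    noncoding = [SeqRecord(tid, lnc_seqs[tid]) for tid in lnc_ids]
    transcripts = coding + noncoding
    by_id = {r.id: r for r in transcripts}

    # --- expression ----------------------------------------------------------
    all_expr_ids = [r.id for r in transcripts] + [r.id for r in organelle]
    consensus = pd.DataFrame(
        rng.uniform(10.0, 28.0, size=(len(all_expr_ids), n_cond)),
        index=all_expr_ids, columns=cond_labels,
    )
    # flatten each base row: constant profile, structure enters only by plants
    consensus.iloc[:, :] = np.repeat(
        consensus.iloc[:, 0].to_numpy()[:, None], n_cond, axis=1
    )

    for j, tid in enumerate(specific_ids):
        focal = cond_labels[j % n_cond]
        consensus.loc[tid] = 250.0 / n_cond
        consensus.loc[tid] = plant_specific_profile(
            consensus, tid, focal, config.specificity_target
        )
    de_conditions: dict[str, str] = {}
    for j, tid in enumerate(de_ids):
        focal = cond_labels[(j + 3) % n_cond]
        consensus.loc[tid] = 12.0
        consensus.loc[tid, focal] = 96.0  # 8-fold spike
        de_conditions[tid] = focal

    profiles = _coexpression_profiles(n_cond)
    coexpr_pairs: list[tuple[str, str, str]] = []
    tf_partners = [coding[config.n_coexpr_pairs + j].id for j in range(config.n_tf_pairs)]
    mrna_partners = [coding[j].id for j in range(config.n_coexpr_pairs)]
    org_partners = [organelle[j].id for j in range(config.n_organelle_pairs)]
    pk = 0
    for lnc, partner in zip(coexpr_lnc, mrna_partners):
        shape = 60.0 * (1.0 + 0.45 * profiles[pk]); pk += 1
        consensus.loc[lnc] = shape
        consensus.loc[partner] = shape
        coexpr_pairs.append((lnc, partner, "mRNA"))
    for lnc, partner in zip(tf_lnc, tf_partners):
        shape = 60.0 * (1.0 + 0.45 * profiles[pk]); pk += 1
        consensus.loc[lnc] = shape
        consensus.loc[partner] = shape
        coexpr_pairs.append((lnc, partner, "TF"))
    for lnc, partner in zip(org_lnc, org_partners):
        shape = 60.0 * (1.0 + 0.45 * profiles[pk]); pk += 1
        consensus.loc[lnc] = shape
        consensus.loc[partner] = shape
        kind = "chloroplast_CDS" if partner.startswith("cp_") else "mitochondrial_CDS"
        coexpr_pairs.append((lnc, partner, kind))

    # replicate noise: multiplicative log-normal, mean-one
    cv = config.fpkm_noise_cv
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    sample_cols = []
    sample_rows = []
    values = {}
    for (tissue, stage), label in zip(conditions, cond_labels):
        for rep in range(1, config.n_replicates + 1):
            sample = f"{tissue}_{stage}_r{rep}"
            sample_cols.append(sample)
            sample_rows.append(
                {"sample": sample, "tissue": tissue, "stage": stage, "replicate": rep}
            )
            base = consensus[label].to_numpy()
            if sigma > 0:
                noise = np.exp(rng.normal(-sigma * sigma / 2.0, sigma, size=base.size))
            else:
                noise = np.ones_like(base)
            values[sample] = base * noise
    expr_values = pd.DataFrame(values, index=all_expr_ids)
    samples = pd.DataFrame(sample_rows).set_index("sample")

    # expected differential set, from the noiseless consensus fold rule
    cons_np = consensus.to_numpy()
    ratio = (cons_np.max(axis=1) + 1.0) / (cons_np.min(axis=1) + 1.0)
    if ((ratio > 3.0) & (ratio < 5.0)).any():
        raise AssertionError("planted fold changes too close to the threshold")
    expected_de = sorted(
        tid for tid, r in zip(all_expr_ids, ratio) if r >= 4.0
    )

    # --- stub external tables ------------------------------------------------
    scores = {}
    for rec in coding:
        scores[rec.id] = float(rng.uniform(0.5, 3.0))
    for rec in noncoding:
        scores[rec.id] = float(-rng.uniform(0.5, 3.0))

    protein_hits = []
    for i, rec in enumerate(coding):
        alen = orf_codons[rec.id]
        protein_hits.append(TabularHit(
            rec.id, f"PROT_{i + 1:04d}", float(rng.uniform(85, 100)), alen,
            int(rng.integers(0, 5)), 0, 1, alen * 3, 1, alen,
            1e-50, 2.0 * alen,
        ))

    genome_hits = []
    for rec in transcripts:
        info = loci[rec.id]
        exons = info.get("exons") or [[info["start"], info["end"]]]
        q_pos = 1
        spans = exons if info["strand"] == "+" else list(reversed(exons))
        for a, b in spans:
            length = b - a
            if info["strand"] == "+":
                s_start, s_end = a + 1, b
            else:
                s_start, s_end = b, a + 1
            genome_hits.append(TabularHit(
                rec.id, info["chrom"], 100.0, length, 0, 0,
                q_pos, q_pos + length - 1, s_start, s_end,
                1e-180, 2.0 * length,
            ))
            q_pos += length

    # --- annotation terms for planted partners -------------------------------
    term_table = TermTable()
    expected_terms: dict[str, list[str]] = {}
    for j, (lnc, partner, _kind) in enumerate(coexpr_pairs):
        acc, label = _GO_TERMS[j % len(_GO_TERMS)]
        term_table.add(partner, acc, label)
        expected_terms.setdefault(lnc, [])
        if acc not in expected_terms[lnc]:
            expected_terms[lnc].append(acc)

    # --- write the bundle ----------------------------------------------------
    write_fasta(genome, outdir / "genome.fasta")
    write_fasta(transcripts, outdir / "transcripts.fasta")
    write_fasta(mirnas, outdir / "mirna_mature.fasta")
    write_fasta(hairpins, outdir / "mirna_hairpins.fasta")
    write_fasta(organelle, outdir / "organelle_cds.fasta")
    write_gtf(gene_models, outdir / "reference.gtf")
    expr_values.to_csv(outdir / "expression.tsv", sep="\t", index_label="transcript_id")
    samples.to_csv(outdir / "samples.tsv", sep="\t", index_label="sample")
    write_score_table(scores, outdir / "coding_scores.tsv")
    write_blast_tab(protein_hits, outdir / "protein_hits.tsv")
    write_blast_tab(genome_hits, outdir / "genome_hits.tsv")
    write_term_table(term_table, outdir / "term_table.tsv")
    with open(outdir / "tf_ids.txt", "w") as fh:
        for tid in tf_partners:
            fh.write(tid + "\n")

    # --- manifest ------------------------------------------------------------
    roles: dict[str, list[str]] = {}
    for site in interaction_sites:
        roles.setdefault(site["transcript"], [])
        if site["kind"] not in roles[site["transcript"]]:
            roles[site["transcript"]].append(site["kind"])

    manifest = GroundTruthManifest()
    manifest.config = asdict(config)
    manifest.condition_labels = cond_labels
    for rec in transcripts:
        kind = "coding" if rec.id in orf_codons else "noncoding"
        info = loci[rec.id]
        manifest.transcripts[rec.id] = {
            "kind": kind,
            "length": len(rec.seq),
            "max_orf_aa": (orf_codons.get(rec.id) or max_orf_aa(rec.seq)),
            "chrom": info["chrom"],
            "strand": info["strand"],
            "start": info["start"],
            "end": info["end"],
            "class_code": planted_code.get(rec.id, ""),
        }
    chrom_counts: dict[str, int] = {c: 0 for c in chrom_names}
    for tid in lnc_ids:
        chrom_counts[loci[tid]["chrom"]] += 1
    code_counts: dict[str, int] = {}
    for tid in lnc_ids:
        code_counts[planted_code[tid]] = code_counts.get(planted_code[tid], 0) + 1
    manifest.expected = {
        "noncoding_ids": lnc_ids,
        "coding_ids": [r.id for r in coding],
        "specific_ids": specific_ids,
        "specific_conditions": {
            tid: cond_labels[j % n_cond] for j, tid in enumerate(specific_ids)
        },
        "specificity_target": config.specificity_target,
        "expected_de_ids": expected_de,
        "de_focal_conditions": de_conditions,
        "coexpr_pairs": [list(p) for p in coexpr_pairs],
        "tf_ids": tf_partners,
        "inherited_terms": expected_terms,
        "interaction_sites": interaction_sites,
        "interaction_roles": {k: sorted(v) for k, v in roles.items()},
        "organelle_homology": homology_plants,
        "class_code_counts": code_counts,
        "chromosome_counts": chrom_counts,
        "chrom_lengths": {c: config.chrom_length for c in chrom_names},
    }
    manifest.save(outdir / "manifest.json", outdir / "manifest.tsv")
    return manifest
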