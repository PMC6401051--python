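import numpy as np
import pandas as pd
import pytest

from helpers_oracles import hypergeom_upper_tail, pearson_formula, sw_score_oracle
from lnckit import coexpress as cx
from lnckit.io_formats import SeqRecord, TabularHit, TermTable


def frame(rows: dict, n_cond=10):
    return pd.DataFrame(
        rows, index=[f"c{i}" for i in range(n_cond)]
    ).T


class TestMeanFilter:
    def test_boundary_is_kept(self):
        cons = frame({"a": [30.0] * 10, "b": [29.9] * 10})
        assert cx.mean_filter(cons) == ["a"]

    def test_matches_naive_recount(self, bundle_consensus):
        got = set(cx.mean_filter(bundle_consensus))
        naive = {
            str(i) for i in bundle_consensus.index
            if sum(bundle_consensus.loc[i]) / bundle_consensus.shape[1] >= 30.0
        }
        assert got == naive


class TestPearsonEdges:
    def test_identical_profiles(self):
        x = list(np.linspace(30, 90, 10))
        cons = frame({"l1": x, "m1": x})
        (edge,) = cx.pearson_edges(["l1"], ["m1"], cons)
        assert edge.r == pytest.approx(1.0)

    def test_anticorrelated_kept_with_negative_sign(self):
        x = np.linspace(30, 90, 10)
        cons = frame({"l1": list(x), "m1": list(120 - x)})
        (edge,) = cx.pearson_edges(["l1"], ["m1"], cons)
        assert edge.r == pytest.approx(-1.0)
        assert edge.sign == -1
        assert edge.r2 == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        cons = frame(
            {f"a{i}": list(rng.uniform(0, 100, 10)) for i in range(5)}
            | {f"b{i}": list(rng.uniform(0, 100, 10)) for i in range(5)}
        )
        edges = cx.pearson_edges(
            [f"a{i}" for i in range(5)], [f"b{i}" for i in range(5)],
            cons, r2_threshold=0.0,
        )
        for e in edges:
            want = pearson_formula(
                list(cons.loc[e.lncrna_id]), list(cons.loc[e.partner_id])
            )
            assert e.r == pytest.approx(want, abs=1e-12)

    def test_zero_variance_yields_no_edges(self):
        cons = frame({"l1": [50.0] * 10, "m1": [50.0] * 10})
        assert cx.pearson_edges(["l1"], ["m1"], cons) == []

    def test_requires_three_conditions(self):
        cons = frame({"l1": [1.0, 2.0], "m1": [1.0, 2.0]}, n_cond=2)
        with pytest.raises(ValueError):
            cx.pearson_edges(["l1"], ["m1"], cons)

    def test_symmetry_and_dedup(self):
        x = list(np.linspace(10, 40, 10))
        cons = frame({"a": x, "b": x})
        fwd = cx.pearson_edges(["a"], ["b"], cons)
        rev = cx.pearson_edges(["b"], ["a"], cons)
        assert fwd[0].r == pytest.approx(rev[0].r)
        both = cx.pearson_edges(["a", "b"], ["a", "b"], cons)
        assert len(both) == 1  # self pairs skipped, unordered pair deduped


class TestBootstrap:
    def test_identical_profiles_full_support(self):
        x = np.linspace(30, 90, 10)
        assert cx.bootstrap_support(x, x, seed=1) == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0, 50, 10), rng.uniform(0, 50, 10)
        s1 = cx.bootstrap_support(a, b, r2_threshold=0.1, seed=42)
        s2 = cx.bootstrap_support(a, b, r2_threshold=0.1, seed=42)
        assert s1 == s2

    def test_noiseless_pair_beats_noisy_pair(self):
        x = np.linspace(30, 90, 10)
        clean = noisy = 0.0
        for seed in range(10):
            rng = np.random.default_rng(seed + 100)
            y = x * rng.normal(1.0, 0.25, size=10)
            clean += cx.bootstrap_support(x, x, seed=seed)
            noisy += cx.bootstrap_support(x, y, seed=seed)
        assert clean >= noisy


class TestTransfer:
    def _table(self):
        t = TermTable()
        t.add("m1", "GO:0015979", "photosynthesis")
        t.add("m2", "GO:0006412", "translation")
        return t

    def test_single_partner_term(self):
        edges = [cx.CoexpressionEdge("l1", "m1", "mRNA", 0.99)]
        got = cx.transfer_annotations(edges, self._table())
        assert got == {"l1": {"GO:0015979": ["m1"]}}

    def test_no_edges_no_terms(self):
        assert cx.transfer_annotations([], self._table()) == {}

    def test_union_with_witnesses(self):
        edges = [
            cx.CoexpressionEdge("l1", "m1", "mRNA", 0.99),
            cx.CoexpressionEdge("l1", "m2", "mRNA", 0.98),
        ]
        got = cx.transfer_annotations(edges, self._table())
        assert set(got["l1"]) == {"GO:0015979", "GO:0006412"}


class TestEnrichment:
    def test_term_in_everything_p_is_one(self):
        t = TermTable()
        for i in range(10):
            t.add(f"x{i}", "GO:1")
        df = cx.enrichment([f"x{i}" for i in range(3)], t, [f"x{i}" for i in range(10)])
        assert df.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_matches_exhaustive_tail_sum(self):
        rng = np.random.default_rng(6)
        for trial in range(20):
            m = int(rng.integers(10, 51))
            background = [f"x{i}" for i in range(m)]
            t = TermTable()
            for tid in background:
                if rng.random() < 0.4:
                    t.add(tid, "GO:7")
            n_sel = int(rng.integers(1, m + 1))
            selected = list(rng.choice(background, size=n_sel, replace=False))
            df = cx.enrichment(selected, t, background)
            if not len(df):
                continue
            row = df.iloc[0]
            want = hypergeom_upper_tail(
                int(row["hits_selected"]), m, int(row["hits_background"]), n_sel
            )
            assert row["p_value"] == pytest.approx(want, abs=1e-12)

    def test_empty_selected(self):
        t = TermTable()
        t.add("x0", "GO:1")
        df = cx.enrichment([], t, ["x0"])
        assert df.iloc[0]["hits_selected"] == 0

    def test_selected_outside_background_is_error(self):
        with pytest.raises(ValueError):
            cx.enrichment(["y"], TermTable(), ["x"])


class TestLocalAlign:
    def test_exact_substring(self):
        aln = cx.local_align("ACGTACGTAC", "TTTACGTACGTACTTT")
        assert aln.score == pytest.approx(10.0)
        assert aln.identity == pytest.approx(1.0)

    def test_score_matches_full_dp_oracle_small(self):
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        for _ in range(40):
            a = "".join(bases[rng.integers(0, 4, size=rng.integers(5, 51))])
            b = "".join(bases[rng.integers(0, 4, size=rng.integers(5, 51))])
            aln = cx.local_align(a, b)
            want = sw_score_oracle(a, b)
            got = aln.score if aln else 0.0
            assert got == pytest.approx(want)

    def test_seeded_path_finds_planted_segment(self):
        rng = np.random.default_rng(13)
        bases = np.array(list("ACGT"))
        segment = "".join(bases[rng.integers(0, 4, size=300)])
        host = (
            "".join(bases[rng.integers(0, 4, size=400)]) + segment
            + "".join(bases[rng.integers(0, 4, size=400)])
        )
        target = "".join(bases[rng.integers(0, 4, size=200)]) + segment
        aln = cx.local_align(host, target)
        assert aln is not None
        assert aln.align_length >= 300
        assert aln.identity > 0.95


class TestOrganelleHomology:
    def test_ingested_boundary_is_strict(self):
        hit = TabularHit("l1", "cp1", 99.0, 200, 1, 0, 1, 200, 1, 200, 1e-80, 350.0)
        assert len(cx.organelle_homology([], [], ingested_hits=[hit])) == 0
        hit201 = TabularHit("l1", "cp1", 99.0, 201, 1, 0, 1, 201, 1, 201, 1e-80, 350.0)
        assert len(cx.organelle_homology([], [], ingested_hits=[hit201])) == 1

    def test_planted_segment_found(self, bundle, bundle_candidates):
        outdir, manifest = bundle
        from lnckit import io_formats as io

        candidates, _ = bundle_candidates
        organelle = io.read_fasta(outdir / "organelle_cds.fasta")
        hits = cx.organelle_homology(candidates, organelle)
        got = {(r.lncrna_id, r.organelle_id) for r in hits.itertuples()}
        want = {(p["lncrna"], p["organelle"])
                for p in manifest.expected["organelle_homology"]}
        assert got == want


class TestBundleEdges:
    def test_noiseless_recovery_is_exact(self, noiseless_bundle):
        outdir, manifest = noiseless_bundle
        from lnckit import expression as ex
        from lnckit import io_formats as io

        mat = ex.ExpressionMatrix.from_tsv(
            outdir / "expression.tsv", outdir / "samples.tsv"
        )
        cons = ex.consensus_expression(mat)
        retained = set(cx.mean_filter(cons))
        lnc_ids = set(manifest.expected["noncoding_ids"])
        tf_ids = set(io.read_id_list(outdir / "tf_ids.txt"))
        organelle = {r.id for r in io.read_fasta(outdir / "organelle_cds.fasta")}
        coding = set(manifest.expected["coding_ids"])
        edges = cx.pearson_edges(
            sorted(lnc_ids & retained), sorted((coding - tf_ids) & retained), cons
        )
        edges += cx.pearson_edges(
            sorted(lnc_ids & retained), sorted(tf_ids & retained), cons,
            partner_kind="TF",
        )
        for prefix, kind in (("cp_", "chloroplast_CDS"), ("mt_", "mitochondrial_CDS")):
            edges += cx.pearson_edges(
                sorted(lnc_ids & retained),
                sorted(i for i in organelle & retained if i.startswith(prefix)),
                cons, partner_kind=kind,
            )
        got = {(e.lncrna_id, e.partner_id, e.partner_kind) for e in edges}
        want = {tuple(p) for p in manifest.expected["coexpr_pairs"]}
        assert got == want
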