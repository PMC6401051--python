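import numpy as np
import pytest

from helpers_oracles import (
    duplex_penalty_oracle,
    nussinov_enumerate,
    revcomp,
    target_windows_oracle,
)
from lnckit import mirna_interact as mi
from lnckit.io_formats import SeqRecord

MIRNA = "TGACAGAAGAGAGTGAGCACA"  # 21 nt


def rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self):
        score, states = mi.score_duplex(MIRNA, revcomp(MIRNA))
        assert score == 0.0
        assert states == "M" * 21

    def test_single_mismatch_outside_seed(self):
        window = list(revcomp(MIRNA))
        # miRNA position 15 pairs window index L-15 = 6
        window[21 - 15] = MIRNA[14]  # same base cannot pair its own kind
        score, states = mi.score_duplex(MIRNA, "".join(window))
        assert score == 1.0
        assert states[14] == "X"

    def test_wobble_in_seed_doubles(self):
        mirna = "G" + MIRNA[1:]
        window = list(revcomp(mirna))
        # give miRNA position 5 a G, pair it with T -> G:U wobble
        mirna = mirna[:4] + "G" + mirna[5:]
        window = list(revcomp(mirna))
        window[21 - 5] = "T"
        score, states = mi.score_duplex(mirna, "".join(window))
        assert score == pytest.approx(1.0)  # 0.5 doubled at position 5
        assert states[4] == "W"

    def test_seed_boundaries(self):
        for pos, expected in ((1, 1.0), (2, 2.0), (13, 2.0), (14, 1.0)):
            mirna = "A" * 21
            window = list("T" * 21)
            window[21 - pos] = "C"  # A:C mismatch at miRNA position pos
            score, _ = mi.score_duplex(mirna, "".join(window))
            assert score == pytest.approx(expected), pos

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            mi.score_duplex(MIRNA, "ACGT")

    def test_matches_oracle_on_random_windows(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            m = rand_seq(rng, 21)
            w = rand_seq(rng, 21)
            score, _ = mi.score_duplex(m, w)
            assert score == pytest.approx(duplex_penalty_oracle(m, w))

    def test_role_swap_symmetry(self):
        """Reading the duplex from the other strand reverses the states."""
        rng = np.random.default_rng(22)
        for _ in range(50):
            m = rand_seq(rng, 21)
            w = rand_seq(rng, 21)
            _, states_fwd = mi.score_duplex(m, w)
            _, states_swp = mi.score_duplex(w, m)
            assert states_swp == states_fwd[::-1]


class TestFindTargetSites:
    def test_planted_perfect_site(self):
        rng = np.random.default_rng(1)
        host = rand_seq(rng, 200) + revcomp(MIRNA) + rand_seq(rng, 200)
        mir = SeqRecord("mir", MIRNA)
        sites = mi.find_target_sites(mir, SeqRecord("t", host))
        assert any(s.start == 200 and s.penalty_score == 0.0 for s in sites)

    def test_heavily_mismatched_site_not_reported(self):
        site = list(revcomp(MIRNA))
        for pos in (3, 5, 7, 9):  # four seed mismatches, 2.0 each
            site[21 - pos] = MIRNA[pos - 1]
        rng = np.random.default_rng(2)
        host = rand_seq(rng, 100) + "".join(site) + rand_seq(rng, 100)
        sites = mi.find_target_sites(SeqRecord("m", MIRNA), SeqRecord("t", host))
        assert not any(90 < s.start < 130 for s in sites)

    def test_equals_window_oracle_stringent(self):
        rng = np.random.default_rng(3)
        mir = rand_seq(rng, 21)
        host = rand_seq(rng, 500) + revcomp(mir) + rand_seq(rng, 480)
        got = mi.find_target_sites(SeqRecord("m", mir), SeqRecord("t", host), 0.0)
        want = target_windows_oracle(mir, host, 0.0)
        assert [(s.start, s.penalty_score) for s in got] == want

    def test_equals_window_oracle_loose(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            mir = rand_seq(rng, 21)
            host = rand_seq(rng, 800)
            got = mi.find_target_sites(
                SeqRecord("m", mir), SeqRecord("t", host), 22.0
            )
            want = target_windows_oracle(mir, host, 22.0)
            assert [(s.start, s.penalty_score) for s in got] == want


def planted_etm(mirna: str, bulge: str = "CCC") -> str:
    return revcomp(mirna[10:]) + bulge + revcomp(mirna[:10])


class TestFindEtmSites:
    def test_planted_mimic_accepted(self):
        rng = np.random.default_rng(5)
        host = rand_seq(rng, 150) + planted_etm(MIRNA) + rand_seq(rng, 150)
        sites = mi.find_etm_sites(SeqRecord("m", MIRNA), SeqRecord("t", host))
        assert any(s.start == 150 for s in sites)
        (site,) = [s for s in sites if s.start == 150]
        assert site.pairing_ratio == pytest.approx(1.0)
        assert site.kind == "eTM"
        assert site.bulge == (10, 3)

    def test_bulgeless_perfect_complement_is_target_not_etm(self):
        rng = np.random.default_rng(6)
        host = rand_seq(rng, 150) + revcomp(MIRNA) + rand_seq(rng, 150)
        mir = SeqRecord("m", MIRNA)
        rec = SeqRecord("t", host)
        targets = mi.find_target_sites(mir, rec)
        etms = mi.find_etm_sites(mir, rec)
        _, _, kept = mi.classify_interactions(targets, etms, [])
        assert any(t.start == 150 for t in targets)
        assert not any(145 <= e.start <= 155 for e in kept)

    def test_low_ratio_mimic_rejected(self):
        # corrupt the 3' half of the 5' flank: ratio drops well below 0.7
        site = planted_etm(MIRNA)
        corrupted = list(site)
        for i in range(7):
            corrupted[i] = MIRNA[20 - i]  # break pairing at miRNA 3' positions
        rng = np.random.default_rng(7)
        host = rand_seq(rng, 100) + "".join(corrupted) + rand_seq(rng, 100)
        sites = mi.find_etm_sites(SeqRecord("m", MIRNA), SeqRecord("t", host))
        assert not any(95 <= s.start <= 105 for s in sites)

    def test_transcript_too_short(self):
        assert mi.find_etm_sites(SeqRecord("m", MIRNA), SeqRecord("t", "ACGT")) == []

    def test_bad_bulge_length(self):
        with pytest.raises(ValueError):
            mi.find_etm_sites(SeqRecord("m", MIRNA), SeqRecord("t", "A" * 100),
                              bulge_len=7)


class TestNussinov:
    def test_hairpin_example(self):
        assert mi.nussinov_max_pairs("GGGAAACCC") == 3
        assert mi.foldback_paired_fraction("GGGAAACCC") == pytest.approx(6 / 9)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        seqs = ["GGGAAACCC", "ACGTACGTACGT"] + [
            rand_seq(rng, int(rng.integers(6, 14))) for _ in range(25)
        ]
        for seq in seqs:
            assert mi.nussinov_max_pairs(seq) == nussinov_enumerate(seq), seq

    def test_min_loop_respected(self):
        # complementary ends but loop shorter than 3 cannot pair
        assert mi.nussinov_max_pairs("GAAC") == 0
        assert mi.nussinov_max_pairs("GAAAC") == 1


class TestFindPrecursors:
    def test_verbatim_embedding_found(self, bundle, bundle_candidates):
        outdir, manifest = bundle
        from lnckit import io_formats as io

        candidates, _ = bundle_candidates
        hairpins = io.read_fasta(outdir / "mirna_hairpins.fasta")
        matches = mi.find_precursors(candidates, hairpins)
        got = {(m.hairpin_id, m.lncrna_id) for m in matches}
        want = {
            (s["hairpin"], s["transcript"])
            for s in manifest.expected["interaction_sites"]
            if s["kind"] == "precursor"
        }
        assert got == want
        for m in matches:
            assert m.identity >= 0.95
            assert m.coverage >= 0.95
            assert 0.0 <= m.foldback_paired_fraction <= 1.0
            # a true foldback pairs most of its bases
            assert m.foldback_paired_fraction > 0.5

    def test_unrelated_hairpin_misses(self):
        rng = np.random.default_rng(10)
        lnc = SeqRecord("l", rand_seq(rng, 400))
        hp = SeqRecord("h", rand_seq(rng, 70))
        assert mi.find_precursors([lnc], [hp]) == []

    def test_empty_hairpin_set_is_error(self):
        with pytest.raises(ValueError):
            mi.find_precursors([], [])


class TestClassifyAndNetwork:
    def _duplex(self, mir, lnc, start=0, kind="target"):
        return mi.DuplexAlignment(mir, lnc, start, start + 21, "M" * 21, kind,
                                  penalty_score=0.0, pairing_ratio=1.0)

    def test_role_sets(self):
        targets = [self._duplex("m1", "l1")]
        prec = [mi.HairpinMatch("h1", "l1", 0, 68, 1.0, 1.0, 0.8)]
        roles, overlaps, _ = mi.classify_interactions(targets, [], prec)
        assert roles == {"l1": {"target", "precursor"}}
        assert overlaps[("target", "precursor")] == 1

    def test_no_interactions_absent(self):
        roles, _, _ = mi.classify_interactions([], [], [])
        assert roles == {}

    def test_bundle_roles_match_manifest(self, bundle, bundle_candidates):
        outdir, manifest = bundle
        from lnckit import io_formats as io

        candidates, _ = bundle_candidates
        mirnas = io.read_fasta(outdir / "mirna_mature.fasta")
        hairpins = io.read_fasta(outdir / "mirna_hairpins.fasta")
        targets, etms = [], []
        for mir in mirnas:
            for rec in candidates:
                targets.extend(mi.find_target_sites(mir, rec))
                etms.extend(mi.find_etm_sites(mir, rec))
        precursors = mi.find_precursors(candidates, hairpins)
        roles, _, _ = mi.classify_interactions(targets, etms, precursors)
        assert {k: sorted(v) for k, v in roles.items()} == (
            manifest.expected["interaction_roles"]
        )

    def test_star_network(self):
        targets = [self._duplex("m1", "l1"), self._duplex("m1", "l2")]
        g = mi.build_network(targets=targets)
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2
        assert g.nodes["m1"]["kind"] == "miRNA"

    def test_empty_network(self):
        g = mi.build_network()
        assert g.number_of_nodes() == 0

    def test_dangling_endpoint_error(self):
        with pytest.raises(ValueError, match="dangling"):
            mi.build_network(targets=[self._duplex("m1", "l1")], known_ids=["m1"])

    def test_network_round_trip_files(self, tmp_path):
        targets = [self._duplex("m1", "l1")]
        g = mi.build_network(targets=targets)
        mi.write_network(g, str(tmp_path / "e.tsv"), str(tmp_path / "g.graphml"))
        import networkx as nx

        back = nx.read_graphml(tmp_path / "g.graphml")
        assert back.number_of_nodes() == 2
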