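from __future__ import annotations

import pytest

from lnckit import expression as ex
from lnckit import identify as idn
from lnckit import io_formats as io
from lnckit.synthetic_data import SimConfig, simulate_study


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """The default synthetic study (seed 1) plus its manifest."""
    outdir = tmp_path_factory.mktemp("bundle")
    manifest = simulate_study(SimConfig(seed=1), outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def bundle_records(bundle):
    outdir, _ = bundle
    return io.read_fasta(outdir / "transcripts.fasta")


@pytest.fixture(scope="session")
def bundle_candidates(bundle, bundle_records):
    outdir, _ = bundle
    candidates, report = idn.run_identification(
        bundle_records,
        scores=io.read_score_table(outdir / "coding_scores.tsv"),
        protein_hits=io.read_blast_tab(outdir / "protein_hits.tsv"),
    )
    return candidates, report


@pytest.fixture(scope="session")
def bundle_matrix(bundle):
    outdir, _ = bundle
    return ex.ExpressionMatrix.from_tsv(
        outdir / "expression.tsv", outdir / "samples.tsv"
    )


@pytest.fixture(scope="session")
def bundle_consensus(bundle_matrix):
    return ex.consensus_expression(bundle_matrix)


@pytest.fixture(scope="session")
def noiseless_bundle(tmp_path_factory):
    """Same study with replicate noise switched off."""
    outdir = tmp_path_factory.mktemp("noiseless")
    manifest = simulate_study(SimConfig(seed=2, fpkm_noise_cv=0.0), outdir)
    return outdir, manifest
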