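import pytest

from paleowgd import PipelineConfig, run_pipeline
from paleowgd.synthetic_data import SimConfig, simulate_history

SMALL = dict(seed=7, ancestral_genes=350, ancestral_chromosomes=7, codons_per_gene=200)


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced three-genome bundle (350 ancestral genes, 200 codons) used
    by most integration tests; the full-size bundle lives in the
    acceptance suite."""
    return simulate_history(SimConfig(**SMALL))


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    """Full pipeline run on the small bundle: (bundle, summary, outdir)."""
    outdir = tmp_path_factory.mktemp("small_run")
    summary = run_pipeline(PipelineConfig(outdir=outdir, seed=SMALL["seed"]),
                           bundle=small_bundle)
    return small_bundle, summary, outdir
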