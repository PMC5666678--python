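import pytest

from stimseq import simulate


@pytest.fixture(scope="session")
def default_cohort():
    """Reference synthetic cohort: 50 genes, 20 planted eRNA pairs, 5 decoys/class."""
    return simulate.generate_cohort(simulate.CohortConfig(seed=42))


@pytest.fixture(scope="session")
def small_pipeline_config():
    """A compact pipeline config for end-to-end runs in tests."""
    from stimseq.pipeline import PipelineConfig

    cfg = PipelineConfig.from_dict(
        {
            "seed": 11,
            "cohort": {
                "seed": 11,
                "n_genes": 30,
                "n_planted_ernas": 8,
                "n_decoys_per_class": 2,
                "chrom_length": 800_000,
            },
        }
    )
    return cfg
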