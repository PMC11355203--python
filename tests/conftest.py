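import pytest

from coiscan.synthetic_data import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_bundle():
    """A modest default-structure cohort shared across read-only tests."""
    cfg = SyntheticConfig(n_genes=120, variants_per_gene_mean=25,
                          n_releases=12, n_enriched_genes=4, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_timelines(small_bundle):
    from coiscan.timeline import build_timelines

    return build_timelines(small_bundle.snapshots)
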