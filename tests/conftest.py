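import pytest

import methperm as mp


@pytest.fixture(scope="session")
def small_config():
    """A compact study: 40 genes on 200 kb, 10 planted DMRs, 3 vs 3."""
    return mp.SimulationConfig(
        seed=11,
        chrom_length=200_000,
        n_genes=40,
        n_true_dmrs=10,
        frac_methylated_genes=0.4,
    )


@pytest.fixture(scope="session")
def annotation(small_config):
    return mp.generate_annotation(small_config)


@pytest.fixture(scope="session")
def truth(annotation, small_config):
    return mp.generate_truth(annotation, small_config)


@pytest.fixture(scope="session")
def counts(annotation, truth, small_config):
    return mp.generate_methylomes(annotation, truth, small_config)


@pytest.fixture(scope="session")
def groups(small_config):
    return small_config.group_labels()


@pytest.fixture(scope="session")
def big_annotation():
    """A 5,000-gene universe for asymptotic set-enrichment checks."""
    cfg = mp.SimulationConfig(seed=1, n_genes=5_000,
                              chrom_length=10_000_000, cpg_density=0.0005)
    return mp.generate_annotation(cfg)
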