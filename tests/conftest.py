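import pytest

from hapsomatic.config import RunConfig
from hapsomatic.simulate import PlantedCluster, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def run_cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def clean_case():
    """Error-free cohort: no tag dropout, no tag/allele errors, a planted
    10-mutation HP1 cluster, methylation and SVs switched off."""
    cfg = SimConfig(
        seed=11,
        planted_cluster=PlantedCluster(window_index=5, n_mutations=10,
                                       haplotype="HP1"),
        tag_dropout_rate=0.0,
        tag_error_rate=0.0,
        allele_error_rate=0.0,
        methylation_depth=0.0,
        n_svs=0,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def full_case():
    """Default-condition cohort including SVs and methylation, scaled to
    one 2-Mb chromosome so the full pipeline runs in seconds."""
    cfg = SimConfig(
        seed=7,
        n_chromosomes=1,
        chrom_length_bp=2_000_000,
        planted_cluster=PlantedCluster(window_index=3, n_mutations=10),
        mutation_rate_per_mb=10.0,
        n_svs=4,
        cpg_spacing_bp=2_000,
    )
    return simulate_cohort(cfg)
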