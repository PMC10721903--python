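import pytest

from icevir.core_io import Config
from icevir.synthetic_data import GeneratorParams, generate_community

SMALL = dict(
    seed=11, n_hosts=6, host_length=40_000, n_viruses=60,
    n_crispr_pairs=6, n_trna_pairs=6, n_amg_pairs=6, n_binning_only=4,
    n_multi_genera=2, genus_size=4, mean_reads_per_virus=60,
)


@pytest.fixture(scope="session")
def small_params():
    return GeneratorParams(**SMALL)


@pytest.fixture(scope="session")
def small_community(small_params):
    return generate_community(small_params)


@pytest.fixture(scope="session")
def small_run(small_params):
    from icevir import pipeline as pl
    return pl.run_all(small_params, Config(seed=SMALL["seed"]))


@pytest.fixture(scope="session")
def default_run():
    """Full default synthetic community: 20 hosts, 200 viruses, 60 pairs."""
    from icevir import pipeline as pl
    params = GeneratorParams(seed=7)
    return pl.run_all(params, Config(seed=7)), params
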