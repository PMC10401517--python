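import pytest

from cliffscape.dataset_io import curate, parse_activity_table
from cliffscape.synthetic_data import SyntheticConfig, generate_series, micro_fixtures, write_rows_csv


@pytest.fixture(scope="session")
def fixtures():
    return micro_fixtures()


@pytest.fixture(scope="session")
def small_config():
    # 2 families, monosubstituted only: 16 records, fast everywhere
    return SyntheticConfig(n_scaffold_families=2, include_disubstituted=False, seed=11)


@pytest.fixture(scope="session")
def small_series(small_config):
    return generate_series(small_config)


@pytest.fixture(scope="session")
def small_curated(small_series, tmp_path_factory):
    rows, truth = small_series
    path = tmp_path_factory.mktemp("synth") / "series.csv"
    write_rows_csv(rows, path)
    records, report = curate(parse_activity_table(path))
    return records, report, truth


@pytest.fixture(scope="session")
def medium_series():
    cfg = SyntheticConfig(n_scaffold_families=4, seed=5)
    return cfg, generate_series(cfg)
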