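import numpy as np
import pandas as pd
import pytest

import pherskit as pk
from pherskit.pipeline import assemble_cohort, train_phers_on_cohort
from pherskit.simulate import (
    disease_definitions,
    generate_cohort_tables,
    scenario_config,
    synthetic_phecode_map,
)


@pytest.fixture(scope="session")
def example_map():
    return pk.example_phecode_map()


@pytest.fixture(scope="session")
def toy_map(tmp_path_factory):
    """A 5-row map with one duplicate-conflict row and one empty phecode."""
    path = tmp_path_factory.mktemp("maps") / "toy.csv"
    path.write_text(
        "icd,phecode,exclude_range\n"
        "E11,250.2,249-250.99\n"
        "C61,185,185-187.99\n"
        "M17,740.1,\n"
        "E11,999,\n"          # conflicting duplicate: first kept
        "Q99,,\n"             # empty phecode: skipped
    )
    return pk.load_phecode_map(path)


@pytest.fixture(scope="session")
def small_cfg():
    return scenario_config("small", seed=7)


@pytest.fixture(scope="session")
def small_tables(small_cfg):
    return generate_cohort_tables(small_cfg, 0)


@pytest.fixture(scope="session")
def small_cohort(small_cfg, small_tables):
    pmap = synthetic_phecode_map(small_cfg)
    dz = disease_definitions(small_cfg)[0]
    return assemble_cohort(small_tables, small_cfg, dz, pmap)


@pytest.fixture(scope="session")
def trained_small(small_cfg, small_cohort):
    pmap = synthetic_phecode_map(small_cfg)
    dz = disease_definitions(small_cfg)[0]
    return train_phers_on_cohort(small_cohort, dz, pmap, seed=7, grid=pk.small_grid())
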