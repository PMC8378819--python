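import pandas as pd
import pytest

from coralbreed import pipeline


@pytest.fixture(scope="session")
def small_cfg() -> pipeline.RunConfig:
    """Desk-scale experiment: fast to simulate, all stages exercised."""
    return pipeline.RunConfig(
        seed=11,
        n_loci=300,
        n_causal=10,
        heritability={"iterations": 4000, "burn_in": 1000, "thin": 5,
                      "nu": 0.002, "V": 1.0},
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return pipeline.simulate_experiment(small_cfg)


@pytest.fixture(scope="session")
def field_table() -> pd.DataFrame:
    from coralbreed import simdata
    return simdata.make_field_table()
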