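import numpy as np
import pandas as pd
import pytest

from lncland.simulate import DatasetSpec, SimulationConfig, simulate_study


def small_config(seed: int = 11, **overrides) -> SimulationConfig:
    """Desk-scale-but-small study: 3 datasets, 2 planted genes per category."""
    defaults = dict(
        seed=seed,
        n_coding=200,
        n_lncrna=100,
        planted_per_category=2,
        # strong effects: the small fixture exercises plumbing, not power
        effect_low=2.5,
        effect_high=4.0,
        module_size=6,
        n_background_terms=10,
        term_size_min=8,
        term_size_max=15,
        datasets=(
            DatasetSpec(
                "rnaseqA", "rnaseq",
                (("NT", 8), ("FA", 5), ("FTC", 5), ("fvPTC", 6), ("clPTC", 6)),
                min_count=2,
            ),
            DatasetSpec(
                "rnaseqB", "rnaseq",
                (("NT", 6), ("fvPTC", 5), ("clPTC", 6)),
                min_count=1,
            ),
            DatasetSpec(
                "array", "microarray",
                (("NT", 6), ("fvPTC", 5), ("clPTC", 5), ("ATC", 5)),
            ),
        ),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def tiny_counts():
    """3-gene x 4-sample count table with two groups."""
    values = pd.DataFrame(
        [[10, 12, 50, 60], [5, 7, 4, 6], [100, 110, 95, 105]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    groups = pd.Series(["NT", "NT", "clPTC", "clPTC"], index=values.columns, name="group")
    return values, groups
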