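import numpy as np
import pandas as pd
import pytest

import dustqi as dq


@pytest.fixture
def small_table() -> dq.ConcentrationTable:
    return dq.ConcentrationTable(
        pd.DataFrame(
            {"Fe": [900.0, 1100.0], "Ca": [14000.0, 15000.0]},
            index=["S1", "S2"],
        )
    )


@pytest.fixture
def small_background() -> dq.BackgroundTable:
    return dq.BackgroundTable.from_mapping({"Fe": 41000.0, "Ca": 25700.0, "Al": 81500.0})


@pytest.fixture(scope="session")
def synthetic_table() -> dq.ConcentrationTable:
    """20-site, 17-element homogeneous survey from the default panel."""
    table, _ = dq.generate_concentrations(dq.default_spec(seed=42))
    return table


@pytest.fixture(scope="session")
def two_group_table():
    """20-site survey with two contamination regimes (shift 4)."""
    spec = dq.two_group_spec(shift=4.0, n_sites=20, seed=7)
    return dq.generate_concentrations(spec)


@pytest.fixture(scope="session")
def background() -> dq.BackgroundTable:
    return dq.default_background()


def baseline_table(background: dq.BackgroundTable, n_sites: int = 3) -> dq.ConcentrationTable:
    """Table with every concentration equal to its background (all PI = 1)."""
    row = background.values
    data = pd.DataFrame(
        np.tile(row.to_numpy(), (n_sites, 1)),
        index=[f"S{i}" for i in range(n_sites)],
        columns=row.index,
    )
    return dq.ConcentrationTable(data)
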