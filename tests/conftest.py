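import numpy as np
import pandas as pd
import pytest

from pfasvar import (
    BirdMeta,
    IsotopeTable,
    MeasurementPanel,
    default_panel,
    default_study_config,
    generate_cohort,
)


@pytest.fixture(scope="session")
def panel_compounds():
    return default_panel()


@pytest.fixture()
def toy_panel(panel_compounds):
    """Four birds, full 15-compound panel; PFHpA censored for one bird,
    PFPeA censored everywhere."""
    names = [c.name for c in panel_compounds]
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.lognormal(1.0, 0.5, size=(4, len(names))),
        index=[f"B{i}" for i in range(1, 5)],
        columns=names,
    )
    censored = pd.DataFrame(False, index=values.index, columns=names)
    censored.loc["B1", "PFHpA"] = True
    censored.loc[:, "PFPeA"] = True
    values = values.mask(censored)
    return MeasurementPanel(values=values, censored=censored, compounds=panel_compounds)


@pytest.fixture()
def toy_meta():
    return BirdMeta(
        pd.DataFrame(
            {"species": ["UA", "UA", "UL", "UA"], "colony": ["SE", "SW", "NW", "N"]},
            index=[f"B{i}" for i in range(1, 5)],
        )
    )


@pytest.fixture()
def toy_iso():
    rows = []
    rng = np.random.default_rng(7)
    for i in range(1, 5):
        base_c, base_n = -20.0 + rng.normal(0, 1), 12.5 + rng.normal(0, 1)
        rows.append((f"B{i}", "plasma", base_c - 0.4 + rng.normal(0, 0.2),
                     base_n + 0.5 + rng.normal(0, 0.2)))
        rows.append((f"B{i}", "rbc", base_c + rng.normal(0, 0.2),
                     base_n + rng.normal(0, 0.2)))
    return IsotopeTable(pd.DataFrame(rows, columns=["bird_id", "tissue", "d13C", "d15N"]))


@pytest.fixture(scope="session")
def default_cohort():
    """One realisation of the default synthetic cohort (seed 0)."""
    return generate_cohort(default_study_config(), seed=0)
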