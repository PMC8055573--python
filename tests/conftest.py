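import numpy as np
import pandas as pd
import pytest

from cardiohi.config import QCParams, SimConfig


def small_sim_config(**overrides) -> SimConfig:
    """A scaled-down study design that keeps tests fast: 3 patients per
    group, ~60 measured cells per well, 4 samples per plate."""
    base = dict(
        group_sizes={"Ctrl": 3, "ATTRv-PN": 3, "ATTRv-CA": 3, "ATTRwt": 3},
        cells_measured_per_well=60.0,
        samples_per_plate=4,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    from cardiohi.synthetic import generate_dataset

    return generate_dataset(small_sim_config(), seed=11)


@pytest.fixture
def qc_params():
    return QCParams(min_cells_per_well=10)


@pytest.fixture
def toy_layout():
    """Two plates, one experiment, one sample, plus FCS controls."""
    rows = []
    for plate in ("E1B01", "E1B02"):
        for i in range(2):
            rows.append(
                dict(well_id=f"{plate}_F{i}", plate_id=plate, experiment_id=1,
                     sample_id="FCS", plasma_source="FCS", plasma_pct=np.nan, pe=0)
            )
        for pe in (0, 1):
            for i in range(2):
                rows.append(
                    dict(well_id=f"{plate}_P{pe}{i}", plate_id=plate, experiment_id=1,
                         sample_id="P001", plasma_source="patient", plasma_pct=5.0, pe=pe)
                )
    return pd.DataFrame(rows)
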