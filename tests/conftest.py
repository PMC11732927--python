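import datetime as dt

import numpy as np
import pandas as pd
import pytest

from edcrowd.crowding import crowding_labels
from edcrowd.features import build_design_matrix
from edcrowd.forecaster import default_split, expanding_window_forecast
from edcrowd.sim_ed import (
    HourlyOccupancyPanel,
    calibrate_default_config,
    replace_config,
    simulate_panel,
)
from edcrowd.subgroups import DEFAULT_CAPACITIES, SUBGROUPS


def panel_from_occupancy(
    occ: dict[str, np.ndarray],
    start: dt.date = dt.date(2018, 1, 1),
    capacities: dict[str, int] | None = None,
) -> HourlyOccupancyPanel:
    """Construct a panel directly from occupancy count arrays (test helper).

    Subgroups absent from ``occ`` get zeros; length must be a whole number
    of days.
    """
    capacities = capacities or dict(DEFAULT_CAPACITIES)
    n = len(next(iter(occ.values())))
    idx = pd.date_range(pd.Timestamp(start), periods=n, freq="h")
    data = {}
    for s in SUBGROUPS:
        v = np.asarray(occ.get(s, np.zeros(n, dtype=int)))
        data[f"occ_{s}"] = v
        data[f"edor_{s}"] = v / capacities[s]
    return HourlyOccupancyPanel(frame=pd.DataFrame(data, index=idx), capacities=capacities)


@pytest.fixture(scope="session")
def sim_150():
    """150-day default-config panel, covariates, labels and design matrix."""
    cfg = replace_config(calibrate_default_config(), n_days=150, seed=3)
    panel, cov = simulate_panel(cfg)
    labels = crowding_labels(panel)
    matrix = build_design_matrix(panel, cov, labels)
    return {"config": cfg, "panel": panel, "covariates": cov,
            "labels": labels, "matrix": matrix}


@pytest.fixture(scope="session")
def run_150(sim_150):
    """Expanding-window forecast on the 150-day matrix (90-day initial train)."""
    matrix = sim_150["matrix"]
    split = default_split(matrix, initial_train_days=90, retrain_stride_days=15)
    return expanding_window_forecast(matrix, split, seed=0)
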