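"""Shared fixtures: small deterministic panels and the Monte Carlo grid
used by the ordering regression tests."""

import numpy as np
import pytest

from panelcf import PanelDataset, replicate_table3


def make_panel(y, treated, T0, X=None, weights=None, covariate_names=()):
    """Tiny-panel builder from plain nested lists."""
    y = np.asarray(y, float)
    n = y.shape[0]
    units = np.array([f"u{i}" for i in range(n)])
    return PanelDataset(
        units=units, y=y, treated=np.asarray(treated, bool), T0=T0,
        X=X, weights=weights, covariate_names=covariate_names,
    )


@pytest.fixture
def panel_2x2():
    """2 units x 2 periods: control flat at 0, treated jumps to 10."""
    return make_panel([[0.0, 0.0], [0.0, 10.0]], [False, True], T0=1)


@pytest.fixture(scope="session")
def grid300():
    """Scenario A-D x T in {3,10,30} x all methods at 300 replications.

    Computed once per session; used by the qualitative-ordering regression
    tests and the acceptance checks.
    """
    return replicate_table3(300, base_seed=0)


def cell(df, scenario, method, T):
    row = df[
        (df["scenario"] == scenario) & (df["method"] == method) & (df["T"] == T)
    ]
    assert len(row) == 1
    return row.iloc[0]
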