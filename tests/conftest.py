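"""Shared fixtures: small hand-built panels with known arithmetic."""

import numpy as np
import pandas as pd
import pytest

from secretomics.io import CrtTable, FactorPanel


def make_samples(n_donors=2):
    rows = {}
    for d in range(1, n_donors + 1):
        for condition in ("resting", "primed"):
            rows[f"D{d}_{condition}"] = {"donor": f"D{d}", "condition": condition}
    return pd.DataFrame.from_dict(rows, orient="index")


@pytest.fixture
def samples4():
    return make_samples(2)


@pytest.fixture
def small_panel(samples4):
    """3 analytes x 4 samples; A1 detected everywhere, A2 fails one resting
    sample, A3 detected in primed only."""
    conc = pd.DataFrame(
        {
            "D1_resting": [500.0, 50.0, 5.0],
            "D1_primed": [1000.0, 60.0, 80.0],
            "D2_resting": [400.0, 8.0, 4.0],
            "D2_primed": [900.0, 70.0, 90.0],
        },
        index=["A1", "A2", "A3"],
    )
    return FactorPanel(
        conc=conc,
        samples=samples4,
        assay_threshold=pd.Series(10.0, index=conc.index),
        dilution_factor=2.0,
        medium_volume=pd.Series(5.0, index=samples4.index),
        cell_count=pd.Series(1.0e6, index=samples4.index),
    )


def make_crt_table(crt_values, panel_of=None, spike=None, n_donors=2):
    """Build a CrtTable from a dict miRNA -> list of Crt per sample."""
    samples = make_samples(n_donors)
    crt = pd.DataFrame(crt_values, index=samples.index).T
    if panel_of is None:
        panel_of = pd.Series("A", index=crt.index)
    else:
        panel_of = pd.Series(panel_of)
    if spike is None:
        spike = pd.DataFrame({"A": 15.0, "B": 16.0}, index=samples.index)
    return CrtTable(crt=crt, samples=samples, panel_of=panel_of, spike_crt=spike)


@pytest.fixture
def small_crt():
    """6 miRNAs (half on panel B) x 4 samples, dyadic Crt values so every
    downstream float operation is exact; m6 never amplified, m5 lost on
    priming."""
    values = {
        # columns: D1_resting, D1_primed, D2_resting, D2_primed
        "m1": [20.0, 19.0, 20.5, 19.5],
        "m2": [22.0, 22.5, 22.25, 22.75],
        "m3": [24.0, 25.0, 23.5, 24.5],
        "m4": [21.0, 20.0, 21.5, 20.5],
        "m5": [26.0, np.nan, 26.5, np.nan],
        "m6": [np.nan, np.nan, np.nan, np.nan],
    }
    panels = {"m1": "A", "m2": "A", "m3": "A", "m4": "B", "m5": "B", "m6": "B"}
    return make_crt_table(values, panels)
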