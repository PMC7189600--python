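"""Flow-cytometry validation readouts.

Works on pre-summarized per-condition tables: background-subtracted MFI
fold-changes vs an untreated control, the CD86/CD163 macrophage
polarization ratio, and VCAM1-positivity ratios for chondrocyte
inflammation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FlowReadout",
    "mfi_fold",
    "polarization_ratio",
    "positivity_ratio",
    "fold_table",
]


@dataclass
class FlowReadout:
    """One marker x condition flow summary (arbitrary fluorescence units)."""

    condition: str
    marker: str
    mfi: float
    unstained_mfi: float
    pct_positive: float | None = None

    def __post_init__(self) -> None:
        if self.mfi < 0 or self.unstained_mfi < 0:
            raise ValueError("MFI values must be >= 0")
        if self.pct_positive is not None and not 0 <= self.pct_positive <= 100:
            raise ValueError("pct_positive must lie in [0, 100]")

    @property
    def net_mfi(self) -> float:
        """MFI minus the unstained control."""
        return self.mfi - self.unstained_mfi


def mfi_fold(readout: FlowReadout, control: FlowReadout) -> float:
    """Background-subtracted MFI fold vs the control condition.

    fold = net MFI / control net MFI, so the control is 1 by construction.
    A negative net sample MFI (signal below its unstained control) is
    clamped to 0 with a warning.
    """
    if readout.marker != control.marker:
        raise ValueError(
            f"marker mismatch: {readout.marker!r} vs {control.marker!r}")
    if control.net_mfi <= 0:
        raise ValueError("control net MFI must be > 0")
    net = readout.net_mfi
    if net < 0:
        warnings.warn(
            f"negative net MFI for {readout.marker} in {readout.condition}; "
            "fold clamped at 0")
        return 0.0
    return net / control.net_mfi


def polarization_ratio(cd86_fold: float, cd163_fold: float) -> float:
    """CD86/CD163 fold ratio; > 1 marks M1 (pro-inflammatory) polarization."""
    if cd163_fold <= 0:
        raise ValueError("CD163 fold must be > 0")
    if cd86_fold <= 0:
        raise ValueError("CD86 fold must be > 0")
    return cd86_fold / cd163_fold


def positivity_ratio(pct_treated, pct_reference):
    """Ratio of %-positive cells, treated vs reference.

    Scalars give a single ratio-of-summaries.  Per-donor arrays give the
    per-donor ratios averaged (mean, SD) — the convention used whenever
    donor-level data exist.
    """
    treated = np.atleast_1d(np.asarray(pct_treated, dtype=float))
    reference = np.atleast_1d(np.asarray(pct_reference, dtype=float))
    if treated.shape != reference.shape:
        raise ValueError("treated and reference must pair up")
    if (reference <= 0).any():
        raise ValueError("reference percentage must be > 0")
    ratios = treated / reference
    if ratios.size == 1:
        return float(ratios[0])
    return float(ratios.mean()), float(ratios.std(ddof=1)), ratios


def fold_table(flow: pd.DataFrame, control_condition: str) -> pd.DataFrame:
    """Per-donor, per-marker MFI folds vs a control condition.

    ``flow`` is a tidy frame with donor, condition, marker, mfi and
    unstained_mfi columns (see :func:`secretomics.io.read_flow_table`).
    Returns the same tidy layout with a ``fold`` column; the control rows
    carry fold 1 by construction.
    """
    rows = []
    for (donor, marker), group in flow.groupby(["donor", "marker"]):
        ctrl_rows = group[group["condition"] == control_condition]
        if len(ctrl_rows) != 1:
            raise ValueError(
                f"donor {donor!r}, marker {marker!r}: need exactly one "
                f"{control_condition!r} row, found {len(ctrl_rows)}")
        ctrl = FlowReadout(control_condition, marker,
                           float(ctrl_rows["mfi"].iloc[0]),
                           float(ctrl_rows["unstained_mfi"].iloc[0]))
        for _, rec in group.iterrows():
            sample = FlowReadout(rec["condition"], marker,
                                 float(rec["mfi"]), float(rec["unstained_mfi"]))
            rows.append({"donor": donor, "marker": marker,
                         "condition": rec["condition"],
                         "fold": mfi_fold(sample, ctrl)})
    return pd.DataFrame(rows)
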