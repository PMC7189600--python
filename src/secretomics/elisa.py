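"""Per-cell quantification of multiplex-ELISA secreted factors.

Concentrations (pg/ml of conditioned medium) are converted to absolute
secreted amounts per million producing cells over the 48 h collection
window::

    amount [pg / 1e6 cells] = conc * dilution * volume_ml * 1e6 / cell_count

A factor counts as *detected* in a condition only when its concentration
exceeds the single-assay threshold in every sample of that condition
(strictly greater).  Detected factors are tiered by their mean per-cell
amount in ng (>100, 10-100, 1-10, <=1), and inter-donor concordance is
summarized as the mean +/- SD of all pairwise Pearson correlations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CONDITIONS, FactorPanel

__all__ = [
    "TIERS",
    "FactorAmountTable",
    "per_cell_amount",
    "detection_filter",
    "amount_table",
    "abundance_tiers",
    "mean_pairwise_correlation",
]

#: Abundance tiers on the mean amount m in ng per 1e6 cells, upper-inclusive.
TIERS = ("gt100ng", "10to100ng", "1to10ng", "lt1ng")


def per_cell_amount(conc, dilution: float = 1.0, volume: float = None,
                    cells: float = None):
    """Absolute secreted amount, pg per 1e6 cells.

    Parameters
    ----------
    conc : scalar or array-like
        Concentration in pg/ml as measured (after any dilution).
    dilution : float
        Dilution factor applied before the assay (>= 1).
    volume : float
        Volume of conditioned medium in ml (> 0).
    cells : float
        Number of producing cells at harvest (> 0).
    """
    if volume is None or cells is None:
        raise ValueError("volume and cells are required (no defaults)")
    if not np.all(np.asarray(volume) > 0):
        raise ValueError("volume must be > 0")
    if not np.all(np.asarray(cells) > 0):
        raise ValueError("cells must be > 0")
    if not np.all(np.asarray(dilution) >= 1):
        raise ValueError("dilution must be >= 1")
    return conc * dilution * volume * 1e6 / cells


@dataclass
class FactorAmountTable:
    """Per-cell amounts with detection flags and abundance tiers.

    ``amount`` is analyte x sample in pg per 1e6 cells; ``detected`` is
    analyte x condition (True where above threshold in all samples of the
    condition); ``tier`` is analyte x condition with a tier label where
    detected, else NaN.
    """

    amount: pd.DataFrame
    samples: pd.DataFrame
    detected: pd.DataFrame
    tier: pd.DataFrame


def detection_filter(panel: FactorPanel) -> dict[str, set[str]]:
    """Apply the all-samples detection rule per condition.

    An analyte is detected in a condition iff its concentration is strictly
    above the assay threshold in *every* sample of that condition.  Returns
    ``{"resting": set, "primed": set, "union": set}``.
    """
    out: dict[str, set[str]] = {}
    for condition in CONDITIONS:
        cols = panel.condition_samples(condition)
        if not cols:
            raise ValueError(f"condition {condition!r} has zero samples")
        conc = panel.conc[cols]
        above = conc.gt(panel.assay_threshold, axis=0) & conc.notna()
        out[condition] = set(conc.index[above.all(axis=1)])
    out["union"] = out["resting"] | out["primed"]
    return out


def amount_table(panel: FactorPanel) -> FactorAmountTable:
    """Convert a panel to per-cell amounts, flag detection and assign tiers."""
    amount = per_cell_amount(
        panel.conc,
        dilution=panel.dilution_factor,
        volume=panel.medium_volume,
        cells=panel.cell_count,
    )
    detected_sets = detection_filter(panel)
    detected = pd.DataFrame(
        {c: amount.index.isin(sorted(detected_sets[c])) for c in CONDITIONS},
        index=amount.index,
    )
    table = FactorAmountTable(amount=amount, samples=panel.samples,
                              detected=detected, tier=None)
    table.tier = abundance_tiers(table)
    return table


def _tier_of(mean_ng: float) -> str:
    if mean_ng > 100:
        return "gt100ng"
    if mean_ng > 10:
        return "10to100ng"
    if mean_ng > 1:
        return "1to10ng"
    return "lt1ng"


def abundance_tiers(amounts: FactorAmountTable) -> pd.DataFrame:
    """Tier each detected analyte by its condition-mean amount in ng.

    Boundaries are upper-inclusive: a mean of exactly 100 ng falls in
    10to100ng, exactly 10 ng in 1to10ng, exactly 1 ng in lt1ng.
    """
    tier = pd.DataFrame(index=amounts.amount.index, columns=list(CONDITIONS),
                        dtype=object)
    for condition in CONDITIONS:
        cols = amounts.samples.index[amounts.samples["condition"] == condition]
        mean_ng = amounts.amount[list(cols)].mean(axis=1) / 1000.0
        for analyte in tier.index:
            if amounts.detected.at[analyte, condition]:
                tier.at[analyte, condition] = _tier_of(mean_ng[analyte])
    return tier


def mean_pairwise_correlation(values: pd.DataFrame, samples: pd.DataFrame,
                              condition: str,
                              analytes=None) -> tuple[float, float]:
    """Mean +/- SD of Pearson R over all unordered sample pairs.

    ``values`` is analyte x sample; rows are restricted to ``analytes`` when
    given (typically the condition's detected set).  Missing values are
    excluded pairwise; a pair where either vector is constant has no defined
    correlation and is skipped with a warning.
    """
    cols = list(samples.index[samples["condition"] == condition])
    if len(cols) < 2:
        raise ValueError(f"need >= 2 samples in condition {condition!r}")
    sub = values.loc[sorted(analytes), cols] if analytes is not None else values[cols]
    rs = []
    for a, b in itertools.combinations(cols, 2):
        pair = sub[[a, b]].dropna()
        x, y = pair[a].to_numpy(float), pair[b].to_numpy(float)
        if len(pair) < 2 or np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"correlation undefined for sample pair ({a}, {b}); skipped")
            continue
        rs.append(np.corrcoef(x, y)[0, 1])
    if not rs:
        raise ValueError("no sample pair had a defined correlation")
    return float(np.mean(rs)), float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0
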