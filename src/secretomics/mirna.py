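"""EV-miRNA quantification from qPCR-array Crt values.

The processing chain mirrors standard OpenArray practice for EV cargo
profiling:

1. **Spike-in equalization** — each sample's panel-B Crt values are shifted
   by the difference between that sample's panel-A and panel-B spike-in
   (ath-miR-159a) Crt, anchoring both panels to a common technical
   reference.  Panel A is left unchanged; any common anchor would yield
   identical normalized expression (see the shift-invariance property).
2. **Censoring** — Crt values strictly above the amplification limit
   (28 cycles by default) are treated as not amplified.
3. **Global-mean normalization** — per sample, dCrt = Crt minus the
   arithmetic mean of that sample's amplified Crt values (spike-in
   excluded); relative expression is 2**(-dCrt).
4. **Detection** — a miRNA is detected in a condition iff amplified in all
   samples of that condition; set differences between conditions give the
   gained / lost calls.
5. **First-quartile selection** — the top ceil(n/4) detected miRNAs ranked
   by condition-mean relative expression (ties at the cutoff broken by
   identifier).
6. **Genetic weight** — a miRNA subset's share, in percent, of the summed
   mean relative expression of the condition's full detected set.

All operations are pure: they return new tables and never mutate inputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CONDITIONS, CategorySet, CrtTable

__all__ = [
    "CENSOR_LIMIT",
    "ExpressionTable",
    "GeneticWeightReport",
    "spike_in_equalize",
    "censor_unamplified",
    "global_mean_normalize",
    "quantify",
    "detected_sets",
    "first_quartile_select",
    "genetic_weight",
    "category_balance",
    "category_weight_from_reference",
]

#: Default amplification limit in cycles; Crt strictly above is unamplified.
CENSOR_LIMIT = 28.0


@dataclass
class ExpressionTable:
    """Censored, equalized, global-mean-normalized relative expression.

    ``delta_crt`` (cycles) and ``rel_expr`` (= 2**-delta_crt, unitless) are
    miRNA x sample with NaN where not amplified.  ``detected`` is miRNA x
    condition: True where amplified in all samples of the condition.
    """

    delta_crt: pd.DataFrame
    rel_expr: pd.DataFrame
    samples: pd.DataFrame
    detected: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.detected is None:
            self.detected = pd.DataFrame(
                {
                    c: self.rel_expr[self.condition_samples(c)].notna().all(axis=1)
                    for c in CONDITIONS
                    if self.condition_samples(c)
                }
            )

    @property
    def mirnas(self) -> list[str]:
        return list(self.rel_expr.index)

    def condition_samples(self, condition: str) -> list[str]:
        mask = self.samples["condition"] == condition
        return list(self.samples.index[mask])

    def condition_mean(self, condition: str) -> pd.Series:
        """Mean relative expression across the condition's samples."""
        return self.rel_expr[self.condition_samples(condition)].mean(axis=1)


@dataclass
class GeneticWeightReport:
    """Share of the genetic message carried by a miRNA subset."""

    name: str
    condition: str
    weight: float                 # % of total detected-set expression
    member_weights: pd.Series     # % per member miRNA
    selection: list[str]          # the subset, as given


# ---------------------------------------------------------------------------
# Crt-level transforms
# ---------------------------------------------------------------------------


def spike_in_equalize(table: CrtTable) -> CrtTable:
    """Anchor panel-B Crt values to the panel-A spike-in, per sample.

    For each sample, panel-B miRNA Crts are shifted by
    ``spike_crt[A] - spike_crt[B]``; panel A is unchanged.  The spike table
    of the returned copy has both panels set to the panel-A value, recording
    that equalization happened.
    """
    out = table.copy()
    on_b = [m for m in out.crt.index if out.panel_of[m] == "B"]
    if not on_b:
        return out
    for sample in out.crt.columns:
        spike_a = out.spike_crt.at[sample, "A"]
        spike_b = out.spike_crt.at[sample, "B"]
        if not (np.isfinite(spike_a) and np.isfinite(spike_b)):
            if out.crt.loc[on_b, sample].notna().any():
                raise ValueError(f"missing spike-in for sample {sample!r}")
            continue
        out.crt.loc[on_b, sample] += spike_a - spike_b
        out.spike_crt.at[sample, "B"] = spike_a
    return out


def censor_unamplified(table: CrtTable, limit: float = CENSOR_LIMIT) -> CrtTable:
    """Mark Crt values strictly greater than ``limit`` as not amplified.

    The boundary value itself (Crt == limit) is retained.  Rows that end up
    all-missing stay in the table; detection flags downstream record them as
    never amplified.
    """
    if not limit > 0:
        raise ValueError("censoring limit must be > 0")
    out = table.copy()
    out.crt = out.crt.mask(out.crt > limit)
    return out


def global_mean_normalize(table: CrtTable) -> ExpressionTable:
    """Per-sample global-mean dCrt and 2**-dCrt relative expression.

    The global mean is the arithmetic mean of the sample's amplified miRNA
    Crt values, spike-in excluded (it is never among the table's miRNAs).
    A sample with zero amplified miRNAs cannot be normalized.
    """
    empty = table.crt.notna().sum(axis=0) == 0
    if empty.any():
        bad = list(table.crt.columns[empty])
        raise ValueError(f"sample(s) with zero amplified miRNAs: {bad}")
    global_mean = table.crt.mean(axis=0)          # per sample, NaN-aware
    delta = table.crt.sub(global_mean, axis=1)
    return ExpressionTable(delta_crt=delta, rel_expr=2.0 ** (-delta),
                           samples=table.samples.copy())


def quantify(table: CrtTable, limit: float = CENSOR_LIMIT) -> ExpressionTable:
    """Full Crt -> expression chain: equalize, censor, normalize."""
    return global_mean_normalize(censor_unamplified(spike_in_equalize(table), limit))


# ---------------------------------------------------------------------------
# detection, selection, weights
# ---------------------------------------------------------------------------


def detected_sets(expr: ExpressionTable) -> dict[str, set[str]]:
    """Per-condition detected miRNA sets plus gained/lost on priming.

    Detected = amplified in every sample of the condition.  ``gained`` are
    primed-only miRNAs, ``lost`` resting-only.
    """
    resting = set(expr.detected.index[expr.detected["resting"]])
    primed = set(expr.detected.index[expr.detected["primed"]])
    return {
        "resting": resting,
        "primed": primed,
        "gained": primed - resting,
        "lost": resting - primed,
    }


def first_quartile_select(expr: ExpressionTable, condition: str) -> list[str]:
    """Top ceil(n/4) detected miRNAs by condition-mean relative expression.

    Ranking is descending; ties at the cutoff are broken lexicographically
    by miRNA identifier so the selection is deterministic.
    """
    members = detected_sets(expr)[condition]
    if not members:
        raise ValueError(f"no detected miRNAs in condition {condition!r}")
    mean_expr = expr.condition_mean(condition).loc[sorted(members)]
    k = math.ceil(len(members) / 4)
    order = sorted(mean_expr.index, key=lambda m: (-mean_expr[m], m))
    return order[:k]


def genetic_weight(expr: ExpressionTable, subset, condition: str,
                   name: str = "subset",
                   per_sample: bool = False) -> GeneticWeightReport:
    """Percent of the condition's genetic message carried by ``subset``.

    weight = 100 * sum_subset(mean rel_expr) / sum_detected(mean rel_expr),
    with means across the condition's samples.  With ``per_sample=True`` the
    weight is computed within each sample and then averaged (documented
    variant; the default condition-mean form is single-valued per condition).
    Subset members outside the detected set contribute 0 and are warned
    about.
    """
    subset = list(subset)
    detected = detected_sets(expr)[condition]
    stray = [m for m in subset if m not in detected]
    if stray:
        warnings.warn(
            f"{len(stray)} subset member(s) not detected in {condition}: {stray}; "
            "contributing 0"
        )
    members = [m for m in subset if m in detected]
    cols = expr.condition_samples(condition)
    det_idx = sorted(detected)
    if per_sample:
        shares = []
        member_shares = []
        for col in cols:
            total = expr.rel_expr.loc[det_idx, col].sum()
            mem = 100.0 * expr.rel_expr.loc[members, col] / total
            member_shares.append(mem)
            shares.append(mem.sum())
        weight = float(np.mean(shares))
        member_weights = pd.concat(member_shares, axis=1).mean(axis=1)
    else:
        mean_expr = expr.condition_mean(condition)
        total = mean_expr.loc[det_idx].sum()
        member_weights = 100.0 * mean_expr.loc[members] / total
        weight = float(member_weights.sum())
    member_weights = member_weights.reindex(subset).fillna(0.0)
    return GeneticWeightReport(name=name, condition=condition, weight=weight,
                               member_weights=member_weights, selection=subset)


def category_balance(report_a: GeneticWeightReport,
                     report_b: GeneticWeightReport) -> dict:
    """Weight difference between two category reports of one condition."""
    if report_a.condition != report_b.condition:
        raise ValueError("balance requires reports from the same condition")
    return {
        "condition": report_a.condition,
        report_a.name: report_a.weight,
        report_b.name: report_b.weight,
        "delta": report_a.weight - report_b.weight,
    }


def category_weight_from_reference(category: CategorySet,
                                   condition: str = "resting") -> float:
    """Category genetic weight from the packaged reference '% weight' columns.

    Sums the published per-member weights of an annotation table
    (``weight_ev`` for resting EVs, ``weight_iev`` for IFN-gamma-primed
    EVs), rounded to the two decimals at which the members are recorded.
    """
    column = {"resting": "weight_ev", "primed": "weight_iev"}[condition]
    if column not in category.entries.columns:
        raise ValueError(f"category {category.name!r} has no {column} column")
    return round(float(category.entries[column].sum()), 2)
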