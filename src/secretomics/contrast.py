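"""Primed-vs-resting contrast statistics for secreted factors and EV-miRNAs.

The experimental design is paired: each donor contributes one resting and
one IFN-gamma-primed culture.  Per analyte, the modulation statistic is the
per-donor ratio primed/resting, summarized as mean +/- SD and tested with a
one-sample t-test against the no-modulation value 1.  Ratios are analyzed
on the arithmetic scale by default (mean of ratios vs 1); a log-scale
option exists but is off by default.

Supporting tools: a two-sided single-outlier Grubbs screen applied to the
donor ratios before testing, a Lilliefors-style Kolmogorov-Smirnov
normality check with Monte-Carlo p-values, and a row-centered PCA utility
for sample-level overviews.

The model surface follows the statsmodels convention:

>>> model = PrimingContrast(resting, primed)          # doctest: +SKIP
>>> res = model.fit()                                 # doctest: +SKIP
>>> print(res.summary())                              # doctest: +SKIP
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "donor_ratios",
    "one_sample_t_vs_1",
    "significance_call",
    "grubbs_outlier",
    "grubbs_critical_value",
    "ks_normality",
    "pca_row_centered",
    "PrimingContrast",
    "PrimingContrastResults",
]

CALLS = ("gained", "lost", "up", "down", "unchanged", "trend")


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------


def donor_ratios(resting: pd.Series, primed: pd.Series) -> pd.Series:
    """Per-donor primed/resting ratios, paired by donor identifier.

    Donors with a zero (or missing) resting value have no defined ratio and
    are excluded with a warning; an unpaired donor is an error.
    """
    if set(resting.index) != set(primed.index):
        raise ValueError(
            f"unpaired donors: resting {sorted(resting.index)} vs "
            f"primed {sorted(primed.index)}"
        )
    primed = primed.reindex(resting.index)
    bad = (resting == 0) | resting.isna() | primed.isna()
    if bad.any():
        warnings.warn(
            f"donor(s) excluded from ratio (zero/missing value): "
            f"{list(resting.index[bad])}"
        )
    return (primed[~bad] / resting[~bad]).rename("ratio")


def one_sample_t_vs_1(ratios) -> float:
    """Two-sided one-sample t-test p-value of mean(ratios) against 1.

    Degenerate SD = 0 cases use the documented conventions: p = 1 when the
    common value is exactly 1, p = 0 (logged) otherwise.
    """
    x = np.asarray(ratios, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 ratios")
    if np.std(x, ddof=1) == 0:
        if np.isclose(x.mean(), 1.0):
            return 1.0
        logger.info("SD = 0 with mean != 1; p set to 0 by convention")
        return 0.0
    return float(stats.ttest_1samp(x, popmean=1.0).pvalue)


def significance_call(mean_ratio: float, p_value: float,
                      detected_resting: bool = True,
                      detected_primed: bool = True,
                      fold_threshold: float = 2.0,
                      alpha: float = 0.05,
                      trend_alpha: float = 0.1) -> str:
    """Classify a contrast as gained/lost/up/down/trend/unchanged.

    Detection flags override everything: present only after priming is
    "gained", only before is "lost".  Otherwise "up"/"down" require both the
    fold criterion (mean ratio > fold_threshold, or < 1/fold_threshold) and
    p < alpha; "trend" keeps the fold criterion with alpha <= p < trend_alpha.
    """
    if detected_primed and not detected_resting:
        return "gained"
    if detected_resting and not detected_primed:
        return "lost"
    fold_up = mean_ratio > fold_threshold
    fold_down = mean_ratio < 1.0 / fold_threshold
    if fold_up or fold_down:
        if p_value < alpha:
            return "up" if fold_up else "down"
        if p_value < trend_alpha:
            return "trend"
    return "unchanged"


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical value of the single-outlier Grubbs statistic.

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student's t on n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_outlier(values, alpha: float = 0.05):
    """Index of the single most extreme point if it is a Grubbs outlier.

    Two-sided test, at most one outlier flagged per invocation.  Returns the
    positional index, or None.  SD = 0 (all values equal) flags nothing.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Grubbs test needs n >= 3")
    sd = np.std(x, ddof=1)
    if sd == 0:
        return None
    dev = np.abs(x - x.mean())
    g = dev.max() / sd
    if g > grubbs_critical_value(x.size, alpha):
        return int(np.argmax(dev))
    return None


def ks_normality(values, n_mc: int = 2000, seed: int = 0) -> float:
    """Lilliefors-style KS normality p-value by Monte Carlo.

    The KS statistic compares the sample against a normal with the sample's
    own mean and SD; because the parameters are estimated, the null
    distribution of the statistic is simulated (``n_mc`` standard-normal
    samples of the same size, fixed ``seed``) rather than taken from the
    parameter-free KS law.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("normality undefined for constant values")

    def lilliefors_stat(samples: np.ndarray) -> np.ndarray:
        # rows are independent samples; statistic per row
        z = (samples - samples.mean(axis=1, keepdims=True)) \
            / samples.std(axis=1, ddof=1, keepdims=True)
        cdf = stats.norm.cdf(np.sort(z, axis=1))
        n = samples.shape[1]
        ecdf_hi = np.arange(1, n + 1) / n
        ecdf_lo = np.arange(0, n) / n
        return np.maximum(ecdf_hi - cdf, cdf - ecdf_lo).max(axis=1)

    d_obs = lilliefors_stat(x[None, :])[0]
    rng = np.random.default_rng(seed)
    d_null = lilliefors_stat(rng.standard_normal((n_mc, x.size)))
    return float((1 + np.sum(d_null >= d_obs)) / (n_mc + 1))


def pca_row_centered(matrix: pd.DataFrame):
    """Sample scores from a PCA of the row-centered analyte x sample matrix.

    Rows with any missing value are dropped (the analysis is restricted to
    analytes measured in every sample).  Scores come from the SVD of the
    centered matrix; each component's sign is fixed so its largest-magnitude
    row loading is positive.  Returns (scores, explained_variance_ratio)
    with scores samples x components.
    """
    complete = matrix.dropna(axis=0)
    if complete.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if complete.shape[0] < 2:
        raise ValueError("need at least 2 complete rows")
    centered = complete.sub(complete.mean(axis=1), axis=0).to_numpy(float)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    for k in range(len(s)):
        j = np.argmax(np.abs(u[:, k]))
        if u[j, k] < 0:
            u[:, k] = -u[:, k]
            vt[k, :] = -vt[k, :]
    scores = vt.T * s            # samples x components
    total = (s ** 2).sum()
    evr = s ** 2 / total if total > 0 else np.zeros_like(s)
    cols = [f"PC{i + 1}" for i in range(len(s))]
    return pd.DataFrame(scores, index=complete.columns, columns=cols), evr


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class PrimingContrast:
    """Paired priming-contrast model over a family of analytes.

    Parameters
    ----------
    resting, primed : DataFrame
        Analyte x donor values for each condition; columns are donor
        identifiers and must agree between the two frames.
    detected : DataFrame, optional
        Analyte x {resting, primed} boolean detection flags; analytes
        detected in only one condition receive "gained"/"lost" calls
        instead of a test.
    """

    def __init__(self, resting: pd.DataFrame, primed: pd.DataFrame,
                 detected: pd.DataFrame | None = None):
        if set(resting.columns) != set(primed.columns):
            raise ValueError("resting and primed must share donor columns")
        if not resting.index.equals(primed.index):
            primed = primed.reindex(resting.index)
        self.resting = resting
        self.primed = primed[resting.columns]
        if detected is None:
            detected = pd.DataFrame(
                {"resting": resting.notna().all(axis=1),
                 "primed": primed.notna().all(axis=1)}
            )
        self.detected = detected

    @classmethod
    def from_amounts(cls, amounts, detected: pd.DataFrame | None = None):
        """Build from a :class:`~secretomics.elisa.FactorAmountTable`."""
        frames = {}
        for condition in ("resting", "primed"):
            cols = amounts.samples.index[amounts.samples["condition"] == condition]
            sub = amounts.amount[list(cols)]
            sub.columns = amounts.samples.loc[cols, "donor"]
            frames[condition] = sub
        return cls(frames["resting"], frames["primed"],
                   detected if detected is not None else amounts.detected)

    @classmethod
    def from_expression(cls, expr):
        """Build from a :class:`~secretomics.mirna.ExpressionTable`."""
        frames = {}
        for condition in ("resting", "primed"):
            cols = expr.condition_samples(condition)
            sub = expr.rel_expr[cols].copy()
            sub.columns = expr.samples.loc[cols, "donor"]
            frames[condition] = sub
        return cls(frames["resting"], frames["primed"], expr.detected)

    def fit(self, fold_threshold: float = 2.0, alpha: float = 0.05,
            trend_alpha: float = 0.1, grubbs: bool = True,
            grubbs_alpha: float = 0.05,
            log_scale: bool = False) -> "PrimingContrastResults":
        """Run ratios, outlier screen, tests and calls for every analyte.

        With ``grubbs=True`` the donor ratios of each analyte are screened
        once for a single Grubbs outlier; a flagged donor is dropped (and
        recorded) before the t-test, which proceeds while n >= 2.  With
        ``log_scale=True`` the test is mean(log ratio) vs 0; calls still use
        the arithmetic mean ratio.
        """
        rows = []
        for analyte in self.resting.index:
            det_r = bool(self.detected.at[analyte, "resting"])
            det_p = bool(self.detected.at[analyte, "primed"])
            row = {
                "analyte": analyte,
                "detected_resting": det_r,
                "detected_primed": det_p,
                "n": 0,
                "ratio_mean": np.nan,
                "ratio_sd": np.nan,
                "p_value": np.nan,
                "outlier_donor": None,
            }
            if det_r != det_p:
                row["call"] = "gained" if det_p else "lost"
                rows.append(row)
                continue
            if not (det_r and det_p):
                row["call"] = "unchanged"
                rows.append(row)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ratios = donor_ratios(self.resting.loc[analyte],
                                      self.primed.loc[analyte])
            if grubbs and len(ratios) >= 3:
                idx = grubbs_outlier(ratios.to_numpy(), alpha=grubbs_alpha)
                if idx is not None:
                    row["outlier_donor"] = ratios.index[idx]
                    logger.info("Grubbs outlier removed for %s: donor %s",
                                analyte, ratios.index[idx])
                    ratios = ratios.drop(ratios.index[idx])
            row["n"] = len(ratios)
            if len(ratios) >= 1:
                row["ratio_mean"] = float(ratios.mean())
                row["ratio_sd"] = float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0
            if len(ratios) >= 2:
                if log_scale:
                    logs = np.log(ratios.to_numpy())
                    if np.std(logs, ddof=1) == 0:
                        row["p_value"] = 1.0 if np.isclose(logs.mean(), 0) else 0.0
                    else:
                        row["p_value"] = float(
                            stats.ttest_1samp(logs, popmean=0.0).pvalue)
                else:
                    row["p_value"] = one_sample_t_vs_1(ratios.to_numpy())
                row["call"] = significance_call(
                    row["ratio_mean"], row["p_value"], det_r, det_p,
                    fold_threshold, alpha, trend_alpha)
            else:
                row["call"] = "unchanged"
            rows.append(row)
        table = pd.DataFrame(rows).set_index("analyte")
        tested = table["p_value"].notna()
        table["q_value"] = np.nan
        if tested.any():
            # informational only; calls are driven by raw p-values
            table.loc[tested, "q_value"] = multipletests(
                table.loc[tested, "p_value"], method="fdr_bh")[1]
        return PrimingContrastResults(self, table, fold_threshold, alpha,
                                      trend_alpha)


class PrimingContrastResults:
    """Fitted priming-contrast results; one row per analyte."""

    def __init__(self, model: PrimingContrast, table: pd.DataFrame,
                 fold_threshold: float, alpha: float, trend_alpha: float):
        self.model = model
        self.table = table
        self.fold_threshold = fold_threshold
        self.alpha = alpha
        self.trend_alpha = trend_alpha

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]

    def of(self, call: str) -> list[str]:
        """Analytes with a given call."""
        return list(self.table.index[self.table["call"] == call])

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def summary(self) -> str:
        counts = self.table["call"].value_counts()
        lines = [
            "Priming contrast (primed/resting ratios vs 1)",
            "=" * 54,
            f"analytes: {len(self.table)}   fold threshold: "
            f"{self.fold_threshold}   alpha: {self.alpha}   "
            f"trend alpha: {self.trend_alpha}",
            "calls: " + ", ".join(f"{k}={v}" for k, v in counts.items()),
            "-" * 54,
        ]
        show = self.table[self.table["call"] != "unchanged"]
        cols = ["ratio_mean", "ratio_sd", "p_value", "q_value", "call"]
        body = show[cols].to_string(
            float_format=lambda v: f"{v:.4g}") if len(show) else "(no calls)"
        lines.append(body)
        return "\n".join(lines)
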