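"""Synthetic paired resting/primed donor panels with known ground truth.

The generator emulates the study design the pipeline was built for: four
donors, each contributing one resting and one IFN-gamma-primed culture,
profiled by a 200-factor multiplex ELISA, a 754-miRNA two-panel qPCR array
with an ath-miR-159a spike-in, and pre-summarized flow-cytometry readouts
on macrophages (CD86/CD163) and chondrocytes (VCAM1).

Every injected effect — per-analyte priming folds, condition-specific
detection (gains/losses), flow fold-changes — is returned alongside the
tables as a :class:`GroundTruth`, so each pipeline stage has a recovery
test that needs no external data.

Model of the qPCR layer: each miRNA has a true log2 abundance drawn from a
normal law whose spread (``sigma_log2``, default 3.6 cycles) makes the
expression distribution heavy-tailed enough that the top ceil(n/4)
detected miRNAs carry roughly 95-97% of total expression.  Crt is
(offset - log2 expression) plus Gaussian cycle noise, a per-sample loading
shift, and a panel-B spike offset; values above the censoring limit count
as unamplified.  Detectability is made exact by construction: miRNAs meant
to be detected sit at least ``detect_margin`` cycles below the limit, and
undetectable ones ``undetect_gap`` cycles above it — a deliberate gap real
arrays do not have.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CONDITIONS, CrtTable, FactorPanel

__all__ = ["SyntheticConfig", "GroundTruth", "generate_elisa_panel",
           "generate_crt_table", "generate_flow_readouts", "generate_all"]


def _default_flow_folds() -> dict:
    # Net-MFI folds vs untreated control, per marker and condition.
    # M1 = IFNg+TNFa inflammation; SEC / PSEC = resting / primed secretome
    # added on top of the inflammatory stimulus.
    return {
        "CD86": {"CTRL": 1.0, "M1": 1.41, "M1_SEC": 1.35, "M1_PSEC": 1.30},
        "CD163": {"CTRL": 1.0, "M1": 0.74, "M1_SEC": 1.07, "M1_PSEC": 1.18},
    }


def _default_vcam_ratios() -> dict:
    # True per-donor suppression of VCAM1+ % vs the IL-1b-only condition.
    return {"IL1B_SEC": 0.58, "IL1B_PSEC": 0.47}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_donors: int = 4
    seed: int = 0

    # --- ELISA layer -------------------------------------------------------
    n_factors: int = 200
    n_detect_factors: int = 57        # detectable in all resting samples
    n_lost_factors: int = 5           # detectable resting-only
    n_gained_factors: int = 6         # detectable primed-only
    factor_cv: float = 0.20           # lognormal CV of concentrations
    assay_threshold_pgml: float = 10.0
    medium_volume_ml: float = 5.0
    cell_count: float = 1.0e6
    dilution_factor: float = 2.0
    factor_fold: dict = field(default_factory=dict)   # analyte -> true fold

    # --- qPCR layer --------------------------------------------------------
    n_mirnas: int = 754
    n_detect_mirnas: int = 242        # detected in all resting samples
    n_lost_mirnas: int = 30           # disappear on priming
    n_gained_mirnas: int = 10         # appear on priming
    sigma_log2: float = 3.6           # spread of true log2 abundance, cycles
    crt_noise_sd: float = 0.25        # replicate noise, cycles
    sample_shift_sd: float = 0.5      # per-sample loading shift, cycles
    censor_limit: float = 28.0
    detect_margin: float = 2.5        # cycles below limit for detectable
    undetect_gap: float = 4.0         # cycles above limit for undetectable
    spike_a_crt: float = 15.0
    spike_b_offset: float = 1.0       # spike B minus spike A, cycles
    mirna_fold: dict = field(default_factory=dict)    # miRNA -> true fold

    # --- flow layer --------------------------------------------------------
    n_flow_donors: int = 3
    flow_cv: float = 0.10
    unstained_mfi: float = 100.0
    control_net_mfi: float = 900.0
    flow_folds: dict = field(default_factory=_default_flow_folds)
    vcam_base_pct: float = 24.0       # VCAM1+ % in untreated chondrocytes
    vcam_inflamed_pct: float = 65.0   # VCAM1+ % under IL-1b
    vcam_ratios: dict = field(default_factory=_default_vcam_ratios)

    def __post_init__(self) -> None:
        if self.n_donors < 2:
            raise ValueError("n_donors must be >= 2")
        if self.factor_cv < 0 or self.flow_cv < 0:
            raise ValueError("CV must be >= 0")
        if self.n_detect_factors + self.n_gained_factors > self.n_factors:
            raise ValueError("more detectable factors than factors")
        if self.n_lost_factors > self.n_detect_factors:
            raise ValueError("cannot lose more factors than are detected")
        if self.n_detect_mirnas + self.n_gained_mirnas > self.n_mirnas:
            raise ValueError("more detectable miRNAs than miRNAs")
        if self.n_lost_mirnas > self.n_detect_mirnas:
            raise ValueError("cannot lose more miRNAs than are detected")
        for fold in list(self.factor_fold.values()) + list(self.mirna_fold.values()):
            if not fold > 0:
                raise ValueError("all true folds must be > 0")


@dataclass
class GroundTruth:
    """Everything injected into a synthetic study, per analyte."""

    factor_fold: pd.Series | None = None
    factor_detected: pd.DataFrame | None = None
    mirna_fold: pd.Series | None = None
    mirna_detected: pd.DataFrame | None = None
    mirna_true_share: pd.DataFrame | None = None
    categories: dict | None = None
    flow_folds: dict | None = None
    vcam_ratios: dict | None = None
    seed: int | None = None


def _sample_ids(n_donors: int) -> pd.DataFrame:
    rows = {}
    for d in range(1, n_donors + 1):
        for condition in CONDITIONS:
            rows[f"D{d}_{condition}"] = {"donor": f"D{d}", "condition": condition}
    return pd.DataFrame.from_dict(rows, orient="index")


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV (exact at cv=0)."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.standard_normal(size) * sigma - sigma * sigma / 2)


# ---------------------------------------------------------------------------
# ELISA panels
# ---------------------------------------------------------------------------


def generate_elisa_panel(config: SyntheticConfig) -> tuple[FactorPanel, GroundTruth]:
    """Paired resting+primed factor panel with injected priming folds.

    Detectable factors get median concentrations 1-3 orders of magnitude
    above the assay threshold; undetectable ones sit a factor 5 below it,
    so with the default 20% CV the configured detected-set sizes are
    realized in every sample with overwhelming probability.
    """
    rng = np.random.default_rng([config.seed, 0])
    analytes = [f"F{i + 1:03d}" for i in range(config.n_factors)]
    samples = _sample_ids(config.n_donors)

    n_both = config.n_detect_factors - config.n_lost_factors
    status = pd.Series("never", index=analytes, dtype=object)
    status.iloc[:n_both] = "both"
    status.iloc[n_both:config.n_detect_factors] = "lost"
    status.iloc[config.n_detect_factors:
                config.n_detect_factors + config.n_gained_factors] = "gained"

    thr = config.assay_threshold_pgml
    median = pd.Series(
        10 ** rng.uniform(np.log10(thr * 10), np.log10(thr * 1000),
                          config.n_factors),
        index=analytes)
    low = thr * 0.2       # safely below threshold even with noise

    fold = pd.Series(1.0, index=analytes)
    for analyte, f in config.factor_fold.items():
        fold[analyte] = f

    conc = pd.DataFrame(index=analytes, columns=samples.index, dtype=float)
    for sample, meta in samples.iterrows():
        primed = meta["condition"] == "primed"
        base = median.copy()
        if primed:
            base = base * fold
            base[status == "lost"] = low
            base[status == "never"] = low
        else:
            base[status == "gained"] = low
            base[status == "never"] = low
        conc[sample] = base.to_numpy() * _lognormal_noise(
            rng, config.factor_cv, config.n_factors)

    detected = pd.DataFrame(
        {"resting": status.isin(["both", "lost"]),
         "primed": status.isin(["both", "gained"])})
    truth = GroundTruth(factor_fold=fold, factor_detected=detected,
                        seed=config.seed)
    panel = FactorPanel(
        conc=conc, samples=samples,
        assay_threshold=pd.Series(thr, index=analytes),
        dilution_factor=config.dilution_factor,
        medium_volume=pd.Series(config.medium_volume_ml, index=samples.index),
        cell_count=pd.Series(config.cell_count, index=samples.index),
    )
    return panel, truth


# ---------------------------------------------------------------------------
# Crt tables
# ---------------------------------------------------------------------------


def generate_crt_table(config: SyntheticConfig) -> tuple[CrtTable, GroundTruth]:
    """Paired resting+primed Crt table with heavy-tailed true expression.

    Noise-free (``crt_noise_sd=0, sample_shift_sd=0``) tables reproduce the
    configured true expression shares exactly after the full quantification
    chain, because global-mean normalization cancels every per-sample
    offset the generator injects.
    """
    rng = np.random.default_rng([config.seed, 1])
    mirnas = [f"syn-miR-{i + 1:04d}" for i in range(config.n_mirnas)]
    samples = _sample_ids(config.n_donors)

    n_both = config.n_detect_mirnas - config.n_lost_mirnas
    status = pd.Series("never", index=mirnas, dtype=object)
    status.iloc[:n_both] = "both"
    status.iloc[n_both:config.n_detect_mirnas] = "lost"
    status.iloc[config.n_detect_mirnas:
                config.n_detect_mirnas + config.n_gained_mirnas] = "gained"

    log2_abund = pd.Series(rng.standard_normal(config.n_mirnas) * config.sigma_log2,
                           index=mirnas)
    fold = pd.Series(1.0, index=mirnas)
    for mirna, f in config.mirna_fold.items():
        fold[mirna] = f

    # noiseless Crt relative to an arbitrary offset; lower = more abundant
    base = {"resting": -log2_abund, "primed": -(log2_abund + np.log2(fold))}
    detect = {
        "resting": status.isin(["both", "lost"]),
        "primed": status.isin(["both", "gained"]),
    }
    # anchor: most abundant *detectable* entry across both conditions defines
    # the offset so that the least abundant detectable one sits at
    # limit - detect_margin
    worst = max(base[c][detect[c]].max() for c in CONDITIONS)
    offset = config.censor_limit - config.detect_margin - worst

    noiseless = pd.DataFrame(index=mirnas, columns=list(CONDITIONS), dtype=float)
    for condition in CONDITIONS:
        vals = base[condition] + offset
        vals[~detect[condition]] = config.censor_limit + config.undetect_gap
        noiseless[condition] = vals

    panel_of = pd.Series(["A", "B"] * (config.n_mirnas // 2 + 1),
                         index=None)[: config.n_mirnas]
    panel_of = pd.Series(panel_of.to_numpy(), index=mirnas)

    spike_crt = pd.DataFrame(index=samples.index, columns=["A", "B"], dtype=float)
    crt = pd.DataFrame(index=mirnas, columns=samples.index, dtype=float)
    is_b = (panel_of == "B").to_numpy()
    for sample, meta in samples.iterrows():
        shift = rng.standard_normal() * config.sample_shift_sd
        spike_a = config.spike_a_crt + rng.standard_normal() * config.crt_noise_sd
        spike_b = spike_a + config.spike_b_offset
        spike_crt.loc[sample] = [spike_a, spike_b]
        vals = (noiseless[meta["condition"]].to_numpy()
                + shift
                + rng.standard_normal(config.n_mirnas) * config.crt_noise_sd)
        vals = vals + is_b * (spike_b - spike_a)
        crt[sample] = vals

    # true expression shares among each condition's detected set
    share = pd.DataFrame(0.0, index=mirnas, columns=list(CONDITIONS))
    for condition in CONDITIONS:
        expr = 2.0 ** (-noiseless[condition][detect[condition]])
        share.loc[expr.index, condition] = 100.0 * expr / expr.sum()

    detected = pd.DataFrame(detect)
    categories = _synthetic_categories(share, detected)
    truth = GroundTruth(mirna_fold=fold, mirna_detected=detected,
                        mirna_true_share=share, categories=categories,
                        seed=config.seed)
    table = CrtTable(crt=crt, samples=samples, panel_of=panel_of,
                     spike_crt=spike_crt)
    return table, truth


def _synthetic_categories(share: pd.DataFrame,
                          detected: pd.DataFrame) -> dict[str, list[str]]:
    """Two disjoint miRNA lists over the both-conditions detected set."""
    core = [m for m in share.index
            if detected.at[m, "resting"] and detected.at[m, "primed"]]
    ranked = sorted(core, key=lambda m: -share.at[m, "resting"])
    return {
        "synthetic_protective": ranked[0:16:2],   # 8, abundance-skewed
        "synthetic_destructive": ranked[1:11:2],  # 5
    }


# ---------------------------------------------------------------------------
# flow readouts
# ---------------------------------------------------------------------------


def generate_flow_readouts(config: SyntheticConfig) -> tuple[dict, GroundTruth]:
    """Per-donor macrophage (MFI) and chondrocyte (% positive) tables.

    Returns ``{"macrophage": frame, "chondrocyte": frame}`` in the tidy
    layout :func:`secretomics.io.read_flow_table` expects.
    """
    rng = np.random.default_rng([config.seed, 2])
    donors = [f"P{d}" for d in range(1, config.n_flow_donors + 1)]

    mac_rows = []
    for donor in donors:
        for marker, per_condition in config.flow_folds.items():
            for condition, fold in per_condition.items():
                net = config.control_net_mfi * fold * _lognormal_noise(
                    rng, config.flow_cv, 1)[0]
                mac_rows.append({
                    "donor": donor, "condition": condition, "marker": marker,
                    "mfi": config.unstained_mfi + net,
                    "unstained_mfi": config.unstained_mfi,
                })
    macrophage = pd.DataFrame(mac_rows)

    cho_rows = []
    for donor in donors:
        base = config.vcam_base_pct * _lognormal_noise(rng, config.flow_cv, 1)[0]
        inflamed = config.vcam_inflamed_pct * _lognormal_noise(
            rng, config.flow_cv, 1)[0]
        pct = {"CTRL": base, "IL1B": inflamed}
        for condition, ratio in config.vcam_ratios.items():
            pct[condition] = inflamed * ratio * _lognormal_noise(
                rng, config.flow_cv, 1)[0]
        for condition, value in pct.items():
            net = config.control_net_mfi * _lognormal_noise(
                rng, config.flow_cv, 1)[0]
            cho_rows.append({
                "donor": donor, "condition": condition, "marker": "VCAM1",
                "mfi": config.unstained_mfi + net,
                "unstained_mfi": config.unstained_mfi,
                "pct_positive": min(float(value), 100.0),
            })
    chondrocyte = pd.DataFrame(cho_rows)

    truth = GroundTruth(flow_folds=config.flow_folds,
                        vcam_ratios=config.vcam_ratios, seed=config.seed)
    return {"macrophage": macrophage, "chondrocyte": chondrocyte}, truth


def generate_all(config: SyntheticConfig):
    """All three layers plus a merged ground truth."""
    panel, t_factor = generate_elisa_panel(config)
    crt, t_mirna = generate_crt_table(config)
    flow, t_flow = generate_flow_readouts(config)
    truth = GroundTruth(
        factor_fold=t_factor.factor_fold,
        factor_detected=t_factor.factor_detected,
        mirna_fold=t_mirna.mirna_fold,
        mirna_detected=t_mirna.mirna_detected,
        mirna_true_share=t_mirna.mirna_true_share,
        categories=t_mirna.categories,
        flow_folds=t_flow.flow_folds,
        vcam_ratios=t_flow.vcam_ratios,
        seed=config.seed,
    )
    return panel, crt, flow, truth
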