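"""Readers, writers and validated containers for secretome panel data.

Three raw data layers are handled:

* multiplex-ELISA factor panels (analyte x sample concentrations, pg/ml),
* qPCR-array Crt tables (miRNA x sample raw Crt cycles, with an A/B panel
  assignment and an ath-miR-159a spike-in per sample and panel),
* functional-category annotation lists (miRNA -> category/direction, with
  published per-miRNA "% weight" reference columns).

All files are delimited text: comma-separated by default, UTF-8, "." decimal,
first column holding the analyte/miRNA identifier.  A ``sep`` argument
switches to tabs.  Empty cells and the vendor string ``Undetermined`` both
map to missing (not detected / not amplified).  Sample metadata (donor and
condition) travels in a sidecar YAML/dict rather than being encoded in
column names.
"""

from __future__ import annotations

import dataclasses
import io as _io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "ParseError",
    "FactorPanel",
    "CrtTable",
    "CategorySet",
    "SPIKE_IN_ID",
    "DIRECTION_VOCABULARY",
    "read_factor_panel",
    "write_factor_panel",
    "read_crt_table",
    "write_crt_table",
    "read_category_sets",
    "write_category_sets",
    "read_flow_table",
    "load_run_config",
]

#: Reserved identifier for the exogenous spike-in rows of a Crt table.
SPIKE_IN_ID = "ath-miR-159a"

#: Closed vocabulary of direction labels for category annotations.
DIRECTION_VOCABULARY = frozenset(
    {
        "protective",
        "destructive",
        "M1_promoting",
        "M1_suppressing",
        "M2_promoting",
        "M2_suppressing",
    }
)

_MISSING_TOKENS = {"", "undetermined", "na", "nan"}

CONDITIONS = ("resting", "primed")


class ValidationError(ValueError):
    """A table violates one of its declared invariants."""


class ParseError(ValueError):
    """A delimited-text cell could not be interpreted."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


def _check_sample_meta(samples: pd.DataFrame) -> None:
    required = {"donor", "condition"}
    if not required.issubset(samples.columns):
        raise ValidationError(
            f"sample metadata must carry columns {sorted(required)}; "
            f"got {list(samples.columns)}"
        )
    bad = set(samples["condition"]) - set(CONDITIONS)
    if bad:
        raise ValidationError(f"unknown condition labels: {sorted(bad)}")
    if samples.index.duplicated().any():
        dup = samples.index[samples.index.duplicated()].tolist()
        raise ValidationError(f"duplicate sample identifiers: {dup}")


@dataclass
class FactorPanel:
    """Raw multiplex-ELISA layer: analyte x sample concentrations in pg/ml.

    ``conc`` holds measured concentrations with NaN for not-detected cells;
    values below the per-analyte ``assay_threshold`` are *kept* (flagging is
    the business of :func:`secretomics.elisa.detection_filter`, never of the
    reader).  ``medium_volume`` (ml) and ``cell_count`` are per sample;
    ``dilution_factor`` is one scalar per panel run.
    """

    conc: pd.DataFrame
    samples: pd.DataFrame
    assay_threshold: pd.Series
    dilution_factor: float
    medium_volume: pd.Series
    cell_count: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    @property
    def analytes(self) -> list[str]:
        return list(self.conc.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.conc.columns)

    def validate(self) -> None:
        _check_sample_meta(self.samples)
        if list(self.samples.index) != list(self.conc.columns):
            raise ValidationError("sample metadata does not match conc columns")
        if self.conc.index.duplicated().any():
            dup = self.conc.index[self.conc.index.duplicated()].tolist()
            raise ValidationError(f"duplicate analyte identifiers: {dup}")
        if (self.conc.to_numpy() < 0).any():
            raise ValidationError("negative concentration present")
        if not self.dilution_factor >= 1:
            raise ValidationError("dilution_factor must be >= 1")
        if not (self.medium_volume > 0).all():
            raise ValidationError("medium_volume must be > 0 for every sample")
        if not (self.cell_count > 0).all():
            raise ValidationError("cell_count must be > 0 for every sample")
        missing = set(self.conc.index) - set(self.assay_threshold.index)
        if missing:
            raise ValidationError(f"no assay threshold for: {sorted(missing)}")

    def condition_samples(self, condition: str) -> list[str]:
        """Sample identifiers belonging to one condition."""
        mask = self.samples["condition"] == condition
        return list(self.samples.index[mask])


@dataclass
class CrtTable:
    """Raw qPCR-array layer: miRNA x sample Crt cycles.

    NaN in ``crt`` means not amplified.  ``panel_of`` assigns each miRNA to
    OpenArray panel A or B; ``spike_crt`` is the per-sample spike-in Crt of
    each panel (samples x {A, B}).
    """

    crt: pd.DataFrame
    samples: pd.DataFrame
    panel_of: pd.Series
    spike_crt: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def mirnas(self) -> list[str]:
        return list(self.crt.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.crt.columns)

    def validate(self) -> None:
        _check_sample_meta(self.samples)
        if list(self.samples.index) != list(self.crt.columns):
            raise ValidationError("sample metadata does not match crt columns")
        if self.crt.index.duplicated().any():
            dup = self.crt.index[self.crt.index.duplicated()].tolist()
            raise ValidationError(f"duplicate miRNA identifiers: {dup}")
        if SPIKE_IN_ID in self.crt.index:
            raise ValidationError("spike-in row must not remain among mirnas")
        if (self.crt.to_numpy() <= 0).any():
            raise ValidationError("Crt values must be > 0 where present")
        unassigned = set(self.crt.index) - set(self.panel_of.index)
        if unassigned:
            raise ValidationError(f"miRNA without panel assignment: {sorted(unassigned)}")
        bad = set(self.panel_of.loc[list(self.crt.index)]) - {"A", "B"}
        if bad:
            raise ValidationError(f"unknown panel labels: {sorted(bad)}")
        # every (sample, panel) pair with any measured miRNA needs its spike
        for panel in ("A", "B"):
            members = [m for m in self.panel_of.index[self.panel_of == panel]
                       if m in self.crt.index]
            if not members:
                continue
            measured = self.crt.loc[members].notna().any(axis=0)
            for sample in self.crt.columns[measured]:
                ok = (
                    panel in self.spike_crt.columns
                    and sample in self.spike_crt.index
                    and np.isfinite(self.spike_crt.at[sample, panel])
                )
                if not ok:
                    raise ValidationError(
                        f"missing spike-in Crt for sample {sample!r}, panel {panel}"
                    )

    def condition_samples(self, condition: str) -> list[str]:
        mask = self.samples["condition"] == condition
        return list(self.samples.index[mask])

    def copy(self) -> "CrtTable":
        return CrtTable(
            crt=self.crt.copy(),
            samples=self.samples.copy(),
            panel_of=self.panel_of.copy(),
            spike_crt=self.spike_crt.copy(),
        )


@dataclass
class CategorySet:
    """A named miRNA list with direction labels and reference weights.

    ``entries`` has one row per member miRNA with columns ``direction``
    (closed vocabulary), ``weight_ev`` / ``weight_iev`` (published
    "% weight" reference values, resting and primed EVs) and free-text
    ``targets`` / ``regulation`` notes.
    """

    name: str
    entries: pd.DataFrame

    def __post_init__(self) -> None:
        if self.entries.index.duplicated().any():
            dup = self.entries.index[self.entries.index.duplicated()].tolist()
            raise ValidationError(f"duplicate miRNA in category {self.name!r}: {dup}")
        bad = set(self.entries["direction"]) - DIRECTION_VOCABULARY
        if bad:
            raise ValidationError(
                f"unknown direction labels in category {self.name!r}: {sorted(bad)}"
            )

    @property
    def mirnas(self) -> list[str]:
        return list(self.entries.index)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------


def _parse_numeric(frame: pd.DataFrame, what: str) -> pd.DataFrame:
    """Coerce a raw string frame to float, mapping missing tokens to NaN.

    Raises :class:`ParseError` naming the offending row and column.
    """
    values = np.full(frame.shape, np.nan)
    for j, col in enumerate(frame.columns):
        for i, raw in enumerate(frame[col].to_numpy()):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                continue
            text = str(raw).strip()
            if text.lower() in _MISSING_TOKENS:
                continue
            try:
                values[i, j] = float(text)
            except ValueError:
                raise ParseError(
                    f"malformed numeric cell {text!r} at row {frame.index[i]!r}, "
                    f"column {col!r} in {what}"
                ) from None
    return pd.DataFrame(values, index=frame.index.rename(None),
                        columns=frame.columns)


def _as_series(value, index: pd.Index, name: str) -> pd.Series:
    """Broadcast a scalar or per-key mapping onto ``index``."""
    if np.isscalar(value):
        return pd.Series(float(value), index=index, name=name)
    series = pd.Series(value, dtype=float).reindex(index)
    if series.isna().any():
        missing = series.index[series.isna()].tolist()
        raise ValidationError(f"{name} missing for: {missing}")
    return series.rename(name)


def _sample_frame(meta: dict, sample_ids: list[str]) -> pd.DataFrame:
    spec = meta.get("samples")
    if spec is None:
        raise ValidationError("run config must carry a 'samples' block")
    rows = {}
    for sid in sample_ids:
        if sid not in spec:
            raise ValidationError(f"sample {sid!r} absent from config 'samples' block")
        entry = spec[sid]
        rows[sid] = {"donor": str(entry["donor"]), "condition": str(entry["condition"])}
    return pd.DataFrame.from_dict(rows, orient="index")


def load_run_config(path: str | os.PathLike) -> dict:
    """Load a YAML run config (samples, volumes, cell counts, thresholds)."""
    with open(path, "r", encoding="utf-8") as handle:
        return yaml.safe_load(handle)


# ---------------------------------------------------------------------------
# factor panels
# ---------------------------------------------------------------------------


def read_factor_panel(path: str | os.PathLike | _io.IOBase, meta: dict,
                      sep: str = ",") -> FactorPanel:
    """Read an ELISA factor panel CSV plus its culture metadata.

    ``meta`` must provide ``samples`` (sample -> donor/condition),
    ``dilution_factor``, ``medium_volume`` (ml, scalar or per sample),
    ``cell_count`` (scalar or per sample) and ``assay_threshold`` (pg/ml,
    scalar or per analyte).
    """
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                      keep_default_na=False, encoding="utf-8")
    conc = _parse_numeric(raw, "factor panel")
    if (conc.to_numpy() < 0).any():
        raise ValidationError("negative concentration present in factor panel")
    samples = _sample_frame(meta, list(conc.columns))
    return FactorPanel(
        conc=conc,
        samples=samples,
        assay_threshold=_as_series(meta["assay_threshold"], conc.index, "assay_threshold"),
        dilution_factor=float(meta.get("dilution_factor", 1.0)),
        medium_volume=_as_series(meta["medium_volume"], samples.index, "medium_volume"),
        cell_count=_as_series(meta["cell_count"], samples.index, "cell_count"),
    )


def write_factor_panel(panel: FactorPanel, path: str | os.PathLike,
                       sep: str = ",") -> None:
    panel.conc.to_csv(path, sep=sep, index_label="analyte", encoding="utf-8")


# ---------------------------------------------------------------------------
# Crt tables
# ---------------------------------------------------------------------------


def read_crt_table(path: str | os.PathLike | _io.IOBase, meta: dict,
                   sep: str = ",") -> CrtTable:
    """Read a qPCR-array Crt CSV (miRNA, panel, then one column per sample).

    Spike-in rows are identified by the reserved ``ath-miR-159a`` identifier
    (one row per panel) and extracted into ``spike_crt``; they never remain
    among the quantified miRNAs.
    """
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                      keep_default_na=False, encoding="utf-8")
    if "panel" not in raw.columns:
        raise ValidationError("Crt table must carry a 'panel' column")
    panel_col = raw["panel"].astype(str).str.strip()
    values = _parse_numeric(raw.drop(columns=["panel"]), "Crt table")

    is_spike = values.index.to_series().astype(str).str.strip() == SPIKE_IN_ID
    spike_rows = values.loc[is_spike]
    spike_panels = panel_col.loc[is_spike]
    spike_crt = pd.DataFrame(index=values.columns, columns=["A", "B"], dtype=float)
    for (mirna, row), panel in zip(spike_rows.iterrows(), spike_panels):
        if panel not in ("A", "B"):
            raise ValidationError(f"spike-in row with unknown panel {panel!r}")
        spike_crt[panel] = row.astype(float)

    crt = values.loc[~is_spike]
    panel_of = panel_col.loc[~is_spike]
    if (panel_of.str.len() == 0).any():
        missing = panel_of.index[panel_of.str.len() == 0].tolist()
        raise ValidationError(f"miRNA without panel assignment: {missing}")
    samples = _sample_frame(meta, list(crt.columns))
    return CrtTable(crt=crt, samples=samples, panel_of=panel_of, spike_crt=spike_crt)


def write_crt_table(table: CrtTable, path: str | os.PathLike, sep: str = ",") -> None:
    """Write a Crt table back to the canonical CSV layout (spike rows included)."""
    body = table.crt.copy()
    body.insert(0, "panel", table.panel_of.loc[body.index])
    spike = pd.DataFrame(
        {panel: table.spike_crt[panel] for panel in ("A", "B")}
    ).T
    spike.index = [SPIKE_IN_ID, SPIKE_IN_ID]
    spike.insert(0, "panel", ["A", "B"])
    out = pd.concat([spike, body])
    out.to_csv(path, sep=sep, index_label="miRNA", encoding="utf-8")


# ---------------------------------------------------------------------------
# category annotations
# ---------------------------------------------------------------------------

_CATEGORY_COLUMNS = ["category", "miRNA", "direction", "weight_ev", "weight_iev",
                     "regulation", "targets"]


def read_category_sets(path: str | os.PathLike | _io.IOBase,
                       sep: str = ",") -> list[CategorySet]:
    """Read functional-category annotations into one CategorySet per category."""
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                            encoding="utf-8")
    except pd.errors.EmptyDataError:
        return []
    if frame.empty:
        return []
    missing = {"category", "miRNA", "direction"} - set(frame.columns)
    if missing:
        raise ValidationError(f"category file lacks columns: {sorted(missing)}")
    out = []
    for name, group in frame.groupby("category", sort=False):
        entries = group.set_index("miRNA").drop(columns=["category"])
        for col in ("weight_ev", "weight_iev"):
            if col in entries.columns:
                entries[col] = pd.to_numeric(entries[col], errors="coerce")
        out.append(CategorySet(name=str(name), entries=entries))
    return out


def write_category_sets(sets: list[CategorySet], path: str | os.PathLike,
                        sep: str = ",") -> None:
    frames = []
    for cset in sets:
        frame = cset.entries.reset_index(names="miRNA")
        frame.insert(0, "category", cset.name)
        frames.append(frame)
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False,
                                                    encoding="utf-8")
    else:
        pd.DataFrame(columns=_CATEGORY_COLUMNS).to_csv(path, sep=sep, index=False,
                                                       encoding="utf-8")


# ---------------------------------------------------------------------------
# flow summaries
# ---------------------------------------------------------------------------


def read_flow_table(path: str | os.PathLike | _io.IOBase, sep: str = ",") -> pd.DataFrame:
    """Read a pre-summarized flow-cytometry table.

    Expected columns: donor, condition, marker, mfi, unstained_mfi and
    optionally pct_positive (% of gated events).
    """
    frame = pd.read_csv(path, sep=sep, encoding="utf-8")
    required = {"donor", "condition", "marker", "mfi", "unstained_mfi"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"flow table lacks columns: {sorted(missing)}")
    if (frame["mfi"] < 0).any() or (frame["unstained_mfi"] < 0).any():
        raise ValidationError("MFI values must be >= 0")
    if "pct_positive" in frame.columns:
        pct = frame["pct_positive"].dropna()
        if ((pct < 0) | (pct > 100)).any():
            raise ValidationError("pct_positive must lie in [0, 100]")
    return frame
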