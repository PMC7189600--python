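"""secretomics: quantification and priming-contrast analysis of MSC
secretome factors and EV-miRNAs.

The package covers the desk side of a secretome potency study: multiplex
ELISA factor quantification per million cells, qPCR-array EV-miRNA
processing (spike-in equalization, censoring, global-mean normalization,
2**-dCrt relative expression, first-quartile selection, genetic-weight
category scoring), paired primed-vs-resting contrast statistics, and
flow-cytometry polarization/inflammation readouts, plus a synthetic data
generator with known ground truth.
"""

from . import contrast, cytometry, elisa, io, mirna, simulate
from .contrast import PrimingContrast, PrimingContrastResults
from .io import (CategorySet, CrtTable, FactorPanel, read_category_sets,
                 read_crt_table, read_factor_panel)
from .mirna import ExpressionTable, quantify
from .simulate import GroundTruth, SyntheticConfig

__version__ = "0.1.0"

__all__ = [
    "contrast", "cytometry", "elisa", "io", "mirna", "simulate",
    "PrimingContrast", "PrimingContrastResults",
    "CategorySet", "CrtTable", "FactorPanel",
    "read_category_sets", "read_crt_table", "read_factor_panel",
    "ExpressionTable", "quantify",
    "GroundTruth", "SyntheticConfig",
    "load_reference_categories",
]


def load_reference_categories(which: str = "macrophage"):
    """Packaged functional-category annotations with published weights.

    ``which`` is ``"macrophage"`` (M1/M2 phenotype lists) or
    ``"cartilage"`` (cartilage-protective/destructive lists).  Entries carry
    the published per-miRNA "% weight" reference columns for resting
    (weight_ev) and primed (weight_iev) vesicles.
    """
    from importlib.resources import files

    name = {"macrophage": "macrophage_categories.csv",
            "cartilage": "cartilage_categories.csv"}[which]
    path = files("secretomics.data").joinpath(name)
    with path.open("r", encoding="utf-8") as handle:
        return read_category_sets(handle)
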