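"""Bundled reference data.

``direct_target_reference`` is the published table of 45 thyroid-hormone
direct-response transcripts found in *Microhyla fissipes* dorsal muscle
(log2 fold change and BH-adjusted q value in the TH-vs-control and
TH+CHX-vs-CHX contrasts).  It serves as the worked example for the
DET filter and direct-target classification: running both at the standard
thresholds must recover 39 up- and 6 down-regulated direct targets.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .detest import ContrastResult

__all__ = ["load_direct_target_reference", "reference_contrasts"]


def load_direct_target_reference() -> pd.DataFrame:
    """The 45-row direct-target reference table, indexed by transcript id."""
    with resources.files("thtargets.data").joinpath(
        "direct_target_reference.tsv"
    ).open() as fh:
        table = pd.read_csv(fh, sep="\t", index_col="gene_id")
    return table


def reference_contrasts() -> tuple[ContrastResult, ContrastResult]:
    """The reference table reshaped as two pre-computed contrast results
    (TH vs control; TH+CHX vs CHX) over the 45-transcript universe."""
    ref = load_direct_target_reference()

    def as_contrast(cond_a: str, cond_b: str, lfc_col: str, q_col: str) -> ContrastResult:
        table = pd.DataFrame(
            {
                "base_mean": np.nan,
                "log2fc": ref[lfc_col],
                "pvalue": np.nan,
                "padj": ref[q_col],
            },
            index=ref.index,
        )
        return ContrastResult(cond_a, cond_b, table)

    return (
        as_contrast("control", "TH", "lfc_th_vs_ctrl", "q_th_vs_ctrl"),
        as_contrast("CHX", "TH_CHX", "lfc_thchx_vs_chx", "q_thchx_vs_chx"),
    )
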