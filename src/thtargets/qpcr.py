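"""Relative quantification of qPCR validation data (2^-ddCt).

Each sample's target Ct is first normalized against a reference
("housekeeping") gene measured in the same sample (dCt = Ct_target -
Ct_ref), then centred on the mean dCt of a calibrator group (ddCt), and
expressed as a fold change 2^-ddCt.  Centring on the arithmetic mean of
the calibrator dCt values makes the calibrator group's *geometric* mean
fold change exactly 1.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

__all__ = ["ddct_fold_change", "group_anova"]

REQUIRED_COLUMNS = ("sample", "group", "gene", "ct")


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"qPCR records missing columns: {sorted(missing)}")
    if (records["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    dup = records.duplicated(subset=["sample", "gene"])
    if dup.any():
        offenders = records.loc[dup, ["sample", "gene"]].to_records(index=False)
        raise ValueError(f"duplicate (sample, gene) measurements: {list(offenders)[:5]}")
    return records


def ddct_fold_change(
    records: pd.DataFrame,
    target: str,
    reference: str,
    calibrator_group: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample fold changes and per-group mean ± SEM for one target gene.

    ``records`` needs columns sample, group, gene, ct.  The reference gene
    must be measured in every sample carrying the target; the calibrator
    group must be non-empty.  Returns ``(per_sample, per_group)`` where
    per_sample has columns group, dct, ddct, fold and per_group has
    mean_fold, sem_fold, n.
    """
    records = _validate(records)
    tgt = records[records["gene"] == target].set_index("sample")
    ref = records[records["gene"] == reference].set_index("sample")
    if tgt.empty:
        raise ValueError(f"no measurements for target gene {target!r}")
    missing_ref = set(tgt.index) - set(ref.index)
    if missing_ref:
        raise ValueError(
            f"reference gene {reference!r} not measured in sample(s): {sorted(missing_ref)}"
        )
    per_sample = pd.DataFrame(
        {"group": tgt["group"], "dct": tgt["ct"] - ref.loc[tgt.index, "ct"]}
    )
    calib = per_sample[per_sample["group"] == calibrator_group]
    if calib.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")
    per_sample["ddct"] = per_sample["dct"] - calib["dct"].mean()
    per_sample["fold"] = 2.0 ** (-per_sample["ddct"])
    per_group = per_sample.groupby("group")["fold"].agg(
        mean_fold="mean", sem_fold="sem", n="size"
    )
    return per_sample, per_group


def group_anova(per_sample: pd.DataFrame) -> float:
    """One-way ANOVA p-value across groups of per-sample fold changes."""
    groups = [g["fold"].to_numpy() for _, g in per_sample.groupby("group")]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    return float(stats.f_oneway(*groups).pvalue)
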