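"""Delta-CT relative-expression analysis with a multi-housekeeper reference.

qPCR threshold cycles (CT) are normalized per sample against the arithmetic
mean CT of a set of housekeeper genes (default GAPDH, RPL13 and beta-actin):
dCT = CT_target - mean(CT_housekeepers). Group fold change follows the
ddCT rule, fold = 2^-(mean dCT_case - mean dCT_control), with a two-sided
Student's t-test on the per-sample dCT values. Samples failing the RNA
integrity threshold (RIN > 6, strict) are excluded up front.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_HOUSEKEEPERS",
    "rin_filter",
    "delta_ct",
    "relative_expression",
]

DEFAULT_HOUSEKEEPERS = ("GAPDH", "RPL13", "ACTB")

_REQUIRED = {"sample", "group", "gene", "CT"}


def _check_table(table: pd.DataFrame) -> None:
    missing = _REQUIRED - set(table.columns)
    if missing:
        raise ValueError(f"expression table lacks columns {sorted(missing)}")
    ct = table["CT"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)) or (ct <= 0).any():
        raise ValueError("CT values must be finite and positive")


def rin_filter(table: pd.DataFrame, min_rin: float = 6.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop samples whose RNA integrity number is not strictly above ``min_rin``.

    Returns (filtered table, exclusion report with one row per dropped
    sample). A sample at exactly the threshold is excluded.
    """
    if "RIN" not in table.columns:
        raise ValueError("table lacks RIN column")
    per_sample = table.groupby("sample")["RIN"].first()
    excluded = per_sample[per_sample <= min_rin]
    report = excluded.rename("RIN").reset_index()
    report["reason"] = f"RIN <= {min_rin}"
    return table[~table["sample"].isin(excluded.index)].copy(), report


def delta_ct(
    table: pd.DataFrame,
    target_gene: str,
    housekeepers=DEFAULT_HOUSEKEEPERS,
) -> pd.DataFrame:
    """Per-sample dCT of ``target_gene`` against the housekeeper-mean CT.

    Samples missing the target or any housekeeper measurement are skipped
    and listed in the ``skipped`` attribute of the returned DataFrame.
    Returns (sample, group, delta_ct).
    """
    _check_table(table)
    wide = table.pivot_table(index="sample", columns="gene", values="CT")
    group = table.groupby("sample")["group"].first()
    missing_hk = [h for h in housekeepers if h not in wide.columns]
    if missing_hk:
        raise ValueError(f"housekeepers never measured: {missing_hk}")
    if target_gene not in wide.columns:
        raise ValueError(f"target gene {target_gene!r} not in table")
    needed = wide[[target_gene, *housekeepers]]
    complete = needed.dropna()
    skipped = sorted(set(needed.index) - set(complete.index))
    dct = complete[target_gene] - complete[list(housekeepers)].mean(axis=1)
    out = pd.DataFrame(
        {
            "sample": complete.index,
            "group": group.loc[complete.index].to_numpy(),
            "delta_ct": dct.to_numpy(),
        }
    ).reset_index(drop=True)
    out.attrs["skipped"] = skipped
    return out


@dataclass
class RelativeExpression:
    fold: float
    p: float
    n_case: int
    n_control: int
    per_sample_fold: pd.Series


def relative_expression(delta_ct_case, delta_ct_control) -> RelativeExpression:
    """ddCT fold change of the case group relative to control.

    fold = 2^-(mean dCT_case - mean dCT_control); p from a two-sided
    Student's t-test (pooled variance) on the dCT values. The per-sample
    fold distribution (case samples against the control mean) is reported
    alongside for transparency.
    """
    a = np.asarray(delta_ct_case, dtype=float)
    b = np.asarray(delta_ct_control, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 samples")
    ddct = a.mean() - b.mean()
    fold = float(2.0**-ddct)
    if np.all(a == a[0]) and np.all(b == b[0]):
        p = 1.0 if a[0] == b[0] else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    per_sample = pd.Series(2.0 ** -(a - b.mean()), name="fold")
    return RelativeExpression(fold, p, len(a), len(b), per_sample)
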