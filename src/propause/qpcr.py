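"""qPCR arithmetic: delta-delta-Ct expression fold changes, the ChIP-qPCR
normalization chain (intergenic background, then total-H3 correction), and
the shared two-tailed paired t-test.

Amplification efficiency is fixed at 2 (one Cq cycle = one doubling), so a
fold change is ``2 ** (-ddCt)``.  Averaging across biological replicates is
done in Cq space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("propause")

REQUIRED_COLUMNS = ["condition", "target_name", "reference_name",
                    "cq_target", "cq_reference"]


def delta_delta_ct(records: pd.DataFrame, control_condition: str) -> pd.DataFrame:
    """Relative expression per target and condition by the delta-delta-Ct method.

    ``records`` has one row per well/replicate with columns ``condition,
    target_name, reference_name, cq_target, cq_reference`` (plus anything
    else, ignored).  Per row, dCt = Cq_target - Cq_reference; dCt is averaged
    within (target, condition); ddCt subtracts the control-condition mean,
    and fold = 2**(-ddCt).  The reference gene makes the result invariant to
    per-sample additive Cq offsets.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns: {missing}")
    if records["cq_reference"].isna().any():
        raise ValueError("missing reference Cq value(s)")
    df = records.assign(dct=records["cq_target"] - records["cq_reference"])
    mean_dct = df.groupby(["target_name", "condition"])["dct"].mean()

    rows = []
    for target, sub in mean_dct.groupby(level="target_name"):
        sub = sub.droplevel("target_name")
        if control_condition not in sub.index:
            raise ValueError(f"control condition {control_condition!r} missing "
                             f"for target {target!r}")
        for condition, dct in sub.items():
            ddct = dct - sub[control_condition]
            rows.append({"target_name": target, "condition": condition,
                         "ddct": ddct, "fold_change": 2.0 ** (-ddct)})
    return pd.DataFrame(rows)


def chip_qpcr_normalize(percent_input: pd.Series, background_loci: list[str],
                        h3_percent_input: pd.Series | None = None) -> pd.Series:
    """ChIP-qPCR enrichment over intergenic background, optionally H3-corrected.

    Step 1 divides each locus's percent-input by the arithmetic mean of the
    background loci (intergenic sites devoid of the modification).  Step 2,
    when an H3 percent-input table is given, divides by the identically
    background-normalized H3 value at the same locus, correcting for
    nucleosome occupancy.
    """
    missing = [b for b in background_loci if b not in percent_input.index]
    if missing:
        raise ValueError(f"background loci missing from table: {missing}")
    bg = percent_input[background_loci].mean()
    if bg == 0:
        raise ValueError("background mean is zero")
    out = percent_input / bg
    if h3_percent_input is not None:
        h3_norm = chip_qpcr_normalize(h3_percent_input, background_loci)
        out = out / h3_norm.loc[out.index]
    return out


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float
    degenerate: bool


def paired_t(x, y) -> PairedTResult:
    """Two-tailed paired t-test on matched vectors (d = y - x).

    Zero variance of the differences is degenerate: t and p are NaN and the
    flag is set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matched 1-d vectors")
    n = x.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = y - x
    if d.std(ddof=1) == 0:
        logger.warning("paired_t: zero-variance differences (degenerate)")
        return PairedTResult(np.nan, n - 1, np.nan, float(d.mean()), True)
    res = stats.ttest_rel(y, x)
    return PairedTResult(float(res.statistic), n - 1, float(res.pvalue),
                         float(d.mean()), False)
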