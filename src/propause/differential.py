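"""Spike-in size factors and negative-binomial Wald differential testing.

The same machinery serves PRO-seq gene bodies, ChIP peaks and ATAC peaks: a
two-group negative-binomial test on integer counts with external (spike-in)
size factors, Benjamini-Hochberg adjustment, and the FDR class labels used
throughout the study (up/down at FDR < 10%, unchanged at FDR > 50%).

Model.  Counts are normalized by the per-sample size factor, ``y_ij =
K_ij / s_j``, and modelled per feature as NB with group means ``m_A, m_B``
and variance ``m + alpha m^2``.  For this saturated two-group design the
log-link GLM likelihood separates by group and the MLE of each group mean
is exactly the arithmetic mean of its normalized counts, for any fixed
dispersion -- so the iteratively-reweighted fit reduces to a closed form,
which is what is computed (vectorized over features).  Fitting on
normalized counts (rather than raw counts with log-offsets) is what makes
the log2 fold change exactly invariant to rescaling any one sample's counts
together with its spike total.

Dispersion.  Per-feature method-of-moments on normalized counts
(``alpha_i = (within-condition residual variance - mean) / mean^2``) feeds
a mean-dispersion trend ``a/mean + b`` fitted across features, and the
trend value at a feature's mean is the dispersion used for its test
(floored at 1e-8).  With two replicates per condition the per-feature
moment estimate has two residual degrees of freedom and is so noisy that
blending it into the test statistic destroys type-I calibration (its log is
strongly median-biased downward); pooling across features via the trend is
the standard remedy for minimal designs and is well calibrated here.  The
Wald statistic is ``log(m_B/m_A)`` over its delta-method standard error,
referred to a standard normal, two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("propause")

MIN_DISPERSION = 1e-8

CLASS_UP = "up"
CLASS_DOWN = "down"
CLASS_UNCHANGED = "unchanged"
CLASS_INDETERMINATE = "indeterminate"
CLASS_UNTESTED = "untested"


@dataclass
class CountMatrix:
    """Features x samples integer counts plus per-sample totals.

    ``samples`` is indexed by sample id with columns ``condition``,
    ``replicate``, ``spike_total`` and ``primary_total``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples table missing entries for {sorted(missing)}")

    @classmethod
    def from_frames(cls, counts: pd.DataFrame, samples: pd.DataFrame) -> "CountMatrix":
        samples = samples.set_index("sample") if "sample" in samples.columns else samples
        return cls(counts, samples)


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------

def spike_size_factors(spike_totals) -> pd.Series:
    """Per-sample size factors from spike-in read totals.

    ``s_j = spike_j / geometric_mean(spike_totals)``, so the factor logs sum
    to zero.  A zero spike total is an error: add a pseudo-count upstream or
    exclude the sample.
    """
    totals = pd.Series(spike_totals, dtype=float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero spike-in total for sample(s) {bad}; add a "
                         "pseudo-count or exclude the sample")
    log = np.log(totals)
    return np.exp(log - log.mean())


def library_size_factors(primary_totals) -> pd.Series:
    """Size factors from primary-genome library sizes (the normalization a
    spike-free analysis would use; destroys global shifts by construction)."""
    totals = pd.Series(primary_totals, dtype=float)
    if (totals <= 0).any():
        raise ValueError("zero primary-genome total")
    log = np.log(totals)
    return np.exp(log - log.mean())


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------

def _fit_dispersion_trend(mom: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Iteratively reweighted fit of the mean-dispersion trend ``a/mean + b``.

    Fitted on the raw (unfloored) method-of-moments values so negative
    estimates pull the trend honestly.  The sampling standard deviation of a
    per-feature moment estimate scales like ``(1 + alpha*mean)/mean``, so an
    unweighted fit is dominated by the huge-variance low-mean features and
    its intercept wanders enough between datasets to distort far-tail
    p-values; three passes of inverse-variance weighting (weights from the
    previous trend) remove that instability.  Predictions are clamped at the
    dispersion floor.
    """
    ok = np.isfinite(mom) & np.isfinite(mean) & (mean > 0)
    if ok.sum() < 2:
        return np.full(mom.shape, max(np.nanmedian(mom), MIN_DISPERSION))
    x = 1.0 / mean[ok]
    X = np.column_stack([x, np.ones_like(x)])
    y = mom[ok]
    w = np.ones_like(y)
    a = b = 0.0
    for _ in range(3):
        coef, *_ = np.linalg.lstsq(w[:, None] * X, w * y, rcond=None)
        a, b = coef
        pred = np.maximum(a * x + b, MIN_DISPERSION)
        w = mean[ok] / (1.0 + pred * mean[ok])
    with np.errstate(divide="ignore"):
        trend = a / mean + b
    return np.maximum(trend, MIN_DISPERSION)


def nb_wald_test(matrix: CountMatrix, size_factors: pd.Series,
                 contrast: tuple[str, str],
                 dispersion: float | None = None) -> pd.DataFrame:
    """Two-group NB Wald test of ``contrast = (treatment, control)``.

    Returns a frame indexed by feature with columns ``base_mean`` (mean
    normalized count), ``log2fc`` (treatment over control), ``se`` (of the
    log2 fold change), ``wald_p`` and ``dispersion``.  Features with all-zero
    counts get NaN statistics (untested).  ``dispersion`` forces a fixed
    alpha for every feature (0 gives the Poisson limit), bypassing the
    moment/trend estimate.
    """
    treat, control = contrast
    cond = matrix.samples["condition"]
    cols_a = [c for c in matrix.counts.columns if cond[c] == control]
    cols_b = [c for c in matrix.counts.columns if cond[c] == treat]
    if not cols_a or not cols_b:
        raise ValueError(f"contrast {contrast} not found in sample conditions")

    raw = matrix.counts[cols_a + cols_b]
    vals = raw.to_numpy()
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("counts must be integers")
    s = size_factors.loc[cols_a + cols_b].to_numpy(dtype=float)
    y = vals / s
    na, nb = len(cols_a), len(cols_b)
    ya, yb = y[:, :na], y[:, na:]

    untested = (vals.sum(axis=1) == 0)
    ma = ya.mean(axis=1)
    mb = yb.mean(axis=1)
    grand = y.mean(axis=1)

    if dispersion is not None:
        alpha = np.full(grand.shape, float(dispersion))
    else:
        dof = na + nb - 2
        if dof <= 0:
            raise ValueError("need at least 2 samples total beyond the two groups "
                             "to estimate dispersion; pass dispersion= explicitly")
        resid = ((ya - ma[:, None]) ** 2).sum(axis=1) + ((yb - mb[:, None]) ** 2).sum(axis=1)
        v = resid / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            mom = (v - grand) / grand ** 2
        alpha = _fit_dispersion_trend(mom, grand)

    # a zero group mean (with signal in the other group) is floored at half
    # a normalized count so the fold change is finite; the matching SE term
    # blows up, keeping the Wald statistic conservative there
    fa = np.maximum(ma, 0.5 / na)
    fb = np.maximum(mb, 0.5 / nb)
    beta = np.log(fb) - np.log(fa)
    se_ln = np.sqrt((1.0 + alpha * fa) / (na * fa) + (1.0 + alpha * fb) / (nb * fb))
    z = beta / se_ln
    wald_p = 2.0 * stats.norm.sf(np.abs(z))

    out = pd.DataFrame({
        "base_mean": grand,
        "log2fc": beta / np.log(2.0),
        "se": se_ln / np.log(2.0),
        "wald_p": wald_p,
        "dispersion": alpha,
    }, index=raw.index)
    out.loc[untested, ["log2fc", "se", "wald_p"]] = np.nan
    return out


# ---------------------------------------------------------------------------
# FDR and classes
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment; NaN (untested) entries are
    excluded from the number of tests and stay NaN."""
    p = pd.Series(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = pd.Series(np.nan, index=p.index)
    tested = p.notna()
    if tested.any():
        out[tested] = multipletests(p[tested].to_numpy(), method="fdr_bh")[1]
    return out


def classify_features(results: pd.DataFrame, up_down_fdr: float = 0.1,
                      unchanged_fdr: float = 0.5) -> pd.Series:
    """FDR class labels: up/down below ``up_down_fdr``, unchanged above
    ``unchanged_fdr``, indeterminate between, untested where fdr is NaN."""
    fdr = results["fdr"]
    lfc = results["log2fc"]
    labels = pd.Series(CLASS_INDETERMINATE, index=results.index)
    labels[(fdr < up_down_fdr) & (lfc > 0)] = CLASS_UP
    labels[(fdr < up_down_fdr) & (lfc < 0)] = CLASS_DOWN
    labels[fdr > unchanged_fdr] = CLASS_UNCHANGED
    labels[fdr.isna()] = CLASS_UNTESTED
    return labels


def run_differential(matrix: CountMatrix, contrast: tuple[str, str],
                     normalization: str = "spike",
                     up_down_fdr: float = 0.1, unchanged_fdr: float = 0.5,
                     dispersion: float | None = None) -> pd.DataFrame:
    """Full differential analysis: size factors, NB Wald, BH-FDR, classes.

    ``normalization`` is ``"spike"`` (spike-in totals; the study's choice) or
    ``"library"`` (primary-genome totals, provided for comparison -- it
    cancels genuine global shifts).
    """
    if normalization == "spike":
        factors = spike_size_factors(matrix.samples["spike_total"])
    elif normalization == "library":
        factors = library_size_factors(matrix.samples["primary_total"])
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    res = nb_wald_test(matrix, factors, contrast, dispersion=dispersion)
    res["fdr"] = bh_adjust(res["wald_p"])
    res["class"] = classify_features(res, up_down_fdr, unchanged_fdr)
    n = res["class"].value_counts()
    logger.info("differential %s vs %s (%s): %s", contrast[0], contrast[1],
                normalization, n.to_dict())
    return res
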