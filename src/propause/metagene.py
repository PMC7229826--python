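"""TSS-anchored, spike-in-scaled metagene profiles and paired window tests.

A metagene matrix holds, per gene and per relative offset (strand-oriented,
no position 0), the spike-scaled 3'-end signal averaged over replicates of
one condition.  The paired window test compares two conditions gene by gene
on summed signal in a relative window (e.g. the pause site +1..+70 versus
the early gene body +70..+200; the shared boundary offset is deliberately
assigned to both windows, as the windows are conventionally printed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import EndCountTrack, GeneModel

logger = logging.getLogger("propause")


def default_offsets(lo: int = -500, hi: int = 1500) -> np.ndarray:
    """Relative offset grid lo..hi with no position 0."""
    off = np.arange(lo, hi + 1)
    return off[off != 0]


@dataclass
class MetageneMatrix:
    """Genes x offsets spike-scaled signal, one frame per condition."""

    offsets: np.ndarray
    values: dict[str, pd.DataFrame]    # condition -> genes x offsets

    def profile(self, condition: str) -> pd.DataFrame:
        """Mean/sem/n over genes per offset (masked positions excluded)."""
        mat = self.values[condition]
        n = mat.notna().sum(axis=0)
        mean = mat.mean(axis=0, skipna=True)
        sem = mat.std(axis=0, ddof=1, skipna=True) / np.sqrt(n.clip(lower=1))
        return pd.DataFrame({"offset": self.offsets, "mean": mean.to_numpy(),
                             "sem": sem.to_numpy(), "n": n.to_numpy()})


def metagene_profile(tracks: dict[str, EndCountTrack],
                     genes: dict[str, GeneModel],
                     conditions: dict[str, str],
                     size_factors: pd.Series,
                     offsets: np.ndarray | None = None) -> MetageneMatrix:
    """Per-gene spike-scaled signal on a relative offset grid, per condition.

    ``conditions`` maps sample id -> condition label; replicate samples of a
    condition are averaged.  Minus-strand genes are mirror-mapped so offsets
    always run in the direction of transcription.  Offsets reaching beyond a
    gene's annotated span are masked (NaN) and excluded from profile means.
    """
    if not genes:
        raise ValueError("empty gene set")
    if offsets is None:
        offsets = default_offsets()
    offsets = np.asarray(offsets)
    if (offsets == 0).any():
        raise ValueError("offset grid must not contain position 0")

    gene_list = list(genes.values())
    gene_ids = [g.gene_id for g in gene_list]
    rel_off = np.where(offsets > 0, offsets - 1, offsets)

    per_condition: dict[str, list[np.ndarray]] = {}
    for sid, track in tracks.items():
        cond = conditions[sid]
        sf = float(size_factors[sid])
        rows = np.empty((len(gene_list), offsets.size))
        for i, g in enumerate(gene_list):
            pos = g.tss + rel_off * g.direction
            vals = track.values_at(g.chrom, g.strand, pos) / sf
            mask = (pos < 0) | (offsets > g.length)
            rows[i] = np.where(mask, np.nan, vals)
        per_condition.setdefault(cond, []).append(rows)

    values = {cond: pd.DataFrame(np.nanmean(np.stack(mats), axis=0)
                                 if len(mats) > 1 else mats[0],
                                 index=gene_ids, columns=offsets)
              for cond, mats in per_condition.items()}
    return MetageneMatrix(offsets, values)


@dataclass(frozen=True)
class WindowTestResult:
    mean_diff: float
    t: float
    p: float
    n: int
    degenerate: bool


def window_paired_test(mat_a: pd.DataFrame, mat_b: pd.DataFrame,
                       window: tuple[int, int]) -> WindowTestResult:
    """Two-tailed paired t-test of per-gene window sums, condition B minus A.

    ``mat_a`` and ``mat_b`` are genes x offsets frames on identical grids
    (e.g. two entries of :attr:`MetageneMatrix.values`).  Genes with any
    masked position inside the window are dropped.  A zero-variance
    difference vector is degenerate: t and p are NaN and the flag is set.
    """
    if not mat_a.index.equals(mat_b.index) or not mat_a.columns.equals(mat_b.columns):
        raise ValueError("condition matrices must share genes and offsets")
    lo, hi = window
    cols = [c for c in mat_a.columns if lo <= c <= hi]
    if not cols:
        raise ValueError(f"window {window} selects no offsets")
    a = mat_a[cols]
    b = mat_b[cols]
    ok = a.notna().all(axis=1) & b.notna().all(axis=1)
    d = (b.loc[ok].sum(axis=1) - a.loc[ok].sum(axis=1)).to_numpy()
    n = d.size
    if n < 2:
        raise ValueError(f"need >= 2 genes with defined window sums, got {n}")
    sd = d.std(ddof=1)
    if sd == 0:
        logger.warning("paired window test %s: zero-variance differences", window)
        return WindowTestResult(float(d.mean()), np.nan, np.nan, n, True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return WindowTestResult(float(d.mean()), float(t), float(p), n, False)
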