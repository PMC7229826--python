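"""Peak-set operations, peak-gene assignment, chromatin-feature z-scores,
state overlap, enhancer classification and acetylation-transcription coupling.

All interval logic is half-open with strict >= 1 bp overlap: book-ended
intervals ``[a,b)`` and ``[b,c)`` never overlap, anywhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import EndCountTrack, GeneModel, Interval

logger = logging.getLogger("propause")


# ---------------------------------------------------------------------------
# Peak-set operations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MergedRegion:
    chrom: str
    start: int
    end: int
    #: contributing source peaks as (input set index, peak name)
    sources: tuple[tuple[int, str], ...] = field(default=())


def merge_overlapping_peaks(peak_sets: list[list[Interval]]) -> list[MergedRegion]:
    """Union-merge peaks from several sets wherever they share >= 1 bp.

    A single sorted sweep per chromosome; book-ended peaks stay separate.
    Each merged region records which source peaks (set index, name) it
    absorbed, so differential counts on merged regions can be traced back.
    """
    tagged = [(iv.chrom, iv.start, iv.end, si, iv.name)
              for si, peaks in enumerate(peak_sets) for iv in peaks]
    tagged.sort(key=lambda r: (r[0], r[1], r[2]))
    merged: list[MergedRegion] = []
    cur = None
    for chrom, start, end, si, name in tagged:
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].append((si, name))
        else:
            if cur is not None:
                merged.append(MergedRegion(cur[0], cur[1], cur[2], tuple(cur[3])))
            cur = [chrom, start, end, [(si, name)]]
    if cur is not None:
        merged.append(MergedRegion(cur[0], cur[1], cur[2], tuple(cur[3])))
    return merged


def filter_blacklist(peaks: list[Interval], blacklist: list[Interval]) -> list[Interval]:
    """Drop any peak overlapping a blacklist interval by >= 1 bp."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in blacklist:
        by_chrom.setdefault(b.chrom, []).append((b.start, b.end))
    for spans in by_chrom.values():
        spans.sort()
    kept = []
    for p in peaks:
        spans = by_chrom.get(p.chrom, ())
        hit = any(p.start < e and s < p.end for s, e in spans)
        if not hit:
            kept.append(p)
    n_dropped = len(peaks) - len(kept)
    if n_dropped:
        logger.info("filter_blacklist: dropped %d of %d peaks", n_dropped, len(peaks))
    return kept


def assign_peaks_to_genes(peaks: pd.DataFrame, genes: dict[str, GeneModel],
                          promoter_halfwidth: int = 1000) -> pd.DataFrame:
    """Per gene, the promoter-overlapping peak with the largest |log2fc|.

    ``peaks`` needs columns ``chrom, start, end, peak_id, log2fc``.  A peak
    belongs to a gene when it overlaps ``[tss - hw, tss + hw)``; of several
    only the maximal-|log2fc| peak is kept; genes with no overlapping peak
    are omitted.  Ties break toward the larger signed change, then the
    lexicographically first peak id, for determinism.
    """
    rows = []
    for g in genes.values():
        lo, hi = g.tss - promoter_halfwidth, g.tss + promoter_halfwidth
        hits = peaks[(peaks["chrom"] == g.chrom)
                     & (peaks["start"] < hi) & (peaks["end"] > lo)]
        if hits.empty:
            continue
        best = hits.assign(_abs=hits["log2fc"].abs()).sort_values(
            ["_abs", "log2fc", "peak_id"], ascending=[False, False, True]).iloc[0]
        rows.append({"gene_id": g.gene_id, "peak_id": best["peak_id"],
                     "log2fc": best["log2fc"]})
    return pd.DataFrame(rows, columns=["gene_id", "peak_id", "log2fc"])


# ---------------------------------------------------------------------------
# Enrichment z-scores and state overlap
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentZMatrix:
    """Standardized (z-score) enrichment matrix, genes x features."""

    raw: pd.DataFrame
    z: pd.DataFrame
    constant_features: list[str]

    def set_mean(self, gene_set) -> pd.Series:
        """Mean z-score of a gene set, per feature."""
        return self.z.loc[list(gene_set)].mean(axis=0)


def enrichment_zscores(raw: pd.DataFrame) -> EnrichmentZMatrix:
    """Standardize each feature by subtracting the mean and dividing by the
    sample standard deviation; constant features become all-zero and are
    flagged."""
    if len(raw) < 2:
        raise ValueError("need >= 2 genes to standardize")
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0, ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        logger.warning("enrichment_zscores: constant features %s set to 0", constant)
    z = (raw - mean) / sd.replace(0, np.nan)
    z[constant] = 0.0
    return EnrichmentZMatrix(raw, z, constant)


def state_overlap_fraction(gene_ids, genes: dict[str, GeneModel],
                           states: dict[str, list[Interval]],
                           promoter_halfwidth: int = 500) -> dict[str, float]:
    """Per chromatin state, the fraction of genes whose promoter window
    ``[tss - hw, tss + hw)`` overlaps >= 1 state interval."""
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("empty gene set")
    out = {}
    for state, ivs in states.items():
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in ivs:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        n_hit = 0
        for gid in gene_ids:
            g = genes[gid]
            lo, hi = g.tss - promoter_halfwidth, g.tss + promoter_halfwidth
            n_hit += any(lo < e and s < hi for s, e in by_chrom.get(g.chrom, ()))
        out[state] = n_hit / len(gene_ids)
    return out


# ---------------------------------------------------------------------------
# Enhancer classification
# ---------------------------------------------------------------------------

def classify_enhancers(peaks: pd.DataFrame, genes: dict[str, GeneModel],
                       min_distance: int = 100,
                       anchor: str = "summit") -> pd.Series:
    """Label peaks ``enhancer`` (> ``min_distance`` bp from every TSS) or
    ``promoter-proximal``.

    ``anchor="summit"`` measures |summit - tss| (requires a ``summit``
    column); ``anchor="edge"`` uses the distance from the nearest peak edge.
    """
    if not genes:
        raise ValueError("no genes to measure distance against")
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes.values():
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}

    labels = []
    for row in peaks.itertuples():
        tss = tss_by_chrom.get(row.chrom)
        if tss is None:
            labels.append("enhancer")
            continue
        if anchor == "summit":
            dist = np.abs(tss - row.summit).min()
        elif anchor == "edge":
            left = tss < row.start
            right = tss >= row.end
            dist = 0 if (~left & ~right).any() else min(
                (row.start - tss[left]).min(initial=np.inf),
                (tss[right] - (row.end - 1)).min(initial=np.inf))
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
        labels.append("enhancer" if dist > min_distance else "promoter-proximal")
    return pd.Series(labels, index=peaks.index)


# ---------------------------------------------------------------------------
# Acetylation-transcription coupling
# ---------------------------------------------------------------------------

def fc_correlation(x, y) -> tuple[float, float, int]:
    """Pearson r and Spearman rho between matched fold-change vectors.

    Pairs with non-finite values are dropped (and counted in the log);
    fewer than 3 surviving pairs is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("fold-change vectors must be matched")
    ok = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("fc_correlation: dropped %d undefined pairs", n_dropped)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 finite pairs, got {x.size}")
    r = stats.pearsonr(x, y).statistic
    rho = stats.spearmanr(x, y).statistic
    return float(r), float(rho), int(x.size)


def threshold_gain_set(log2fc: pd.Series, fold: float = 1.5) -> pd.Index:
    """Genes with a strictly greater than ``fold``-fold increase
    (log2fc > log2(fold))."""
    return log2fc.index[log2fc > np.log2(fold)]


def log2_ip_over_input(ip_track: EndCountTrack, input_track: EndCountTrack,
                       chrom: str, start: int, end: int,
                       ip_size_factor: float, input_size_factor: float,
                       pseudocount: float = 1.0,
                       bin_width: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Binned log2 ratio of spike-scaled IP signal over input.

    Per bin: ``log2((ip/s_ip + pc) / (input/s_in + pc))``.  Returns
    (bin start positions, values); both strands are pooled (ChIP fragments
    are unstranded).
    """
    if ip_size_factor <= 0 or input_size_factor <= 0:
        raise ValueError("size factors must be positive")
    ip = ip_track.binned_counts(chrom, start, end, bin_width) / ip_size_factor
    inp = input_track.binned_counts(chrom, start, end, bin_width) / input_size_factor
    values = np.log2((ip + pseudocount) / (inp + pseudocount))
    starts = start + bin_width * np.arange(values.size)
    return starts, values
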