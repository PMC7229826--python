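"""Window counting, TPM, expressed-gene filtering, and the pausing index.

All windows are given in strand-oriented 1-based relative coordinates with
no position 0 (TSS = +1); see :mod:`propause.formats_io`.  The standard
windows are:

* pausing-index promoter window: -50..+100 (150 bp)
* gene-body window (used both for differential testing and as the PI
  denominator): +500..L-100, i.e. 500 bp downstream of the TSS to 100 bp
  upstream of the TES of a gene of length L.

"TPM" here is a region read density: reads per kilobase of window per
million primary-genome mapped reads.  The per-region quantity cannot be the
transcript-sum TPM definition; the density form is what makes the pausing
index depth- and length-invariant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import EndCountTrack, GeneModel

logger = logging.getLogger("propause")

#: PI promoter window, relative inclusive coordinates.
PROMOTER_WINDOW = (-50, 100)
#: Gene-body window start (relative); the end is L - BODY_END_OFFSET.
BODY_START = 500
BODY_END_OFFSET = 100


def body_window(gene: GeneModel, mode: str = "methods") -> tuple[int, int]:
    """Relative gene-body window.

    ``mode="methods"`` ends 100 bp upstream of the TES (+500..L-100, the
    operative definition); ``mode="to_tes"`` runs to the TES (+500..L), the
    variant some figure legends describe.
    """
    if mode == "methods":
        return BODY_START, gene.length - BODY_END_OFFSET
    if mode == "to_tes":
        return BODY_START, gene.length
    raise ValueError(f"unknown body-window mode {mode!r}")


def window_count(track: EndCountTrack, gene: GeneModel,
                 rel_start: int, rel_end: int) -> int:
    """Sum of 3'-end counts on the gene's strand over a relative window.

    The window [rel_start, rel_end] is inclusive in relative coordinates,
    mirror-mapped for minus-strand genes, intersected with chromosome bounds
    (positions < 0 are clipped; a window entirely off-chromosome counts 0
    with a warning).
    """
    lo, hi = gene.rel_window_span(rel_start, rel_end)
    if hi <= 0:
        logger.warning("window %+d..%+d of %s lies entirely outside the "
                       "chromosome; counting 0", rel_start, rel_end, gene.gene_id)
        return 0
    lo = max(lo, 0)
    return track.count_range(gene.chrom, gene.strand, lo, hi)


def region_tpm(count: float, region_length: int, primary_total: int) -> float:
    """Reads per kb of region per million primary-genome mapped reads."""
    if region_length <= 0:
        raise ValueError(f"region_length must be positive, got {region_length}")
    if primary_total <= 0:
        raise ValueError("primary_total must be positive (no mapped reads?)")
    return (count / (region_length / 1e3)) / (primary_total / 1e6)


def filter_expressed(body_tpm: pd.DataFrame, threshold_log2: float = 3.0) -> pd.Index:
    """Genes whose mean log2(TPM+1) across samples exceeds the threshold.

    ``body_tpm`` is genes x samples.  The +1 pseudocount keeps all-zero
    genes finite (and excluded).  Strictly greater than, so a gene sitting
    exactly at the threshold is not called expressed.
    """
    mean_log = np.log2(body_tpm + 1.0).mean(axis=1)
    return body_tpm.index[mean_log > threshold_log2]


@dataclass(frozen=True)
class PausingRow:
    gene_id: str
    promoter_tpm: float
    body_tpm: float
    pi: float          # NaN when undefined
    defined: bool


def pausing_index(track: EndCountTrack, gene: GeneModel,
                  body_mode: str = "methods") -> PausingRow | None:
    """Pausing index: promoter-window TPM over gene-body TPM.

    Returns ``None`` for genes flagged too short for a non-empty body window
    (the caller logs the count).  The PI is flagged undefined (NaN) when the
    body TPM is zero.
    """
    if gene.short:
        return None
    ps, pe = PROMOTER_WINDOW
    bs, be = body_window(gene, body_mode)
    total = track.primary_total
    p_tpm = region_tpm(window_count(track, gene, ps, pe), pe - ps, total)
    b_tpm = region_tpm(window_count(track, gene, bs, be), be - bs + 1, total)
    defined = b_tpm > 0
    return PausingRow(gene.gene_id, p_tpm, b_tpm,
                      p_tpm / b_tpm if defined else math.nan, defined)


def pausing_table(track: EndCountTrack, genes: dict[str, GeneModel],
                  body_mode: str = "methods") -> pd.DataFrame:
    """Per-gene pausing table for one sample; short genes omitted and logged."""
    rows, n_skipped = [], 0
    for gene in genes.values():
        row = pausing_index(track, gene, body_mode)
        if row is None:
            n_skipped += 1
        else:
            rows.append(row)
    if n_skipped:
        logger.warning("pausing_table(%s): %d short genes omitted",
                       track.sample_id, n_skipped)
    return pd.DataFrame(rows).set_index("gene_id")


def body_count_matrix(tracks: dict[str, EndCountTrack],
                      genes: dict[str, GeneModel],
                      body_mode: str = "methods") -> pd.DataFrame:
    """Gene-body window counts, genes x samples; short genes omitted."""
    usable = [g for g in genes.values() if not g.short]
    n_short = len(genes) - len(usable)
    if n_short:
        logger.warning("body_count_matrix: %d short genes omitted", n_short)
    data = {}
    for sid, track in tracks.items():
        data[sid] = [window_count(track, g, *body_window(g, body_mode))
                     for g in usable]
    return pd.DataFrame(data, index=pd.Index([g.gene_id for g in usable],
                                             name="gene_id"))


def body_tpm_matrix(counts: pd.DataFrame, genes: dict[str, GeneModel],
                    primary_totals: pd.Series,
                    body_mode: str = "methods") -> pd.DataFrame:
    """Convert a body count matrix to the TPM density used by the expressed filter."""
    lengths = np.array([(lambda w: w[1] - w[0] + 1)(body_window(genes[g], body_mode))
                        for g in counts.index], dtype=float)
    tpm = counts.div(lengths / 1e3, axis=0)
    return tpm.div(primary_totals.loc[counts.columns] / 1e6, axis=1)
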