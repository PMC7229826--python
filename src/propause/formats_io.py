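"""Reading and writing the standard formats the pipeline touches.

Conventions enforced here and relied on by every other module:

* Genomic coordinates are 0-based, half-open ``[start, end)`` internally and
  in BED/bedGraph files. Any 1-based table is converted at the boundary.
* Relative (gene-anchored) coordinates use the 1-based biology convention
  with no position 0: the TSS is +1, the base immediately upstream is -1,
  and a window like -50..+100 spans 150 bases.  Relative coordinates are
  strand-oriented: on the minus strand they run against the genomic axis.
* Spike-in reads are recognised by a chromosome-name prefix (default
  ``spike_``) rather than by a second genome alignment; a read on a
  spike-prefixed chromosome contributes to the sample's spike-in total and
  to nothing else.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("propause")

__version__ = "0.1.0"

#: Chromosome-name prefix identifying spike-in (foreign-genome) reads.
DEFAULT_SPIKE_PREFIX = "spike_"

#: Genes shorter than this are flagged: the +500..TES-100 body window of a
#: shorter gene is empty, so they are excluded from pausing-index and
#: differential analyses (with a logged count) but retained in annotation.
DEFAULT_MIN_GENE_LENGTH = 700

_STRANDS = ("+", "-")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """One canonical transcript per gene with strand-aware TSS/TES.

    ``tss`` and ``tes`` are 0-based genomic positions of the first and last
    transcribed base; on the minus strand ``tss > tes``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    cds_length: int
    length: int
    transcript_id: str = ""
    short: bool = False

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if self.length < 1:
            raise ValueError(f"gene {self.gene_id} has length {self.length} < 1")
        span = (self.tes - self.tss if self.strand == "+" else self.tss - self.tes) + 1
        if span != self.length:
            raise ValueError(f"gene {self.gene_id}: tss/tes span {span} != length {self.length}")

    @property
    def direction(self) -> int:
        return 1 if self.strand == "+" else -1

    def rel_to_genomic(self, rel: int) -> int:
        """Map a 1-based relative coordinate (no zero) to a genomic position."""
        if rel == 0:
            raise ValueError("relative coordinate 0 does not exist (TSS is +1)")
        off = rel - 1 if rel > 0 else rel
        return self.tss + off * self.direction

    def genomic_to_rel(self, pos: int) -> int:
        """Inverse of :meth:`rel_to_genomic`."""
        d = (pos - self.tss) * self.direction
        return d + 1 if d >= 0 else d

    def rel_window_span(self, rel_start: int, rel_end: int) -> tuple[int, int]:
        """Genomic half-open ``[start, end)`` covering relative ``rel_start..rel_end``.

        Both bounds are inclusive relative coordinates; because there is no
        position 0 the window is genomically contiguous even when it crosses
        the TSS.
        """
        if rel_start == 0 or rel_end == 0:
            raise ValueError("relative coordinates have no position 0")
        if rel_start > rel_end:
            raise ValueError(f"rel_start {rel_start} > rel_end {rel_end}")
        a = self.rel_to_genomic(rel_start)
        b = self.rel_to_genomic(rel_end)
        lo, hi = (a, b) if a <= b else (b, a)
        return lo, hi + 1


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval with BED semantics."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"interval {self.name or ''} [{self.start},{self.end}) is empty")

    def overlaps(self, other: "Interval") -> bool:
        """Strict >=1 bp overlap; book-ended intervals [a,b),[b,c) do not overlap."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


class EndCountTrack:
    """Sparse per-(chromosome, strand) map of base position -> 3' end read count.

    Positions are single bases (the 3' end of each nascent-RNA read, i.e. the
    position of the engaged polymerase).  Counts are stored as parallel sorted
    numpy arrays per (chrom, strand) for fast window queries.
    """

    def __init__(self, sample_id: str = "",
                 data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] | None = None,
                 spike_total: int = 0):
        self.sample_id = sample_id
        self._data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = data or {}
        self.spike_total = int(spike_total)
        self.primary_total = int(sum(int(c.sum()) for _, c in self._data.values()))

    # -- construction -------------------------------------------------------

    @classmethod
    def from_positions(cls, sample_id: str,
                       positions: dict[tuple[str, str], np.ndarray],
                       spike_total: int = 0) -> "EndCountTrack":
        """Build from raw (possibly repeated, unsorted) read positions."""
        data = {}
        for key, pos in positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if pos.size:
                upos, cnt = np.unique(pos, return_counts=True)
                data[key] = (upos, cnt.astype(np.int64))
        return cls(sample_id, data, spike_total)

    # -- queries ------------------------------------------------------------

    def keys(self):
        return self._data.keys()

    def arrays(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        empty = np.empty(0, dtype=np.int64)
        return self._data.get((chrom, strand), (empty, empty))

    def count_range(self, chrom: str, strand: str, start: int, end: int) -> int:
        """Sum of counts at positions in half-open genomic [start, end)."""
        pos, cnt = self.arrays(chrom, strand)
        if pos.size == 0 or start >= end:
            return 0
        i = np.searchsorted(pos, start, side="left")
        j = np.searchsorted(pos, end, side="left")
        return int(cnt[i:j].sum())

    def values_at(self, chrom: str, strand: str, positions: np.ndarray) -> np.ndarray:
        """Counts at each queried genomic position (0 where uncovered)."""
        positions = np.asarray(positions, dtype=np.int64)
        pos, cnt = self.arrays(chrom, strand)
        out = np.zeros(positions.shape, dtype=np.int64)
        if pos.size:
            idx = np.searchsorted(pos, positions, side="left")
            ok = (idx < pos.size)
            ok[ok] &= pos[idx[ok]] == positions[ok]
            out[ok] = cnt[idx[ok]]
        return out

    def binned_counts(self, chrom: str, start: int, end: int, bin_width: int,
                      strand: str | None = None) -> np.ndarray:
        """Per-bin summed counts over [start, end); both strands unless given."""
        n_bins = -(-(end - start) // bin_width)
        out = np.zeros(n_bins, dtype=np.int64)
        strands = (strand,) if strand else _STRANDS
        for s in strands:
            pos, cnt = self.arrays(chrom, s)
            if pos.size == 0:
                continue
            i = np.searchsorted(pos, start, side="left")
            j = np.searchsorted(pos, end, side="left")
            if i < j:
                bins = (pos[i:j] - start) // bin_width
                np.add.at(out, bins, cnt[i:j])
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, EndCountTrack):
            return NotImplemented
        if self.spike_total != other.spike_total or set(self._data) != set(other._data):
            return False
        return all(np.array_equal(self._data[k][0], other._data[k][0])
                   and np.array_equal(self._data[k][1], other._data[k][1])
                   for k in self._data)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_ANNOT_COLS = ["gene_id", "transcript_id", "chrom", "strand",
               "txStart", "txEnd", "cdsStart", "cdsEnd"]


def read_gene_annotation(path, min_length: int = DEFAULT_MIN_GENE_LENGTH) -> dict[str, GeneModel]:
    """Read a transcript table and select one canonical transcript per gene.

    The canonical transcript is the one with the longest CDS; ties are broken
    by the longest transcript, then by the lexicographically smallest
    transcript id.  Genes shorter than ``min_length`` are flagged
    (``GeneModel.short``) but retained.

    The table is tab-separated with header columns ``gene_id, transcript_id,
    chrom, strand, txStart, txEnd, cdsStart, cdsEnd`` (0-based half-open).
    Returns an insertion-ordered dict ``gene_id -> GeneModel``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    dup = df.duplicated(subset=["gene_id", "transcript_id"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValueError(f"duplicate (gene_id, transcript_id) row: "
                         f"({row.gene_id}, {row.transcript_id})")
    bad = ~df["strand"].isin(_STRANDS)
    if bad.any():
        raise ValueError(f"unknown strand symbol {df.loc[bad.idxmax(), 'strand']!r}")

    df = df.assign(cds_len=df.cdsEnd - df.cdsStart, tx_len=df.txEnd - df.txStart)
    # canonical: max CDS, then max transcript length, then min transcript_id
    df = df.sort_values(["gene_id", "cds_len", "tx_len", "transcript_id"],
                        ascending=[True, False, False, True], kind="mergesort")
    canon = df.drop_duplicates("gene_id", keep="first")

    genes: dict[str, GeneModel] = {}
    n_short = 0
    for row in canon.itertuples():
        length = int(row.txEnd - row.txStart)
        if row.strand == "+":
            tss, tes = int(row.txStart), int(row.txEnd) - 1
        else:
            tss, tes = int(row.txEnd) - 1, int(row.txStart)
        short = length < min_length
        n_short += short
        genes[row.gene_id] = GeneModel(
            gene_id=row.gene_id, chrom=row.chrom, strand=row.strand,
            tss=tss, tes=tes, cds_length=int(row.cds_len), length=length,
            transcript_id=str(row.transcript_id), short=short)
    if n_short:
        logger.warning("%d genes shorter than %d bp flagged (excluded from PI/DE)",
                       n_short, min_length)
    return genes


def read_end_counts(path, spike_prefix: str = DEFAULT_SPIKE_PREFIX,
                    sample_id: str | None = None) -> EndCountTrack:
    """Read a BED6 file of single-base 3'-end reads into an :class:`EndCountTrack`.

    Reads on chromosomes whose name starts with ``spike_prefix`` increment the
    spike-in total only; all other reads are accumulated per (chrom, strand)
    base position.  Each record must satisfy ``end == start + 1``.
    """
    positions: dict[tuple[str, str], list[int]] = {}
    spike_total = 0
    if sample_id is None:
        sample_id = str(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 record needs 6 fields, "
                                 f"got {len(fields)}")
            chrom, start, end, _name, _score, strand = fields[:6]
            start, end = int(start), int(end)
            if end != start + 1:
                raise ValueError(f"{path}:{lineno}: 3'-end record must be a single "
                                 f"base (end == start+1), got [{start},{end})")
            if strand not in _STRANDS:
                raise ValueError(f"{path}:{lineno}: missing or invalid strand "
                                 f"{strand!r}")
            if chrom.startswith(spike_prefix):
                spike_total += 1
            else:
                positions.setdefault((chrom, strand), []).append(start)
    arrays = {k: np.asarray(v, dtype=np.int64) for k, v in positions.items()}
    return EndCountTrack.from_positions(sample_id, arrays, spike_total)


def read_bed(path) -> list[Interval]:
    """Read BED3+ intervals (name/score/strand optional)."""
    out: list[Interval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(Interval(
                chrom=f[0], start=int(f[1]), end=int(f[2]),
                name=f[3] if len(f) > 3 else "",
                score=float(f[4]) if len(f) > 4 and f[4] not in (".", "") else 0.0,
                strand=f[5] if len(f) > 5 and f[5] in _STRANDS else None))
    return out


def read_bedgraph(path) -> list[tuple[str, int, int, float]]:
    """Read a bedGraph written by :func:`write_bedgraph` (comments skipped)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")
            out.append((chrom, int(start), int(end), float(value)))
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _header(**params) -> str:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# propause {__version__} {kv}\n"


def write_bedgraph(track: EndCountTrack, path, size_factor: float, strand: str) -> None:
    """Write one strand of a track as spike-in-scaled bedGraph coverage.

    Each covered base is emitted at ``raw_count / size_factor``; adjacent
    bases with equal scaled value are merged into one record; uncovered bases
    are omitted.  Values are printed with 10 significant digits so a
    round-trip read reproduces them at printed precision.
    """
    if size_factor <= 0:
        raise ValueError(f"size_factor must be positive, got {size_factor}")
    if strand not in _STRANDS:
        raise ValueError(f"invalid strand {strand!r}")
    buf = io.StringIO()
    buf.write(_header(format="bedGraph", sample=track.sample_id,
                      size_factor=repr(size_factor), strand=strand))
    chroms = sorted(c for c, s in track.keys() if s == strand)
    for chrom in chroms:
        pos, cnt = track.arrays(chrom, strand)
        if pos.size == 0:
            continue
        # run starts: position not adjacent to previous, or count changes
        brk = np.flatnonzero((np.diff(pos) != 1) | (np.diff(cnt) != 0)) + 1
        starts = np.concatenate(([0], brk))
        ends = np.concatenate((brk, [pos.size]))
        for i, j in zip(starts, ends):
            value = cnt[i] / size_factor
            buf.write(f"{chrom}\t{pos[i]}\t{pos[j - 1] + 1}\t{value:.10g}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_bed(intervals: list[Interval], path, **params) -> None:
    with open(path, "w") as fh:
        fh.write(_header(format="BED", **params))
        for iv in intervals:
            strand = iv.strand or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{strand}\n")


def write_table(df: pd.DataFrame, path, index: bool = False, **params) -> None:
    """Write a TSV with the standard provenance header comment."""
    with open(path, "w") as fh:
        fh.write(_header(format="tsv", **params))
        df.to_csv(fh, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
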