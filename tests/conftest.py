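import numpy as np
import pandas as pd
import pytest

from propause import EndCountTrack, GeneModel


def make_track(records, spike_total=0, sample_id="s1"):
    """Track from (chrom, pos, strand) read records."""
    positions = {}
    for chrom, pos, strand in records:
        positions.setdefault((chrom, strand), []).append(pos)
    arrays = {k: np.asarray(v) for k, v in positions.items()}
    return EndCountTrack.from_positions(sample_id, arrays, spike_total)


def write_bed6(path, records):
    """Write (chrom, start, end, strand) records as BED6."""
    with open(path, "w") as fh:
        for i, (chrom, start, end, strand) in enumerate(records):
            fh.write(f"{chrom}\t{start}\t{end}\tr{i}\t0\t{strand}\n")


@pytest.fixture
def plus_gene():
    return GeneModel(gene_id="gP", chrom="chr2L", strand="+", tss=1000,
                     tes=4598, cds_length=3599, length=3599)


@pytest.fixture
def minus_gene():
    return GeneModel(gene_id="gM", chrom="chr2L", strand="-", tss=5000,
                     tes=1402, cds_length=3599, length=3599)


@pytest.fixture
def annotation_frame():
    """Three genes: multi-transcript CDS selection, a tie, and a singleton."""
    return pd.DataFrame([
        # geneA: CDS 300 vs 900 -> t2
        ("geneA", "t1", "chr2L", "+", 1000, 3000, 1200, 1500),
        ("geneA", "t2", "chr2L", "+", 1000, 4000, 1200, 2100),
        # geneB: equal CDS 600, transcript lengths 2000 vs 1500 -> t3
        ("geneB", "t3", "chr2L", "-", 10000, 12000, 10200, 10800),
        ("geneB", "t4", "chr2L", "-", 10000, 11500, 10300, 10900),
        # geneC: single transcript
        ("geneC", "t5", "chr3R", "+", 500, 5500, 600, 5000),
    ], columns=["gene_id", "transcript_id", "chrom", "strand",
                "txStart", "txEnd", "cdsStart", "cdsEnd"])


@pytest.fixture
def annotation_file(tmp_path, annotation_frame):
    path = tmp_path / "annotation.tsv"
    annotation_frame.to_csv(path, sep="\t", index=False)
    return path
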