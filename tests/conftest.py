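import numpy as np
import pysam
import pytest

from depthcnv import CoverageMatrix, make_binning


@pytest.fixture
def toy_binning():
    """One 1 Mb chromosome tiled at 100 kb: 10 bins."""
    return make_binning([("chr1", 1_000_000)], 100_000)


@pytest.fixture
def tiny_sam(tmp_path, toy_binning):
    """A small SAM exercising every read filter.

    Passing reads: 3 starting inside bin 1, one spanning the bin 0/1
    boundary (counted in bin 0), one clean read in bin 4.  Excluded reads:
    duplicate-flagged, MAPQ 5, unmapped, secondary.
    """
    path = tmp_path / "sample1.sam"
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": "chr1", "LN": 1_000_000}],
        }
    )

    def read(name, pos, *, mapq=60, flag=0):
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.query_sequence = "A" * 50
        a.query_qualities = pysam.qualitystring_to_array("I" * 50)
        a.flag = flag
        a.reference_id = 0 if not flag & 4 else -1
        a.reference_start = pos if not flag & 4 else -1
        a.mapping_quality = mapq
        a.cigarstring = "50M" if not flag & 4 else None
        return a

    reads = [
        read("span_boundary", 99_990),  # starts in bin 0, ends in bin 1
        read("in_bin1_a", 100_000),
        read("in_bin1_b", 150_000),
        read("in_bin1_c", 199_950),
        read("in_bin4", 450_000),
        read("dup", 250_000, flag=1024),
        read("low_mapq", 350_000, mapq=5),
        read("unmapped", 0, flag=4),
        read("secondary", 450_000, flag=256),
    ]
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in sorted(reads, key=lambda a: a.reference_start):
            out.write(a)
    return path


def make_counts(counts, bin_size=100_000, sample_ids=None, chrom="chr1"):
    """CoverageMatrix from a plain 2-D array on a single chromosome."""
    counts = np.asarray(counts)
    n_samples, n_bins = counts.shape
    binning = make_binning([(chrom, n_bins * bin_size)], bin_size)
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n_samples)]
    return CoverageMatrix(sample_ids=sample_ids, binning=binning, counts=counts)
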