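import numpy as np
import pysam
import pytest

from tribepas.simulate import build_toy_genome, make_sample_sheet


@pytest.fixture(scope="session")
def toy_genome():
    return build_toy_genome(seed=7, n_genes=12, decoy_density=0.6)


@pytest.fixture(scope="session")
def sheet_fc():
    """Fusion/control sheet, 3 replicates each."""
    return make_sample_sheet(["fusion", "control"], n_replicates=3, seed=7)


def write_mini_bam(path, contig_lengths, reads):
    """Write a sorted, indexed BAM from (name, contig, start, seq, reverse) tuples."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in contig_lengths.items()],
    }
    tids = {c: i for i, c in enumerate(contig_lengths)}
    unsorted = str(path) + ".unsorted"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
        for name, contig, start, seq, reverse in reads:
            a = pysam.AlignedSegment()
            a.query_name = name
            a.query_sequence = seq
            a.reference_id = tids[contig]
            a.reference_start = start
            a.cigartuples = [(0, len(seq))]
            a.mapping_quality = 60
            a.flag = 16 if reverse else 0
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            bam.write(a)
    pysam.sort("-o", str(path), unsorted)
    pysam.index(str(path))
    return str(path)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
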