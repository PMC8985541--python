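import pathlib

import pysam
import pytest

from riquant.synthetic_data import (
    LocusSet,
    SyntheticConfig,
    make_locus_set,
    simulate_short_reads,
)


def make_sam(path, reads, lengths=None):
    """Write a SAM file from (qname, chrom, pos, cigar, seq, flag[, mapq]) tuples."""
    lengths = lengths or {"c1": 100_000}
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6"},
            "SQ": [{"SN": c, "LN": l} for c, l in sorted(lengths.items())],
        }
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in reads:
            qname, chrom, pos, cigar, seq, flag = rec[:6]
            a = pysam.AlignedSegment(header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = out.get_tid(chrom)
            a.reference_start = pos
            a.mapping_quality = rec[6] if len(rec) > 6 else 60
            a.cigarstring = cigar
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            out.write(a)
    return path


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    return SyntheticConfig(seed=11, n_genes=6, reads_per_gene=200)


@pytest.fixture(scope="session")
def small_locus(small_cfg) -> LocusSet:
    return make_locus_set(small_cfg)


@pytest.fixture(scope="session")
def short_read_paths(small_cfg, small_locus, tmp_path_factory) -> dict[str, pathlib.Path]:
    outdir = tmp_path_factory.mktemp("short_reads")
    return simulate_short_reads(small_cfg, small_locus, outdir)
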