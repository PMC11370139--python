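from __future__ import annotations

import pytest
import pysam

from scallele.variants import VariantSite

SITE = VariantSite("chrS", 1000, "C", "T", id="site1")


@pytest.fixture
def site() -> VariantSite:
    return SITE


def make_bam(path, reads, chrom="chrS", contig_len=5000):
    """Write a small coordinate-sorted indexed BAM from read dicts.

    Each read dict: start (1-based), cigar, seq; optional qual (str or list),
    cb, ub, mapq, flag, name.
    """
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": chrom, "LN": contig_len}]}
    )
    segs = []
    for i, spec in enumerate(reads):
        rec = pysam.AlignedSegment(header)
        rec.query_name = spec.get("name", f"r{i:04d}")
        rec.flag = spec.get("flag", 0)
        rec.reference_id = 0
        rec.reference_start = spec["start"] - 1
        rec.cigarstring = spec["cigar"]
        rec.query_sequence = spec["seq"]
        qual = spec.get("qual", "I" * len(spec["seq"]))
        if isinstance(qual, str):
            rec.query_qualities = pysam.qualitystring_to_array(qual)
        else:
            rec.query_qualities = qual
        rec.mapping_quality = spec.get("mapq", 60)
        if spec.get("cb") is not None:
            rec.set_tag("CB", spec["cb"])
        if spec.get("ub") is not None:
            rec.set_tag("UB", spec["ub"])
        segs.append(rec)
    segs.sort(key=lambda r: r.reference_start)
    path = str(path)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for rec in segs:
            bam.write(rec)
    pysam.index(path)
    return path
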