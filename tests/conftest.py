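import numpy as np
import pysam
import pytest
from hypothesis import settings

from linksv import BarcodeWhitelist, synthetic_whitelist

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def whitelist() -> BarcodeWhitelist:
    # entries at pairwise Hamming distance >= 3, so 1-substitution errors
    # always have a unique closest match
    return synthetic_whitelist(n_per_segment=12, seed=42)


@pytest.fixture()
def sam_factory(tmp_path):
    """Write a small single-chromosome SAM from (start, mapq, flags, bx) tuples."""

    def _write(records, chrom="chr1", length=1_000_000, name="reads.sam"):
        path = tmp_path / name
        header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": length}]}
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for k, (start, mapq, flag, bx) in enumerate(records):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = f"r{k}"
                rec.flag = flag
                rec.reference_id = 0
                rec.reference_start = start
                rec.mapping_quality = mapq
                rec.cigartuples = [(0, 100)]
                rec.query_sequence = "A" * 100
                if bx is not None:
                    rec.set_tag("BX", bx, "Z")
                out.write(rec)
        return str(path)

    return _write
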