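import numpy as np
import pytest

from methylquant.datamodel import Region, SiteCounts


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_site(site_id="s1", chrom="chr1", pos=100, mspi=(5, 3),
              hpaii=None) -> SiteCounts:
    hpaii = hpaii if hpaii is not None else {"lib1": (2, 1)}
    return SiteCounts(
        site_id=site_id, chrom=chrom, pos=pos,
        mspi_fwd=mspi[0], mspi_rev=mspi[1],
        hpaii_fwd={k: v[0] for k, v in hpaii.items()},
        hpaii_rev={k: v[1] for k, v in hpaii.items()},
    )


@pytest.fixture
def two_site_region() -> Region:
    return Region("r1", [
        make_site("s1", pos=100, mspi=(10, 4), hpaii={"lib1": (5, 2)}),
        make_site("s2", pos=150, mspi=(6, 8), hpaii={"lib1": (0, 3)}),
    ])


@pytest.fixture
def tagcount_file(tmp_path):
    """Small tag-count TSV: two regions, one site failing assayability."""
    lines = [
        "chrom\tpos\tregion_id\tsite_id\tmspi_fwd\tmspi_rev\t"
        "hpaii_lib1_fwd\thpaii_lib1_rev",
        "chr1\t100\tr1\ts1\t10\t4\t5\t2",
        "chr1\t150\tr1\ts2\t6\t8\t0\t3",
        "chr1\t900\tr2\ts3\t3\t2\t1\t1",  # not assayable: both strands < 4
        "chr2\t50\tr3\ts4\t4\t0\t2\t2",
    ]
    path = tmp_path / "counts.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path
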