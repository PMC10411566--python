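import pytest

from lsutools import AnchorSpec, MarkerRecord, define_lsus, filter_usable, make_anchor

V5_TABLE = """\
# BUSCO version is: 5.4.3
# The lineage dataset is: synthetic_odb
# Busco id\tStatus\tSequence\tGene Start\tGene End\tStrand\tScore\tLength
1at7088\tComplete\tChr1\t100\t200\t+\t500.0\t100
2at7088\tMissing
3at7088\tDuplicated\tChr1\t300\t400\t-\t450.1\t100
3at7088\tDuplicated\tChr2\t10\t90\t+\t440.0\t80
4at7088\tFragmented\tChr2\t500\t600\t+\t100.0\t50
"""


@pytest.fixture
def v5_table_text():
    return V5_TABLE


@pytest.fixture(scope="session")
def small_anchor():
    """5 chromosomes x 40 markers: fast enough for per-test pipelines."""
    return make_anchor(AnchorSpec(n_chromosomes=5, markers_per_chromosome=40, seed=11))


@pytest.fixture(scope="session")
def small_units(small_anchor):
    return define_lsus(filter_usable(small_anchor), anchor_name="small")


@pytest.fixture(scope="session")
def study_anchor():
    """Full study-scale anchor: 31 chromosomes x 170 markers (Z last)."""
    return make_anchor(AnchorSpec(seed=42))


@pytest.fixture(scope="session")
def study_units(study_anchor):
    return define_lsus(filter_usable(study_anchor), anchor_name="study")


def make_record(marker_id="1at0", status="Complete", sequence_id="Chr1",
                start=100, end=200, **kwargs):
    if status == "Missing":
        return MarkerRecord(marker_id=marker_id, status=status)
    return MarkerRecord(marker_id=marker_id, status=status, sequence_id=sequence_id,
                        start=start, end=end, **kwargs)
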