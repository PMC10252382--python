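import numpy as np
import pysam
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_genome():
    """Genome whose contig midpoints hit folded distances 0 and 1 exactly
    at 20 contigs (length 2000, ori at 50)."""
    from ptrmetab.synthetic import GenomeModel

    return GenomeModel(length=2000, ori_position=50)


def write_sam(path, genome_length, records):
    """Write a minimal SAM: records are (start, aligned_length, mapq, nm)."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": "ref", "LN": int(genome_length)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i, (start, alen, mapq, nm) in enumerate(records):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"r{i:06d}"
            a.reference_id = 0
            a.reference_start = int(start)
            a.flag = 0
            a.mapping_quality = int(mapq)
            a.cigarstring = f"{int(alen)}M"
            a.query_sequence = "A" * int(alen)
            a.set_tag("NM", int(nm))
            fh.write(a)
    return path


@pytest.fixture
def sam_writer():
    return write_sam


@pytest.fixture(scope="session")
def default_metabolome():
    """One medium synthetic metabolome shared across read-only tests."""
    from ptrmetab.synthetic import MetabolomeScenario, simulate_metabolome

    scenario = MetabolomeScenario(n_metabolites=200, seed=5)
    table, community, truth = simulate_metabolome(scenario)
    return scenario, table, community, truth
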