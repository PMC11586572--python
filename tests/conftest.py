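import pytest
from hypothesis import HealthCheck, settings

from triomap.simulate import SimConfig, emit_table2_fixture, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1,length=100000000>
##contig=<ID=2,length=100000000>
##contig=<ID=12,length=100000000>
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


@pytest.fixture
def make_vcf(tmp_path):
    """Write a small VCF from data lines and sample names; returns the path."""

    def _make(lines, samples=("case1", "dam1", "sire"), name="test.vcf"):
        path = tmp_path / name
        body = VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        body += "\t".join(samples) + "\n"
        for line in lines:
            body += line.replace(" ", "\t") + "\n"
        path.write_text(body)
        return path

    return _make


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort under the default study conditions."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def table2():
    """Deterministic two-locus carrier-screen fixture."""
    return emit_table2_fixture()
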