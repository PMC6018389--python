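import pytest
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
def fastq_text():
    """Hand-written FASTQ corpus with the classic traps: a quality line
    starting with '@' and a wrapped record."""
    return (
        "@r1 spot=1\n"
        "ACGT\n"
        "+\n"
        "@AAA\n"
        "@r2 spot=2\n"
        "ACGTAC\n"
        "GTAC\n"
        "+\n"
        "IIIII\n"
        "IIIII\n"
        "@r3 spot=3\n"
        "GGCC\n"
        "+\n"
        "!!!!\n"
    )


@pytest.fixture
def tinyseq_xml():
    return (
        '<?xml version="1.0"?>\n'
        "<TSeqSet>\n"
        "<TSeq>\n"
        '  <TSeq_seqtype value="nucleotide"/>\n'
        "  <TSeq_accver>NC_000001.1</TSeq_accver>\n"
        "  <TSeq_taxid>9606</TSeq_taxid>\n"
        "  <TSeq_orgname>Homo sapiens</TSeq_orgname>\n"
        "  <TSeq_defline>test chromosome</TSeq_defline>\n"
        "  <TSeq_length>4</TSeq_length>\n"
        "  <TSeq_sequence>AC\nGT</TSeq_sequence>\n"
        "</TSeq>\n"
        "</TSeqSet>\n"
    )
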