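from pathlib import Path

import pytest

import ribosig as rs

REPO = Path(__file__).resolve().parent.parent
EXAMPLES = REPO / "examples"


@pytest.fixture(scope="session")
def examples_dir() -> Path:
    return EXAMPLES


@pytest.fixture(scope="session")
def demo_alignment():
    return rs.read_alignment(EXAMPLES / "demo_alignment.fasta")


@pytest.fixture(scope="session")
def demo_groups():
    return rs.read_group_map(EXAMPLES / "demo_groups.tsv")


@pytest.fixture
def toy_alignment():
    """9 taxa x 8 columns, three groups of three, hand-designed."""
    records = [
        ("b1", "GCAACGTT"),
        ("b2", "GCAACGTT"),
        ("b3", "GCATCGTT"),
        ("a1", "GGA-CGAT"),
        ("a2", "GGA-CGAT"),
        ("a3", "GGA-CGAT"),
        ("e1", "GGA-CCAT"),
        ("e2", "GGA-CTAT"),
        ("e3", "GGA-CYAT"),
    ]
    aln = rs.Alignment.from_records(records)
    gmap = rs.GroupMap(
        {t: {"b": "Bacteria", "a": "Archaea", "e": "Eukaryota"}[t[0]]
         for t, _ in records}
    )
    return aln, gmap
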