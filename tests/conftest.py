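import textwrap

import pytest

from mitochar.datasets import moschiola_feature_table
from mitochar.simulate import default_spec, simulate_genome


@pytest.fixture(scope="session")
def moschiola():
    """The published M. indica annotation (coordinate-only)."""
    return moschiola_feature_table()


@pytest.fixture(scope="session")
def synthetic():
    """Default tragulid-like synthetic genome plus its ground-truth ledger."""
    return simulate_genome(default_spec(seed=11))


# A minimal but well-formed GenBank record: forward CDS (ND5 dialect name),
# reverse CDS, a tRNA with anticodon, and a D-loop.
TINY_GENBANK = textwrap.dedent(
    """\
    LOCUS       TEST0001                 210 bp    DNA     circular VRT 01-JAN-2000
    DEFINITION  synthetic test record.
    ACCESSION   TEST0001
    VERSION     TEST0001.1
    SOURCE      synthetic construct
      ORGANISM  synthetic construct
    FEATURES             Location/Qualifiers
         source          1..210
                         /organism="synthetic construct"
         tRNA            1..30
                         /gene="tRNA-Phe"
                         /product="tRNA-Phe"
         CDS             31..90
                         /gene="ND5"
         CDS             complement(91..150)
                         /gene="ND6"
         D-loop          151..210
    ORIGIN
            1 atgcatgcat gcatgcatgc atgcatgcat atgaaaccca aacccaaacc caaaccctaa
           61 atgaaaccca aacccaaacc caaaccctaa ttagggtttg ggtttgggtt tgggtttcat
          121 ttagggtttg ggtttgggtt tgggtttcat acgtacgtac gtacgtacgt acgtacgtac
          181 gtacgtacgt acgtacgtac gtacgtacgt
    //
    """
)


@pytest.fixture()
def tiny_genbank(tmp_path):
    p = tmp_path / "tiny.gb"
    p.write_text(TINY_GENBANK)
    return p
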