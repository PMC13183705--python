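import sys
from pathlib import Path

import pytest

from igconvert.germline import GeneOrderTable, GermlineGene, GermlineSet

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py


@pytest.fixture
def toy_gset() -> GermlineSet:
    """Hand-built locus: P1 (rank 1) < F (rank 2) < P2 (rank 3).

    P1 carries a perfect implant site for F: identical 6-nt 5' anchor,
    3-nt divergent tract at [16, 19), identical 1-nt 3' anchor.
    """
    f_seq = "ACGTACGTAC" + "GGATCC" + "AAA" + "T" + "ACGTACGTACGTACGTACGT"
    p1_seq = "TGCAGTCAGT" + "GGATCC" + "CCC" + "T" + "TGCATGCATGCATGCATGCA"
    p2_seq = "GTCAGTCAGT" + "CCTAGG" + "GGG" + "A" + "CATGCATGCATGCATGCATG"
    genes = [
        GermlineGene("IGHV1-2", "*01", "F", f_seq, leader_seq="ATGGACTGGACCTGGAGG"),
        GermlineGene("IGHV1-1", "*01", "P", p1_seq, leader_seq="CCCCACTGGACCTGGAGG"),
        GermlineGene("IGHV1-3", "*01", "P", p2_seq, leader_seq="ATGGACTGGACCTGGAGC"),
    ]
    order = GeneOrderTable({"IGHV1-1": 1, "IGHV1-2": 2, "IGHV1-3": 3})
    return GermlineSet(genes=genes, order=order)


@pytest.fixture
def germline_files(tmp_path):
    """Write a minimal 1F + 1P FASTA/order pair; returns the two paths."""
    fasta = tmp_path / "germline.fasta"
    fasta.write_text(
        ">IGHV4-21*01|F\nACGTACGTACGT\n"
        ">IGHV4-11*01|P\nACGTACCTACGT\n"
    )
    order = tmp_path / "order.tsv"
    order.write_text("gene_name\tposition\tstrand\nIGHV4-11\t1\t+\nIGHV4-21\t2\t+\n")
    return fasta, order
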