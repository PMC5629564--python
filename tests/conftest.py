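"""Shared fixtures: tiny hand-traced SAM/GTF/BED files written at test time."""

from __future__ import annotations

import textwrap

import pytest

SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:10000\n"


def _sam_line(qname, flag, pos, cigar, rname="chr1", mapq=60):
    if flag & 4:
        return f"{qname}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t*\t*"
    return f"{qname}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t*\t*"


@pytest.fixture
def gene_gtf(tmp_path):
    """Two genes on chr1 (+): geneA exons 101-200 & 301-400, geneB 501-600."""
    text = textwrap.dedent("""\
        chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "geneA"; transcript_id "tA";
        chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "geneA"; transcript_id "tA";
        chr1\tsrc\texon\t501\t600\t.\t+\t.\tgene_id "geneB"; transcript_id "tB";
    """)
    path = tmp_path / "genes.gtf"
    path.write_text(text)
    return path


@pytest.fixture
def three_read_sam(tmp_path):
    """read1 inside geneA; read2 spliced across geneA and geneB exons
    (ambiguous); read3 unmapped."""
    lines = [
        _sam_line("r1", 0, 120, "50M"),
        _sam_line("r2", 0, 380, "30M91N20M"),  # blocks [379,409) + [500,520)
        _sam_line("r3", 4, 0, "*"),
    ]
    path = tmp_path / "reads.sam"
    path.write_text(SAM_HEADER + "\n".join(lines) + "\n")
    return path


@pytest.fixture
def empty_sam(tmp_path):
    path = tmp_path / "empty.sam"
    path.write_text(SAM_HEADER)
    return path


@pytest.fixture
def apa_bed(tmp_path):
    """geneC: PRE [1000,1200) (200 bp), POST [1200,1250) (50 bp)."""
    text = (
        "chr1\t1000\t1200\tgeneC_PRE\t0\t+\n"
        "chr1\t1200\t1250\tgeneC_POST\t0\t+\n"
    )
    path = tmp_path / "apa.bed"
    path.write_text(text)
    return path


@pytest.fixture
def apa_sam(tmp_path):
    """Five reads against the geneC PRE/POST layout.

    Hand trace: a1 PRE-only, a2 straddles the PRE/POST boundary (counts PRE
    only), a3+a4 POST-only, a5 upstream of both -> (r_pre, r_post) = (2, 2).
    """
    lines = [
        _sam_line("a5", 0, 951, "40M"),   # [950, 990) - neither
        _sam_line("a1", 0, 1051, "50M"),  # [1050, 1100) - PRE
        _sam_line("a2", 0, 1191, "50M"),  # [1190, 1240) - PRE and POST
        _sam_line("a3", 0, 1206, "20M"),  # [1205, 1225) - POST
        _sam_line("a4", 0, 1211, "30M"),  # [1210, 1240) - POST
    ]
    path = tmp_path / "apa.sam"
    path.write_text(SAM_HEADER + "\n".join(lines) + "\n")
    return path
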