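"""Shared fixtures: in-memory transcript builders and tiny on-disk annotations."""

from __future__ import annotations

from pathlib import Path

import pytest
from Bio.Seq import Seq

from utrindel.annotation_io import TranscriptModel

VALID_CDS = "ATGAAATAA"  # ATG AAA TAA: minimal valid CDS


def make_transcript(utr5: str, cds: str = VALID_CDS, *,
                    transcript_id: str = "tx1", gene_id: str = "g1",
                    species: str = "sp", chrom: str = "chr1",
                    offset: int = 0) -> TranscriptModel:
    """Plus-strand single-exon transcript embedded at a genomic offset."""
    start, end = offset, offset + len(utr5) + len(cds)
    return TranscriptModel(
        gene_id=gene_id, transcript_id=transcript_id, species=species,
        chrom=chrom, strand="+", exons=((start, end),),
        tis_offset=len(utr5), utr5_seq=utr5, cds_seq=cds,
        utr_genomic=((start, start + len(utr5)),),
        cds_genomic=((start + len(utr5), end),),
    )


def write_annotation(tmp_path: Path, name: str, spliced: str, tis: int,
                     strand: str = "+", gene_id: str = "g1",
                     transcript_id: str = "tx1") -> tuple[Path, Path]:
    """One single-exon gene as GTF + genome FASTA; minus-strand genes are
    embedded as the reverse complement."""
    length = len(spliced)
    genome = spliced if strand == "+" else str(Seq(spliced).reverse_complement())
    if strand == "+":
        cds_lo, cds_hi = tis + 1, length          # 1-based inclusive
    else:
        cds_lo, cds_hi = 1, length - tis
    fasta = tmp_path / f"{name}.fa"
    gtf = tmp_path / f"{name}.gtf"
    fasta.write_text(f">chr1\n{genome}\n")
    attrs = f'gene_id "{gene_id}"; transcript_id "{transcript_id}";'
    gtf.write_text(
        f"chr1\ttoy\texon\t1\t{length}\t.\t{strand}\t.\t{attrs}\n"
        f"chr1\ttoy\tCDS\t{cds_lo}\t{cds_hi}\t.\t{strand}\t0\t{attrs}\n")
    return gtf, fasta


@pytest.fixture
def toy_utr13() -> str:
    # 13 nt, ATG-free
    return "CCTTCCTTCCTTC"
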