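"""Transcript models from GTF + FASTA, and per-gene transcript selection.

Coordinates are 0-based half-open genomic; transcript coordinates are 0-based
offsets from the cap on the spliced transcript. Minus-strand transcripts are
reverse-complemented on loading so every downstream module works in cap->3'
orientation.

The GTF dialect is Ensembl-style (``gene_id``/``transcript_id`` attributes,
``exon`` and ``CDS`` features). CDS features are expected to include the
terminal stop codon; if separate ``stop_codon`` features are present they are
merged into the CDS. Transcripts violating the model invariants (no 5'UTR, CDS
not starting with ATG, internal in-frame stop, missing terminal stop, length
not a multiple of 3) are treated as misannotated: excluded and counted, never
fatal.
"""

from __future__ import annotations

import collections
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio.Seq import Seq
from pyfaidx import Fasta

from ._util import (
    ConfigError,
    DataError,
    Interval,
    intervals_overlap,
    log,
    merge_intervals,
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """One spliced protein-coding transcript in cap->3' orientation."""

    gene_id: str
    transcript_id: str
    species: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]       # genomic, ordered 5'->3' on the transcript strand
    tis_offset: int                   # first CDS base, spliced-transcript coords
    utr5_seq: str
    cds_seq: str
    utr_genomic: tuple[Interval, ...] = ()   # genomic footprint of the 5'UTR
    cds_genomic: tuple[Interval, ...] = ()   # genomic footprint of the CDS

    @property
    def utr5_len(self) -> int:
        return len(self.utr5_seq)

    def genomic_span(self) -> Interval:
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        return lo, hi


@dataclass
class GeneIsoformSet:
    """All retained isoforms of one gene plus their joint CDS footprint."""

    gene_id: str
    isoforms: list[TranscriptModel]

    @property
    def cds_genomic_footprint(self) -> list[Interval]:
        return merge_intervals(
            iv for t in self.isoforms for iv in t.cds_genomic
        )

    def cds_footprint_excluding(self, transcript_id: str) -> list[Interval]:
        return merge_intervals(
            iv
            for t in self.isoforms
            if t.transcript_id != transcript_id
            for iv in t.cds_genomic
        )


@dataclass(frozen=True)
class OrthologPair:
    gene_id_species1: str
    gene_id_species2: str
    relationship: str = "one-to-one"


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _spliced_sequence(genome: Fasta, chrom: str, strand: str,
                      intervals: Sequence[Interval]) -> str:
    """Concatenated sequence of genomic intervals in transcript orientation."""
    try:
        seqs = [str(genome[chrom][s:e]) for s, e in sorted(intervals)]
    except KeyError as exc:
        raise DataError(f"sequence missing for chromosome {chrom!r}") from exc
    plus = "".join(seqs).upper()
    if strand == "-":
        return str(Seq(plus).reverse_complement())
    return plus


def _cds_is_sane(cds: str) -> str | None:
    """Return a rejection reason for a bad CDS, or None if it is valid."""
    if len(cds) < 6 or len(cds) % 3 != 0:
        return "cds_bad_length"
    if not cds.startswith("ATG"):
        return "cds_no_start_atg"
    if cds[-3:] not in STOP_CODONS:
        return "cds_no_terminal_stop"
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] in STOP_CODONS:
            return "cds_internal_stop"
    return None


def load_transcripts(gtf_path: str | Path, fasta_path: str | Path,
                     species: str,
                     allow_list: Iterable[str] | None = None,
                     ) -> list[TranscriptModel]:
    """Build TranscriptModels from a GTF + genome FASTA.

    Only transcripts passing all model invariants are returned; counts of
    rejections per filter are logged. A chromosome referenced by the GTF but
    absent from the FASTA is a hard error.
    """
    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genome = Fasta(str(fasta_path), sequence_always_upper=True)
    allowed = set(allow_list) if allow_list is not None else None

    by_tx: dict[str, dict[str, list]] = collections.defaultdict(
        lambda: {"exon": [], "CDS": [], "stop_codon": [], "meta": None}
    )
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        tid = feat.attributes["transcript_id"][0]
        rec = by_tx[tid]
        rec[feat.featuretype].append((feat.start - 1, feat.end))  # GTF is 1-based closed
        rec["meta"] = (feat.attributes["gene_id"][0], feat.seqid, feat.strand)

    rejections: collections.Counter[str] = collections.Counter()
    models: list[TranscriptModel] = []
    for tid in sorted(by_tx):
        rec = by_tx[tid]
        if allowed is not None and tid not in allowed:
            rejections["not_in_allow_list"] += 1
            continue
        gene_id, chrom, strand = rec["meta"]
        if chrom not in genome:
            raise DataError(f"sequence missing for chromosome {chrom!r} "
                            f"(transcript {tid})")
        if not rec["CDS"]:
            rejections["non_coding"] += 1
            continue
        exons = merge_intervals(rec["exon"])
        cds_iv = merge_intervals(rec["CDS"] + rec["stop_codon"])
        spliced = _spliced_sequence(genome, chrom, strand, exons)
        cds_seq = _spliced_sequence(genome, chrom, strand, cds_iv)

        # TIS offset: spliced position of the first CDS base in transcript
        # orientation (leftmost CDS base on '+', rightmost on '-').
        tis = 0
        if strand == "+":
            cds_first = min(s for s, _ in cds_iv)
            for s, e in exons:
                if cds_first >= e:
                    tis += e - s
                elif cds_first >= s:
                    tis += cds_first - s
                    break
        else:
            cds_last = max(e for _, e in cds_iv)
            for s, e in sorted(exons, reverse=True):
                if cds_last <= s:
                    tis += e - s
                elif cds_last <= e:
                    tis += e - cds_last
                    break

        if tis < 1:
            rejections["no_utr5"] += 1
            continue
        reason = _cds_is_sane(cds_seq)
        if reason is not None:
            rejections[reason] += 1
            continue
        utr5 = spliced[:tis]
        if spliced[tis : tis + len(cds_seq)] != cds_seq:
            # CDS not contiguous with the exon chain as annotated
            rejections["cds_inconsistent_with_exons"] += 1
            continue

        utr_genomic, cds_genomic = _split_footprints(exons, cds_iv, strand, tis)
        tx_exons = tuple(sorted(exons, reverse=(strand == "-")))
        models.append(TranscriptModel(
            gene_id=gene_id, transcript_id=tid, species=species,
            chrom=chrom, strand=strand, exons=tx_exons, tis_offset=tis,
            utr5_seq=utr5, cds_seq=cds_seq,
            utr_genomic=tuple(utr_genomic), cds_genomic=tuple(cds_genomic),
        ))

    if rejections:
        log.info("load_transcripts(%s): kept %d, rejected %s",
                 species, len(models), dict(rejections))
    else:
        log.info("load_transcripts(%s): kept %d", species, len(models))
    return models


def _split_footprints(exons: list[Interval], cds_iv: list[Interval],
                      strand: str, tis: int,
                      ) -> tuple[list[Interval], list[Interval]]:
    """Genomic footprints of the 5'UTR (exonic bases 5' of the CDS) and CDS."""
    if strand == "+":
        cds_first = min(s for s, _ in cds_iv)
        utr = [(s, min(e, cds_first)) for s, e in exons if s < cds_first]
    else:
        cds_last = max(e for _, e in cds_iv)
        utr = [(max(s, cds_last), e) for s, e in exons if e > cds_last]
    return merge_intervals(utr), merge_intervals(cds_iv)


def group_by_gene(transcripts: Iterable[TranscriptModel]) -> list[GeneIsoformSet]:
    by_gene: dict[str, list[TranscriptModel]] = collections.defaultdict(list)
    for t in transcripts:
        by_gene[t.gene_id].append(t)
    return [GeneIsoformSet(g, sorted(ts, key=lambda t: t.transcript_id))
            for g, ts in sorted(by_gene.items())]


# ---------------------------------------------------------------------------
# transcript selection (one isoform per gene)
# ---------------------------------------------------------------------------

SELECTION_CRITERIA = ("random", "longest_utr", "pure_utr")


def select_transcript(gene: GeneIsoformSet, criterion: str,
                      seed: int = 0) -> TranscriptModel | None:
    """Pick one isoform per gene.

    random
        uniform seeded choice (reproducible);
    longest_utr
        maximal 5'UTR length, ties broken by transcript_id;
    pure_utr
        among isoforms whose 5'UTR genomic footprint avoids the CDS footprint
        of every *other* isoform of the same gene, the one with the longest
        5'UTR (same tie-break); None if no isoform qualifies.
    """
    if criterion not in SELECTION_CRITERIA:
        raise ConfigError(f"unknown selection criterion {criterion!r}; "
                          f"expected one of {SELECTION_CRITERIA}")
    if not gene.isoforms:
        return None
    if criterion == "random":
        rng = random.Random((seed, gene.gene_id).__str__())
        return rng.choice(sorted(gene.isoforms, key=lambda t: t.transcript_id))
    if criterion == "longest_utr":
        return _longest(gene.isoforms)
    pure = [
        t for t in gene.isoforms
        if not intervals_overlap(t.utr_genomic,
                                 gene.cds_footprint_excluding(t.transcript_id))
    ]
    return _longest(pure) if pure else None


def _longest(isoforms: Sequence[TranscriptModel]) -> TranscriptModel:
    # longest 5'UTR; ties broken by lexicographically smallest transcript_id
    return min(isoforms, key=lambda t: (-t.utr5_len, t.transcript_id))


# ---------------------------------------------------------------------------
# writing / tables / orthologs
# ---------------------------------------------------------------------------

def write_transcript_annotation(transcripts: Sequence[TranscriptModel],
                                gtf_path: str | Path,
                                fasta_path: str | Path) -> None:
    """Serialize models as single-exon genes on per-transcript contigs.

    Intron structure is not preserved (it is irrelevant to every downstream
    stage, which work in spliced coordinates); reloading reproduces utr5_seq,
    cds_seq and tis_offset exactly.
    """
    with open(fasta_path, "w") as fa:
        for t in transcripts:
            fa.write(f">{t.transcript_id}\n{t.utr5_seq}{t.cds_seq}\n")
    with open(gtf_path, "w") as gtf:
        for t in transcripts:
            end = t.tis_offset + len(t.cds_seq)
            attrs = (f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";')
            gtf.write(f"{t.transcript_id}\tutrindel\texon\t1\t{end}\t.\t+\t.\t{attrs}\n")
            gtf.write(f"{t.transcript_id}\tutrindel\tCDS\t{t.tis_offset + 1}\t{end}"
                      f"\t.\t+\t0\t{attrs}\n")


def transcript_table(transcripts: Sequence[TranscriptModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in transcripts],
            "transcript_id": [t.transcript_id for t in transcripts],
            "species": [t.species for t in transcripts],
            "chrom": [t.chrom for t in transcripts],
            "strand": [t.strand for t in transcripts],
            "utr5_len": [t.utr5_len for t in transcripts],
            "cds_len": [len(t.cds_seq) for t in transcripts],
        }
    )


def load_orthologs(tsv_path: str | Path) -> list[OrthologPair]:
    """Two-column TSV with a header line; each gene may appear only once."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"ortholog table {tsv_path} needs two columns")
    col1, col2 = df.columns[:2]
    for col in (col1, col2):
        dup = df[col][df[col].duplicated()]
        if not dup.empty:
            raise DataError(
                f"gene {dup.iloc[0]!r} appears in more than one ortholog pair")
    return [OrthologPair(a, b) for a, b in zip(df[col1], df[col2])]


def load_allow_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
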