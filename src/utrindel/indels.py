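"""Alignment-quality filters and indel extraction from pairwise alignments.

Gaps are read from MAF blocks of a pairwise genomic alignment. A maximal run
of gap characters in either row is one indel; insertions and deletions are
pooled (a pairwise alignment cannot tell them apart). Each indel is anchored
to a single point: the ungapped reference coordinate of the first reference
base following the run, converted to a spliced 5'UTR offset of the annotated
transcript. Indels longer than 100 bp are discarded (counted, not fatal);
indels outside the 5'UTR are dropped.

A gene enters the catalogue only if (a) the alignable sequence of each
species covers strictly more than 80% of the other species' annotated exonic
bases, and (b) the alignment covers every base of the annotated 5'UTR.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO

from ._util import DataError, Interval, intersect_length, log, total_length
from .annotation_io import TranscriptModel

MAX_INDEL_NT = 100


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentBlock:
    """One pairwise MAF block; reference coordinates are plus-strand."""

    ref_species: str
    ref_chrom: str
    ref_start: int
    ref_end: int
    ref_text: str
    other_species: str
    other_chrom: str
    other_start: int
    other_end: int
    other_text: str
    other_strand: str = "+"
    other_src_size: int = 0

    def __post_init__(self):
        if len(self.ref_text) != len(self.other_text):
            raise DataError("alignment rows differ in length "
                            f"({self.ref_chrom}:{self.ref_start})")
        ungapped = sum(c != "-" for c in self.ref_text)
        if ungapped != self.ref_end - self.ref_start:
            raise DataError("reference row ungapped length does not match "
                            f"coordinates ({self.ref_chrom}:{self.ref_start})")


@dataclass
class IndelRecord:
    """One alignment gap mapped to an ungapped 5'UTR coordinate."""

    transcript_id: str
    utr_offset: int
    length_nt: int
    size_class: str = field(init=False)   # "n3n" | "3n"
    side: str | None = None               # filled by partition_indels

    def __post_init__(self):
        self.size_class = "3n" if self.length_nt % 3 == 0 else "n3n"


@dataclass(frozen=True)
class IndelCounts:
    """Indels tallied by size class and side of the reference point."""

    n_n3n_down: int = 0
    n_3n_down: int = 0
    n_n3n_up: int = 0
    n_3n_up: int = 0

    @property
    def total(self) -> int:
        return self.n_n3n_down + self.n_3n_down + self.n_n3n_up + self.n_3n_up

    def swapped(self) -> "IndelCounts":
        return IndelCounts(self.n_n3n_up, self.n_3n_up,
                           self.n_n3n_down, self.n_3n_down)


# ---------------------------------------------------------------------------
# MAF input
# ---------------------------------------------------------------------------

def read_maf(path: str | Path, ref_species: str) -> list[AlignmentBlock]:
    """Read a pairwise MAF; the row whose src starts with ref_species is the
    reference and must be on the plus strand."""
    blocks: list[AlignmentBlock] = []
    for msa in AlignIO.parse(str(path), "maf"):
        if len(msa) != 2:
            raise DataError(f"MAF block with {len(msa)} rows; expected 2")
        rows = {}
        for rec in msa:
            species, _, chrom = rec.id.partition(".")
            ann = rec.annotations
            strand = "+" if ann["strand"] == 1 else "-"
            rows[species] = (chrom, int(ann["start"]), int(ann["size"]),
                             strand, int(ann["srcSize"]), str(rec.seq).upper())
        if ref_species not in rows:
            raise DataError(f"MAF block lacks reference species {ref_species!r}")
        (other_sp,) = [s for s in rows if s != ref_species]
        rchrom, rstart, rsize, rstrand, _, rtext = rows[ref_species]
        ochrom, ostart, osize, ostrand, osrc, otext = rows[other_sp]
        if rstrand != "+":
            raise DataError("reference MAF row must be plus-strand")
        blocks.append(AlignmentBlock(
            ref_species=ref_species, ref_chrom=rchrom,
            ref_start=rstart, ref_end=rstart + rsize, ref_text=rtext,
            other_species=other_sp, other_chrom=ochrom,
            other_start=ostart, other_end=ostart + osize, other_text=otext,
            other_strand=ostrand, other_src_size=osrc,
        ))
    return blocks


# ---------------------------------------------------------------------------
# alignment-quality filters
# ---------------------------------------------------------------------------

EXON_OVERLAP_MIN = 0.80


def _check_no_overlap(blocks: Sequence[AlignmentBlock]) -> None:
    spans = sorted((b.ref_start, b.ref_end) for b in blocks)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise DataError("alignment blocks overlap on the reference "
                            f"({s2} < {e1})")


def _aligned_intervals_ref(block: AlignmentBlock) -> list[Interval]:
    """Reference genomic intervals of columns where the other row is aligned."""
    out: list[Interval] = []
    g = block.ref_start
    run_start = None
    for rc, oc in zip(block.ref_text, block.other_text):
        if rc == "-":
            continue
        if oc != "-":
            if run_start is None:
                run_start = g
        elif run_start is not None:
            out.append((run_start, g))
            run_start = None
        g += 1
    if run_start is not None:
        out.append((run_start, g))
    return out


def _aligned_intervals_other(block: AlignmentBlock) -> list[Interval]:
    """Other-species genomic (plus-strand) intervals of columns where the
    reference row is aligned."""
    segs: list[Interval] = []
    p = block.other_start  # strand coordinates
    run_start = None
    for rc, oc in zip(block.ref_text, block.other_text):
        if oc == "-":
            continue
        if rc != "-":
            if run_start is None:
                run_start = p
        elif run_start is not None:
            segs.append((run_start, p))
            run_start = None
        p += 1
    if run_start is not None:
        segs.append((run_start, p))
    if block.other_strand == "-":
        n = block.other_src_size
        segs = [(n - e, n - s) for s, e in segs]
    return segs


def filter_alignments(blocks: Sequence[AlignmentBlock],
                      transcript: TranscriptModel,
                      ortholog_transcript: TranscriptModel,
                      ) -> tuple[list[AlignmentBlock] | None, str | None]:
    """Apply the exon-overlap and full-5'UTR-coverage filters.

    Returns (blocks, None) on acceptance or (None, reason) on rejection.
    Reasons: "no_alignment", "exon_overlap<=0.80", "utr_not_fully_covered".
    """
    if not blocks:
        return None, "no_alignment"
    _check_no_overlap(blocks)

    # symmetric exon-overlap filter: alignable (non-gap in the other row)
    # bases must cover > 80% of each species' annotated exons
    ref_aligned = [iv for b in blocks for iv in _aligned_intervals_ref(b)]
    oth_aligned = [iv for b in blocks for iv in _aligned_intervals_other(b)]
    for exons, aligned in ((transcript.exons, ref_aligned),
                           (ortholog_transcript.exons, oth_aligned)):
        exonic = total_length(exons)
        covered = intersect_length(list(exons), aligned)
        if exonic == 0 or covered / exonic <= EXON_OVERLAP_MIN:
            return None, "exon_overlap<=0.80"

    block_spans = [(b.ref_start, b.ref_end) for b in blocks]
    utr_bases = total_length(transcript.utr_genomic)
    if intersect_length(list(transcript.utr_genomic), block_spans) < utr_bases:
        return None, "utr_not_fully_covered"
    return list(blocks), None


# ---------------------------------------------------------------------------
# indel extraction
# ---------------------------------------------------------------------------

def _genomic_boundary_to_utr_offset(transcript: TranscriptModel,
                                    g_lo: int, g_hi: int) -> int | None:
    """Spliced offset of the first transcript base following the reference
    interval [g_lo, g_hi) in transcript orientation; None if the anchor is
    outside the transcript. The interval is empty (g_lo == g_hi) for gaps in
    the reference row."""
    off = 0
    if transcript.strand == "+":
        anchor = g_hi
        for s, e in transcript.exons:  # genomic order on '+'
            if anchor >= e:
                off += e - s
            elif anchor >= s:
                return off + (anchor - s)
            else:
                return off  # anchor falls in an intron/upstream: snap to next base
        return off
    # minus strand: transcript order is decreasing genomic coordinate; the
    # base following the gap is the first base with genomic position < g_lo
    anchor = g_lo
    for s, e in transcript.exons:  # ordered 5'->3' i.e. decreasing genomic
        if anchor <= s:
            off += e - s
        elif anchor <= e:
            return off + (e - anchor)
        else:
            return off
    return off


def extract_indels(blocks: Sequence[AlignmentBlock],
                   transcript: TranscriptModel,
                   max_len: int = MAX_INDEL_NT,
                   ) -> tuple[list[IndelRecord], int]:
    """Catalogue gaps as indels in 5'UTR coordinates.

    Returns (records, n_oversize) where n_oversize counts gap runs longer
    than max_len (discarded). A column that is a gap in both rows is a hard
    error.
    """
    utr_len = transcript.utr5_len
    records: list[IndelRecord] = []
    n_oversize = 0
    for block in blocks:
        for g_lo, g_hi, length in _gap_runs(block):
            if length > max_len:
                n_oversize += 1
                continue
            off = _genomic_boundary_to_utr_offset(transcript, g_lo, g_hi)
            if off is None or not (0 <= off <= utr_len):
                continue
            records.append(IndelRecord(transcript.transcript_id, off, length))
    if n_oversize:
        log.info("extract_indels(%s): discarded %d gap runs > %d bp",
                 transcript.transcript_id, n_oversize, max_len)
    records.sort(key=lambda r: (r.utr_offset, r.length_nt))
    return records, n_oversize


def _gap_runs(block: AlignmentBlock) -> list[tuple[int, int, int]]:
    """Maximal gap runs of either row as (ref_g_lo, ref_g_hi, length).

    For a run in the reference row the genomic interval is empty (the run
    sits between reference bases); for a run in the other row it spans the
    reference bases the other species lacks.
    """
    runs: list[tuple[int, int, int]] = []
    g = block.ref_start
    ref_run = 0          # current run of '-' in the ref row
    oth_run_start = None  # genomic start of current '-' run in the other row
    for rc, oc in zip(block.ref_text, block.other_text):
        if rc == "-" and oc == "-":
            raise DataError("gap aligned to gap at reference position "
                            f"{block.ref_chrom}:{g}")
        if rc == "-":
            if oth_run_start is not None:
                runs.append((oth_run_start, g, g - oth_run_start))
                oth_run_start = None
            ref_run += 1
            continue
        if ref_run:
            runs.append((g, g, ref_run))
            ref_run = 0
        if oc == "-":
            if oth_run_start is None:
                oth_run_start = g
        elif oth_run_start is not None:
            runs.append((oth_run_start, g, g - oth_run_start))
            oth_run_start = None
        g += 1
    if ref_run:
        runs.append((g, g, ref_run))
    if oth_run_start is not None:
        runs.append((oth_run_start, g, g - oth_run_start))
    return runs


def partition_indels(indels: Iterable[IndelRecord],
                     reference_offset: int) -> IndelCounts:
    """Tally indels by size class and side; an indel exactly at the
    reference point counts as downstream."""
    c = collections.Counter()
    for r in indels:
        r.side = "downstream" if r.utr_offset >= reference_offset else "upstream"
        c[(r.size_class, r.side)] += 1
    return IndelCounts(
        n_n3n_down=c[("n3n", "downstream")],
        n_3n_down=c[("3n", "downstream")],
        n_n3n_up=c[("n3n", "upstream")],
        n_3n_up=c[("3n", "upstream")],
    )
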