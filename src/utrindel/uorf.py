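"""uAUG scanning and uORF classification.

Every ATG lying entirely within the 5'UTR opens a candidate upstream ORF.
Translation is walked codon-by-codon along the spliced transcript
(5'UTR + CDS) until the first stop codon (TAA/TAG/TGA, mammalian nuclear
code). The resulting uORF is classified:

strict
    the stop codon lies entirely within the 5'UTR;
overlapping
    the reading frame differs from the main CDS frame and the stop codon
    extends into the CDS;
alternative
    the uAUG is in the main CDS frame with no intervening stop before the
    TIS, so the uORF shares the main stop codon (its uAUG is an alternative
    initiation site, AIS).

A uORF must be at least 9 nt long including its stop codon. Transcripts are
then grouped as G0 (no uAUG), Ga / Gs / Gv (only alternative / strict /
overlapping uORFs), or Gmulti (mixed types, excluded downstream).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._util import log
from .annotation_io import STOP_CODONS, TranscriptModel

MIN_UORF_NT = 9

GROUPS = ("G0", "Ga", "Gs", "Gv", "Gmulti")
_TYPE_TO_GROUP = {"alternative": "Ga", "strict": "Gs", "overlapping": "Gv"}


@dataclass(frozen=True)
class UorfAnnotation:
    """One upstream ORF anchored at a uAUG, in spliced-transcript coordinates."""

    uaug_offset: int       # 0-based offset of the A of the uAUG from the cap
    uorf_type: str         # strict | overlapping | alternative
    orf_length_nt: int     # including the stop codon
    stop_offset: int       # offset of the first base of the stop codon
    in_cds_frame: bool


@dataclass(frozen=True)
class TranscriptClass:
    transcript_id: str
    group: str
    reference_uaug_offset: int | None   # first uAUG of the group's type
    relative_position: float | None     # reference_uaug_offset / tis_offset
    utr5_len: int = 0


def scan_uaugs(transcript: TranscriptModel) -> list[UorfAnnotation]:
    """All uORFs of a transcript, sorted by uAUG offset."""
    utr = transcript.utr5_seq
    tis = transcript.tis_offset
    full = utr + transcript.cds_seq
    out: list[UorfAnnotation] = []
    for i in range(tis - 2):
        if utr[i : i + 3] != "ATG":
            continue
        ann = _walk_orf(full, i, tis, transcript.transcript_id)
        if ann is not None:
            out.append(ann)
    return out


def _walk_orf(full: str, start: int, tis: int,
              transcript_id: str) -> UorfAnnotation | None:
    in_frame = (tis - start) % 3 == 0
    pos = start
    while pos + 3 <= len(full):
        codon = full[pos : pos + 3]
        if any(b not in "ACGT" for b in codon):
            log.warning("transcript %s: non-ACGT base in candidate uORF at "
                        "offset %d; candidate dropped", transcript_id, start)
            return None
        if codon in STOP_CODONS:
            break
        if in_frame and pos + 3 == tis:
            # reached the TIS in the main frame with no stop: shares the
            # main CDS stop codon
            stop = len(full) - 3
            length = stop + 3 - start
            return _checked(start, "alternative", length, stop, True)
        pos += 3
    else:
        return None  # ran off the transcript end without a stop
    stop = pos
    length = stop + 3 - start
    if stop + 3 <= tis:
        uorf_type = "strict"
    else:
        # the stop codon extends into (or lies within) the CDS; an in-frame
        # stop before the TIS was already handled as strict above
        uorf_type = "overlapping"
    return _checked(start, uorf_type, length, stop, in_frame)


def _checked(start: int, uorf_type: str, length: int,
             stop: int, in_frame: bool) -> UorfAnnotation | None:
    if length < MIN_UORF_NT:
        return None
    return UorfAnnotation(start, uorf_type, length, stop, in_frame)


def classify_transcript(transcript: TranscriptModel,
                        uorfs: Sequence[UorfAnnotation]) -> TranscriptClass:
    """Assign the transcript to G0 / Ga / Gs / Gv / Gmulti.

    The reference point of a single-type transcript is its first uAUG from
    the cap; G0 and Gmulti carry no reference point.
    """
    types = {u.uorf_type for u in uorfs}
    if not types:
        group, ref = "G0", None
    elif len(types) > 1:
        group, ref = "Gmulti", None
    else:
        group = _TYPE_TO_GROUP[next(iter(types))]
        ref = min(u.uaug_offset for u in uorfs)
    rel = ref / transcript.tis_offset if ref is not None else None
    return TranscriptClass(transcript.transcript_id, group, ref, rel,
                           utr5_len=transcript.utr5_len)


def uaug_bed_records(transcript_id: str,
                     uorfs: Iterable[UorfAnnotation]) -> list[str]:
    """BED6 lines for the uAUGs (transcript-relative coordinates)."""
    return [
        f"{transcript_id}\t{u.uaug_offset}\t{u.uaug_offset + 3}\t"
        f"{u.uorf_type}\t{u.orf_length_nt}\t+"
        for u in uorfs
    ]
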