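"""Synthetic two-species datasets with known uORF structure and indels.

The generator emulates the study conditions end to end: a cohort of
orthologous gene pairs whose 5'UTRs carry a planted uORF of a known type
(or none), separated by indels placed uniformly along the UTR, with an
optional purifying-selection step that removes each non-3n indel downstream
of the planted uAUG with probability s. Two layers are exposed:

* a statistical layer (:func:`simulate_truth`) that draws groups, UTR
  lengths, uAUG positions and indels without constructing sequences — the
  cheap input for calibration and power studies; and
* a sequence layer (:func:`generate_gene` / :func:`emit_dataset`) that
  realises every transcript as actual FASTA + GTF + MAF + ortholog-table
  files, with the surviving indels appearing as alignment gaps, so the full
  file-reading pipeline can be exercised and checked against the recorded
  truth.

Default parameters: group mixture 0.55/0.02/0.30/0.13 over G0/Ga/Gs/Gv,
log-normal UTR lengths with median 300 nt (90th percentile < 1 kb), Beta
uAUG relative positions concentrated around means 0.25 (Gs), 0.40 (Gv) and
0.50 (Ga) — each group's uAUGs cluster near one characteristic fraction of
the UTR, which is what makes a single matched reference percent per group a
valid neutral comparison — and Poisson(3) indels per transcript with
truncated-geometric lengths on 1..100.

Indels are realised as gaps between an "ancestral" and a "derived" sequence;
whether a gap is written as an insertion or a deletion is a coin flip, since
the pairwise pipeline cannot (and must not) distinguish them. UTR regions
outside the planted uORF are sampled from an ATG-excluding walk, so the
planted uAUG is the only one — the scanner must recover exactly the planted
structure.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import AlignIO

from ._util import ConfigError, log
from .annotation_io import STOP_CODONS, TranscriptModel
from .indels import IndelRecord
from .isi import TranscriptIndels
from .uorf import TranscriptClass, classify_transcript, scan_uaugs

_GROUPS = ("G0", "Ga", "Gs", "Gv")
_GROUP_TO_TYPE = {"Ga": "alternative", "Gs": "strict", "Gv": "overlapping"}
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


# ---------------------------------------------------------------------------
# configuration and truth records
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort; seed is mandatory."""

    seed: int
    n_genes: int = 500
    group_mixture: dict = field(default_factory=lambda: {
        "G0": 0.55, "Ga": 0.02, "Gs": 0.30, "Gv": 0.13})
    utr_median_nt: float = 300.0
    utr_log_sigma: float = 0.8      # 90th percentile ~ 840 nt < 1 kb
    min_utr_nt: int = 30
    max_utr_nt: int = 2000
    uaug_beta: dict = field(default_factory=lambda: {
        "Gs": (10.0, 30.0), "Gv": (16.0, 24.0), "Ga": (20.0, 20.0)})
    indel_rate: float = 3.0         # Poisson mean per transcript
    indel_length_p: float = 0.3     # geometric parameter, truncated to 1..100
    max_indel_nt: int = 100
    selection_strength: float = 0.0
    selected_groups: tuple = ()
    cds_n_codons: int = 60          # internal codons (CDS adds ATG + stop)
    two_isoform_fraction: float = 0.0
    species: tuple = ("speciesA", "speciesB")
    flank_nt: int = 20

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("simulation seed is mandatory")
        total = sum(self.group_mixture.get(g, 0.0) for g in _GROUPS)
        if abs(total - 1.0) > 1e-6:
            raise ConfigError("group_mixture must sum to 1")
        if not 0.0 <= self.selection_strength <= 1.0:
            raise ConfigError("selection_strength must lie in [0, 1]")
        if self.indel_rate < 0 or self.indel_length_p <= 0:
            raise ConfigError("indel rates must be positive")
        self.selected_groups = tuple(self.selected_groups)
        unknown = set(self.selected_groups) - {"Ga", "Gs", "Gv"}
        if unknown:
            raise ConfigError(f"selected_groups contains {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seed" not in data:
            raise ConfigError("simulation config must set a seed")
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown simulation config keys: {sorted(bad)}")
        for key in ("selected_groups", "species"):
            if key in data:
                data[key] = tuple(data[key])
        if "uaug_beta" in data:
            data["uaug_beta"] = {k: tuple(v) for k, v in data["uaug_beta"].items()}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["selected_groups"] = list(self.selected_groups)
        d["species"] = list(self.species)
        d["uaug_beta"] = {k: list(v) for k, v in self.uaug_beta.items()}
        return d


@dataclass(frozen=True)
class SimTranscript:
    """Ground truth for one synthetic transcript (annotated species)."""

    gene_id: str
    transcript_id: str
    group: str
    utr_length: int
    uaug_offset: int | None
    uaug_type: str | None
    indels_pre: tuple[tuple[int, int], ...]    # (anchor, length) before selection
    indels_post: tuple[tuple[int, int], ...]   # surviving indels


# ---------------------------------------------------------------------------
# statistical layer
# ---------------------------------------------------------------------------

def _draw_utr_length(config: SimulationConfig, rng: np.random.Generator) -> int:
    length = rng.lognormal(np.log(config.utr_median_nt), config.utr_log_sigma)
    return int(min(max(round(length), config.min_utr_nt), config.max_utr_nt))


def _draw_uaug_offset(config: SimulationConfig, group: str, utr_len: int,
                      rng: np.random.Generator) -> int:
    a, b = config.uaug_beta[group]
    rel = rng.beta(a, b)
    hi = utr_len - 9 if group == "Gs" else utr_len - 3
    off = int(min(max(round(rel * utr_len), 1), hi))
    if group == "Ga":
        # the uAUG must share the main CDS frame
        off += (utr_len - off) % 3
        if off > hi:
            off -= 3
    elif group == "Gv":
        # the uAUG must be out of the main frame
        if (utr_len - off) % 3 == 0:
            off += 1 if off + 1 <= hi else -1
    return off


def _draw_indels(config: SimulationConfig, utr_len: int,
                 rng: np.random.Generator) -> list[tuple[int, int]]:
    k = int(min(rng.poisson(config.indel_rate), utr_len + 1))
    if k == 0:
        return []
    # distinct anchors keep realised gap runs separable; each anchor is still
    # marginally uniform on {0..utr_len}
    positions = np.sort(rng.choice(utr_len + 1, size=k, replace=False))
    lengths = []
    for _ in range(k):
        length = int(rng.geometric(config.indel_length_p))
        while length > config.max_indel_nt:
            length = int(rng.geometric(config.indel_length_p))
        lengths.append(length)
    return [(int(p), l) for p, l in zip(positions, lengths)]


def _apply_selection(config: SimulationConfig, group: str,
                     uaug_offset: int | None,
                     indels: Sequence[tuple[int, int]],
                     rng: np.random.Generator) -> list[tuple[int, int]]:
    s = config.selection_strength
    if s == 0 or group not in config.selected_groups or uaug_offset is None:
        return list(indels)
    kept = []
    for pos, length in indels:
        if length % 3 != 0 and pos >= uaug_offset and rng.random() < s:
            continue  # purged by purifying selection
        kept.append((pos, length))
    return kept


def _draw_sim_transcript(config: SimulationConfig, gene_index: int,
                         rng: np.random.Generator) -> SimTranscript:
    probs = [config.group_mixture.get(g, 0.0) for g in _GROUPS]
    group = str(rng.choice(_GROUPS, p=probs))
    utr_len = _draw_utr_length(config, rng)
    uaug = None if group == "G0" else _draw_uaug_offset(config, group, utr_len, rng)
    pre = _draw_indels(config, utr_len, rng)
    post = _apply_selection(config, group, uaug, pre, rng)
    gid = f"G{gene_index:05d}"
    return SimTranscript(
        gene_id=gid, transcript_id=f"T{gene_index:05d}.1", group=group,
        utr_length=utr_len, uaug_offset=uaug,
        uaug_type=_GROUP_TO_TYPE.get(group),
        indels_pre=tuple(pre), indels_post=tuple(post),
    )


def _gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(gene_index,)))


def simulate_truth(config: SimulationConfig) -> list[SimTranscript]:
    """Statistical layer: the cohort's ground truth without sequences."""
    return [_draw_sim_transcript(config, i, _gene_rng(config.seed, i))
            for i in range(config.n_genes)]


def truth_classes(truth: Sequence[SimTranscript]) -> list[TranscriptClass]:
    """TranscriptClass records as the pipeline would assign them."""
    out = []
    for t in truth:
        rel = t.uaug_offset / t.utr_length if t.uaug_offset is not None else None
        out.append(TranscriptClass(t.transcript_id, t.group, t.uaug_offset,
                                   rel, utr5_len=t.utr_length))
    return out


def truth_indels(truth: Sequence[SimTranscript]) -> dict[str, TranscriptIndels]:
    """Post-selection indels as IndelRecords keyed by transcript."""
    return {
        t.transcript_id: TranscriptIndels(
            t.transcript_id, t.utr_length,
            tuple(IndelRecord(t.transcript_id, pos, length)
                  for pos, length in t.indels_post))
        for t in truth
    }


# ---------------------------------------------------------------------------
# sequence layer
# ---------------------------------------------------------------------------

_BASES = "ACGT"


class _AtgFreeSampler:
    """Sequential base sampler that never completes an 'ATG' trinucleotide."""

    def __init__(self, rng: np.random.Generator, tail: str = ""):
        self.rng = rng
        self.tail = tail[-2:]

    def feed(self, seq: str) -> str:
        self.tail = (self.tail + seq)[-2:]
        return seq

    def draw(self, n: int) -> str:
        out = []
        for _ in range(n):
            choices = _BASES.replace("G", "") if self.tail.endswith("AT") else _BASES
            base = choices[int(self.rng.integers(len(choices)))]
            out.append(base)
            self.tail = (self.tail + base)[-2:]
        return "".join(out)

    def draw_codon(self, forbid_stops: bool = True) -> str:
        for _ in range(100):
            saved = self.tail
            codon = self.draw(3)
            if forbid_stops and codon in STOP_CODONS:
                self.tail = saved
                continue
            return codon
        raise RuntimeError("codon sampling failed")  # pragma: no cover

    def draw_stop(self) -> str:
        # 'A' + 'TGA' would spell ATG across the boundary
        options = ("TAA", "TAG") if self.tail.endswith("A") else ("TAA", "TAG", "TGA")
        stop = options[int(self.rng.integers(len(options)))]
        return self.feed(stop)


def _build_utr(config: SimulationConfig, entry: SimTranscript,
               rng: np.random.Generator) -> str:
    """UTR sequence realising exactly the planted uORF structure."""
    utr_len, u = entry.utr_length, entry.uaug_offset
    s = _AtgFreeSampler(rng)
    if entry.group == "G0":
        return s.draw(utr_len)
    parts = [s.draw(u), s.feed("ATG")]
    if entry.group == "Gs":
        max_codons = (utr_len - u - 6) // 3
        n_codons = int(rng.integers(1, min(max_codons, 10) + 1))
        parts += [s.draw_codon() for _ in range(n_codons)]
        parts.append(s.draw_stop())
        parts.append(s.draw(utr_len - u - 6 - 3 * n_codons))
    else:
        # Ga / Gv: no stop may appear in the uAUG's frame before the TIS
        remaining = utr_len - u - 3
        parts += [s.draw_codon() for _ in range(remaining // 3)]
        parts.append(s.draw(remaining % 3))
    seq = "".join(parts)
    assert len(seq) == utr_len
    return seq


def _build_cds(config: SimulationConfig, rng: np.random.Generator) -> str:
    codons = [_NON_STOP_CODONS[i]
              for i in rng.integers(len(_NON_STOP_CODONS),
                                    size=config.cds_n_codons)]
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
    return "ATG" + "".join(codons) + stop


def _make_model(entry: SimTranscript, utr: str, cds: str, species: str,
                chrom: str, offset: int, transcript_id: str | None = None,
                ) -> TranscriptModel:
    tid = transcript_id or entry.transcript_id
    start, end = offset, offset + len(utr) + len(cds)
    return TranscriptModel(
        gene_id=entry.gene_id, transcript_id=tid, species=species,
        chrom=chrom, strand="+", exons=((start, end),),
        tis_offset=len(utr), utr5_seq=utr, cds_seq=cds,
        utr_genomic=((start, start + len(utr)),),
        cds_genomic=((start + len(utr), end),),
    )


@dataclass
class GeneRealization:
    """One synthetic orthologous gene pair with its gapped alignment rows."""

    truth: SimTranscript
    ref_model: TranscriptModel
    other_model: TranscriptModel
    ref_genome: str
    other_genome: str
    ref_row: str            # gapped alignment text, transcript region
    other_row: str
    extra_isoform: TranscriptModel | None = None


def generate_gene(config: SimulationConfig, gene_index: int,
                  ) -> GeneRealization:
    """Realise one gene pair; the planted classification is verified with
    the scanner and construction is retried until it holds exactly."""
    rng = _gene_rng(config.seed, gene_index)
    entry = _draw_sim_transcript(config, gene_index, rng)
    chrom = f"g{gene_index:05d}"
    sp_ref, sp_other = config.species

    for _attempt in range(100):
        utr = _build_utr(config, entry, rng)
        cds = _build_cds(config, rng)
        model = _make_model(entry, utr, cds, sp_ref, chrom, config.flank_nt)
        cls = classify_transcript(model, scan_uaugs(model))
        if cls.group == entry.group and cls.reference_uaug_offset == entry.uaug_offset:
            break
    else:  # pragma: no cover - construction is verified to converge
        raise RuntimeError(
            f"could not realise planted class {entry.group} for gene "
            f"{gene_index} (utr_len={entry.utr_length})")

    ref_row, other_row, derived_utr = _realize_alignment(
        utr, entry.indels_post, rng)
    ref_row += cds
    other_row += cds

    flank_ref = _AtgFreeSampler(rng).draw(config.flank_nt)
    flank_ref2 = _AtgFreeSampler(rng).draw(config.flank_nt)
    flank_oth = _AtgFreeSampler(rng).draw(config.flank_nt)
    flank_oth2 = _AtgFreeSampler(rng).draw(config.flank_nt)
    ref_genome = flank_ref + utr + cds + flank_ref2
    other_genome = flank_oth + derived_utr + cds + flank_oth2
    other_model = _make_model(entry, derived_utr, cds, sp_other, chrom,
                              config.flank_nt)

    extra = None
    if rng.random() < config.two_isoform_fraction and entry.utr_length > 12:
        shift = int(rng.integers(3, entry.utr_length - 3))
        extra = _make_model(entry, utr[shift:], cds, sp_ref, chrom,
                            config.flank_nt + shift,
                            transcript_id=f"T{gene_index:05d}.2")
    return GeneRealization(entry, model, other_model, ref_genome,
                           other_genome, ref_row, other_row, extra)


def _realize_alignment(utr: str, indels: Sequence[tuple[int, int]],
                       rng: np.random.Generator) -> tuple[str, str, str]:
    """Write the surviving indels as gap runs over the UTR.

    Each indel anchored at ``pos`` becomes either an insertion in the derived
    species (gap in the reference row immediately before reference base
    ``pos``) or a deletion of the reference bases [pos - len, pos) (gap in
    the derived row); both leave the extraction anchor at ``pos``. Deletions
    are only used where they stay clear of the previous indel and keep at
    least 5 nt of derived UTR.
    """
    utr_len = len(utr)
    ins_at: dict[int, int] = {}
    deleted = np.zeros(utr_len, dtype=bool)
    prev_anchor = -1
    budget = utr_len - 5
    for pos, length in sorted(indels):
        feasible = pos - length >= prev_anchor + 1 and length <= budget
        if feasible and rng.random() < 0.5:
            deleted[pos - length : pos] = True
            budget -= length
        else:
            ins_at[pos] = length
        prev_anchor = pos
    sampler = _AtgFreeSampler(rng)
    ref_row: list[str] = []
    other_row: list[str] = []
    for i in range(utr_len + 1):
        if i in ins_at:
            ref_row.append("-" * ins_at[i])
            other_row.append(sampler.draw(ins_at[i]))
        if i < utr_len:
            ref_row.append(utr[i])
            other_row.append("-" if deleted[i] else sampler.feed(utr[i]))
    ref_text = "".join(ref_row)
    other_text = "".join(other_row)
    derived_utr = other_text.replace("-", "")
    return ref_text, other_text, derived_utr


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def _gtf_lines(model: TranscriptModel) -> list[str]:
    attrs = (f'gene_id "{model.gene_id}"; '
             f'transcript_id "{model.transcript_id}";')
    lines = []
    for s, e in model.exons:
        lines.append(f"{model.chrom}\tutrindel_sim\texon\t{s + 1}\t{e}\t.\t"
                     f"{model.strand}\t.\t{attrs}")
    for s, e in model.cds_genomic:
        lines.append(f"{model.chrom}\tutrindel_sim\tCDS\t{s + 1}\t{e}\t.\t"
                     f"{model.strand}\t0\t{attrs}")
    return lines


def emit_dataset(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA + GTF per species, the pairwise MAF, the ortholog table,
    the truth JSON and a config echo. Byte-identical for a fixed seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sp_ref, sp_other = config.species
    paths = {
        "ref_fasta": out / f"{sp_ref}.fa",
        "other_fasta": out / f"{sp_other}.fa",
        "ref_gtf": out / f"{sp_ref}.gtf",
        "other_gtf": out / f"{sp_other}.gtf",
        "maf": out / "alignment.maf",
        "orthologs": out / "orthologs.tsv",
        "truth": out / "truth.json",
        "config": out / "config.yaml",
    }
    genes = [generate_gene(config, i) for i in range(config.n_genes)]

    with open(paths["ref_fasta"], "w") as fa_r, \
         open(paths["other_fasta"], "w") as fa_o:
        for g in genes:
            fa_r.write(f">{g.ref_model.chrom}\n{g.ref_genome}\n")
            fa_o.write(f">{g.other_model.chrom}\n{g.other_genome}\n")

    with open(paths["ref_gtf"], "w") as gtf_r, \
         open(paths["other_gtf"], "w") as gtf_o:
        for g in genes:
            for line in _gtf_lines(g.ref_model):
                gtf_r.write(line + "\n")
            if g.extra_isoform is not None:
                for line in _gtf_lines(g.extra_isoform):
                    gtf_r.write(line + "\n")
            for line in _gtf_lines(g.other_model):
                gtf_o.write(line + "\n")

    alignments = []
    for g in genes:
        ref_size = sum(c != "-" for c in g.ref_row)
        oth_size = sum(c != "-" for c in g.other_row)
        rec_r = SeqRecord(Seq(g.ref_row), id=f"{sp_ref}.{g.ref_model.chrom}")
        rec_r.annotations = {"start": config.flank_nt, "size": ref_size,
                             "strand": 1, "srcSize": len(g.ref_genome)}
        rec_o = SeqRecord(Seq(g.other_row), id=f"{sp_other}.{g.other_model.chrom}")
        rec_o.annotations = {"start": config.flank_nt, "size": oth_size,
                             "strand": 1, "srcSize": len(g.other_genome)}
        alignments.append(MultipleSeqAlignment([rec_r, rec_o]))
    with open(paths["maf"], "w") as mh:
        AlignIO.write(alignments, mh, "maf")

    with open(paths["orthologs"], "w") as oh:
        oh.write("gene_id_species1\tgene_id_species2\n")
        for g in genes:
            oh.write(f"{g.truth.gene_id}\t{g.truth.gene_id}\n")

    truth_payload = {
        "config": config.to_dict(),
        "transcripts": [dataclasses.asdict(g.truth) for g in genes],
    }
    with open(paths["truth"], "w") as th:
        json.dump(truth_payload, th, indent=1, sort_keys=True)
    with open(paths["config"], "w") as ch:
        yaml.safe_dump(config.to_dict(), ch, sort_keys=True)
    log.info("emit_dataset: wrote %d genes to %s", len(genes), out)
    return paths
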