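"""Transcript loading, invariant filters and per-gene isoform selection."""

import collections

import pytest

from utrindel._util import ConfigError, DataError
from utrindel.annotation_io import (
    GeneIsoformSet,
    TranscriptModel,
    load_orthologs,
    load_transcripts,
    select_transcript,
    write_transcript_annotation,
)
from conftest import VALID_CDS, make_transcript, write_annotation


class TestLoadTranscripts:
    def test_single_plus_strand_round_trip(self, tmp_path, toy_utr13):
        gtf, fasta = write_annotation(tmp_path, "toy", toy_utr13 + VALID_CDS, 13)
        (model,) = load_transcripts(gtf, fasta, "human")
        assert model.tis_offset == 13
        assert model.utr5_seq == toy_utr13
        assert model.cds_seq == VALID_CDS

    def test_cds_without_atg_is_excluded(self, tmp_path, toy_utr13):
        bad_cds = "TTGAAATAA"
        gtf, fasta = write_annotation(tmp_path, "bad", toy_utr13 + bad_cds, 13)
        assert load_transcripts(gtf, fasta, "human") == []

    @pytest.mark.parametrize("bad_cds,reason", [
        ("ATGTAAAAATAA", "internal stop"),
        ("ATGAAACCC", "no terminal stop"),
        ("ATGAATAA", "length not multiple of 3"),
    ])
    def test_misannotated_cds_variants_excluded(self, tmp_path, toy_utr13,
                                                bad_cds, reason):
        gtf, fasta = write_annotation(tmp_path, "bad", toy_utr13 + bad_cds, 13)
        assert load_transcripts(gtf, fasta, "human") == [], reason

    def test_transcript_without_utr_excluded(self, tmp_path):
        gtf, fasta = write_annotation(tmp_path, "noutr", VALID_CDS, 0)
        assert load_transcripts(gtf, fasta, "human") == []

    def test_minus_strand_equals_plus_strand(self, tmp_path, toy_utr13):
        spliced = toy_utr13 + VALID_CDS
        gtf_p, fasta_p = write_annotation(tmp_path, "plus", spliced, 13, "+")
        gtf_m, fasta_m = write_annotation(tmp_path, "minus", spliced, 13, "-")
        (mp,) = load_transcripts(gtf_p, fasta_p, "human")
        (mm,) = load_transcripts(gtf_m, fasta_m, "human")
        assert (mm.utr5_seq, mm.cds_seq, mm.tis_offset) == \
               (mp.utr5_seq, mp.cds_seq, mp.tis_offset)

    def test_missing_chromosome_is_hard_error(self, tmp_path, toy_utr13):
        gtf, fasta = write_annotation(tmp_path, "toy", toy_utr13 + VALID_CDS, 13)
        fasta.write_text(">chrOTHER\nACGT\n")
        with pytest.raises(DataError, match="chr1"):
            load_transcripts(gtf, fasta, "human")

    def test_allow_list_filters(self, tmp_path, toy_utr13):
        gtf, fasta = write_annotation(tmp_path, "toy", toy_utr13 + VALID_CDS, 13)
        assert load_transcripts(gtf, fasta, "h", allow_list=["other"]) == []
        assert len(load_transcripts(gtf, fasta, "h", allow_list=["tx1"])) == 1

    def test_write_then_reload_is_identity(self, tmp_path):
        models = [
            make_transcript("CCTTCCTTCCTTC", transcript_id="a", gene_id="ga"),
            make_transcript("GGCCTTGGCC", "ATGCCCGATTAA",
                            transcript_id="b", gene_id="gb"),
        ]
        gtf, fasta = tmp_path / "w.gtf", tmp_path / "w.fa"
        write_transcript_annotation(models, gtf, fasta)
        reloaded = {t.transcript_id: t for t in load_transcripts(gtf, fasta, "sp")}
        for m in models:
            r = reloaded[m.transcript_id]
            assert (r.utr5_seq, r.cds_seq, r.tis_offset) == \
                   (m.utr5_seq, m.cds_seq, m.tis_offset)


def _gene(*isoforms):
    return GeneIsoformSet(isoforms[0].gene_id, list(isoforms))


class TestSelectTranscript:
    def test_longest_utr_picks_maximum(self):
        a = make_transcript("C" * 40, transcript_id="a")
        b = make_transcript("C" * 100, transcript_id="b", offset=500)
        assert select_transcript(_gene(a, b), "longest_utr").transcript_id == "b"

    def test_longest_utr_tie_breaks_by_id(self):
        a = make_transcript("C" * 40, transcript_id="z")
        b = make_transcript("C" * 40, transcript_id="a", offset=500)
        assert select_transcript(_gene(a, b), "longest_utr").transcript_id == "a"

    def test_random_is_seed_reproducible_and_uniform(self):
        a = make_transcript("C" * 40, transcript_id="a")
        b = make_transcript("C" * 40, transcript_id="b", offset=500)
        gene = _gene(a, b)
        assert (select_transcript(gene, "random", seed=42).transcript_id
                == select_transcript(gene, "random", seed=42).transcript_id)
        picks = collections.Counter(
            select_transcript(gene, "random", seed=s).transcript_id
            for s in range(10_000))
        assert abs(picks["a"] / 10_000 - 0.5) <= 0.02

    def test_pure_utr_single_isoform_is_vacuously_pure(self):
        a = make_transcript("C" * 40, transcript_id="a")
        assert select_transcript(_gene(a), "pure_utr").transcript_id == "a"

    def test_pure_utr_rejects_utr_over_other_cds(self):
        # isoform A's 5'UTR genomically contains isoform B's CDS start;
        # B's UTR avoids A's CDS footprint, so only B is pure
        a = TranscriptModel("g1", "A", "sp", "chr1", "+", ((0, 200),),
                            100, "C" * 100, "X", ((0, 100),), ((100, 200),))
        b = TranscriptModel("g1", "B", "sp", "chr1", "+", ((0, 150),),
                            40, "C" * 40, "X", ((0, 40),), ((50, 150),))
        gene = _gene(a, b)
        chosen = select_transcript(gene, "pure_utr")
        assert chosen.transcript_id == "B"
        # independent base-level check of the purity predicate
        for iso in gene.isoforms:
            utr_bases = {p for s, e in iso.utr_genomic for p in range(s, e)}
            other_cds = {p for t in gene.isoforms
                         if t.transcript_id != iso.transcript_id
                         for s, e in t.cds_genomic for p in range(s, e)}
            pure = not (utr_bases & other_cds)
            assert pure == (iso.transcript_id == "B")

    def test_pure_utr_none_when_no_isoform_qualifies(self):
        a = TranscriptModel("g1", "A", "sp", "chr1", "+", ((0, 200),),
                            100, "C" * 100, "X", ((0, 100),), ((100, 200),))
        # B laid out on the other strand: its UTR sits inside A's CDS and
        # its CDS inside A's UTR, so neither isoform is pure
        b = TranscriptModel("g1", "B", "sp", "chr1", "-", ((50, 170),),
                            20, "C" * 20, "X", ((150, 170),), ((50, 150),))
        assert select_transcript(_gene(a, b), "pure_utr") is None

    def test_pure_utr_never_overlaps_other_cds_property(self):
        # randomized battery against an independent per-base intersection check
        import random
        rng = random.Random(0)
        for trial in range(50):
            isoforms = []
            for i in range(rng.randint(1, 4)):
                u0 = rng.randrange(0, 50)
                ulen = rng.randint(10, 60)
                clen = rng.randint(30, 90)
                isoforms.append(TranscriptModel(
                    "g", f"t{i}", "sp", "chr1", "+",
                    ((u0, u0 + ulen + clen),), ulen, "C" * ulen, "X",
                    ((u0, u0 + ulen),), ((u0 + ulen, u0 + ulen + clen),)))
            chosen = select_transcript(_gene(*isoforms), "pure_utr")
            if chosen is None:
                continue
            utr = {p for s, e in chosen.utr_genomic for p in range(s, e)}
            cds_others = {p for t in isoforms
                          if t.transcript_id != chosen.transcript_id
                          for s, e in t.cds_genomic for p in range(s, e)}
            assert not (utr & cds_others)

    def test_unknown_criterion_raises(self):
        a = make_transcript("C" * 40)
        with pytest.raises(ConfigError):
            select_transcript(_gene(a), "best_utr")


class TestOrthologs:
    def test_duplicate_gene_rejected(self, tmp_path):
        p = tmp_path / "orth.tsv"
        p.write_text("a\tb\ng1\tm1\ng1\tm2\n")
        with pytest.raises(DataError):
            load_orthologs(p)

    def test_pairs_loaded(self, tmp_path):
        p = tmp_path / "orth.tsv"
        p.write_text("a\tb\ng1\tm1\ng2\tm2\n")
        pairs = load_orthologs(p)
        assert [(q.gene_id_species1, q.gene_id_species2) for q in pairs] == \
               [("g1", "m1"), ("g2", "m2")]
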