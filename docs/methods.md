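# Methods

This note records the model, the conventions and the deliberate choices
behind `utrindel`, at the level of detail a maintainer or reviewer needs to
reproduce or challenge them.

## Transcript models and selection of one isoform per gene

Genomic coordinates are 0-based half-open; transcript coordinates are
0-based offsets from the cap along the spliced transcript. Minus-strand
transcripts are reverse-complemented at load time so all downstream code
sees cap→3' sequence. A transcript is retained only if it has a 5'UTR of at
least 1 nt and a sane CDS (starts ATG, length a multiple of 3, no internal
in-frame stop, ends in a stop codon); anything else is counted as
misannotated and dropped, never fatal. The GTF dialect expects CDS features
to include the terminal stop codon; separate `stop_codon` features are
merged in when present.

One isoform represents each gene, by one of three criteria: `random`
(seeded, uniform), `longest_utr`, or `pure_utr` — the isoform whose 5'UTR
genomic footprint does not intersect the CDS footprint of any *other*
isoform of the same gene (evaluated within the gene only), longest 5'UTR
among the qualifiers. Ties in either length criterion break by
lexicographically smallest transcript id; this is a convention chosen for
determinism, nothing more.

## uORF classification

Stop codons are TAA/TAG/TGA (mammalian nuclear code; no alternatives, no
near-cognate starts, no Kozak scoring). A uAUG must lie entirely within the
5'UTR; an AUG straddling the main start is not a uAUG. Reading proceeds in
steps of 3 along UTR+CDS to the first stop. Conventions worth writing
down:

* an in-frame uAUG whose reading meets a stop before the TIS is **strict**
  (its ORF ends in the UTR), not alternative;
* the ≥ 9 nt minimum (including the stop) applies to all three types;
* an out-of-frame uORF whose stop codon straddles the TIS is classified
  **overlapping** (the stop extends into the CDS);
* a reading that runs off the transcript without a stop yields no uORF;
* nested same-frame uAUGs sharing one stop are each reported — only the
  first uAUG from the cap is ever used as a reference point, so downstream
  statistics are unaffected.

## Indel catalogue

Alignment blocks come from pairwise MAF with the annotated species as the
(plus-strand) reference. A gene enters the catalogue only if the alignable
sequence of each species covers strictly more than 80% of the other
species' annotated exonic bases (applied symmetrically) and the alignment
covers every base of the annotated 5'UTR. Blocks overlapping on the
reference, or columns that are gaps in both rows, are hard errors.

Each maximal gap run in either row is one indel; insertions and deletions
are pooled — a pairwise alignment cannot distinguish them, and the package
never pretends to. Runs longer than 100 nt are discarded (counted, not
fatal; they are outside the small-indel regime under study). A gap needs a
single point location for the upstream/downstream dichotomy and for
shuffling; the convention is the **ungapped reference coordinate of the
first reference base following the run**, converted to the spliced 5'UTR
offset. An indel exactly at the reference point counts as downstream (a gap
at the uAUG disrupts the element it starts). Adjacent runs in opposite rows
are separate indels; there is no gap merging or realignment, no
polarisation against an outgroup, and no lineage assignment.

## R and the Indel Selection Index

With downstream/upstream counts per size class and pseudocount c > 0
(default 0.5),

    R = log2[ ((N_n3n,d + c)/(N_3n,d + c)) / ((N_n3n,u + c)/(N_3n,u + c)) ]

The pseudocount keeps R finite for any counts; R is exactly 0 for
proportional counts and antisymmetric under swapping sides. The log base
only rescales R; every downstream quantity (ISI, all tests) depends on rank
order alone and is base-invariant. Changing c generally changes |R| but not
its sign on realistic count patterns; this is *not* a theorem — patterns
such as (1,4,0,1) flip sign between c = 0.25 and c = 1 — and the test suite
asserts only the empirical ≥ 95% sign stability on the default synthetic
cohort.

ISI is the proportion of 1,000 positional shuffles with R_shuffled strictly
below R_observed. Shuffles redraw each indel's anchor independently and
uniformly on the utr_length + 1 integer positions; lengths, size classes
and counts are retained; shuffled indels may coincide (only the side of the
reference point matters). The default tie rule is strict (ties do not
count); a `midp` option adds half the ties, which is the better-behaved
choice when tie probability is large. R-value equality is tested at
tolerance 1e-9 on log2 scale. `exact_isi` replaces the Monte Carlo by exact
enumeration: downstream counts per size class are binomial with
p = (#positions ≥ reference)/(utr_length + 1), and the
(k_n3n+1)(k_3n+1) outcomes are summed. It is the oracle for `compute_isi`
in the tests and is exposed for ≤ 12 indels.

Transcripts with no indels, and reference points at the extreme ends of the
UTR (offset 0 or utr_length), are excluded from all ISI distributions: the
former carry no information, the latter make every shuffle a tie.

## Neutral reference and group inference

ISI is not position-free: its median dips toward both UTR ends (a
pseudocount- and tie-driven effect, reproduced by the test suite), so group
comparisons must control the reference position. The neutral table holds
ISI distributions of indel-containing G₀ transcripts with an artificial
reference point at p% of each transcript's UTR length (clamped inside the
UTR), built at whatever percents the run needs; all percents use the same
transcript set. Each uAUG group is compared against the neutral
distribution at its **median** relative uAUG position (rounded to an
integer percent, half-up, clamped to [1, 99]) with a two-sided
Mann-Whitney U test (scipy: exact for small untied samples, normal
approximation with tie correction otherwise). Gᵥ is additionally split into
three contiguous position tertiles (remainder-first sizes, ties broken by
transcript id), each matched and tested independently.

Matching by a single percent per group is only adequate when the
within-group spread of relative uAUG positions is small; with a wide
spread, the mixture of positions inside the group no longer resembles any
single neutral slice and the comparison acquires a systematic bias.
`pooled_matched_neutral` implements per-transcript matching (pooling each
member's own neutral slice) for that situation; the pipeline's default
remains single-percent matching, which is the design the matched-percent
report reproduces.

The size-equalised bootstrap redraws each group's ISIs with replacement
(default 1,000 resamples) down to a common n — the pipeline uses the Gₐ
count, the smallest group — and re-runs the comparison against the group's
*fixed* matched neutral distribution; only the uAUG group is resampled.
F_sig is the fraction of resample P values below 0.05, and P-value
distributions are compared across groups with two-sample KS tests (computed
on P; a −log10 display transform would not change the statistic). No
multiple-testing correction is applied across group comparisons.

## The synthetic generator

The generator defines the study conditions; defaults:

| parameter | default | meaning |
|---|---|---|
| group_mixture | 0.55 / 0.02 / 0.30 / 0.13 | G₀/Gₐ/Gₛ/Gᵥ proportions |
| utr_median_nt, utr_log_sigma | 300, 0.8 | log-normal UTR length; 90th pct ≈ 840 nt, clamped to [30, 2000] |
| uaug_beta | Gₛ (10,30), Gᵥ (16,24), Gₐ (20,20) | relative uAUG position; means 0.25 / 0.40 / 0.50, sd ≈ 0.07-0.08 |
| indel_rate | 3.0 | Poisson indels per transcript |
| indel_length_p | 0.3 | geometric length, truncated to 1..100 |
| selection_strength s, selected_groups | 0, () | removal probability for non-3n indels downstream of the uAUG |
| cds_n_codons | 60 | internal CDS codons |

The position distributions are deliberately concentrated: each group's
uAUGs cluster near one characteristic fraction of the UTR, which is the
regime in which single-percent neutral matching is a calibrated comparison
(type-I error at the nominal level under s = 0, verified by the test
suite). Widening them breaks that premise before it breaks anything else in
the package — see the matching discussion above.

Sequences are built so the planted structure is exact: non-uORF UTR regions
come from a sampler that never completes an ATG (including across segment
junctions), planted uORFs get non-stop codons in the relevant frame and a
stop placed per type, and every gene is verified by the scanner itself
(scan → classify must reproduce the planted group and offset) with bounded
retries. Indel anchors are drawn uniformly but *distinct* within a
transcript (marginal uniformity is preserved; distinctness keeps realised
gap runs separable). Survivors are realised as MAF gaps — insertion or
deletion in the derived species by coin flip, with deletions constrained to
stay clear of the previous indel and to keep ≥ 5 nt of derived UTR — both
realisations leave the extraction anchor at the drawn position, so the
pipeline's catalogue must reproduce the truth exactly, and a round-trip
test asserts that it does. A cheap statistical layer (`simulate_truth`)
exposes the same draws without sequence construction for calibration and
power studies.

What the generator does **not** emulate: nucleotide substitutions
(alignments are exact apart from gaps), alignment error, annotation error,
multi-exon UTRs (all synthetic genes are single-exon; multi-exon support is
exercised at the loader level), genuinely ambiguous uORFs, or correlated
indel placement. Passing tests therefore show the machinery is correct and
calibrated under clean conditions, not that real alignments are free of the
corresponding artefacts.

## Problem sizes in the tests and acceptance script

The test suite runs the null-sweep shape on ~2,100 indel-containing G₀
transcripts, calibration on 200 replicates (~24,000 ISI computations), and
the selection-recovery study on 20 seeds × (3 × 400 + 800) transcripts at
1,000 shuffles each — sizes chosen to make binomial error small relative to
the asserted margins. The acceptance script runs the full file-based
pipeline at 800 gene pairs with s = 0.8 on Gₐ and Gᵥ plus the calibration
studies; every random stream derives from the single `--seed`.

## Known limitations

* Insertions vs deletions, and the lineage an indel occurred on, are
  irrecoverable from pairwise alignments; results are therefore about gap
  prevalence, not directional mutation.
* The strict tie rule forces ISI toward 0 for tie-heavy transcripts (few
  indels, extreme reference points); the neutral reference absorbs this on
  average, and `midp` is available when a smoother statistic is wanted.
* One species' annotation drives a run; cross-species consistency is two
  runs plus `diff`, not a joint model.
* The log base of R and the placement of the pseudocount are conventions;
  any variant preserving the ratio-of-ratios form (R = 0 under no
  preference, antisymmetry under side swap, finiteness) differs from this
  one only in scale, which cannot affect ISI or any downstream test.
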