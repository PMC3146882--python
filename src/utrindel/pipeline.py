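"""End-to-end orchestration: simulate/load -> select -> classify -> indels
-> ISI -> neutral table -> group comparisons.

A run is driven by a single RunConfig (YAML-loadable) holding either a
``simulate`` block or explicit input paths. One species' annotation drives a
run (the MAF reference species); the cross-species consistency check of the
original design is two runs diffed by the user or the ``diff`` subcommand.
Every stage writes its table under the output directory and the machine-
readable summary lands in results.json; reruns with the same config and
seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import ConfigError, log
from .annotation_io import (
    TranscriptModel,
    group_by_gene,
    load_orthologs,
    load_transcripts,
    select_transcript,
)
from .compare import (
    bootstrap_equalized,
    compare_group,
    match_neutral,
    tertile_analysis,
)
from .indels import extract_indels, filter_alignments, read_maf
from .isi import (
    TranscriptIndels,
    build_neutral_table,
    compute_isi,
)
from .simulate import SimulationConfig, emit_dataset
from .uorf import classify_transcript, scan_uaugs

UAUG_GROUPS = ("Ga", "Gs", "Gv")


@dataclass
class RunConfig:
    """One pipeline run: either a simulate block or explicit input paths."""

    seed: int
    out_dir: Path
    simulate: SimulationConfig | None = None
    ref_gtf: Path | None = None
    ref_fasta: Path | None = None
    other_gtf: Path | None = None
    other_fasta: Path | None = None
    maf: Path | None = None
    orthologs: Path | None = None
    ref_species: str = "speciesA"
    other_species: str = "speciesB"
    selection_criterion: str = "random"
    pseudocount: float = 0.5
    n_shuffles: int = 1000
    n_resamples: int = 1000
    tie_rule: str = "strict"
    neutral_sweep: tuple = ()       # extra percents for a reference sweep
    allow_list: Path | None = None

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        has_paths = all(p is not None for p in (
            self.ref_gtf, self.ref_fasta, self.other_gtf, self.other_fasta,
            self.maf, self.orthologs))
        if (self.simulate is None) == (not has_paths):
            raise ConfigError("exactly one of a simulate block or the full "
                              "set of input paths must be given")
        if self.simulate is not None:
            self.ref_species, self.other_species = self.simulate.species

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seed" not in data:
            raise ConfigError("run config must set a seed")
        if "simulate" in data and data["simulate"] is not None:
            sim = dict(data["simulate"])
            sim.setdefault("seed", data["seed"])
            data["simulate"] = SimulationConfig(**{
                k: tuple(v) if k in ("selected_groups", "species") else v
                for k, v in sim.items()})
        if "neutral_sweep" in data:
            data["neutral_sweep"] = tuple(data["neutral_sweep"])
        for key in ("out_dir", "ref_gtf", "ref_fasta", "other_gtf",
                    "other_fasta", "maf", "orthologs", "allow_list"):
            if data.get(key) is not None:
                data[key] = Path(data[key])
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown run config keys: {sorted(bad)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the results dict written to results.json."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: Counter[str] = Counter()

    if config.simulate is not None:
        paths = emit_dataset(config.simulate, out / "data")
        config = dataclasses.replace(
            config, simulate=None,
            ref_gtf=paths["ref_gtf"], ref_fasta=paths["ref_fasta"],
            other_gtf=paths["other_gtf"], other_fasta=paths["other_fasta"],
            maf=paths["maf"], orthologs=paths["orthologs"])

    allow = None
    if config.allow_list is not None:
        from .annotation_io import load_allow_list
        allow = load_allow_list(config.allow_list)

    ref_tx = load_transcripts(config.ref_gtf, config.ref_fasta,
                              config.ref_species, allow_list=allow)
    oth_tx = load_transcripts(config.other_gtf, config.other_fasta,
                              config.other_species)
    ref_genes = {g.gene_id: g for g in group_by_gene(ref_tx)}
    oth_genes = {g.gene_id: g for g in group_by_gene(oth_tx)}
    pairs = load_orthologs(config.orthologs)
    counts["ortholog_pairs"] = len(pairs)

    blocks_by_chrom: dict[str, list] = {}
    for b in read_maf(config.maf, config.ref_species):
        blocks_by_chrom.setdefault(b.ref_chrom, []).append(b)

    selected: list[tuple[TranscriptModel, TranscriptModel]] = []
    for pair in pairs:
        g_ref = ref_genes.get(pair.gene_id_species1)
        g_oth = oth_genes.get(pair.gene_id_species2)
        if g_ref is None or g_oth is None:
            counts["pair_gene_missing"] += 1
            continue
        t_ref = select_transcript(g_ref, config.selection_criterion, config.seed)
        t_oth = select_transcript(g_oth, config.selection_criterion, config.seed)
        if t_ref is None or t_oth is None:
            counts["pair_no_selectable_transcript"] += 1
            continue
        selected.append((t_ref, t_oth))
    counts["genes_selected"] = len(selected)

    # classification
    classes = {}
    uorf_rows = []
    for t_ref, _ in selected:
        uorfs = scan_uaugs(t_ref)
        cls = classify_transcript(t_ref, uorfs)
        classes[t_ref.transcript_id] = cls
        counts[f"group_{cls.group}"] += 1
        for u in uorfs:
            uorf_rows.append((t_ref.transcript_id, u.uaug_offset, u.uorf_type,
                              u.orf_length_nt, u.stop_offset))

    # alignment filters + indel extraction
    indel_map: dict[str, TranscriptIndels] = {}
    rejection_rows = []
    indel_rows = []
    for t_ref, t_oth in selected:
        span = t_ref.genomic_span()
        cand = [b for b in blocks_by_chrom.get(t_ref.chrom, [])
                if b.ref_end > span[0] and b.ref_start < span[1]]
        accepted, reason = filter_alignments(cand, t_ref, t_oth)
        if accepted is None:
            rejection_rows.append((t_ref.gene_id, reason))
            counts[f"rejected_{reason}"] += 1
            continue
        records, n_over = extract_indels(accepted, t_ref)
        counts["oversize_gaps"] += n_over
        indel_map[t_ref.transcript_id] = TranscriptIndels(
            t_ref.transcript_id, t_ref.utr5_len, tuple(records))
        for r in records:
            indel_rows.append((t_ref.transcript_id, r.utr_offset,
                               r.length_nt, r.size_class))
    counts["genes_with_alignment"] = len(indel_map)
    counts["indels_total"] = len(indel_rows)

    # per-transcript ISI for uAUG groups
    isi_rows = []
    group_isis: dict[str, dict[str, float]] = {g: {} for g in UAUG_GROUPS}
    seeds = np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    tx_order = sorted(tid for tid in indel_map
                      if classes[tid].group in UAUG_GROUPS)
    for tid, ss in zip(tx_order, seeds.spawn(len(tx_order))):
        cls = classes[tid]
        ti = indel_map[tid]
        ref_off = cls.reference_uaug_offset
        if not ti.indels or not 0 < ref_off < ti.utr_length:
            continue
        res = compute_isi(ti.indels, ti.utr_length, ref_off,
                          config.n_shuffles, tie_rule=config.tie_rule,
                          pseudocount=config.pseudocount,
                          rng=np.random.default_rng(ss), transcript_id=tid)
        group_isis[cls.group][tid] = res.isi
        isi_rows.append((tid, cls.group, len(ti.indels),
                         res.r_observed.value, res.isi, res.exact))

    # neutral table from indel-containing G0 transcripts
    g0_items = [indel_map[tid] for tid in sorted(indel_map)
                if classes[tid].group == "G0" and indel_map[tid].indels]
    counts["g0_indel_containing"] = len(g0_items)

    needed = set(int(p) for p in config.neutral_sweep)
    matched: dict[str, int] = {}
    for g in UAUG_GROUPS:
        members = [classes[tid] for tid in group_isis[g]]
        if members:
            matched[g] = match_neutral(members)
            needed.add(matched[g])
    gv_classes = [classes[tid] for tid in group_isis["Gv"]]
    if len(gv_classes) >= 3:
        from .compare import tertile_split
        usable = sorted(gv_classes,
                        key=lambda c: (c.relative_position, c.transcript_id))
        start = 0
        for size in tertile_split(len(usable)):
            needed.add(match_neutral(usable[start:start + size]))
            start += size

    results: dict = {"counts": dict(sorted(counts.items())),
                     "matched_percent": matched,
                     "comparisons": [], "tertiles": [], "bootstrap": {},
                     "neutral_sweep_median_isi": {}}
    table = None
    if g0_items and needed:
        table = build_neutral_table(
            g0_items, sorted(needed), config.n_shuffles,
            seed=config.seed, tie_rule=config.tie_rule,
            pseudocount=config.pseudocount)
        for p in sorted(int(q) for q in config.neutral_sweep):
            results["neutral_sweep_median_isi"][str(p)] = table.median(p)

    # comparisons
    if table is not None:
        for g in UAUG_GROUPS:
            isis = list(group_isis[g].values())
            if len(isis) < 2:
                continue
            comp = compare_group(isis, table.distributions[matched[g]],
                                 group=g, matched_percent=matched[g])
            results["comparisons"].append(_comp_dict(comp))
        if len(gv_classes) >= 3:
            for comp in tertile_analysis(gv_classes, group_isis["Gv"], table):
                results["tertiles"].append(_comp_dict(comp))
        boot_groups = {g: list(group_isis[g].values()) for g in UAUG_GROUPS
                       if len(group_isis[g]) >= 2}
        if boot_groups:
            target_n = len(group_isis["Ga"]) if len(group_isis["Ga"]) >= 2 \
                else min(len(v) for v in boot_groups.values())
            boot = bootstrap_equalized(
                boot_groups,
                {g: table.distributions[matched[g]] for g in boot_groups},
                target_n=target_n, n_resamples=config.n_resamples,
                seed=config.seed)
            for g, b in sorted(boot.items()):
                results["bootstrap"][g] = {
                    "resample_size": b.resample_size,
                    "n_resamples": b.n_resamples,
                    "f_sig": b.f_sig,
                    "ks_vs": {o: {"ks_statistic": v[0], "ks_p": v[1]}
                              for o, v in sorted(b.ks_vs.items())},
                }
            _write_bootstrap_tsv(out, boot)

    _write_stage_tables(out, selected, classes, uorf_rows, indel_rows,
                        rejection_rows, isi_rows, table)
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True)
    _write_report(out / "report.txt", results)
    log.info("run_pipeline: finished, results in %s", out)
    return results


def _comp_dict(comp) -> dict:
    d = dataclasses.asdict(comp)
    d["stars"] = comp.stars
    return d


def _write_stage_tables(out, selected, classes, uorf_rows, indel_rows,
                        rejection_rows, isi_rows, table) -> None:
    pd.DataFrame(
        [(t.gene_id, t.transcript_id, t.species, t.utr5_len,
          classes[t.transcript_id].group,
          classes[t.transcript_id].reference_uaug_offset,
          classes[t.transcript_id].relative_position)
         for t, _ in selected],
        columns=["gene_id", "transcript_id", "species", "utr5_len",
                 "group", "reference_uaug_offset", "relative_position"],
    ).to_csv(out / "transcripts.tsv", sep="\t", index=False)
    pd.DataFrame(uorf_rows, columns=[
        "transcript_id", "uaug_offset", "uorf_type", "orf_length_nt",
        "stop_offset"]).to_csv(out / "uorfs.tsv", sep="\t", index=False)
    pd.DataFrame(indel_rows, columns=[
        "transcript_id", "utr_offset", "length_nt", "size_class",
    ]).to_csv(out / "indels.tsv", sep="\t", index=False)
    pd.DataFrame(rejection_rows, columns=["gene_id", "reason"]).to_csv(
        out / "rejections.tsv", sep="\t", index=False)
    pd.DataFrame(isi_rows, columns=[
        "transcript_id", "group", "n_indels", "r_observed", "isi", "exact",
    ]).to_csv(out / "isi.tsv", sep="\t", index=False)
    if table is not None:
        rows = []
        for p in table.percents:
            for tid, v in zip(table.transcript_ids, table.distributions[p]):
                rows.append((p, tid, v))
        pd.DataFrame(rows, columns=["percent", "transcript_id", "isi"]).to_csv(
            out / "neutral.tsv", sep="\t", index=False)


def _write_bootstrap_tsv(out, boot) -> None:
    rows = []
    for g, b in sorted(boot.items()):
        for i, p in enumerate(b.p_values):
            rows.append((g, i, p))
    pd.DataFrame(rows, columns=["group", "resample", "p_value"]).to_csv(
        out / "bootstrap_pvalues.tsv", sep="\t", index=False)


def _write_report(path: Path, results: dict) -> None:
    lines = ["utrindel pipeline report", "=" * 24, "", "Stage counts:"]
    for k, v in results["counts"].items():
        lines.append(f"  {k}: {v}")
    lines += ["", "Group vs matched neutral (Mann-Whitney U, two-sided):"]
    for c in results["comparisons"] + results["tertiles"]:
        lines.append(
            f"  {c['group']:5s} vs G0({c['matched_percent']}%): "
            f"n={c['n_group']} median ISI {c['median_group_isi']:.3f} vs "
            f"{c['median_neutral_isi']:.3f}, U={c['u_statistic']:.1f}, "
            f"P={c['p_value']:.3g} {c['stars']}")
    if results["bootstrap"]:
        lines += ["", "Size-equalised bootstrap:"]
        for g, b in results["bootstrap"].items():
            ks = ", ".join(f"KS vs {o}: P={v['ks_p']:.3g}"
                           for o, v in b["ks_vs"].items())
            lines.append(f"  {g}: n={b['resample_size']} "
                         f"F_sig={b['f_sig']:.3f}  {ks}")
    if results["neutral_sweep_median_isi"]:
        lines += ["", "Neutral reference sweep (median ISI):"]
        for p, v in sorted(results["neutral_sweep_median_isi"].items(),
                           key=lambda kv: int(kv[0])):
            lines.append(f"  {p:>3s}%: {v:.3f}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# resume support: comparisons from cached stage tables
# ---------------------------------------------------------------------------

def compare_from_tables(isi_tsv: str | Path, neutral_tsv: str | Path,
                        transcripts_tsv: str | Path) -> list[dict]:
    """Recompute the group comparisons from the on-disk stage tables."""
    isi = pd.read_csv(isi_tsv, sep="\t")
    neutral = pd.read_csv(neutral_tsv, sep="\t")
    tx = pd.read_csv(transcripts_tsv, sep="\t").set_index("transcript_id")
    out = []
    for g in UAUG_GROUPS:
        sub = isi[isi.group == g]
        if len(sub) < 2:
            continue
        rel = tx.loc[sub.transcript_id, "relative_position"].astype(float)
        from ._util import round_half_up
        percent = min(max(round_half_up(100.0 * float(np.median(rel))), 1), 99)
        ref = neutral[neutral.percent == percent]
        comp = compare_group(sub.isi.to_numpy(), ref.isi.to_numpy(),
                             group=g, matched_percent=percent)
        out.append(_comp_dict(comp))
    return out
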