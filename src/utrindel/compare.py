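"""Group-versus-neutral inference on ISI distributions.

Each uAUG group (Ga, Gs, Gv) is matched to the neutral (G0) reference whose
artificial reference point sits at the group's median relative uAUG
position, then compared with a two-sided Mann-Whitney U test. The Gv group
is additionally split into position tertiles, and a size-equalised bootstrap
(resampling each group down to a common n, 1,000 resamples by default)
yields per-group P-value distributions summarised by F_sig (the fraction of
P values below 0.05) and compared pairwise with two-sample
Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._util import ConfigError, round_half_up
from .isi import NeutralIsiTable
from .uorf import TranscriptClass

SIGNIFICANCE_BANDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))
F_SIG_ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    group: str
    matched_percent: int
    n_group: int
    n_neutral: int
    median_group_isi: float
    median_neutral_isi: float
    u_statistic: float
    p_value: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass(frozen=True)
class BootstrapResult:
    group: str
    n_resamples: int
    resample_size: int
    p_values: np.ndarray
    f_sig: float
    ks_vs: dict = field(default_factory=dict)  # other group -> (ks_stat, ks_p)


def significance_stars(p: float) -> str:
    for cutoff, stars in SIGNIFICANCE_BANDS:
        if p < cutoff:
            return stars
    return ""


def match_neutral(group_classes: Sequence[TranscriptClass],
                  table: NeutralIsiTable | None = None) -> int:
    """Neutral reference percent: the rounded median relative uAUG position
    of the group, clamped to [1, 99]."""
    positions = [c.relative_position for c in group_classes
                 if c.relative_position is not None]
    if not positions:
        raise ConfigError("match_neutral requires a non-empty group with "
                          "reference uAUGs")
    percent = round_half_up(100.0 * float(np.median(positions)))
    percent = min(max(percent, 1), 99)
    if table is not None and percent not in table.distributions:
        raise ConfigError(f"neutral table lacks percent {percent}")
    return percent


def pooled_matched_neutral(group_classes: Sequence[TranscriptClass],
                           table: NeutralIsiTable) -> np.ndarray:
    """Per-transcript matching: pool, for every group transcript, the
    neutral distribution at that transcript's own reference percent.

    This absorbs within-group position spread that a single median-matched
    percent cannot; it needs a table covering every member's percent.
    """
    pools = []
    for c in group_classes:
        if c.relative_position is None:
            continue
        percent = min(max(round_half_up(100.0 * c.relative_position), 1), 99)
        if percent not in table.distributions:
            raise ConfigError(f"neutral table lacks percent {percent} "
                              f"needed by {c.transcript_id}")
        pools.append(table.distributions[percent])
    if not pools:
        raise ConfigError("pooled_matched_neutral requires a non-empty group")
    return np.concatenate(pools)


def compare_group(group_isis: Sequence[float], neutral_isis: Sequence[float],
                  group: str = "", matched_percent: int = 0,
                  ) -> ComparisonResult:
    """Two-sided Mann-Whitney U comparison of a group's ISIs against the
    matched neutral distribution (exact for small untied samples, normal
    approximation with tie correction otherwise)."""
    g = np.asarray(group_isis, dtype=float)
    n = np.asarray(neutral_isis, dtype=float)
    if g.size < 2 or n.size < 2:
        raise ConfigError("compare_group needs at least 2 values per sample")
    u, p = stats.mannwhitneyu(g, n, alternative="two-sided", method="auto")
    return ComparisonResult(
        group=group, matched_percent=matched_percent,
        n_group=int(g.size), n_neutral=int(n.size),
        median_group_isi=float(np.median(g)),
        median_neutral_isi=float(np.median(n)),
        u_statistic=float(u), p_value=float(p),
    )


def tertile_split(n: int) -> tuple[int, int, int]:
    """Sizes of three near-equal contiguous groups, remainder-first."""
    base, rem = divmod(n, 3)
    return tuple(base + (1 if i < rem else 0) for i in range(3))


def tertile_analysis(gv_classes: Sequence[TranscriptClass],
                     isis: Mapping[str, float],
                     table: NeutralIsiTable) -> list[ComparisonResult]:
    """Split Gv transcripts into three position tertiles (Gv_1 closest to the
    cap) and compare each against its own matched neutral distribution.

    `isis` maps transcript_id to ISI for the indel-containing transcripts;
    classes without an ISI are ignored.
    """
    usable = sorted(
        (c for c in gv_classes if c.transcript_id in isis
         and c.relative_position is not None),
        key=lambda c: (c.relative_position, c.transcript_id),
    )
    if len(usable) < 3:
        raise ConfigError("tertile_analysis needs >= 3 indel-containing "
                          "transcripts")
    sizes = tertile_split(len(usable))
    out: list[ComparisonResult] = []
    start = 0
    for i, size in enumerate(sizes, start=1):
        sub = usable[start : start + size]
        start += size
        percent = match_neutral(sub, table)
        out.append(compare_group(
            [isis[c.transcript_id] for c in sub],
            table.distributions[percent],
            group=f"Gv_{i}", matched_percent=percent,
        ))
    return out


def bootstrap_equalized(group_isis: Mapping[str, Sequence[float]],
                        neutral_isis: Mapping[str, Sequence[float]],
                        target_n: int,
                        n_resamples: int = 1000,
                        seed: int = 0) -> dict[str, BootstrapResult]:
    """Size-equalised bootstrap of the group-vs-neutral comparisons.

    For each group, target_n ISIs are drawn with replacement and compared
    (Mann-Whitney U, two-sided) against the group's fixed matched neutral
    distribution; the resulting P-value vectors give F_sig and feed pairwise
    Kolmogorov-Smirnov tests between groups.
    """
    if n_resamples < 1:
        raise ConfigError("n_resamples must be >= 1")
    if target_n < 2:
        raise ConfigError("target_n must be >= 2")
    rng = np.random.default_rng(seed)
    results: dict[str, BootstrapResult] = {}
    for group in sorted(group_isis):
        g = np.asarray(group_isis[group], dtype=float)
        n = np.asarray(neutral_isis[group], dtype=float)
        draws = rng.choice(g, size=(n_resamples, target_n), replace=True)
        pvals = np.empty(n_resamples)
        for i in range(n_resamples):
            _, pvals[i] = stats.mannwhitneyu(
                draws[i], n, alternative="two-sided", method="asymptotic")
        results[group] = BootstrapResult(
            group=group, n_resamples=n_resamples, resample_size=target_n,
            p_values=pvals, f_sig=float(np.mean(pvals < F_SIG_ALPHA)),
        )
    labels = sorted(results)
    for a in labels:
        for b in labels:
            if a != b:
                ks, ksp = stats.ks_2samp(results[a].p_values,
                                         results[b].p_values)
                results[a].ks_vs[b] = (float(ks), float(ksp))
    return results
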