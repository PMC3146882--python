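"""The R statistic and the Indel Selection Index (ISI).

R compares the non-3n : 3n indel ratio downstream of a reference point with
the same ratio upstream, on a log2 scale and with a pseudocount c:

    R = log2[ ((N_n3n,d + c) / (N_3n,d + c)) / ((N_n3n,u + c) / (N_3n,u + c)) ]

R = 0 when the two ratios are equal (no size preference); R < 0 indicates
relative depletion of non-3n indels downstream. The default pseudocount is
0.5, which keeps R finite for any counts. The log base only rescales R and
cannot change any rank-based quantity built on it.

ISI is the proportion of positionally shuffled indel configurations whose R
is strictly smaller than the observed R. Shuffling redraws each indel's
position independently and uniformly over the utr_length + 1 possible
anchor points while preserving indel lengths and numbers (1,000 shuffles by
default). A small ISI therefore means the observed configuration places
unexpectedly few non-3n indels downstream. ``exact_isi`` replaces the Monte
Carlo with exact enumeration over the binomial placement distribution and
serves as the oracle for the shuffle-based estimate.

The neutral reference is built from uAUG-free (G0) transcripts, computing
ISI with an artificial reference point swept across the 5'UTR in 1% steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from ._util import ConfigError, round_half_up
from .indels import IndelCounts, IndelRecord, partition_indels

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_N_SHUFFLES = 1000
_R_TOL = 1e-9
EXACT_MAX_INDELS = 12

TIE_RULES = ("strict", "midp")


@dataclass(frozen=True)
class RValue:
    value: float
    pseudocount: float
    counts: IndelCounts


@dataclass(frozen=True)
class IsiResult:
    transcript_id: str
    r_observed: RValue
    n_shuffles: int
    n_smaller: int
    n_tied: int
    isi: float
    exact: bool = False


class TranscriptIndels(NamedTuple):
    """Minimal per-transcript input for ISI computations."""

    transcript_id: str
    utr_length: int
    indels: tuple[IndelRecord, ...]


@dataclass(frozen=True)
class NeutralIsiTable:
    """Empirical ISI distributions of G0 transcripts per reference percent."""

    distributions: Mapping[int, np.ndarray]   # percent -> ISI values
    transcript_ids: tuple[str, ...]           # same transcript set at every percent

    @property
    def percents(self) -> list[int]:
        return sorted(self.distributions)

    def median(self, percent: int) -> float:
        return float(np.median(self.distributions[percent]))


# ---------------------------------------------------------------------------
# R
# ---------------------------------------------------------------------------

def compute_r(counts: IndelCounts,
              pseudocount: float = DEFAULT_PSEUDOCOUNT) -> RValue:
    """Log2 ratio-of-ratios of non-3n to 3n counts, downstream vs upstream."""
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be > 0")
    value = _r_value(counts.n_n3n_down, counts.n_3n_down,
                     counts.n_n3n_up, counts.n_3n_up, pseudocount)
    return RValue(float(value), pseudocount, counts)


def _r_value(nd, td, nu, tu, c):
    return (np.log2((nd + c) / (td + c)) - np.log2((nu + c) / (tu + c)))


# ---------------------------------------------------------------------------
# shuffle null and ISI
# ---------------------------------------------------------------------------

def _class_counts(indels: Sequence[IndelRecord]) -> tuple[int, int]:
    k_n3n = sum(1 for r in indels if r.size_class == "n3n")
    return k_n3n, len(indels) - k_n3n


def shuffle_null(indels: Sequence[IndelRecord], utr_length: int,
                 reference_offset: int, n_shuffles: int = DEFAULT_N_SHUFFLES,
                 seed: int | None = None,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """R values of positionally shuffled configurations.

    Each shuffle redraws every indel's anchor uniformly on
    {0, ..., utr_length}; lengths and size classes are retained.
    """
    if n_shuffles < 1:
        raise ConfigError("n_shuffles must be >= 1")
    if not indels:
        raise ConfigError("shuffle_null requires at least one indel")
    if not 0 < reference_offset < utr_length:
        raise ConfigError("reference_offset must lie strictly inside the 5'UTR")
    if rng is None:
        rng = np.random.default_rng(seed)
    k_n3n, k_3n = _class_counts(indels)
    down = rng.integers(0, utr_length + 1,
                        size=(n_shuffles, k_n3n + k_3n)) >= reference_offset
    nd = down[:, :k_n3n].sum(axis=1)
    td = down[:, k_n3n:].sum(axis=1)
    return _r_value(nd, td, k_n3n - nd, k_3n - td, pseudocount)


def compute_isi(indels: Sequence[IndelRecord], utr_length: int,
                reference_offset: int, n_shuffles: int = DEFAULT_N_SHUFFLES,
                seed: int | None = None, tie_rule: str = "strict",
                pseudocount: float = DEFAULT_PSEUDOCOUNT,
                rng: np.random.Generator | None = None,
                transcript_id: str = "") -> IsiResult:
    """Monte Carlo ISI: proportion of shuffled R values below the observed R.

    tie_rule "strict" (default) counts only strictly smaller shuffles;
    "midp" adds half of the ties (avoiding forced ISI = 0 for tie-only
    configurations).
    """
    _check_tie_rule(tie_rule)
    observed = compute_r(partition_indels(indels, reference_offset), pseudocount)
    shuffled = shuffle_null(indels, utr_length, reference_offset,
                            n_shuffles, seed, pseudocount, rng)
    n_smaller = int(np.sum(shuffled < observed.value - _R_TOL))
    n_tied = int(np.sum(np.abs(shuffled - observed.value) <= _R_TOL))
    isi = n_smaller / n_shuffles
    if tie_rule == "midp":
        isi = (n_smaller + 0.5 * n_tied) / n_shuffles
    return IsiResult(transcript_id, observed, n_shuffles, n_smaller,
                     n_tied, float(isi), exact=False)


def exact_isi(indels: Sequence[IndelRecord], utr_length: int,
              reference_offset: int, tie_rule: str = "strict",
              pseudocount: float = DEFAULT_PSEUDOCOUNT,
              transcript_id: str = "") -> IsiResult:
    """Exact ISI by enumerating the placement distribution.

    Under uniform independent placement the downstream count of each size
    class is binomial with p = (# anchor points >= reference) / (utr_length
    + 1); the (k_n3n + 1)(k_3n + 1) outcomes are enumerated exactly.
    """
    _check_tie_rule(tie_rule)
    if not indels:
        raise ConfigError("exact_isi requires at least one indel")
    if len(indels) > EXACT_MAX_INDELS:
        raise ConfigError(f"exact_isi supports at most {EXACT_MAX_INDELS} "
                          "indels; use compute_isi")
    if not 0 < reference_offset < utr_length:
        raise ConfigError("reference_offset must lie strictly inside the 5'UTR")
    observed = compute_r(partition_indels(indels, reference_offset), pseudocount)
    k_n3n, k_3n = _class_counts(indels)
    p_down = (utr_length - reference_offset + 1) / (utr_length + 1)
    pn = stats.binom.pmf(np.arange(k_n3n + 1), k_n3n, p_down)
    pt = stats.binom.pmf(np.arange(k_3n + 1), k_3n, p_down)
    nd, td = np.meshgrid(np.arange(k_n3n + 1), np.arange(k_3n + 1),
                         indexing="ij")
    r = _r_value(nd, td, k_n3n - nd, k_3n - td, pseudocount)
    prob = pn[:, None] * pt[None, :]
    p_smaller = float(prob[r < observed.value - _R_TOL].sum())
    p_tied = float(prob[np.abs(r - observed.value) <= _R_TOL].sum())
    isi = p_smaller if tie_rule == "strict" else p_smaller + 0.5 * p_tied
    return IsiResult(transcript_id, observed, 0, 0, 0, float(isi), exact=True)


def _check_tie_rule(tie_rule: str) -> None:
    if tie_rule not in TIE_RULES:
        raise ConfigError(f"tie_rule must be one of {TIE_RULES}")


# ---------------------------------------------------------------------------
# neutral reference table
# ---------------------------------------------------------------------------

def reference_offset_for_percent(percent: int, utr_length: int) -> int:
    """Reference point at a percent of the 5'UTR length, clamped so it stays
    strictly inside the UTR."""
    off = round_half_up(percent / 100.0 * utr_length)
    return min(max(off, 1), utr_length - 1)


def build_neutral_table(g0_transcripts: Sequence[TranscriptIndels],
                        percents: Sequence[int],
                        n_shuffles: int = DEFAULT_N_SHUFFLES,
                        seed: int = 0, tie_rule: str = "strict",
                        pseudocount: float = DEFAULT_PSEUDOCOUNT,
                        ) -> NeutralIsiTable:
    """ISI distributions of indel-containing G0 transcripts with the
    reference point placed at each given percent of each 5'UTR's length."""
    items = [t for t in g0_transcripts if t.indels and t.utr_length >= 2]
    if not items:
        raise ConfigError("build_neutral_table requires at least one "
                          "indel-containing G0 transcript")
    percents = sorted(set(int(p) for p in percents))
    if any(not 1 <= p <= 99 for p in percents):
        raise ConfigError("percents must lie in 1..99")
    dists: dict[int, np.ndarray] = {p: np.empty(len(items)) for p in percents}
    seeds = np.random.SeedSequence(seed).spawn(len(items))
    for i, (t, ss) in enumerate(zip(items, seeds)):
        rng = np.random.default_rng(ss)
        for p in percents:
            ref = reference_offset_for_percent(p, t.utr_length)
            res = compute_isi(t.indels, t.utr_length, ref, n_shuffles,
                              tie_rule=tie_rule, pseudocount=pseudocount,
                              rng=rng, transcript_id=t.transcript_id)
            dists[p][i] = res.isi
    return NeutralIsiTable(distributions=dists,
                           transcript_ids=tuple(t.transcript_id for t in items))
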