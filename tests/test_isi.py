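"""R statistic, shuffle-null ISI, exact enumeration oracle, neutral table."""

import itertools
import math

import numpy as np
import pytest

from utrindel._util import ConfigError
from utrindel.indels import IndelCounts, IndelRecord, partition_indels
from utrindel.isi import (
    build_neutral_table,
    compute_isi,
    compute_r,
    exact_isi,
    shuffle_null,
)


def recs(*pos_len):
    return [IndelRecord("t", p, l) for p, l in pos_len]


class TestComputeR:
    def test_matches_hand_formula_on_grid(self):
        for nd, td, nu, tu in itertools.product(range(6), repeat=4):
            for c in (0.25, 0.5, 1.0):
                expected = math.log2(((nd + c) / (td + c)) /
                                     ((nu + c) / (tu + c)))
                got = compute_r(IndelCounts(nd, td, nu, tu), c).value
                assert got == pytest.approx(expected, abs=1e-12)

    def test_antisymmetry_under_side_swap(self):
        for nd, td, nu, tu in itertools.product(range(6), repeat=4):
            for c in (0.25, 0.5, 1.0):
                counts = IndelCounts(nd, td, nu, tu)
                assert compute_r(counts.swapped(), c).value == pytest.approx(
                    -compute_r(counts, c).value, abs=1e-12)

    @pytest.mark.parametrize("counts", [
        IndelCounts(0, 0, 0, 0), IndelCounts(2, 1, 2, 1),
        IndelCounts(3, 3, 1, 1),
    ])
    def test_zero_for_proportional_counts(self, counts):
        for c in (0.25, 0.5, 1.0):
            assert compute_r(counts, c).value == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        assert compute_r(IndelCounts(1, 3, 4, 2), 0.5).value == pytest.approx(
            -2.0704, abs=1e-4)

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(ConfigError):
            compute_r(IndelCounts(1, 1, 1, 1), 0.0)


class TestShuffleNull:
    def test_single_indel_two_outcomes(self):
        r = shuffle_null(recs((60, 2)), 100, 50, n_shuffles=4000, seed=0)
        values = set(np.round(r, 10))
        assert values == {round(math.log2(3), 10), round(-math.log2(3), 10)}
        frac_down = np.mean(r > 0)
        assert abs(frac_down - 51 / 101) < 0.03

    def test_errors(self):
        with pytest.raises(ConfigError):
            shuffle_null(recs((60, 2)), 100, 50, n_shuffles=0)
        with pytest.raises(ConfigError):
            shuffle_null(recs((60, 2)), 100, 0)
        with pytest.raises(ConfigError):
            shuffle_null([], 100, 50)

    def test_seed_determinism(self):
        a = shuffle_null(recs((60, 2), (10, 3)), 100, 50, 500, seed=7)
        b = shuffle_null(recs((60, 2), (10, 3)), 100, 50, 500, seed=7)
        assert np.array_equal(a, b)


class TestComputeIsi:
    def test_single_downstream_indel_near_half(self):
        res = compute_isi(recs((60, 2)), 100, 50, n_shuffles=1000, seed=3)
        exact = 50 / 101
        sd = math.sqrt(exact * (1 - exact) / 1000)
        assert abs(res.isi - exact) <= 4 * sd
        assert res.n_smaller == res.isi * 1000

    def test_tie_handling(self):
        # one indel of each size class, both downstream: observed R = 0, and
        # every shuffle placing both indels on the same side ties with it
        config = recs((60, 1), (70, 3))
        strict = compute_isi(config, 100, 50, 1000, seed=1)
        midp = compute_isi(config, 100, 50, 1000, seed=1, tie_rule="midp")
        assert strict.n_tied > 0
        assert strict.isi == strict.n_smaller / 1000
        assert midp.isi == (strict.n_smaller + 0.5 * strict.n_tied) / 1000
        # exact enumeration: only the (n3n up, 3n down) outcome has R < 0
        # (~1/4); same-side outcomes (~1/2) tie, so midp sits at 1/2
        ex_strict = exact_isi(config, 100, 50).isi
        ex_midp = exact_isi(config, 100, 50, tie_rule="midp").isi
        assert ex_midp == pytest.approx(0.5, abs=0.02)
        assert abs(strict.isi - ex_strict) < 0.05

    def test_determinism_bit_for_bit(self):
        a = compute_isi(recs((60, 2), (10, 1)), 100, 40, 500, seed=11)
        b = compute_isi(recs((60, 2), (10, 1)), 100, 40, 500, seed=11)
        assert a == b

    def test_log_base_invariance(self):
        # ISI depends only on the rank order of R, which any log base
        # preserves: counting with ln-scaled values changes nothing
        r_obs = compute_r(partition_indels(recs((60, 2), (10, 1)), 40)).value
        sh = shuffle_null(recs((60, 2), (10, 1)), 100, 40, 500, seed=5)
        assert np.sum(sh < r_obs - 1e-9) == np.sum(
            sh * math.log(2) < (r_obs * math.log(2)) - 1e-9)


def brute_force_isi(lengths, utr_len, ref, observed_positions,
                    tie_rule="strict"):
    """Independent oracle: enumerate every placement of every indel."""
    obs = recs(*zip(observed_positions, lengths))
    r_obs = compute_r(partition_indels(obs, ref)).value
    smaller = tied = total = 0
    for pos in itertools.product(range(utr_len + 1), repeat=len(lengths)):
        r = compute_r(partition_indels(recs(*zip(pos, lengths)), ref)).value
        total += 1
        if r < r_obs - 1e-9:
            smaller += 1
        elif abs(r - r_obs) <= 1e-9:
            tied += 1
    if tie_rule == "strict":
        return smaller / total
    return (smaller + 0.5 * tied) / total


class TestExactIsi:
    def test_single_indel_closed_form(self):
        res = exact_isi(recs((60, 2)), 100, 50)
        assert res.isi == pytest.approx(50 / 101, abs=1e-12)
        assert res.exact

    @pytest.mark.parametrize("lengths,positions,ref", [
        ((2, 1), (3, 9), 5),        # two non-3n indels
        ((3, 3), (2, 8), 4),        # all 3n: R fixed, strict ISI 0
        ((1, 3, 2), (0, 5, 10), 6),  # mixed classes
        ((2, 6), (10, 1), 7),
    ])
    def test_matches_full_position_enumeration(self, lengths, positions, ref):
        utr_len = 10
        for tie_rule in ("strict", "midp"):
            expected = brute_force_isi(lengths, utr_len, ref, positions,
                                       tie_rule)
            got = exact_isi(recs(*zip(positions, lengths)), utr_len, ref,
                            tie_rule=tie_rule).isi
            assert got == pytest.approx(expected, abs=1e-12)

    def test_symmetric_midpoint(self):
        # two non-3n indels, one per side, reference at the exact middle of
        # the placement grid: observed R = 0 and midp ISI is 1/2 by symmetry
        res = exact_isi(recs((30, 1), (70, 1)), 99, 50, tie_rule="midp")
        assert res.isi == pytest.approx(0.5, abs=1e-12)

    def test_too_many_indels_rejected(self):
        with pytest.raises(ConfigError):
            exact_isi(recs(*[(i, 1) for i in range(13)]), 100, 50)

    def test_monte_carlo_agrees_with_exact(self):
        rng = np.random.default_rng(0)
        fails = 0
        for i in range(100):
            k = int(rng.integers(1, 7))
            utr = int(rng.integers(20, 400))
            ref = int(rng.integers(1, utr))
            config = recs(*[(int(rng.integers(0, utr + 1)),
                             int(rng.integers(1, 30))) for _ in range(k)])
            e = exact_isi(config, utr, ref).isi
            m = compute_isi(config, utr, ref, 1000, seed=1000 + i).isi
            sd = max(math.sqrt(e * (1 - e) / 1000), 1e-9)
            if abs(m - e) > 3 * sd:
                fails += 1
        assert fails <= 1


class TestNeutralTable:
    def _g0_items(self, n, seed):
        from utrindel.simulate import (SimulationConfig, simulate_truth,
                                       truth_indels)
        cfg = SimulationConfig(seed=seed, n_genes=n, group_mixture={
            "G0": 1.0, "Ga": 0, "Gs": 0, "Gv": 0})
        return [v for v in truth_indels(simulate_truth(cfg)).values()
                if v.indels]

    def test_bookkeeping_nine_distributions(self):
        items = self._g0_items(60, 4)
        table = build_neutral_table(items, range(10, 100, 10), n_shuffles=50,
                                    seed=1)
        assert table.percents == list(range(10, 100, 10))
        for p in table.percents:
            assert len(table.distributions[p]) == len(items)
            assert np.all((table.distributions[p] >= 0)
                          & (table.distributions[p] <= 1))

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigError):
            build_neutral_table([], [50])

    def test_determinism(self):
        items = self._g0_items(30, 9)
        t1 = build_neutral_table(items, [25, 50], n_shuffles=100, seed=3)
        t2 = build_neutral_table(items, [25, 50], n_shuffles=100, seed=3)
        for p in (25, 50):
            assert np.array_equal(t1.distributions[p], t2.distributions[p])


class TestPseudocountDiagnostic:
    def test_sign_mostly_stable_across_pseudocounts(self):
        """On the default synthetic cohort the sign of R rarely changes with
        the pseudocount (a diagnostic, not a universal law: patterns like
        counts (1,4,0,1) do flip)."""
        from utrindel.simulate import (SimulationConfig, simulate_truth,
                                       truth_indels)
        cfg = SimulationConfig(seed=21, n_genes=400)
        truth = simulate_truth(cfg)
        ind = truth_indels(truth)
        n_tested = n_stable = 0
        for t in truth:
            ti = ind[t.transcript_id]
            ref = t.uaug_offset if t.uaug_offset else t.utr_length // 2
            if not ti.indels or not 0 < ref < t.utr_length:
                continue
            counts = partition_indels(list(ti.indels), ref)
            signs = {np.sign(round(compute_r(counts, c).value, 9))
                     for c in (0.25, 0.5, 1.0)}
            n_tested += 1
            n_stable += len(signs) == 1
        assert n_tested > 200
        assert n_stable / n_tested >= 0.95
        # and the known counterexample does flip
        flips = {np.sign(compute_r(IndelCounts(1, 4, 0, 1), c).value)
                 for c in (0.25, 1.0)}
        assert len(flips) == 2
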