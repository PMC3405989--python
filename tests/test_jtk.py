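"""Unit and property tests for the rank-based rhythm detector."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import circadia.jtk as jtk
from circadia import (
    NullDistribution,
    RhythmScanner,
    TimeGrid,
    bh_adjust,
    build_reference,
    exact_null_tail,
    kendall_s,
    scan_rhythm,
)


def _ref_from_ranks(ranks):
    return jtk.ReferenceWaveform(period=24.0, phase=0.0,
                                 ranks=np.asarray(ranks, dtype=float),
                                 grid=None)


def _brute_force_null(group_sizes):
    """Exact S distribution by enumerating all n! data orderings."""
    ranks, start = [], 1
    for size in group_sizes:
        ranks += [start + (size - 1) / 2.0] * size
        start += size
    ref_signs = jtk._pair_signs(np.array(ranks))
    n = len(ranks)
    from collections import Counter
    counts = Counter()
    for perm in itertools.permutations(range(n)):
        s = int(round(float(np.dot(
            jtk._pair_signs(np.array(perm, dtype=float)), ref_signs))))
        counts[s] += 1
    total = math.factorial(n)
    return {s: c / total for s, c in counts.items()}


class TestTimeGrid:
    def test_regular_design(self, grid):
        assert grid.n == 24 and grid.interval == 2.0 and grid.span == 46.0

    @pytest.mark.parametrize("times", [(0, 2, 4), (0, 2, 2, 4, 6, 8),
                                       (4, 2, 0, 6, 8, 10)])
    def test_invalid_grids_rejected(self, times):
        with pytest.raises(ValueError):
            TimeGrid(times=times)


class TestBuildReference:
    def test_24h_peak_recurs_once_per_day(self, grid):
        ref = build_reference(24, 0, grid)
        top = np.flatnonzero(ref.ranks == ref.ranks.max())
        assert [grid.times[i] for i in top] == [0.0, 24.0]

    def test_12h_reference_has_four_tied_peaks(self, grid):
        ref = build_reference(12, 0, grid)
        top = np.flatnonzero(ref.ranks == ref.ranks.max())
        assert [grid.times[i] for i in top] == [0.0, 12.0, 24.0, 36.0]

    def test_phase_shift_is_cyclic_rank_shift(self):
        one_day = TimeGrid.regular(0, 22, 2)  # 12 points over one period
        r0 = build_reference(24, 0, one_day)
        r6 = build_reference(24, 6, one_day)
        assert np.allclose(np.roll(r0.ranks, 3), r6.ranks)

    def test_full_period_phase_shift_is_identity(self, grid):
        a = build_reference(24, 5, grid)
        b = build_reference(24, 5 + 24, grid)
        assert np.array_equal(a.ranks, b.ranks)

    def test_nonpositive_period_rejected(self, grid):
        with pytest.raises(ValueError):
            build_reference(0, 0, grid)


class TestKendallS:
    @pytest.mark.parametrize("data, ref_ranks, expected", [
        ([1, 2, 3], [1, 2, 3], 3),
        ([3, 2, 1], [1, 2, 3], -3),
        ([1, 3, 2, 4], [1, 2, 3, 4], 4),          # 5 concordant, 1 discordant
        ([1, 2, 3, 4], [1.5, 1.5, 3, 4], 5),      # the tied pair contributes 0
    ])
    def test_pair_counting(self, data, ref_ranks, expected):
        assert kendall_s(data, _ref_from_ranks(ref_ranks)) == expected

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length mismatch"):
            kendall_s([1, 2], _ref_from_ranks([1, 2, 3]))


class TestExactNull:
    @pytest.mark.parametrize("pattern", [
        (1, 1, 1), (2, 1), (2, 2), (3, 1, 2), (2, 2, 2), (1, 1, 1, 1, 1, 1),
        (4, 2, 1),
    ])
    def test_matches_brute_force_enumeration(self, pattern):
        dist = jtk._null_distribution_cached(pattern)
        brute = _brute_force_null(pattern)
        ours = {int(s): m for s, m in zip(dist.support, dist.mass) if m > 0}
        assert set(ours) == set(brute)
        for s, p in brute.items():
            assert ours[s] == pytest.approx(p, abs=1e-12)

    def test_three_distinct_points(self):
        ref = _ref_from_ranks([1, 2, 3])
        assert exact_null_tail(ref, 3) == pytest.approx(2 / 6)
        assert exact_null_tail(ref, 0) == 1.0

    def test_four_distinct_points(self):
        ref = _ref_from_ranks([1, 2, 3, 4])
        assert exact_null_tail(ref, 4) == pytest.approx(8 / 24)

    def test_distribution_invariants(self, grid):
        for period in (12.0, 17.0, 24.0):
            dist = jtk.null_distribution(build_reference(period, 0, grid))
            assert np.sum(dist.mass) == pytest.approx(1.0, abs=1e-12)
            # symmetric about zero
            assert np.allclose(dist.mass, dist.mass[::-1])
            assert dist.support[0] == -dist.support[-1]

    def test_out_of_support_rejected(self):
        ref = _ref_from_ranks([1, 2, 3])
        with pytest.raises(ValueError, match="exceeds"):
            exact_null_tail(ref, 4)

    def test_mass_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            NullDistribution(support=np.array([1, -1]),
                             mass=np.array([0.5, 0.4]))


class TestScan:
    def test_noiseless_cosine_recovered_exactly(self, scanner, grid):
        t = grid.as_array()
        res = scanner.scan(np.cos(2 * np.pi * (t - 8) / 24))
        assert (res.best_period, res.best_phase) == (24.0, 8.0)
        assert res.tau == 1.0
        # the p-value is the smallest attainable tail for that reference
        dist = jtk.null_distribution(build_reference(24, 8, grid))
        assert res.p_value == pytest.approx(dist.two_sided_tail(dist.max_score))

    def test_negated_cosine_is_antiphase(self, scanner, grid):
        t = grid.as_array()
        res = scanner.scan(-np.cos(2 * np.pi * (t - 8) / 24))
        assert (res.best_period, res.best_phase) == (24.0, 20.0)

    def test_constant_series_is_undefined(self, scanner):
        res = scanner.scan(np.ones(24))
        assert res.p_value == 1.0 and res.tau == 0.0
        assert math.isnan(res.best_period) and res.method == "undefined"

    def test_harmonic_cosine_found_at_12h(self, scanner, grid):
        t = grid.as_array()
        res = scanner.scan(np.cos(2 * np.pi * (t - 3) / 12))
        assert (res.best_period, res.best_phase) == (12.0, 3.0)

    def test_reported_p_is_attainable(self, scanner, rng):
        """Every p-value lies in the winning reference's exact tail set."""
        for _ in range(25):
            y = rng.normal(size=24)
            res = scanner.scan(y)
            # the reference at the reported (period, phase) has the winning
            # tie pattern (an antiphase flip reverses ranks, preserving ties)
            dist = jtk.null_distribution(
                build_reference(res.best_period, res.best_phase, scanner.grid))
            tails = {dist.two_sided_tail(int(s)) for s in dist.support if s >= 0}
            assert any(math.isclose(res.p_value, t0) for t0 in tails)

    def test_monotone_transform_invariance(self, scanner, rng):
        for _ in range(10):
            y = rng.normal(size=24)
            a = scanner.scan(y)
            b = scanner.scan(np.exp(y))
            c = scanner.scan(3.0 * y + 17.0)
            assert (a.best_period, a.best_phase, a.p_value, a.s_statistic) == \
                   (b.best_period, b.best_phase, b.p_value, b.s_statistic) == \
                   (c.best_period, c.best_phase, c.p_value, c.s_statistic)

    @pytest.mark.parametrize("shift", [1, 2, 3, 5, 11])
    def test_circular_shift_moves_phase(self, scanner, grid, shift):
        t = grid.as_array()
        base = np.cos(2 * np.pi * t / 24)
        res = scanner.scan(np.roll(base, shift))
        assert res.best_period == 24.0
        assert res.best_phase == pytest.approx(
            (shift * grid.interval) % 24.0)

    def test_missing_values_dropped(self, scanner, grid):
        t = grid.as_array()
        y = np.cos(2 * np.pi * (t - 8) / 24)
        y[[3, 10]] = np.nan
        res = scanner.scan(y)
        assert res.n_used == 22
        assert abs(res.best_period - 24) <= 2 and res.p_value < 1e-6

    def test_too_many_missing_values_rejected(self, scanner):
        y = np.full(24, np.nan)
        y[:5] = [1, 2, 3, 4, 5]
        with pytest.raises(ValueError, match="non-missing"):
            scanner.scan(y)

    def test_heavily_tied_series_uses_permutation_null(self, scanner, rng):
        y = np.tile([1.0, 2.0, 1.0, 3.0], 6)  # >10% tied pairs
        res = scanner.scan(y, rng=rng)
        assert res.method == "permutation"
        assert 0 < res.p_value <= 1
        with pytest.raises(ValueError, match="seeded rng"):
            scanner.scan(y)

    def test_matrix_path_matches_single_path(self, scanner, rng):
        y = rng.normal(size=(40, 24))
        y[5] = 1.0                      # constant row
        y[7, 3] = np.nan                # row with a missing value
        batch = scanner.scan_matrix(y, [f"g{i}" for i in range(40)], rng=rng)
        for i in (0, 5, 7, 13, 39):
            single = scanner.scan(y[i], gene_id=f"g{i}",
                                  rng=np.random.default_rng(0))
            assert batch[i].gene_id == f"g{i}"
            if batch[i].method != "permutation":
                assert (batch[i].best_period, batch[i].best_phase,
                        batch[i].p_value) == \
                       (single.best_period, single.best_phase, single.p_value)

    def test_window_wider_than_span_rejected(self, grid):
        with pytest.raises(ValueError, match="span"):
            RhythmScanner(grid, 10, 50)

    def test_scan_rhythm_convenience_wrapper(self, grid):
        t = grid.as_array()
        res = scan_rhythm(np.cos(2 * np.pi * t / 24), grid)
        assert res.best_period == 24.0


def _bh_oracle(p):
    """Independent textbook step-up implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return q


class TestBHAdjust:
    @pytest.mark.parametrize("p, expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.2], [0.2]),
        ([0.001, 0.5], [0.002, 0.5]),
    ])
    def test_hand_computed_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=60))
    def test_agrees_with_independent_oracle(self, p):
        assert np.allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_q_never_below_p(self, rng):
        p = rng.uniform(size=500)
        assert np.all(bh_adjust(p) >= p - 1e-12)
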