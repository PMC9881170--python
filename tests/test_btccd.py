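"""Burst detection, gating and coincidence against independent brute-force
oracles, plus the statistical behavior of the full pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoinit.btccd import (
    Burst,
    BurstParams,
    GateConfig,
    analyze_trace,
    apply_gate,
    bootstrap_ci,
    chance_coincidence,
    coincidence_fraction,
    detect_bursts,
)
from mitoinit.errors import (
    InvalidConfigError,
    InvalidInputError,
    UndefinedResultError,
)
from mitoinit.photon_sim import ConfocalSimConfig, PhotonTrace, SpeciesMix, simulate_trace


# ---------------------------------------------------------------------------
# independent brute-force oracles (exhaustive scans by definition)

def brute_force_bursts(counts, threshold, min_bins, max_gap):
    """Exhaustive burst search: enumerate candidate intervals directly."""
    n = len(counts)
    above = [c >= threshold for c in counts]
    # all maximal above-threshold runs
    runs = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    # repeatedly merge any pair of adjacent runs with a small enough gap
    changed = True
    while changed:
        changed = False
        for k in range(len(runs) - 1):
            if runs[k + 1][0] - runs[k][1] <= max_gap:
                runs[k: k + 2] = [(runs[k][0], runs[k + 1][1])]
                changed = True
                break
    return [(s, e) for s, e in runs if e - s >= min_bins]


def brute_force_coincident(ref_intervals, partner_intervals, min_overlap):
    """Per-reference exhaustive overlap check."""
    out = []
    for s, e in ref_intervals:
        hit = any(min(e, pe) - max(s, ps) >= min_overlap
                  for ps, pe in partner_intervals)
        out.append(hit)
    return out


def make_trace(red, green, bin_width=1e-3):
    return PhotonTrace(bin_width, np.asarray(red), np.asarray(green))


def intervals(bursts):
    return [(b.start_bin, b.end_bin) for b in bursts]


# ---------------------------------------------------------------------------
# detect_bursts

class TestDetectBursts:
    def test_all_zero_trace_yields_no_bursts(self):
        trace = make_trace(np.zeros(50, int), np.zeros(50, int))
        assert detect_bursts(trace, "red", BurstParams(4)) == []

    def test_single_run_with_counts(self):
        trace = make_trace([0, 0, 5, 7, 6, 0, 0], [1, 0, 2, 3, 1, 0, 0])
        bursts = detect_bursts(trace, "red", BurstParams(4, min_bins=2, max_gap=0))
        assert intervals(bursts) == [(2, 5)]
        assert bursts[0].own_channel_counts == 18
        assert bursts[0].partner_channel_counts == 6

    def test_gap_merging(self):
        trace = make_trace([5, 0, 5], [0, 0, 0])
        no_gap = detect_bursts(trace, "red", BurstParams(4, min_bins=1, max_gap=0))
        merged = detect_bursts(trace, "red", BurstParams(4, min_bins=1, max_gap=1))
        assert intervals(no_gap) == [(0, 1), (2, 3)]
        assert intervals(merged) == [(0, 3)]
        assert merged[0].own_channel_counts == 10

    def test_invalid_channel_rejected(self):
        trace = make_trace([1], [1])
        with pytest.raises(InvalidInputError):
            detect_bursts(trace, "blue", BurstParams(2))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 10), min_size=1, max_size=200),
        threshold=st.integers(1, 8),
        min_bins=st.integers(1, 4),
        max_gap=st.integers(0, 3),
    )
    def test_matches_brute_force_oracle(self, counts, threshold, min_bins, max_gap):
        trace = make_trace(counts, np.zeros(len(counts), int))
        params = BurstParams(threshold, min_bins, max_gap)
        got = intervals(detect_bursts(trace, "red", params))
        assert got == brute_force_bursts(counts, threshold, min_bins, max_gap)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(counts=st.lists(st.integers(0, 10), min_size=5, max_size=100))
    def test_burst_counts_equal_interval_sums(self, counts):
        red = np.asarray(counts)
        green = (red * 2 + 1) % 7
        trace = make_trace(red, green)
        for b in detect_bursts(trace, "red", BurstParams(3, 1, 1)):
            assert b.own_channel_counts == red[b.start_bin:b.end_bin].sum()
            assert b.partner_channel_counts == green[b.start_bin:b.end_bin].sum()


# ---------------------------------------------------------------------------
# gating

def burst_with_brightness(values, channel="red"):
    return [Burst(channel, 10 * i, 10 * i + 2, int(v), 0)
            for i, v in enumerate(values)]


class TestApplyGate:
    def test_zero_quantile_is_identity(self):
        bursts = burst_with_brightness([5, 10, 20, 40])
        assert apply_gate(bursts, GateConfig("quantile", 0.0)) == bursts

    def test_median_gate_keeps_brightest_half(self):
        bursts = burst_with_brightness([5, 10, 20, 40])
        kept = apply_gate(bursts, GateConfig("quantile", 0.5))
        assert [b.own_channel_counts for b in kept] == [20, 40]

    def test_empty_input(self):
        assert apply_gate([], GateConfig()) == []

    def test_absolute_gate(self):
        bursts = burst_with_brightness([5, 10, 20, 40])
        kept = apply_gate(bursts, GateConfig("absolute", 15))
        assert [b.own_channel_counts for b in kept] == [20, 40]

    def test_quantile_outside_range_rejected(self):
        with pytest.raises(InvalidConfigError):
            GateConfig("quantile", 1.0)


# ---------------------------------------------------------------------------
# coincidence

def bursts_from(intervals_, channel):
    return [Burst(channel, s, e, 1, 0) for s, e in intervals_]


class TestCoincidenceFraction:
    def test_identical_lists_fully_coincident(self):
        iv = [(0, 5), (10, 15), (20, 26)]
        r = coincidence_fraction(bursts_from(iv, "red"), bursts_from(iv, "green"))
        assert r.fraction == 1.0 and r.n_coincident == 3

    def test_interleaved_disjoint_bursts_never_coincident(self):
        red = bursts_from([(0, 2), (10, 12)], "red")
        green = bursts_from([(5, 7), (15, 17)], "green")
        assert coincidence_fraction(red, green).fraction == 0.0

    def test_partial_overlap_worked_example(self):
        red = bursts_from([(0, 5), (10, 15)], "red")
        green = bursts_from([(4, 6), (20, 22)], "green")
        r = coincidence_fraction(red, green, min_overlap_bins=1, reference="red")
        assert (r.n_reference_bursts, r.n_coincident, r.fraction) == (2, 1, 0.5)

    def test_empty_reference_flagged(self):
        r = coincidence_fraction([], bursts_from([(0, 3)], "green"))
        assert r.empty and r.fraction == 0.0

    def test_shift_of_both_channels_leaves_fraction_unchanged(self):
        rng = np.random.default_rng(0)
        starts = np.sort(rng.choice(1000, 40, replace=False)) * 3
        red = bursts_from([(int(s), int(s) + 2) for s in starts[::2]], "red")
        green = bursts_from([(int(s) + 1, int(s) + 4) for s in starts[1::2]], "green")
        base = coincidence_fraction(red, green).fraction
        for off in (7, 123):
            red2 = bursts_from([(b.start_bin + off, b.end_bin + off) for b in red], "red")
            green2 = bursts_from([(b.start_bin + off, b.end_bin + off) for b in green], "green")
            assert coincidence_fraction(red2, green2).fraction == base

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        red=st.lists(st.tuples(st.integers(0, 180), st.integers(1, 10)),
                     min_size=0, max_size=15),
        green=st.lists(st.tuples(st.integers(0, 180), st.integers(1, 10)),
                       min_size=0, max_size=15),
        min_overlap=st.integers(1, 3),
        reference=st.sampled_from(["red", "green"]),
    )
    def test_matches_brute_force_oracle(self, red, green, min_overlap, reference):
        red_iv = sorted((s, s + w) for s, w in red)
        green_iv = sorted((s, s + w) for s, w in green)
        result = coincidence_fraction(bursts_from(red_iv, "red"),
                                      bursts_from(green_iv, "green"),
                                      min_overlap, reference)
        ref_iv = red_iv if reference == "red" else green_iv
        par_iv = green_iv if reference == "red" else red_iv
        expected = sum(brute_force_coincident(ref_iv, par_iv, min_overlap))
        assert result.n_coincident == expected


# ---------------------------------------------------------------------------
# chance control and bootstrap

class TestChanceCoincidence:
    def test_shift_destroys_real_correlation(self):
        iv = [(i * 50, i * 50 + 3) for i in range(40)]
        red = bursts_from(iv, "red")
        green = bursts_from(iv, "green")
        unshifted = coincidence_fraction(red, green).fraction
        chance = chance_coincidence(red, green, trace_length_bins=2000,
                                    shift_bins=25)
        assert unshifted == 1.0
        assert chance < 0.25 * unshifted

    def test_empty_green_gives_zero(self):
        red = bursts_from([(0, 3)], "red")
        assert chance_coincidence(red, [], 100, 50) == 0.0

    def test_shift_shorter_than_longest_burst_rejected(self):
        red = bursts_from([(0, 30)], "red")
        green = bursts_from([(50, 55)], "green")
        with pytest.raises(InvalidConfigError):
            chance_coincidence(red, green, 100, 10)

    def test_independent_processes_chance_matches_unshifted(self):
        """With no true association the shifted and unshifted fractions
        agree (both are accidental coincidence)."""
        with pytest.warns(UserWarning, match="single-molecule"):
            cfg = ConfocalSimConfig(duration=600.0, occupancy=0.02, seed=21)
        trace = simulate_trace(cfg, SpeciesMix.negative_control())
        result = analyze_trace(trace, reference="green", seed=21)
        assert abs(result.fraction - result.chance_fraction) < 0.02

    def test_chance_vanishes_with_occupancy(self):
        chances = []
        import warnings
        for occ in (0.002, 0.01, 0.02):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cfg = ConfocalSimConfig(duration=400.0, occupancy=occ, seed=22)
            trace = simulate_trace(cfg, SpeciesMix.negative_control())
            result = analyze_trace(trace, reference="green", seed=22)
            chances.append(result.chance_fraction)
        assert chances[0] <= chances[2]
        assert chances[0] < 0.01


class TestBootstrapCI:
    def test_degenerate_all_coincident_ci(self):
        iv = [(i * 10, i * 10 + 2) for i in range(30)]
        lo, hi = bootstrap_ci(bursts_from(iv, "red"), bursts_from(iv, "green"))
        assert (lo, hi) == (1.0, 1.0)

    def test_half_coincident_ci_width_matches_binomial_se(self):
        # 1000 reference bursts, half with a partner: SE = sqrt(0.25/1000)
        red = bursts_from([(i * 20, i * 20 + 3) for i in range(1000)], "red")
        green = bursts_from([(i * 20 + 1, i * 20 + 4) for i in range(0, 1000, 2)],
                            "green")
        lo, hi = bootstrap_ci(red, green, level=0.68, seed=1)
        half_width = (hi - lo) / 2
        se = np.sqrt(0.25 / 1000)
        assert abs(half_width - se) < 0.3 * se

    def test_same_seed_reproduces_ci(self):
        red = bursts_from([(i * 10, i * 10 + 2) for i in range(50)], "red")
        green = bursts_from([(i * 20, i * 20 + 2) for i in range(25)], "green")
        assert bootstrap_ci(red, green, seed=9) == bootstrap_ci(red, green, seed=9)

    def test_empty_reference_rejected(self):
        with pytest.raises(UndefinedResultError):
            bootstrap_ci([], bursts_from([(0, 2)], "green"))


# ---------------------------------------------------------------------------
# full pipeline

class TestAnalyzeTrace:
    def test_zero_length_trace_rejected(self):
        trace = PhotonTrace(1e-3, np.array([], dtype=int), np.array([], dtype=int))
        with pytest.raises(InvalidInputError):
            analyze_trace(trace)

    def test_estimated_fraction_monotone_in_true_association(self):
        """Planted double-labeled fractions 0..1 must order the estimates
        strictly, each with at least 1000 gated reference bursts."""
        estimates = []
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            cfg = ConfocalSimConfig(duration=1800.0, occupancy=0.01, seed=30)
            trace = simulate_trace(cfg, SpeciesMix.exchange_experiment(frac))
            result = analyze_trace(trace, reference="green", seed=30)
            assert result.n_reference_bursts >= 1000
            estimates.append(result.fraction)
        assert all(a < b for a, b in zip(estimates, estimates[1:]))

    def test_reference_gating_raises_coincidence_when_dim_bursts_are_noise(self):
        """With a permissive detection threshold, dim reference bursts are
        background noise without partners; brightness gating removes them,
        so the gated fraction must not be lower."""
        cfg = ConfocalSimConfig(duration=400.0, occupancy=0.01,
                                background_rate_green=3000.0, seed=31)
        trace = simulate_trace(cfg, SpeciesMix.positive_control())
        loose = BurstParams(threshold=5, min_bins=2, max_gap=1)
        ungated = analyze_trace(trace, burst_params_green=loose,
                                gate_green=GateConfig("quantile", 0.0),
                                reference="green", shift_control=False, seed=31)
        gated = analyze_trace(trace, burst_params_green=loose,
                              gate_green=GateConfig("quantile", 0.7),
                              reference="green", shift_control=False, seed=31)
        assert gated.fraction >= ungated.fraction

    def test_result_invariants(self):
        cfg = ConfocalSimConfig(duration=200.0, occupancy=0.01, seed=32)
        trace = simulate_trace(cfg, SpeciesMix.positive_control())
        r = analyze_trace(trace, reference="red", seed=32)
        assert r.n_coincident <= r.n_reference_bursts
        assert r.ci_low <= r.fraction <= r.ci_high
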