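"""Poisson scan statistics: tail oracle, window plan, peak finding, CIS calls."""

from math import exp, factorial

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tnscan import (CandidateWindow, InsertionEvent, ScanConfig,
                    anchored_window_p, bonferroni_correct, call_cis,
                    count_events, determine_window_sizes, find_peaks,
                    poisson_upper_tail, resolve_across_window_sizes,
                    simulate_random_positions)


def tail_by_summation(x, u):
    """Independent oracle: direct pmf summation, complemented."""
    if x <= 0:
        return 1.0
    return 1.0 - sum(exp(-u) * u**k / factorial(k) for k in range(x))


def ev(lib, bin_index, chrom="chr1", orient="+", n=1):
    return InsertionEvent(lib, chrom, bin_index, orient, n)


class TestPoissonTail:
    def test_closed_form_values(self):
        assert poisson_upper_tail(0, 5.0) == 1.0
        assert poisson_upper_tail(1, 1.0) == pytest.approx(1 - exp(-1), abs=1e-12)
        assert poisson_upper_tail(7, 0.186) == pytest.approx(
            1.2988854436457586e-09, rel=1e-9)

    @given(st.integers(0, 100), st.floats(0.01, 10))
    def test_matches_summation_oracle(self, x, u):
        assert poisson_upper_tail(x, u) == pytest.approx(
            tail_by_summation(x, u), abs=1e-12)

    @given(st.floats(0.05, 8))
    def test_strictly_decreasing_in_x(self, u):
        vals = [poisson_upper_tail(x, u) for x in range(1, 30)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @given(st.integers(1, 30))
    def test_strictly_increasing_in_u(self, x):
        vals = [poisson_upper_tail(x, u) for u in np.linspace(0.05, 10, 20)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_invalid_u(self):
        with pytest.raises(ValueError):
            poisson_upper_tail(3, 0.0)


class TestBonferroni:
    @pytest.mark.parametrize("p,n,expected", [
        (0.001, 100, 0.1), (0.5, 10, 1.0), (0.37, 1, 0.37)])
    def test_arithmetic(self, p, n, expected):
        assert bonferroni_correct(p, n) == pytest.approx(expected)


class TestWindowPlan:
    @pytest.mark.parametrize("total", [1500, 250_000, 0])
    def test_defaults_outside_range(self, total):
        cfg = ScanConfig(genome_size=2.5e9)
        assert determine_window_sizes(total, cfg) == [
            301000, 200000, 100000, 50000, 25000, 12500]

    def test_derived_plan_matches_brute_force(self):
        """Plan equals a double loop over every (window, count) pair."""
        cfg = ScanConfig(genome_size=2.5e9)
        total = 20_000
        expected = set()
        for k in range(2, 200):
            best = None
            for w in range(cfg.w_min, cfg.w_max + 1, cfg.w_step):
                u = total * w / cfg.genome_size
                if bonferroni_correct(anchored_window_p(k, u), total) < cfg.alpha:
                    best = w
            if best is not None:
                expected.add(best)
                if best == cfg.w_max:
                    break
        plan = determine_window_sizes(total, cfg)
        assert plan == sorted(expected, reverse=True)
        assert plan[0] == cfg.w_max

    def test_min_significant_count_nondecreasing_in_window(self):
        cfg = ScanConfig(genome_size=2.5e9)
        total = 20_000
        ks = []
        for w in (10_000, 50_000, 150_000, 301_000):
            u = total * w / cfg.genome_size
            k = 2
            while bonferroni_correct(anchored_window_p(k, u), total) >= cfg.alpha:
                k += 1
            ks.append(k)
        assert ks == sorted(ks)


class TestCountEvents:
    @pytest.fixture()
    def ideal_cis_events(self):
        # 10 inserts from 6 libraries; 6 of them share one 100-bp region,
        # the remaining 4 sit in 4 distinct regions.
        events = [ev(f"lib{i}", 50) for i in range(6)]
        events += [ev("lib0", 51), ev("lib1", 53), ev("lib2", 60), ev("lib3", 70)]
        return events

    def test_three_counting_schemes(self, ideal_cis_events):
        window = ("chr1", 0, 10_000)
        assert count_events(window, ideal_cis_events, "insert") == 10
        assert count_events(window, ideal_cis_events, "library") == 6
        assert count_events(window, ideal_cis_events, "region") == 5

    def test_window_edges_half_open(self):
        events = [ev("a", 0), ev("b", 9), ev("c", 10)]
        # bin_start 900 < 1000 inside; bin_start 1000 outside
        assert count_events(("chr1", 0, 1000), events, "insert") == 2


def oracle_find_peaks(events, window_size, cfg, mode):
    """Exhaustive anchored-window enumeration under the same greedy rule,
    with no pruning: every anchored window participates in selection."""
    from scipy.stats import poisson as P
    insert_total = len(events)
    if mode == "region":
        total = len({(e.chrom, e.bin_index) for e in events})
    else:
        total = insert_total
    u = total * window_size / cfg.genome_size
    chrom_order = list(dict.fromkeys(e.chrom for e in events))

    def count(chrom, start):
        inside = [e for e in events
                  if e.chrom == chrom and start <= e.bin_start < start + window_size]
        if mode == "insert":
            return len(inside)
        if mode == "library":
            return len({e.library for e in inside})
        return len({e.bin_index for e in inside})

    windows = sorted({(e.chrom, e.bin_start) for e in events})
    ranked = sorted(((count(c, s), c, s) for c, s in windows),
                    key=lambda t: (-t[0], chrom_order.index(t[1]), t[2]))
    selected, out = [], []
    for cnt, chrom, start in ranked:
        end = start + window_size
        if any(c == chrom and start < e0 and s0 < end for c, s0, e0 in selected):
            continue
        selected.append((chrom, start, end))
        p_raw = float(P.sf(cnt - 2, u)) if cnt >= 2 else 1.0
        if min(1.0, p_raw * insert_total) < cfg.alpha:
            out.append((chrom, start, end, cnt))
    return sorted(out)


class TestFindPeaks:
    def test_cluster_collapses_to_one_window(self):
        cfg = ScanConfig(genome_size=2.5e9)
        events = [ev(f"l{i}", 100 + i) for i in range(8)] + [
            ev("x", 10_000_000), ev("y", 20_000_000)]
        peaks = find_peaks(events, 10_000, cfg)
        assert len(peaks) == 1
        assert peaks[0].start == 10_000 and peaks[0].event_count == 8

    def test_isolated_events_not_significant(self):
        cfg = ScanConfig(genome_size=2.5e9)
        events = [ev("a", 0), ev("b", 1_000_000), ev("c", 2_000_000)]
        assert find_peaks(events, 10_000, cfg) == []

    def test_spec_cluster_example(self):
        # 8 events in 5 kb among 5,000 total over 2.5 Gb at w=25000:
        # exactly one peak containing all 8
        rng = np.random.default_rng(42)
        events = [ev(f"bg{i}", int(b)) for i, b in enumerate(
            sorted(rng.integers(1_000, 25_000_000, size=4992)))]
        cluster_bins = [500_000 + j * 12 for j in range(8)]  # 5 kb span
        events += [ev(f"cl{j}", b) for j, b in enumerate(cluster_bins)]
        events.sort(key=lambda e: e.bin_start)
        cfg = ScanConfig(genome_size=2.5e9)
        peaks = find_peaks(events, 25_000, cfg)
        spans = [(p.start, p.end) for p in peaks]
        covering = [s for s in spans
                    if s[0] <= cluster_bins[0] * 100 and cluster_bins[-1] * 100 < s[1]]
        assert len(covering) == 1
        peak = peaks[spans.index(covering[0])]
        assert peak.event_count == 8

    @pytest.mark.parametrize("mode", ["insert", "library", "region"])
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed, mode):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        events = sorted(
            (ev(f"l{rng.integers(8)}", int(rng.integers(0, 3000)),
                chrom=f"chr{rng.integers(1, 3)}",
                orient="+-"[rng.integers(2)])
             for _ in range(n)),
            key=lambda e: (e.chrom, e.bin_start))
        # dedupe identical events (insert events are unique by definition)
        events = list({(e.library, e.chrom, e.bin_index, e.orientation): e
                       for e in events}.values())
        cfg = ScanConfig(genome_size=2_000_000)
        got = sorted((p.chrom, p.start, p.end, p.event_count)
                     for p in find_peaks(events, 10_000, cfg, count_mode=mode))
        assert got == oracle_find_peaks(events, 10_000, cfg, mode)


class TestResolveAcrossSizes:
    def _cw(self, start, size, p, chrom="chr1", count=5):
        return CandidateWindow(chrom, start, start + size, size, count, p, p)

    def test_lower_p_wins(self):
        small = self._cw(10_000, 24_000, 1e-8)
        big = self._cw(5_000, 44_000, 1e-6)
        assert resolve_across_window_sizes([big, small]) == [small]

    def test_tie_prefers_larger_window(self):
        a = self._cw(10_000, 10_000, 1e-7)
        b = self._cw(5_000, 44_000, 1e-7)
        assert resolve_across_window_sizes([a, b]) == [b]

    def test_non_overlapping_all_kept(self):
        a = self._cw(0, 10_000, 1e-7)
        b = self._cw(50_000, 10_000, 1e-6)
        c = self._cw(0, 10_000, 1e-6, chrom="chr2")
        assert len(resolve_across_window_sizes([a, b, c])) == 3


class TestCallCis:
    def test_empty_and_single_event(self):
        cfg = ScanConfig(genome_size=2.5e9)
        assert call_cis([], cfg) == []
        assert call_cis([ev("a", 100)], cfg) == []

    def test_planted_cluster_called_with_three_pvalues(self):
        rng = np.random.default_rng(0)
        events = [ev(f"bg{i % 40}", int(b), orient="+-"[i % 2]) for i, b in
                  enumerate(sorted(rng.integers(0, 25_000_000, size=3000)))]
        events += [ev(f"driver{j}", 600_000 + j * 10) for j in range(9)]
        cfg = ScanConfig(genome_size=2.5e9)
        cis = call_cis(events, cfg)
        hits = [c for c in cis if c.start <= 60_000_000 <= c.end]
        assert len(hits) == 1
        c = hits[0]
        assert c.insert_count >= 9 and c.library_count >= 9 and c.region_count >= 9
        assert max(c.p_insert, c.p_library, c.p_region) < cfg.alpha
        assert c.region_count <= c.insert_count
        assert c.library_count <= c.insert_count
        assert c.n_pos_strand >= 9

    def test_final_cis_non_overlapping_and_deterministic(self):
        events = simulate_random_positions(3000, 100_000_000, 30, seed=9)
        cfg = ScanConfig(genome_size=1e8)
        a = call_cis(events, cfg, require_all=False)
        b = call_cis(events, cfg, require_all=False)
        assert a == b
        by_chrom = {}
        for c in a:
            by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(e0 <= s1 for (_, e0), (s1, _) in zip(spans, spans[1:]))

    def test_null_random_events_mostly_clean(self):
        cfg = ScanConfig(genome_size=2.5e9)
        clean = sum(
            not call_cis(simulate_random_positions(10_000, 2_500_000_000, 100,
                                                   seed=s), cfg)
            for s in range(5))
        assert clean >= 4
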