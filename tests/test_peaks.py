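"""Unit and property tests for the windowed peak detector, permutation FPR
estimator, first-detection sweep and replicate-consensus filter."""

import math
import statistics

import numpy as np
import pytest

from allelotile.peaks import (
    CutoffSchedule,
    Peak,
    PermutationPlan,
    ProbeTrack,
    call_peaks,
    compute_cutoff,
    consensus_peaks,
    detect_peaks,
    estimate_fpr,
    permute_track,
)


def make_track(ratios, spacing=100, chrom="chr1"):
    ratios = np.asarray(ratios, dtype=float)
    return ProbeTrack(chrom, np.arange(ratios.size) * spacing, ratios)


def brute_force_peaks(track, threshold, min_probes=4, flank=250):
    """Independent oracle: enumerate every probe's closed +/-flank window
    with explicit loops, merge qualifying windows, span above probes."""
    starts = list(track.starts)
    ratios = list(track.ratios)
    seeds = []
    for i, s in enumerate(starts):
        n_above = sum(
            1
            for j, t in enumerate(starts)
            if s - flank <= t <= s + flank and ratios[j] > threshold
        )
        if n_above >= min_probes:
            seeds.append(i)
    if not seeds:
        return []
    windows = [(starts[i] - flank, starts[i] + flank) for i in seeds]
    merged = [list(windows[0])]
    for a, b in windows[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    peaks = []
    for a, b in merged:
        above = [
            j for j, s in enumerate(starts)
            if a <= s <= b and ratios[j] > threshold
        ]
        peaks.append(
            (
                starts[above[0]],
                starts[above[-1]] + track.probe_length,
                max(ratios[j] for j in above),
            )
        )
    return peaks


class TestComputeCutoff:
    def test_all_zero_ratios_give_zero(self):
        assert compute_cutoff(make_track([0, 0, 0, 0]), 50) == 0.0

    def test_constant_ratios_reduce_to_mean(self):
        assert compute_cutoff(make_track([1, 1, 1, 1]), 100) == pytest.approx(1.0)

    def test_matches_hand_arithmetic(self):
        vals = [0, 0, 0, 0, 2, 2]
        expected = 0.5 * (statistics.mean(vals) + 6 * statistics.stdev(vals))
        assert compute_cutoff(make_track(vals), 50) == pytest.approx(expected)

    def test_single_probe_is_an_error(self):
        with pytest.raises(ValueError, match="nsufficient"):
            compute_cutoff(make_track([1.0]), 50)

    def test_percent_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_cutoff(make_track([0, 1, 2]), 0)


class TestDetectPeaks:
    def test_all_below_threshold_gives_no_peaks(self):
        track = make_track(np.zeros(50))
        assert detect_peaks(track, 1.0) == []

    def test_minimal_qualifying_run(self):
        # 4 consecutive probes at 100-bp spacing above threshold: one peak
        ratios = np.zeros(20)
        ratios[8:12] = 5.0
        track = make_track(ratios)
        peaks = detect_peaks(track, 1.0)
        assert len(peaks) == 1
        assert peaks[0].start == track.starts[8]
        assert peaks[0].end == track.starts[11] + track.probe_length
        assert peaks[0].height == 5.0

    def test_three_high_probes_do_not_qualify(self):
        ratios = np.zeros(20)
        ratios[8:11] = 5.0
        assert detect_peaks(make_track(ratios), 1.0) == []

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 300))
        # irregular spacing exercises the window-boundary logic
        starts = np.cumsum(rng.integers(30, 200, size=n))
        track = ProbeTrack("chr1", starts, rng.normal(0, 1, n))
        threshold = float(rng.normal(0.5, 0.5))
        got = detect_peaks(track, threshold)
        expected = brute_force_peaks(track, threshold)
        assert [(p.start, p.end) for p in got] == [(s, e) for s, e, _ in expected]
        assert [p.height for p in got] == pytest.approx([h for *_, h in expected])

    @pytest.mark.parametrize("seed", range(5))
    def test_peaks_nest_as_threshold_drops(self, seed):
        rng = np.random.default_rng(seed)
        track = make_track(rng.normal(0, 1, 400))
        hi, lo = 1.2, 0.6
        for p_hi in detect_peaks(track, hi):
            assert any(
                q.start <= p_hi.start and p_hi.end <= q.end
                for q in detect_peaks(track, lo)
            ), "every stringent-threshold peak is contained at the looser one"


class TestPermuteTrack:
    def test_ratio_multiset_conserved(self):
        track = make_track(np.random.default_rng(0).normal(0, 1, 100))
        perm = permute_track(track, 1)
        assert sorted(perm.ratios) == pytest.approx(sorted(track.ratios))
        assert np.array_equal(perm.starts, track.starts)

    def test_single_probe_identity(self):
        track = make_track([2.5])
        assert permute_track(track, 3).ratios[0] == 2.5

    def test_different_seeds_differ(self):
        track = make_track(np.arange(50, dtype=float))
        a = permute_track(track, 1).ratios
        b = permute_track(track, 2).ratios
        assert not np.array_equal(a, b)

    def test_same_seed_is_deterministic(self):
        track = make_track(np.arange(50, dtype=float))
        assert np.array_equal(
            permute_track(track, 9).ratios, permute_track(track, 9).ratios
        )


class TestEstimateFpr:
    def test_zero_observed_peaks_gives_nan_sentinel(self):
        track = make_track(np.zeros(50))
        assert math.isnan(estimate_fpr(track, 100, PermutationPlan(5, 0)))

    def test_no_null_peaks_with_observed_gives_zero(self):
        # one tight block of high probes among many; scrambling scatters
        # them so no 4 land in one window (seeded, deterministic)
        ratios = np.zeros(500)
        ratios[100:104] = 50.0
        track = make_track(ratios)
        assert estimate_fpr(track, 50, PermutationPlan(20, 0)) == 0.0

    def test_pure_noise_fpr_near_one(self):
        # observed and permuted tracks are exchangeable under the null
        vals = []
        for seed in range(3):
            rng = np.random.default_rng(200 + seed)
            track = make_track(rng.normal(0, 0.5, 20000))
            vals.append(estimate_fpr(track, 20.0, PermutationPlan(20, seed)))
        assert abs(float(np.mean(vals)) - 1.0) < 0.3


class TestCallPeaks:
    def test_spike_first_detected_at_stringent_cutoff(self):
        rng = np.random.default_rng(0)
        ratios = rng.normal(0, 0.5, 2000)
        ratios[1000:1005] += 10.0  # enormous effect: found at P = 100
        track = make_track(ratios)
        peaks = call_peaks(track, plan=PermutationPlan(20, 1))
        spike = [p for p in peaks if p.start <= 100_000 < p.end]
        assert len(spike) == 1
        assert spike[0].cutoff_percent == 100
        assert spike[0].fpr == 0.0

    def test_every_final_peak_carries_an_fpr(self):
        rng = np.random.default_rng(3)
        track = make_track(rng.normal(0, 0.5, 5000))
        peaks = call_peaks(
            track,
            CutoffSchedule.from_string("100:20:5"),
            PermutationPlan(10, 2),
        )
        for p in peaks:
            assert p.cutoff_percent is not None
            assert math.isfinite(p.fpr) and p.fpr >= 0

    def test_peak_counts_monotone_in_cutoff(self):
        rng = np.random.default_rng(4)
        track = make_track(rng.normal(0, 0.5, 5000))
        counts = [
            len(detect_peaks(track, compute_cutoff(track, pct)))
            for pct in CutoffSchedule().percentages
        ]
        assert counts == sorted(counts), "lowering the cutoff only adds peaks"


class TestConsensus:
    @staticmethod
    def _peaks(intervals, fpr=0.0, chrom="chr1"):
        return [Peak(chrom, s, e, 1.0, fpr=fpr) for s, e in intervals]

    def test_identical_replicates_pass_through(self):
        sets = [self._peaks([(100, 200), (400, 500)]) for _ in range(3)]
        cons = consensus_peaks(sets)
        assert [(p.start, p.end) for p in cons] == [(100, 200), (400, 500)]
        assert all(p.support == 3 for p in cons)

    def test_peak_missing_in_one_replicate_is_dropped(self):
        sets = [
            self._peaks([(100, 200), (400, 500)]),
            self._peaks([(100, 200)]),
            self._peaks([(100, 200), (400, 500)]),
        ]
        cons = consensus_peaks(sets)
        assert [(p.start, p.end) for p in cons] == [(100, 200)]

    def test_high_fpr_contributor_disqualifies(self):
        sets = [
            self._peaks([(100, 200)], fpr=0.0),
            self._peaks([(100, 200)], fpr=0.2),
            self._peaks([(100, 200)], fpr=0.0),
        ]
        assert consensus_peaks(sets, max_fpr=0.05) == []

    def test_nan_fpr_contributor_disqualifies(self):
        sets = [
            self._peaks([(100, 200)]),
            [Peak("chr1", 100, 200, 1.0)],  # fpr defaults to NaN
            self._peaks([(100, 200)]),
        ]
        assert consensus_peaks(sets) == []

    def test_too_few_replicates_is_an_error(self):
        with pytest.raises(ValueError):
            consensus_peaks([self._peaks([(0, 10)])], required_support=3)

    @pytest.mark.parametrize("seed", range(8))
    def test_jittered_replicates_match_intersection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        base = np.sort(rng.choice(np.arange(100, 20000, 400), 12, replace=False))
        sets = []
        for _ in range(3):
            ivals = []
            for s in base:
                if rng.random() < 0.85:
                    j = int(rng.integers(-80, 81))
                    ivals.append((s + j, s + j + 200))
            sets.append(self._peaks(ivals))
        cons = consensus_peaks(sets)
        # oracle: brute-force triple loop over one peak per replicate
        expected = set()
        for a in sets[0]:
            for b in sets[1]:
                for c in sets[2]:
                    lo = max(a.start, b.start, c.start)
                    hi = min(a.end, b.end, c.end)
                    if lo < hi:
                        expected.add((lo, hi))
        assert {(p.start, p.end) for p in cons} == expected

    def test_all_consensus_peaks_respect_fpr_bound(self):
        rng = np.random.default_rng(11)
        sets = [
            self._peaks(
                [(s, s + 150) for s in range(0, 5000, 500)],
                fpr=float(rng.random() * 0.1),
            )
            for _ in range(3)
        ]
        for p in consensus_peaks(sets, max_fpr=0.05):
            assert p.fpr < 0.05
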