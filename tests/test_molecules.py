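"""Molecule recovery, size statistics, and the depth profile."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from linksv.io import Fragments, RegionMask
from linksv.molecules import (DepthProfile, MoleculeRecoveryError,
                              MoleculeStats, Submolecules,
                              compute_depth_profile, estimate_molecule_stats,
                              recover_molecule_iteration,
                              recover_submolecules, scan_group)


def make_fragments(rows, chroms=("chr1",), barcodes=("b0", "b1")):
    """rows: (chrom, start, end, barcode)."""
    arr = np.asarray(rows, dtype=np.int64).reshape(-1, 4)
    return Fragments(chroms, barcodes, arr[:, 0].astype(np.int32),
                     arr[:, 1], arr[:, 2], arr[:, 3])


def greedy_oracle(frags, T, Q, min_length):
    """Independent left-to-right simulation of the merge rules."""
    out = []
    groups = {}
    for c, s, e, b in frags:
        groups.setdefault((b, c), []).append((s, e))
    for (b, c), lst in sorted(groups.items()):
        lst.sort()
        open_frags = [lst[0]]
        for s, e in lst[1:]:
            right = max(x[1] for x in open_frags)
            left = open_frags[0][0]
            if s - right <= T or s - left <= Q:
                open_frags.append((s, e))
            else:
                out.append((c, left, right, b, len(open_frags)))
                open_frags = [(s, e)]
        right = max(x[1] for x in open_frags)
        out.append((c, open_frags[0][0], right, b, len(open_frags)))
    return sorted(t for t in out if t[2] - t[1] >= min_length)


class TestRecovery:
    def test_default_scan_parameters_from_mu(self):
        stats = MoleculeStats.from_mu(50_000)
        assert stats.T == 12_500
        assert stats.Q == 100_000
        assert stats.min_length == 3_000

    def test_short_single_fragment_is_discarded(self):
        frags = make_fragments([(0, 0, 2_000, 0)])
        subs = recover_submolecules(frags, MoleculeStats.from_mu(50_000))
        assert len(subs) == 0

    def test_gap_rule_examples(self):
        # T = 12.5 kbp joins across a 9 kbp gap
        raw = scan_group([0, 10_000], [1_000, 11_000], T=12_500, Q=100_000)
        assert raw == [(0, 11_000, 2)]
        # with T = 5 kbp and Q = 8 kbp the gap closes the submolecule
        raw = scan_group([0, 10_000], [1_000, 11_000], T=5_000, Q=8_000)
        assert raw == [(0, 1_000, 1), (10_000, 11_000, 1)]

    def test_unsorted_group_is_fatal(self):
        with pytest.raises(MoleculeRecoveryError, match="sorted"):
            scan_group([5_000, 0], [6_000, 1_000], 1_000, 2_000)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 300_000), st.integers(200, 2_000),
                              st.integers(0, 1), st.integers(0, 1)),
                    min_size=1, max_size=50))
    def test_greedy_equals_exhaustive_oracle(self, raw):
        """For <= 50 fragments the scan equals an independent simulation."""
        rows = [(c, s, s + l, b) for s, l, c, b in raw]
        frags = make_fragments(rows, chroms=("chr1", "chr2"))
        stats = MoleculeStats.from_mu(40_000, min_length=1_000)
        subs = recover_submolecules(frags, stats)
        got = sorted(zip(subs.chrom.tolist(), subs.start.tolist(),
                         subs.end.tolist(), subs.barcode.tolist(),
                         subs.n_fragments.tolist()))
        assert got == greedy_oracle(rows, stats.T, stats.Q, stats.min_length)

    def test_consecutive_submolecules_never_overlap(self):
        rng = np.random.default_rng(5)
        rows = [(0, int(s), int(s) + 500, 0)
                for s in np.sort(rng.integers(0, 2_000_000, size=400))]
        stats = MoleculeStats.from_mu(50_000, min_length=0)
        subs = recover_submolecules(make_fragments(rows), stats)
        starts, ends = subs.start, subs.end
        assert np.all(starts[1:] - ends[:-1] > stats.T)


class TestStats:
    def test_two_point_mean_and_population_sd(self):
        subs = Submolecules(("chr1",), ("b0",), np.zeros(2, np.int32),
                            np.array([0, 0]), np.array([40_000, 60_000]),
                            np.zeros(2, np.int64), np.ones(2, np.int64))
        stats = estimate_molecule_stats(subs)
        assert stats.mu == 50_000 and stats.sigma == 10_000
        assert stats.T == 12_500 and stats.Q == 100_000

    def test_equal_lengths_give_zero_sigma(self):
        subs = Submolecules(("chr1",), ("b0",), np.zeros(3, np.int32),
                            np.array([0, 0, 0]), np.full(3, 30_000),
                            np.zeros(3, np.int64), np.ones(3, np.int64))
        assert estimate_molecule_stats(subs).sigma == 0.0

    def test_too_few_submolecules_is_fatal(self):
        subs = Submolecules(("chr1",), ("b0",), np.zeros(1, np.int32),
                            np.array([0]), np.array([30_000]),
                            np.zeros(1, np.int64), np.ones(1, np.int64))
        with pytest.raises(MoleculeRecoveryError):
            estimate_molecule_stats(subs)

    def test_moments_match_streaming_oracle(self):
        """Welford's online algorithm as an independent second computation."""
        rng = np.random.default_rng(11)
        lengths = rng.lognormal(10.5, 0.5, size=1000).astype(np.int64) + 3000
        subs = Submolecules(("chr1",), ("b0",),
                            np.zeros(1000, np.int32),
                            np.zeros(1000, np.int64), lengths,
                            np.zeros(1000, np.int64),
                            np.ones(1000, np.int64))
        stats = estimate_molecule_stats(subs)
        mean = m2 = 0.0
        for k, x in enumerate(lengths.tolist(), start=1):
            d = x - mean
            mean += d / k
            m2 += d * (x - mean)
        assert stats.mu == pytest.approx(mean, rel=1e-12)
        assert stats.sigma == pytest.approx(np.sqrt(m2 / 1000), rel=1e-9)


class TestTwoPassBootstrap:
    def test_fixed_point_when_initial_mu_is_true(self):
        rows = [(0, s + m * 1_000_000, s + m * 1_000_000 + 1_000, m % 2)
                for m in range(8) for s in range(0, 40_000, 2_000)]
        frags = make_fragments(rows)
        subs1, stats1 = recover_molecule_iteration(frags, initial_mu=45_000,
                                                   T=10_000, Q=50_000)
        subs2 = recover_submolecules(frags, stats1)
        assert np.array_equal(subs1.start, subs2.start)
        assert np.array_equal(subs1.end, subs2.end)

    def test_empty_input_is_fatal(self):
        frags = make_fragments(np.zeros((0, 4)))
        with pytest.raises(MoleculeRecoveryError):
            recover_molecule_iteration(frags, initial_mu=45_000)

    def test_parameter_recovery_on_synthetic_molecules(self):
        """Second-pass mu within 20% of the true 50 kbp molecule mean."""
        rng = np.random.default_rng(2)
        rows = []
        for m in range(400):
            length = int(np.clip(rng.lognormal(np.log(50_000) - 0.15, 0.55),
                                 5_000, 300_000))
            start = int(rng.integers(0, 30_000_000 - length))
            bc = m // 16
            n = max(2, int(0.1 * length / 200))
            pos = np.sort(rng.integers(start, start + length - 400, size=n))
            rows += [(0, int(p), int(p) + 400, bc) for p in pos]
        subs, stats = recover_molecule_iteration(make_fragments(rows),
                                                 initial_mu=45_000)
        assert abs(stats.mu - 50_000) / 50_000 < 0.20


class TestDepthProfile:
    def test_no_submolecules_gives_zero_profile(self):
        subs = Submolecules(("chr1",), (), np.zeros(0, np.int32),
                            np.zeros(0, np.int64), np.zeros(0, np.int64),
                            np.zeros(0, np.int64), np.zeros(0, np.int64))
        prof = compute_depth_profile(subs, None, {"chr1": 100_000}, 10_000)
        assert prof.mu_depth == 0.0
        assert prof.counts["chr1"].sum() == 0

    def test_single_submolecule_covers_its_bins(self):
        subs = Submolecules(("chr1",), ("b0",), np.zeros(1, np.int32),
                            np.array([10_000]), np.array([40_000]),
                            np.zeros(1, np.int64), np.ones(1, np.int64))
        prof = compute_depth_profile(subs, None, {"chr1": 100_000}, 10_000)
        assert prof.counts["chr1"].tolist() == [0, 1, 1, 1, 0, 0, 0, 0, 0, 0]

    def test_counts_match_bruteforce_overlap(self):
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 9_900_000, size=200)
        ends = starts + rng.integers(1_000, 120_000, size=200)
        subs = Submolecules(("chr1",), ("b0",), np.zeros(200, np.int32),
                            starts, ends, np.zeros(200, np.int64),
                            np.ones(200, np.int64))
        bs = 10_000
        prof = compute_depth_profile(subs, None, {"chr1": 10_000_000}, bs)
        brute = np.zeros(1000, dtype=int)
        for b in range(1000):
            lo, hi = b * bs, (b + 1) * bs
            brute[b] = int(((starts < hi) & (ends > lo)).sum())
        assert np.array_equal(prof.counts["chr1"], brute)
        # sum over bins equals sum over submolecules of bins overlapped
        per_sub = ((np.minimum(ends, 10_000_000) - 1) // bs - starts // bs + 1)
        assert prof.counts["chr1"].sum() == per_sub.sum()

    def test_masked_bins_excluded_from_moments(self):
        subs = Submolecules(("chr1",), ("b0",), np.zeros(1, np.int32),
                            np.array([0]), np.array([50_000]),
                            np.zeros(1, np.int64), np.ones(1, np.int64))
        mask = RegionMask.from_intervals([("chr1", 50_000, 100_000)])
        prof = compute_depth_profile(subs, mask, {"chr1": 100_000}, 10_000,
                                     robust=False)
        assert prof.mu_depth == 1.0  # only the 5 covered, unmasked bins

    def test_interval_mean_is_length_weighted(self):
        prof = DepthProfile(10_000, {"chr1": np.array([2, 4, 8])},
                            {"chr1": np.ones(3, bool)}, 0, 0)
        assert prof.interval_mean("chr1", 5_000, 15_000) == pytest.approx(3.0)
        assert prof.interval_mean("chr1", 0, 30_000) == pytest.approx(14 / 3)
        assert prof.interval_mean("chrX", 0, 1000) is None
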