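"""Candidate splits, signature predicates, and split-molecule matching."""
import numpy as np
import pytest

from linksv.io import (DiscordantPairs, INTERCHROM, INTRA_FAR,
                       INTRA_INVERTED_FF, INTRA_INVERTED_RR)
from linksv.molecules import MoleculeStats, Submolecules
from linksv.splits import (CandidateSplits, DiscordantIndex, SizeWindows,
                           SplitView, _PREDICATES, _support_parts,
                           anchor_translocation_splits,
                           count_read_pair_support,
                           enumerate_candidate_splits, filter_splits_by_rp,
                           match_split_molecule_pairs, signature_predicate)

CHROMS = ("chr1", "chr2")


def make_submolecules(rows):
    """rows: (chrom, start, end, barcode)."""
    arr = np.asarray(rows, dtype=np.int64).reshape(-1, 4)
    return Submolecules(CHROMS, (), arr[:, 0].astype(np.int32), arr[:, 1],
                        arr[:, 2], arr[:, 3],
                        np.ones(len(arr), dtype=np.int64))


def make_discordant(rows):
    """rows: (c1, p1, c2, p2, barcode, pair_class); canonical order."""
    arr = np.asarray(rows, dtype=np.int64).reshape(-1, 6)
    rev1 = arr[:, 5] == INTRA_INVERTED_RR
    rev2 = (arr[:, 5] == INTRA_INVERTED_RR) | (arr[:, 5] == INTRA_FAR)
    return DiscordantPairs(CHROMS, (), arr[:, 0].astype(np.int32), arr[:, 1],
                           rev1, arr[:, 2].astype(np.int32), arr[:, 3], rev2,
                           arr[:, 4], arr[:, 5].astype(np.int8))


def view(i, bc, cl, ls, le, cr, rs, re):
    return SplitView(i, bc, cl, ls, le, cr, rs, re)


class TestEnumeration:
    def test_span_sum_bound_rejects_large_split(self):
        # mu=50k sigma=10k -> bound 80k; spans 50k + 40k = 90k rejected
        subs = make_submolecules([(0, 0, 50_000, 0), (0, 200_000, 240_000, 0)])
        stats = MoleculeStats.from_mu(50_000, 10_000)
        assert len(enumerate_candidate_splits(subs, stats)) == 0

    def test_single_submolecule_yields_no_split(self):
        subs = make_submolecules([(0, 0, 30_000, 0)])
        stats = MoleculeStats.from_mu(50_000, 10_000)
        assert len(enumerate_candidate_splits(subs, stats)) == 0

    def test_four_short_submolecules_give_six_splits(self):
        rows = [(0, k * 1_000_000, k * 1_000_000 + 10_000, 0) for k in range(4)]
        stats = MoleculeStats.from_mu(50_000, 10_000)
        splits = enumerate_candidate_splits(make_submolecules(rows), stats)
        assert len(splits) == 6  # C(4,2)

    def test_per_barcode_cap_keeps_largest(self):
        rows = [(0, k * 1_000_000, k * 1_000_000 + 10_000 + k, 0)
                for k in range(6)]
        stats = MoleculeStats.from_mu(50_000, 10_000)
        splits = enumerate_candidate_splits(make_submolecules(rows), stats,
                                            max_per_barcode=5)
        assert len(splits) == 5
        spans = ((splits.le - splits.ls) + (splits.re - splits.rs))
        assert spans.min() >= 10_000 + 10_004  # smallest pairs dropped first


class TestSignaturePredicates:
    T = 10_000
    SW = SizeWindows()

    def test_identical_deletion_splits_match(self):
        X = view(0, 0, 0, 900_000, 1_000_000, 0, 1_200_000, 1_300_000)
        Y = view(1, 1, 0, 910_000, 1_002_000, 0, 1_201_000, 1_290_000)
        res = signature_predicate("DEL", X, Y, self.T, self.SW)
        assert res is not None
        chrom1, bp1, bp2, chrom2, bp3 = res
        # breakpoint intervals inside both splits' gaps (up to read slack)
        from linksv.splits import ANCHOR_SLACK

        for s in (X, Y):
            assert s.le - ANCHOR_SLACK <= bp1[0] and \
                bp1[1] <= s.rs + ANCHOR_SLACK + 1
            assert s.le <= bp2[0] - self.T <= s.rs

    def test_inversion_pair_beyond_cap_is_rejected(self):
        # gaps 10 Mbp apart exceed the ~7 Mbp inversion cap
        X = view(0, 0, 0, 900_000, 1_000_000, 0, 10_990_000, 11_100_000)
        Y = view(1, 1, 0, 1_000_000, 1_080_000, 0, 11_000_000, 11_200_000)
        assert signature_predicate("INV", X, Y, self.T, self.SW) is None

    def test_unknown_type_is_fatal(self):
        X = view(0, 0, 0, 0, 10, 0, 20, 30)
        with pytest.raises(ValueError):
            signature_predicate("MEI", X, X, self.T, self.SW)

    @staticmethod
    def ideal_splits(sv_type, p, q, ins, arm=30_000):
        """Construct the two junction splits a true event would produce."""
        if sv_type == "DEL":
            a = view(0, 0, 0, p - arm, p, 0, q, q + arm)
            b = view(1, 1, 0, p - arm + 500, p - 200, 0, q + 150, q + arm)
        elif sv_type == "INV":
            a = view(0, 0, 0, p - arm, p, 0, q - arm, q)       # ends at p, q
            b = view(1, 1, 0, p, p + arm, 0, q, q + arm)       # starts at p, q
        elif sv_type == "DUP_DIRECT":
            if ins > q:
                a = view(0, 0, 0, p, p + arm, 0, ins - arm, ins)
                b = view(1, 1, 0, q - arm, q, 0, ins, ins + arm)
            else:
                a = view(0, 0, 0, ins - arm, ins, 0, p, p + arm)
                b = view(1, 1, 0, ins, ins + arm, 0, q - arm, q)
        elif sv_type == "DUP_INVERTED":
            if ins > q:
                a = view(0, 0, 0, q - arm, q, 0, ins - arm, ins)
                b = view(1, 1, 0, p, p + arm, 0, ins, ins + arm)
            else:
                a = view(0, 0, 0, ins - arm, ins, 0, q - arm, q)
                b = view(1, 1, 0, ins, ins + arm, 0, p, p + arm)
        else:  # TRA: source on chr1, insertion on chr2
            a = view(0, 0, 0, p, p + arm, 1, ins - arm, ins)
            b = view(1, 1, 0, q - arm, q, 1, ins, ins + arm)
        return a, b

    @pytest.mark.parametrize("sv_type,p,q,ins", [
        ("DEL", 1_000_000, 1_250_000, None),
        ("INV", 2_000_000, 2_400_000, None),
        ("DUP_DIRECT", 1_000_000, 1_100_000, 2_000_000),
        ("DUP_DIRECT", 1_000_000, 1_100_000, 500_000),
        ("DUP_INVERTED", 3_000_000, 3_200_000, 4_000_000),
        ("DUP_INVERTED", 3_000_000, 3_200_000, 1_000_000),
        ("TRA", 1_000_000, 1_200_000, 5_000_000),
    ])
    def test_ideal_geometry_matches_and_brackets_breakpoints(
            self, sv_type, p, q, ins):
        a, b = self.ideal_splits(sv_type, p, q, ins)
        res = signature_predicate(sv_type, a, b, self.T, self.SW)
        assert res is not None
        chrom1, bp1, bp2, chrom2, bp3 = res
        assert bp1[0] <= p <= bp1[1]
        assert bp2[0] <= q <= bp2[1]
        if bp3 is not None:
            assert bp3[0] <= ins <= bp3[1]
        # symmetry: swapping the splits gives the same geometry
        res2 = signature_predicate(sv_type, b, a, self.T, self.SW)
        assert res2 is not None and res2[1] == bp1 and res2[2] == bp2

    def test_random_quadruples_match_geometric_oracle(self):
        """Random split pairs: predicate verdict equals a brute-force check
        that some valid event geometry explains the four intervals."""
        rng = np.random.default_rng(17)
        sw = self.SW
        for _ in range(30):
            vals = np.sort(rng.integers(0, 5_000_000, size=8))
            X = view(0, 0, 0, int(vals[0]), int(vals[1]), 0, int(vals[2]),
                     int(vals[3]))
            Y = view(1, 1, 0, int(vals[4]), int(vals[5]), 0, int(vals[6]),
                     int(vals[7]))
            got = signature_predicate("DEL", X, Y, self.T, sw) is not None
            expect = (abs(X.le - Y.le) <= self.T and
                      abs(X.rs - Y.rs) <= self.T and
                      (max(X.rs, Y.rs) - self.T + min(X.rs, Y.rs) + 1) // 2 -
                      (max(X.le, Y.le) + min(X.le, Y.le) + self.T + 1) // 2
                      > sw.min_del)
            assert got == expect


class TestReadPairSupport:
    def test_no_discordant_pairs_gives_zero(self):
        idx = DiscordantIndex(make_discordant(np.zeros((0, 6))))
        assert count_read_pair_support("DEL", 0, (0, 100), (5000, 5100),
                                       None, None, idx, 500) == 0

    def test_three_ff_pairs_bridge_an_inversion(self):
        rows = [(0, 1_000_000 - 300 * k, 0, 1_500_000 - 300 * k, 0,
                 INTRA_INVERTED_FF) for k in range(3)]
        idx = DiscordantIndex(make_discordant(rows))
        n = count_read_pair_support("INV", 0, (995_000, 1_001_000),
                                    (1_495_000, 1_501_000), None, None, idx,
                                    600)
        assert n == 3

    def test_del_support_equals_linear_scan(self):
        rng = np.random.default_rng(4)
        rows = []
        for _ in range(12):  # planted spanning pairs
            rows.append((0, int(rng.integers(999_000, 1_000_000)), 0,
                         int(rng.integers(1_400_000, 1_401_000)), 0,
                         INTRA_FAR))
        for _ in range(50):  # scattered background
            a, b = sorted(rng.integers(0, 5_000_000, size=2).tolist())
            rows.append((0, a, 0, b, 0, int(rng.integers(0, 3))))
        idx = DiscordantIndex(make_discordant(rows))
        bp1, bp2, pad = (999_500, 1_000_500), (1_399_500, 1_400_500), 1_000
        got = count_read_pair_support("DEL", 0, bp1, bp2, None, None, idx, pad)
        brute = sum(1 for c1, p1, c2, p2, _, cls in rows
                    if cls == INTRA_FAR and
                    bp1[0] - pad <= p1 < bp1[1] + pad and
                    bp2[0] - pad <= p2 < bp2[1] + pad)
        assert got == brute

    def test_batch_count_matches_scalar_count(self):
        rng = np.random.default_rng(9)
        rows = [(int(rng.integers(0, 2)),) + tuple(
            sorted(rng.integers(0, 2_000_000, size=2).tolist()))[:1] +
            (int(rng.integers(0, 2)), int(rng.integers(0, 2_000_000)), 0,
             int(rng.integers(0, 4))) for _ in range(200)]
        rows = [(c1, p1, c2, p2, b, cls) if (c1, p1) <= (c2, p2)
                else (c2, p2, c1, p1, b, cls)
                for c1, p1, c2, p2, b, cls in rows]
        idx = DiscordantIndex(make_discordant(rows))
        qs = []
        for _ in range(100):
            cA, cB = int(rng.integers(0, 2)), int(rng.integers(0, 2))
            loA = int(rng.integers(0, 2_000_000))
            loB = int(rng.integers(0, 2_000_000))
            qs.append((cA, loA, loA + 50_000, cB, loB, loB + 50_000))
        qs = np.asarray(qs)
        for classes in ((INTRA_FAR,), (INTRA_INVERTED_FF, INTRA_INVERTED_RR)):
            batch = idx.batch_count(qs[:, 0], qs[:, 1], qs[:, 2], qs[:, 3],
                                    qs[:, 4], qs[:, 5], classes)
            for k in range(len(qs)):
                assert batch[k] == idx.count(
                    int(qs[k, 0]), (int(qs[k, 1]), int(qs[k, 2])),
                    int(qs[k, 3]), (int(qs[k, 4]), int(qs[k, 5])), classes)


class TestTranslocationAnchoring:
    def test_anchor_without_nearby_submolecule_emits_nothing(self):
        subs = make_submolecules([(0, 0, 30_000, 0)])
        disc = make_discordant([(0, 5_000_000, 1, 8_000_000, 0, INTERCHROM)])
        stats = MoleculeStats.from_mu(50_000)
        assert len(anchor_translocation_splits(disc, subs, stats)) == 0

    def test_anchor_window_arithmetic(self):
        # submolecule ending 10 kbp before the chr1 anchor end and one
        # starting 10 kbp after the chr2 end, window 50 kbp -> one split
        subs = make_submolecules([(0, 4_940_000, 4_990_000, 0),
                                  (1, 8_010_000, 8_050_000, 0)])
        disc = make_discordant([(0, 5_000_000, 1, 8_000_000, 0, INTERCHROM)])
        stats = MoleculeStats.from_mu(50_000, 20_000)
        splits = anchor_translocation_splits(disc, subs, stats,
                                             anchor_window=50_000)
        assert len(splits) == 1
        assert splits.cl[0] == 0 and splits.cr[0] == 1

    def test_matches_exhaustive_anchor_window_search(self):
        rng = np.random.default_rng(6)
        sub_rows = [(int(rng.integers(0, 2)), 0, 0, int(rng.integers(0, 4)))
                    for _ in range(40)]
        sub_rows = [(c, s, s + int(rng.integers(5_000, 60_000)), b)
                    for (c, _, _, b), s in
                    zip(sub_rows, rng.integers(0, 9_000_000, size=40))]
        disc_rows = [(0, int(rng.integers(0, 9_000_000)), 1,
                      int(rng.integers(0, 9_000_000)),
                      int(rng.integers(0, 4)), INTERCHROM)
                     for _ in range(10)]
        subs = make_submolecules(sub_rows)
        disc = make_discordant(disc_rows)
        stats = MoleculeStats.from_mu(50_000, 30_000)
        w = 50_000
        got = anchor_translocation_splits(disc, subs, stats, anchor_window=w)
        got_keys = set(zip(got.cl.tolist(), got.ls.tolist(), got.cr.tolist(),
                           got.rs.tolist()))
        expect = set()
        for c1, p1, c2, p2, bc, _ in disc_rows:
            for i, (ci, si, ei, bi) in enumerate(sub_rows):
                for j, (cj, sj, ej, bj) in enumerate(sub_rows):
                    if i == j or bi != bc or bj != bc:
                        continue
                    if not (ci == c1 and si - w <= p1 <= ei + w):
                        continue
                    if not (cj == c2 and sj - w <= p2 <= ej + w):
                        continue
                    if (ei - si) + (ej - sj) > stats.span_bound:
                        continue
                    expect.add((ci, si, cj, sj) if (ci, si) <= (cj, sj)
                               else (cj, sj, ci, si))
        assert got_keys == expect


class TestMatching:
    def _run(self, splits_rows, disc_rows, mu=50_000, sigma=10_000):
        arr = np.asarray(splits_rows, dtype=np.int64).reshape(-1, 8)
        splits = CandidateSplits(CHROMS, arr[:, 0],
                                 arr[:, 1].astype(np.int32), arr[:, 2],
                                 arr[:, 3], arr[:, 4].astype(np.int32),
                                 arr[:, 5], arr[:, 6])
        idx = DiscordantIndex(make_discordant(disc_rows))
        stats = MoleculeStats.from_mu(mu, sigma)
        return match_split_molecule_pairs(splits, idx, stats, pad=700)

    def test_same_barcode_splits_never_pair(self):
        p, q = 1_000_000, 1_300_000
        rows = [(0, 0, p - 30_000, p, 0, q, q + 30_000, 0),
                (0, 0, p - 25_000, p - 100, 0, q + 50, q + 28_000, 0)]
        disc = [(0, p - 300 * k, 0, q + 300 * k, 0, INTRA_FAR)
                for k in range(5)]
        assert self._run(rows, disc) == []

    def test_deletion_pair_from_two_barcodes(self):
        p, q = 1_000_000, 1_300_000
        rows = [(0, 0, p - 30_000, p, 0, q, q + 30_000, 0),
                (1, 0, p - 25_000, p - 100, 0, q + 50, q + 28_000, 0)]
        disc = [(0, p - 100 * k, 0, q + 100 * k, 0, INTRA_FAR)
                for k in range(5)]
        pairs = self._run(rows, disc)
        assert len(pairs) == 1 and pairs[0].sv_type == "DEL"
        assert pairs[0].bp1[0] <= p <= pairs[0].bp1[1]
        assert pairs[0].bp2[0] <= q <= pairs[0].bp2[1]
        assert pairs[0].rp_support == 5

    def test_dup_displacement_below_floor_is_rejected(self):
        # insertion only 60 kbp from the source: below the 80 kbp floor
        p, q, ins = 1_000_000, 1_050_000, 1_110_000
        rows = [(0, 0, p, p + 20_000, 0, ins - 20_000, ins, 0),
                (1, 0, q - 20_000, q, 0, ins, ins + 20_000, 0)]
        disc = [(0, p, 0, ins, 0, INTRA_FAR), (0, q, 0, ins, 1, INTRA_FAR),
                (0, q - 100, 0, ins + 100, 1, INTRA_FAR)]
        assert all(sm.sv_type != "DUP_DIRECT"
                   for sm in self._run(rows, disc))

    def test_support_below_three_is_removed(self):
        p, q = 1_000_000, 1_300_000
        rows = [(0, 0, p - 30_000, p, 0, q, q + 30_000, 0),
                (1, 0, p - 25_000, p - 100, 0, q + 50, q + 28_000, 0)]
        disc = [(0, p, 0, q, 0, INTRA_FAR), (0, p - 300, 0, q + 300, 1,
                                             INTRA_FAR)]
        assert self._run(rows, disc) == []

    def test_vectorized_matching_equals_predicate_bruteforce(self):
        """The array engine agrees with the per-pair reference predicates."""
        rng = np.random.default_rng(23)
        stats = MoleculeStats.from_mu(50_000, 10_000)
        T, pad = int(stats.T), 700
        rows = []
        for k in range(40):
            s1 = int(rng.integers(0, 4_000_000))
            l1 = int(rng.integers(5_000, 40_000))
            gap = int(rng.integers(1_000, 500_000))
            l2 = int(rng.integers(5_000, 40_000))
            rows.append((k % 7, 0, s1, s1 + l1, 0, s1 + l1 + gap,
                         s1 + l1 + gap + l2, 0))
        disc_rows = []
        for _ in range(300):
            a, b = sorted(rng.integers(0, 5_000_000, size=2).tolist())
            disc_rows.append((0, a, 0, b, 0, int(rng.integers(0, 3))))
        arr = np.asarray(rows, dtype=np.int64)
        splits = CandidateSplits(CHROMS, arr[:, 0],
                                 arr[:, 1].astype(np.int32), arr[:, 2],
                                 arr[:, 3], arr[:, 4].astype(np.int32),
                                 arr[:, 5], arr[:, 6])
        idx = DiscordantIndex(make_discordant(disc_rows))
        got = match_split_molecule_pairs(splits, idx, stats, pad=pad)
        got_keys = {(p.sv_type, min(p.a.id, p.b.id), max(p.a.id, p.b.id))
                    for p in got}
        sw = SizeWindows()
        expect = set()
        for i in range(len(splits)):
            for j in range(len(splits)):
                if i == j:
                    continue
                vi, vj = splits.view(i), splits.view(j)
                if vi.barcode == vj.barcode:
                    continue
                for sv_type in ("DEL", "INV", "DUP_DIRECT", "DUP_INVERTED"):
                    res = _PREDICATES[sv_type](vi, vj, T, sw)
                    if res is None:
                        continue
                    chrom1, bp1, bp2, chrom2, bp3 = res[:5]
                    parts = _support_parts(sv_type, chrom1, bp1, bp2, chrom2,
                                           bp3, idx, pad)
                    if sum(parts) >= 3 and min(parts) >= 1:
                        expect.add((sv_type, min(i, j), max(i, j)))
        assert got_keys == expect

    def test_pair_intervals_lie_inside_split_gaps_for_del_inv(self):
        p, q = 2_000_000, 2_500_000
        rows = [(0, 0, p - 30_000, p, 0, q - 30_000, q, 0),       # ends-type
                (1, 0, p, p + 30_000, 0, q, q + 30_000, 0)]       # starts-type
        disc = [(0, p - 200 * k, 0, q - 200 * k, 0, INTRA_INVERTED_FF)
                for k in range(3)]
        disc += [(0, p + 200 * k, 0, q + 200 * k, 1, INTRA_INVERTED_RR)
                 for k in range(3)]
        pairs = self._run(rows, disc)
        inv = [sm for sm in pairs if sm.sv_type == "INV"]
        assert len(inv) == 1
        sm = inv[0]
        from linksv.splits import ANCHOR_SLACK

        lo = min(sm.a.ls, sm.b.ls) - ANCHOR_SLACK
        hi = max(sm.a.re, sm.b.re) + ANCHOR_SLACK
        for bp in (sm.bp1, sm.bp2):
            assert lo <= bp[0] and bp[1] <= hi + 1
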