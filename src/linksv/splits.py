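"""Candidate splits and split-molecule pairing.

A *candidate split* is a pair of same-barcode submolecules that may be the
two mapped halves of one SV-spanning molecule; two candidate splits with
different barcodes whose geometry is consistent with the same event form a
*split molecule pair*.  Each SV type imposes a distinct arrangement of the
four submolecule intervals; the per-type predicates below encode those
arrangements together with the breakpoint-uncertainty windows they imply.

Breakpoint anchoring uses the scan parameter ``T``: a submolecule's
terminal read lies within ``T`` of the true junction (a larger gap would
have split the submolecule), so a submolecule *end* ``e`` anchors a
junction in ``[e, e + T)`` and a *start* ``s`` anchors one in
``(s - T, s]``, each widened by a small slack on the far side because a
junction-crossing read is placed with an error of up to its own length.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .io import (DiscordantPairs, INTERCHROM, INTRA_FAR, INTRA_INVERTED_FF,
                 INTRA_INVERTED_RR)
from .molecules import MoleculeStats, Submolecules

SV_TYPES = ("DEL", "INV", "DUP_DIRECT", "DUP_INVERTED", "TRA")


class SplitView(NamedTuple):
    """One candidate split: left/right submolecules of one barcode."""

    id: int
    barcode: int
    cl: int       # chromosome code of the left submolecule
    ls: int
    le: int
    cr: int       # chromosome code of the right submolecule
    rs: int
    re: int


@dataclass
class CandidateSplits:
    """Columnar candidate splits; rows follow :class:`SplitView`."""

    chroms: tuple[str, ...]
    barcode: np.ndarray
    cl: np.ndarray
    ls: np.ndarray
    le: np.ndarray
    cr: np.ndarray
    rs: np.ndarray
    re: np.ndarray

    def __len__(self) -> int:
        return len(self.barcode)

    def view(self, i: int) -> SplitView:
        return SplitView(i, int(self.barcode[i]), int(self.cl[i]),
                         int(self.ls[i]), int(self.le[i]), int(self.cr[i]),
                         int(self.rs[i]), int(self.re[i]))

    def subset(self, idx) -> "CandidateSplits":
        return CandidateSplits(self.chroms, self.barcode[idx], self.cl[idx],
                               self.ls[idx], self.le[idx], self.cr[idx],
                               self.rs[idx], self.re[idx])

    @classmethod
    def concat(cls, a: "CandidateSplits", b: "CandidateSplits"
               ) -> "CandidateSplits":
        return cls(a.chroms,
                   np.concatenate([a.barcode, b.barcode]),
                   np.concatenate([a.cl, b.cl]),
                   np.concatenate([a.ls, b.ls]),
                   np.concatenate([a.le, b.le]),
                   np.concatenate([a.cr, b.cr]),
                   np.concatenate([a.rs, b.rs]),
                   np.concatenate([a.re, b.re]))


@dataclass
class SplitMoleculePair:
    """Two candidate splits (different barcodes) signaling one SV event.

    For types with two distinct junctions (INV/DUP/TRA) the splits carry
    roles: ``a`` anchors the first junction, ``b`` the second
    (``roled=True``); DEL splits each span the single junction.
    """

    sv_type: str
    a: SplitView
    b: SplitView
    chrom1: int                  # source/body chromosome code
    bp1: tuple[int, int]         # half-open breakpoint intervals
    bp2: tuple[int, int]
    chrom2: int | None = None    # insertion chromosome (DUP/TRA)
    bp3: tuple[int, int] | None = None
    rp_support: int = 0
    roled: bool = False


# ---------------------------------------------------------------------------
# Candidate split enumeration
# ---------------------------------------------------------------------------

def enumerate_candidate_splits(submolecules: Submolecules,
                               stats: MoleculeStats,
                               max_per_barcode: int = 128) -> CandidateSplits:
    """All same-barcode, same-chromosome submolecule pairs under the
    span-sum bound ``mu + 3 sigma``.

    When a barcode yields more pairs than ``max_per_barcode`` only the
    largest (by total span) are kept, bounding the quadratic matching step.
    """
    order = np.lexsort((submolecules.start, submolecules.chrom,
                        submolecules.barcode))
    bc = submolecules.barcode[order]
    ch = submolecules.chrom[order]
    st = submolecules.start[order]
    en = submolecules.end[order]
    bound = stats.span_bound

    rows: list[tuple[int, int, int, int, int, int]] = []
    n = len(bc)
    i = 0
    while i < n:
        j = i + 1
        while j < n and bc[j] == bc[i] and ch[j] == ch[i]:
            j += 1
        group = range(i, j)
        per_bc: list[tuple[int, tuple]] = []
        for a in group:
            for b in range(a + 1, j):
                span = (en[a] - st[a]) + (en[b] - st[b])
                if span <= bound:
                    per_bc.append((int(span),
                                   (int(bc[i]), int(ch[i]), int(st[a]),
                                    int(en[a]), int(st[b]), int(en[b]))))
        if len(per_bc) > max_per_barcode:
            per_bc.sort(key=lambda t: (-t[0], t[1]))
            per_bc = per_bc[:max_per_barcode]
        rows.extend(r for _, r in per_bc)
        i = j
    if not rows:
        z = np.zeros(0, dtype=np.int64)
        return CandidateSplits(submolecules.chroms, z, z.astype(np.int32), z,
                               z, z.astype(np.int32), z, z)
    arr = np.asarray(rows, dtype=np.int64)
    return CandidateSplits(submolecules.chroms, arr[:, 0],
                           arr[:, 1].astype(np.int32), arr[:, 2], arr[:, 3],
                           arr[:, 1].astype(np.int32), arr[:, 4], arr[:, 5])


# ---------------------------------------------------------------------------
# Discordant-pair index
# ---------------------------------------------------------------------------

class DiscordantIndex:
    """Positional index over discordant pairs for window-pair queries."""

    def __init__(self, disc: DiscordantPairs):
        order = np.lexsort((disc.p1, disc.c1))
        self.c1 = disc.c1[order]
        self.p1 = disc.p1[order]
        self.c2 = disc.c2[order]
        self.p2 = disc.p2[order]
        self.pair_class = disc.pair_class[order]
        self.slices: dict[int, tuple[int, int]] = {}
        if len(self.c1):
            bounds = np.flatnonzero(np.diff(self.c1)) + 1
            starts = np.concatenate([[0], bounds])
            ends = np.concatenate([bounds, [len(self.c1)]])
            for s, e in zip(starts, ends):
                self.slices[int(self.c1[s])] = (int(s), int(e))

    def count(self, cA: int, wA: tuple[int, int], cB: int, wB: tuple[int, int],
              classes: tuple[int, ...] | None = None) -> int:
        """Pairs with one end in window A and the other in window B.

        Windows are canonicalized to match the stored (chrom, pos)
        ordering of mates.
        """
        if (cB, wB[0]) < (cA, wA[0]):
            cA, wA, cB, wB = cB, wB, cA, wA
        if cA not in self.slices:
            return 0
        lo, hi = self.slices[cA]
        i0 = lo + np.searchsorted(self.p1[lo:hi], wA[0], side="left")
        i1 = lo + np.searchsorted(self.p1[lo:hi], wA[1], side="left")
        if i0 >= i1:
            return 0
        sel = (self.c2[i0:i1] == cB) & (self.p2[i0:i1] >= wB[0]) & \
            (self.p2[i0:i1] < wB[1])
        if classes is not None:
            cls_ok = np.zeros(i1 - i0, dtype=bool)
            for c in classes:
                cls_ok |= self.pair_class[i0:i1] == c
            sel &= cls_ok
        return int(sel.sum())

    def has_link(self, cA: int, wA: tuple[int, int], cB: int,
                 wB: tuple[int, int]) -> bool:
        return self.count(cA, wA, cB, wB) > 0

    def batch_count(self, cA, loA, hiA, cB, loB, hiB,
                    classes: tuple[int, ...]) -> np.ndarray:
        """Vectorized :meth:`count` over arrays of window pairs."""
        nq = len(loA)
        out = np.zeros(nq, dtype=np.int64)
        if nq == 0 or not len(self.p1):
            return out
        cA = np.asarray(cA)
        cB = np.asarray(cB)
        swap = (cB < cA) | ((cB == cA) & (loB < loA))
        cA_ = np.where(swap, cB, cA)
        cB_ = np.where(swap, cA, cB)
        loA_ = np.where(swap, loB, loA)
        hiA_ = np.where(swap, hiB, hiA)
        loB_ = np.where(swap, loA, loB)
        hiB_ = np.where(swap, hiA, hiB)
        cls_lut = np.zeros(8, dtype=bool)
        for c in classes:
            cls_lut[c] = True
        for c, (lo, hi) in self.slices.items():
            q = np.flatnonzero(cA_ == c)
            if not len(q):
                continue
            block = self.p1[lo:hi]
            i0 = lo + np.searchsorted(block, loA_[q], side="left")
            i1 = lo + np.searchsorted(block, hiA_[q], side="left")
            lens = i1 - i0
            tot = int(lens.sum())
            if tot == 0:
                continue
            rep = np.repeat(np.arange(len(q)), lens)
            base = np.cumsum(lens) - lens
            pt = np.repeat(i0, lens) + (np.arange(tot) - np.repeat(base, lens))
            ok = (self.c2[pt] == cB_[q][rep]) & \
                (self.p2[pt] >= loB_[q][rep]) & (self.p2[pt] < hiB_[q][rep]) & \
                cls_lut[self.pair_class[pt]]
            np.add.at(out, q[rep[ok]], 1)
        return out


def filter_splits_by_rp(splits: CandidateSplits, index: DiscordantIndex,
                        pad: int) -> CandidateSplits:
    """Drop candidate splits with no discordant pair linking their halves.

    A split survives iff at least one discordant pair has one end within
    the left submolecule (padded by ``pad``) and the other within the
    padded right submolecule.  ``pad`` must cover both the breakpoint
    uncertainty ``T`` (a submolecule may end up to ``T`` short of the
    junction) and the insert size of a junction-straddling pair.
    """
    keep = np.zeros(len(splits), dtype=bool)
    for i in range(len(splits)):
        keep[i] = index.has_link(int(splits.cl[i]),
                                 (int(splits.ls[i]) - pad,
                                  int(splits.le[i]) + pad),
                                 int(splits.cr[i]),
                                 (int(splits.rs[i]) - pad,
                                  int(splits.re[i]) + pad))
    return splits.subset(keep)


# ---------------------------------------------------------------------------
# Translocation anchoring
# ---------------------------------------------------------------------------

def anchor_translocation_splits(disc: DiscordantPairs,
                                submolecules: Submolecules,
                                stats: MoleculeStats,
                                anchor_window: float | None = None
                                ) -> CandidateSplits:
    """Inter-chromosomal candidate splits seeded by discordant anchors.

    Exhaustive cross-chromosome pairing is infeasible; instead each
    inter-chromosomal discordant pair acts as an anchor and same-barcode
    submolecules within ``anchor_window`` (default ``mu_molecule``) of each
    anchor end are attached.
    """
    window = int(anchor_window if anchor_window is not None else stats.mu)
    inter = disc.pair_class == INTERCHROM
    if not inter.any() or len(submolecules) == 0:
        z = np.zeros(0, dtype=np.int64)
        return CandidateSplits(submolecules.chroms, z, z.astype(np.int32), z,
                               z, z.astype(np.int32), z, z)
    # submolecule lookup by (barcode, chrom), sorted by start
    order = np.lexsort((submolecules.start, submolecules.chrom,
                        submolecules.barcode))
    sbc = submolecules.barcode[order]
    sch = submolecules.chrom[order]
    sst = submolecules.start[order]
    sen = submolecules.end[order]
    groups: dict[tuple[int, int], tuple[int, int]] = {}
    n = len(sbc)
    i = 0
    while i < n:
        j = i + 1
        while j < n and sbc[j] == sbc[i] and sch[j] == sch[i]:
            j += 1
        groups[(int(sbc[i]), int(sch[i]))] = (i, j)
        i = j

    def near(bc: int, chrom: int, pos: int) -> list[int]:
        g = groups.get((bc, chrom))
        if g is None:
            return []
        lo, hi = g
        out = []
        for k in range(lo, hi):
            if sst[k] - window <= pos <= sen[k] + window:
                out.append(k)
        return out

    bound = stats.span_bound
    seen: set[tuple[int, int]] = set()
    rows: list[tuple[int, int, int, int, int, int, int]] = []
    for a in np.flatnonzero(inter):
        bc = int(disc.barcode[a])
        side1 = near(bc, int(disc.c1[a]), int(disc.p1[a]))
        side2 = near(bc, int(disc.c2[a]), int(disc.p2[a]))
        for k1 in side1:
            for k2 in side2:
                span = (sen[k1] - sst[k1]) + (sen[k2] - sst[k2])
                if span > bound:
                    continue
                key = (min(k1, k2), max(k1, k2))
                if key in seen:
                    continue
                seen.add(key)
                u, v = key
                rows.append((bc, int(sch[u]), int(sst[u]), int(sen[u]),
                             int(sch[v]), int(sst[v]), int(sen[v])))
    if not rows:
        z = np.zeros(0, dtype=np.int64)
        return CandidateSplits(submolecules.chroms, z, z.astype(np.int32), z,
                               z, z.astype(np.int32), z, z)
    arr = np.asarray(rows, dtype=np.int64)
    return CandidateSplits(submolecules.chroms, arr[:, 0],
                           arr[:, 1].astype(np.int32), arr[:, 2], arr[:, 3],
                           arr[:, 4].astype(np.int32), arr[:, 5], arr[:, 6])


# ---------------------------------------------------------------------------
# Signature predicates
# ---------------------------------------------------------------------------

#: far-side slack of an anchor window (bp): junction-crossing reads are
#: placed by their dominant side, misplacing a submolecule endpoint by up
#: to a read length across the junction
ANCHOR_SLACK = 150


def _wstart(x: int, T: int) -> tuple[int, int]:
    """Half-open uncertainty window of a junction anchored by a submolecule
    start (true junction in (x - T, x + slack])."""
    return (x - T, x + ANCHOR_SLACK + 1)


def _wend(x: int, T: int) -> tuple[int, int]:
    """Window of a junction anchored by a submolecule end."""
    return (x - ANCHOR_SLACK, x + T + 1)


def _isect(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int] | None:
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    return (lo, hi) if lo < hi else None


def _mid(iv: tuple[int, int]) -> int:
    return (iv[0] + iv[1]) // 2


@dataclass
class SizeWindows:
    """Per-type event-size windows (bp); caps apply to INV and DUP only."""

    min_del: int = 100_000
    min_inv: int = 80_000
    min_dup: int = 40_000
    min_tra: int = 100_000
    max_event: int = 7_000_000
    dup_min_distance: int = 80_000


def _del_predicate(X: SplitView, Y: SplitView, T: int, sw: SizeWindows):
    bp1 = _isect(_wend(X.le, T), _wend(Y.le, T))
    if bp1 is None:
        return None
    bp2 = _isect(_wstart(X.rs, T), _wstart(Y.rs, T))
    if bp2 is None:
        return None
    size = _mid(bp2) - _mid(bp1)
    if size <= sw.min_del:
        return None
    return (X.cl, bp1, bp2, None, None, X, Y)


def _inv_predicate(X: SplitView, Y: SplitView, T: int, sw: SizeWindows):
    # A carries submolecules *ending* at both breakpoints (left-junction
    # molecule), B carries submolecules *starting* at both (right junction).
    for A, B in ((X, Y), (Y, X)):
        bp1 = _isect(_wend(A.le, T), _wstart(B.ls, T))
        if bp1 is None:
            continue
        bp2 = _isect(_wend(A.re, T), _wstart(B.rs, T))
        if bp2 is None:
            continue
        size = _mid(bp2) - _mid(bp1)
        if sw.min_inv < size <= sw.max_event:
            return (A.cl, bp1, bp2, None, None, A, B)
    return None


def _dup_direct_predicate(X: SplitView, Y: SplitView, T: int, sw: SizeWindows):
    # J1 spans (insertion | source-start) so it anchors p by a submolecule
    # start and the insertion locus i by a submolecule end; J2 spans
    # (source-end | insertion) anchoring q by an end and i by a start.
    for A, B in ((X, Y), (Y, X)):
        # insertion to the right of the source: p < q < i
        bp3 = _isect(_wend(A.re, T), _wstart(B.rs, T))
        if bp3 is not None:
            bp1, bp2 = _wstart(A.ls, T), _wend(B.le, T)
            p, q, ins = _mid(bp1), _mid(bp2), _mid(bp3)
            if p < q and sw.min_dup < q - p <= sw.max_event and \
                    ins - q > sw.dup_min_distance:
                return (A.cl, bp1, bp2, A.cr, bp3, A, B)
        # insertion to the left: i < p < q
        bp3 = _isect(_wend(A.le, T), _wstart(B.ls, T))
        if bp3 is not None:
            bp1, bp2 = _wstart(A.rs, T), _wend(B.re, T)
            p, q, ins = _mid(bp1), _mid(bp2), _mid(bp3)
            if p < q and sw.min_dup < q - p <= sw.max_event and \
                    p - ins > sw.dup_min_distance:
                return (A.cl, bp1, bp2, A.cl, bp3, A, B)
    return None


def _dup_inverted_predicate(X: SplitView, Y: SplitView, T: int,
                            sw: SizeWindows):
    # The inverted copy reverses the junction geometry: one junction
    # molecule ends at both i and q, the other starts at both p and i.
    for A, B in ((X, Y), (Y, X)):
        # insertion right: p < q < i; A ends at (q, i), B starts at (p, i)
        bp3 = _isect(_wend(A.re, T), _wstart(B.rs, T))
        if bp3 is not None:
            bp1, bp2 = _wstart(B.ls, T), _wend(A.le, T)
            p, q, ins = _mid(bp1), _mid(bp2), _mid(bp3)
            if p < q and sw.min_dup < q - p <= sw.max_event and \
                    ins - q > sw.dup_min_distance:
                return (A.cl, bp1, bp2, A.cr, bp3, A, B)
        # insertion left: i < p < q; A ends at (i, q), B starts at (i, p)
        bp3 = _isect(_wend(A.le, T), _wstart(B.ls, T))
        if bp3 is not None:
            bp1, bp2 = _wstart(B.rs, T), _wend(A.re, T)
            p, q, ins = _mid(bp1), _mid(bp2), _mid(bp3)
            if p < q and sw.min_dup < q - p <= sw.max_event and \
                    p - ins > sw.dup_min_distance:
                return (A.cl, bp1, bp2, A.cl, bp3, A, B)
    return None


def _tra_predicate(X: SplitView, Y: SplitView, T: int, sw: SizeWindows):
    # Source segment [p, q) on one chromosome moved to locus i on another.
    # J1 anchors p (start) and i (end); J2 anchors q (end) and i (start).
    for A, B in ((X, Y), (Y, X)):
        for a_src in ("l", "r"):
            if a_src == "l":
                src_c, p_w = A.cl, _wstart(A.ls, T)
                ins_c, ia_w = A.cr, _wend(A.re, T)
            else:
                src_c, p_w = A.cr, _wstart(A.rs, T)
                ins_c, ia_w = A.cl, _wend(A.le, T)
            for b_src in ("l", "r"):
                if b_src == "l":
                    if B.cl != src_c or B.cr != ins_c:
                        continue
                    q_w = _wend(B.le, T)
                    ib_w = _wstart(B.rs, T)
                else:
                    if B.cr != src_c or B.cl != ins_c:
                        continue
                    q_w = _wend(B.re, T)
                    ib_w = _wstart(B.ls, T)
                bp3 = _isect(ia_w, ib_w)
                if bp3 is None:
                    continue
                p, q = _mid(p_w), _mid(q_w)
                if p < q and q - p > sw.min_tra:
                    return (src_c, p_w, q_w, ins_c, bp3, A, B)
    return None


_PREDICATES = {"DEL": _del_predicate, "INV": _inv_predicate,
               "DUP_DIRECT": _dup_direct_predicate,
               "DUP_INVERTED": _dup_inverted_predicate,
               "TRA": _tra_predicate}


def signature_predicate(sv_type: str, split_a: SplitView, split_b: SplitView,
                        T: float, windows: SizeWindows | None = None):
    """Test whether two candidate splits arrange as ``sv_type``'s signature.

    Returns ``(chrom1, bp1, bp2, chrom2, bp3)`` (``chrom2``/``bp3`` None
    for DEL/INV) or None.  Symmetric in the two splits.
    """
    if sv_type not in _PREDICATES:
        raise ValueError(f"unknown SV type: {sv_type}")
    windows = windows or SizeWindows()
    intra_a = split_a.cl == split_a.cr
    intra_b = split_b.cl == split_b.cr
    if sv_type == "TRA":
        if intra_a or intra_b:
            return None
    else:
        if not (intra_a and intra_b) or split_a.cl != split_b.cl:
            return None
    res = _PREDICATES[sv_type](split_a, split_b, int(T), windows)
    return None if res is None else res[:5]


# ---------------------------------------------------------------------------
# Read-pair support
# ---------------------------------------------------------------------------

def _pad(iv: tuple[int, int], pad: int) -> tuple[int, int]:
    return (iv[0] - pad, iv[1] + pad)


def _support_parts(sv_type: str, chrom1: int, bp1, bp2, chrom2, bp3,
                   index: DiscordantIndex, pad: int) -> tuple[int, ...]:
    """Per-junction discordant support counts for the type's signature.

    A deletion has a single bridged junction.  An inversion's two
    junctions produce FF and RR pairs respectively over the same window
    pair, so its parts are the FF and RR counts.  DUP/TRA have one part
    per source-edge/insertion junction.
    """
    if sv_type == "DEL":
        return (index.count(chrom1, _pad(bp1, pad), chrom1, _pad(bp2, pad),
                            classes=(INTRA_FAR,)),)
    if sv_type == "INV":
        return (index.count(chrom1, _pad(bp1, pad), chrom1, _pad(bp2, pad),
                            classes=(INTRA_INVERTED_FF,)),
                index.count(chrom1, _pad(bp1, pad), chrom1, _pad(bp2, pad),
                            classes=(INTRA_INVERTED_RR,)))
    if sv_type == "DUP_DIRECT":
        classes: tuple[int, ...] = (INTRA_FAR,)
    elif sv_type == "DUP_INVERTED":
        classes = (INTRA_INVERTED_FF, INTRA_INVERTED_RR)
    elif sv_type == "TRA":
        classes = (INTERCHROM,)
    else:
        raise ValueError(f"unknown SV type: {sv_type}")
    return (index.count(chrom1, _pad(bp1, pad), chrom2, _pad(bp3, pad),
                        classes=classes),
            index.count(chrom1, _pad(bp2, pad), chrom2, _pad(bp3, pad),
                        classes=classes))


def count_read_pair_support(sv_type: str, chrom1: int, bp1, bp2,
                            chrom2, bp3, index: DiscordantIndex,
                            pad: int) -> int:
    """Discordant pairs matching the type's orientation signature whose
    ends fall in the breakpoint windows padded by the insert bound."""
    return sum(_support_parts(sv_type, chrom1, bp1, bp2, chrom2, bp3,
                              index, pad))


def count_pair_support(pair: SplitMoleculePair, index: DiscordantIndex,
                       pad: int) -> int:
    return count_read_pair_support(pair.sv_type, pair.chrom1, pair.bp1,
                                   pair.bp2, pair.chrom2, pair.bp3, index,
                                   pad)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _pairs_within(avals: np.ndarray, bvals: np.ndarray, lo_off: int,
                  hi_off: int) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i, j) with ``avals[i]+lo_off <= bvals[j] <= avals[i]+hi_off``."""
    order = np.argsort(bvals, kind="stable")
    bs = bvals[order]
    i0 = np.searchsorted(bs, avals + lo_off, side="left")
    i1 = np.searchsorted(bs, avals + hi_off, side="right")
    lens = i1 - i0
    tot = int(lens.sum())
    if tot == 0:
        return (np.zeros(0, dtype=np.int64),) * 2
    ai = np.repeat(np.arange(len(avals)), lens)
    base = np.cumsum(lens) - lens
    bj = order[np.repeat(i0, lens) + (np.arange(tot) - np.repeat(base, lens))]
    return ai, bj


def _match_intra_chrom(splits: CandidateSplits, rows: np.ndarray,
                       index: DiscordantIndex, chrom: int, T: int,
                       sw: SizeWindows, min_rp: int, pad: int
                       ) -> list[SplitMoleculePair]:
    """Vectorized intra-chromosomal matching on one chromosome.

    Candidate ordered pairs (A, B) come from junction-anchor coincidences:
    an end-anchor of A within the breakpoint window of a start-anchor of B
    (all two-junction signatures), or coincident left-submolecule ends
    (deletions).  Geometry, size windows and per-junction read-pair
    support are then evaluated on whole arrays.
    """
    ls = splits.ls[rows]
    le = splits.le[rows]
    rs = splits.rs[rows]
    re = splits.re[rows]
    bc = splits.barcode[rows]
    out: list[SplitMoleculePair] = []

    def emit(sv_type, ai, bj, keep, bp1lo, bp1hi, bp2lo, bp2hi,
             bp3lo=None, bp3hi=None):
        """Score support for geometry-passing candidates and emit pairs."""
        ai, bj = ai[keep], bj[keep]
        if not len(ai):
            return
        b1lo, b1hi = bp1lo[keep], bp1hi[keep]
        b2lo, b2hi = bp2lo[keep], bp2hi[keep]
        c = np.full(len(ai), chrom)
        if sv_type == "DEL":
            cnt = index.batch_count(c, b1lo - pad, b1hi + pad, c,
                                    b2lo - pad, b2hi + pad, (INTRA_FAR,))
            ok = cnt >= min_rp
            parts = (cnt,)
        elif sv_type == "INV":
            ff = index.batch_count(c, b1lo - pad, b1hi + pad, c,
                                   b2lo - pad, b2hi + pad,
                                   (INTRA_INVERTED_FF,))
            rr = index.batch_count(c, b1lo - pad, b1hi + pad, c,
                                   b2lo - pad, b2hi + pad,
                                   (INTRA_INVERTED_RR,))
            cnt = ff + rr
            ok = (ff >= 1) & (rr >= 1) & (cnt >= min_rp)
        else:
            classes = (INTRA_FAR,) if sv_type == "DUP_DIRECT" \
                else (INTRA_INVERTED_FF, INTRA_INVERTED_RR)
            b3lo, b3hi = bp3lo[keep], bp3hi[keep]
            s1 = index.batch_count(c, b1lo - pad, b1hi + pad, c,
                                   b3lo - pad, b3hi + pad, classes)
            s2 = index.batch_count(c, b2lo - pad, b2hi + pad, c,
                                   b3lo - pad, b3hi + pad, classes)
            cnt = s1 + s2
            ok = (s1 >= 1) & (s2 >= 1) & (cnt >= min_rp)
        for k in np.flatnonzero(ok):
            a = splits.view(int(rows[ai[k]]))
            b = splits.view(int(rows[bj[k]]))
            bp3 = None
            if bp3lo is not None:
                bp3 = (int(bp3lo[keep][k]), int(bp3hi[keep][k]))
            out.append(SplitMoleculePair(
                sv_type, a, b, chrom,
                (int(b1lo[k]), int(b1hi[k])), (int(b2lo[k]), int(b2hi[k])),
                None if bp3 is None else chrom, bp3,
                int(cnt[k]), roled=sv_type != "DEL"))

    S = ANCHOR_SLACK

    # --- deletions: coincident left-submolecule ends, both splits gap over
    # the deleted segment
    ai, bj = _pairs_within(le, le, -(T + S), T + S)
    if len(ai):
        keep = (ai < bj) & (bc[ai] != bc[bj]) & \
            (np.abs(rs[ai] - rs[bj]) <= T + S)
        bp1lo = np.maximum(le[ai], le[bj]) - S
        bp1hi = np.minimum(le[ai], le[bj]) + T + 1
        bp2lo = np.maximum(rs[ai], rs[bj]) - T
        bp2hi = np.minimum(rs[ai], rs[bj]) + S + 1
        size = (bp2lo + bp2hi) // 2 - (bp1lo + bp1hi) // 2
        keep &= size > sw.min_del
        emit("DEL", ai, bj, keep, bp1lo, bp1hi, bp2lo, bp2hi)

    def win_end_start(e, s):
        # intersection of the end-anchor window [e-S, e+T] and the
        # start-anchor window [s-T, s+S]; valid iff -2S <= s - e <= 2T
        return np.maximum(e - S, s - T), np.minimum(e + T + 1, s + S + 1)

    # --- combo A.le (end anchor) ~ B.ls (start anchor)
    ai, bj = _pairs_within(le, ls, -2 * S, 2 * T)
    if len(ai):
        diff = bc[ai] != bc[bj]
        wlo, whi = win_end_start(le[ai], ls[bj])
        # INV: A ends at both breakpoints, B starts at both
        k2lo, k2hi = win_end_start(re[ai], rs[bj])
        size = (k2lo + k2hi) // 2 - (wlo + whi) // 2
        keep = diff & (rs[bj] - re[ai] >= -2 * S) & \
            (rs[bj] - re[ai] <= 2 * T) & \
            (size > sw.min_inv) & (size <= sw.max_event)
        emit("INV", ai, bj, keep, wlo, whi, k2lo, k2hi)
        # DUP_DIRECT, insertion left of source: bp3 at the coincidence,
        # p from A.rs (start anchor), q from B.re (end anchor)
        b1lo, b1hi = rs[ai] - T, rs[ai] + S + 1
        b2lo, b2hi = re[bj] - S, re[bj] + T + 1
        p = (b1lo + b1hi) // 2
        q = (b2lo + b2hi) // 2
        ins = (wlo + whi) // 2
        keep = diff & (p < q) & (q - p > sw.min_dup) & \
            (q - p <= sw.max_event) & (p - ins > sw.dup_min_distance)
        emit("DUP_DIRECT", ai, bj, keep, b1lo, b1hi, b2lo, b2hi, wlo, whi)
        # DUP_INVERTED, insertion left: p from B.rs, q from A.re
        b1lo, b1hi = rs[bj] - T, rs[bj] + S + 1
        b2lo, b2hi = re[ai] - S, re[ai] + T + 1
        p = (b1lo + b1hi) // 2
        q = (b2lo + b2hi) // 2
        keep = diff & (p < q) & (q - p > sw.min_dup) & \
            (q - p <= sw.max_event) & (p - ins > sw.dup_min_distance)
        emit("DUP_INVERTED", ai, bj, keep, b1lo, b1hi, b2lo, b2hi, wlo, whi)

    # --- combo A.re (end anchor) ~ B.rs (start anchor)
    ai, bj = _pairs_within(re, rs, -2 * S, 2 * T)
    if len(ai):
        diff = bc[ai] != bc[bj]
        wlo, whi = win_end_start(re[ai], rs[bj])
        ins = (wlo + whi) // 2
        # DUP_DIRECT, insertion right: p from A.ls, q from B.le
        b1lo, b1hi = ls[ai] - T, ls[ai] + S + 1
        b2lo, b2hi = le[bj] - S, le[bj] + T + 1
        p = (b1lo + b1hi) // 2
        q = (b2lo + b2hi) // 2
        keep = diff & (p < q) & (q - p > sw.min_dup) & \
            (q - p <= sw.max_event) & (ins - q > sw.dup_min_distance)
        emit("DUP_DIRECT", ai, bj, keep, b1lo, b1hi, b2lo, b2hi, wlo, whi)
        # DUP_INVERTED, insertion right: p from B.ls, q from A.le
        b1lo, b1hi = ls[bj] - T, ls[bj] + S + 1
        b2lo, b2hi = le[ai] - S, le[ai] + T + 1
        p = (b1lo + b1hi) // 2
        q = (b2lo + b2hi) // 2
        keep = diff & (p < q) & (q - p > sw.min_dup) & \
            (q - p <= sw.max_event) & (ins - q > sw.dup_min_distance)
        emit("DUP_INVERTED", ai, bj, keep, b1lo, b1hi, b2lo, b2hi, wlo, whi)

    return out


def match_split_molecule_pairs(splits: CandidateSplits,
                               index: DiscordantIndex,
                               stats: MoleculeStats,
                               windows: SizeWindows | None = None,
                               min_rp_support: int = 3,
                               pad: int | None = None
                               ) -> list[SplitMoleculePair]:
    """All cross-barcode split pairs passing a signature predicate, size
    windows, and the read-pair support floor (>= 3 by default).

    Every signature requires at least one junction anchored within ``T``
    by endpoints of *both* splits, so candidate pairs are generated from
    endpoint coincidences rather than all-against-all comparison, and
    each junction of a two-junction signature must be signaled by at
    least one correctly oriented discordant pair (FF *and* RR junctions
    for inversions; each source-edge/insertion junction for DUP/TRA).

    Output is canonical and deterministic: pairs are sorted by
    (type, chromosome, bp1 start) and deduplicated per unordered pair.
    """
    windows = windows or SizeWindows()
    T = int(stats.T)
    if pad is None:
        pad = int(stats.T)
    out: list[SplitMoleculePair] = []

    intra_idx = np.flatnonzero(splits.cl == splits.cr)
    for c in np.unique(splits.cl[intra_idx]):
        rows = intra_idx[splits.cl[intra_idx] == c]
        out.extend(_match_intra_chrom(splits, rows, index, int(c), T,
                                      windows, min_rp_support, pad))

    # inter-chromosomal (translocations): anchor-restricted splits are few
    inter_idx = np.flatnonzero(splits.cl != splits.cr)
    if len(inter_idx):
        order = inter_idx[np.lexsort((splits.ls[inter_idx],
                                      splits.cr[inter_idx],
                                      splits.cl[inter_idx]))]
        views = [splits.view(int(k)) for k in order]
        for x in range(len(views)):
            vi = views[x]
            for y in range(x + 1, len(views)):
                vj = views[y]
                if vj.cl != vi.cl or vj.cr != vi.cr:
                    break
                if vi.barcode == vj.barcode:
                    continue
                res = _tra_predicate(vi, vj, T, windows)
                if res is None:
                    continue
                chrom1, bp1, bp2, chrom2, bp3, A, B = res
                parts = _support_parts("TRA", chrom1, bp1, bp2, chrom2, bp3,
                                       index, pad)
                if sum(parts) >= min_rp_support and min(parts) >= 1:
                    out.append(SplitMoleculePair("TRA", A, B, chrom1, bp1,
                                                 bp2, chrom2, bp3,
                                                 sum(parts), roled=True))

    # canonical order and per-unordered-pair dedup
    out.sort(key=lambda p: (p.sv_type, p.chrom1, p.bp1[0], p.bp2[0],
                            p.a.id, p.b.id))
    seen: set[tuple] = set()
    uniq: list[SplitMoleculePair] = []
    for p in out:
        key = (p.sv_type, min(p.a.id, p.b.id), max(p.a.id, p.b.id))
        if key in seen:
            continue
        seen.add(key)
        uniq.append(p)
    return uniq
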