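"""Barcoded alignment input.

Reads coordinate-sorted alignments carrying per-read barcode tags (10x
Genomics style ``BX`` tags), classifies read pairs into concordant
*fragments* (the full span of a properly oriented FR pair) and *discordant
pairs* (everything else, by orientation class), and applies an exclusion
mask for satellite / low-complexity regions.

Bulk data is held columnar (numpy arrays) because a linked-read run at
useful physical coverage contains :math:`10^5`–:math:`10^8` read pairs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

#: discordant pair orientation classes
INTRA_FAR = 0          # same chromosome, FR/RF but span outside concordance bounds
INTRA_INVERTED_FF = 1  # same chromosome, both mates forward
INTRA_INVERTED_RR = 2  # same chromosome, both mates reverse
INTERCHROM = 3         # mates on different chromosomes

PAIR_CLASS_NAMES = ("intra_far", "intra_inverted_FF", "intra_inverted_RR",
                    "interchromosomal")


class MaskFormatError(ValueError):
    """Raised when a BED mask file cannot be parsed."""


class AlignmentInputError(ValueError):
    """Raised on fatal alignment-input problems (unsorted file, no barcodes)."""


# ---------------------------------------------------------------------------
# Region mask
# ---------------------------------------------------------------------------

@dataclass
class RegionMask:
    """Per-chromosome set of excluded intervals (0-based, half-open).

    Intervals are normalized on construction: sorted and merged, so
    membership queries are deterministic and order-independent.
    """

    intervals: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def empty(cls) -> "RegionMask":
        return cls({})

    @classmethod
    def from_intervals(cls, ivs) -> "RegionMask":
        """Build a normalized mask from an iterable of (chrom, start, end)."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in ivs:
            start, end = int(start), int(end)
            if end <= start:
                raise MaskFormatError(f"empty/negative interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, lst in by_chrom.items():
            lst.sort()
            starts: list[int] = []
            ends: list[int] = []
            for s, e in lst:
                if starts and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            out[chrom] = (np.asarray(starts, dtype=np.int64),
                         np.asarray(ends, dtype=np.int64))
        return cls(out)

    @classmethod
    def from_bed(cls, path) -> "RegionMask":
        """Load a BED3+ file; malformed lines raise with their line number."""
        ivs = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 3:
                    raise MaskFormatError(
                        f"{path}: line {lineno}: expected >=3 BED columns")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise MaskFormatError(
                        f"{path}: line {lineno}: non-integer coordinates") from exc
                if end <= start or start < 0:
                    raise MaskFormatError(
                        f"{path}: line {lineno}: invalid interval {start}-{end}")
                ivs.append((fields[0], start, end))
        return cls.from_intervals(ivs)

    def n_intervals(self) -> int:
        return sum(len(s) for s, _ in self.intervals.values())

    def contains(self, chrom: str, pos: int) -> bool:
        """True iff ``pos`` falls inside a masked interval."""
        return bool(self.overlaps_many(chrom,
                                       np.asarray([pos]),
                                       np.asarray([pos + 1]))[0])

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return bool(self.overlaps_many(chrom, np.asarray([start]),
                                       np.asarray([end]))[0])

    def overlaps_many(self, chrom: str, starts: np.ndarray,
                      ends: np.ndarray) -> np.ndarray:
        """Vectorized: does each half-open [start, end) touch the mask?"""
        if chrom not in self.intervals:
            return np.zeros(len(starts), dtype=bool)
        ms, me = self.intervals[chrom]
        idx = np.searchsorted(ms, ends, side="left") - 1
        ok = idx >= 0
        hit = np.zeros(len(starts), dtype=bool)
        hit[ok] = me[idx[ok]] > starts[ok]
        return hit

    def masked_bins(self, chrom: str, n_bins: int, bin_size: int) -> np.ndarray:
        """Boolean vector: bins touched by any masked interval."""
        out = np.zeros(n_bins, dtype=bool)
        if chrom not in self.intervals:
            return out
        ms, me = self.intervals[chrom]
        for s, e in zip(ms, me):
            b0 = max(0, int(s) // bin_size)
            b1 = min(n_bins - 1, (int(e) - 1) // bin_size)
            if b0 <= b1:
                out[b0:b1 + 1] = True
        return out


# ---------------------------------------------------------------------------
# Columnar read-pair / fragment / discordant-pair containers
# ---------------------------------------------------------------------------

@dataclass
class ReadPairs:
    """Canonicalized mate pairs: (chrom1, begin1) <= (chrom2, begin2).

    ``rev*`` is True for reverse-strand mates; ``b*``/``e*`` are 0-based
    half-open mate intervals.  ``barcode`` indexes into ``barcodes``.
    """

    chroms: tuple[str, ...]
    barcodes: tuple[str, ...]
    c1: np.ndarray
    b1: np.ndarray
    e1: np.ndarray
    rev1: np.ndarray
    c2: np.ndarray
    b2: np.ndarray
    e2: np.ndarray
    rev2: np.ndarray
    barcode: np.ndarray

    def __len__(self) -> int:
        return len(self.c1)

    @classmethod
    def from_mates(cls, chroms, barcodes, cA, bA, eA, revA, cB, bB, eB, revB,
                   barcode) -> "ReadPairs":
        """Canonicalize mate order by (chrom, begin)."""
        cA = np.asarray(cA, dtype=np.int32)
        cB = np.asarray(cB, dtype=np.int32)
        bA = np.asarray(bA, dtype=np.int64)
        bB = np.asarray(bB, dtype=np.int64)
        swap = (cB < cA) | ((cB == cA) & (bB < bA))
        pick = lambda x, y: np.where(swap, y, x)  # noqa: E731
        return cls(tuple(chroms), tuple(barcodes),
                   pick(cA, cB).astype(np.int32), pick(bA, bB),
                   pick(np.asarray(eA, np.int64), np.asarray(eB, np.int64)),
                   pick(np.asarray(revA, bool), np.asarray(revB, bool)),
                   pick(cB, cA).astype(np.int32), pick(bB, bA),
                   pick(np.asarray(eB, np.int64), np.asarray(eA, np.int64)),
                   pick(np.asarray(revB, bool), np.asarray(revA, bool)),
                   np.asarray(barcode, dtype=np.int64))


@dataclass
class Fragments:
    """Full spans of concordantly mapped read pairs."""

    chroms: tuple[str, ...]
    barcodes: tuple[str, ...]
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    barcode: np.ndarray

    def __len__(self) -> int:
        return len(self.chrom)


@dataclass
class DiscordantPairs:
    """Read pairs violating concordance, by orientation class."""

    chroms: tuple[str, ...]
    barcodes: tuple[str, ...]
    c1: np.ndarray
    p1: np.ndarray
    rev1: np.ndarray
    c2: np.ndarray
    p2: np.ndarray
    rev2: np.ndarray
    barcode: np.ndarray
    pair_class: np.ndarray

    def __len__(self) -> int:
        return len(self.c1)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def estimate_concordance_bounds(pairs: ReadPairs, n_sd: float = 4.0,
                                sample: int = 1_000_000,
                                span_cap: int = 50_000) -> tuple[int, int]:
    """Concordant insert-size bounds: center +/- n_sd * spread of FR spans.

    Spans are taken from the first ``sample`` same-chromosome FR pairs with
    span below ``span_cap`` (a loose prior excluding obvious SV pairs).
    The center/spread are the median and the MAD-derived sigma, which are
    insensitive to the long tail of mismapped and SV-spanning pairs.
    """
    span = pairs.e2 - pairs.b1
    ok = (pairs.c1 == pairs.c2) & ~pairs.rev1 & pairs.rev2 & \
        (span > 0) & (span < span_cap)
    vals = span[ok][:sample]
    if len(vals) < 10:
        raise AlignmentInputError("too few proper pairs to estimate insert size")
    mu = float(np.median(vals))
    sd = 1.4826 * float(np.median(np.abs(vals - mu)))
    lo = max(0, int(mu - n_sd * sd))
    hi = int(np.ceil(mu + n_sd * sd))
    return lo, hi


def classify_pairs(pairs: ReadPairs, mask: RegionMask | None,
                   concordance_min: int, concordance_max: int
                   ) -> tuple[Fragments, DiscordantPairs, dict]:
    """Partition read pairs into Fragments xor DiscordantPairs.

    A pair becomes one Fragment iff same chromosome, FR orientation
    (leftmost mate forward, rightmost reverse) and full span within the
    concordance bounds.  Pairs with either mate inside the mask are dropped
    and counted.  Every retained pair contributes to exactly one output.
    """
    n = len(pairs)
    keep = np.ones(n, dtype=bool)
    if mask is not None and mask.intervals:
        hit = np.zeros(n, dtype=bool)
        for ci, chrom in enumerate(pairs.chroms):
            m1 = pairs.c1 == ci
            if m1.any():
                hit[m1] |= mask.overlaps_many(chrom, pairs.b1[m1], pairs.e1[m1])
            m2 = pairs.c2 == ci
            if m2.any():
                hit[m2] |= mask.overlaps_many(chrom, pairs.b2[m2], pairs.e2[m2])
        keep &= ~hit
    span = pairs.e2 - pairs.b1
    concordant = keep & (pairs.c1 == pairs.c2) & ~pairs.rev1 & pairs.rev2 & \
        (span >= concordance_min) & (span <= concordance_max)
    disc = keep & ~concordant

    frags = Fragments(pairs.chroms, pairs.barcodes,
                      pairs.c1[concordant], pairs.b1[concordant],
                      pairs.e2[concordant], pairs.barcode[concordant])

    pc = np.full(n, INTRA_FAR, dtype=np.int8)
    pc[pairs.c1 != pairs.c2] = INTERCHROM
    same = pairs.c1 == pairs.c2
    pc[same & ~pairs.rev1 & ~pairs.rev2] = INTRA_INVERTED_FF
    pc[same & pairs.rev1 & pairs.rev2] = INTRA_INVERTED_RR
    discordant = DiscordantPairs(pairs.chroms, pairs.barcodes,
                                 pairs.c1[disc], pairs.b1[disc], pairs.rev1[disc],
                                 pairs.c2[disc], pairs.b2[disc], pairs.rev2[disc],
                                 pairs.barcode[disc], pc[disc])
    counts = {"n_pairs": int(n),
              "n_masked": int(n - keep.sum()),
              "n_fragments": int(concordant.sum()),
              "n_discordant": int(disc.sum())}
    return frags, discordant, counts


# ---------------------------------------------------------------------------
# BAM input
# ---------------------------------------------------------------------------

def read_bam_pairs(path, barcode_tag: str = "BX", min_mapq: int = 20
                   ) -> tuple[ReadPairs, dict, dict]:
    """Read a coordinate-sorted barcoded BAM into mate-paired arrays.

    Secondary/supplementary/duplicate/unmapped records are skipped, as are
    records below the MAPQ floor or without the barcode tag; skip counts are
    returned.  Raises :class:`AlignmentInputError` if the file is not
    coordinate-sorted or no record carries the barcode tag.
    """
    af = pysam.AlignmentFile(str(path), "rb")
    so = (af.header.to_dict().get("HD") or {}).get("SO")
    if so != "coordinate":
        raise AlignmentInputError(f"{path}: alignment file is not coordinate-sorted")
    chroms = tuple(af.references)
    chrom_lengths = {name: af.get_reference_length(name) for name in chroms}

    counts = {"n_records": 0, "skip_flag": 0, "skip_mapq": 0, "skip_no_barcode": 0,
              "n_orphans": 0}
    pending: dict[str, tuple] = {}
    bc_codes: dict[str, int] = {}
    rows = []  # (cA,bA,eA,revA,cB,bB,eB,revB,bc)
    last = (-1, -1)
    for rec in af:
        counts["n_records"] += 1
        if rec.is_unmapped:
            counts["skip_flag"] += 1
            continue
        pos_key = (rec.reference_id, rec.reference_start)
        if pos_key < last:
            raise AlignmentInputError(f"{path}: records out of coordinate order")
        last = pos_key
        if rec.is_secondary or rec.is_supplementary or rec.is_duplicate or \
                not rec.is_paired or rec.mate_is_unmapped:
            counts["skip_flag"] += 1
            continue
        if rec.mapping_quality < min_mapq:
            counts["skip_mapq"] += 1
            continue
        if not rec.has_tag(barcode_tag):
            counts["skip_no_barcode"] += 1
            continue
        bc = rec.get_tag(barcode_tag)
        mate = pending.pop(rec.query_name, None)
        if mate is None:
            pending[rec.query_name] = (rec.reference_id, rec.reference_start,
                                       rec.reference_end, rec.is_reverse, bc)
            continue
        code = bc_codes.setdefault(mate[4], len(bc_codes))
        rows.append((mate[0], mate[1], mate[2], mate[3],
                     rec.reference_id, rec.reference_start, rec.reference_end,
                     rec.is_reverse, code))
    af.close()
    counts["n_orphans"] = len(pending)
    if counts["n_records"] and not rows and not bc_codes and \
            counts["skip_no_barcode"] > 0:
        raise AlignmentInputError(
            f"{path}: no record carries the barcode tag '{barcode_tag}'")
    barcodes = tuple(bc_codes)
    if rows:
        arr = np.asarray(rows, dtype=np.int64)
        pairs = ReadPairs.from_mates(chroms, barcodes,
                                     arr[:, 0], arr[:, 1], arr[:, 2],
                                     arr[:, 3].astype(bool),
                                     arr[:, 4], arr[:, 5], arr[:, 6],
                                     arr[:, 7].astype(bool), arr[:, 8])
    else:
        z = np.zeros(0, dtype=np.int64)
        pairs = ReadPairs(chroms, barcodes, z.astype(np.int32), z, z,
                          z.astype(bool), z.astype(np.int32), z, z,
                          z.astype(bool), z)
    return pairs, counts, chrom_lengths
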