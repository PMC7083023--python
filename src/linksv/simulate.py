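"""Synthetic barcoded linked-read data with planted SVs.

Emulates the statistical structure the caller assumes — barcode pools of
2–30 molecules, a long-tailed (lognormal by default) molecule size
distribution, low per-molecule sequence coverage (~0.1x) with high
aggregate physical coverage — without simulating bases or a mapper.
Reads are placed on a donor genome built by applying the planted SVs and
mapped back to reference coordinates through the donor's piecewise-linear
coordinate map, so molecules spanning SV breakpoints produce split
mappings and discordant read-pair orientations naturally.

Everything is driven by one integer seed; identical configurations give
byte-identical output.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pysam

from .io import ReadPairs

DEFAULT_SIZE_RANGES = {
    "DEL": (100_000, 1_000_000),
    "INV": (80_000, 1_000_000),
    "DUP_DIRECT": (40_000, 1_000_000),
    "DUP_INVERTED": (40_000, 1_000_000),
    "TRA": (100_000, 1_000_000),
}


@dataclass
class TruthRecord:
    """A planted SV: source interval, optional insertion locus, zygosity."""

    sv_type: str
    chrom: str
    start: int
    end: int
    ins_chrom: str | None = None
    ins_pos: int | None = None
    zygosity: str = "het"

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class SimConfig:
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 30_000_000})
    ploidy: int = 2
    molecule_size_mean: float = 50_000.0
    molecule_size_distribution: str = "lognormal"  # or "exponential"
    molecule_sigma_log: float = 0.55
    pool_size_range: tuple[int, int] = (2, 30)
    physical_coverage: float = 50.0
    per_molecule_coverage: float = 0.1
    read_length: int = 100
    insert_mean: float = 450.0
    insert_sd: float = 45.0
    sv_counts: dict[str, int] = field(default_factory=dict)
    sv_size_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_RANGES))
    svs: list[TruthRecord] | None = None   # explicit list overrides sv_counts
    zygosity: str = "mixed"                # "het" | "hom" | "mixed"
    dup_min_distance: int = 80_000
    placement_margin: int = 100_000
    noise_pair_fraction: float = 0.01
    jitter_sd: float = 2.0
    seed: int = 0

    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())


# ---------------------------------------------------------------------------
# SV planting and the donor coordinate map
# ---------------------------------------------------------------------------

def plant_svs(config: SimConfig, rng: np.random.Generator
              ) -> list[TruthRecord]:
    """Place non-overlapping SVs of the requested counts and size ranges.

    Insertion loci (DUP/TRA) are drawn uniformly at random subject to the
    displacement floor (> ``dup_min_distance`` from the source for
    duplications) and non-overlap margins; translocations insert on a
    different chromosome.
    """
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    margin = config.placement_margin
    blocked: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def free(chrom: str, lo: int, hi: int) -> bool:
        return all(hi <= s or lo >= e for s, e in blocked[chrom])

    def block(chrom: str, lo: int, hi: int) -> None:
        blocked[chrom].append((lo - margin, hi + margin))

    def pick_chrom(exclude: str | None = None) -> str:
        opts = [c for c in chroms if c != exclude]
        if not opts:
            raise ValueError("translocations require at least 2 chromosomes")
        w = np.array([config.chrom_lengths[c] for c in opts], dtype=float)
        return opts[rng.choice(len(opts), p=w / w.sum())]

    def zyg() -> str:
        if config.ploidy == 1:
            return "hom"
        if config.zygosity == "mixed":
            return "het" if rng.random() < 0.5 else "hom"
        return config.zygosity

    truths: list[TruthRecord] = []
    for sv_type in ("DEL", "INV", "DUP_DIRECT", "DUP_INVERTED", "TRA"):
        for _ in range(config.sv_counts.get(sv_type, 0)):
            lo, hi = config.sv_size_ranges.get(sv_type,
                                               DEFAULT_SIZE_RANGES[sv_type])
            placed = False
            for _try in range(2000):
                size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                chrom = chroms[rng.choice(len(chroms),
                                          p=lengths / lengths.sum())]
                L = config.chrom_lengths[chrom]
                if L < size + 2 * margin:
                    continue
                start = int(rng.integers(margin, L - size - margin))
                if not free(chrom, start - margin, start + size + margin):
                    continue
                rec = TruthRecord(sv_type, chrom, start, start + size,
                                  zygosity=zyg())
                if sv_type in ("DUP_DIRECT", "DUP_INVERTED", "TRA"):
                    ok = False
                    for _t2 in range(200):
                        ic = chrom if sv_type != "TRA" else pick_chrom(chrom)
                        IL = config.chrom_lengths[ic]
                        ip = int(rng.integers(margin, IL - margin))
                        if ic == chrom:
                            dist = min(abs(ip - start), abs(ip - rec.end))
                            if start - margin < ip < rec.end + margin or \
                                    dist <= config.dup_min_distance:
                                continue
                        if free(ic, ip - margin, ip + margin):
                            rec.ins_chrom, rec.ins_pos = ic, ip
                            ok = True
                            break
                    if not ok:
                        continue
                block(chrom, start, rec.end)
                if rec.ins_pos is not None:
                    block(rec.ins_chrom, rec.ins_pos, rec.ins_pos + 1)
                truths.append(rec)
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"could not place a {sv_type} of the requested size; "
                    "genome too small or too crowded")
    return truths


@dataclass
class DonorChrom:
    """Piecewise map from one donor chromosome to reference coordinates."""

    dstarts: np.ndarray      # len n_seg + 1, cumulative donor offsets
    ref_chrom: np.ndarray    # chromosome code per segment
    ref_start: np.ndarray
    ref_end: np.ndarray
    rev: np.ndarray          # segment mapped in inverted orientation

    @property
    def length(self) -> int:
        return int(self.dstarts[-1])

    def map_positions(self, dpos: np.ndarray, span: int
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map donor start positions of features of length ``span``.

        A feature is assigned to the segment containing its start; returns
        (ref chromosome code, ref start, orientation-flipped?).
        """
        seg = np.searchsorted(self.dstarts, dpos, side="right") - 1
        seg = np.clip(seg, 0, len(self.ref_chrom) - 1)
        off = dpos - self.dstarts[seg]
        fwd = self.ref_start[seg] + off
        bwd = self.ref_end[seg] - off - span
        pos = np.where(self.rev[seg], bwd, fwd)
        return self.ref_chrom[seg], pos, self.rev[seg]

    def footprint(self, dstart: int, dend: int,
                  chroms: tuple[str, ...]) -> list[tuple[str, int, int]]:
        """Reference-space intervals covered by donor range [dstart, dend)."""
        out = []
        s0 = int(np.searchsorted(self.dstarts, dstart, side="right") - 1)
        s1 = int(np.searchsorted(self.dstarts, dend - 1, side="right") - 1)
        for seg in range(max(0, s0), min(len(self.ref_chrom), s1 + 1)):
            lo = max(dstart, int(self.dstarts[seg]))
            hi = min(dend, int(self.dstarts[seg + 1]))
            if hi <= lo:
                continue
            o0 = lo - int(self.dstarts[seg])
            o1 = hi - int(self.dstarts[seg])
            if self.rev[seg]:
                out.append((chroms[int(self.ref_chrom[seg])],
                            int(self.ref_end[seg]) - o1,
                            int(self.ref_end[seg]) - o0))
            else:
                out.append((chroms[int(self.ref_chrom[seg])],
                            int(self.ref_start[seg]) + o0,
                            int(self.ref_start[seg]) + o1))
        return out


def build_donor(chrom_lengths: dict[str, int], svs: list[TruthRecord]
                ) -> dict[str, DonorChrom]:
    """Apply SVs to the reference layout: DEL removes, INV reverses in
    place, DUP inserts a (possibly inverted) copy, TRA inserts a copy and
    removes the source."""
    chroms = list(chrom_lengths)
    code = {c: i for i, c in enumerate(chroms)}
    edits: dict[str, list[tuple[int, int, str, tuple | None]]] = \
        {c: [] for c in chroms}
    for sv in svs:
        if sv.sv_type == "DEL":
            edits[sv.chrom].append((sv.start, 0, "rm", (sv.start, sv.end)))
        elif sv.sv_type == "INV":
            edits[sv.chrom].append((sv.start, 0, "inv", (sv.start, sv.end)))
        elif sv.sv_type in ("DUP_DIRECT", "DUP_INVERTED"):
            seg = (code[sv.chrom], sv.start, sv.end,
                   sv.sv_type == "DUP_INVERTED")
            edits[sv.ins_chrom].append((sv.ins_pos, -1, "ins", seg))
        elif sv.sv_type == "TRA":
            edits[sv.chrom].append((sv.start, 0, "rm", (sv.start, sv.end)))
            seg = (code[sv.chrom], sv.start, sv.end, False)
            edits[sv.ins_chrom].append((sv.ins_pos, -1, "ins", seg))
        else:
            raise ValueError(f"unknown SV type {sv.sv_type}")

    donors: dict[str, DonorChrom] = {}
    for chrom in chroms:
        L = chrom_lengths[chrom]
        segs: list[tuple[int, int, int, bool]] = []
        cur = 0
        for pos, _prio, kind, payload in sorted(edits[chrom]):
            if kind == "ins":
                if pos > cur:
                    segs.append((code[chrom], cur, pos, False))
                    cur = pos
                segs.append(payload)
            else:
                s, e = payload
                if s > cur:
                    segs.append((code[chrom], cur, s, False))
                if kind == "inv":
                    segs.append((code[chrom], s, e, True))
                cur = e
        if cur < L:
            segs.append((code[chrom], cur, L, False))
        segs = [s for s in segs if s[2] > s[1]]
        lens = np.array([e - s for _, s, e, _ in segs], dtype=np.int64)
        donors[chrom] = DonorChrom(
            np.concatenate([[0], np.cumsum(lens)]),
            np.array([c for c, _, _, _ in segs], dtype=np.int32),
            np.array([s for _, s, _, _ in segs], dtype=np.int64),
            np.array([e for _, _, e, _ in segs], dtype=np.int64),
            np.array([r for _, _, _, r in segs], dtype=bool))
    return donors


# ---------------------------------------------------------------------------
# Read-pair simulation
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    pairs: ReadPairs
    truths: list[TruthRecord]
    chrom_lengths: dict[str, int]
    donors: list[dict[str, DonorChrom]]   # one donor genome per haplotype
    mol_hap: np.ndarray
    mol_chrom: np.ndarray                 # donor chromosome index
    mol_start: np.ndarray                 # donor coordinates
    mol_len: np.ndarray
    mol_barcode: np.ndarray


def _molecule_lengths(config: SimConfig, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    mean = config.molecule_size_mean
    if config.molecule_size_distribution == "lognormal":
        sig = config.molecule_sigma_log
        mu_log = np.log(mean) - 0.5 * sig ** 2
        lens = rng.lognormal(mu_log, sig, size=n)
    elif config.molecule_size_distribution == "exponential":
        lens = rng.exponential(mean, size=n)
    else:
        raise ValueError("molecule_size_distribution must be "
                         "'lognormal' or 'exponential'")
    return np.clip(lens, 1_000, 10 * mean).astype(np.int64)


def simulate_readpairs(config: SimConfig) -> SimResult:
    """Generate mapped, barcoded read pairs for the configured genome."""
    rng = np.random.default_rng(config.seed)
    chroms = tuple(config.chrom_lengths)
    chrom_len = np.array([config.chrom_lengths[c] for c in chroms],
                         dtype=np.int64)
    truths = config.svs if config.svs is not None else plant_svs(config, rng)
    if config.ploidy == 1:
        donors = [build_donor(config.chrom_lengths, truths)]
    else:
        hom = [t for t in truths if t.zygosity == "hom"]
        donors = [build_donor(config.chrom_lengths, hom),
                  build_donor(config.chrom_lengths, truths)]

    genome = config.genome_length()
    n_mol = int(round(config.physical_coverage * genome /
                      config.molecule_size_mean))
    mol_hap = rng.integers(0, len(donors), size=n_mol).astype(np.int8)
    mol_len = _molecule_lengths(config, n_mol, rng)
    mol_chrom = np.zeros(n_mol, dtype=np.int32)
    mol_start = np.zeros(n_mol, dtype=np.int64)
    for h, donor in enumerate(donors):
        sel = np.flatnonzero(mol_hap == h)
        if not len(sel):
            continue
        dlen = np.array([donor[c].length for c in chroms], dtype=float)
        mol_chrom[sel] = rng.choice(len(chroms), size=len(sel),
                                    p=dlen / dlen.sum())
        for ci in range(len(chroms)):
            s2 = sel[mol_chrom[sel] == ci]
            if not len(s2):
                continue
            cap = int(dlen[ci])
            mol_len[s2] = np.minimum(mol_len[s2], cap)
            mol_start[s2] = rng.integers(
                0, np.maximum(cap - mol_len[s2], 0) + 1, size=len(s2))

    # barcode pools of 2-30 molecules
    lo, hi = config.pool_size_range
    sizes = rng.integers(lo, hi + 1, size=max(1, 2 * n_mol // (lo + hi) + 2))
    while sizes.sum() < n_mol:
        sizes = np.concatenate([sizes, rng.integers(lo, hi + 1, size=16)])
    pool_of = np.repeat(np.arange(len(sizes)), sizes)[:n_mol]
    mol_barcode = np.empty(n_mol, dtype=np.int64)
    mol_barcode[rng.permutation(n_mol)] = pool_of
    barcodes = tuple(f"BX{i:06d}" for i in range(int(mol_barcode.max()) + 1)) \
        if n_mol else ()

    # read pairs along each molecule at the per-molecule coverage
    rl = config.read_length
    rate = config.per_molecule_coverage / (2 * rl)
    n_pairs = rng.poisson(rate * mol_len)
    tot = int(n_pairs.sum())
    mol = np.repeat(np.arange(n_mol), n_pairs)
    insert = np.clip(np.round(rng.normal(config.insert_mean, config.insert_sd,
                                         size=tot)),
                     2 * rl + 10, None).astype(np.int64)
    insert = np.minimum(insert, mol_len[mol])
    rel = np.floor(rng.random(tot) * (mol_len[mol] - insert + 1)).astype(np.int64)
    d1 = mol_start[mol] + rel
    d2 = mol_start[mol] + rel + insert - rl

    c1 = np.zeros(tot, dtype=np.int32)
    p1 = np.zeros(tot, dtype=np.int64)
    f1 = np.zeros(tot, dtype=bool)
    c2 = np.zeros(tot, dtype=np.int32)
    p2 = np.zeros(tot, dtype=np.int64)
    f2 = np.zeros(tot, dtype=bool)
    for h, donor in enumerate(donors):
        for ci, chrom in enumerate(chroms):
            sel = (mol_hap[mol] == h) & (mol_chrom[mol] == ci)
            if not sel.any():
                continue
            dc = donor[chrom]
            c1[sel], p1[sel], f1[sel] = dc.map_positions(d1[sel], rl)
            c2[sel], p2[sel], f2[sel] = dc.map_positions(d2[sel], rl)
    rev1 = f1          # mate 1 simulated forward; flipped by inverted segments
    rev2 = ~f2         # mate 2 simulated reverse

    if config.jitter_sd > 0 and tot:
        p1 += np.round(rng.normal(0, config.jitter_sd, size=tot)).astype(np.int64)
        p2 += np.round(rng.normal(0, config.jitter_sd, size=tot)).astype(np.int64)

    # mismapping noise: relocate one mate of a random subset of pairs
    n_noise = int(round(config.noise_pair_fraction * tot))
    if n_noise:
        idx = rng.choice(tot, size=n_noise, replace=False)
        c2[idx] = rng.choice(len(chroms), size=n_noise,
                             p=chrom_len / chrom_len.sum())
        p2[idx] = (rng.random(n_noise) *
                   (chrom_len[c2[idx]] - rl)).astype(np.int64)
        rev2[idx] = rng.random(n_noise) < 0.5

    p1 = np.clip(p1, 0, chrom_len[c1] - rl)
    p2 = np.clip(p2, 0, chrom_len[c2] - rl)
    pairs = ReadPairs.from_mates(chroms, barcodes, c1, p1, p1 + rl, rev1,
                                 c2, p2, p2 + rl, rev2, mol_barcode[mol])
    return SimResult(pairs, truths, dict(config.chrom_lengths), donors,
                     mol_hap, mol_chrom, mol_start, mol_len, mol_barcode)


def molecule_reference_footprints(result: SimResult
                                  ) -> list[list[tuple[str, int, int]]]:
    """Per molecule, the reference-space intervals its donor span covers."""
    chroms = tuple(result.chrom_lengths)
    out = []
    for i in range(len(result.mol_hap)):
        dc = result.donors[int(result.mol_hap[i])][chroms[int(result.mol_chrom[i])]]
        out.append(dc.footprint(int(result.mol_start[i]),
                                int(result.mol_start[i] + result.mol_len[i]),
                                chroms))
    return out


# ---------------------------------------------------------------------------
# Alignment-file output
# ---------------------------------------------------------------------------

def write_bam(result: SimResult, path, barcode_tag: str = "BX") -> None:
    """Write the simulated pairs as a coordinate-sorted, indexed BAM."""
    chroms = tuple(result.chrom_lengths)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": c, "LN": int(result.chrom_lengths[c])}
                     for c in chroms]}
    p = result.pairs
    rl1 = p.e1 - p.b1
    rl2 = p.e2 - p.b2
    rows = []
    for i in range(len(p)):
        rows.append((int(p.c1[i]), int(p.b1[i]), int(rl1[i]),
                     bool(p.rev1[i]), i, True,
                     int(p.c2[i]), int(p.b2[i]), bool(p.rev2[i])))
        rows.append((int(p.c2[i]), int(p.b2[i]), int(rl2[i]),
                     bool(p.rev2[i]), i, False,
                     int(p.c1[i]), int(p.b1[i]), bool(p.rev1[i])))
    rows.sort(key=lambda r: (r[0], r[1], r[4], not r[5]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for tid, pos, length, rev, pid, first, mtid, mpos, mrev in rows:
            a = pysam.AlignedSegment()
            a.query_name = f"p{pid}"
            a.reference_id = tid
            a.reference_start = pos
            a.cigarstring = f"{length}M"
            a.query_sequence = "A" * length
            a.mapping_quality = 60
            a.flag = (0x1 | (0x10 if rev else 0) | (0x20 if mrev else 0)
                      | (0x40 if first else 0x80))
            a.next_reference_id = mtid
            a.next_reference_start = mpos
            a.set_tag(barcode_tag, p.barcodes[int(p.barcode[pid])], "Z")
            bam.write(a)
    pysam.index(str(path))


def simulate_alignments(config: SimConfig, out_prefix: str,
                        barcode_tag: str = "BX") -> SimResult:
    """Simulate and write <prefix>.bam/.bam.bai, <prefix>.truth.bedpe and a
    config echo <prefix>.sim.yaml."""
    import yaml

    result = simulate_readpairs(config)
    write_bam(result, f"{out_prefix}.bam", barcode_tag=barcode_tag)
    write_truth(result.truths, f"{out_prefix}.truth.bedpe")
    cfg = dataclasses.asdict(config)
    cfg["svs"] = [dataclasses.asdict(t) for t in result.truths]
    with open(f"{out_prefix}.sim.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return result


def write_truth(truths: list[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tins_chrom\tins_pos\tsv_type\tzygosity\n")
        for t in truths:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t"
                     f"{t.ins_chrom or '.'}\t"
                     f"{t.ins_pos if t.ins_pos is not None else -1}\t"
                     f"{t.sv_type}\t{t.zygosity}\n")


def read_truth(path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end, ic, ip, sv_type, zyg = line.rstrip("\n").split("\t")
            out.append(TruthRecord(sv_type, chrom, int(start), int(end),
                                   None if ic == "." else ic,
                                   None if int(ip) < 0 else int(ip), zyg))
    return out
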