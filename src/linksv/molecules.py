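"""Molecule recovery and molecule-depth profiling.

Large input molecules (tens of kbp) are reconstructed per barcode from the
concordant fragments of their low-coverage reads: a left-to-right greedy
scan merges a fragment into the open submolecule when the gap to its
current right end is at most ``T``, or when the fragment starts within
``Q`` of the submolecule's leftmost anchor.  Defaults are
``T = mu_molecule / 4`` and ``Q = 2 * mu_molecule``; submolecules shorter
than 3 kbp are discarded.

Molecule depth (submolecules overlapping a genomic bin) is the
physical-coverage analogue of read depth and drives the copy-number
filters downstream.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Fragments, RegionMask

DEFAULT_MIN_SUBMOLECULE_LENGTH = 3_000


class MoleculeRecoveryError(ValueError):
    pass


@dataclass
class MoleculeStats:
    """Molecule size statistics and the derived scan parameters (bp)."""

    mu: float
    sigma: float
    T: float
    Q: float
    min_length: int = DEFAULT_MIN_SUBMOLECULE_LENGTH

    @classmethod
    def from_mu(cls, mu: float, sigma: float = 0.0,
                T: float | None = None, Q: float | None = None,
                min_length: int = DEFAULT_MIN_SUBMOLECULE_LENGTH
                ) -> "MoleculeStats":
        return cls(mu=float(mu), sigma=float(sigma),
                   T=float(T) if T is not None else mu / 4.0,
                   Q=float(Q) if Q is not None else 2.0 * mu,
                   min_length=int(min_length))

    @property
    def span_bound(self) -> float:
        """Candidate-split span-sum bound mu + 3*sigma."""
        return self.mu + 3.0 * self.sigma


@dataclass
class Submolecules:
    """Recovered molecule footprints, columnar."""

    chroms: tuple[str, ...]
    barcodes: tuple[str, ...]
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    barcode: np.ndarray
    n_fragments: np.ndarray

    def __len__(self) -> int:
        return len(self.chrom)

    @property
    def lengths(self) -> np.ndarray:
        return self.end - self.start


def scan_group(starts, ends, T: float, Q: float) -> list[tuple[int, int, int]]:
    """Greedy scan of one sorted (barcode, chromosome) fragment group.

    Returns raw (start, end, n_fragments) submolecules, unfiltered.
    Raises if the starts are not sorted.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if len(starts) == 0:
        return []
    if np.any(np.diff(starts) < 0):
        raise MoleculeRecoveryError("fragment group is not sorted by start")
    out = []
    left = int(starts[0])
    right = int(ends[0])
    count = 1
    for s, e in zip(starts[1:].tolist(), ends[1:].tolist()):
        if (s - right <= T) or (s - left <= Q):
            right = max(right, e)
            count += 1
        else:
            out.append((left, right, count))
            left, right, count = s, e, 1
    out.append((left, right, count))
    return out


def recover_submolecules(fragments: Fragments, stats: MoleculeStats
                         ) -> Submolecules:
    """Reconstruct submolecules from concordant fragments (all barcodes).

    Fragments are grouped by (barcode, chromosome), scanned greedily, and
    submolecules shorter than ``stats.min_length`` are discarded.
    """
    n = len(fragments)
    if n == 0:
        z = np.zeros(0, dtype=np.int64)
        return Submolecules(fragments.chroms, fragments.barcodes,
                            z.astype(np.int32), z, z, z, z)
    order = np.lexsort((fragments.start, fragments.chrom, fragments.barcode))
    bc = fragments.barcode[order].tolist()
    ch = fragments.chrom[order].tolist()
    st = fragments.start[order].tolist()
    en = fragments.end[order].tolist()
    T, Q, min_len = stats.T, stats.Q, stats.min_length

    o_ch, o_st, o_en, o_bc, o_nf = [], [], [], [], []
    i = 0
    while i < n:
        b, c = bc[i], ch[i]
        left = st[i]
        right = en[i]
        count = 1
        j = i + 1
        while j < n and bc[j] == b and ch[j] == c:
            s = st[j]
            if (s - right <= T) or (s - left <= Q):
                if en[j] > right:
                    right = en[j]
                count += 1
            else:
                if right - left >= min_len:
                    o_ch.append(c); o_st.append(left); o_en.append(right)
                    o_bc.append(b); o_nf.append(count)
                left, right, count = s, en[j], 1
            j += 1
        if right - left >= min_len:
            o_ch.append(c); o_st.append(left); o_en.append(right)
            o_bc.append(b); o_nf.append(count)
        i = j
    return Submolecules(fragments.chroms, fragments.barcodes,
                        np.asarray(o_ch, dtype=np.int32),
                        np.asarray(o_st, dtype=np.int64),
                        np.asarray(o_en, dtype=np.int64),
                        np.asarray(o_bc, dtype=np.int64),
                        np.asarray(o_nf, dtype=np.int64))


def estimate_molecule_stats(submolecules: Submolecules,
                            T: float | None = None, Q: float | None = None,
                            min_length: int = DEFAULT_MIN_SUBMOLECULE_LENGTH
                            ) -> MoleculeStats:
    """mu/sigma (population sd) of submolecule lengths; T, Q recomputed
    from the estimated mu unless overridden."""
    if len(submolecules) < 2:
        raise MoleculeRecoveryError(
            "need at least 2 submolecules to estimate molecule statistics")
    lengths = submolecules.lengths
    mu = float(lengths.mean())
    sigma = float(lengths.std())
    return MoleculeStats.from_mu(mu, sigma, T=T, Q=Q, min_length=min_length)


def recover_molecule_iteration(fragments: Fragments, initial_mu: float = 45_000,
                               T: float | None = None, Q: float | None = None,
                               min_length: int = DEFAULT_MIN_SUBMOLECULE_LENGTH
                               ) -> tuple[Submolecules, MoleculeStats]:
    """Two-pass recovery bootstrapping mu_molecule from ``initial_mu``.

    Pass 1 scans with parameters derived from ``initial_mu``; mu/sigma are
    re-estimated from its output and a second scan runs with the updated
    T and Q.  Returns the second-pass submolecules and statistics.
    """
    if initial_mu <= 0:
        raise MoleculeRecoveryError("initial_mu must be positive")
    stats0 = MoleculeStats.from_mu(initial_mu, 0.0, T=T, Q=Q,
                                   min_length=min_length)
    subs0 = recover_submolecules(fragments, stats0)
    stats1 = estimate_molecule_stats(subs0, T=T, Q=Q, min_length=min_length)
    subs1 = recover_submolecules(fragments, stats1)
    stats2 = estimate_molecule_stats(subs1, T=T, Q=Q, min_length=min_length)
    return subs1, stats2


# ---------------------------------------------------------------------------
# Molecule depth
# ---------------------------------------------------------------------------

@dataclass
class DepthProfile:
    """Binned molecule-depth vectors with genome-wide moments.

    ``counts[chrom][b]`` is the number of submolecules overlapping bin
    ``b``; ``mu_depth`` / ``sigma_depth`` are computed over unmasked bins
    only.
    """

    bin_size: int
    counts: dict[str, np.ndarray]
    unmasked: dict[str, np.ndarray]
    mu_depth: float = 0.0
    sigma_depth: float = 0.0

    def interval_mean(self, chrom: str, start: int, end: int) -> float | None:
        """Length-weighted mean depth over [start, end); None if off-profile."""
        if chrom not in self.counts or end <= start:
            return None
        vec = self.counts[chrom]
        bs = self.bin_size
        start = max(0, int(start))
        end = min(len(vec) * bs, int(end))
        if end <= start:
            return None
        b0 = start // bs
        b1 = (end - 1) // bs
        total = 0.0
        weight = 0.0
        for b in range(b0, b1 + 1):
            lo = max(start, b * bs)
            hi = min(end, (b + 1) * bs)
            total += vec[b] * (hi - lo)
            weight += hi - lo
        return total / weight if weight else None


def compute_depth_profile(submolecules: Submolecules,
                          mask: RegionMask | None,
                          chrom_lengths: dict[str, int],
                          bin_size: int = 10_000,
                          robust: bool = True) -> DepthProfile:
    """Count submolecules overlapping each bin.

    ``mu_depth`` / ``sigma_depth`` summarize the genome-wide background
    depth over unmasked bins.  With ``robust=True`` (default) they are
    the median and the MAD-derived sigma, so that bins inside real
    copy-number events do not drag the background estimate; ``False``
    gives the plain mean/sd.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    counts: dict[str, np.ndarray] = {}
    unmasked: dict[str, np.ndarray] = {}
    name_to_code = {name: i for i, name in enumerate(submolecules.chroms)}
    for chrom, length in chrom_lengths.items():
        n_bins = max(1, -(-int(length) // bin_size))
        diff = np.zeros(n_bins + 1, dtype=np.int64)
        code = name_to_code.get(chrom)
        if code is not None:
            sel = submolecules.chrom == code
            if sel.any():
                b0 = submolecules.start[sel] // bin_size
                b1 = (submolecules.end[sel] - 1) // bin_size
                b0 = np.clip(b0, 0, n_bins - 1)
                b1 = np.clip(b1, 0, n_bins - 1)
                np.add.at(diff, b0, 1)
                np.add.at(diff, b1 + 1, -1)
        counts[chrom] = np.cumsum(diff[:-1])
        if mask is not None and mask.intervals:
            unmasked[chrom] = ~mask.masked_bins(chrom, n_bins, bin_size)
        else:
            unmasked[chrom] = np.ones(n_bins, dtype=bool)
    pooled = np.concatenate([counts[c][unmasked[c]] for c in counts]) \
        if counts else np.zeros(0)
    if not len(pooled):
        mu = sd = 0.0
    elif robust:
        mu = float(np.median(pooled))
        sd = 1.4826 * float(np.median(np.abs(pooled - mu)))
    else:
        mu = float(pooled.mean())
        sd = float(pooled.std())
    return DepthProfile(bin_size, counts, unmasked, mu, sd)
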