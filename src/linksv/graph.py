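"""SV graph construction and quasi-clique clustering.

Each read-pair-supported split molecule pair is a vertex; an edge joins
two vertices of the same SV type whose corresponding breakpoint intervals
all overlap ("agreement").  Connected components are decomposed into
gamma-quasi-cliques (vertex sets with at least ``gamma * C(n, 2)`` induced
edges, gamma = 0.6 by default) by deterministic greedy peeling; each
reported quasi-clique defines one putative SV call.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .splits import SplitMoleculePair


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def pairs_agree(u: SplitMoleculePair, v: SplitMoleculePair) -> bool:
    """Same type and every corresponding breakpoint interval overlaps."""
    if u.sv_type != v.sv_type or u.chrom1 != v.chrom1 or u.chrom2 != v.chrom2:
        return False
    if not (_overlap(u.bp1, v.bp1) and _overlap(u.bp2, v.bp2)):
        return False
    if u.bp3 is not None:
        return _overlap(u.bp3, v.bp3)
    return True


def build_sv_graph(pairs: list[SplitMoleculePair]) -> nx.Graph:
    """Simple graph over pair indices; edge iff :func:`pairs_agree`.

    Vertices are indices into ``pairs`` (assumed sorted by locus for
    deterministic downstream processing); node attribute ``pair`` holds
    the object.
    """
    G = nx.Graph()
    for i, p in enumerate(pairs):
        G.add_node(i, pair=p)
    # sweep within (type, chrom) groups ordered by bp1 start
    order = sorted(range(len(pairs)),
                   key=lambda i: (pairs[i].sv_type, pairs[i].chrom1,
                                  pairs[i].chrom2 or -1, pairs[i].bp1[0], i))
    for a in range(len(order)):
        i = order[a]
        u = pairs[i]
        max_end = u.bp1[1]
        for b in range(a + 1, len(order)):
            j = order[b]
            v = pairs[j]
            if (v.sv_type, v.chrom1, v.chrom2 or -1) != \
                    (u.sv_type, u.chrom1, u.chrom2 or -1):
                break
            if v.bp1[0] >= max_end:
                break
            if pairs_agree(u, v):
                G.add_edge(i, j)
    return G


@dataclass
class QuasiClique:
    members: tuple[int, ...]
    gamma_achieved: float
    sv_type: str


def _density_ok(n_edges: int, n_vertices: int, gamma: float) -> bool:
    possible = n_vertices * (n_vertices - 1) // 2
    return n_edges >= gamma * possible


def find_quasi_cliques(G: nx.Graph, gamma: float = 0.6,
                       min_vertices: int = 2) -> list[QuasiClique]:
    """Greedy peel-and-repeat quasi-clique extraction per component.

    Within a component, vertices of minimum in-set degree are removed
    (ties to the smallest vertex id, which encodes locus order) until the
    edge density reaches ``gamma``; peeled vertices that still fit are
    greedily added back.  The found set is reported, removed, and the
    search repeats while sets of ``min_vertices`` or more remain.  Every
    reported set satisfies the density bound by construction.
    """
    if not (0 < gamma <= 1):
        raise ValueError("gamma must be in (0, 1]")
    out: list[QuasiClique] = []
    for comp in sorted(nx.connected_components(G), key=lambda c: min(c)):
        remaining = set(comp)
        while len(remaining) >= min_vertices:
            S = set(remaining)
            deg = {v: sum(1 for w in G.adj[v] if w in S) for v in S}
            m = sum(deg.values()) // 2
            removed: list[int] = []
            while len(S) > 2 and not _density_ok(m, len(S), gamma):
                v = min(S, key=lambda x: (deg[x], x))
                S.remove(v)
                removed.append(v)
                m -= deg.pop(v)
                for w in G.adj[v]:
                    if w in S:
                        deg[w] -= 1
            if not _density_ok(m, len(S), gamma):
                break
            # add-back pass: peeled vertices that keep the density bound
            for v in sorted(removed):
                gain = sum(1 for w in G.adj[v] if w in S)
                if _density_ok(m + gain, len(S) + 1, gamma):
                    S.add(v)
                    m += gain
            if len(S) < min_vertices:
                break
            possible = len(S) * (len(S) - 1) // 2
            sv_type = G.nodes[min(S)]["pair"].sv_type
            out.append(QuasiClique(tuple(sorted(S)),
                                   m / possible if possible else 1.0,
                                   sv_type))
            remaining -= S
    return out


@dataclass
class SVCall:
    """A typed SV call with 2 (DEL/INV) or 3 (DUP/TRA) breakpoint intervals."""

    sv_type: str
    chrom1: str
    bp1: tuple[int, int]
    bp2: tuple[int, int]
    chrom2: str | None = None
    bp3: tuple[int, int] | None = None
    n_split_molecules: int = 0
    n_barcodes: int = 0
    rp_support: int = 0
    depth: float | None = None
    filter_status: str = "PASS"

    @property
    def body(self) -> tuple[int, int]:
        """Source/body interval between the midpoints of bp1 and bp2."""
        a = (self.bp1[0] + self.bp1[1]) // 2
        b = (self.bp2[0] + self.bp2[1]) // 2
        return (min(a, b), max(a, b))

    @property
    def insertion_point(self) -> int | None:
        if self.bp3 is None:
            return None
        return (self.bp3[0] + self.bp3[1]) // 2


def _consensus_interval(intervals: list[tuple[int, int]]) -> tuple[int, int]:
    """Intersection if non-empty, else the median-endpoint interval."""
    lo = max(iv[0] for iv in intervals)
    hi = min(iv[1] for iv in intervals)
    if lo < hi:
        return (lo, hi)
    lo = int(np.median([iv[0] for iv in intervals]))
    hi = int(np.median([iv[1] for iv in intervals]))
    if hi <= lo:
        hi = lo + 1
    return (lo, hi)


def clique_to_call(clique: QuasiClique, pairs: list[SplitMoleculePair],
                   chroms: tuple[str, ...],
                   min_support: int = 4) -> SVCall:
    """Collapse a quasi-clique into one SV call.

    Breakpoint intervals are the intersections of the members' intervals
    (median-bounded when empty); support is counted in distinct candidate
    splits and distinct barcodes.  Calls below ``min_support`` in either
    count are flagged ``min_support_fail``, as are two-junction calls
    (INV/DUP/TRA) where either junction is anchored by fewer than
    ``min_support // 2`` independent splits — a cluster built on a single
    coincidental anchor is not a call.
    """
    members = [pairs[i] for i in clique.members]
    bp1 = _consensus_interval([p.bp1 for p in members])
    bp2 = _consensus_interval([p.bp2 for p in members])
    has3 = members[0].bp3 is not None
    bp3 = _consensus_interval([p.bp3 for p in members]) if has3 else None
    split_keys = set()
    bc = set()
    j_splits: tuple[set, set] = (set(), set())
    for p in members:
        for side, v in enumerate((p.a, p.b)):
            key = (v.barcode, v.cl, v.ls, v.le, v.cr, v.rs, v.re)
            split_keys.add(key)
            bc.add(v.barcode)
            if p.roled:
                j_splits[side].add(key)
    n_splits = len(split_keys)
    status = "PASS"
    if n_splits < min_support or len(bc) < min_support:
        status = "min_support_fail"
    elif members[0].roled:
        per_junction = max(1, min_support // 2)
        if len(j_splits[0]) < per_junction or len(j_splits[1]) < per_junction:
            status = "min_support_fail"
    chrom2 = chroms[members[0].chrom2] if has3 else None
    return SVCall(clique.sv_type, chroms[members[0].chrom1], bp1, bp2,
                  chrom2, bp3, n_splits, len(bc),
                  max(p.rp_support for p in members), None, status)
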