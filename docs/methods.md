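# Methods

This note documents the model behind `linksv`, the choices made where
the design was genuinely open, what the synthetic-data generator does
and does not emulate, and the numerical conventions used throughout.

## Signal model

A linked-read library partitions large DNA molecules (mean
μ<sub>molecule</sub> ≈ 50 kbp, long-tailed size distribution) into pools
of roughly 2–30 molecules sharing one barcode, each sequenced at ~0.1×.
A molecule spanning an SV breakpoint maps to the reference as two
disjoint intervals — a *split molecule*.  Because per-molecule coverage
is sparse, a recovered submolecule's terminal read lies up to a
fragment-gap short of the true junction; since any gap larger than the
merge distance *T* would have opened a new submolecule, a submolecule
**end** *e* brackets its junction in `[e, e + T)` and a **start** *s* in
`(s - T, s]`.  These anchor windows, widened by a small slack (150 bp;
junction-crossing reads are placed by their dominant side and can
overshoot by up to a read length), are the breakpoint confidence
intervals that propagate through pairing, clustering, and reporting.

Each SV type imposes a distinct arrangement of the four intervals of two
candidate splits, derived from the donor→reference geometry:

| type | junction 1 split | junction 2 split | read-pair orientation |
|------|------------------|------------------|----------------------|
| DEL  | ends at *p*, starts at *q* (single junction) | — | FR, long span |
| INV  | ends at *p* and *q* | starts at *p* and *q* | FF (left) and RR (right) |
| DUP direct | starts at *p*, ends at *i* | ends at *q*, starts at *i* | long-span FR/RF |
| DUP inverted | ends at *q* and *i* | starts at *p* and *i* | FF / RR |
| TRA  | starts at *p* (source chrom), ends at *i* (target) | ends at *q*, starts at *i* | inter-chromosomal |

with source segment `[p, q)` and insertion locus *i*.  Note that for
duplications and translocations the source-edge anchors are *outer*
endpoints of the split (the copy jumps backwards in coordinate space),
so breakpoint intervals legitimately lie outside the inter-submolecule
gap; for DEL/INV they lie inside it.

Two supported split pairs *agree* when their per-position breakpoint
intervals all overlap; agreement edges define the SV graph, and γ-quasi-
cliques (γ = 0.6) of that graph are the calls.

## Key parameters

| parameter | default | meaning |
|-----------|---------|---------|
| `T`, `Q` | μ/4, 2μ | fragment-merge gap and leftmost-anchor distance of the greedy scan |
| min submolecule | 3 kbp | shorter recovered intervals are noise |
| span-sum bound | μ + 3σ | two submolecules can be one molecule's halves |
| min read pairs | 3 | discordant pairs required per split molecule pair |
| γ | 0.6 | quasi-clique edge-density bound |
| min support | 4 (diploid), 2 (haploid) | distinct splits *and* barcodes per call |
| size windows | DEL/TRA > 100 kbp, INV > 80 kbp, DUP > 40 kbp; INV/DUP ≤ 7 Mbp; DUP displacement > 80 kbp | detection spectrum |
| depth rules | DUP ≥ μ_d + σ_d; DEL ≤ 0.5μ_d + 0.5σ_d; TRA within μ_d ± 1.5σ_d | copy-number consistency at the source |
| anchor window (TRA) | μ | submolecule attachment distance around a discordant anchor end |

Discard conditions of the depth rules are strict inequalities, so
boundary values are kept.  MAPQ floor (20), barcode tag (`BX`), and
concordance bounds (median ± 4·MAD-σ of proper-pair spans, estimated
from data) are conventions of the alignment layer, all configurable.

## Open design points, and what was decided

* **Merge-rule reference point.**  The gap condition is evaluated
  against the open submolecule's current right end; the *Q* condition
  against its leftmost fragment start.  This is the only reading
  consistent with a single left-to-right sliding window.
* **Junction-oriented support.**  A two-junction signature must be
  signaled at *both* junctions: at least one correctly oriented
  discordant pair per source-edge/insertion junction (DUP/TRA), and at
  least one FF *and* one RR pair for inversions, within the ≥ 3 total.
  Without this, clusters of genuine one-junction splits paired with a
  single coincidental partner survive and mimic other SV types.
* **Per-junction split support.**  For the same reason, a reported
  quasi-clique must contain at least `min_support / 2` distinct splits
  in each junction role; a cluster built on one shared anchor split is
  suppressed (`min_support_fail`).
* **Quasi-clique heuristic.**  Greedy peeling (remove the minimum
  in-set-degree vertex until the density bound holds, add back peeled
  vertices that still fit, report, remove, repeat).  Deterministic; on
  ≤ 12-vertex graphs it is within one vertex of the exhaustive optimum
  (asserted in the test suite).
* **Duplicate-call consolidation.**  Peel-and-repeat can emit several
  cliques for one event; PASS calls of the same type overlapping > 50 %
  reciprocally (insertion loci within μ/2 for three-breakpoint types)
  are consolidated keeping the best-supported call, the rest marked
  `duplicate`.
* **Translocations are inter-chromosomal.**  An intra-chromosomal move
  produces exactly the direct-duplication split signature and differs
  only in source depth; candidate generation for translocations is
  anchor-driven and inter-chromosomal.  Reciprocal translocations are
  not modeled; two co-located non-reciprocal calls would be reported
  separately.
* **Depth background estimation.**  μ_d/σ_d default to the median and
  MAD-derived σ over unmasked bins (10 kbp default).  On a real genome
  the mean over the entire genome is equivalent (SVs are a negligible
  fraction); on a desk-scale synthetic genome where planted events
  occupy ~20 % of the sequence, robust estimation recovers the intended
  background.  `robust=False` restores plain moments.
* **Two-pass μ bootstrap.**  μ_molecule is estimated from a first scan
  seeded with 45 kbp, then the scan is repeated once with updated
  *T*, *Q* — one refinement, not iteration to convergence, for bounded
  and deterministic runtime.

## The synthetic-data generator

`simulate_readpairs` builds, per haplotype, a piecewise-linear donor →
reference map from the planted SVs (deletion removes, inversion
reverses in place, duplication inserts a possibly inverted copy,
non-reciprocal translocation inserts a copy and deletes the source),
samples molecules uniformly on the donor (lognormal sizes, σ_log = 0.55,
mean 50 kbp; pools uniform on 2–30 molecules; ~50× physical coverage
relative to the reference), places read pairs along each molecule at
0.1× (insert 450 ± 45 bp, 100 bp reads), and maps every read through the
donor map — split mappings and discordant orientations at breakpoints
arise from the geometry, not from injected labels.  Zygosity defaults to
an even het/hom mix per event.  Noise: 1 % of pairs have one mate
relocated uniformly at random (mismapping surrogate), and mapped
positions get 2 bp Gaussian jitter.  Everything is a deterministic
function of one seed.

What it does **not** emulate: actual sequence and mapper behavior
(mapping ambiguity in repeats, clipped/split *reads*, barcode errors and
collisions, GC and mappability waves in coverage, chimeric molecules).
Consequently, passing the simulation study shows that the algorithmic
chain — recovery, pairing, clustering, depth filtering — is correct and
well-calibrated under the stated statistical structure of linked-read
data; it does not bound false-positive rates driven by real-genome
repeat structure, which the mask, MAPQ floor, support thresholds and
depth rules exist to control.

## Numerical conventions and degenerate inputs

Coordinates are 0-based, half-open everywhere internally; conversion to
1-based happens only at VCF emission.  Breakpoint consensus across a
clique is the interval intersection, or the median-endpoint interval
when empty.  Ties in peeling and all orderings are broken by locus then
id, making every pipeline output byte-reproducible.  Empty alignment
input yields an empty call set with a zeroed report; fewer than two
submolecules, unsorted input, and absent barcode tags are fatal errors.
Read-pair support for a reported call is recomputed over the consensus
windows rather than summed over members, which would double-count shared
pairs.

## Problem sizes

The bundled study (tests and `scripts/acceptance.py`) uses 30 Mbp
single-chromosome genomes with 20 planted events per replicate (DEL,
INV, DUP) and a 2 × 20 Mbp genome with 10 inter-chromosomal
translocations, 10 replicates per class, event sizes log-uniform within
each class's detection window up to 1 Mbp.  These sizes keep a replicate
in seconds on one CPU while pooling 100–200 events per class, enough for
stable precision/recall estimates.

## Known limitations

* Events near the lower size windows (80–120 kbp) lose split-molecule
  support when an outer arm is short enough for the *Q* rule to bridge
  the junction; inversion recall in particular degrades toward 80 kbp.
* Heterozygous translocations are detected through discordant-pair
  anchors; with ~0.1× per-molecule coverage the expected number of
  anchored junction-crossing molecules is ~4–5 per junction, so recall
  is anchor-limited rather than threshold-limited.
* Insertion loci are reported to the anchor-window scale (roughly
  *T*/2 ≈ 6 kbp at μ = 50 kbp); no base-pair-resolution breakpoint
  refinement (e.g., local assembly) is attempted.
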