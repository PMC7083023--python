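"""Scaled-down simulation study.

One replicate = simulate a synthetic genome with planted SVs of one
class under the standard linked-read conditions (50 kbp mean molecules,
pools of 2–30, ~50x physical coverage, ~0.1x per-molecule coverage, 1%
relocated noise pairs), run the full caller, and score the PASS calls
against the truth set.  Results are pooled over replicates.

Problem sizes (30 Mbp genomes, 10–20 events per replicate) keep one
replicate in seconds while leaving event counts large enough for stable
pooled rates.
"""
from __future__ import annotations

from dataclasses import dataclass

from .config import CallerConfig
from .evaluate import ClassReport, match_calls
from .pipeline import call_from_pairs
from .simulate import SimConfig, simulate_readpairs

STUDY_SETUPS: dict[str, dict] = {
    "DUP": dict(chrom_lengths={"chr1": 30_000_000},
                sv_counts={"DUP_DIRECT": 10, "DUP_INVERTED": 10}),
    "INV": dict(chrom_lengths={"chr1": 30_000_000},
                sv_counts={"INV": 20}),
    "DEL": dict(chrom_lengths={"chr1": 30_000_000},
                sv_counts={"DEL": 20}),
    "TRA": dict(chrom_lengths={"chr1": 20_000_000, "chr2": 20_000_000},
                sv_counts={"TRA": 10}),
}


def run_replicate(sv_class: str, seed: int,
                  config: CallerConfig | None = None) -> ClassReport:
    """Simulate one replicate of the class's setup, call, and score it."""
    setup = STUDY_SETUPS[sv_class]
    sim = SimConfig(seed=seed, **setup)
    result = simulate_readpairs(sim)
    out = call_from_pairs(result.pairs, result.chrom_lengths,
                          config or CallerConfig())
    mu = out.stats.mu if out.stats is not None else sim.molecule_size_mean
    report = match_calls(result.truths, out.calls, mu)
    return report.per_class.get(sv_class, ClassReport())


@dataclass
class StudyResult:
    sv_class: str
    n_sim: int
    n_pred: int
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None


def run_study(sv_class: str, seeds, config: CallerConfig | None = None
              ) -> StudyResult:
    """Pool TP/FP/FN over replicates seeded by ``seeds``."""
    tot = StudyResult(sv_class, 0, 0, 0, 0, 0)
    for seed in seeds:
        r = run_replicate(sv_class, int(seed), config)
        tot.n_sim += r.n_sim
        tot.n_pred += r.n_pred
        tot.tp += r.tp
        tot.fp += r.fp
        tot.fn += r.fn
    return tot
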