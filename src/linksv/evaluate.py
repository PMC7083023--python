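"""Call-set scoring against a truth set.

A prediction matches a truth record when the types are compatible, the
source/body intervals overlap reciprocally by strictly more than 50%, and
— for duplications and translocations — the predicted insertion locus
lies within ``mu_molecule / 2`` of the simulated one.  Matching is
one-to-one, greedy by descending overlap.  Direct and inverted
duplications are scored as one DUP class by default.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .graph import SVCall
from .simulate import TruthRecord

DEFAULT_SIZE_FILTERS = {"DEL": 100_000, "INV": 80_000, "DUP": 40_000,
                        "TRA": 100_000}


def _eval_class(sv_type: str, combine_dup: bool) -> str:
    if combine_dup and sv_type.startswith("DUP"):
        return "DUP"
    return sv_type


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(overlap/|a|, overlap/|b|); 0 for empty intervals."""
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0 or a[1] <= a[0] or b[1] <= b[0]:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


@dataclass
class ClassReport:
    n_sim: int = 0
    n_pred: int = 0
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or (p + r) == 0:
            return None
        return 2 * p * r / (p + r)


@dataclass
class EvalReport:
    per_class: dict[str, ClassReport] = field(default_factory=dict)
    matches: list[tuple[int, int]] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for cls, r in sorted(self.per_class.items()):
            rows.append({"sv_type": cls, "n_sim": r.n_sim, "n_pred": r.n_pred,
                         "TP": r.tp, "FP": r.fp, "FN": r.fn,
                         "precision": r.precision, "recall": r.recall,
                         "F1": r.f1})
        return pd.DataFrame(rows)


def match_calls(truths: list[TruthRecord], calls: list[SVCall],
                mu_molecule: float, min_overlap: float = 0.5,
                size_filters: dict[str, int] | None = None,
                combine_dup: bool = True,
                pass_only: bool = True) -> EvalReport:
    """Score calls against truth with the reciprocal-overlap protocol."""
    filters = size_filters if size_filters is not None else DEFAULT_SIZE_FILTERS
    ins_tol = mu_molecule / 2.0

    t_keep = [(i, t) for i, t in enumerate(truths)
              if t.size > filters.get(_eval_class(t.sv_type, combine_dup), 0)]
    c_keep = [(j, c) for j, c in enumerate(calls)
              if (not pass_only or c.filter_status == "PASS")
              and (c.body[1] - c.body[0]) >
              filters.get(_eval_class(c.sv_type, combine_dup), 0)]

    report = EvalReport()
    classes = sorted({_eval_class(t.sv_type, combine_dup) for _, t in t_keep} |
                     {_eval_class(c.sv_type, combine_dup) for _, c in c_keep})
    for cls in classes:
        ts = [(i, t) for i, t in t_keep
              if _eval_class(t.sv_type, combine_dup) == cls]
        cs = [(j, c) for j, c in c_keep
              if _eval_class(c.sv_type, combine_dup) == cls]
        cands = []
        for i, t in ts:
            for j, c in cs:
                if c.chrom1 != t.chrom:
                    continue
                ro = reciprocal_overlap((t.start, t.end), c.body)
                if ro <= min_overlap:
                    continue
                if t.ins_pos is not None or c.bp3 is not None:
                    if t.ins_pos is None or c.bp3 is None:
                        continue
                    if c.chrom2 != t.ins_chrom:
                        continue
                    if abs(c.insertion_point - t.ins_pos) > ins_tol:
                        continue
                cands.append((-ro, i, j))
        cands.sort()
        used_t: set[int] = set()
        used_c: set[int] = set()
        tp = 0
        for _, i, j in cands:
            if i in used_t or j in used_c:
                continue
            used_t.add(i)
            used_c.add(j)
            report.matches.append((i, j))
            tp += 1
        report.per_class[cls] = ClassReport(
            n_sim=len(ts), n_pred=len(cs), tp=tp,
            fp=len(cs) - tp, fn=len(ts) - tp)
    return report


# ---------------------------------------------------------------------------
# Call-set merging (union / intersection of two callers' output)
# ---------------------------------------------------------------------------

def _merge_pairs(set_a: list[SVCall], set_b: list[SVCall],
                 min_overlap: float = 0.5) -> list[tuple[int, int, float]]:
    cands = []
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            if a.sv_type != b.sv_type or a.chrom1 != b.chrom1:
                continue
            ro = reciprocal_overlap(a.body, b.body)
            if ro > min_overlap:
                cands.append((-ro, i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for nro, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j, -nro))
    return out


def merge_call_sets(set_a: list[SVCall], set_b: list[SVCall],
                    mode: str = "union",
                    min_overlap: float = 0.5) -> list[SVCall]:
    """Merge two call sets at > 50% reciprocal overlap.

    ``union``: matching calls collapse to one spanning call, unmatched
    calls pass through.  ``intersection``: only matching pairs survive,
    as the interval intersection.
    """
    if mode not in ("union", "intersection"):
        raise ValueError("mode must be 'union' or 'intersection'")
    matched = _merge_pairs(set_a, set_b, min_overlap)
    out: list[SVCall] = []
    in_a = {i for i, _, _ in matched}
    in_b = {j for _, j, _ in matched}
    for i, j, _ in matched:
        a, b = set_a[i], set_b[j]
        if mode == "union":
            body = (min(a.body[0], b.body[0]), max(a.body[1], b.body[1]))
        else:
            body = (max(a.body[0], b.body[0]), min(a.body[1], b.body[1]))
        out.append(SVCall(a.sv_type, a.chrom1,
                          (body[0], body[0] + 1), (body[1], body[1] + 1),
                          a.chrom2, a.bp3,
                          a.n_split_molecules + b.n_split_molecules,
                          max(a.n_barcodes, b.n_barcodes),
                          a.rp_support + b.rp_support, a.depth, "PASS"))
    if mode == "union":
        out.extend(a for i, a in enumerate(set_a) if i not in in_a)
        out.extend(b for j, b in enumerate(set_b) if j not in in_b)
    out.sort(key=lambda c: (c.chrom1, c.body[0], c.sv_type))
    return out
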