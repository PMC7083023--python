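"""Molecule-depth filtering of SV calls.

Copy-number-changing calls must agree with the molecule-depth profile:
duplications are kept only when the source segment's mean molecule depth
is at least ``mu_depth + sigma_depth``; deletions only when depth is at
most ``0.5 mu_depth + 0.5 sigma_depth``; translocations (balanced moves)
only when source depth lies inside ``mu_depth +/- 1.5 sigma_depth``.
Discard conditions are strict inequalities, so boundary values are kept.
Inversions are copy-neutral in place and pass unconditionally.
"""
from __future__ import annotations

from dataclasses import dataclass

from .graph import SVCall
from .molecules import DepthProfile


@dataclass
class DepthThresholds:
    """Multipliers for the three depth rules (defaults as published)."""

    dup_sigma: float = 1.0      # keep DUP iff depth >= mu + dup_sigma * sd
    del_mu_coeff: float = 0.5   # keep DEL iff depth <= del_mu*mu + del_sd*sd
    del_sd_coeff: float = 0.5
    tra_band_sigma: float = 1.5  # keep TRA iff |depth - mu| <= band * sd


def filter_by_molecule_depth(calls: list[SVCall], profile: DepthProfile,
                             thresholds: DepthThresholds | None = None
                             ) -> list[SVCall]:
    """Annotate calls with source-interval depth and set filter_status.

    Calls already failing an earlier filter are left untouched.  The
    source interval for DUP/TRA (and the deleted interval for DEL) is the
    segment between the bp1 and bp2 midpoints on chrom1.  Failing calls
    are retained with ``filter_status='depth_fail'`` (or ``'no_depth'``
    when the interval lies outside the profile) but excluded from PASS
    output downstream.
    """
    th = thresholds or DepthThresholds()
    mu, sd = profile.mu_depth, profile.sigma_depth
    dup_min = mu + th.dup_sigma * sd
    del_max = th.del_mu_coeff * mu + th.del_sd_coeff * sd
    tra_lo = mu - th.tra_band_sigma * sd
    tra_hi = mu + th.tra_band_sigma * sd
    for call in calls:
        if call.filter_status != "PASS":
            continue
        if call.sv_type == "INV":
            body = call.body
            call.depth = profile.interval_mean(call.chrom1, body[0], body[1])
            continue
        body = call.body
        depth = profile.interval_mean(call.chrom1, body[0], body[1])
        call.depth = depth
        if depth is None:
            call.filter_status = "no_depth"
            continue
        if call.sv_type in ("DUP_DIRECT", "DUP_INVERTED"):
            if depth < dup_min:
                call.filter_status = "depth_fail"
        elif call.sv_type == "DEL":
            if depth > del_max:
                call.filter_status = "depth_fail"
        elif call.sv_type == "TRA":
            if not (tra_lo <= depth <= tra_hi):
                call.filter_status = "depth_fail"
    return calls
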