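"""Caller configuration: every tunable with its published default."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml


@dataclass
class CallerConfig:
    # alignment input
    barcode_tag: str = "BX"
    min_mapq: int = 20
    concordance_min: int | None = None   # estimated from data when None
    concordance_max: int | None = None
    insert_nsd: float = 4.0
    insert_sample: int = 1_000_000
    # molecule recovery
    initial_mu: float = 45_000.0
    t_override: float | None = None      # default mu / 4
    q_override: float | None = None      # default 2 * mu
    min_submolecule_length: int = 3_000
    min_length_mode: str = "fixed"       # or "fraction" (10% of mu)
    depth_bin_size: int = 10_000
    # split matching
    max_splits_per_barcode: int = 128
    min_rp_support: int = 3
    min_del_size: int = 100_000
    min_inv_size: int = 80_000
    min_dup_size: int = 40_000
    min_tra_size: int = 100_000
    max_event_size: int = 7_000_000
    dup_min_distance: int = 80_000
    tra_anchor_window: float | None = None  # default mu_molecule
    # clustering
    gamma: float = 0.6
    min_support: int | None = None       # default 4 diploid, 2 haploid
    # depth filtering
    dup_depth_sigma: float = 1.0
    del_depth_mu_coeff: float = 0.5
    del_depth_sd_coeff: float = 0.5
    tra_depth_band_sigma: float = 1.5
    # mode
    ploidy_mode: str = "diploid"         # or "haploid"
    seed: int = 0

    def __post_init__(self):
        if self.ploidy_mode not in ("diploid", "haploid"):
            raise ValueError(f"unknown ploidy_mode: {self.ploidy_mode}")
        if self.min_length_mode not in ("fixed", "fraction"):
            raise ValueError(f"unknown min_length_mode: {self.min_length_mode}")

    @property
    def resolved_min_support(self) -> int:
        if self.min_support is not None:
            return self.min_support
        return 2 if self.ploidy_mode == "haploid" else 4

    def resolved_min_length(self, mu: float) -> int:
        if self.min_length_mode == "fraction":
            return int(0.1 * mu)
        return self.min_submolecule_length

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CallerConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
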