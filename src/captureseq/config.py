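"""Run configuration: every rule threshold in one place, YAML round-trip.

Defaults are the constants the design and evaluation rules were built
around: genome-wide significance p < 5e-8, 50 nt coding-proximity trim,
50 kb lncRNA window, the 100/150/200 nt partial-probing slices, the
500/100/50 nt intronic-control margins, the 0.5%/5% highly-expressed
cut-offs, CPM pseudocount 1 and a 1-read detection rule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # NG design
    gwas_p_threshold: float = 5e-8
    lncrna_window_nt: int = 50_000
    coding_trim_margin_nt: int = 50
    ng_repeat_margin_nt: int = 50
    ng_intronic_control_len_nt: int = 500

    # TF design
    tf_neuronal_share_thresh: float = 0.005
    tf_encode_share_thresh: float = 0.05
    cds_tail_nt: int = 200
    penultimate_exon_nt: int = 100
    final_exon_nt: int = 150
    tf_probe_repeat_margin_nt: int = 120
    tf_nontarget_margin_nt: int = 150
    intronic_ann_margin_nt: int = 500
    intronic_repeat_margin_nt: int = 100
    intronic_est_margin_nt: int = 50
    intronic_min_piece_nt: int = 200
    intronic_control_len_nt: int = 200
    spikein_min_len_nt: int = 30
    spikein_pad_to_nt: int = 50

    # evaluation
    pseudocount: float = 1.0
    min_reads_detected: int = 1
    min_replicates_detected: int = 1

    # run
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.endswith("_nt") and v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")
        if not 0 < self.gwas_p_threshold <= 1:
            raise ValueError("gwas_p_threshold must be in (0,1]")
        if self.intronic_control_len_nt > self.intronic_min_piece_nt:
            raise ValueError("intronic control length exceeds minimum piece size")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data).validate()
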