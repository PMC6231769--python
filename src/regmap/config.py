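"""Pipeline configuration: every threshold with its default, YAML round-trip,
and a stable hash recorded in output headers."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    # peak calling
    bandwidth: float = 50.0
    min_region: int = 20
    idr_cutoff: float = 0.001
    boundary_flank: int = 75
    # elongation / initiation evidence
    jump_window_up: tuple[int, int] = (-250, -75)
    jump_window_down: tuple[int, int] = (75, 250)
    jump_lfc: float = 1.5
    jump_padj: float = 0.1
    incr_min_total: int = 3
    initiation_window: int = 125
    best_guess_offset: int = 60
    # classification
    exon_distance: int = 250
    rescue_lfc: float = 1.0
    # dynamics
    regulated_fold: float = 2.0
    regulated_padj: float = 0.01
    k_dev: int = 16
    k_age: int = 10
    merge_map_dev: dict = field(default_factory=dict)
    merge_map_age: dict = field(default_factory=dict)
    # enrichment
    tissue_fold: float = 3.0
    tissue_padj: float = 0.01
    tpm_pseudo: float = 0.1
    hot_threshold: int = 19
    tf_min_peaks: int = 200
    tf_p: float = 0.01
    tf_min_or: float = 2.0
    tf_window: int = 400
    # synthetic-source parameters
    seed: int = 0
    n_genes: int = 200
    chrom_length: int = 2_000_000
    class_counts: dict = field(
        default_factory=lambda: {
            "coding_promoter": 150,
            "enhancer": 100,
            "inactive": 50,
        }
    )
    depth: float = 50.0
    dispersion: float = 0.05
    n_tfs: int = 25
    n_tissues: int = 5
    synthetic_k: int = 4
    synthetic_tf_min_peaks: int = 20

    def validate(self) -> None:
        positive = {
            "bandwidth": self.bandwidth,
            "idr_cutoff": self.idr_cutoff,
            "boundary_flank": self.boundary_flank,
            "jump_lfc": self.jump_lfc,
            "jump_padj": self.jump_padj,
            "incr_min_total": self.incr_min_total,
            "initiation_window": self.initiation_window,
            "best_guess_offset": self.best_guess_offset,
            "exon_distance": self.exon_distance,
            "rescue_lfc": self.rescue_lfc,
            "regulated_fold": self.regulated_fold,
            "regulated_padj": self.regulated_padj,
            "k_dev": self.k_dev,
            "k_age": self.k_age,
            "tissue_fold": self.tissue_fold,
            "tissue_padj": self.tissue_padj,
            "tpm_pseudo": self.tpm_pseudo,
            "hot_threshold": self.hot_threshold,
            "tf_min_peaks": self.tf_min_peaks,
            "tf_p": self.tf_p,
            "tf_min_or": self.tf_min_or,
            "tf_window": self.tf_window,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"config threshold {name} must be positive")
        if not self.idr_cutoff < 1:
            raise ValueError("idr_cutoff must be in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["jump_window_up"] = list(self.jump_window_up)
        d["jump_window_down"] = list(self.jump_window_down)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("jump_window_up", "jump_window_down"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
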