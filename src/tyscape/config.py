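"""Declarative pipeline configuration with full provenance capture."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .align import AlignmentParams
from .synthetic import CategoryCounts, PlantSpec


@dataclass
class PipelineConfig:
    """Everything a run needs; serialized verbatim into the run MANIFEST."""

    outdir: str = "tyscape_run"
    seed: int = 0
    log_level: str = "INFO"
    threads: int = 1  # wall-time only; never affects output bytes
    flank_len: int = 2500
    segment_len: int = 300
    locus_window: int = 40
    polIII_window: int = 1000
    map_margin: int = 30
    subfamily_threshold: float = 0.95
    spectrum_mode: str = "insertions"  # or "loci"
    reference_strain: str | None = None  # for shared-with-reference flags
    alignment: dict = field(default_factory=dict)  # AlignmentParams overrides
    simulate: dict | None = None  # PlantSpec overrides; None = use inputs
    inputs: dict | None = None  # assemblies, panel, reference, annotation

    def __post_init__(self) -> None:
        if self.simulate is None and self.inputs is None:
            self.simulate = {}
        if self.spectrum_mode not in ("insertions", "loci"):
            raise ValueError("spectrum_mode must be 'insertions' or 'loci'")

    @property
    def alignment_params(self) -> AlignmentParams:
        return AlignmentParams(**self.alignment)

    @property
    def plant_spec(self) -> PlantSpec:
        if self.simulate is None:
            raise ValueError("no simulate section in config")
        kw = dict(self.simulate)
        if "counts" in kw:
            kw["counts"] = {
                fam: CategoryCounts(**cc) for fam, cc in kw["counts"].items()
            }
        if "trna_window" in kw:
            kw["trna_window"] = tuple(kw["trna_window"])
        kw.setdefault("seed", self.seed)
        return PlantSpec(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return asdict(self)

    def run_dir(self) -> Path:
        return Path(self.outdir)
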