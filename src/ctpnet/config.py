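"""Pipeline configuration: every numeric constant of the method with its
default, serialisable to/from JSON or YAML for provenance."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

STAGES = ("simulate", "preprocess", "ctpa", "netbuild", "metrics", "infer",
          "report")


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline.

    Defaults are the method's reference values: 5-TR sampling stride,
    Z > 2 voxel threshold, 2.5% count bound, 30% overlap rule,
    1.5 mm / 1.5 deg motion exclusion, 0.01-0.08 Hz band-pass, 4 mm FWHM
    smoothing, 128 s task high-pass, 3-voxel cube edge, sparsity grid
    0.05-0.25 in steps of 0.05, 100 null networks, 10,000 permutations,
    p < 0.01 predictor screen, FDR q = 0.05 with a > 50 voxel extent rule.
    """

    # sampling / CTPA
    stride: int = 5
    z_threshold: float = 2.0
    frac_threshold: float = 0.025
    overlap_threshold: float = 0.30
    zscore_mode: str = "temporal"
    # preprocessing
    n_discard_rest: int = 10
    n_discard_task: int = 5
    motion_threshold_mm: float = 1.5
    motion_threshold_deg: float = 1.5
    bandpass_low_hz: float = 0.01
    bandpass_high_hz: float = 0.08
    smooth_fwhm_mm: float = 4.0
    task_highpass_s: float = 128.0
    filter_before_regression: bool = True
    spatial_steps_done_upstream: bool = True
    # group map
    fdr_q: float = 0.05
    cluster_min_voxels: int = 50
    cluster_connectivity: int = 26
    # networks
    cube_edge: int = 3
    # metrics
    sparsity_min: float = 0.05
    sparsity_max: float = 0.25
    sparsity_step: float = 0.05
    n_null: int = 100
    null_swap_factor: int = 10
    # inference
    n_perm: int = 10000
    alpha: float = 0.05
    screen_alpha: float = 0.01
    permutation_method: str = "signflip"
    # cohort / run
    n_subjects: int = 16
    master_seed: int = 0
    out_dir: str = "ctpnet_run"
    stages: tuple = STAGES
    write_volumes: bool = False
    scene: dict = field(default_factory=dict)  # SyntheticSceneConfig overrides

    def __post_init__(self) -> None:
        if self.sparsity_step <= 0 or not (0 < self.sparsity_min
                                           <= self.sparsity_max < 1):
            raise ValueError("invalid sparsity grid")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @property
    def sparsity_levels(self) -> list:
        n = int(round((self.sparsity_max - self.sparsity_min)
                      / self.sparsity_step)) + 1
        return [round(self.sparsity_min + k * self.sparsity_step, 10)
                for k in range(n)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        # JSON/YAML have no tuples; normalise so round-trips compare equal
        d["scene"] = json.loads(json.dumps(d["scene"]))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
            else json.loads(text)
        return cls.from_dict(d)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})
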