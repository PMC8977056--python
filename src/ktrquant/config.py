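"""Pipeline configuration: every tunable with its protocol default, YAML round-trip."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class ImagePrepConfig:
    subtract_c: float = 250.0          # counts removed from the nuclear-marker channel
    rolling_ball_radius: float = 70.0  # px, Akt reporter channel background
    mask_sigma: float = 2.0            # px, blur before cell-mask threshold
    mask_lo: float = 300.0             # counts, inclusive lower threshold
    mask_hi: float = 65535.0


@dataclass
class SegmentationConfig:
    nuclear_threshold: float = 330.0   # counts
    diameter_min: float = 8.0          # px
    diameter_max: float = 20.0
    expand_px: float = 5.0


@dataclass
class TrackingConfig:
    max_link_dist: float = 3.0         # px between consecutive centroids


@dataclass
class QCConfig:
    intensity_lo: float = 260.0
    intensity_hi: float = 4000.0
    area_min: float = 100.0            # px
    radius_min: float = 1.0            # mean-radius floor (exclusive)


@dataclass
class TimingConfig:
    frame_interval: float = 3.5        # minutes
    well_offset: float = 0.5           # minutes between consecutive wells
    stim_timepoint: int = 7            # 1-based
    baseline_timepoints: tuple[int, int] = (5, 6)
    auc_window: tuple[int, int] = (9, 18)


@dataclass
class ClusterGridConfig:
    erk_ks: tuple[int, ...] = (8, 9, 10)
    akt_ks: tuple[int, ...] = (3, 4, 5)
    kmeans_restarts: int = 25
    neighborhood: int = 25             # connectivity neighborhood size
    subsample: int = 15000             # max cells used for clustering
    seed: int = 0


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their protocol defaults."""

    imageprep: ImagePrepConfig = field(default_factory=ImagePrepConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    timing: TimingConfig = field(default_factory=TimingConfig)
    clustering: ClusterGridConfig = field(default_factory=ClusterGridConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)

        def tup2list(obj):
            if isinstance(obj, dict):
                return {k: tup2list(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        return tup2list(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, sub):
            kwargs = {}
            for f in dataclasses.fields(klass):
                if f.name not in sub:
                    continue
                v = sub[f.name]
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
            return klass(**kwargs)
        sections = {
            "imageprep": ImagePrepConfig, "segmentation": SegmentationConfig,
            "tracking": TrackingConfig, "qc": QCConfig, "timing": TimingConfig,
            "clustering": ClusterGridConfig,
        }
        kwargs = {name: build(klass, d.get(name, {}))
                  for name, klass in sections.items()}
        kwargs["seed"] = d.get("seed", 0)
        return cls(**kwargs)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
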