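"""Pipeline configuration with YAML round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from .core import RetoctError
from .features import CurvinessParams, FeatureConfig
from .segmentation import BoundaryParams, SegmentationConfig


@dataclass(frozen=True)
class CVConfig:
    k: int = 15
    repeats: int = 10
    algorithm: str = "rf"
    n_classes: int = 3
    seed: int = 0
    grids: Optional[Dict[str, List[Dict[str, float]]]] = None
    positive_class: Optional[str] = None


@dataclass(frozen=True)
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    voxel_dims: Optional[Tuple[float, float, float]] = None

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        seg_d = dict(d.get("segmentation", {}))
        bp = seg_d.pop("boundary_params", None)
        seg_kwargs = dict(seg_d)
        if bp is not None:
            seg_kwargs["boundary_params"] = {
                name: BoundaryParams(**{
                    **v,
                    "roi_upper": tuple(v["roi_upper"]) if v.get("roi_upper") else None,
                    "roi_lower": tuple(v["roi_lower"]) if v.get("roi_lower") else None,
                })
                for name, v in bp.items()
            }
        feat_d = dict(d.get("features", {}))
        curv = feat_d.pop("curviness", None)
        feat_kwargs = dict(feat_d)
        if curv is not None:
            feat_kwargs["curviness"] = CurvinessParams(**curv)
        cv_d = dict(d.get("cv", {}))
        vd = d.get("voxel_dims")
        return cls(
            segmentation=SegmentationConfig(**seg_kwargs),
            features=FeatureConfig(**feat_kwargs),
            cv=CVConfig(**cv_d),
            voxel_dims=tuple(vd) if vd else None,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise RetoctError(f"config file {path} is not a mapping")
        return cls.from_dict(d)
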