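"""YAML configuration: marker, camera and detector parameters in one file.

Layout::

    marker:   { cylinder_radius: 5.0, ... }       # MarkerSpec fields
    camera:   { fx: 1000.0, ..., image_size: [960, 540] }
    detector:
      dots:           { thresholds: [70, 80, 90, 100], ... }
      vertices:       { ring_radius: 5.0, ... }
      identification: { link_factor: 3.0, ... }
      flow:           { window: 21, ... }

Every section is optional; omitted fields take the package defaults,
which are the values used throughout the reference experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .camera import CameraIntrinsics
from .dots import DotFilterCriteria
from .geometry import MarkerSpec
from .identification import IdentifyConfig
from .tracking import FlowConfig
from .vertices import VertexDetectorConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    marker: MarkerSpec = field(default_factory=MarkerSpec)
    camera: CameraIntrinsics = field(default_factory=CameraIntrinsics)
    dots: DotFilterCriteria = field(default_factory=DotFilterCriteria)
    vertices: VertexDetectorConfig = field(default_factory=VertexDetectorConfig)
    identification: IdentifyConfig = field(default_factory=IdentifyConfig)
    flow: FlowConfig = field(default_factory=FlowConfig)

    def make_tracker(self, refine: bool = True, seed: int = 0):
        from .pipeline import MarkerTracker

        return MarkerTracker(self.marker, self.camera,
                             identify_config=self.identification,
                             dot_criteria=self.dots,
                             vertex_params=self.vertices,
                             flow_config=self.flow,
                             refine=refine, seed=seed)


def _tupled(d: dict, *keys) -> dict:
    out = dict(d)
    for k in keys:
        if k in out and out[k] is not None:
            out[k] = tuple(out[k])
    return out


def load_config(source) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file path or stream."""
    if hasattr(source, "read"):
        data = yaml.safe_load(source) or {}
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    if "marker" in data:
        cfg.marker = MarkerSpec(**_tupled(data["marker"],
                                          "pattern_row_y", "vertex_row_y"))
    if "camera" in data:
        cfg.camera = CameraIntrinsics(**_tupled(data["camera"],
                                                "distortion", "image_size"))
    det = data.get("detector", {})
    if "dots" in det:
        cfg.dots = DotFilterCriteria(**_tupled(det["dots"],
                                               "thresholds", "area_range"))
    if "vertices" in det:
        cfg.vertices = VertexDetectorConfig(**det["vertices"])
    if "identification" in det:
        cfg.identification = IdentifyConfig(**det["identification"])
    if "flow" in det:
        cfg.flow = FlowConfig(**det["flow"])
    return cfg
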