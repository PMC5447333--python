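"""Frame-by-frame tracking pipeline: detection, temporal fallback, pose.

:class:`MarkerTracker` is the top-level object.  Feed it frames in order;
each call runs the full detector + identifier, falls back to optical-flow
tracking when identification fails, estimates both planar pose
candidates from the best visible dot pattern, resolves the ambiguity
with the chessboard vertices (or the previous pose while occluded) and
refines the result over all identified features (which are jointly
non-planar, strengthening the estimate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .camera import CameraIntrinsics, Pose
from .dots import DotFilterCriteria, to_grayscale
from .geometry import MarkerSpec, ModelPointSet, build_model_points, pattern_template
from .identification import FrameDetection, IdentifyConfig, identify_frame
from .pose import (InsufficientConstraintError, estimate_pose_candidates,
                   reprojection_error, resolve_pose)
from .tracking import FlowConfig, TrackMode, TrackState, step
from .vertices import VertexDetectorConfig

__all__ = ["MarkerTracker", "FrameResult"]


@dataclass
class FrameResult:
    frame_index: int
    mode: TrackMode
    detection: FrameDetection | None
    pose: Pose | None = None
    mean_reprojection_error: float | None = None
    ambiguous: bool = False
    unresolved: bool = False
    diagnostics: dict = field(default_factory=dict)
    tracked_points: np.ndarray | None = None
    tracked_ids: np.ndarray | None = None

    @property
    def localized(self) -> bool:
        return self.mode is not TrackMode.LOST

    def to_record(self) -> dict:
        return {
            "frame": self.frame_index,
            "mode": self.mode.value,
            "pose": None if self.pose is None
            else self.pose.matrix().ravel().tolist(),
            "reprojection_error": self.mean_reprojection_error,
            "ambiguous": self.ambiguous,
            "unresolved": self.unresolved,
        }


class MarkerTracker:
    """Stateful tracker for one marker over one video sequence."""

    def __init__(self, spec: MarkerSpec, K: CameraIntrinsics,
                 identify_config: IdentifyConfig | None = None,
                 dot_criteria: DotFilterCriteria | None = None,
                 vertex_params: VertexDetectorConfig | None = None,
                 flow_config: FlowConfig | None = None,
                 refine: bool = True, seed: int = 0):
        self.spec = spec
        self.K = K
        self.model: ModelPointSet = build_model_points(spec)
        self.identify_config = identify_config or IdentifyConfig()
        self.dot_criteria = dot_criteria
        self.vertex_params = vertex_params
        self.flow_config = flow_config
        self.refine = refine
        self.seed = seed
        self.state = TrackState()
        self.prev_pose: Pose | None = None
        self._frame_index = 0

    # -- helpers -----------------------------------------------------------

    def _detection_tuple(self, fd: FrameDetection):
        best = fd.best_pattern()
        if best is None:
            return None
        ref = pattern_template(self.spec, best.pattern)[best.template_indices]
        return best.pattern, best.dot_ids, ref, best.image_points

    def _pose_from_detection(self, fd: FrameDetection):
        best = fd.best_pattern()
        mp = self.model.dot_xyz(best.dot_ids)
        ip = best.image_points
        cands = estimate_pose_candidates(self.K, mp, ip)
        vm = vi = None
        if fd.vertex_ids is not None and len(fd.vertex_ids) > 0:
            vm = self.model.vertex_xyz(fd.vertex_ids)
            vi = fd.vertex_points
        # refinement set: every identified dot of every pattern (with the
        # curved-boundary centroid measurement model) plus the vertices
        all_ids = np.concatenate([p.dot_ids for p in fd.patterns.values()])
        all_obs = np.vstack([p.image_points for p in fd.patterns.values()])
        boundaries = self.model.dot_boundary_xyz(all_ids)
        pose, diag = resolve_pose(cands, self.K, vm, vi,
                                  prior_pose=self.prev_pose,
                                  refine=self.refine,
                                  refine_model_points=vm,
                                  refine_image_points=vi,
                                  refine_dot_boundaries=boundaries,
                                  refine_dot_observations=all_obs)
        err = reprojection_error(pose, self.K,
                                 self.model.dot_xyz(all_ids), all_obs)
        return pose, err, diag

    def _pose_from_tracking(self, ids, points, mask):
        ids = np.asarray(ids)[mask]
        pts = np.asarray(points)[mask]
        if len(ids) < 4:
            return None, None, {}
        mp = self.model.dot_xyz(ids)
        cands = estimate_pose_candidates(self.K, mp, pts)
        pose, diag = resolve_pose(cands, self.K, prior_pose=self.prev_pose,
                                  refine=self.refine,
                                  refine_dot_boundaries=self.model.dot_boundary_xyz(ids),
                                  refine_dot_observations=pts)
        return pose, reprojection_error(pose, self.K, mp, pts), diag

    # -- main entry --------------------------------------------------------

    def process(self, frame: np.ndarray) -> FrameResult:
        gray = to_grayscale(frame)
        fd = identify_frame(gray, self.spec, self.model, self.identify_config,
                            self.dot_criteria, self.vertex_params)
        detection = self._detection_tuple(fd) if fd.status == "identified" else None
        st = step(self.state, gray, detection,
                  flow_cfg=self.flow_config, seed=self.seed)
        res = FrameResult(self._frame_index, st.mode, fd,
                          tracked_points=st.image_points,
                          tracked_ids=st.ids)
        try:
            if st.mode is TrackMode.DETECTED:
                pose, err, diag = self._pose_from_detection(fd)
            elif st.mode is TrackMode.FLOW_TRACKING:
                pose, err, diag = self._pose_from_tracking(
                    st.ids, st.image_points, st.tracked_mask)
            else:
                pose, err, diag = None, None, {}
        except InsufficientConstraintError:
            pose, err, diag = None, None, {}
        res.pose = pose
        res.mean_reprojection_error = err
        res.ambiguous = bool(diag.get("ambiguous", False))
        res.unresolved = bool(diag.get("unresolved", False))
        res.diagnostics = diag
        if pose is not None:
            self.prev_pose = pose
        self._frame_index += 1
        return res

    def reset(self) -> None:
        self.state = TrackState()
        self.prev_pose = None
        self._frame_index = 0
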