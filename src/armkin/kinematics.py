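"""Segment-frame construction and the 13 upper-limb joint-angle channels.

Workflow
--------
1. :func:`calibrate_landmarks` — from the static trial, learn where each
   anatomical landmark sits relative to its segment's technical (cluster)
   markers, and re-express all cluster markers in the segment's *anatomical*
   frame (built from the landmarks by the per-segment recipe).
2. :func:`compute_segment_frames` — for each dynamic frame, least-squares
   (Kabsch) fit of the calibrated cluster coordinates to the observed
   markers gives the anatomical pose of each segment directly.
3. :func:`compute_joint_angles` — decompose proximal-to-distal relative
   rotations with the per-joint Euler/Cardan sequences into the 13 reported
   channels (degrees, unwrapped).

Rotation sequences follow the ISB upper-limb recommendations: thorax vs lab
Z-X-Y, scapula vs thorax Y-X-Z, humerus vs thorax Y-X-Y (plane of elevation,
*negative* elevation, axial rotation), forearm vs humerus Z-X-Y (flexion,
carrying angle, pro/supination), hand vs forearm Z-X-Y. Left-impaired
subjects are mirrored about the sagittal plane before frame construction so
a single sign convention serves the cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from armkin.bodymodel import FRAME_RECIPES, SEGMENTS, frame_from_landmarks
from armkin.markers import (
    MarkerSetDefinition,
    MarkerTrajectorySet,
    MarkerValidationError,
)


class DegenerateFrameError(ValueError):
    """Cluster or landmark geometry too close to collinear to define a frame."""


@dataclass(frozen=True)
class JointConvention:
    """One joint: proximal/distal segments, Euler sequence and channel names.

    ``channels`` has one entry per sequence position; ``None`` marks an
    angle that is computed but not reported (e.g. the elbow carrying angle).
    ``signs`` multiply the raw decomposition, fixing clinical sign
    conventions.
    """

    name: str
    proximal: str | None
    distal: str
    sequence: str
    channels: tuple[str | None, str | None, str | None]
    signs: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: report the equivalent decomposition with a negative middle angle
    #: (the clinical shoulder convention: an elevated arm reads negative)
    negative_middle: bool = False


DEFAULT_CONVENTIONS: tuple[JointConvention, ...] = (
    JointConvention("trunk", None, "trunk", "ZXY",
                    ("trunk_flex_ext", "trunk_lat_bend", "trunk_rot"),
                    (-1.0, 1.0, 1.0)),
    JointConvention("scapula", "trunk", "scapula", "YXZ",
                    ("scap_pro_retr", "scap_med_lat", "scap_tilt")),
    JointConvention("shoulder", "trunk", "humerus", "YXY",
                    ("shoulder_plane", "shoulder_elev", "shoulder_rot"),
                    negative_middle=True),
    JointConvention("elbow", "humerus", "forearm", "ZXY",
                    ("elbow_flex_ext", None, "elbow_pro_sup")),
    JointConvention("wrist", "forearm", "hand", "ZXY",
                    ("wrist_flex_ext", "wrist_dev", None)),
)

#: The 13 reported joint-angle channels, distal to proximal.
CHANNELS: tuple[str, ...] = (
    "wrist_flex_ext",
    "wrist_dev",
    "elbow_flex_ext",
    "elbow_pro_sup",
    "shoulder_plane",
    "shoulder_elev",
    "shoulder_rot",
    "scap_pro_retr",
    "scap_med_lat",
    "scap_tilt",
    "trunk_flex_ext",
    "trunk_lat_bend",
    "trunk_rot",
)


@dataclass
class LandmarkModel:
    """Static-calibration result: local coordinates in anatomical frames.

    ``cluster_local[seg]`` and ``landmark_local[seg]`` map marker labels to
    time-invariant coordinates expressed in the segment's anatomical frame;
    ``residual`` is the rms landmark reconstruction error over the static
    trial (meters).
    """

    markerset: MarkerSetDefinition
    cluster_local: dict[str, dict[str, np.ndarray]]
    landmark_local: dict[str, dict[str, np.ndarray]]
    residual: float
    subject_id: str | None = None


@dataclass
class SegmentFrameSeries:
    """Per-frame anatomical pose of the five segments.

    ``rotations[seg]`` is ``(frames, 3, 3)`` with orthonormal rows where
    ``valid[seg]`` is True (NaN elsewhere); ``origins[seg]`` is
    ``(frames, 3)`` in meters.
    """

    rate: float
    origins: dict[str, np.ndarray]
    rotations: dict[str, np.ndarray]
    valid: dict[str, np.ndarray]

    @property
    def frames(self) -> int:
        return next(iter(self.origins.values())).shape[0]


@dataclass
class JointAngleSeries:
    """13 joint-angle channels in degrees over frames (NaN = invalid frame)."""

    rate: float
    values: np.ndarray  # (frames, 13)
    channels: tuple[str, ...] = CHANNELS
    gimbal: np.ndarray | None = None  # (frames,) any-joint gimbal proximity

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channels):
            raise ValueError("values must be (frames, n_channels)")

    @property
    def frames(self) -> int:
        return self.values.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channels.index(name)]

    def to_dataframe(self, tidy: bool = False):
        """Wide (default) or tidy ``frame,time,channel,value_deg`` table."""
        import pandas as pd

        t = np.arange(self.frames) / self.rate
        wide = pd.DataFrame(self.values, columns=list(self.channels))
        wide.insert(0, "time", t)
        wide.insert(0, "frame", np.arange(self.frames))
        if not tidy:
            return wide
        return wide.melt(
            id_vars=["frame", "time"], var_name="channel", value_name="value_deg"
        )


# ---------------------------------------------------------------------------
# rotation decomposition

_PROPER = {"XYX", "XZX", "YXY", "YZY", "ZXZ", "ZYZ"}


def decompose_rotation(
    R: np.ndarray, sequence: str, degrees: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Intrinsic Euler/Cardan decomposition with a deterministic gimbal rule.

    Returns ``(angles, gimbal_flag)``; for a batch input the leading axes
    are preserved. At a singular middle angle the third angle is set to 0
    and the full twist assigned to the first (the convention scipy also
    applies), and the flag is raised when the middle angle is within
    ~1e-6 degrees of its singular value.
    """
    R = np.asarray(R, float)
    single = R.ndim == 2
    Rb = R[None] if single else R.reshape(-1, 3, 3)
    finite = np.isfinite(Rb).all(axis=(1, 2))
    angles = np.full((Rb.shape[0], 3), np.nan)
    if finite.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy gimbal-lock warning
            rot = Rotation.from_matrix(Rb[finite])
            angles[finite] = rot.as_euler(sequence, degrees=True)
    mid = angles[:, 1]
    if sequence.upper() in _PROPER:
        gimbal = np.isfinite(mid) & (
            (np.abs(mid) < 1e-6) | (np.abs(np.abs(mid) - 180.0) < 1e-6)
        )
    else:
        gimbal = np.isfinite(mid) & (np.abs(np.abs(mid) - 90.0) < 1e-6)
    if not degrees:
        angles = np.deg2rad(angles)
    if single:
        return angles[0], gimbal[0]
    shape = R.shape[:-2]
    return angles.reshape(*shape, 3), gimbal.reshape(shape)


def compose_rotation(angles, sequence: str, degrees: bool = True) -> np.ndarray:
    """Inverse of :func:`decompose_rotation` (intrinsic sequence)."""
    return Rotation.from_euler(sequence, np.asarray(angles, float), degrees=degrees
                               ).as_matrix()


# ---------------------------------------------------------------------------
# static calibration


def _technical_frames(pos: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame technical frame from the first three cluster markers.

    ``pos``: (frames, k, 3). Returns (origin (F,3), R (F,3,3), ok (F,)).
    """
    m0, m1, m2 = pos[:, 0], pos[:, 1], pos[:, 2]
    x = m1 - m0
    nx = np.linalg.norm(x, axis=1, keepdims=True)
    v = m2 - m0
    z = np.cross(x, v)
    nz = np.linalg.norm(z, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = x / nx
        z = z / nz
    ok = np.isfinite(pos).all(axis=(1, 2)) & (nx[:, 0] > 1e-9) & (
        nz[:, 0] > 1e-6 * np.maximum(nx[:, 0], 1e-12)
    )
    y = np.cross(z, x)
    R = np.stack([x, y, z], axis=-1)
    return m0, R, ok


def calibrate_landmarks(
    static: MarkerTrajectorySet,
    markerset: MarkerSetDefinition,
    max_occlusion: float = 0.05,
) -> LandmarkModel:
    """Learn landmark and cluster local coordinates from the static trial.

    Requires every technical and landmark marker with less than
    ``max_occlusion`` missing samples; raises a validation error naming any
    absent marker and :class:`DegenerateFrameError` for collinear clusters.
    On rigid (noiseless) input the landmark reconstruction residual is at
    numerical precision; with 1 mm marker noise it stays in the low
    millimeters because locals are averaged over the whole static trial.
    """
    static.validate_against(markerset)
    trial = static.mirrored() if markerset.side == "left" else static
    for label in markerset.static_labels:
        frac = trial.occlusion_mask[:, trial.index_of(label)].mean()
        if frac > max_occlusion:
            raise MarkerValidationError(
                f"static marker {label!r} occluded in {frac:.0%} of frames "
                f"(limit {max_occlusion:.0%})"
            )

    cluster_local: dict[str, dict[str, np.ndarray]] = {}
    landmark_local: dict[str, dict[str, np.ndarray]] = {}
    sq_res, n_res = 0.0, 0
    for seg in SEGMENTS:
        cluster = markerset.segments[seg]
        lms = markerset.landmarks_of(seg)
        pos = np.stack([trial.get(l) for l in cluster], axis=1)
        o, R, ok = _technical_frames(pos)
        if not ok.any():
            raise DegenerateFrameError(
                f"segment {seg!r}: no static frame with a well-formed cluster"
            )
        # average local coordinates (technical frame) over valid frames
        def local_mean(world: np.ndarray) -> np.ndarray:
            rel = world[ok] - o[ok]
            loc = np.einsum("fij,fi->fj", R[ok], rel)
            loc = loc[np.isfinite(loc).all(axis=1)]
            if len(loc) == 0:
                raise MarkerValidationError("marker never visible in a valid frame")
            return loc.mean(axis=0)

        tech_cluster = {l: local_mean(trial.get(l)) for l in cluster}
        tech_lms = {l: local_mean(trial.get(l)) for l in lms}
        spread = np.ptp(np.array(list(tech_cluster.values())), axis=0)
        if np.sort(spread)[1] < 1e-6:
            raise DegenerateFrameError(f"segment {seg!r}: collinear cluster markers")
        try:
            a_o, a_R = frame_from_landmarks(tech_lms, FRAME_RECIPES[seg])
        except ValueError as exc:
            raise DegenerateFrameError(f"segment {seg!r}: {exc}") from exc
        cluster_local[seg] = {l: a_R.T @ (p - a_o) for l, p in tech_cluster.items()}
        landmark_local[seg] = {l: a_R.T @ (p - a_o) for l, p in tech_lms.items()}
        # reconstruction residual against the observed static landmarks
        Rw, tw, okw = _kabsch_series(
            np.array(list(cluster_local[seg].values())), pos
        )
        for l in lms:
            obs = trial.get(l)
            rec = np.einsum("fij,j->fi", Rw, landmark_local[seg][l]) + tw
            d = obs[okw] - rec[okw]
            d = d[np.isfinite(d).all(axis=1)]
            sq_res += float((d ** 2).sum())
            n_res += d.size
    residual = float(np.sqrt(sq_res / n_res)) if n_res else float("nan")
    return LandmarkModel(
        markerset=markerset,
        cluster_local=cluster_local,
        landmark_local=landmark_local,
        residual=residual,
    )


# ---------------------------------------------------------------------------
# dynamic frames


def _kabsch_series(
    local: np.ndarray, world: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid fit local -> world per frame.

    ``local``: (k, 3); ``world``: (frames, k, 3) with NaN for occlusions.
    Returns (R (F,3,3), t (F,3), valid (F,)); frames with fewer than three
    visible markers are invalid.
    """
    F, k = world.shape[0], world.shape[1]
    R = np.full((F, 3, 3), np.nan)
    t = np.full((F, 3), np.nan)
    vis = np.isfinite(world).all(axis=2)
    valid = vis.sum(axis=1) >= 3

    def fit(idx: np.ndarray, cols: np.ndarray) -> None:
        loc = local[cols]
        lmean = loc.mean(axis=0)
        lc = loc - lmean
        w = world[np.ix_(idx, cols)]
        wm = w.mean(axis=1, keepdims=True)
        H = np.einsum("ki,fkj->fij", lc, w - wm)  # sum_k l_k w_k^T
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(U @ Vt))
        d = np.where(d == 0, 1.0, d)  # rank-deficient guard
        U = U.copy()
        U[:, :, 2] *= d[:, None]
        Rf = np.transpose(U @ Vt, (0, 2, 1))  # R = V D U^T
        R[idx] = Rf
        t[idx] = wm[:, 0] - np.einsum("fij,j->fi", Rf, lmean)

    full = valid & vis.all(axis=1)
    if full.any():
        fit(np.where(full)[0], np.arange(k))
    rest = np.where(valid & ~full)[0]
    for f in rest:
        fit(np.array([f]), np.where(vis[f])[0])
    return R, t, valid


def lowpass_positions(
    positions: np.ndarray, rate: float, cutoff: float = 6.0, order: int = 4
) -> np.ndarray:
    """Zero-lag Butterworth low-pass of marker trajectories.

    NaN gaps are linearly bridged before filtering and restored after, so
    occlusion accounting is unaffected. Standard kinematic smoothing; pass
    ``cutoff=None`` upstream to skip.
    """
    out = positions.copy()
    F = positions.shape[0]
    if F < 15:
        return out
    b, a = butter(order, cutoff / (rate / 2.0), btype="low")
    x = np.arange(F)
    flat = out.reshape(F, -1)
    for j in range(flat.shape[1]):
        col = flat[:, j]
        bad = ~np.isfinite(col)
        if bad.all():
            continue
        if bad.any():
            col = col.copy()
            col[bad] = np.interp(x[bad], x[~bad], col[~bad])
        sm = filtfilt(b, a, col)
        sm[bad] = np.nan
        flat[:, j] = sm
    return out


def compute_segment_frames(
    dynamic: MarkerTrajectorySet,
    model: LandmarkModel,
    lowpass_hz: float | None = 6.0,
) -> SegmentFrameSeries:
    """Anatomical pose of the five segments for every dynamic frame.

    A segment's pose at a frame is the Kabsch fit of its calibrated cluster
    coordinates to the observed markers; frames with fewer than three
    visible cluster markers are flagged invalid and propagate as NaN.
    """
    dynamic.validate_against(model.markerset)
    trial = dynamic.mirrored() if model.markerset.side == "left" else dynamic
    origins, rotations, valid = {}, {}, {}
    for seg, locals_ in model.cluster_local.items():
        labels = list(locals_)
        world = np.stack([trial.get(l) for l in labels], axis=1)
        if lowpass_hz is not None:
            world = lowpass_positions(world, trial.rate, lowpass_hz)
        R, t, ok = _kabsch_series(np.array(list(locals_.values())), world)
        origins[seg], rotations[seg], valid[seg] = t, R, ok
    return SegmentFrameSeries(rate=trial.rate, origins=origins,
                              rotations=rotations, valid=valid)


def reconstruct_landmarks(
    frames: SegmentFrameSeries, model: LandmarkModel
) -> dict[str, np.ndarray]:
    """Virtual landmark world positions from the calibrated local coordinates."""
    out = {}
    for seg, lms in model.landmark_local.items():
        R, t = frames.rotations[seg], frames.origins[seg]
        for label, loc in lms.items():
            out[label] = np.einsum("fij,j->fi", R, loc) + t
    return out


# ---------------------------------------------------------------------------
# joint angles


def _unwrap_deg(col: np.ndarray) -> np.ndarray:
    """Unwrap a degree series across NaN gaps (180-degree jump threshold)."""
    out = col.copy()
    finite = np.isfinite(col)
    if finite.sum() >= 2:
        out[finite] = np.rad2deg(np.unwrap(np.deg2rad(col[finite])))
    return out


def compute_joint_angles(
    frames: SegmentFrameSeries,
    conventions: tuple[JointConvention, ...] = DEFAULT_CONVENTIONS,
    unwrap: bool = True,
) -> JointAngleSeries:
    """Decompose relative segment rotations into the 13 angle channels.

    The relative orientation of each joint is ``R_proximal^T R_distal``
    (trunk is referenced to the lab frame); each is decomposed with the
    joint's intrinsic sequence, signed per convention, and unwrapped per
    channel so RMSE waveform scoring sees continuous traces.
    """
    F = frames.frames
    values = np.full((F, len(CHANNELS)), np.nan)
    gimbal = np.zeros(F, bool)
    for conv in conventions:
        Rd = frames.rotations[conv.distal]
        ok = frames.valid[conv.distal].copy()
        if conv.proximal is None:
            rel = Rd
        else:
            Rp = frames.rotations[conv.proximal]
            ok &= frames.valid[conv.proximal]
            rel = np.einsum("fji,fjk->fik", Rp, Rd)  # Rp^T Rd
        rel = np.where(ok[:, None, None], rel, np.nan)
        ang, flag = decompose_rotation(rel, conv.sequence)
        gimbal |= flag
        if conv.negative_middle:
            # equivalent proper-Euler representation (a+180, -b, c+180)
            flip = ang[:, 1] > 0
            ang[flip, 1] *= -1.0
            for j in (0, 2):
                ang[flip, j] = (ang[flip, j] + 360.0) % 360.0 - 180.0
        for pos_idx, name in enumerate(conv.channels):
            if name is None:
                continue
            col = ang[:, pos_idx] * conv.signs[pos_idx]
            if unwrap:
                col = _unwrap_deg(col)
            values[:, CHANNELS.index(name)] = col
    return JointAngleSeries(rate=frames.rate, values=values, gimbal=gimbal)
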