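"""Default upper-limb placement model and anatomical frame recipes.

The study protocol fixes segment marker *counts* but not exact placements,
so the package ships one documented default placement model that is used by
the forward-kinematic simulator and, implicitly, by the calibration step
(which learns the actual local coordinates from the static trial — it never
reads this module's numbers).

Lab frame: right-handed, X anterior, Y vertical-up, Z to the subject's
right. Every segment's anatomical frame is aligned with the lab frame in
the neutral (anatomical) pose, with the origin at the segment's proximal
joint and the segment extending along -Y (distal is down).

Each segment's anatomical frame is constructed from three landmark points
(origin / long-axis point / plane point); the recipe kind says whether the
plane point fixes the anterior (X) or the lateral (Z) direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SEGMENTS = ("trunk", "scapula", "humerus", "forearm", "hand")

#: proximal-to-distal chain; offsets of each child origin in the parent's
#: anatomical frame (meters). The trunk root sits above the chair seat.
CHAIN_PARENT = {"trunk": None, "scapula": "trunk", "humerus": "scapula",
                "forearm": "humerus", "hand": "forearm"}

#: the segment each joint's *orientation* is referenced to. The humerus is
#: expressed against the thorax (humerothoracic angles, the clinical
#: convention) even though its position rides on the scapula.
ORIENT_PARENT = {"trunk": None, "scapula": "trunk", "humerus": "trunk",
                 "forearm": "humerus", "hand": "forearm"}

#: default anthropometry: trunk 0.45 m, upper arm 0.28 m, forearm 0.25 m,
#: hand 0.08 m; acromion offset near the top of the trunk, on the right.
CHAIN_OFFSET = {
    "trunk": np.array([0.0, 0.50, 0.0]),
    "scapula": np.array([0.0, 0.42, 0.17]),
    "humerus": np.array([0.01, -0.02, 0.03]),
    "forearm": np.array([0.0, -0.28, 0.0]),
    "hand": np.array([0.0, -0.25, 0.0]),
}


@dataclass(frozen=True)
class FrameRecipe:
    """How to build a segment's anatomical frame from three landmarks.

    ``origin``/``long_pt``/``plane_pt`` are tuples of landmark labels that
    are averaged (so an origin may be, e.g., the elbow epicondyle midpoint).
    ``plane_kind`` is ``"anterior"`` (plane point fixes +X) or ``"lateral"``
    (plane point fixes +Z, right side).
    """

    origin: tuple[str, ...]
    long_pt: tuple[str, ...]
    plane_pt: tuple[str, ...]
    plane_kind: str = "anterior"


FRAME_RECIPES: dict[str, FrameRecipe] = {
    "trunk": FrameRecipe(("T8",), ("C7",), ("IJ",), "anterior"),
    "scapula": FrameRecipe(("AI",), ("AA",), ("PC",), "anterior"),
    "humerus": FrameRecipe(("EL", "EM"), ("GH",), ("EL",), "lateral"),
    "forearm": FrameRecipe(("WRU", "WRR"), ("OLE",), ("WRR",), "lateral"),
    "hand": FrameRecipe(("MC2", "MC5"), ("CAP",), ("MC2",), "lateral"),
}


def frame_from_landmarks(
    points: dict[str, np.ndarray], recipe: FrameRecipe
) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal anatomical frame (origin, 3x3 rotation, columns = axes).

    Y is the unit long axis (long point minus origin). For an "anterior"
    recipe X is the plane direction orthogonalized against Y and Z = X x Y;
    for a "lateral" recipe Z is orthogonalized and X = Y x Z.
    """

    def mean_of(labels: tuple[str, ...]) -> np.ndarray:
        return np.mean([points[l] for l in labels], axis=0)

    o = mean_of(recipe.origin)
    y = mean_of(recipe.long_pt) - o
    ny = np.linalg.norm(y)
    if ny < 1e-12:
        raise ValueError("degenerate frame: long-axis landmarks coincide")
    y = y / ny
    w = mean_of(recipe.plane_pt) - o
    w = w - (w @ y) * y
    nw = np.linalg.norm(w)
    if nw < 1e-9:
        raise ValueError("degenerate frame: collinear landmarks")
    w = w / nw
    if recipe.plane_kind == "anterior":
        x = w
        z = np.cross(x, y)
    else:
        z = w
        x = np.cross(y, z)
    R = np.column_stack([x, y, z])
    return o, R


# ---------------------------------------------------------------------------
# default placements (design coordinates, segment anatomical frame, meters)

_TECH_DESIGN: dict[str, dict[str, list[float]]] = {
    "trunk": {
        "TRU1": [0.00, 0.42, -0.08],
        "TRU2": [0.00, 0.42, 0.08],
        "TRU3": [-0.06, 0.18, 0.00],
    },
    "scapula": {
        "ACR1": [0.00, 0.025, -0.040],
        "ACR2": [0.045, -0.005, 0.020],
        "ACR3": [-0.045, -0.005, 0.030],
    },
    "humerus": {  # cluster plate with laterally offset wand markers
        "HUM1": [0.000, -0.060, 0.055],
        "HUM2": [0.055, -0.110, 0.025],
        "HUM3": [0.000, -0.220, 0.055],
        "HUM4": [-0.055, -0.160, 0.025],
    },
    "forearm": {
        "FOR1": [0.045, -0.050, 0.030],
        "FOR2": [-0.045, -0.100, 0.030],
        "FOR3": [0.045, -0.160, 0.030],
        "FOR4": [-0.045, -0.215, 0.030],
    },
    "hand": {
        "HAN1": [0.015, -0.010, 0.000],
        "HAN2": [0.015, -0.078, 0.035],
        "HAN3": [0.015, -0.078, -0.035],
    },
}

_LANDMARK_DESIGN: dict[str, dict[str, list[float]]] = {
    "trunk": {
        "T8": [-0.070, 0.220, 0.000],
        "C7": [-0.060, 0.430, 0.000],
        "IJ": [0.060, 0.400, 0.000],
    },
    "scapula": {
        "AI": [-0.020, -0.100, -0.020],
        "AA": [0.000, 0.010, 0.030],
        "PC": [0.050, -0.010, 0.000],
    },
    "humerus": {
        "GH": [0.000, 0.010, 0.010],
        "EL": [0.005, -0.280, 0.035],
        "EM": [0.005, -0.280, -0.035],
    },
    "forearm": {
        "OLE": [-0.030, -0.010, 0.000],
        "WRU": [0.000, -0.250, -0.025],
        "WRR": [0.000, -0.250, 0.025],
    },
    "hand": {
        "CAP": [0.000, -0.015, 0.000],
        "MC2": [0.000, -0.078, 0.022],
        "MC5": [0.000, -0.078, -0.022],
    },
}


@dataclass(frozen=True)
class BodyModel:
    """Local marker coordinates per segment, expressed in that segment's
    anatomical frame, plus the kinematic-chain offsets.

    Constructed so that applying the segment's :data:`FRAME_RECIPES` recipe
    to the stored landmark coordinates yields the identity pose — i.e. the
    anatomical frame the pipeline reconstructs from markers *is* the frame
    the simulator animates, making forward-kinematics / angle-recovery an
    exact loop on noiseless data.
    """

    tech_local: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    landmark_local: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    chain_offset: dict[str, np.ndarray] = field(
        default_factory=lambda: {k: v.copy() for k, v in CHAIN_OFFSET.items()}
    )

    @classmethod
    def default(cls) -> "BodyModel":
        tech: dict[str, dict[str, np.ndarray]] = {}
        land: dict[str, dict[str, np.ndarray]] = {}
        for seg in SEGMENTS:
            lm_pts = {k: np.asarray(v, float) for k, v in _LANDMARK_DESIGN[seg].items()}
            o, R = frame_from_landmarks(lm_pts, FRAME_RECIPES[seg])
            # re-express design coordinates in the recipe's own frame
            land[seg] = {k: R.T @ (p - o) for k, p in lm_pts.items()}
            tech[seg] = {
                k: R.T @ (np.asarray(v, float) - o)
                for k, v in _TECH_DESIGN[seg].items()
            }
        return cls(tech_local=tech, landmark_local=land)
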