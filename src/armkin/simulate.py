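"""Forward-kinematic synthetic motion-capture generator with ground truth.

Every input the analysis pipeline needs can be generated here: a
typically-developing (TD) reference bank of time-normalized joint-angle
waveforms, per-subject static calibration and dynamic task recordings as
17-marker trajectories, and a clinical covariate table whose couplings to
the injected movement deviations are known exactly.

Motion model
------------
Each task (hand-to-head, hand-to-mouth, reach-to-grasp-vertical) is a
joint-space template: a rest posture (hand resting near the ipsilateral
knee) and an endpoint posture, connected by a minimum-jerk transition.
A recording holds four repetitions (reach - hold - return - rest), matching
the study protocol of four repetitions per recording and two recordings per
task. Movement pathology is injected per channel as a constant offset plus
a small within-cycle slope, scaled by MACS level and coupled to the
subject's grip-force deficit; marker trajectories come from a five-segment
forward-kinematic chain with isotropic Gaussian marker noise (default
1 mm) and optional occlusion blocks. Scripted event frames, injected
offsets and generative couplings are returned as ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from armkin.bodymodel import BodyModel, CHAIN_PARENT, ORIENT_PARENT, SEGMENTS
from armkin.kinematics import CHANNELS, DEFAULT_CONVENTIONS, compose_rotation
from armkin.markers import (
    DEFAULT_MARKER_SET,
    MarkerSetDefinition,
    MarkerTrajectorySet,
    TASKS,
    write_marker_trial,
)
from armkin.outcomes import ReferenceBank

# ---------------------------------------------------------------------------
# task templates (degrees): rest posture and point-of-task-achievement posture

REST_POSTURE: dict[str, float] = {
    "wrist_flex_ext": 10.0, "wrist_dev": 5.0,
    "elbow_flex_ext": 70.0, "elbow_pro_sup": 60.0,
    "shoulder_plane": 30.0, "shoulder_elev": -30.0, "shoulder_rot": 20.0,
    "scap_pro_retr": 15.0, "scap_med_lat": 5.0, "scap_tilt": 5.0,
    "trunk_flex_ext": 5.0, "trunk_lat_bend": 0.0, "trunk_rot": 0.0,
}

PTA_POSTURE: dict[str, dict[str, float]] = {
    "HTH": {
        "wrist_flex_ext": -10.0, "wrist_dev": 0.0,
        "elbow_flex_ext": 110.0, "elbow_pro_sup": 30.0,
        "shoulder_plane": 60.0, "shoulder_elev": -100.0, "shoulder_rot": 40.0,
        "scap_pro_retr": 25.0, "scap_med_lat": 10.0, "scap_tilt": 12.0,
        "trunk_flex_ext": 8.0, "trunk_lat_bend": 5.0, "trunk_rot": 8.0,
    },
    "HTM": {
        "wrist_flex_ext": 0.0, "wrist_dev": 5.0,
        "elbow_flex_ext": 130.0, "elbow_pro_sup": 45.0,
        "shoulder_plane": 50.0, "shoulder_elev": -60.0, "shoulder_rot": 30.0,
        "scap_pro_retr": 20.0, "scap_med_lat": 8.0, "scap_tilt": 10.0,
        "trunk_flex_ext": 10.0, "trunk_lat_bend": 3.0, "trunk_rot": 5.0,
    },
    "RGV": {  # cylinder at shoulder height, arm-length distance
        "wrist_flex_ext": -15.0, "wrist_dev": 8.0,
        "elbow_flex_ext": 25.0, "elbow_pro_sup": 20.0,
        "shoulder_plane": 70.0, "shoulder_elev": -85.0, "shoulder_rot": 25.0,
        "scap_pro_retr": 28.0, "scap_med_lat": 12.0, "scap_tilt": 15.0,
        "trunk_flex_ext": 12.0, "trunk_lat_bend": 6.0, "trunk_rot": 10.0,
    },
}

#: hidden sequence angles that are computed but not reported
CARRYING_ANGLE = 8.0

#: per-channel base deviation magnitude (deg); distal channels dominate
BASE_DEVIATION: dict[str, float] = {
    "wrist_flex_ext": 8.0, "wrist_dev": 4.0,
    "elbow_flex_ext": 6.0, "elbow_pro_sup": 7.0,
    "shoulder_plane": 4.0, "shoulder_elev": 4.0, "shoulder_rot": 4.0,
    "scap_pro_retr": 3.0, "scap_med_lat": 2.5, "scap_tilt": 2.5,
    "trunk_flex_ext": 2.0, "trunk_lat_bend": 1.5, "trunk_rot": 2.0,
}

#: deviation / duration / path-curvature scaling per MACS level
MACS_DEVIATION_FACTOR = {"I": 0.6, "II": 1.2, "III": 2.0}
MACS_DURATION_FACTOR = {"I": 1.1, "II": 1.3, "III": 1.6}
MACS_CURVATURE_FACTOR = {"I": 0.3, "II": 0.7, "III": 1.2}
MACS_GRIP_MEAN = {"I": 0.75, "II": 0.55, "III": 0.35}


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile 10 t^3 - 15 t^4 + 6 t^5 on [0, 1]."""
    t = np.clip(tau, 0.0, 1.0)
    return 10 * t**3 - 15 * t**4 + 6 * t**5


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults of the generator.

    Cohort shape 15/26/9 across MACS I-III, a TD reference bank of N = 20,
    100 Hz sampling, four repetitions per recording and two recordings per
    task, 1 mm isotropic marker noise. ``aps_grip_beta``/``aps_noise_sd``
    parameterize the clinical-level generative coupling of APS to the
    grip-force deficit used for regression-recovery simulations.
    """

    seed: int = 0
    n_per_macs: dict[str, int] = field(
        default_factory=lambda: {"I": 15, "II": 26, "III": 9}
    )
    reference_n: int = 20
    tasks: tuple[str, ...] = TASKS
    rate: float = 100.0
    repetitions: int = 4
    recordings: int = 2
    reach_time: float = 1.2  # TD outbound reach duration (s)
    hold_time: float = 0.5
    rest_time: float = 0.6
    marker_noise: float = 0.001  # m
    occlusion_rate: float = 0.0  # per-marker per-repetition block probability
    occlusion_fraction_range: tuple[float, float] = (0.05, 0.30)
    # reference-bank inter-subject variability
    bank_offset_sd: float = 2.0   # deg
    bank_amp_sd: float = 0.06     # relative amplitude scaling
    bank_shift_sd: float = 0.02   # cycle-phase shift
    # deviation structure
    deviation_scale: float = 1.0
    deviation_rel_sd: float = 0.4
    slope_sd: float = 1.0  # deg over the cycle
    grip_coupling: float = 1.2  # deviation inflation per unit grip deficit
    # clinical-level APS coupling (regression-recovery simulations)
    aps_grip_beta: float = 12.0  # deg APS per unit grip deficit
    aps_noise_sd: float = 2.2    # deg
    P: int = 101


@dataclass
class GroundTruth:
    """Everything needed to verify pipeline output analytically."""

    macs: str
    grip: float
    offsets: dict[str, float]            # injected constant offset per channel
    slopes: dict[str, float]
    duration_factor: float
    events: dict[str, list[dict]]        # task -> per recording/rep start & PTA
    reach_frames: int
    clinical: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# reference bank


def template_waveform(task: str, channel: str, tau: np.ndarray) -> np.ndarray:
    """TD template on the movement-cycle grid (start -> PTA)."""
    rest = REST_POSTURE[channel]
    return rest + (PTA_POSTURE[task][channel] - rest) * minimum_jerk(tau)


def _boundary_calibration(
    config: SimulationConfig, body: BodyModel
) -> dict[str, tuple[float, float]]:
    """Relative event-detection bias per task.

    Reference waveforms must be framed by the *same* event conventions the
    pipeline applies to a child's recording, or the boundary convention
    itself would register as movement pathology. A noiseless
    typically-developing recording per task is run through the detector and
    the mean offsets of detected start/PTA, as fractions of the reach
    duration, define the movement-cycle grid the bank is tabulated on.
    """
    from armkin.segmentation import detect_repetitions

    out: dict[str, tuple[float, float]] = {}
    for task in config.tasks:
        q, ev = _recording_channels(task, config, {}, {}, 1.0, 0.0)
        R, o = forward_kinematics(q, body)
        labels, pos = markers_from_poses(R, o, body)
        trial = MarkerTrajectorySet(labels=labels, positions=pos,
                                    rate=config.rate, task=task)
        segs = detect_repetitions(trial, task)
        n_reach = int(round(config.reach_time * config.rate))
        if len(segs) != len(ev):
            out[task] = (0.0, 0.0)
            continue
        # the scripted start event is the last rest frame; the movement's
        # tau = 0 instant is one frame later
        rel0 = np.mean([
            ((s.start if s.start_exact is None else s.start_exact)
             - (e["start"] + 1)) / n_reach
            for s, e in zip(segs, ev)
        ])
        rel1 = np.mean([
            ((s.end if s.end_exact is None else s.end_exact)
             - e["pta"]) / n_reach
            for s, e in zip(segs, ev)
        ])
        out[task] = (float(rel0), float(rel1))
    return out


def generate_reference_bank(
    config: SimulationConfig = SimulationConfig(),
    rng: np.random.Generator | None = None,
    body: BodyModel | None = None,
) -> tuple[ReferenceBank, dict[str, dict[str, np.ndarray]]]:
    """TD reference bank plus its generating templates.

    Each reference subject perturbs the template with a per-channel offset
    (sd ``bank_offset_sd``), amplitude scaling (sd ``bank_amp_sd``) and a
    small phase shift (sd ``bank_shift_sd``); the bank's point-wise mean
    converges to the template as N grows. The movement-cycle grid is
    calibrated to the pipeline's event-detection conventions (see
    :func:`_boundary_calibration`) so a deviation-free child scores an APS
    of ~0 rather than the boundary convention itself.
    """
    if config.reference_n < 2:
        raise ValueError("reference bank needs N >= 2")
    rng = rng or np.random.default_rng(config.seed)
    bounds = _boundary_calibration(config, body or BodyModel.default())
    waveforms: dict[str, dict[str, np.ndarray]] = {}
    templates: dict[str, dict[str, np.ndarray]] = {}
    for task in config.tasks:
        rel0, rel1 = bounds[task]
        tau = np.linspace(rel0, 1.0 + rel1, config.P)
        waveforms[task] = {}
        templates[task] = {}
        for ch in CHANNELS:
            tpl = template_waveform(task, ch, tau)
            templates[task][ch] = tpl
            rows = np.empty((config.reference_n, config.P))
            delta = PTA_POSTURE[task][ch] - REST_POSTURE[ch]
            for s in range(config.reference_n):
                off = rng.normal(0.0, config.bank_offset_sd)
                amp = rng.normal(1.0, config.bank_amp_sd)
                shift = rng.normal(0.0, config.bank_shift_sd)
                rows[s] = (
                    REST_POSTURE[ch]
                    + amp * delta * minimum_jerk(tau + shift)
                    + off
                )
            waveforms[task][ch] = rows
    bank = ReferenceBank(
        waveforms=waveforms, P=config.P,
        meta={"N": config.reference_n, "source": "synthetic TD generator",
              "cycle_bounds": {t: list(b) for t, b in bounds.items()}},
    )
    return bank, templates


# ---------------------------------------------------------------------------
# forward kinematics


_SIGNS = {c.name: c.signs for c in DEFAULT_CONVENTIONS}
_SEQS = {c.name: c.sequence for c in DEFAULT_CONVENTIONS}
_JOINT_OF_SEG = {"trunk": "trunk", "scapula": "scapula", "humerus": "shoulder",
                 "forearm": "elbow", "hand": "wrist"}
_CHANNEL_POS = {c.name: c.channels for c in DEFAULT_CONVENTIONS}


def _joint_sequence_angles(q: dict[str, np.ndarray], joint: str, F: int) -> np.ndarray:
    """Raw intrinsic sequence angles (F, 3) from named channel values."""
    out = np.zeros((F, 3))
    for pos, name in enumerate(_CHANNEL_POS[joint]):
        if name is None:
            # hidden angles: elbow carrying angle, wrist axial rotation
            out[:, pos] = CARRYING_ANGLE if joint == "elbow" else 0.0
        else:
            out[:, pos] = q[name] / _SIGNS[joint][pos]
    return out


def forward_kinematics(
    q: dict[str, np.ndarray], body: BodyModel
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Segment poses from channel trajectories (degrees).

    Returns per segment ``R`` (F, 3, 3) and origin (F, 3). The composition
    mirrors the analysis-side conventions exactly, so decomposing the
    relative rotations recovers the input channels.
    """
    F = len(next(iter(q.values())))
    R: dict[str, np.ndarray] = {}
    o: dict[str, np.ndarray] = {}
    for seg in SEGMENTS:
        joint = _JOINT_OF_SEG[seg]
        Rj = compose_rotation(
            _joint_sequence_angles(q, joint, F), _SEQS[joint], degrees=True
        )
        o_parent = CHAIN_PARENT[seg]       # position rides on this segment
        r_parent = ORIENT_PARENT[seg]      # angles are referenced to this one
        off = body.chain_offset[seg]
        R[seg] = Rj if r_parent is None else np.einsum(
            "fij,fjk->fik", R[r_parent], Rj
        )
        if o_parent is None:
            o[seg] = np.broadcast_to(off, (F, 3)).copy()
        else:
            o[seg] = o[o_parent] + np.einsum("fij,j->fi", R[o_parent], off)
    return R, o


def markers_from_poses(
    R: dict[str, np.ndarray],
    o: dict[str, np.ndarray],
    body: BodyModel,
    include_landmarks: bool = False,
) -> tuple[tuple[str, ...], np.ndarray]:
    """World marker positions (frames, n_markers, 3) from segment poses."""
    labels: list[str] = []
    cols: list[np.ndarray] = []
    for seg in SEGMENTS:
        sources = dict(body.tech_local[seg])
        if include_landmarks:
            sources.update(body.landmark_local[seg])
        for label, loc in sources.items():
            labels.append(label)
            cols.append(np.einsum("fij,j->fi", R[seg], loc) + o[seg])
    return tuple(labels), np.stack(cols, axis=1)


# ---------------------------------------------------------------------------
# child trials


def _recording_channels(
    task: str,
    cfg: SimulationConfig,
    offsets: dict[str, float],
    slopes: dict[str, float],
    duration_factor: float,
    curvature: float,
) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Joint-space channel trajectories for one recording + scripted events."""
    rate = cfg.rate
    n_reach = int(round(cfg.reach_time * duration_factor * rate))
    n_hold = int(round(cfg.hold_time * rate))
    n_rest = int(round(cfg.rest_time * rate))

    tau_reach = np.arange(n_reach + 1) / n_reach  # inclusive endpoint
    phases: list[np.ndarray] = [np.zeros(n_rest)]  # initial rest
    events: list[dict] = []
    cursor = n_rest
    for _ in range(cfg.repetitions):
        start = cursor - 1          # last frame at rest before the reach
        phases.append(tau_reach)
        cursor += n_reach + 1
        pta = cursor - 1            # endpoint frame (tau = 1)
        phases.append(np.ones(n_hold))
        cursor += n_hold
        phases.append(tau_reach[::-1])  # return
        cursor += n_reach + 1
        phases.append(np.zeros(n_rest))
        cursor += n_rest
        events.append({"start": start, "pta": pta})
    tau = np.concatenate(phases)
    mj = minimum_jerk(tau)
    bump = np.sin(np.pi * tau) ** 2  # transient mid-movement detour
    q: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        rest = REST_POSTURE[ch]
        delta = PTA_POSTURE[task][ch] - rest
        dev = offsets.get(ch, 0.0) + slopes.get(ch, 0.0) * (tau - 0.5)
        curve = 0.0
        if ch == "elbow_flex_ext":
            curve = 8.0 * curvature * bump
        elif ch == "shoulder_plane":
            curve = 6.0 * curvature * bump
        q[ch] = rest + delta * mj + dev + curve
    return q, events


def simulate_child_trial(
    macs_level: str,
    config: SimulationConfig = SimulationConfig(),
    seed: int | None = None,
    body: BodyModel | None = None,
    markerset: MarkerSetDefinition = DEFAULT_MARKER_SET,
    grip: float | None = None,
    offsets_override: dict[str, float] | None = None,
    curvature_override: float | None = None,
) -> tuple[MarkerTrajectorySet, dict[str, list[MarkerTrajectorySet]], GroundTruth]:
    """One subject: static calibration trial, dynamic recordings, ground truth.

    Deviations are drawn per channel around the MACS-scaled base magnitudes,
    inflated by the subject's grip-force deficit via ``grip_coupling``.
    ``offsets_override`` fixes the per-channel constant offsets exactly
    (channels not listed get zero) and ``curvature_override`` pins the
    path-curvature factor — both for controlled parameter-recovery
    experiments. Same seed, same output, bit for bit.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    body = body or BodyModel.default()
    if grip is None:
        grip = float(np.clip(rng.normal(MACS_GRIP_MEAN[macs_level], 0.10),
                             0.05, 1.0))
    dev_inflation = 1.0 + config.grip_coupling * max(0.0, 0.6 - grip)
    offsets = {
        ch: float(rng.normal(
            BASE_DEVIATION[ch] * MACS_DEVIATION_FACTOR[macs_level]
            * config.deviation_scale * dev_inflation,
            BASE_DEVIATION[ch] * MACS_DEVIATION_FACTOR[macs_level]
            * config.deviation_scale * config.deviation_rel_sd,
        ))
        for ch in CHANNELS
    }
    if offsets_override is not None:
        offsets = {ch: float(offsets_override.get(ch, 0.0)) for ch in CHANNELS}
    slopes = {ch: float(rng.normal(0.0, config.slope_sd)) for ch in CHANNELS}
    duration_factor = MACS_DURATION_FACTOR[macs_level]
    # path curvature is itself a movement deviation: scale it like one
    curvature = MACS_CURVATURE_FACTOR[macs_level] * config.deviation_scale
    if curvature_override is not None:
        curvature = curvature_override

    # static calibration trial: 2 s of the rest posture, landmarks included
    n_static = int(2.0 * config.rate)
    q_static = {ch: np.full(n_static, REST_POSTURE[ch]) for ch in CHANNELS}
    R, o = forward_kinematics(q_static, body)
    labels, pos = markers_from_poses(R, o, body, include_landmarks=True)
    pos = pos + rng.normal(0.0, config.marker_noise, pos.shape)
    static = MarkerTrajectorySet(labels=labels, positions=pos, rate=config.rate,
                                 trial_kind="static")

    recordings: dict[str, list[MarkerTrajectorySet]] = {}
    events: dict[str, list[dict]] = {}
    reach_frames = int(round(config.reach_time * duration_factor * config.rate))
    for task in config.tasks:
        recordings[task] = []
        events[task] = []
        for rec in range(config.recordings):
            q, ev = _recording_channels(task, config, offsets, slopes,
                                        duration_factor, curvature)
            R, o = forward_kinematics(q, body)
            labels, pos = markers_from_poses(R, o, body)
            pos = pos + rng.normal(0.0, config.marker_noise, pos.shape)
            trial = MarkerTrajectorySet(labels=labels, positions=pos,
                                        rate=config.rate, trial_kind="dynamic",
                                        task=task)
            if config.occlusion_rate > 0:
                for m_i, label in enumerate(labels):
                    for e in ev:
                        if rng.random() < config.occlusion_rate:
                            frac = rng.uniform(*config.occlusion_fraction_range)
                            _occlude_window(trial, label, frac,
                                            (e["start"], e["pta"] + 1), rng)
            if markerset.side == "left":
                trial = trial.mirrored()
            recordings[task].append(trial)
            events[task].extend(
                {"recording": rec, "repetition": i + 1, **e}
                for i, e in enumerate(ev)
            )
    if markerset.side == "left":
        static = static.mirrored()
    truth = GroundTruth(macs=macs_level, grip=grip, offsets=offsets,
                        slopes=slopes, duration_factor=duration_factor,
                        events=events, reach_frames=reach_frames)
    return static, recordings, truth


# ---------------------------------------------------------------------------
# occlusion injection


def _occlude_window(
    trial: MarkerTrajectorySet,
    marker: str,
    fraction: float,
    window: tuple[int, int],
    rng: np.random.Generator,
) -> None:
    start, stop = window
    n = stop - start
    block = int(round(fraction * n))
    if block <= 0:
        return
    pos0 = start + int(rng.integers(0, n - block + 1)) if block < n else start
    trial.positions[pos0 : pos0 + block, trial.index_of(marker), :] = np.nan


def inject_occlusion(
    trial: MarkerTrajectorySet,
    marker: str,
    fraction: float,
    seed: int = 0,
    windows: list[tuple[int, int]] | None = None,
) -> MarkerTrajectorySet:
    """Return a copy with a contiguous occlusion block of ``fraction`` of
    each window (default: the whole trial), placed uniformly at random."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("occlusion fraction must lie in [0, 1]")
    out = dc_replace(trial, positions=trial.positions.copy())
    rng = np.random.default_rng(seed)
    for window in windows or [(0, trial.frames)]:
        _occlude_window(out, marker, fraction, window, rng)
    return out


# ---------------------------------------------------------------------------
# cohorts


def _clinical_from_grip(rng: np.random.Generator, grip: float) -> dict[str, float]:
    """Clinical covariates correlated with the grip-force deficit."""
    return {
        "age": float(rng.uniform(5.0, 15.0)),
        "grip_force": grip,
        "strength": float(np.clip(4.0 + 16.0 * grip + rng.normal(0, 1.2), 0, 20)),
        "tone": float(np.clip(2.0 + 18.0 * (1 - grip) + rng.normal(0, 1.5), 0, 24)),
        "tpd": float(np.clip(3.0 + 10.0 * (1 - grip) + rng.normal(0, 1.0), 2, 15)),
        "stereognosis": float(np.clip(round(6.0 * grip + rng.normal(0, 0.7)), 0, 6)),
        "aha": float(np.clip(100 * (0.15 + 0.80 * grip) + rng.normal(0, 4), 0, 100)),
        "ma2_rom": float(np.clip(100 * (0.20 + 0.75 * grip) + rng.normal(0, 5), 0, 100)),
        "ma2_accuracy": float(np.clip(100 * (0.20 + 0.75 * grip) + rng.normal(0, 5), 0, 100)),
        "ma2_dexterity": float(np.clip(100 * (0.15 + 0.80 * grip) + rng.normal(0, 6), 0, 100)),
        "ma2_fluency": float(np.clip(100 * (0.25 + 0.70 * grip) + rng.normal(0, 5), 0, 100)),
    }


@dataclass
class CohortBundle:
    """In-memory synthetic cohort: trials, clinical table and ground truth."""

    config: SimulationConfig
    bank: ReferenceBank
    subjects: dict[str, dict]      # id -> {static, recordings, truth, macs}
    clinical: pd.DataFrame


def simulate_cohort(
    config: SimulationConfig = SimulationConfig(),
) -> CohortBundle:
    """Full synthetic study cohort with MACS-graded deviations.

    Subject ids are ``S001..``; each carries a static trial, two recordings
    per task and its ground truth; the clinical table includes MACS level
    and the grip-coupled covariates.
    """
    rng = np.random.default_rng(config.seed)
    bank, _ = generate_reference_bank(config, rng=rng)
    subjects: dict[str, dict] = {}
    rows = []
    i = 0
    for macs, n in config.n_per_macs.items():
        for _ in range(n):
            i += 1
            sid = f"S{i:03d}"
            seed = int(rng.integers(0, 2**31 - 1))
            static, recs, truth = simulate_child_trial(macs, config, seed=seed)
            clin = _clinical_from_grip(np.random.default_rng(seed + 1),
                                       truth.grip)
            truth.clinical = clin
            subjects[sid] = {"static": static, "recordings": recs,
                             "truth": truth, "macs": macs}
            rows.append({"subject": sid, "macs": macs, **clin})
    return CohortBundle(config=config, bank=bank, subjects=subjects,
                        clinical=pd.DataFrame(rows))


def simulate_clinical_cohort(
    config: SimulationConfig = SimulationConfig(),
    seed: int | None = None,
    coupling: str = "grip_only",
) -> pd.DataFrame:
    """Outcome-level cohort for statistics-recovery simulations.

    Draws a clinical table and generates per-task APS directly from the
    generative model, bypassing marker synthesis. Under ``"grip_only"``
    the APS is driven by the grip-force deficit alone
    (``APS = a + aps_grip_beta * (1 - grip) + noise``) and every other
    predictor is drawn independently; under ``"none"`` all predictors are
    independent and the APS is pure noise around its baseline. One row per
    subject x task.
    """
    if coupling not in ("grip_only", "none"):
        raise ValueError(f"unknown coupling {coupling!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    i = 0
    for macs, n in config.n_per_macs.items():
        for _ in range(n):
            i += 1
            # pooled grip draw, independent of the MACS label, so that in
            # the grip-only design every other predictor is truly
            # uninformative about the APS
            grip = float(np.clip(rng.normal(0.55, 0.15), 0.05, 1.0))
            # non-grip predictors independent of both grip and APS: drawn
            # from an unrelated grip value, keeping realistic marginals
            clin = _clinical_from_grip(
                rng, float(np.clip(rng.normal(0.55, 0.15), 0.05, 1.0))
            )
            clin["grip_force"] = grip
            if coupling == "grip_only":
                base = 4.0 + config.aps_grip_beta * (1.0 - grip)
            else:
                base = 8.0
            for task in config.tasks:
                rows.append({
                    "subject": f"S{i:03d}", "macs": macs, "task": task,
                    "APS": float(base + rng.normal(0.0, config.aps_noise_sd)),
                    **clin,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file tree export


def write_cohort(
    bundle: CohortBundle, directory: str | Path, format: str = "trc"
) -> Path:
    """Write the cohort as a per-subject file tree plus clinical CSV,
    reference bank and ground-truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle.bank.save(directory / "reference_bank")
    bundle.clinical.to_csv(directory / "clinical.csv", index=False)
    truths = {}
    for sid, sub in bundle.subjects.items():
        sdir = directory / sid
        sdir.mkdir(exist_ok=True)
        write_marker_trial(sub["static"], sdir / f"static.{format}")
        for task, recs in sub["recordings"].items():
            for r, trial in enumerate(recs):
                write_marker_trial(trial, sdir / f"{task}_rec{r}.{format}")
        t = sub["truth"]
        truths[sid] = {
            "macs": t.macs, "grip": t.grip, "offsets": t.offsets,
            "slopes": t.slopes, "duration_factor": t.duration_factor,
            "events": t.events, "reach_frames": t.reach_frames,
            "clinical": t.clinical,
        }
    (directory / "ground_truth.json").write_text(json.dumps(truths, indent=2))
    return directory
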