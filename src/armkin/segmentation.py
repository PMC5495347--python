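"""Movement-repetition detection, occlusion filtering and selection.

The study protocol records each task four times within one recording and
collects two recordings per task (eight repetitions), marks each
repetition's start (hand resting on the ipsilateral knee) and end (point of
task achievement, PTA), excludes repetitions with marker occlusions on more
than 20% of the movement duration, and selects two repetitions per task.

The original events were picked manually in vendor software; this module
implements a reproducible surrogate based on the hand-centroid speed
profile: a repetition starts at the last frame the hand still rests in the
start zone before speed rises, and ends at the speed minimum of the
following dwell away from the start zone (the reach's endpoint); the return
phase is excluded. All thresholds are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from armkin.kinematics import lowpass_positions
from armkin.markers import MarkerTrajectorySet, occlusion_fraction

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RepetitionSegment:
    """One outbound movement repetition, ``[start, end]`` frames inclusive;
    ``end`` is the PTA frame."""

    task: str
    recording: str
    repetition: int
    start: int
    end: int
    occlusion: float = 0.0
    selected: bool = False
    #: sub-frame movement onset/settle estimates (speed-flank extrapolation);
    #: used for time normalization and duration when available
    start_exact: float | None = None
    end_exact: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("repetition must satisfy start < end")
        if not 0.0 <= self.occlusion <= 1.0:
            raise ValueError("occlusion fraction must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DetectionConfig:
    """Tunables of the surrogate event detector.

    ``speed_rise`` — fraction of the recording's peak hand speed that marks
    a movement bout; ``speed_rest`` — fraction below which the hand counts
    as resting when walking back to the repetition start; ``min_peak`` —
    absolute floor (m/s) under which a recording is treated as motionless;
    ``home_radius`` — start-zone radius (m) around the calibrated rest
    point; ``min_bout`` — minimum bout duration (s); ``lowpass_hz`` — hand
    trajectory smoothing cutoff.
    """

    speed_rise: float = 0.05
    speed_rest: float = 0.005
    min_peak: float = 0.05
    home_radius: float = 0.05
    min_bout: float = 0.15
    lowpass_hz: float = 6.0
    #: lighter smoothing for the sub-frame boundary fit (heavy smoothing
    #: shifts the apparent onset by a fixed absolute time)
    refine_lowpass_hz: float = 12.0


HAND_MARKERS = ("HAN1", "HAN2", "HAN3")


def hand_centroid(
    trial: MarkerTrajectorySet,
    markers: tuple[str, ...] = HAND_MARKERS,
    lowpass_hz: float | None = 6.0,
) -> np.ndarray:
    """Smoothed centroid of the hand markers, ``(frames, 3)`` (meters).

    The centroid over the visible subset is robust to single-marker noise
    and brief occlusions; remaining gaps are bridged linearly.
    """
    pts = np.stack([trial.get(m) for m in markers], axis=1)
    with np.errstate(invalid="ignore"):
        centroid = np.nanmean(pts, axis=1)
    if lowpass_hz is not None:
        centroid = lowpass_positions(centroid[:, None, :], trial.rate, lowpass_hz)[
            :, 0, :
        ]
    # bridge any all-occluded gaps so speed stays defined
    x = np.arange(trial.frames)
    for j in range(3):
        col = centroid[:, j]
        bad = ~np.isfinite(col)
        if bad.any() and not bad.all():
            col[bad] = np.interp(x[bad], x[~bad], col[~bad])
    return centroid


def _speed(path: np.ndarray, rate: float) -> np.ndarray:
    vel = np.gradient(path, axis=0) * rate
    return np.linalg.norm(vel, axis=1)


def _refine_bout(
    speed: np.ndarray, start: int, pta: int, vref: float
) -> tuple[float, float] | None:
    """Sub-frame movement onset/settle by minimum-jerk speed-profile fit.

    A point-to-point reach follows the minimum-jerk speed profile
    ``v(tau) = 16 v_p tau^2 (1 - tau)^2`` to good approximation; fitting
    that three-parameter model (onset, duration, peak) to the bout's
    supra-threshold speed samples localizes the movement boundaries with
    sub-frame precision, independent of sampling density and movement
    duration. Returns ``(onset, settle)`` in fractional frames, or None
    when the fit is degenerate.
    """
    from scipy.optimize import least_squares

    lo = max(start - 5, 0)
    hi = min(pta + 5, len(speed) - 1)
    t = np.arange(lo, hi + 1, dtype=float)
    v = speed[lo : hi + 1]
    m = np.isfinite(v) & (v >= 0.05 * vref)
    if m.sum() < 10:
        return None

    def resid(p: np.ndarray) -> np.ndarray:
        t_on, dur, vp = p
        tau = np.clip((t[m] - t_on) / dur, 0.0, 1.0)
        return 16.0 * vp * tau**2 * (1.0 - tau) ** 2 - v[m]

    try:
        fit = least_squares(
            resid,
            x0=[float(start), float(max(pta - start, 6)), vref],
            bounds=([lo - 20.0, 5.0, vref * 0.2],
                    [float(hi), (hi - lo) * 2.0, vref * 3.0]),
        )
    except Exception:
        return None
    t_on, dur, _ = fit.x
    t_off = t_on + dur
    if not (lo - 10 <= t_on < t_off <= hi + 10):
        return None
    return float(t_on), float(t_off)


def detect_repetitions(
    trial: MarkerTrajectorySet,
    task: str | None = None,
    config: DetectionConfig = DetectionConfig(),
    recording: str = "rec",
) -> list[RepetitionSegment]:
    """Find outbound repetitions in one dynamic recording.

    Returns one segment per reach, ordered; an empty list (with a warning
    log) when no movement is detected.
    """
    task = task or trial.task or "HTH"
    path = hand_centroid(trial, lowpass_hz=config.lowpass_hz)
    speed = _speed(path, trial.rate)
    vmax = float(np.nanmax(speed))
    if not np.isfinite(vmax) or vmax < config.min_peak:
        log.warning("no movement detected (peak speed %.3f m/s)", vmax)
        return []
    rise = config.speed_rise * vmax
    moving = speed >= rise
    # home position: rest frames before the first movement bout
    first_move = int(np.argmax(moving))
    home = np.median(path[: max(first_move, 1)], axis=0)
    near_home = np.linalg.norm(path - home, axis=1) <= config.home_radius
    # resting threshold for the start walk-back: the configured fraction of
    # peak speed, floored at twice the measured rest-noise speed
    rest_noise = float(np.median(speed[~moving])) if (~moving).any() else 0.0
    rest_thr = max(config.speed_rest * vmax, 2.0 * rest_noise)
    max_walkback = int(trial.rate)  # at most 1 s

    # contiguous movement bouts
    bounds = np.flatnonzero(np.diff(np.concatenate([[0], moving.astype(int), [0]])))
    bouts = [
        (int(bounds[i]), int(bounds[i + 1]) - 1)  # inclusive frame span
        for i in range(0, len(bounds), 2)
    ]
    min_len = int(config.min_bout * trial.rate)
    bouts = [b for b in bouts if b[1] - b[0] + 1 >= min_len]

    segments: list[RepetitionSegment] = []
    speed_refine: np.ndarray | None = None
    rep = 0
    for i, (b0, b1) in enumerate(bouts):
        if not near_home[max(b0 - 1, 0)]:
            continue  # bout does not leave the start zone: a return phase
        # walk back to the last truly resting frame
        start = b0
        while start > max(0, b0 - max_walkback) and speed[start - 1] > rest_thr:
            start -= 1
        start = max(start - 1, 0)
        # dwell between this bout and the next is the task endpoint; PTA is
        # the first frame there at which the hand has come to rest
        dwell_end = bouts[i + 1][0] - 1 if i + 1 < len(bouts) else trial.frames - 1
        dwell = np.arange(b1 + 1, dwell_end + 1)
        dwell = dwell[~near_home[dwell]] if len(dwell) else dwell
        if len(dwell) == 0:
            # reach with no resolvable dwell: take the bout's speed minimum
            # in its second half (endpoint deceleration)
            half = np.arange((b0 + b1) // 2, b1 + 1)
            pta = int(half[np.argmin(speed[half])])
        else:
            settled = dwell[speed[dwell] <= rest_thr]
            pta = int(settled[0]) if len(settled) else int(
                dwell[np.argmin(speed[dwell])]
            )
        if np.linalg.norm(path[pta] - home) <= config.home_radius:
            continue  # endpoint back at the start zone: not an outbound reach
        if pta <= start:
            continue
        # sub-frame refinement by minimum-jerk speed-profile fit
        if speed_refine is None:
            speed_refine = _speed(
                hand_centroid(trial, lowpass_hz=config.refine_lowpass_hz),
                trial.rate,
            )
        vbout = float(np.nanmax(speed_refine[b0 : b1 + 1]))
        refined = _refine_bout(speed_refine, start, pta, vbout)
        start_exact, end_exact = refined if refined else (None, None)
        rep += 1
        segments.append(
            RepetitionSegment(task=task, recording=recording, repetition=rep,
                              start=start, end=pta,
                              start_exact=start_exact, end_exact=end_exact)
        )
    if not segments:
        log.warning("no repetitions detected in recording %s", recording)
    return segments


def attach_occlusion(
    segments: list[RepetitionSegment],
    trial: MarkerTrajectorySet,
    markers: tuple[str, ...] | None = None,
) -> list[RepetitionSegment]:
    """Fill each segment's occlusion fraction (any required marker missing)."""
    if not segments:
        return []
    windows = [(s.start, s.end + 1) for s in segments]
    fracs = occlusion_fraction(trial, markers, windows)
    return [replace(s, occlusion=float(f)) for s, f in zip(segments, fracs)]


def filter_by_occlusion(
    segments: list[RepetitionSegment],
    trial: MarkerTrajectorySet | None = None,
    threshold: float = 0.20,
    markers: tuple[str, ...] | None = None,
) -> list[RepetitionSegment]:
    """Drop repetitions occluded on **more than** ``threshold`` of their
    duration (a fraction exactly at the threshold is retained).

    When ``trial`` is given the occlusion fractions are (re)computed from
    it; otherwise the fractions already attached to the segments are used.
    Idempotent, and never increases the segment count.
    """
    if trial is not None:
        segments = attach_occlusion(segments, trial, markers)
    kept = [s for s in segments if s.occlusion <= threshold]
    for s in segments:
        if s.occlusion > threshold:
            log.info(
                "repetition %s/%s excluded: occlusion %.0f%% > %.0f%%",
                s.recording, s.repetition, 100 * s.occlusion, 100 * threshold,
            )
    return kept


def select_repetitions(
    segments: list[RepetitionSegment], k: int = 2
) -> list[RepetitionSegment]:
    """Deterministic stand-in for the study's compliance-based selection:
    keep the ``k`` repetitions with the lowest occlusion fraction, ties
    broken by recording id then earliest repetition index.

    Returns all survivors (with a warning) when fewer than ``k`` remain;
    an empty input marks the task as missing for the subject.
    """
    if not segments:
        log.warning("no surviving repetitions: task missing for subject")
        return []
    ranked = sorted(segments, key=lambda s: (s.occlusion, s.recording, s.repetition))
    if len(ranked) < k:
        log.warning("only %d repetition(s) survive selection (wanted %d)",
                    len(ranked), k)
    chosen = ranked[:k]
    chosen_ids = {(s.recording, s.repetition) for s in chosen}
    return [
        replace(s, selected=(s.recording, s.repetition) in chosen_ids)
        for s in segments
        if (s.recording, s.repetition) in chosen_ids
    ]


def segments_to_table(segments: list[RepetitionSegment], subject: str = ""):
    """Tab-friendly table: subject task recording rep start end occl selected."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "subject": subject,
                "task": s.task,
                "recording": s.recording,
                "repetition": s.repetition,
                "start_frame": s.start,
                "end_frame": s.end,
                "occl_frac": s.occlusion,
                "selected": s.selected,
            }
            for s in segments
        ]
    )
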