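"""Per-repetition outcome measures: AVS/APS, spatiotemporal metrics, PTA, ROM.

The Arm Variable Score (AVS) of a joint-angle channel is the RMSE between
the child's time-normalized waveform and the corresponding waveform of a
typically-developing (TD) reference bank, compared point by point on a
common 0-100% movement-cycle grid; the Arm Profile Score (APS) is the mean
of the 13 AVS. Spatiotemporal parameters are movement duration, maximum
hand velocity, its timing (% of duration) and trajectory straightness
(hand-path length over start-to-end chord, >= 1). Endpoint (PTA) angles and
active ROM (max - min) come from the raw joint-angle time series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from armkin.kinematics import CHANNELS, JointAngleSeries
from armkin.markers import MarkerTrajectorySet
from armkin.segmentation import HAND_MARKERS, RepetitionSegment, hand_centroid


@dataclass
class ReferenceBank:
    """Per-task, per-channel bank of time-normalized TD reference waveforms.

    ``waveforms[task][channel]`` is an ``(N, P)`` array (degrees) of the N
    reference subjects on the P-point movement-cycle grid; ``mean`` caches
    the point-wise mean row.
    """

    waveforms: dict[str, dict[str, np.ndarray]]
    P: int = 101
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for task, chans in self.waveforms.items():
            for ch, arr in chans.items():
                arr = np.asarray(arr, float)
                if arr.ndim != 2 or arr.shape[1] != self.P:
                    raise ValueError(f"{task}/{ch}: expected (N, {self.P}) waveforms")
                chans[ch] = arr

    def n_subjects(self, task: str) -> int:
        return next(iter(self.waveforms[task].values())).shape[0]

    def mean(self, task: str, channel: str) -> np.ndarray:
        try:
            return self.waveforms[task][channel].mean(axis=0)
        except KeyError:
            raise KeyError(f"reference bank has no {task}/{channel} waveform") from None

    # -- persistence: one wide CSV per task + a JSON manifest ---------------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for task, chans in self.waveforms.items():
            rows = []
            for ch, arr in chans.items():
                for subj in range(arr.shape[0]):
                    rows.append([ch, subj] + list(arr[subj]))
            cols = ["channel", "subject"] + [f"p{i:03d}" for i in range(self.P)]
            pd.DataFrame(rows, columns=cols).to_csv(
                directory / f"reference_{task}.csv", index=False
            )
        manifest = {"P": self.P, "tasks": sorted(self.waveforms), **self.meta}
        (directory / "reference_manifest.json").write_text(
            json.dumps(manifest, indent=2)
        )
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceBank":
        directory = Path(directory)
        manifest = json.loads((directory / "reference_manifest.json").read_text())
        P = int(manifest["P"])
        waveforms: dict[str, dict[str, np.ndarray]] = {}
        for task in manifest["tasks"]:
            df = pd.read_csv(directory / f"reference_{task}.csv")
            pcols = [f"p{i:03d}" for i in range(P)]
            waveforms[task] = {
                ch: g.sort_values("subject")[pcols].to_numpy(float)
                for ch, g in df.groupby("channel")
            }
        meta = {k: v for k, v in manifest.items() if k not in ("P", "tasks")}
        return cls(waveforms=waveforms, P=P, meta=meta)


# ---------------------------------------------------------------------------
# time normalization and scoring


def time_normalize(
    angles: JointAngleSeries,
    segment: RepetitionSegment,
    P: int = 101,
) -> dict[str, np.ndarray]:
    """Resample each channel onto ``P`` equispaced points over the segment.

    Linear interpolation over frames ``start..end`` inclusive; endpoint
    preserving, so the 0% and 100% grid values equal the segment's first and
    last frame values. NaN gaps inside the segment (occluded frames) are
    bridged linearly; the repetition filter guarantees they cover at most
    20% of the duration.
    """
    if segment.end >= angles.frames:
        raise ValueError("segment extends past the angle series")
    if segment.n_frames < 2:
        raise ValueError("segment must span at least 2 frames")
    a = segment.start if segment.start_exact is None else segment.start_exact
    b = segment.end if segment.end_exact is None else segment.end_exact
    lo = max(int(np.floor(a)), 0)
    hi = min(int(np.ceil(b)), angles.frames - 1)
    src = np.arange(lo, hi + 1, dtype=float)
    grid = np.linspace(a, b, P)
    out: dict[str, np.ndarray] = {}
    for i, ch in enumerate(angles.channels):
        col = angles.values[lo : hi + 1, i]
        finite = np.isfinite(col)
        if finite.sum() < 2:
            out[ch] = np.full(P, np.nan)
            continue
        out[ch] = np.interp(grid, src[finite], col[finite])
    return out


def compute_avs(
    child: np.ndarray,
    bank: ReferenceBank,
    task: str,
    channel: str,
    mode: str = "mean_reference",
) -> float:
    """Arm Variable Score: RMSE of the child waveform against the TD bank.

    ``mode="mean_reference"`` (default) compares against the bank's
    point-wise mean waveform; ``mode="per_subject"`` averages the RMSE
    against every reference subject individually. Both readings of
    "comparison with the reference database" are provided; the mean-
    reference form mirrors the Gait Profile Score family.
    """
    child = np.asarray(child, float)
    ref = bank.waveforms.get(task, {}).get(channel)
    if ref is None:
        raise KeyError(f"reference bank has no {task}/{channel} waveform")
    if child.shape != (bank.P,):
        raise ValueError(f"child waveform must have {bank.P} points")
    if mode == "mean_reference":
        return float(np.sqrt(np.mean((child - ref.mean(axis=0)) ** 2)))
    if mode == "per_subject":
        return float(np.mean(np.sqrt(np.mean((child[None] - ref) ** 2, axis=1))))
    raise ValueError(f"unknown AVS mode {mode!r}")


def compute_aps(avs) -> float:
    """Arm Profile Score: the arithmetic mean of exactly 13 AVS values."""
    if isinstance(avs, dict):
        missing = [ch for ch in CHANNELS if ch not in avs]
        if missing or len(avs) != len(CHANNELS):
            raise ValueError(f"APS needs the 13 AVS channels (missing: {missing})")
        vals = np.array([avs[ch] for ch in CHANNELS], float)
    else:
        vals = np.asarray(avs, float)
        if vals.shape != (len(CHANNELS),):
            raise ValueError(f"APS needs exactly {len(CHANNELS)} AVS values, "
                             f"got {vals.size}")
    if not np.isfinite(vals).all():
        raise ValueError("APS input contains non-finite AVS values")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# spatiotemporal parameters


def compute_spatiotemporal(
    trial: MarkerTrajectorySet,
    segment: RepetitionSegment,
    hand_point: np.ndarray | None = None,
    lowpass_hz: float = 6.0,
) -> dict[str, float]:
    """Movement duration, maximum velocity, its timing and straightness.

    The hand point defaults to the centroid of the three hand markers,
    low-pass filtered (4th-order Butterworth, 6 Hz) before differentiation.
    Duration is ``(end - start) / rate`` seconds; timing of Vmax is the
    percentage of the duration at which the speed peaks; straightness is
    hand-path length divided by the start-to-end chord (>= 1; exactly 1 for
    a straight monotone reach).
    """
    if segment.n_frames < 2:
        raise ValueError("segment must span at least 2 frames")
    if hand_point is None:
        hand_point = hand_centroid(trial, HAND_MARKERS, lowpass_hz=lowpass_hz)
    vis = np.isfinite(hand_point[segment.start : segment.end + 1]).all(axis=1)
    if vis.mean() < 0.8:
        raise ValueError("hand point occluded on more than 20% of the segment")
    path = hand_point[segment.start : segment.end + 1]
    rate = trial.rate
    if segment.start_exact is not None and segment.end_exact is not None:
        duration = (segment.end_exact - segment.start_exact) / rate
    else:
        duration = (segment.end - segment.start) / rate
    vel = np.gradient(path, axis=0) * rate
    speed = np.linalg.norm(vel, axis=1)
    imax = int(np.nanargmax(speed))
    vmax = float(speed[imax])
    timing = 100.0 * imax / (segment.n_frames - 1)
    steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
    path_len = float(np.nansum(steps))
    chord = float(np.linalg.norm(path[-1] - path[0]))
    if chord < 1e-9:
        raise ValueError("zero start-to-end chord: straightness undefined")
    straightness = max(path_len / chord, 1.0)
    return {
        "duration": duration,
        "vmax": vmax,
        "timing_vmax": timing,
        "straightness": straightness,
    }


def extract_pta_and_rom(
    angles: JointAngleSeries, segment: RepetitionSegment
) -> tuple[dict[str, float], dict[str, float]]:
    """Endpoint (PTA) angle and active ROM per channel over the segment.

    PTA is the channel value at the segment's end frame (nearest finite
    sample if that frame is occluded); ROM is max - min over the segment.
    """
    if segment.end >= angles.frames:
        raise ValueError("segment extends past the angle series")
    pta: dict[str, float] = {}
    rom: dict[str, float] = {}
    for i, ch in enumerate(angles.channels):
        col = angles.values[segment.start : segment.end + 1, i]
        finite = np.isfinite(col)
        if not finite.any():
            pta[ch] = float("nan")
            rom[ch] = float("nan")
            continue
        if finite[-1]:
            pta[ch] = float(col[-1])
        else:
            pta[ch] = float(col[np.flatnonzero(finite)[-1]])
        rom[ch] = float(np.nanmax(col) - np.nanmin(col))
    return pta, rom


# ---------------------------------------------------------------------------
# per-repetition record assembly


def score_repetition(
    trial: MarkerTrajectorySet,
    angles: JointAngleSeries,
    segment: RepetitionSegment,
    bank: ReferenceBank,
    subject: str = "",
    avs_mode: str = "mean_reference",
) -> dict:
    """All outcome measures for one repetition, as a flat record row."""
    waves = time_normalize(angles, segment, P=bank.P)
    avs = {
        ch: compute_avs(waves[ch], bank, segment.task, ch, mode=avs_mode)
        for ch in CHANNELS
    }
    aps = compute_aps(avs)
    spatio = compute_spatiotemporal(trial, segment)
    pta, rom = extract_pta_and_rom(angles, segment)
    row = {
        "subject": subject,
        "task": segment.task,
        "recording": segment.recording,
        "repetition": segment.repetition,
        "APS": aps,
        **spatio,
    }
    row.update({f"AVS_{ch}": avs[ch] for ch in CHANNELS})
    row.update({f"PTA_{ch}": pta[ch] for ch in CHANNELS})
    row.update({f"ROM_{ch}": rom[ch] for ch in CHANNELS})
    return row


def aggregate_subject(rep_rows: pd.DataFrame) -> pd.DataFrame:
    """Per-subject task outcome: mean over the selected repetitions."""
    numeric = rep_rows.select_dtypes("number").columns.drop(
        ["repetition"], errors="ignore"
    )
    return (
        rep_rows.groupby(["subject", "task"], as_index=False)[list(numeric)]
        .mean()
    )
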