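"""Marker-trajectory containers and file I/O (TRC, CSV dialect, C3D).

Internal conventions
--------------------
* Positions are stored in **meters** in a right-handed lab frame with
  X anterior, Y vertical-up, Z to the subject's right.
* Occluded samples are stored as NaN; the boolean occlusion mask is derived
  (a sample is occluded iff any of its three coordinates is non-finite).
* Frames are 0-based; frame windows are half-open ``[start, stop)``.

File formats
------------
TRC
    Tab-separated Motion Analysis / OpenSim dialect: three header rows
    (``PathFileType``, the ``DataRate .. Units`` key row and its value row),
    a two-row label header, then one row per frame
    (``Frame# Time X1 Y1 Z1 ...``). Units may be mm or m; values are
    converted to meters on read. Occlusion is encoded as empty fields.
CSV
    The package dialect: header ``frame,time,<label>_x,<label>_y,<label>_z,...``
    with coordinates in meters and empty cells for occluded samples. A
    ``# rate=<Hz>`` comment line may precede the header; otherwise the rate
    is inferred from the time column.
C3D
    Binary industry standard, available only when the optional ``ezc3d``
    dependency is installed. mm -> m conversion on read, occlusion via
    negative residuals / NaN points per the de-facto convention.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

TASKS = ("HTH", "HTM", "RGV")

#: Dynamic (cluster) markers per segment; 3+3+4+4+3 = 17 markers total.
DEFAULT_SEGMENT_MARKERS: dict[str, tuple[str, ...]] = {
    "trunk": ("TRU1", "TRU2", "TRU3"),
    "scapula": ("ACR1", "ACR2", "ACR3"),
    "humerus": ("HUM1", "HUM2", "HUM3", "HUM4"),
    "forearm": ("FOR1", "FOR2", "FOR3", "FOR4"),
    "hand": ("HAN1", "HAN2", "HAN3"),
}

#: Anatomical landmark markers, present only in the static calibration
#: trial, mapped to the segment whose frame they define.
DEFAULT_LANDMARKS: dict[str, str] = {
    "IJ": "trunk",   # incisura jugularis
    "C7": "trunk",
    "T8": "trunk",
    "AA": "scapula",  # acromial angle
    "AI": "scapula",  # angulus inferior
    "PC": "scapula",  # processus coracoideus
    "GH": "humerus",  # glenohumeral centre (static surrogate marker)
    "EL": "humerus",  # lateral epicondyle
    "EM": "humerus",  # medial epicondyle
    "OLE": "forearm",  # olecranon
    "WRU": "forearm",  # ulnar styloid
    "WRR": "forearm",  # radial styloid
    "CAP": "hand",    # capitate
    "MC2": "hand",    # 2nd metacarpal head
    "MC5": "hand",    # 5th metacarpal head
}


class MarkerValidationError(ValueError):
    """A trial does not satisfy the marker-set contract."""


class MarkerFormatError(ValueError):
    """A marker file could not be parsed under the named standard."""


@dataclass(frozen=True)
class MarkerSetDefinition:
    """The study marker set: five segment clusters plus static-only landmarks.

    Parameters
    ----------
    segments
        Ordered marker labels per segment (trunk 3, acromion cluster 3,
        humerus 4, forearm 4, hand 3 — 17 dynamic markers in total).
    anatomical_landmarks
        Labels identified only in the static trial, mapped to their segment.
    side
        ``"left"`` or ``"right"`` — the impaired side captured by the trial.
        Left-side trials are mirrored about the sagittal plane before frame
        construction so one sign convention serves the whole cohort.
    """

    segments: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_MARKERS)
    )
    anatomical_landmarks: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_LANDMARKS)
    )
    side: str = "right"

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise MarkerValidationError(f"side must be left/right, got {self.side!r}")
        dyn = self.dynamic_labels
        if len(dyn) != len(set(dyn)):
            raise MarkerValidationError("duplicate dynamic marker labels")
        if len(dyn) != 17:
            raise MarkerValidationError(
                f"marker set must contain 17 dynamic markers, got {len(dyn)}"
            )
        for lm, seg in self.anatomical_landmarks.items():
            if seg not in self.segments:
                raise MarkerValidationError(
                    f"landmark {lm!r} maps to unknown segment {seg!r}"
                )
            if lm in dyn:
                raise MarkerValidationError(
                    f"landmark {lm!r} duplicates a dynamic marker label"
                )

    @property
    def dynamic_labels(self) -> tuple[str, ...]:
        return tuple(l for labels in self.segments.values() for l in labels)

    @property
    def static_labels(self) -> tuple[str, ...]:
        return self.dynamic_labels + tuple(self.anatomical_landmarks)

    def landmarks_of(self, segment: str) -> tuple[str, ...]:
        return tuple(
            lm for lm, seg in self.anatomical_landmarks.items() if seg == segment
        )


DEFAULT_MARKER_SET = MarkerSetDefinition()


@dataclass
class MarkerTrajectorySet:
    """Time-indexed 3D marker positions with occlusion encoded as NaN.

    ``positions`` has shape ``(frames, n_markers, 3)`` in meters; column
    order follows ``labels``.
    """

    labels: tuple[str, ...]
    positions: np.ndarray
    rate: float = 100.0
    trial_kind: str = "dynamic"
    task: str | None = None

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise MarkerValidationError("positions must have shape (frames, markers, 3)")
        if self.positions.shape[1] != len(self.labels):
            raise MarkerValidationError("positions second axis must match labels")
        if self.rate <= 0:
            raise MarkerValidationError("sampling rate must be positive")
        if self.trial_kind not in ("static", "dynamic"):
            raise MarkerValidationError(f"bad trial_kind {self.trial_kind!r}")
        if self.task is not None and self.task not in TASKS:
            raise MarkerValidationError(f"unknown task {self.task!r}")
        # an occluded sample must not carry partial coordinates
        partial = np.isfinite(self.positions).any(axis=2) & ~np.isfinite(
            self.positions
        ).all(axis=2)
        if partial.any():
            self.positions[partial] = np.nan

    @property
    def frames(self) -> int:
        return self.positions.shape[0]

    @property
    def occlusion_mask(self) -> np.ndarray:
        """Boolean ``(frames, markers)``; True where the sample is missing."""
        return ~np.isfinite(self.positions).all(axis=2)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.frames) / self.rate

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise MarkerValidationError(f"marker {label!r} not in trial") from None

    def get(self, label: str) -> np.ndarray:
        """Positions of one marker, shape ``(frames, 3)``."""
        return self.positions[:, self.index_of(label), :]

    def validate_against(self, markerset: MarkerSetDefinition) -> None:
        """Check every required label is present and not fully occluded."""
        required = (
            markerset.static_labels
            if self.trial_kind == "static"
            else markerset.dynamic_labels
        )
        for label in required:
            if label not in self.labels:
                raise MarkerValidationError(f"required marker {label!r} missing")
            if self.occlusion_mask[:, self.index_of(label)].all():
                raise MarkerValidationError(f"marker {label!r} is fully occluded")

    def mirrored(self) -> "MarkerTrajectorySet":
        """Reflect about the sagittal (X-Y) plane: z -> -z."""
        pos = self.positions.copy()
        pos[:, :, 2] *= -1.0
        return replace(self, positions=pos)


# ---------------------------------------------------------------------------
# occlusion accounting


def occlusion_fraction(
    trial: MarkerTrajectorySet,
    markers: tuple[str, ...] | list[str] | None = None,
    windows: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Fraction of frames, per window, in which **any** listed marker is occluded.

    ``windows`` are half-open ``[start, stop)`` frame ranges; the default is
    the whole trial. Used by the repetition filter that drops repetitions
    with occlusions on more than 20% of the movement duration.
    """
    if markers is None:
        markers = trial.labels
    idx = [trial.index_of(m) for m in markers]
    any_occluded = trial.occlusion_mask[:, idx].any(axis=1)
    if windows is None:
        windows = [(0, trial.frames)]
    out = np.empty(len(windows))
    for i, (start, stop) in enumerate(windows):
        if not (0 <= start < stop <= trial.frames):
            raise ValueError(f"window [{start}, {stop}) empty or outside trial")
        out[i] = any_occluded[start:stop].mean()
    return out


# ---------------------------------------------------------------------------
# TRC


def _write_trc(trial: MarkerTrajectorySet, path: Path) -> None:
    n, m = trial.frames, len(trial.labels)
    with open(path, "w", newline="") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{trial.rate:g}\t{trial.rate:g}\t{n}\t{m}\tm\t{trial.rate:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(trial.labels) + "\t\t\t\n")
        fh.write(
            "\t\t"
            + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(m))
            + "\n"
        )
        for f in range(n):
            cells = [str(f + 1), f"{f / trial.rate:.6f}"]
            for j in range(m):
                p = trial.positions[f, j]
                if np.isfinite(p).all():
                    cells.extend(f"{c:.9f}" for c in p)
                else:
                    cells.extend(["", "", ""])
            fh.write("\t".join(cells) + "\n")


def _read_trc(path: Path) -> MarkerTrajectorySet:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise MarkerFormatError(f"{path}: not a TRC file")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    meta = dict(zip(keys, vals))
    try:
        rate = float(meta["DataRate"])
        units = meta.get("Units", "mm")
    except (KeyError, ValueError) as exc:
        raise MarkerFormatError(f"{path}: bad TRC header") from exc
    label_row = lines[3].split("\t")
    labels = tuple(l for l in label_row[2:] if l)
    scale = {"mm": 1e-3, "m": 1.0}.get(units)
    if scale is None:
        raise MarkerFormatError(f"{path}: unsupported TRC units {units!r}")
    rows = []
    for line in lines[5:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        vals3 = cells[2 : 2 + 3 * len(labels)]
        vals3 += [""] * (3 * len(labels) - len(vals3))
        rows.append([float(c) if c.strip() else np.nan for c in vals3])
    if not rows:
        raise MarkerFormatError(f"{path}: TRC file has no data rows")
    pos = np.asarray(rows).reshape(len(rows), len(labels), 3) * scale
    return MarkerTrajectorySet(labels=labels, positions=pos, rate=rate)


# ---------------------------------------------------------------------------
# CSV dialect


def _write_csv(trial: MarkerTrajectorySet, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# rate={trial.rate:g}\n")
        writer = _csv.writer(fh)
        header = ["frame", "time"]
        for label in trial.labels:
            header += [f"{label}_x", f"{label}_y", f"{label}_z"]
        writer.writerow(header)
        for f in range(trial.frames):
            row: list[object] = [f, f"{f / trial.rate:.6f}"]
            for j in range(len(trial.labels)):
                p = trial.positions[f, j]
                row += [f"{c:.9f}" for c in p] if np.isfinite(p).all() else ["", "", ""]
            writer.writerow(row)


def _read_csv(path: Path) -> MarkerTrajectorySet:
    rate = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# rate="):
            rate = float(first.split("=", 1)[1])
            header_line = fh.readline()
        else:
            header_line = first
        header = next(_csv.reader([header_line]))
        if header[:2] != ["frame", "time"] or (len(header) - 2) % 3:
            raise MarkerFormatError(f"{path}: not the documented CSV dialect")
        labels = tuple(h[:-2] for h in header[2::3])
        for h, label in zip(header[2:], [l for l in labels for _ in range(3)]):
            if not h.startswith(label + "_"):
                raise MarkerFormatError(f"{path}: inconsistent coordinate columns")
        rows, times = [], []
        for cells in _csv.reader(fh):
            if not cells:
                continue
            times.append(float(cells[1]))
            vals = cells[2:]
            vals += [""] * (3 * len(labels) - len(vals))
            rows.append([float(c) if c.strip() else np.nan for c in vals])
    if not rows:
        raise MarkerFormatError(f"{path}: CSV file has no data rows")
    if rate is None:
        if len(times) < 2:
            raise MarkerFormatError(f"{path}: cannot infer rate from a single frame")
        rate = 1.0 / float(np.median(np.diff(times)))
    pos = np.asarray(rows).reshape(len(rows), len(labels), 3)
    return MarkerTrajectorySet(labels=labels, positions=pos, rate=rate)


# ---------------------------------------------------------------------------
# C3D (optional dependency)


def _require_ezc3d():
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise MarkerFormatError(
            "C3D support requires the optional 'ezc3d' dependency "
            "(pip install armkin[c3d]); TRC and CSV need no extras"
        ) from exc
    return ezc3d


def _read_c3d(path: Path) -> MarkerTrajectorySet:  # pragma: no cover
    ezc3d = _require_ezc3d()
    c3d = ezc3d.c3d(str(path))
    labels = tuple(c3d["parameters"]["POINT"]["LABELS"]["value"])
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    pts = c3d["data"]["points"]  # (4, markers, frames), mm
    residuals = c3d["data"].get("meta_points", {}).get("residuals")
    pos = np.transpose(pts[:3], (2, 1, 0)) * 1e-3
    if residuals is not None:
        occluded = residuals[0].T < 0
        pos[occluded] = np.nan
    return MarkerTrajectorySet(labels=labels, positions=pos, rate=rate)


def _write_c3d(trial: MarkerTrajectorySet, path: Path) -> None:  # pragma: no cover
    ezc3d = _require_ezc3d()
    c3d = ezc3d.c3d()
    c3d["parameters"]["POINT"]["RATE"]["value"] = [trial.rate]
    c3d["parameters"]["POINT"]["LABELS"]["value"] = list(trial.labels)
    pts = np.zeros((4, len(trial.labels), trial.frames))
    pts[:3] = np.transpose(trial.positions, (2, 1, 0)) * 1e3
    pts[3] = 1.0
    residuals = np.zeros((1, len(trial.labels), trial.frames))
    residuals[0][trial.occlusion_mask.T] = -1.0
    pts[:3, :, :][:, trial.occlusion_mask.T] = 0.0
    c3d["data"]["points"] = pts
    c3d["data"]["meta_points"]["residuals"] = residuals
    c3d.write(str(path))


# ---------------------------------------------------------------------------
# public API

_FORMATS = {"trc": (_read_trc, _write_trc), "csv": (_read_csv, _write_csv),
            "c3d": (_read_c3d, _write_c3d)}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise MarkerFormatError(f"unsupported marker format {fmt!r}")
    return fmt


def read_marker_trial(
    path: str | Path,
    format: str | None = None,
    markerset: MarkerSetDefinition | None = None,
    trial_kind: str = "dynamic",
    task: str | None = None,
) -> MarkerTrajectorySet:
    """Read a marker trial, converting coordinates to meters.

    When ``markerset`` is given the trial is validated against it: every
    required label must be present (17 dynamic markers, plus the anatomical
    landmarks for a static trial) and not fully occluded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    trial = _FORMATS[fmt][0](path)
    trial.trial_kind = trial_kind
    trial.task = task
    trial.__post_init__()
    if markerset is not None:
        trial.validate_against(markerset)
    return trial


def write_marker_trial(
    trial: MarkerTrajectorySet, path: str | Path, format: str | None = None
) -> Path:
    """Write a trial; ``read_marker_trial`` round-trips it losslessly
    (to format precision), including the occlusion mask."""
    if trial.frames == 0:
        raise MarkerValidationError("refusing to write a 0-frame trial")
    path = Path(path)
    fmt = _infer_format(path, format)
    _FORMATS[fmt][1](trial, path)
    return path
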