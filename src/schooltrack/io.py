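"""File formats, configuration and provenance.

All artifacts are plain CSV with ``#``-prefixed provenance comment
lines (tool version, config hash, seed) so every output can be traced
back to the run that produced it.  Angles are serialized in radians
wrapped to ``[0, 2*pi)``; the image ``y`` axis increases downward.

Formats
-------
Detections : ``frame,x_min,y_min,x_max,y_max,cx,cy,px,py,theta`` —
    header mandatory; ``cx..theta`` may be empty, in which case the
    centroid/angle are computed downstream from patches or box centers
    and the record is flagged.
Trajectories : ``track_id,frame,x,y,theta,interpolated``.
Merge log : ``kept_id,absorbed_id,t_end,t_start,dist``.
Occlusion events : ``start_frame,end_frame,participants,detected``
    (participants ``;``-separated).
Config : YAML mapping with only known keys; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import BoundingBox, HeadDetection, wrap_angle
from .metrics import OcclusionEvent
from .simulate import SimConfig
from .trajectory import TrackerConfig, TrajectorySet

DETECTION_COLUMNS = [
    "frame", "x_min", "y_min", "x_max", "y_max", "cx", "cy", "px", "py", "theta",
]
FLOAT_FMT = "%.10g"


def _version() -> str:
    from . import __version__

    return __version__


def config_hash(config) -> str:
    """Short stable hash of a config dataclass (provenance stamp)."""
    if dataclasses.is_dataclass(config):
        payload = dataclasses.asdict(config)
    else:
        payload = dict(config)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(config=None, seed=None, extra: dict | None = None) -> list[str]:
    lines = [f"# schooltrack {_version()}"]
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return lines


def _write_csv(df: pd.DataFrame, path, header_lines: list[str]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


# -- detections ------------------------------------------------------


def write_detections(
    detections: dict[int, list[HeadDetection]], path, config=None, seed=None
) -> None:
    rows = []
    for frame in sorted(detections):
        for d in detections[frame]:
            b = d.bbox
            tip = d.tip or (math.nan, math.nan)
            rows.append(
                (
                    frame, b.x_min, b.y_min, b.x_max, b.y_max,
                    d.centroid[0], d.centroid[1], tip[0], tip[1], d.angle,
                )
            )
    df = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    _write_csv(df, path, provenance_header(config, seed))


class DetectionFormatError(ValueError):
    """Malformed detection file, with offending line numbers."""


def read_detections(path) -> tuple[dict[int, list[HeadDetection]], bool]:
    """Read a detection CSV grouped by ascending frame.

    Returns ``(per_frame_lists, complete)`` where ``complete`` is False
    when any record lacked centroid/angle fields (those records fall
    back to the box center and an angle of 0 and should be recomputed
    from patches upstream when available).

    Malformed rows are reported with their 1-based line numbers in the
    file (comments and header included in the count).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header_line = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                header_line = lineno
                cols = [c.strip() for c in line.strip().split(",")]
                break
        else:
            raise DetectionFormatError(f"{path}: no header found")
    required = DETECTION_COLUMNS[:5]
    missing = [c for c in required if c not in cols]
    if missing:
        raise DetectionFormatError(
            f"{path}: missing required columns: {', '.join(missing)}"
        )
    df = pd.read_csv(path, comment="#")
    bad_lines = []
    out: dict[int, list[HeadDetection]] = {}
    complete = True
    for i, row in df.iterrows():
        lineno = header_line + 1 + int(i)
        try:
            frame = int(row["frame"])
            bbox = BoundingBox(
                float(row["x_min"]), float(row["y_min"]),
                float(row["x_max"]), float(row["y_max"]), frame=frame,
            )
            if _has(row, "cx") and _has(row, "cy"):
                centroid = (float(row["cx"]), float(row["cy"]))
            else:
                centroid = bbox.center
                complete = False
            theta = float(row["theta"]) if _has(row, "theta") else 0.0
            if not _has(row, "theta"):
                complete = False
            tip = (
                (float(row["px"]), float(row["py"]))
                if _has(row, "px") and _has(row, "py")
                else None
            )
            det = HeadDetection(
                centroid=centroid, angle=wrap_angle(theta), bbox=bbox,
                frame=frame, tip=tip,
            )
        except (ValueError, KeyError):
            bad_lines.append(lineno)
            continue
        out.setdefault(frame, []).append(det)
    if bad_lines:
        raise DetectionFormatError(
            f"{path}: malformed rows at line(s) {', '.join(map(str, bad_lines))}"
        )
    return {f: out[f] for f in sorted(out)}, complete


def _has(row, col) -> bool:
    return col in row.index and pd.notna(row[col])


# -- trajectories ----------------------------------------------------


def write_trajectories(
    trajectories: TrajectorySet | pd.DataFrame, path, config=None, seed=None
) -> None:
    df = (
        trajectories.to_dataframe()
        if isinstance(trajectories, TrajectorySet)
        else trajectories
    )
    _write_csv(df, path, provenance_header(config, seed))


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"track_id", "frame", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise DetectionFormatError(
            f"{path}: missing required columns: {', '.join(sorted(missing))}"
        )
    return df


def write_ground_truth(gt: pd.DataFrame, path, config=None, seed=None) -> None:
    _write_csv(gt, path, provenance_header(config, seed))


def read_ground_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"fish_id", "frame", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise DetectionFormatError(
            f"{path}: missing required columns: {', '.join(sorted(missing))}"
        )
    return df


def write_merge_log(trajectories: TrajectorySet, path, config=None, seed=None) -> None:
    _write_csv(trajectories.merge_log(), path, provenance_header(config, seed))


# -- occlusion events ------------------------------------------------


def write_occlusions(events: list[OcclusionEvent], path, config=None, seed=None) -> None:
    rows = [
        (
            e.start_frame, e.end_frame,
            ";".join(str(p) for p in sorted(e.participants)),
            "" if e.detected is None else int(e.detected),
        )
        for e in events
    ]
    df = pd.DataFrame(
        rows, columns=["start_frame", "end_frame", "participants", "detected"]
    )
    _write_csv(df, path, provenance_header(config, seed))


def read_occlusions(path) -> list[OcclusionEvent]:
    df = pd.read_csv(path, comment="#")
    events = []
    for _, row in df.iterrows():
        detected = row.get("detected")
        events.append(
            OcclusionEvent(
                int(row["start_frame"]),
                int(row["end_frame"]),
                frozenset(int(p) for p in str(row["participants"]).split(";")),
                None if pd.isna(detected) else bool(int(detected)),
            )
        )
    return events


# -- run configuration -----------------------------------------------

_TRACKER_KEYS = {f.name for f in dataclasses.fields(TrackerConfig)}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)}
_METRIC_KEYS = {"radius", "separation_px", "odr_within"}

METRIC_DEFAULTS = {"radius": 15.0, "separation_px": 20.0, "odr_within": 1}


@dataclasses.dataclass
class RunConfig:
    """Full pipeline configuration: tracker + simulator + metrics.

    Every key has a documented default; the defaults reproduce the
    tracker's reference constants (R diag 24.1/24.8/22.7 px^2, dedup
    threshold 0.4, correctness radius 15 px, grid overlap 30 px).
    """

    tracker: TrackerConfig = dataclasses.field(default_factory=TrackerConfig)
    simulate: SimConfig = dataclasses.field(default_factory=SimConfig)
    metrics: dict = dataclasses.field(default_factory=lambda: dict(METRIC_DEFAULTS))
    dedup_threshold: float = 0.4
    grid_overlap_px: int = 30

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        unknown = set(data) - {"tracker", "simulate", "metrics",
                               "dedup_threshold", "grid_overlap_px"}
        if unknown:
            raise ValueError(f"unknown config section(s): {', '.join(sorted(unknown))}")
        tr = dict(data.get("tracker") or {})
        if bad := set(tr) - _TRACKER_KEYS:
            raise ValueError(f"unknown tracker key(s): {', '.join(sorted(bad))}")
        sim = dict(data.get("simulate") or {})
        if bad := set(sim) - _SIM_KEYS:
            raise ValueError(f"unknown simulate key(s): {', '.join(sorted(bad))}")
        met = dict(METRIC_DEFAULTS)
        user_met = dict(data.get("metrics") or {})
        if bad := set(user_met) - _METRIC_KEYS:
            raise ValueError(f"unknown metrics key(s): {', '.join(sorted(bad))}")
        met.update(user_met)
        if "r_diag" in tr:
            tr["r_diag"] = tuple(tr["r_diag"])
        for key in ("tank", "measurement_noise"):
            if key in sim and isinstance(sim[key], list):
                sim[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in sim[key]
                )
        return cls(
            tracker=TrackerConfig(**tr),
            simulate=SimConfig(**sim),
            metrics=met,
            dedup_threshold=float(data.get("dedup_threshold", 0.4)),
            grid_overlap_px=int(data.get("grid_overlap_px", 30)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, tuple):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        d = {
            "tracker": {
                k: clean(v) for k, v in dataclasses.asdict(self.tracker).items()
            },
            "simulate": {
                k: clean(v) for k, v in dataclasses.asdict(self.simulate).items()
            },
            "metrics": dict(self.metrics),
            "dedup_threshold": self.dedup_threshold,
            "grid_overlap_px": self.grid_overlap_px,
        }
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
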