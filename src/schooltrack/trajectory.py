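"""Track lifecycle: creation, per-frame stepping, interruption and
distance-gated reconnection of fragmented trajectories.

Per frame the tracker (i) predicts every live track one step ahead,
(ii) associates predictions with the frame's detections one-to-one, and
(iii) updates matched tracks while letting unmatched ones coast on
prediction.  A track that goes unmatched for ``beta`` consecutive frames
is *interrupted*: its trailing coasted points are trimmed and its last
observed position/time is stored as a tau endpoint.  Detections that no
track claims spawn new tracks, whose birth position/time is stored as a
rho endpoint.  After the whole stream is processed, interrupted
trajectories are reconnected to later-starting ones whose start lies
within a distance threshold ``d`` of the interruption point, walking
interruptions in ascending end-time order and giving each the nearest
unclaimed candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kalman
from .association import build_cost_matrix, solve_assignment
from .geometry import HeadDetection
from .kalman import KalmanState, MotionModel, Observation


@dataclass(frozen=True)
class TrackerConfig:
    """All tracking knobs in one place.

    beta : consecutive unassigned frames before a trajectory is
        interrupted (default 15: occlusions longer than about 15 frames
        carry a high identity-swap risk, so coasting further is not
        worth it).
    d : reconnection distance threshold in pixels; ``0`` disables
        reconnection entirely.
    w1, w2 : cost-function weights (position, angle modulation).
    gate : maximum association cost; matches above it are rejected.
    q, dt, r_diag : Kalman process-noise intensity, frame interval and
        observation-noise variances.
    confirm_frames : a new track must be re-matched within its first
        ``confirm_frames`` frames or it is discarded as a spurious
        detection; ``1`` confirms immediately.
    max_gap : maximum temporal gap (frames) a reconnection may bridge.
    interpolate_gaps : linearly fill reconnected gaps with rows flagged
        as interpolated.
    smooth_birth : retrodict a track's birth point with a one-step
        fixed-interval smoother once the track is confirmed, so the
        first reported position is a posterior estimate rather than the
        raw (noisier) first measurement.
    """

    beta: float = 15
    d: float = 50.0
    w1: float = 1.0
    w2: float = 1.0
    gate: float = 50.0
    q: float = 1.0
    dt: float = 1.0
    r_diag: tuple[float, float, float] = kalman.R_DEFAULT_DIAG
    confirm_frames: int = 2
    max_gap: float = math.inf
    interpolate_gaps: bool = True
    smooth_birth: bool = True

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.d < 0:
            raise ValueError("d must be >= 0")

    def motion_model(self) -> MotionModel:
        return kalman.default_model(dt=self.dt, q=self.q, r_diag=self.r_diag)


@dataclass(frozen=True)
class TrajectoryEndpoint:
    """Stored endpoint of a trajectory: an interruption (tau, kind
    ``"end"``) or a birth (rho, kind ``"start"``)."""

    kind: str  # "end" | "start"
    x: float
    y: float
    t: int
    track_id: int

    def __post_init__(self) -> None:
        if self.kind not in ("end", "start"):
            raise ValueError("endpoint kind must be 'end' or 'start'")


def endpoint_distance(tau: TrajectoryEndpoint, rho: TrajectoryEndpoint) -> float:
    """Euclidean distance between an interruption end and a track start."""
    if tau.kind != "end" or rho.kind != "start":
        raise ValueError("expected an 'end' endpoint and a 'start' endpoint")
    return math.hypot(tau.x - rho.x, tau.y - rho.y)


@dataclass
class Track:
    """One fish trajectory under construction."""

    id: int
    kstate: KalmanState
    points: list[tuple[int, float, float, float, bool]] = field(default_factory=list)
    status: str = "active"  # active | interrupted | closed | discarded
    misses: int = 0
    hits: int = 1
    predicted: KalmanState | None = None
    birth_state: KalmanState | None = None  # kept until the birth point is smoothed

    @property
    def last_observed(self) -> tuple[int, float, float, float, bool]:
        for p in reversed(self.points):
            if not p[4]:
                return p
        return self.points[0]

    def trim_coasted(self) -> None:
        """Drop trailing predicted-only points (unconfirmed coasting)."""
        while self.points and self.points[-1][4]:
            self.points.pop()


@dataclass(frozen=True)
class TrajectorySet:
    """Finalized per-fish trajectories plus the reconnection merge log."""

    tracks: tuple[Track, ...]
    merges: tuple[tuple[int, int, int, int, float], ...] = ()
    # merge rows: (kept_id, absorbed_id, t_end, t_start, dist)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            for (t, x, y, th, interp) in tr.points:
                rows.append((tr.id, t, x, y, th, interp))
        df = pd.DataFrame(
            rows, columns=["track_id", "frame", "x", "y", "theta", "interpolated"]
        )
        return df.sort_values(["track_id", "frame"], ignore_index=True)

    def merge_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.merges),
            columns=["kept_id", "absorbed_id", "t_end", "t_start", "dist"],
        )

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)


class Tracker:
    """Stateful per-frame tracking engine; use :func:`run` for streams."""

    def __init__(self, config: TrackerConfig | None = None) -> None:
        self.config = config or TrackerConfig()
        self.model = self.config.motion_model()
        self.tracks: list[Track] = []
        self.taus: list[TrajectoryEndpoint] = []
        self.rhos: list[TrajectoryEndpoint] = []
        self._next_id = 0

    # -- lifecycle ---------------------------------------------------

    def _spawn(self, det: HeadDetection, frame: int) -> None:
        obs = Observation(z=[det.centroid[0], det.centroid[1], det.angle], frame=frame)
        state = kalman.init_state(obs, self.model)
        tr = Track(id=self._next_id, kstate=state, birth_state=state)
        tr.points.append((frame, det.centroid[0], det.centroid[1], det.angle, False))
        self._next_id += 1
        self.tracks.append(tr)
        self.rhos.append(
            TrajectoryEndpoint("start", det.centroid[0], det.centroid[1], frame, tr.id)
        )

    def _interrupt(self, tr: Track) -> None:
        tr.trim_coasted()
        t, x, y, _, _ = tr.last_observed
        tr.status = "interrupted"
        self.taus.append(TrajectoryEndpoint("end", x, y, t, tr.id))

    def _smooth_birth_point(self, tr: Track) -> None:
        """One-step fixed-interval smoothing of the spawn point.

        The birth point as reported at spawn is the raw first
        measurement; once the next frame's update exists, the standard
        smoother step x0|1 = x0|0 + C (x1|1 - x1|0) with
        C = P0 F' (F P0 F' + Q)^-1 retrodicts it, roughly halving its
        error variance.
        """
        s0 = tr.birth_state
        pred = tr.predicted  # x1|0, P1|0 (from this frame's predict)
        post = tr.kstate  # x1|1
        F = self.model.F
        try:
            C = np.linalg.solve(pred.P.T, (s0.P @ F.T).T).T
        except np.linalg.LinAlgError:
            return
        dx = post.x - pred.x
        dx[2] = kalman.angle_difference(post.angle, pred.angle)
        x0 = s0.x + C @ dx
        t0, _, _, _, interp = tr.points[0]
        tr.points[0] = (
            t0, float(x0[0]), float(x0[1]), float(np.mod(x0[2], 2.0 * np.pi)),
            interp,
        )

    def _discard(self, tr: Track) -> None:
        tr.status = "discarded"
        self.rhos = [r for r in self.rhos if r.track_id != tr.id]

    # -- per-frame step ----------------------------------------------

    def step(self, detections: list[HeadDetection], frame: int) -> None:
        """Advance one frame: predict, associate, update, spawn/retire.

        All detections must carry the same frame index (deduplicate them
        first); ``detections`` may be empty for a blank frame.
        """
        if any(d.frame != frame for d in detections):
            raise ValueError("detections from mixed frames in one step")
        live = [t for t in self.tracks if t.status == "active"]
        for tr in live:
            tr.predicted = kalman.predict(tr.kstate, self.model)
        predicted = [
            (t.predicted.x[0], t.predicted.x[1], t.predicted.angle) for t in live
        ]
        cm = build_cost_matrix(predicted, detections, self.config.w1, self.config.w2)
        assn = solve_assignment(cm, gate=self.config.gate)

        for i, j in assn.pairs:
            tr, det = live[i], detections[j]
            obs = Observation(
                z=[det.centroid[0], det.centroid[1], det.angle], frame=frame
            )
            tr.kstate = kalman.update(tr.predicted, obs, self.model)
            tr.misses = 0
            tr.hits += 1
            # store the filtered estimate, not the raw measurement: the
            # posterior is the tracker's best state for this frame
            tr.points.append(
                (frame, tr.kstate.x[0], tr.kstate.x[1], tr.kstate.angle, False)
            )
            if (
                self.config.smooth_birth
                and tr.birth_state is not None
                and len(tr.points) == 2
            ):
                self._smooth_birth_point(tr)
            tr.birth_state = None
        for i in assn.unmatched_sources:
            tr = live[i]
            tr.misses += 1
            if tr.hits < self.config.confirm_frames:
                # unconfirmed single-detection track: treat as spurious
                self._discard(tr)
                continue
            tr.kstate = tr.predicted
            tr.points.append(
                (frame, tr.kstate.x[0], tr.kstate.x[1], tr.kstate.angle, True)
            )
            if tr.misses >= self.config.beta:
                self._interrupt(tr)
        for j in assn.unmatched_targets:
            self._spawn(detections[j], frame)

    # -- finalization ------------------------------------------------

    def finalize(self) -> TrajectorySet:
        """Close open tracks, reconnect fragments, return trajectories."""
        for tr in self.tracks:
            if tr.status == "active":
                if tr.hits < self.config.confirm_frames and len(tr.points) <= 1:
                    self._discard(tr)
                    continue
                tr.trim_coasted()
                tr.status = "closed"
        merges = reconnect(
            self.taus,
            self.rhos,
            self.config.d,
            max_gap=self.config.max_gap,
        )
        kept = _apply_merges(
            [t for t in self.tracks if t.status != "discarded"],
            merges,
            interpolate=self.config.interpolate_gaps,
        )
        return TrajectorySet(tuple(kept), tuple(merges))


def reconnect(
    interrupted: list[TrajectoryEndpoint],
    started: list[TrajectoryEndpoint],
    d: float,
    max_gap: float = math.inf,
) -> list[tuple[int, int, int, int, float]]:
    """Pair interruption endpoints with later track starts.

    Interruptions are processed in ascending end-time order; each takes
    the not-yet-claimed start with minimal Euclidean distance among
    those strictly closer than ``d`` that begin strictly after the
    interruption (and within ``max_gap`` frames).  Returns merge rows
    ``(kept_id, absorbed_id, t_end, t_start, dist)``.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    merges: list[tuple[int, int, int, int, float]] = []
    claimed: set[int] = set()
    # chain bookkeeping: a started track that is absorbed passes any of
    # its own later interruptions to the keeper
    alias: dict[int, int] = {}
    for tau in sorted(interrupted, key=lambda e: (e.t, e.track_id)):
        best = None
        best_dist = d
        for rho in started:
            if rho.track_id in claimed or rho.track_id == tau.track_id:
                continue
            if not (tau.t < rho.t <= tau.t + max_gap):
                continue
            dist = endpoint_distance(tau, rho)
            if dist < best_dist:
                best, best_dist = rho, dist
        if best is None:
            continue
        keeper = alias.get(tau.track_id, tau.track_id)
        claimed.add(best.track_id)
        alias[best.track_id] = keeper
        merges.append((keeper, best.track_id, tau.t, best.t, best_dist))
    return merges


def _apply_merges(
    tracks: list[Track],
    merges: list[tuple[int, int, int, int, float]],
    interpolate: bool = True,
) -> list[Track]:
    by_id = {t.id: t for t in tracks}
    for kept_id, absorbed_id, t_end, t_start, _ in merges:
        keeper, absorbed = by_id[kept_id], by_id[absorbed_id]
        if interpolate and t_start - t_end > 1:
            _, x0, y0, th0, _ = keeper.last_observed
            t0 = keeper.points[-1][0]
            t1, x1, y1, th1, _ = absorbed.points[0]
            for t in range(t0 + 1, t1):
                a = (t - t0) / (t1 - t0)
                dth = kalman.angle_difference(th1, th0)
                keeper.points.append(
                    (
                        t,
                        x0 + a * (x1 - x0),
                        y0 + a * (y1 - y0),
                        float(np.mod(th0 + a * dth, 2.0 * np.pi)),
                        True,
                    )
                )
        keeper.points.extend(absorbed.points)
        keeper.status = absorbed.status if absorbed.status != "interrupted" else "interrupted"
        keeper.status = "closed" if keeper.status in ("active", "closed") else keeper.status
        del by_id[absorbed_id]
    return sorted(by_id.values(), key=lambda t: t.id)


def run(
    detection_stream: dict[int, list[HeadDetection]] | list[list[HeadDetection]],
    config: TrackerConfig | None = None,
) -> TrajectorySet:
    """Track a whole detection stream and reconnect fragments.

    ``detection_stream`` maps contiguous ascending frame indices to
    per-frame detection lists (a plain list is taken as frames
    ``0..n-1``).  Deterministic given inputs and config.
    """
    if isinstance(detection_stream, dict):
        frames = sorted(detection_stream)
        if frames and frames != list(range(frames[0], frames[-1] + 1)):
            raise ValueError("frames must be contiguous and ascending")
        stream = [(f, detection_stream[f]) for f in frames]
    else:
        stream = list(enumerate(detection_stream))
    tracker = Tracker(config)
    for frame, dets in stream:
        tracker.step(dets, frame)
    return tracker.finalize()
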