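"""Detection and tracking evaluation against ground-truth trajectories.

Detection quality is scored from per-frame one-to-one matches between
detections and ground-truth head positions (precision, recall,
F-measure, Similarity Index, miss/error ratios) together with
occlusion-centric counts (occlusion ratio OR, occlusion detection ratio
ODR).  Tracking quality is scored by the Correct Tracking Rate (CTR,
the fraction of fish-frames where some tracker point lies within the
correctness radius of the true head center — identity exchanges are not
penalized) and the Correct Identification Ratio (CIR, the fraction of
occlusion events after which every participating fish carries the same
track identity it had before the event).

The correctness radius defaults to 15 px throughout, used both for
detection TP matching and for CTR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .geometry import BoundingBox, min_intersection

DEFAULT_RADIUS = 15.0


@dataclass(frozen=True)
class FrameMatchResult:
    """TP/FP/FN counts for one frame plus per-match distances."""

    true_positive: int
    false_positive: int
    false_negative: int
    distances: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if min(self.true_positive, self.false_positive, self.false_negative) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class OcclusionEvent:
    """A contiguous run of frames in which >= 2 fish overlap."""

    start_frame: int
    end_frame: int
    participants: frozenset
    detected: bool | None = None

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise ValueError("start_frame must be <= end_frame")
        if len(self.participants) < 2:
            raise ValueError("an occlusion involves at least two fish")


@dataclass(frozen=True)
class MetricsReport:
    """All evaluation quantities for one run.

    Ratio fields are ``None`` when their denominator is zero (for
    example CIR with no occlusion events) rather than NaN.
    """

    precision: float | None = None
    recall: float | None = None
    f_measure: float | None = None
    similarity_index: float | None = None
    occlusion_ratio: float | None = None
    occlusion_detection_ratio: float | None = None
    miss_ratio: float | None = None
    error_ratio: float | None = None
    ctr: float | None = None
    cir: float | None = None
    counts: dict = field(default_factory=dict)

    def rounded(self, ndigits: int = 4) -> dict:
        """Table-style view: ratios rounded to ``ndigits`` decimals."""
        out = {}
        for k in (
            "precision",
            "recall",
            "f_measure",
            "similarity_index",
            "occlusion_ratio",
            "occlusion_detection_ratio",
            "miss_ratio",
            "error_ratio",
            "ctr",
            "cir",
        ):
            v = getattr(self, k)
            out[k] = None if v is None else round(v, ndigits)
        return out

    def merge(self, other: "MetricsReport") -> "MetricsReport":
        """Combine a detection-part and a tracking-part report."""
        kwargs = {}
        for k in self.__dataclass_fields__:
            a, b = getattr(self, k), getattr(other, k)
            if k == "counts":
                kwargs[k] = {**a, **b}
            else:
                kwargs[k] = b if b is not None else a
        return MetricsReport(**kwargs)


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * recall * precision / (recall + precision)


def similarity_index(f: float, num_missed: float, num_ground_truth: float) -> float:
    """F-measure penalized by the fraction of undetected objects."""
    return f - num_missed / (2.0 * num_ground_truth)


def match_frame(
    detections: np.ndarray | list,
    ground_truth: np.ndarray | list,
    radius: float = DEFAULT_RADIUS,
) -> FrameMatchResult:
    """One-to-one minimal-total-distance matching within ``radius``.

    ``detections`` and ``ground_truth`` are (n, 2) position arrays (or
    lists of objects with ``.centroid``).  Matched pairs farther than
    ``radius`` are rejected; TP = accepted pairs, FN = unmatched ground
    truth, FP = unmatched detections.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    det = _positions(detections)
    gt = _positions(ground_truth)
    n_det, n_gt = len(det), len(gt)
    if n_det == 0 or n_gt == 0:
        return FrameMatchResult(0, n_det, n_gt)
    dmat = np.linalg.norm(det[:, None, :] - gt[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(dmat)
    dists = tuple(
        float(dmat[i, j]) for i, j in zip(rows, cols) if dmat[i, j] <= radius
    )
    tp = len(dists)
    return FrameMatchResult(tp, n_det - tp, n_gt - tp, dists)


def _positions(objs) -> np.ndarray:
    if isinstance(objs, np.ndarray):
        return objs.reshape(-1, 2).astype(float)
    pts = []
    for o in objs:
        if hasattr(o, "centroid"):
            pts.append(o.centroid)
        else:
            pts.append((float(o[0]), float(o[1])))
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def detection_metrics(
    frame_results: list[FrameMatchResult],
    occlusions: list[OcclusionEvent],
    n_fish: int,
    n_frames: int,
) -> MetricsReport:
    """Aggregate per-frame matches into the detection metric suite.

    ``Num_GroundTruth`` and "total number of targets" are both
    ``n_fish * n_frames`` (every fish is a target in every frame).
    """
    if n_fish <= 0 or n_frames <= 0:
        raise ValueError("n_fish and n_frames must be positive")
    tp = sum(r.true_positive for r in frame_results)
    fp = sum(r.false_positive for r in frame_results)
    fn = sum(r.false_negative for r in frame_results)
    targets = n_fish * n_frames
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    f = f_measure(precision, recall) if None not in (precision, recall) else None
    si = similarity_index(f, fn, targets) if f is not None else None
    n_occ = len(occlusions)
    n_occ_ok = sum(1 for e in occlusions if e.detected)
    return MetricsReport(
        precision=precision,
        recall=recall,
        f_measure=f,
        similarity_index=si,
        occlusion_ratio=n_occ / targets,
        occlusion_detection_ratio=(n_occ_ok / n_occ) if n_occ else None,
        miss_ratio=fn / targets,
        error_ratio=fp / targets,
        counts={
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "n_fish": n_fish,
            "n_frames": n_frames,
            "n_occlusions": n_occ,
            "n_occlusions_detected": n_occ_ok,
        },
    )


def detect_occlusions(
    boxes_by_frame: dict[int, dict[int, BoundingBox]],
) -> list[OcclusionEvent]:
    """Derive occlusion events from ground-truth head-box geometry.

    Two fish are occluding in a frame when their head boxes overlap
    (``min_intersection > 0``).  Overlapping pairs form per-frame
    connected components; components in consecutive frames sharing any
    participant are merged into one event whose participant set is the
    union.  Deterministic.
    """
    runs: list[dict] = []  # open events: {"start", "end", "ids"}
    events: list[OcclusionEvent] = []
    prev_open: list[dict] = []
    for frame in sorted(boxes_by_frame):
        boxes = boxes_by_frame[frame]
        comps = _overlap_components(boxes)
        new_open: list[dict] = []
        used_prev: set[int] = set()
        for comp in comps:
            joined = None
            for idx, run in enumerate(prev_open):
                if idx in used_prev or not (run["ids"] & comp):
                    continue
                joined = run
                used_prev.add(idx)
                break
            if joined is None:
                joined = {"start": frame, "ids": set()}
            joined["ids"] |= comp
            joined["end"] = frame
            new_open.append(joined)
        for idx, run in enumerate(prev_open):
            if idx not in used_prev:
                events.append(
                    OcclusionEvent(run["start"], run["end"], frozenset(run["ids"]))
                )
        prev_open = new_open
    for run in prev_open:
        events.append(OcclusionEvent(run["start"], run["end"], frozenset(run["ids"])))
    events.sort(key=lambda e: (e.start_frame, min(e.participants)))
    return events


def _overlap_components(boxes: dict[int, BoundingBox]) -> list[set]:
    ids = sorted(boxes)
    adj = {i: set() for i in ids}
    for a_idx, a in enumerate(ids):
        for b in ids[a_idx + 1 :]:
            if min_intersection(boxes[a], boxes[b]) > 0:
                adj[a].add(b)
                adj[b].add(a)
    comps, seen = [], set()
    for i in ids:
        if i in seen or not adj[i]:
            continue
        comp, stack = set(), [i]
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def mark_occlusion_success(
    events: list[OcclusionEvent],
    detections_by_frame: dict[int, list],
    gt: pd.DataFrame,
    radius: float = DEFAULT_RADIUS,
    within: int = 1,
) -> list[OcclusionEvent]:
    """Flag events whose participants all re-acquire a detection within
    ``within`` frames of the occlusion end (the "successfully handled"
    criterion behind ODR)."""
    out = []
    max_frame = int(gt["frame"].max())
    for e in events:
        ok = True
        for fish in e.participants:
            found = False
            for f in range(e.end_frame, min(e.end_frame + within, max_frame) + 1):
                row = gt[(gt["fish_id"] == fish) & (gt["frame"] == f)]
                if row.empty:
                    continue
                pos = row[["x", "y"]].to_numpy()[0]
                dets = _positions(detections_by_frame.get(f, []))
                if len(dets) and np.min(np.linalg.norm(dets - pos, axis=1)) <= radius:
                    found = True
                    break
            if not found:
                ok = False
                break
        out.append(OcclusionEvent(e.start_frame, e.end_frame, e.participants, ok))
    return out


def tracking_metrics(
    trajectories: pd.DataFrame,
    ground_truth: pd.DataFrame,
    occlusions: list[OcclusionEvent] | None = None,
    radius: float = DEFAULT_RADIUS,
    separation_px: float = 20.0,
) -> MetricsReport:
    """CTR and CIR for a finished tracking run.

    ``trajectories`` has columns ``track_id, frame, x, y`` (theta and
    the interpolated flag are ignored here); ``ground_truth`` has
    ``fish_id, frame, x, y`` with persistent identities.

    CTR: per frame, tracker points are matched one-to-one to ground
    truth within ``radius``; a fish-frame is correct when its fish got a
    match.  Identity exchanges do not count against CTR, which is
    therefore invariant to track relabeling.

    CIR: an occlusion event is resolved when every participant carries
    the same track identity at the comparison frames before and after
    the event; the comparison frames are the nearest frames outside the
    event at which all participants are at least ``separation_px``
    apart (identity is not judged mid-clump).
    """
    fish_ids = sorted(ground_truth["fish_id"].unique())
    frames = sorted(ground_truth["frame"].unique())
    n_fish, n_frames = len(fish_ids), len(frames)
    gt_by_frame = {f: g for f, g in ground_truth.groupby("frame")}
    tr_by_frame = {f: g for f, g in trajectories.groupby("frame")}

    correct = 0
    for f in frames:
        g = gt_by_frame[f]
        t = tr_by_frame.get(f)
        if t is None or t.empty:
            continue
        res = match_frame(
            t[["x", "y"]].to_numpy(), g[["x", "y"]].to_numpy(), radius=radius
        )
        correct += res.true_positive
    ctr = correct / (n_fish * n_frames)

    cir = None
    counts = {"ctr_correct_frames": correct, "n_fish": n_fish, "n_frames": n_frames}
    if occlusions:
        resolved, unjudged = 0, 0
        for e in occlusions:
            ok = _identity_preserved(
                e, trajectories, ground_truth, gt_by_frame, tr_by_frame,
                radius, separation_px, frames,
            )
            if ok is None:
                # no separated pre-event frame exists (for example the
                # fish already overlap when the video starts): there is
                # no pre-occlusion identity to preserve, so the event
                # cannot be judged and leaves the denominator
                unjudged += 1
            elif ok:
                resolved += 1
        judged = len(occlusions) - unjudged
        cir = resolved / judged if judged else None
        counts["n_occlusion_events"] = len(occlusions)
        counts["n_occlusion_events_unjudged"] = unjudged
        counts["n_identity_preserved"] = resolved
    return MetricsReport(ctr=ctr, cir=cir, counts=counts)


def _identity_map(
    frame: int,
    participants: frozenset,
    gt_by_frame: dict,
    tr_by_frame: dict,
    radius: float,
) -> dict | None:
    g = gt_by_frame.get(frame)
    t = tr_by_frame.get(frame)
    if g is None or t is None or t.empty:
        return None
    mapping = {}
    tpos = t[["x", "y"]].to_numpy()
    tids = t["track_id"].to_numpy()
    for fish in participants:
        row = g[g["fish_id"] == fish]
        if row.empty:
            return None
        pos = row[["x", "y"]].to_numpy()[0]
        dist = np.linalg.norm(tpos - pos, axis=1)
        k = int(np.argmin(dist))
        if dist[k] > radius:
            return None
        mapping[fish] = int(tids[k])
    if len(set(mapping.values())) != len(mapping):
        return None  # two fish claimed by one tracker: ambiguous
    return mapping


def _separated(frame: int, participants: frozenset, gt_by_frame, separation_px) -> bool:
    g = gt_by_frame.get(frame)
    if g is None:
        return False
    pts = []
    for fish in participants:
        row = g[g["fish_id"] == fish]
        if row.empty:
            return False
        pts.append(row[["x", "y"]].to_numpy()[0])
    pts = np.asarray(pts)
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if np.linalg.norm(pts[i] - pts[j]) < separation_px:
                return False
    return True


def _identity_preserved(
    event: OcclusionEvent,
    trajectories: pd.DataFrame,
    ground_truth: pd.DataFrame,
    gt_by_frame: dict,
    tr_by_frame: dict,
    radius: float,
    separation_px: float,
    frames: list[int],
) -> bool | None:
    """True/False when the event can be judged, None when no separated
    pre-event frame exists (no pre-occlusion identity is defined)."""
    first, last = frames[0], frames[-1]
    pre = None
    for f in range(event.start_frame - 1, first - 1, -1):
        if _separated(f, event.participants, gt_by_frame, separation_px):
            pre = f
            break
    if pre is None:
        return None
    post = None
    for f in range(event.end_frame + 1, last + 1):
        if _separated(f, event.participants, gt_by_frame, separation_px):
            post = f
            break
    if post is None:
        return False
    m0 = _identity_map(pre, event.participants, gt_by_frame, tr_by_frame, radius)
    m1 = _identity_map(post, event.participants, gt_by_frame, tr_by_frame, radius)
    return m0 is not None and m0 == m1
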