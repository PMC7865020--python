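"""Synthetic fish-school generator.

Stands in for the camera + detector front end: produces ground-truth
trajectories with persistent identities, occlusion events derived from
head-box overlap, and noisy per-frame head detections (optionally with
rendered grayscale head patches for the moment operators).

The motion model is a correlated random walk: each fish keeps a
persistent heading perturbed by wrapped-Gaussian turn noise, swims at a
per-fish speed drawn around the configured mean, and reflects off the
tank walls.  ``agitation="feeding"`` adds a shared attraction point at
the tank center and doubles the turn variance, mimicking the crowded,
agitated swimming of a feeding school; ``"calm"`` is the free-swimming
regime.  Speeds are configured in cm/s (typical zebrafish schools swim
at roughly 6-10 cm/s) and converted to px/frame through ``px_per_cm``
and ``fps``.

Measurement noise is zero-mean Gaussian on ``(x, y, theta)`` with a
configurable covariance whose default matches the tracker's observation
noise ``diag(24.1, 24.8, 22.7)``; during occlusion events each
participant's detection is dropped with a configurable probability.
Everything is driven by one seeded generator stream, so a given config
and seed reproduce the output bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import BoundingBox, HeadDetection, IntensityPatch, wrap_angle
from .metrics import OcclusionEvent, detect_occlusions

TWO_PI = 2.0 * math.pi

R_NOISE_DEFAULT = ((24.1, 0.0, 0.0), (0.0, 24.8, 0.0), (0.0, 0.0, 22.7))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic recording.

    Defaults mirror the smallest real recording regime this generator
    emulates: 3 fish filmed for 904 frames at 30 fps swimming at
    9.42 cm/s on average, with a 10 px/cm image scale so mean speeds
    land at 2-4 px/frame.
    """

    n_fish: int = 3
    n_frames: int = 904
    fps: float = 30.0
    tank: tuple[float, float] = (450.0, 250.0)
    px_per_cm: float = 10.0
    speed_mean: float = 9.42  # cm/s
    speed_sd: float = 1.0  # cm/s, between-fish spread
    heading_persistence: float = 0.95
    agitation: str = "calm"  # calm | feeding
    occlusion_radius: float = 14.0  # GT head-box side, px; 0 = no occlusions
    dropout_prob_in_occlusion: float = 0.5
    false_positive_rate: float = 0.0  # expected spurious detections/frame
    duplicate_rate: float = 0.0  # prob. of re-emitting a jittered copy
    measurement_noise: tuple = R_NOISE_DEFAULT
    head_length_px: float = 10.0
    bbox_px: float = 20.0  # detection box side
    wall_margin: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish < 1 or self.n_frames < 1:
            raise ValueError("need at least one fish and one frame")
        if self.agitation not in ("calm", "feeding"):
            raise ValueError("agitation must be 'calm' or 'feeding'")
        if not 0 <= self.heading_persistence <= 1:
            raise ValueError("heading_persistence must be in [0, 1]")
        for p in (self.dropout_prob_in_occlusion, self.duplicate_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        w, h = self.tank
        usable = (w - 2 * self.wall_margin) * (h - 2 * self.wall_margin)
        if usable <= 0 or usable < self.n_fish * max(self.occlusion_radius, 1.0) ** 2:
            raise ValueError("tank too small for this many fish")

    @property
    def speed_px_per_frame(self) -> float:
        return self.speed_mean * self.px_per_cm / self.fps

    def noise_cov(self) -> np.ndarray:
        cov = np.asarray(self.measurement_noise, dtype=float).reshape(3, 3)
        if not np.allclose(cov, cov.T) or np.any(np.linalg.eigvalsh(cov) < -1e-12):
            raise ValueError("measurement_noise must be symmetric PSD")
        return cov


# Presets named after the real recordings whose fish count, length and
# mean speed they copy (D6 is the feeding-period regime; D7/D8 come
# from a larger high-resolution tank, so they get a larger arena).
PRESETS: dict[str, SimConfig] = {
    "D1": SimConfig(n_fish=3, n_frames=904, speed_mean=9.42),
    "D2": SimConfig(n_fish=6, n_frames=1269, speed_mean=7.81),
    "D3": SimConfig(n_fish=8, n_frames=789, speed_mean=6.37),
    "D4": SimConfig(n_fish=10, n_frames=1366, speed_mean=6.44),
    "D5": SimConfig(n_fish=13, n_frames=2422, speed_mean=7.44),
    "D6_food": SimConfig(
        n_fish=13, n_frames=1519, speed_mean=10.22, agitation="feeding"
    ),
    "D7": SimConfig(n_fish=10, n_frames=5410, speed_mean=8.14, tank=(900.0, 900.0)),
    "D8": SimConfig(n_fish=100, n_frames=1410, speed_mean=7.49, tank=(900.0, 900.0)),
}


@dataclass(frozen=True)
class SimOutput:
    """Everything one simulated recording produces."""

    ground_truth: pd.DataFrame  # fish_id, frame, x, y, theta
    detections: dict[int, list[HeadDetection]]
    occlusion_events: list[OcclusionEvent]
    config: SimConfig

    @property
    def gt_boxes_by_frame(self) -> dict[int, dict[int, BoundingBox]]:
        return gt_head_boxes(self.ground_truth, self.config.occlusion_radius)


def gt_head_boxes(
    gt: pd.DataFrame, side: float
) -> dict[int, dict[int, BoundingBox]]:
    """Ground-truth head boxes of a given side length, per frame."""
    out: dict[int, dict[int, BoundingBox]] = {}
    if side <= 0:
        return {int(f): {} for f in gt["frame"].unique()}
    half = side / 2.0
    for (fish, frame), row in gt.set_index(["fish_id", "frame"]).iterrows():
        out.setdefault(int(frame), {})[int(fish)] = BoundingBox(
            row["x"] - half, row["y"] - half, row["x"] + half, row["y"] + half,
            frame=int(frame),
        )
    return out


def _reflect(p: float, lo: float, hi: float) -> tuple[float, bool]:
    flipped = False
    while p < lo or p > hi:
        if p < lo:
            p = 2 * lo - p
        else:
            p = 2 * hi - p
        flipped = not flipped
    return p, flipped


def simulate_ground_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Correlated-random-walk trajectories inside the tank."""
    w, h = config.tank
    m = config.wall_margin
    n = config.n_fish
    x = rng.uniform(m, w - m, size=n)
    y = rng.uniform(m, h - m, size=n)
    theta = rng.uniform(0.0, TWO_PI, size=n)
    speed_cm = np.clip(
        rng.normal(config.speed_mean, config.speed_sd, size=n), 0.1, None
    )
    speed = speed_cm * config.px_per_cm / config.fps  # px/frame
    sigma_turn = (1.0 - config.heading_persistence) * (math.pi / 2.0)
    feeding = config.agitation == "feeding"
    if feeding:
        sigma_turn *= math.sqrt(2.0)  # doubled turn variance
        attractor = np.array([w / 2.0, h / 2.0])
        kappa = 0.08  # heading pull toward the shared food point
    rows = []
    for t in range(config.n_frames):
        for k in range(n):
            rows.append((k, t, float(x[k]), float(y[k]), float(wrap_angle(theta[k]))))
        turn = rng.normal(0.0, sigma_turn, size=n)
        if feeding:
            for k in range(n):
                to_food = math.atan2(attractor[1] - y[k], attractor[0] - x[k])
                delta = (to_food - theta[k] + math.pi) % TWO_PI - math.pi
                turn[k] += kappa * delta
        theta = theta + turn
        nx = x + speed * np.cos(theta)
        ny = y + speed * np.sin(theta)
        for k in range(n):
            px, fx = _reflect(nx[k], m, w - m)
            py, fy = _reflect(ny[k], m, h - m)
            if fx:
                theta[k] = math.pi - theta[k]
            if fy:
                theta[k] = -theta[k]
            nx[k], ny[k] = px, py
        x, y = nx, ny
        theta = np.mod(theta, TWO_PI)
    return pd.DataFrame(rows, columns=["fish_id", "frame", "x", "y", "theta"])


def corrupt_to_detections(
    ground_truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    occlusion_events: list[OcclusionEvent] | None = None,
) -> dict[int, list[HeadDetection]]:
    """Noisy detections from ground truth.

    Adds Gaussian ``(x, y, theta)`` noise with the configured
    covariance; inside occlusion events each participant's detection is
    dropped with ``dropout_prob_in_occlusion``; optional false-positive
    and near-duplicate injection exercise the error-ratio and dedup
    paths.
    """
    cov = config.noise_cov()
    # PSD-safe square root so an exactly-zero covariance yields
    # detections identical to ground truth
    evals, evecs = np.linalg.eigh(cov)
    chol = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    half = config.bbox_px / 2.0
    occluded: dict[int, set] = {}
    for e in occlusion_events or []:
        for f in range(e.start_frame, e.end_frame + 1):
            occluded.setdefault(f, set()).update(e.participants)
    w, h = config.tank
    detections: dict[int, list[HeadDetection]] = {}
    for frame, g in ground_truth.groupby("frame"):
        frame = int(frame)
        dets: list[HeadDetection] = []
        for _, row in g.iterrows():
            fish = int(row["fish_id"])
            if (
                fish in occluded.get(frame, ())
                and rng.random() < config.dropout_prob_in_occlusion
            ):
                continue
            noise = chol @ rng.standard_normal(3)
            cx = row["x"] + noise[0]
            cy = row["y"] + noise[1]
            th = wrap_angle(row["theta"] + noise[2])
            det = _make_detection(cx, cy, th, half, config.head_length_px, frame)
            dets.append(det)
            if config.duplicate_rate and rng.random() < config.duplicate_rate:
                jitter = rng.normal(0.0, 1.0, size=2)
                dets.append(
                    _make_detection(
                        cx + jitter[0], cy + jitter[1], th, half,
                        config.head_length_px, frame,
                    )
                )
        n_fp = rng.poisson(config.false_positive_rate) if config.false_positive_rate else 0
        for _ in range(n_fp):
            fx = rng.uniform(0, w)
            fy = rng.uniform(0, h)
            fth = rng.uniform(0, TWO_PI)
            dets.append(_make_detection(fx, fy, fth, half, config.head_length_px, frame))
        detections[frame] = dets
    return detections


def _make_detection(
    cx: float, cy: float, th: float, half: float, head_len: float, frame: int
) -> HeadDetection:
    bbox = BoundingBox(cx - half, cy - half, cx + half, cy + half, frame=frame)
    tip = (cx + head_len * math.cos(th), cy + head_len * math.sin(th))
    return HeadDetection(centroid=(cx, cy), angle=th, bbox=bbox, frame=frame, tip=tip)


def simulate_school(config: SimConfig | None = None, **overrides) -> SimOutput:
    """Run the full generator: trajectories, occlusions, detections."""
    config = replace(config or SimConfig(), **overrides) if overrides else (
        config or SimConfig()
    )
    rng = np.random.default_rng(config.seed)
    gt = simulate_ground_truth(config, rng)
    events = detect_occlusions(gt_head_boxes(gt, config.occlusion_radius))
    detections = corrupt_to_detections(gt, config, rng, events)
    return SimOutput(gt, detections, events, config)


def scripted_crossings(
    k: int,
    separation: float = 80.0,
    crossing_gap: float = 40.0,
    speed: float = 3.0,
    box_side: float = 14.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Deterministic two-fish scene with exactly ``k`` crossing events.

    Fish swim horizontally toward each other and cross at known frames,
    separated by straight well-apart stretches, so the head boxes of
    side ``box_side`` overlap in exactly ``k`` disjoint frame runs.
    Useful when a test needs an occlusion count known by construction.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rows = []
    frame = 0
    y_mid = 100.0
    for _ in range(k):
        # approach: fish 0 from the left, fish 1 from the right, meeting
        # in the middle, then separating again
        span = separation + crossing_gap
        steps = int(2 * span / speed)
        x0 = y_mid - span  # reuse scalar arithmetic; x positions
        x1 = y_mid + span
        for s in range(steps):
            xa = x0 + s * speed
            xb = x1 - s * speed
            rows.append((0, frame, xa, y_mid, 0.0))
            rows.append((1, frame, xb, y_mid, math.pi))
            frame += 1
        # well-separated parallel stretch between crossings
        for s in range(20):
            rows.append((0, frame, x0 + steps * speed + s * speed, y_mid - separation, 0.0))
            rows.append((1, frame, x1 - steps * speed - s * speed, y_mid + separation, math.pi))
            frame += 1
    return pd.DataFrame(rows, columns=["fish_id", "frame", "x", "y", "theta"])


def render_patch(
    x: float,
    y: float,
    theta: float,
    head_length_px: float = 10.0,
    patch_half: int = 16,
    frame_size: tuple[int, int] | None = None,
) -> IntensityPatch:
    """Render one fish as an anisotropic teardrop intensity blob.

    The head is a short bright lobe ahead of the body center, the tail a
    longer dim taper behind it, so the moment pipeline (centroid +
    second-moment major axis + skew side selection) recovers the
    heading.  Patches at the frame edge are clipped; moments stay
    finite.
    """
    cx0 = int(round(x)) - patch_half
    cy0 = int(round(y)) - patch_half
    x_lo, y_lo = cx0, cy0
    x_hi, y_hi = cx0 + 2 * patch_half + 1, cy0 + 2 * patch_half + 1
    if frame_size is not None:
        w, h = frame_size
        x_lo, x_hi = max(0, x_lo), min(w, x_hi)
        y_lo, y_hi = max(0, y_lo), min(h, y_hi)
    xs = np.arange(x_lo, x_hi, dtype=float)
    ys = np.arange(y_lo, y_hi, dtype=float)
    xx, yy = np.meshgrid(xs - x, ys - y)
    c, s = math.cos(theta), math.sin(theta)
    u = xx * c + yy * s  # along heading
    v = -xx * s + yy * c  # across heading
    sigma_head = 0.35 * head_length_px
    sigma_tail = 0.9 * head_length_px
    amp_tail = 0.35
    along = np.where(
        u >= 0,
        np.exp(-(u**2) / (2 * sigma_head**2)),
        amp_tail * np.exp(-(u**2) / (2 * sigma_tail**2)),
    )
    across = np.exp(-(v**2) / (2 * (0.3 * head_length_px) ** 2))
    values = along * across
    values[values < 1e-6] = 0.0
    return IntensityPatch(values=values, origin=(float(x_lo), float(y_lo)))


def render_patches(
    ground_truth_frame: pd.DataFrame,
    config: SimConfig,
    frame_size: tuple[int, int] | None = None,
) -> dict[int, IntensityPatch]:
    """Render every fish of one ground-truth frame."""
    out = {}
    for _, row in ground_truth_frame.iterrows():
        out[int(row["fish_id"])] = render_patch(
            row["x"], row["y"], row["theta"],
            head_length_px=config.head_length_px,
            frame_size=frame_size or tuple(int(v) for v in config.tank),
        )
    return out
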