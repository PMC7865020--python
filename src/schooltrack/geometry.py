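"""Head-region geometry.

Everything downstream of the detector and upstream of the filter lives
here: splitting a full frame into overlapping grids (and mapping boxes
back), removing the duplicate detections that the overlap stripes
produce, and turning a grayscale head patch into a centroid, a head-tip
point and a motion-direction angle.

Conventions
-----------
Coordinates are continuous, 0-based and pixel-center registered: pixel
``(i, j)`` of a patch is the unit square ``[i, i+1) x [j, j+1)`` and its
intensity mass sits at the integer position ``(i, j)``.  The image ``y``
axis increases downward.  Angles are radians wrapped to ``[0, 2*pi)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

TWO_PI = 2.0 * math.pi


def wrap_angle(theta: float) -> float:
    """Wrap an angle (radians) into ``[0, 2*pi)``."""
    return float(np.mod(theta, TWO_PI))


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned detection box in full-frame pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    frame: int = 0

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max


@dataclass(frozen=True)
class IntensityPatch:
    """Grayscale sub-image with its offset in the full frame.

    ``values[j, i]`` is the intensity of the pixel at full-frame position
    ``(origin[0] + i, origin[1] + j)`` (row index = y, column index = x).
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("patch must be a 2-D array")
        if np.any(v < 0):
            raise ValueError("patch intensities must be non-negative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class HeadDetection:
    """One fish-head observation in one frame."""

    centroid: tuple[float, float]
    angle: float
    bbox: BoundingBox
    frame: int = 0
    tip: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "angle", wrap_angle(self.angle))

    @property
    def z(self) -> np.ndarray:
        """Observation vector ``(c_x, c_y, c_theta)``."""
        return np.array([self.centroid[0], self.centroid[1], self.angle])


@dataclass(frozen=True)
class GridLayout:
    """Overlapping grid decomposition of a frame.

    ``overlap_px`` is the margin by which each grid extends past its
    partition boundary into each neighbour, so two adjacent interior
    grids share a stripe of ``2 * overlap_px`` pixels (a grid touching
    the frame edge has no margin there).  For a 1920x1080 frame split in
    two with a 30 px margin this yields two 990x1080 grids covering
    x-ranges [0, 990) and [930, 1920).
    """

    boxes: tuple[BoundingBox, ...]
    overlap_px: int
    frame_size: tuple[int, int]

    def to_full_frame(self, grid_index: int, x: float, y: float) -> tuple[float, float]:
        """Map grid-local coordinates to full-frame coordinates."""
        g = self.boxes[grid_index]
        return (x + g.x_min, y + g.y_min)


def split_into_grids(
    frame_size: tuple[int, int], n_splits: int, overlap_px: int
) -> GridLayout:
    """Partition a frame into ``n_splits`` overlapping grids.

    The split runs along the longer frame axis.  Grid ``i`` covers the
    partition cell ``[i*L/n, (i+1)*L/n)`` extended by ``overlap_px``
    into each neighbouring cell and clipped to the frame.
    """
    w, h = frame_size
    if w <= 0 or h <= 0:
        raise ValueError("frame dimensions must be positive")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if overlap_px < 0:
        raise ValueError("overlap_px must be >= 0")
    axis = 0 if w >= h else 1  # split along the longer axis
    length = w if axis == 0 else h
    cell = length / n_splits
    if n_splits > 1 and overlap_px >= cell:
        raise ValueError("overlap_px must be smaller than the grid cell size")
    boxes = []
    for i in range(n_splits):
        lo = max(0.0, i * cell - overlap_px)
        hi = min(float(length), (i + 1) * cell + overlap_px)
        if axis == 0:
            boxes.append(BoundingBox(lo, 0.0, hi, float(h)))
        else:
            boxes.append(BoundingBox(0.0, lo, float(w), hi))
    return GridLayout(tuple(boxes), overlap_px, (w, h))


def min_intersection(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection area over the smaller box area (0 when disjoint).

    Symmetric, in [0, 1]; the duplicate score thresholded during grid
    reassembly.
    """
    iw = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    ih = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if iw <= 0 or ih <= 0:
        return 0.0
    return (iw * ih) / min(a.area, b.area)


def dedup_detections(
    detections: list[BoundingBox], threshold: float = 0.4
) -> list[BoundingBox]:
    """Remove duplicate boxes arising in grid-overlap stripes.

    Two boxes are duplicates when their intersection-over-minimum-area
    score is strictly greater than ``threshold``.  Each duplicate
    cluster is represented by the box with the larger area (ties broken
    by lower ``(x_min, y_min)``), which favours the more complete
    detection.  Idempotent; for every retained pair the score is
    ``<= threshold``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(
        range(len(detections)),
        key=lambda i: (-detections[i].area, detections[i].x_min, detections[i].y_min),
    )
    kept: list[int] = []
    for i in order:
        if all(min_intersection(detections[i], detections[j]) <= threshold for j in kept):
            kept.append(i)
    kept.sort()
    return [detections[i] for i in kept]


def _raw_moments(patch: IntensityPatch) -> tuple[float, float, float]:
    """Zeroth and first raw intensity moments (M00, M10, M01)."""
    v = patch.values
    h, w = v.shape
    i = np.arange(w, dtype=float)  # x
    j = np.arange(h, dtype=float)  # y
    m00 = float(v.sum())
    m10 = float((v * i[None, :]).sum())
    m01 = float((v * j[:, None]).sum())
    return m00, m10, m01


def centroid_from_patch(patch: IntensityPatch) -> tuple[float, float]:
    """Intensity-weighted centroid ``(M10/M00, M01/M00)`` in full-frame
    coordinates (patch origin added)."""
    m00, m10, m01 = _raw_moments(patch)
    if m00 <= 0:
        raise ValueError("degenerate region: patch has zero total intensity")
    ox, oy = patch.origin
    return (m10 / m00 + ox, m01 / m00 + oy)


def head_orientation(centroid: tuple[float, float], tip: tuple[float, float]) -> float:
    """Motion-direction angle of the head, wrapped to ``[0, 2*pi)``.

    Five-case arctangent of the centroid-to-tip vector: plain arctan in
    the right half-plane, shifted by +/- pi in the left half-plane, and
    +/- pi/2 on the vertical.
    """
    cx, cy = centroid
    px, py = tip
    dx, dy = px - cx, py - cy
    if dx == 0 and dy == 0:
        raise ValueError("undefined direction: tip coincides with centroid")
    if dx > 0:
        theta = math.atan(dy / dx)
    elif dx < 0 and dy >= 0:
        theta = math.atan(dy / dx) + math.pi
    elif dx < 0:  # dy < 0
        theta = math.atan(dy / dx) - math.pi
    elif dy > 0:  # dx == 0
        theta = math.pi / 2
    else:  # dx == 0, dy < 0
        theta = -math.pi / 2
    return wrap_angle(theta)


def tip_from_patch(
    patch: IntensityPatch,
    centroid: tuple[float, float] | None = None,
    *,
    isotropy_tol: float = 1e-9,
) -> tuple[float, float]:
    """Head-tip point from the intensity ellipse of a patch.

    The second central moments define an intensity ellipse; the tip lies
    on the major axis at one major-semi-axis length (``2*sqrt(lambda_max)``
    of the normalized second-moment matrix) from the centroid, on the
    side carrying the larger intensity mass.  For a backlit fish head
    patch the head is the short, heavy lobe and the tail the long, dim
    taper, so the heavy side is the head.  The side is selected by the
    sign of the third central moment along the axis: the skew tail
    points away from the heavy lobe, so the tip direction is
    ``-sign(mu3)``.

    Raises on (near-)isotropic patches, where the major axis is
    undefined.
    """
    m00, m10, m01 = _raw_moments(patch)
    if m00 <= 0:
        raise ValueError("degenerate region: patch has zero total intensity")
    v = patch.values
    h, w = v.shape
    cx_local = m10 / m00
    cy_local = m01 / m00
    i = np.arange(w, dtype=float) - cx_local
    j = np.arange(h, dtype=float) - cy_local
    xx, yy = np.meshgrid(i, j)
    mu20 = float((v * xx**2).sum()) / m00
    mu02 = float((v * yy**2).sum()) / m00
    mu11 = float((v * xx * yy).sum()) / m00
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_min, lam_max = evals
    if lam_max - lam_min <= isotropy_tol * max(lam_max, 1.0):
        raise ValueError("undefined axis: patch is isotropic")
    u = evecs[:, 1]
    # canonical orientation before the skew decides the side
    if u[0] < 0 or (u[0] == 0 and u[1] < 0):
        u = -u
    proj = xx * u[0] + yy * u[1]
    mu3 = float((v * proj**3).sum()) / m00
    sign = -1.0 if mu3 > 0 else 1.0  # heavy lobe opposes the skew tail
    semi_axis = 2.0 * math.sqrt(lam_max)
    ox, oy = patch.origin
    cx, cy = cx_local + ox, cy_local + oy
    if centroid is not None:
        cx, cy = centroid
    return (cx + sign * semi_axis * u[0], cy + sign * semi_axis * u[1])


def detection_from_patch(
    patch: IntensityPatch, bbox: BoundingBox, frame: int = 0
) -> HeadDetection:
    """Full moment pipeline: centroid, tip and angle from one patch."""
    centroid = centroid_from_patch(patch)
    tip = tip_from_patch(patch)
    angle = head_orientation(centroid, tip)
    return HeadDetection(centroid=centroid, angle=angle, bbox=bbox, frame=frame, tip=tip)
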