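"""Constant-velocity Kalman filtering of head position and orientation.

Each fish is filtered independently with a 6-dimensional state
``[c_x, c_y, c_theta, dc_x, dc_y, dc_theta]`` (pixels, radians and their
per-frame rates) under a linear constant-velocity motion model.  The
observation is the moment-based head measurement ``(c_x, c_y, c_theta)``.

The observation-noise covariance defaults to
``R = diag(24.1, 24.8, 22.7)``, the empirical head-measurement noise of
the detector this tracker was designed around.  The process noise is a
white-acceleration (near-constant-velocity) model with a single scalar
knob ``q``.

The predict/update equations are the standard textbook Kalman forms with
one circular twist: the angle component of the innovation is the minimal
signed circular difference in ``(-pi, pi]``, and the state angle is
re-wrapped to ``[0, 2*pi)`` after every step, so the filter is
continuous across the 0/2*pi seam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import wrap_angle

R_DEFAULT_DIAG = (24.1, 24.8, 22.7)


def angle_difference(a: float, b: float) -> float:
    """Minimal signed circular difference ``a - b`` in ``(-pi, pi]``."""
    d = (a - b) % (2.0 * np.pi)
    if d > np.pi:
        d -= 2.0 * np.pi
    return float(d)


@dataclass(frozen=True)
class MotionModel:
    """Linear constant-velocity system matrices.

    F : (6, 6) state transition — identity plus ``dt`` on the velocity
        off-diagonal.
    H : (3, 6) observation matrix — selects position and angle.
    R : (3, 3) observation-noise covariance.
    Q : (6, 6) process-noise covariance.
    dt : frame interval (frames by default; seconds if you rescale).
    """

    F: np.ndarray
    H: np.ndarray
    R: np.ndarray
    Q: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        for name in ("F", "H", "R", "Q"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.F.shape != (6, 6) or self.H.shape != (3, 6):
            raise ValueError("F must be 6x6 and H 3x6")
        if not np.allclose(self.R, self.R.T) or np.any(np.linalg.eigvalsh(self.R) <= 0):
            raise ValueError("R must be symmetric positive definite")
        if not np.allclose(self.Q, self.Q.T) or np.any(
            np.linalg.eigvalsh(self.Q) < -1e-12
        ):
            raise ValueError("Q must be symmetric positive semidefinite")


def default_model(
    dt: float = 1.0,
    q: float = 1.0,
    r_diag: tuple[float, float, float] = R_DEFAULT_DIAG,
) -> MotionModel:
    """Build the default constant-velocity model.

    Parameters
    ----------
    dt : frame interval (> 0).
    q : white-acceleration process-noise intensity (px^2/frame^4 on the
        position block); the single tuning knob for filter smoothness.
    r_diag : observation-noise variances for (x, y, theta).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    F = np.eye(6)
    F[0, 3] = F[1, 4] = F[2, 5] = dt
    H = np.zeros((3, 6))
    H[0, 0] = H[1, 1] = H[2, 2] = 1.0
    R = np.diag(r_diag).astype(float)
    Q = q * np.diag([dt**4 / 4.0] * 3 + [dt**2] * 3)
    return MotionModel(F=F, H=H, R=R, Q=Q, dt=dt)


@dataclass(frozen=True)
class KalmanState:
    """Filter state: 6-vector ``x``, covariance ``P``, frame index ``t``."""

    x: np.ndarray
    P: np.ndarray
    t: int = 0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float).reshape(6)
        x[2] = wrap_angle(x[2])
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "P", np.asarray(self.P, dtype=float).reshape(6, 6))

    @property
    def position(self) -> tuple[float, float]:
        return (float(self.x[0]), float(self.x[1]))

    @property
    def angle(self) -> float:
        return float(self.x[2])

    @property
    def velocity(self) -> np.ndarray:
        return self.x[3:6]


@dataclass(frozen=True)
class Observation:
    """Head measurement ``z = (c_x, c_y, c_theta)`` at one frame."""

    z: np.ndarray
    frame: int = 0

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float).reshape(3)
        z[2] = wrap_angle(z[2])
        object.__setattr__(self, "z", z)


def init_state(obs: Observation, model: MotionModel) -> KalmanState:
    """Start a track from its first detection.

    Position/angle take the measurement with measurement-level
    uncertainty; velocities start at zero with a weakly informative
    prior (variance 100 px^2/frame^2 in position rate, 10 rad^2/frame^2
    in turn rate).
    """
    x = np.zeros(6)
    x[:3] = obs.z
    P = np.diag(
        [model.R[0, 0], model.R[1, 1], model.R[2, 2], 100.0, 100.0, 10.0]
    )
    return KalmanState(x=x, P=P, t=obs.frame)


def predict(state: KalmanState, model: MotionModel) -> KalmanState:
    """Time update: ``x <- F x``, ``P <- F P F' + Q``; angle re-wrapped."""
    x = model.F @ state.x
    P = model.F @ state.P @ model.F.T + model.Q
    return KalmanState(x=x, P=P, t=state.t + 1)


def update(state: KalmanState, obs: Observation, model: MotionModel) -> KalmanState:
    """Measurement update with circular angle innovation.

    ``y = z - H x`` with the third component replaced by the minimal
    signed circular difference; ``K = P H' (H P H' + R)^-1``;
    ``P <- (I - K H) P``, symmetrized.
    """
    H, R = model.H, model.R
    y = obs.z - H @ state.x
    y[2] = angle_difference(obs.z[2], state.angle)
    S = H @ state.P @ H.T + R
    try:
        K = np.linalg.solve(S.T, (state.P @ H.T).T).T
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError("singular innovation covariance") from exc
    x = state.x + K @ y
    P = (np.eye(6) - K @ H) @ state.P
    P = 0.5 * (P + P.T)
    return KalmanState(x=x, P=P, t=state.t)


def gain(state: KalmanState, model: MotionModel) -> np.ndarray:
    """Kalman gain for a predicted state (diagnostic helper)."""
    H, R = model.H, model.R
    S = H @ state.P @ H.T + R
    return state.P @ H.T @ np.linalg.inv(S)
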