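"""Planar geometry and closed-loop kinematics of the treadmill virtual world.

The fictive bee walks on a 2D floor plane. Conventions, fixed once for the
whole package:

* world frame: x/y in cm, the bee starts at the origin;
* heading: degrees, counterclockwise-positive, ``0`` = the initial facing
  direction, which is the +y axis; headings are normalized to (-180, 180];
* ego-motion: ``forward`` along the body axis, ``lateral`` to the bee's
  right, ``yaw`` counterclockwise-positive.

Ball-surface displacements map 1:1 onto world displacements (1 cm on the
ball = 1 cm in the virtual landscape). Two optic sensors sit on the ball
equator 90 degrees apart: sensor A on the body axis behind the bee, sensor B
to the side. Their vertical flow components read forward/lateral
translation; the shared horizontal component reads rotation of the ball
about its vertical axis, i.e. yaw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError, GeometryError, InputError

__all__ = [
    "BeePose",
    "BallMotionSample",
    "EgoMotion",
    "StimulusCuboid",
    "StimulusView",
    "WorldConfig",
    "wrap_angle_deg",
    "visual_angle_deg",
    "sensors_to_ego_motion",
    "update_pose",
    "stimulus_view",
    "place_stimulus",
    "poses_from_sensor_log",
]

CS_PLUS = "CS_PLUS"
CS_MINUS = "CS_MINUS"

_EPS_DISTANCE = 1e-9


def wrap_angle_deg(angle: float) -> float:
    """Normalize an angle in degrees to the half-open interval (-180, 180]."""
    a = math.fmod(angle, 360.0)
    if a > 180.0:
        a -= 360.0
    elif a <= -180.0:
        a += 360.0
    return a


@dataclass(frozen=True, slots=True)
class BeePose:
    """Planar position (cm) and heading (deg, CCW, 0 = +y) of the fictive bee."""

    x: float = 0.0
    y: float = 0.0
    heading: float = 0.0

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y) and math.isfinite(self.heading)):
            raise InputError(f"non-finite pose: {self}")
        object.__setattr__(self, "heading", wrap_angle_deg(self.heading))


@dataclass(frozen=True, slots=True)
class BallMotionSample:
    """One timestamped reading of the two ball-flow sensors (cm of surface motion)."""

    t: float
    flow_a: tuple[float, float]
    flow_b: tuple[float, float]


@dataclass(frozen=True, slots=True)
class EgoMotion:
    """Body-frame displacement over one tick: forward/lateral in cm, yaw in deg."""

    forward: float = 0.0
    lateral: float = 0.0
    yaw: float = 0.0


@dataclass(frozen=True, slots=True)
class StimulusCuboid:
    """A vertical colored cuboid, reduced to its frontal face in the floor plane.

    The cuboid base is 4.5 x 4.5 cm; only the frontal width enters the
    subtended-angle computation, so the planar representation is a center
    point plus ``half_width``.
    """

    center: tuple[float, float]
    half_width: float = 2.25
    color: str = "BLUE"
    role: str = CS_PLUS

    def __post_init__(self):
        if self.half_width <= 0:
            raise GeometryError(f"half_width must be > 0, got {self.half_width}")


@dataclass(frozen=True, slots=True)
class StimulusView:
    """What the bee sees of one stimulus: signed azimuth (deg, CCW-positive,
    relative to heading), distance to the stimulus center (cm) and the
    horizontal angle it subtends (deg)."""

    azimuth: float
    center_distance: float
    subtended_angle: float


@dataclass(frozen=True, slots=True)
class WorldConfig:
    """Physical/virtual constants of the setup.

    ball_diameter
        Treadmill ball diameter in cm (the study used a 5 cm styrofoam ball).
    tick
        Closed-loop update period in seconds (0.017 s).
    start_azimuths
        Bearings of the two stimuli from the bee's body axis at trial start,
        degrees. CCW-positive, so +50 is to the bee's left.
    start_distance
        Distance from the bee to each stimulus center at trial start, cm
        (the screen distance, 9 cm).
    """

    ball_diameter: float = 5.0
    tick: float = 0.017
    start_azimuths: tuple[float, float] = (-50.0, 50.0)
    start_distance: float = 9.0

    def __post_init__(self):
        if self.tick <= 0:
            raise GeometryError(f"tick must be > 0, got {self.tick}")
        if self.ball_diameter <= 0:
            raise GeometryError(f"ball_diameter must be > 0, got {self.ball_diameter}")
        if self.start_distance <= 0:
            raise GeometryError(f"start_distance must be > 0, got {self.start_distance}")


def visual_angle_deg(object_width: float, center_distance: float) -> float:
    """Horizontal angle (deg) subtended by a flat object of ``object_width`` cm
    seen frontally from ``center_distance`` cm.

    Closed form ``2 * arctan(w / 2d)``: a 4.5 cm face at the 9 cm screen
    distance subtends 28 degrees (28.07 before rounding).
    """
    if not (math.isfinite(object_width) and math.isfinite(center_distance)):
        raise GeometryError("non-finite width/distance")
    if object_width <= 0 or center_distance <= 0:
        raise GeometryError(
            f"width and distance must be > 0, got w={object_width}, d={center_distance}"
        )
    return math.degrees(2.0 * math.atan2(object_width, 2.0 * center_distance))


def sensors_to_ego_motion(sample: BallMotionSample, config: WorldConfig) -> EgoMotion:
    """Decompose one dual-sensor flow sample into body-frame ego-motion.

    Sensor A (on the body axis) reads forward translation on its vertical
    channel; sensor B (90 degrees around the equator) reads lateral
    translation on its vertical channel. Both horizontal channels see the
    same equatorial arc when the ball spins about its vertical axis, so yaw
    is their mean arc length converted to degrees of rotation.
    """
    ax, ay = sample.flow_a
    bx, by = sample.flow_b
    if not all(math.isfinite(v) for v in (ax, ay, bx, by)):
        raise InputError(f"non-finite sensor flows at t={sample.t}")
    arc = 0.5 * (ax + bx)
    yaw = 360.0 * arc / (math.pi * config.ball_diameter)
    return EgoMotion(forward=ay, lateral=by, yaw=yaw)


def update_pose(pose: BeePose, motion: EgoMotion) -> BeePose:
    """Advance the world pose by one ego-motion step.

    The body-frame displacement (lateral, forward) is rotated by the current
    heading and added to the position; yaw is added to the heading. A 1 cm
    forward step advances the bee exactly 1 cm along its heading.
    """
    if not all(math.isfinite(v) for v in (motion.forward, motion.lateral, motion.yaw)):
        raise InputError(f"non-finite ego-motion: {motion}")
    theta = math.radians(pose.heading)
    sin_t, cos_t = math.sin(theta), math.cos(theta)
    # forward axis = (-sin, cos); right (lateral) axis = (cos, sin)
    x = pose.x + motion.lateral * cos_t - motion.forward * sin_t
    y = pose.y + motion.lateral * sin_t + motion.forward * cos_t
    return BeePose(x=x, y=y, heading=wrap_angle_deg(pose.heading + motion.yaw))


def stimulus_view(pose: BeePose, stim: StimulusCuboid) -> StimulusView:
    """Compute azimuth, distance and subtended angle of a stimulus from a pose."""
    dx = stim.center[0] - pose.x
    dy = stim.center[1] - pose.y
    dist = math.hypot(dx, dy)
    if dist < _EPS_DISTANCE:
        raise DegenerateGeometryError("bee coincident with stimulus center")
    bearing = math.degrees(math.atan2(-dx, dy))
    return StimulusView(
        azimuth=wrap_angle_deg(bearing - pose.heading),
        center_distance=dist,
        subtended_angle=visual_angle_deg(2.0 * stim.half_width, dist),
    )


def place_stimulus(
    azimuth: float,
    distance: float,
    *,
    half_width: float = 2.25,
    color: str = "BLUE",
    role: str = CS_PLUS,
) -> StimulusCuboid:
    """Place a cuboid at a given bearing/distance from the origin pose.

    The origin pose faces +y, so a stimulus at azimuth ``a`` and distance
    ``d`` sits at ``(-d sin a, d cos a)``.
    """
    rad = math.radians(azimuth)
    center = (-distance * math.sin(rad), distance * math.cos(rad))
    return StimulusCuboid(center=center, half_width=half_width, color=color, role=role)


def poses_from_sensor_log(
    samples: Sequence[BallMotionSample], config: WorldConfig, start: BeePose | None = None
) -> list[BeePose]:
    """Integrate a sensor log into a pose trajectory (fictive-path reconstruction).

    Sample times must be non-negative and non-decreasing. Returns one pose
    per sample plus the starting pose at index 0.
    """
    pose = start if start is not None else BeePose()
    poses = [pose]
    last_t = -0.0
    for s in samples:
        if s.t < 0 or s.t < last_t:
            raise InputError(f"sample times must be non-negative and non-decreasing (t={s.t})")
        last_t = s.t
        pose = update_pose(pose, sensors_to_ego_motion(s, config))
        poses.append(pose)
    return poses


def resample_sensor_log(
    t: np.ndarray, flows: np.ndarray, tick: float
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate a raw sensor log onto the fixed tick grid.

    ``flows`` is (n, 4) with columns ax, ay, bx, by holding *cumulative*
    displacement; the returned per-tick flows are differences of the
    interpolated cumulative signal, so total displacement is preserved.
    """
    t = np.asarray(t, dtype=float)
    flows = np.asarray(flows, dtype=float)
    if t.ndim != 1 or flows.shape != (t.size, 4):
        raise InputError("expected t of shape (n,) and flows of shape (n, 4)")
    grid = np.arange(0.0, t[-1] + 0.5 * tick, tick)
    cum = np.cumsum(flows, axis=0)
    interp = np.stack([np.interp(grid, t, cum[:, j]) for j in range(4)], axis=1)
    per_tick = np.diff(interp, axis=0, prepend=interp[:1] * 0.0)
    return grid, per_tick
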