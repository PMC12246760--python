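"""Core data model for swipe-gesture session logs.

A *session* is one participant playing one game for (at most) 15 minutes on a
handset. During play every swipe (touch-down -> drag -> touch-up) is logged as
an event carrying its full touch path, timing, kinematics and a contact-area
pressure proxy; accelerometer and gyroscope streams are recorded alongside,
independently of the swipes.

Coordinate convention: origin at the bottom-left corner of the screen in the
session's orientation, y increases upward ("higher on the screen" = larger y),
units are pixels. Times are seconds; a swipe's ``event_time`` is anchored at
game launch while ``start_time``/``end_time`` are anchored at the most recent
level (or round) load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional

import numpy as np

GAMES = ("puzzle", "runner", "slicer")
ORIENTATIONS = ("landscape", "portrait")
#: the runner is played in portrait, the other two in landscape
ORIENTATION_FOR_GAME = {"puzzle": "landscape", "runner": "portrait", "slicer": "landscape"}
DIRECTIONS = ("up", "down", "left", "right")
#: swipe direction is only defined for the four-direction games
DIRECTIONAL_GAMES = ("puzzle", "runner")
SENSOR_STREAMS = ("accelerometer", "gyroscope")

#: handset pixel dimensions (width, height) in portrait orientation
PORTRAIT_DIMS = (1080, 2400)
DEFAULT_SESSION_LIMIT = 900.0  # 15 minutes, in seconds


def default_screen_dims(orientation: str) -> tuple[int, int]:
    """(width, height) in px for the default handset in the given orientation."""
    if orientation == "portrait":
        return PORTRAIT_DIMS
    if orientation == "landscape":
        return (PORTRAIT_DIMS[1], PORTRAIT_DIMS[0])
    raise ValueError(f"unknown orientation: {orientation!r}")


class TouchPoint(NamedTuple):
    """One sampled point of a swipe path.

    ``t`` is seconds since the swipe started; ``x``/``y`` are screen px;
    ``press`` is the dimensionless contact-area pressure proxy in [0, 1].
    """

    t: float
    x: float
    y: float
    press: float


class SensorSample(NamedTuple):
    """One reading of a device motion stream (m/s^2 or rad/s per axis)."""

    stream: str
    t: float
    x: float
    y: float
    z: float


@dataclass(eq=False)
class SensorStream:
    """Array-backed motion stream: ``t`` (s since launch) and ``values`` (n, 3)."""

    stream: str
    t: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def samples(self) -> Iterator[SensorSample]:
        for i in range(len(self.t)):
            v = self.values[i]
            yield SensorSample(self.stream, float(self.t[i]), float(v[0]), float(v[1]), float(v[2]))


@dataclass(eq=False)
class SwipeEvent:
    """One logged swipe with its path and derived per-swipe metrics.

    ``path`` is an (n, 4) float array with columns (t, x, y, press); ``t`` is
    seconds since the swipe started. ``time_between_swipes`` is the gap since
    the previous swipe ended and is ``None`` for the first swipe of a session.
    """

    swipe_id: int
    event_time: float
    start_time: float
    end_time: float
    start_pos: tuple[float, float]
    end_pos: tuple[float, float]
    path: np.ndarray
    start_press: float
    end_press: float
    press_mean: float
    start_press_variance: float
    end_press_variance: float
    press_variance: float
    speed: float
    duration: float
    distance: float
    direction: str
    time_between_swipes: Optional[float] = None

    def touch_points(self) -> list[TouchPoint]:
        return [TouchPoint(*row) for row in self.path.tolist()]


@dataclass(eq=False)
class GameSession:
    """One participant x game x (up to) 15-minute play record."""

    participant_id: str
    game: str
    orientation: str
    screen_dims: tuple[int, int]
    swipes: list[SwipeEvent] = field(default_factory=list)
    sensors: dict[str, SensorStream] = field(default_factory=dict)
    session_limit: float = DEFAULT_SESSION_LIMIT
    gameplay_window: tuple[float, float] = (0.0, DEFAULT_SESSION_LIMIT)


@dataclass
class CohortRecord:
    """One participant with linked gameplay sessions and questionnaires.

    A record only enters analysis when at least one session and both
    questionnaires share the participant id (enforced by ``io.link_records``).
    """

    participant_id: str
    sessions: dict[str, "GameSession"]
    gad7_items: list[int]
    phq8_items: list[int]
    demographics: dict[str, object] = field(default_factory=dict)


_TOL = 1e-6


def _check_swipe(sw: SwipeEvent, session: GameSession, issues: list[str]) -> None:
    w, h = session.screen_dims
    tag = f"swipe {sw.swipe_id}"
    if sw.end_time < sw.start_time - _TOL:
        issues.append(f"{tag}: end_time {sw.end_time} < start_time {sw.start_time}")
    if abs(sw.duration - (sw.end_time - sw.start_time)) > _TOL:
        issues.append(f"{tag}: duration {sw.duration} != end_time - start_time")
    p = np.asarray(sw.path, dtype=float)
    if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] < 2:
        issues.append(f"{tag}: path must be an (n>=2, 4) array of (t, x, y, press)")
        return
    t, x, y, press = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    if t[0] < -_TOL or np.any(np.diff(t) < -_TOL):
        issues.append(f"{tag}: path times must be >= 0 and nondecreasing")
    if np.any(x < -_TOL) or np.any(x > w + _TOL):
        issues.append(f"{tag}: path x outside [0, {w}]")
    if np.any(y < -_TOL) or np.any(y > h + _TOL):
        issues.append(f"{tag}: path y outside [0, {h}]")
    if np.any(press < -_TOL) or np.any(press > 1 + _TOL):
        issues.append(f"{tag}: path press outside [0, 1]")
    disp = float(np.hypot(sw.end_pos[0] - sw.start_pos[0], sw.end_pos[1] - sw.start_pos[1]))
    if sw.distance < disp - 1e-3:
        issues.append(f"{tag}: distance {sw.distance} < start-to-end displacement {disp}")
    if sw.duration > 0:
        expect = sw.distance / sw.duration
        if abs(sw.speed - expect) > _TOL * max(1.0, abs(expect)):
            issues.append(f"{tag}: speed {sw.speed} != distance/duration {expect}")
    if session.game in DIRECTIONAL_GAMES:
        if sw.direction not in DIRECTIONS:
            issues.append(
                f"{tag}: direction {sw.direction!r} invalid for {session.game} "
                f"(must be one of {DIRECTIONS})"
            )
    elif sw.direction != "none":
        issues.append(
            f"{tag}: direction {sw.direction!r} invalid for {session.game} "
            "(direction is only computed for puzzle and runner)"
        )
    if sw.time_between_swipes is not None and sw.time_between_swipes < -_TOL:
        issues.append(f"{tag}: time_between_swipes {sw.time_between_swipes} < 0")


def validate_session(session: GameSession) -> list[str]:
    """Check every type invariant; return one human-readable issue per rule broken.

    Pure: never mutates its input. An empty list means the session is valid.
    """
    issues: list[str] = []
    if session.game not in GAMES:
        issues.append(f"session: unknown game {session.game!r}")
        return issues
    if session.orientation != ORIENTATION_FOR_GAME[session.game]:
        issues.append(
            f"session: {session.game} must be played in "
            f"{ORIENTATION_FOR_GAME[session.game]} orientation, got {session.orientation!r}"
        )
    ev = [sw.event_time for sw in session.swipes]
    if any(b < a for a, b in zip(ev, ev[1:])):
        issues.append("session: swipes not ordered by event_time")
    if any(t > session.session_limit + _TOL for t in ev):
        issues.append(f"session: swipe event_time beyond session_limit {session.session_limit}")
    ids = [sw.swipe_id for sw in session.swipes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        issues.append(f"session: duplicate swipe_id {dupes}")
    for sw in session.swipes:
        _check_swipe(sw, session, issues)
    for name, stream in session.sensors.items():
        if stream.stream not in SENSOR_STREAMS or name != stream.stream:
            issues.append(f"sensor {name!r}: stream must be one of {SENSOR_STREAMS}")
        if len(stream.t) and (stream.t[0] < -_TOL or np.any(np.diff(stream.t) < -_TOL)):
            issues.append(f"sensor {name!r}: times must be >= 0 and nondecreasing")
        if np.asarray(stream.values).shape != (len(stream.t), 3):
            issues.append(f"sensor {name!r}: values must be shaped (n, 3)")
    return issues


def swipes_equal(a: SwipeEvent, b: SwipeEvent, tol: float = 1e-9) -> bool:
    if a.swipe_id != b.swipe_id or a.direction != b.direction:
        return False
    if (a.time_between_swipes is None) != (b.time_between_swipes is None):
        return False
    scalars_a = [a.event_time, a.start_time, a.end_time, *a.start_pos, *a.end_pos,
                 a.start_press, a.end_press, a.press_mean, a.start_press_variance,
                 a.end_press_variance, a.press_variance, a.speed, a.duration, a.distance]
    scalars_b = [b.event_time, b.start_time, b.end_time, *b.start_pos, *b.end_pos,
                 b.start_press, b.end_press, b.press_mean, b.start_press_variance,
                 b.end_press_variance, b.press_variance, b.speed, b.duration, b.distance]
    if a.time_between_swipes is not None:
        scalars_a.append(a.time_between_swipes)
        scalars_b.append(b.time_between_swipes)
    if not np.allclose(scalars_a, scalars_b, rtol=0, atol=tol):
        return False
    return a.path.shape == b.path.shape and np.allclose(a.path, b.path, rtol=0, atol=tol)


def sessions_equal(a: GameSession, b: GameSession, tol: float = 1e-9) -> bool:
    """Field-wise equality of two sessions within a numeric tolerance."""
    if (a.participant_id, a.game, a.orientation, tuple(a.screen_dims)) != (
        b.participant_id, b.game, b.orientation, tuple(b.screen_dims)
    ):
        return False
    if abs(a.session_limit - b.session_limit) > tol:
        return False
    if not np.allclose(a.gameplay_window, b.gameplay_window, rtol=0, atol=tol):
        return False
    if len(a.swipes) != len(b.swipes) or set(a.sensors) != set(b.sensors):
        return False
    if not all(swipes_equal(x, y, tol) for x, y in zip(a.swipes, b.swipes)):
        return False
    for name in a.sensors:
        sa, sb = a.sensors[name], b.sensors[name]
        if len(sa) != len(sb):
            return False
        if not (np.allclose(sa.t, sb.t, rtol=0, atol=tol)
                and np.allclose(sa.values, sb.values, rtol=0, atol=tol)):
            return False
    return True
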