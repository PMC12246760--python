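"""Reading, writing and linking of session logs and questionnaire tables.

Session logs are JSON documents in a dialect that mirrors the per-swipe field
names of the in-game logger (``swipe_ID``, ``swipe_event_time``, ...). The
formal contract is published in ``swipescreen/schema/session_log.schema.json``;
validation here is field-by-field so that errors can name the offending field.

The questionnaire table is a CSV with columns::

    participant_id, gad7_q1..gad7_q7, phq8_q1..phq8_q8, age_band, sex, gamer_identity
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    DIRECTIONAL_GAMES,
    DIRECTIONS,
    GAMES,
    ORIENTATIONS,
    SENSOR_STREAMS,
    CohortRecord,
    GameSession,
    SensorStream,
    SwipeEvent,
)

QUESTIONNAIRE_COLUMNS = (
    ["participant_id"]
    + [f"gad7_q{i}" for i in range(1, 8)]
    + [f"phq8_q{i}" for i in range(1, 9)]
    + ["age_band", "sex", "gamer_identity"]
)

#: Table-3 style key for each SwipeEvent attribute, in on-disk order
_SWIPE_KEYS = [
    ("swipe_ID", "swipe_id"),
    ("swipe_event_time", "event_time"),
    ("swipe_start_time", "start_time"),
    ("swipe_end_time", "end_time"),
    ("swipe_start_pos", "start_pos"),
    ("swipe_end_pos", "end_pos"),
    ("swipe_pos", "path"),
    ("swipe_start_press", "start_press"),
    ("swipe_end_press", "end_press"),
    ("swipe_start_press_variance", "start_press_variance"),
    ("swipe_end_press_variance", "end_press_variance"),
    ("swipe_press", "press_mean"),
    ("swipe_press_variance", "press_variance"),
    ("swipe_speed", "speed"),
    ("swipe_duration", "duration"),
    ("swipe_distance", "distance"),
    ("swipe_direction", "direction"),
    ("time_between_swipes", "time_between_swipes"),
]


class SwipeLogError(Exception):
    """Base error for session-log IO."""


class SessionParseError(SwipeLogError):
    """The document is not parseable or a field has the wrong shape/type."""


class SessionValidationError(SwipeLogError):
    """The document parses but violates the schema; lists every violation."""

    def __init__(self, issues: Sequence[str]):
        self.issues = list(issues)
        super().__init__("invalid session log:\n  " + "\n  ".join(self.issues))


class LinkError(SwipeLogError):
    """Conflicting duplicate questionnaire rows for one participant id."""


def _require_number(obj: dict, key: str, issues: list[str], ctx: str, allow_none: bool = False):
    if key not in obj:
        issues.append(f"{ctx}: missing field {key!r}")
        return None
    v = obj[key]
    if v is None and allow_none:
        return None
    if isinstance(v, bool) or not isinstance(v, (int, float)) or (
        isinstance(v, float) and not math.isfinite(v)
    ):
        issues.append(f"{ctx}: field {key!r} must be a finite number, got {v!r}")
        return None
    return v


def _require_pair(obj: dict, key: str, issues: list[str], ctx: str):
    v = obj.get(key)
    if (
        not isinstance(v, (list, tuple))
        or len(v) != 2
        or any(isinstance(c, bool) or not isinstance(c, (int, float)) for c in v)
    ):
        issues.append(f"{ctx}: field {key!r} must be a [x, y] pair of numbers")
        return (0.0, 0.0)
    return (float(v[0]), float(v[1]))


def _swipe_from_json(obj: dict, idx: int, issues: list[str]) -> SwipeEvent | None:
    ctx = f"swipes[{idx}]"
    if not isinstance(obj, dict):
        issues.append(f"{ctx}: must be an object")
        return None
    before = len(issues)
    sid = _require_number(obj, "swipe_ID", issues, ctx)
    scalars = {}
    for key in ("swipe_event_time", "swipe_start_time", "swipe_end_time",
                "swipe_start_press", "swipe_end_press", "swipe_start_press_variance",
                "swipe_end_press_variance", "swipe_press", "swipe_press_variance",
                "swipe_speed", "swipe_duration", "swipe_distance"):
        scalars[key] = _require_number(obj, key, issues, ctx)
    start_pos = _require_pair(obj, "swipe_start_pos", issues, ctx)
    end_pos = _require_pair(obj, "swipe_end_pos", issues, ctx)
    raw_path = obj.get("swipe_pos")
    path = None
    if not isinstance(raw_path, list) or len(raw_path) < 2:
        issues.append(f"{ctx}: field 'swipe_pos' must be a list of >= 2 [t, x, y, press] rows")
    else:
        try:
            path = np.asarray(raw_path, dtype=float)
        except (TypeError, ValueError):
            path = None
        if path is None or path.ndim != 2 or path.shape[1] != 4:
            issues.append(f"{ctx}: field 'swipe_pos' rows must be [t, x, y, press] numbers")
            path = None
    direction = obj.get("swipe_direction")
    if direction not in DIRECTIONS and direction != "none":
        issues.append(f"{ctx}: field 'swipe_direction' must be one of "
                      f"{DIRECTIONS + ('none',)}, got {direction!r}")
    tbs = _require_number(obj, "time_between_swipes", issues, ctx, allow_none=True)
    if len(issues) > before or path is None:
        return None
    return SwipeEvent(
        swipe_id=int(sid),
        event_time=float(scalars["swipe_event_time"]),
        start_time=float(scalars["swipe_start_time"]),
        end_time=float(scalars["swipe_end_time"]),
        start_pos=start_pos,
        end_pos=end_pos,
        path=path,
        start_press=float(scalars["swipe_start_press"]),
        end_press=float(scalars["swipe_end_press"]),
        press_mean=float(scalars["swipe_press"]),
        start_press_variance=float(scalars["swipe_start_press_variance"]),
        end_press_variance=float(scalars["swipe_end_press_variance"]),
        press_variance=float(scalars["swipe_press_variance"]),
        speed=float(scalars["swipe_speed"]),
        duration=float(scalars["swipe_duration"]),
        distance=float(scalars["swipe_distance"]),
        direction=direction,
        time_between_swipes=None if tbs is None else float(tbs),
    )


def session_from_json(doc: dict) -> GameSession:
    """Build a :class:`GameSession` from a parsed log document.

    Raises :class:`SessionValidationError` listing *all* schema violations.
    Swipes are returned sorted by ``swipe_event_time``.
    """
    issues: list[str] = []
    if not isinstance(doc, dict):
        raise SessionParseError("session log must be a JSON object")
    pid = doc.get("participant_id")
    if not isinstance(pid, str) or not pid:
        issues.append("session: field 'participant_id' must be a non-empty string")
        pid = ""
    game = doc.get("game")
    if game not in GAMES:
        issues.append(f"session: field 'game' must be one of {GAMES}, got {game!r}")
    orientation = doc.get("orientation")
    if orientation not in ORIENTATIONS:
        issues.append(f"session: field 'orientation' must be one of {ORIENTATIONS}")
    dims = doc.get("screen_dims")
    if (not isinstance(dims, (list, tuple)) or len(dims) != 2
            or any(isinstance(d, bool) or not isinstance(d, int) or d <= 0 for d in dims)):
        issues.append("session: field 'screen_dims' must be [width, height] positive integers")
        dims = (1, 1)
    limit = _require_number(doc, "session_limit", issues, "session")
    window = doc.get("gameplay_window")
    if (not isinstance(window, (list, tuple)) or len(window) != 2
            or any(isinstance(w, bool) or not isinstance(w, (int, float)) for w in window)):
        issues.append("session: field 'gameplay_window' must be [start_s, end_s]")
        window = (0.0, 0.0)
    raw_swipes = doc.get("swipes")
    swipes: list[SwipeEvent] = []
    if not isinstance(raw_swipes, list):
        issues.append("session: field 'swipes' must be an array")
    else:
        for i, s in enumerate(raw_swipes):
            sw = _swipe_from_json(s, i, issues)
            if sw is not None:
                swipes.append(sw)
    sensors: dict[str, SensorStream] = {}
    raw_sensors = doc.get("sensors")
    if not isinstance(raw_sensors, list):
        issues.append("session: field 'sensors' must be an array of stream objects")
    else:
        for i, s in enumerate(raw_sensors):
            ctx = f"sensors[{i}]"
            if not isinstance(s, dict) or s.get("stream") not in SENSOR_STREAMS:
                issues.append(f"{ctx}: field 'stream' must be one of {SENSOR_STREAMS}")
                continue
            try:
                t = np.asarray(s["t"], dtype=float)
                vals = np.column_stack([np.asarray(s[ax], dtype=float) for ax in "xyz"])
            except (KeyError, TypeError, ValueError):
                issues.append(f"{ctx}: fields 't', 'x', 'y', 'z' must be equal-length "
                              "number arrays")
                continue
            if vals.shape[0] != t.shape[0]:
                issues.append(f"{ctx}: fields 't', 'x', 'y', 'z' must have equal length")
                continue
            sensors[s["stream"]] = SensorStream(s["stream"], t, vals)
    if issues:
        raise SessionValidationError(issues)
    swipes.sort(key=lambda sw: sw.event_time)
    return GameSession(
        participant_id=pid,
        game=game,
        orientation=orientation,
        screen_dims=(int(dims[0]), int(dims[1])),
        swipes=swipes,
        sensors=sensors,
        session_limit=float(limit),
        gameplay_window=(float(window[0]), float(window[1])),
    )


def session_to_json(session: GameSession) -> dict:
    """Serialize a session to the on-disk dialect (stable key order)."""
    swipes = []
    for sw in sorted(session.swipes, key=lambda s: s.event_time):
        obj = {}
        for key, attr in _SWIPE_KEYS:
            v = getattr(sw, attr)
            if attr == "path":
                v = np.asarray(v, dtype=float).tolist()
            elif attr in ("start_pos", "end_pos"):
                v = [float(v[0]), float(v[1])]
            elif attr == "swipe_id":
                v = int(v)
            elif attr == "direction":
                pass
            elif v is not None:
                v = float(v)
            obj[key] = v
        swipes.append(obj)
    sensors = []
    for name in sorted(session.sensors):
        st = session.sensors[name]
        sensors.append({
            "stream": st.stream,
            "t": np.asarray(st.t, dtype=float).tolist(),
            "x": np.asarray(st.values[:, 0], dtype=float).tolist(),
            "y": np.asarray(st.values[:, 1], dtype=float).tolist(),
            "z": np.asarray(st.values[:, 2], dtype=float).tolist(),
        })
    return {
        "participant_id": session.participant_id,
        "game": session.game,
        "orientation": session.orientation,
        "screen_dims": [int(session.screen_dims[0]), int(session.screen_dims[1])],
        "session_limit": float(session.session_limit),
        "gameplay_window": [float(session.gameplay_window[0]), float(session.gameplay_window[1])],
        "swipes": swipes,
        "sensors": sensors,
    }


def read_session_log(path: str | Path) -> GameSession:
    """Read one JSON session log; raise on parse or schema violations."""
    path = Path(path)
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SessionParseError(f"{path}: not valid JSON ({exc})") from exc
    try:
        return session_from_json(doc)
    except SessionValidationError as exc:
        raise SessionValidationError([f"{path}: {i}" for i in exc.issues]) from None


def write_session_log(session: GameSession, path: str | Path) -> None:
    """Write a session log; two writes of the same session are byte-identical."""
    doc = session_to_json(session)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, separators=(",", ":"), allow_nan=False)
        fh.write("\n")


def read_questionnaires(path: str | Path) -> pd.DataFrame:
    """Read the questionnaire CSV, checking the required columns exist."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in QUESTIONNAIRE_COLUMNS if c not in df.columns]
    if missing:
        raise SwipeLogError(f"questionnaire table missing columns: {missing}")
    return df


def write_questionnaires(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


_ITEM_COLS_GAD = [f"gad7_q{i}" for i in range(1, 8)]
_ITEM_COLS_PHQ = [f"phq8_q{i}" for i in range(1, 9)]


def link_records(
    sessions: Iterable[GameSession],
    questionnaires: pd.DataFrame,
) -> tuple[list[CohortRecord], list[tuple[str, str]]]:
    """Join gameplay sessions to questionnaire rows by participant id.

    Only participants with at least one session *and* complete GAD-7 and PHQ-8
    responses are returned. The second element is a drop log of
    ``(participant_id, reason)`` pairs for every id excluded. Duplicate
    questionnaire rows with conflicting answers raise :class:`LinkError`.
    """
    by_pid: dict[str, dict[str, GameSession]] = {}
    for s in sessions:
        by_pid.setdefault(s.participant_id, {})[s.game] = s

    if "participant_id" not in questionnaires.columns:
        if len(questionnaires) == 0:
            questionnaires = pd.DataFrame(columns=QUESTIONNAIRE_COLUMNS)
        else:
            raise SwipeLogError("questionnaire table lacks a participant_id column")
    q = questionnaires.drop_duplicates()
    dupes = q["participant_id"][q["participant_id"].duplicated()]
    if len(dupes):
        raise LinkError(
            "conflicting questionnaire rows for participant id(s): "
            f"{sorted(set(dupes))}"
        )
    q = q.set_index("participant_id")

    records: list[CohortRecord] = []
    drop_log: list[tuple[str, str]] = []
    for pid in sorted(by_pid):
        if pid not in q.index:
            drop_log.append((pid, "no_questionnaire"))
            continue
        row = q.loc[pid]
        gad = row[_ITEM_COLS_GAD]
        phq = row[_ITEM_COLS_PHQ]
        if gad.isna().any() or phq.isna().any():
            drop_log.append((pid, "incomplete_questionnaire"))
            continue
        records.append(CohortRecord(
            participant_id=pid,
            sessions=by_pid[pid],
            gad7_items=[int(v) for v in gad],
            phq8_items=[int(v) for v in phq],
            demographics={k: row[k] for k in ("age_band", "sex", "gamer_identity")
                          if k in row.index},
        ))
    for pid in q.index:
        if pid not in by_pid:
            drop_log.append((pid, "no_sessions"))
    return records, drop_log
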