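"""Cleaning, per-swipe kinematics and per-session feature aggregation.

The raw event stream of a session is turned into one participant x game
feature vector in three steps:

1. *Cleaning* — swipes logged outside the gameplay window (menu interactions)
   and sub-threshold swipes (taps, palm touches) are removed.
2. *Outlier removal* — each per-swipe metric sequence is filtered with the
   Tukey IQR rule (fences at Q1 - m*IQR / Q3 + m*IQR, linear-interpolation
   quantiles, m = 1.5 by default) before aggregation.
3. *Aggregation* — every per-swipe base metric is summarised with 8 statistical
   functions (mean, median, max, min, SD, range, first, last); pooled path
   positions with 4 (SD, min, max, range); inter-swipe gaps with 6; each sensor
   axis with 6 (mean, median, SD, min, max, range). Sample (n-1) SD is used
   throughout. Together with the per-direction and total swipe counts this
   yields ~150-160 named features per game.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import DIRECTIONAL_GAMES, DIRECTIONS, GAMES, GameSession, SwipeEvent

#: number of path points over which the start/end pressure "variance" is taken
PRESS_WINDOW = 5


class TapError(ValueError):
    """Signal that a path is a tap (single point or zero duration), not a swipe."""


class CatalogError(ValueError):
    pass


@dataclass(frozen=True)
class CleaningConfig:
    """Knobs of the cleaning and outlier-removal steps.

    ``min_swipe_distance`` separates intentional swipes from taps/false touches
    (px of total path length). ``iqr_scope`` selects whether the Tukey filter
    runs on each participant's per-swipe value sequences before aggregation
    (``per_participant_metric``, default) or on the aggregated participant-level
    features across the cohort (``pooled_metric``). ``speed_mode`` selects the
    numerator of speed: total path length (default) or net displacement.
    """

    min_swipe_distance: float = 20.0
    iqr_multiplier: float = 1.5
    iqr_scope: str = "per_participant_metric"
    speed_mode: str = "path"

    def __post_init__(self):
        if self.min_swipe_distance < 0:
            raise ValueError("min_swipe_distance must be >= 0")
        if self.iqr_multiplier <= 0:
            raise ValueError("iqr_multiplier must be > 0")
        if self.iqr_scope not in ("per_participant_metric", "pooled_metric"):
            raise ValueError(f"unknown iqr_scope {self.iqr_scope!r}")
        if self.speed_mode not in ("path", "displacement"):
            raise ValueError(f"unknown speed_mode {self.speed_mode!r}")


def quantize_direction(dx: float, dy: float) -> str:
    """Dominant-axis swipe direction; exact ties go to the horizontal axis."""
    if dx == 0 and dy == 0:
        raise ValueError("zero displacement has no direction (should be filtered as a tap)")
    if abs(dx) >= abs(dy):
        return "right" if dx > 0 else "left"
    return "up" if dy > 0 else "down"


def path_length(path: np.ndarray) -> float:
    """Total screen distance covered: sum of consecutive segment lengths."""
    p = np.asarray(path, dtype=float)
    return float(np.hypot(np.diff(p[:, 1]), np.diff(p[:, 2])).sum())


def _window_var(press: np.ndarray) -> float:
    # sample variance; a single-point window has no spread
    return float(np.var(press, ddof=1)) if press.size > 1 else 0.0


def derive_swipe_metrics(
    path: np.ndarray | Sequence[Sequence[float]],
    *,
    swipe_id: int,
    event_time: float,
    start_time: float,
    game: str,
    time_between_swipes: Optional[float] = None,
    config: CleaningConfig | None = None,
) -> SwipeEvent:
    """Recompute every per-swipe metric from a raw touch path.

    ``path`` rows are (t, x, y, press) with t in seconds since the swipe
    started. Single-point paths and zero-duration paths raise :class:`TapError`
    so the caller can filter them as taps.
    """
    config = config or CleaningConfig()
    p = np.asarray(path, dtype=float)
    if p.ndim != 2 or p.shape[1] != 4:
        raise ValueError("path must be an (n, 4) array of (t, x, y, press)")
    if p.shape[0] < 2:
        raise TapError("single-point path is a tap, not a swipe")
    duration = float(p[-1, 0] - p[0, 0])
    if duration <= 0:
        raise TapError("zero-duration path is a tap, not a swipe")
    dist = path_length(p)
    dx = float(p[-1, 1] - p[0, 1])
    dy = float(p[-1, 2] - p[0, 2])
    displacement = float(np.hypot(dx, dy))
    speed_dist = dist if config.speed_mode == "path" else displacement
    press = p[:, 3]
    k = min(PRESS_WINDOW, p.shape[0])
    if game in DIRECTIONAL_GAMES:
        direction = quantize_direction(dx, dy)
    else:
        direction = "none"
    return SwipeEvent(
        swipe_id=swipe_id,
        event_time=float(event_time),
        start_time=float(start_time),
        end_time=float(start_time) + duration,
        start_pos=(float(p[0, 1]), float(p[0, 2])),
        end_pos=(float(p[-1, 1]), float(p[-1, 2])),
        path=p,
        start_press=float(press[0]),
        end_press=float(press[-1]),
        press_mean=float(press.mean()),
        start_press_variance=_window_var(press[:k]),
        end_press_variance=_window_var(press[-k:]),
        press_variance=_window_var(press),
        speed=speed_dist / duration,
        duration=duration,
        distance=dist,
        direction=direction,
        time_between_swipes=time_between_swipes,
    )


def clean_swipes(
    session: GameSession, config: CleaningConfig | None = None
) -> tuple[GameSession, dict[str, int]]:
    """Drop menu-window swipes and sub-threshold swipes (taps/false touches).

    Returns a new session (input untouched) plus a removal log counting drops
    by reason: ``menu`` (event_time outside the gameplay window) and
    ``sub_threshold`` (total path length below ``min_swipe_distance``).
    """
    config = config or CleaningConfig()
    lo, hi = session.gameplay_window
    kept: list[SwipeEvent] = []
    log = {"menu": 0, "sub_threshold": 0}
    for sw in session.swipes:
        if not lo <= sw.event_time <= hi:
            log["menu"] += 1
            continue
        # the logged distance is the total path length (recompute if absent)
        dist = sw.distance if np.isfinite(sw.distance) else path_length(sw.path)
        if dist < config.min_swipe_distance:
            log["sub_threshold"] += 1
            continue
        kept.append(sw)
    cleaned = replace(session, swipes=kept)
    return cleaned, log


def iqr_filter(
    values: Sequence[float] | np.ndarray, multiplier: float = 1.5
) -> tuple[np.ndarray, np.ndarray]:
    """Tukey fence outlier removal on a numeric sequence.

    Returns ``(retained, outlier_mask)`` where ``retained`` preserves the input
    order and ``outlier_mask`` is True for removed values. Quartiles use the
    linear-interpolation rule. Sequences with fewer than 4 values pass through
    unchanged (quartiles are not meaningful there).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        return v.copy(), np.zeros(v.size, dtype=bool)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    mask = (v < q1 - multiplier * iqr) | (v > q3 + multiplier * iqr)
    return v[~mask], mask


# ---------------------------------------------------------------------------
# Feature catalog
# ---------------------------------------------------------------------------

#: per-swipe scalar bases in log order, with a plain-language description
_SCALAR_BASES = [
    ("swipe_start_posX", "x coordinate (px) where the swipe started"),
    ("swipe_start_posY", "y coordinate (px) where the swipe started"),
    ("swipe_end_posX", "x coordinate (px) where the swipe ended"),
    ("swipe_end_posY", "y coordinate (px) where the swipe ended"),
    ("swipe_start_press", "pressure proxy at the first touch point of the swipe"),
    ("swipe_end_press", "pressure proxy at the last touch point of the swipe"),
    ("swipe_start_press_variance",
     f"variance of the pressure proxy over the first {PRESS_WINDOW} path points"),
    ("swipe_end_press_variance",
     f"variance of the pressure proxy over the last {PRESS_WINDOW} path points"),
    ("swipe_press", "average pressure proxy over the whole swipe"),
    ("swipe_press_variance", "variance of the pressure proxy over the whole swipe"),
    ("swipe_speed", "swipe speed in px/s (path length over duration)"),
    ("swipe_duration", "time in seconds the swipe took"),
    ("swipe_distance", "total screen distance in px covered by the swipe"),
]
_POOLED_BASES = [
    ("swipe_posX", "x coordinates (px) of every touch point of every swipe, pooled"),
    ("swipe_posY", "y coordinates (px) of every touch point of every swipe, pooled"),
]
_TBS_BASE = ("time_between_swipes", "seconds elapsed since the previous swipe ended")

AGGREGATORS_FULL = ("mean", "median", "max", "min", "std", "range", "first", "last")
AGGREGATORS_POOLED = ("std", "min", "max", "range")
AGGREGATORS_TBS = ("mean", "median", "std", "min", "max", "range")
AGGREGATORS_SENSOR = ("mean", "median", "std", "min", "max", "range")

_SENSOR_BASES = [
    (f"{prefix}_{axis}", f"{name} reading along the {axis.lower()}-axis")
    for prefix, name in (("acl", "accelerometer"), ("gyro", "gyroscope"))
    for axis in ("X", "Y", "Z")
]

_AGG_DESCRIPTION = {
    "mean": "mean", "median": "median", "max": "maximum", "min": "minimum",
    "std": "SD", "range": "range (max - min)", "first": "first value",
    "last": "last value",
}


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    base: str
    aggregator: str
    definition: str


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered, deterministic list of the features extracted for one game."""

    game: str
    entries: tuple[CatalogEntry, ...]

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def build_catalog(game: str) -> FeatureCatalog:
    """Deterministic feature catalog for a game (direction features only for
    the four-direction games; the slicer has none)."""
    if game not in GAMES:
        raise CatalogError(f"unknown game {game!r}; expected one of {GAMES}")
    entries: list[CatalogEntry] = []

    def add(base, agg, desc):
        entries.append(CatalogEntry(f"{base}_{agg}", base, agg,
                                    f"{_AGG_DESCRIPTION[agg]} across the session of the {desc}"))

    for base, desc in _SCALAR_BASES:
        for agg in AGGREGATORS_FULL:
            add(base, agg, desc)
    for base, desc in _POOLED_BASES:
        for agg in AGGREGATORS_POOLED:
            add(base, agg, desc)
    for agg in AGGREGATORS_TBS:
        add(_TBS_BASE[0], agg, _TBS_BASE[1])
    if game in DIRECTIONAL_GAMES:
        for d in DIRECTIONS:
            entries.append(CatalogEntry(
                f"swipe_count_{d}", "swipe_count", f"count_{d}",
                f"number of swipes performed in the {d} direction"))
    for base, desc in _SENSOR_BASES:
        for agg in AGGREGATORS_SENSOR:
            add(base, agg, desc)
    entries.append(CatalogEntry("swipe_count", "swipe_count", "count",
                                "total number of swipes performed in the session"))
    return FeatureCatalog(game, tuple(entries))


@dataclass
class FeatureVector:
    """Per participant x game mapping of catalog feature name -> value."""

    participant_id: str
    game: str
    values: dict[str, float]


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _agg(values: np.ndarray, agg: str) -> float:
    if values.size == 0:
        return np.nan
    if agg == "mean":
        return float(values.mean())
    if agg == "median":
        return float(np.median(values))
    if agg == "max":
        return float(values.max())
    if agg == "min":
        return float(values.min())
    if agg == "std":
        return float(np.std(values, ddof=1)) if values.size > 1 else np.nan
    if agg == "range":
        return float(values.max() - values.min())
    if agg == "first":
        return float(values[0])
    if agg == "last":
        return float(values[-1])
    raise CatalogError(f"unknown aggregator {agg!r}")


_BASE_ATTR = {
    "swipe_start_press": "start_press",
    "swipe_end_press": "end_press",
    "swipe_start_press_variance": "start_press_variance",
    "swipe_end_press_variance": "end_press_variance",
    "swipe_press": "press_mean",
    "swipe_press_variance": "press_variance",
    "swipe_speed": "speed",
    "swipe_duration": "duration",
    "swipe_distance": "distance",
}


def _base_values(session: GameSession) -> dict[str, np.ndarray]:
    """Per-swipe value sequence (event_time order) for every base metric."""
    swipes = sorted(session.swipes, key=lambda s: s.event_time)
    out: dict[str, np.ndarray] = {}
    out["swipe_start_posX"] = np.array([s.start_pos[0] for s in swipes], dtype=float)
    out["swipe_start_posY"] = np.array([s.start_pos[1] for s in swipes], dtype=float)
    out["swipe_end_posX"] = np.array([s.end_pos[0] for s in swipes], dtype=float)
    out["swipe_end_posY"] = np.array([s.end_pos[1] for s in swipes], dtype=float)
    for base, attr in _BASE_ATTR.items():
        out[base] = np.array([getattr(s, attr) for s in swipes], dtype=float)
    out["time_between_swipes"] = np.array(
        [s.time_between_swipes for s in swipes if s.time_between_swipes is not None],
        dtype=float,
    )
    if swipes:
        out["swipe_posX"] = np.concatenate([s.path[:, 1] for s in swipes])
        out["swipe_posY"] = np.concatenate([s.path[:, 2] for s in swipes])
    else:
        out["swipe_posX"] = out["swipe_posY"] = np.empty(0)
    return out


def aggregate_session(
    session: GameSession,
    catalog: FeatureCatalog | None = None,
    config: CleaningConfig | None = None,
) -> FeatureVector:
    """Aggregate a *cleaned* session into its feature vector.

    With the default ``per_participant_metric`` scope every per-swipe metric
    sequence is IQR-filtered before the aggregators run. Sessions with no
    swipes report all swipe features as missing and ``swipe_count`` 0. Sensor
    streams are aggregated unfiltered: their extremes (e.g. minimum axis
    acceleration) are part of the signal and the streams are not event noise.
    """
    config = config or CleaningConfig()
    catalog = catalog or build_catalog(session.game)
    if catalog.game != session.game:
        raise CatalogError(
            f"catalog is for {catalog.game!r} but session is {session.game!r}"
        )
    base_vals = _base_values(session)
    if config.iqr_scope == "per_participant_metric":
        base_vals = {
            k: iqr_filter(v, config.iqr_multiplier)[0] for k, v in base_vals.items()
        }
    sensor_stats: dict[str, dict[str, float]] = {}
    for prefix, stream_name in (("acl", "accelerometer"), ("gyro", "gyroscope")):
        stream = session.sensors.get(stream_name)
        for j, axis in enumerate(("X", "Y", "Z")):
            if stream is None or len(stream) == 0:
                sensor_stats[f"{prefix}_{axis}"] = {
                    agg: float("nan") for agg in AGGREGATORS_SENSOR}
                continue
            col = np.ascontiguousarray(np.asarray(stream.values)[:, j])
            mn, mx = float(col.min()), float(col.max())
            sensor_stats[f"{prefix}_{axis}"] = {
                "mean": float(col.mean()),
                "median": float(np.median(col)),
                "std": float(col.std(ddof=1)) if col.size > 1 else float("nan"),
                "min": mn, "max": mx, "range": mx - mn,
            }
    dir_counts = {d: 0 for d in DIRECTIONS}
    for sw in session.swipes:
        if sw.direction in dir_counts:
            dir_counts[sw.direction] += 1

    values: dict[str, float] = {}
    for entry in catalog.entries:
        if entry.base == "swipe_count":
            if entry.aggregator == "count":
                values[entry.name] = float(len(session.swipes))
            else:  # count_<direction>
                values[entry.name] = float(dir_counts[entry.aggregator[len("count_"):]])
        elif entry.base in sensor_stats:
            values[entry.name] = sensor_stats[entry.base][entry.aggregator]
        else:
            values[entry.name] = _agg(base_vals[entry.base], entry.aggregator)
    return FeatureVector(session.participant_id, session.game, values)


def feature_table(
    sessions: Iterable[GameSession],
    config: CleaningConfig | None = None,
    catalog: FeatureCatalog | None = None,
    clean: bool = True,
) -> pd.DataFrame:
    """Clean and aggregate single-game sessions into a participant x feature table.

    Rows are indexed by participant id, columns follow the catalog order. With
    ``iqr_scope='pooled_metric'`` the Tukey filter runs column-wise on the
    aggregated table (outlying participant values become missing) instead of on
    the per-swipe sequences.
    """
    config = config or CleaningConfig()
    rows = {}
    for session in sessions:
        if catalog is None:
            catalog = build_catalog(session.game)
        if clean:
            session, _ = clean_swipes(session, config)
        fv = aggregate_session(session, catalog, config)
        rows[fv.participant_id] = fv.values
    df = pd.DataFrame.from_dict(rows, orient="index")
    if catalog is not None:
        df = df.reindex(columns=catalog.names)
    df.index.name = "participant_id"
    if config.iqr_scope == "pooled_metric":
        df = iqr_filter_table(df, config.iqr_multiplier)
    return df.sort_index()


def iqr_filter_table(df: pd.DataFrame, multiplier: float = 1.5) -> pd.DataFrame:
    """Column-wise Tukey filtering of an aggregated feature table.

    Outlying participant-level values are replaced with NaN; count columns are
    left untouched (they are discrete totals, not trace noise).
    """
    out = df.copy()
    for col in out.columns:
        if col.startswith("swipe_count"):
            continue
        v = out[col].to_numpy(dtype=float)
        ok = np.isfinite(v)
        if ok.sum() < 4:
            continue
        q1, q3 = np.percentile(v[ok], [25, 75])
        iqr = q3 - q1
        bad = ok & ((v < q1 - multiplier * iqr) | (v > q3 + multiplier * iqr))
        out.loc[bad, col] = np.nan
    return out


def catalog_to_frame(catalog: FeatureCatalog) -> pd.DataFrame:
    """Catalog as a (name, base, aggregator, definition) table for export."""
    return pd.DataFrame(
        [(e.name, e.base, e.aggregator, e.definition) for e in catalog.entries],
        columns=["name", "base", "aggregator", "definition"],
    )
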