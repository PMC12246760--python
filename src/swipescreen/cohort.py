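"""Synthetic cohort generator with calibrated planted effects.

Real cohorts of this kind (participants playing three casual mobile games
while their swipes are logged, then answering GAD-7/PHQ-8) are rarely shared,
so this module generates complete stand-in cohorts: a latent bivariate-normal
(anxiety, depression) severity per participant drives both the questionnaire
item responses and selected swipe parameters of the generated touch streams.

Two calibration layers make the cohorts quantitatively useful:

* The ordinal item model (each item is a clamped, discretised noisy reading of
  the latent trait) is solved deterministically by Gauss-Hermite quadrature so
  the population total means/SDs hit the configured targets
  (defaults 9.09 / 5.26 for GAD-7 and 8.24 / 4.95 for PHQ-8).
* Each planted effect maps a latent-trait combination onto one swipe parameter
  (log-link for positive-only parameters) such that the *end-to-end* pipeline
  (synthesize -> clean -> IQR -> aggregate -> Spearman) recovers a target rank
  correlation. Loadings are solved analytically from the target, with a
  per-mechanism attenuation factor (session aggregation + rank conversion
  losses) refined by Monte-Carlo in :func:`calibrate_effect`; the shipped
  ``ATTENUATION`` table holds the calibrated values for the default effect map.

Planting an effect never changes a swipe parameter's marginal distribution:
the participant-level deviation is always a unit-variance mixture of the two
traits and independent noise, so effects alter only the correlation structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .features import CleaningConfig, build_catalog, feature_table
from .io import QUESTIONNAIRE_COLUMNS
from .model import (
    DIRECTIONAL_GAMES,
    GAMES,
    GameSession,
    ORIENTATION_FOR_GAME,
    SensorStream,
    SwipeEvent,
    default_screen_dims,
)
from .questionnaires import N_ITEMS, score_table
from .screen import spearman


class CohortConfigError(ValueError):
    pass


class CalibrationError(RuntimeError):
    """A planted-effect target cannot be reached given the noise floor."""


# ---------------------------------------------------------------------------
# Effect specification
# ---------------------------------------------------------------------------

#: which participant-level swipe parameter each plantable feature rides on
MECHANISM_FOR_FEATURE = {
    "swipe_speed_mean": "speed",
    "swipe_end_press_variance_mean": "press_jitter",
    "swipe_start_posY_min": "start_y",
    "swipe_press_min": "press_level",
}

TRAIT_FOR_INSTRUMENT = {"PHQ8": "dep", "GAD7": "anx"}


@dataclass(frozen=True)
class EffectSpec:
    """One planted (game, feature, instrument) rank-correlation target."""

    game: str
    feature_name: str
    instrument: str
    target_spearman: float
    #: which swipe parameter the latent trait shifts
    mechanism: str = ""
    note: str = ""

    def __post_init__(self):
        if not abs(self.target_spearman) < 1:
            raise CohortConfigError("target_spearman must be in (-1, 1)")
        if self.game not in GAMES:
            raise CohortConfigError(f"unknown game {self.game!r}")
        if self.instrument not in TRAIT_FOR_INSTRUMENT:
            raise CohortConfigError(f"unknown instrument {self.instrument!r}")
        if not self.mechanism:
            mech = MECHANISM_FOR_FEATURE.get(self.feature_name)
            if mech is None:
                raise CohortConfigError(
                    f"no known mechanism for feature {self.feature_name!r}; "
                    "set EffectSpec.mechanism explicitly"
                )
            object.__setattr__(self, "mechanism", mech)
        if self.feature_name not in _catalog_names(self.game):
            raise CohortConfigError(
                f"{self.feature_name!r} is not in the {self.game} feature catalog"
            )


@lru_cache(maxsize=8)
def _catalog_names(game: str) -> frozenset:
    return frozenset(build_catalog(game).names)


#: Default planted-effect map: the strongest association per mechanism and
#: game from the exploratory-study effect catalog this generator emulates
#: (mean swipe speed and end-pressure variability fall with severity; slicer
#: swipe start height and minimum pressure rise with it).
DEFAULT_EFFECTS = (
    EffectSpec("puzzle", "swipe_speed_mean", "PHQ8", -0.405,
               note="psychomotor slowing: depression lowers swipe speed"),
    EffectSpec("puzzle", "swipe_speed_mean", "GAD7", -0.400,
               note="attentional-control load: anxiety lowers swipe speed"),
    EffectSpec("puzzle", "swipe_end_press_variance_mean", "PHQ8", -0.425,
               note="flatter end-of-swipe pressure modulation with depression"),
    EffectSpec("puzzle", "swipe_end_press_variance_mean", "GAD7", -0.317),
    EffectSpec("runner", "swipe_end_press_variance_mean", "PHQ8", -0.405),
    EffectSpec("runner", "swipe_end_press_variance_mean", "GAD7", -0.309),
    EffectSpec("slicer", "swipe_start_posY_min", "PHQ8", 0.368,
               note="attentional fixation: swipes start higher on the screen"),
    EffectSpec("slicer", "swipe_start_posY_min", "GAD7", 0.370),
    EffectSpec("slicer", "swipe_press_min", "PHQ8", 0.388,
               note="muscle tension raises the pressure floor"),
    EffectSpec("slicer", "swipe_press_min", "GAD7", 0.430),
)

#: Monte-Carlo calibrated end-to-end correction per (game, mechanism): the
#: factor by which session aggregation, cleaning/IQR, order-statistic noise
#: and the rank conversion on discrete totals rescale the planted latent
#: correlation (values slightly above 1 occur where the Spearman-to-Pearson
#: conversion overshoots on tied totals). Averaged over 3 x 100 replicates of
#: n=78; regenerate with scripts/calibrate_defaults.py.
ATTENUATION = {
    ("puzzle", "speed"): 0.9914,
    ("puzzle", "press_jitter"): 1.0070,
    ("runner", "press_jitter"): 1.0049,
    ("slicer", "start_y"): 0.9057,
    ("slicer", "press_level"): 1.0129,
}
_DEFAULT_ATTENUATION = 0.95


@dataclass(frozen=True)
class CalibratedEffect:
    """Loadings of one swipe parameter on the latent traits.

    The participant's parameter deviation is the unit-variance driver
    ``u = w_dep * z_dep + w_anx * z_anx + w_noise * eps``.
    """

    game: str
    mechanism: str
    w_dep: float
    w_anx: float
    w_noise: float
    attenuation: Optional[float] = None
    achieved: Optional[dict] = None


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

def _default_swipes():
    return {"puzzle": 350, "runner": 500, "slicer": 400}


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generator needs; fully determines a cohort given a seed.

    The questionnaire targets default to the reference sample's totals
    (GAD-7 mean 9.09, SD 5.26; PHQ-8 mean 8.24, SD 4.95). ``item_noise_sd``
    is the per-item measurement noise of the ordinal item model, on the latent
    (standard-normal) scale. ``unmatched_id_count`` mislabels the device ids
    of the last k participants' sessions so record linkage can be exercised.
    """

    n_participants: int = 82
    seed: int = 0
    gad7_mean: float = 9.09
    gad7_sd: float = 5.26
    phq8_mean: float = 8.24
    phq8_sd: float = 4.95
    item_noise_sd: float = 0.9
    trait_correlation: float = 0.6
    games: tuple[str, ...] = GAMES
    swipes_per_session: dict = field(default_factory=_default_swipes)
    within_speed_sigma: float = 0.25
    sensor_rate_hz: float = 50.0
    session_limit: float = 900.0
    gameplay_window: tuple[float, float] = (5.0, 895.0)
    effects: tuple[EffectSpec, ...] = DEFAULT_EFFECTS
    #: overrides for the calibrated attenuation table, keyed (game, mechanism)
    attenuation: dict = field(default_factory=dict)
    unmatched_id_count: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise CohortConfigError("n_participants must be >= 1")
        for name in ("gad7_sd", "phq8_sd", "item_noise_sd"):
            if getattr(self, name) <= 0:
                raise CohortConfigError(f"{name} must be > 0")
        if not -1 <= self.trait_correlation <= 1:
            raise CohortConfigError("trait_correlation must be in [-1, 1]")
        unknown = [g for g in self.games if g not in GAMES]
        if unknown:
            raise CohortConfigError(f"unknown games {unknown}")
        if not 0 <= self.unmatched_id_count <= self.n_participants:
            raise CohortConfigError("unmatched_id_count must be in [0, n_participants]")
        if not 0 <= self.gameplay_window[0] < self.gameplay_window[1] <= self.session_limit:
            raise CohortConfigError("gameplay_window must be inside [0, session_limit]")


# ---------------------------------------------------------------------------
# Ordinal item model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ItemModel:
    """Item = clamp(round(a + b*z + s*eps)) with thresholds at 0.5/1.5/2.5."""

    n_items: int
    a: float
    b: float
    s: float
    mean_total: float
    sd_total: float
    r_latent: float  # corr(z, total)


@lru_cache(maxsize=32)
def item_model(n_items: int, mean_total: float, sd_total: float,
               noise_sd: float) -> ItemModel:
    """Solve the item intercept/slope so the total hits the target mean/SD.

    Items are conditionally iid given the trait z, so the total's moments are
    one-dimensional Gaussian integrals, evaluated by Gauss-Hermite quadrature;
    (a, b) then solve a smooth 2x2 root problem. Deterministic and exact to
    quadrature/solver precision — no simulation involved.
    """
    nodes, wts = np.polynomial.hermite_e.hermegauss(81)
    w = wts / math.sqrt(2 * math.pi)
    ks = np.array([0.5, 1.5, 2.5])

    def moments(a: float, b: float):
        lin = a + b * nodes  # (q,)
        z01 = (lin[:, None] - ks[None, :]) / noise_sd
        tail = stats.norm.sf(-z01)  # P(item >= j | z) for j = 1, 2, 3
        m = tail.sum(axis=1)                      # E[item | z]
        e2 = (tail * np.array([1.0, 3.0, 5.0])).sum(axis=1)  # E[item^2 | z]
        v = e2 - m ** 2
        em = float(w @ m)
        mean_t = n_items * em
        var_t = n_items * float(w @ v) + n_items ** 2 * (float(w @ m ** 2) - em ** 2)
        cov_zt = n_items * float(w @ (nodes * m))
        return mean_t, var_t, cov_zt

    def fun(p):
        mean_t, var_t, _ = moments(p[0], math.exp(p[1]))
        return [mean_t - mean_total, math.sqrt(max(var_t, 1e-12)) - sd_total]

    per_item = mean_total / n_items
    sol = optimize.root(fun, x0=[per_item, math.log(0.8)], method="hybr", tol=1e-12)
    if not sol.success or max(abs(np.asarray(fun(sol.x)))) > 1e-6:
        raise CalibrationError(
            f"item model unsolvable for mean={mean_total}, sd={sd_total}: {sol.message}"
        )
    a, b = float(sol.x[0]), float(math.exp(sol.x[1]))
    mean_t, var_t, cov_zt = moments(a, b)
    return ItemModel(n_items, a, b, noise_sd, mean_t, math.sqrt(var_t),
                     cov_zt / math.sqrt(var_t))


def _items_from_latent(im: ItemModel, z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    z = np.atleast_1d(np.asarray(z, dtype=float))
    raw = im.a + im.b * z[:, None] + im.s * rng.standard_normal((z.size, im.n_items))
    return np.clip(np.floor(raw + 0.5), 0, 3).astype(int)


def generate_item_responses(latent: float, instrument: str, config: CohortConfig,
                            rng: np.random.Generator) -> np.ndarray:
    """Item ratings (ints in 0..3) for one participant's latent trait value."""
    if instrument == "GAD7":
        im = item_model(N_ITEMS["GAD7"], config.gad7_mean, config.gad7_sd,
                        config.item_noise_sd)
    elif instrument == "PHQ8":
        im = item_model(N_ITEMS["PHQ8"], config.phq8_mean, config.phq8_sd,
                        config.item_noise_sd)
    else:
        raise CohortConfigError(f"unknown instrument {instrument!r}")
    return _items_from_latent(im, np.array([latent]), rng)[0]


def _instrument_models(config: CohortConfig) -> dict[str, ItemModel]:
    return {
        "GAD7": item_model(7, config.gad7_mean, config.gad7_sd, config.item_noise_sd),
        "PHQ8": item_model(8, config.phq8_mean, config.phq8_sd, config.item_noise_sd),
    }


# ---------------------------------------------------------------------------
# Loading solver
# ---------------------------------------------------------------------------

def _solve_loadings(
    targets: dict[str, float],
    config: CohortConfig,
    game: str,
    mechanism: str,
    attenuation: float | None = None,
) -> CalibratedEffect:
    """Trait loadings whose end-to-end Spearman hits the targets.

    Converts each Spearman target to the latent Pearson scale (Greiner's
    relation r = 2 sin(pi * rho / 6)), divides out the instrument's latent-to-
    total correlation and the mechanism's attenuation factor, and solves the
    2x2 linear system given the trait correlation. Raises
    :class:`CalibrationError` when the implied driver variance exceeds 1
    (target unreachable over the noise floor).
    """
    if attenuation is None:
        attenuation = config.attenuation.get(
            (game, mechanism), ATTENUATION.get((game, mechanism), _DEFAULT_ATTENUATION))
    models = _instrument_models(config)
    rho_t = config.trait_correlation
    c = {"dep": 0.0, "anx": 0.0}
    have = {"dep": False, "anx": False}
    for inst, target in targets.items():
        trait = TRAIT_FOR_INSTRUMENT[inst]
        r_needed = 2 * math.sin(math.pi * target / 6) / (attenuation * models[inst].r_latent)
        if abs(r_needed) >= 1:
            raise CalibrationError(
                f"target rho {target} for {inst} needs latent correlation "
                f"{r_needed:.3f} >= 1 given attenuation {attenuation:.3f}"
            )
        c[trait] = r_needed
        have[trait] = True
    if have["dep"] and have["anx"]:
        det = 1 - rho_t ** 2
        if det <= 1e-9:
            raise CalibrationError("trait correlation +-1 cannot separate two targets")
        v_d = (c["dep"] - rho_t * c["anx"]) / det
        v_a = (c["anx"] - rho_t * c["dep"]) / det
    elif have["dep"]:
        v_d, v_a = c["dep"], 0.0
    else:
        v_d, v_a = 0.0, c["anx"]
    q = v_d ** 2 + v_a ** 2 + 2 * rho_t * v_d * v_a
    if q >= 0.98:
        raise CalibrationError(
            f"targets {targets} for ({game}, {mechanism}) imply driver variance "
            f"{q:.3f} >= 1: unattainable over the noise floor"
        )
    return CalibratedEffect(game, mechanism, v_d, v_a, math.sqrt(1 - q),
                            attenuation=attenuation)


def resolve_effects(config: CohortConfig) -> dict[tuple[str, str], CalibratedEffect]:
    """Group the config's effect specs by (game, mechanism) and solve loadings."""
    groups: dict[tuple[str, str], dict[str, float]] = {}
    for spec in config.effects:
        key = (spec.game, spec.mechanism)
        tgt = groups.setdefault(key, {})
        if spec.instrument in tgt and tgt[spec.instrument] != spec.target_spearman:
            raise CohortConfigError(
                f"conflicting targets for {key} / {spec.instrument}"
            )
        tgt[spec.instrument] = spec.target_spearman
    return {
        key: _solve_loadings(targets, config, key[0], key[1])
        for key, targets in groups.items()
    }


# ---------------------------------------------------------------------------
# Participant profiles and session synthesis
# ---------------------------------------------------------------------------

#: parameter -> (link, per-game base, between-participant scale). The scale is
#: the SD of the parameter deviation: multiplicative (log-link) for
#: positive-only parameters, additive for bounded/positional ones.
_PARAM_LINKS = {
    "speed": ("log", {"puzzle": 500.0, "runner": 700.0, "slicer": 900.0}, 0.18),
    "press_level": ("add", {"puzzle": 0.45, "runner": 0.45, "slicer": 0.45}, 0.06),
    "press_jitter": ("log", {"puzzle": 0.03, "runner": 0.03, "slicer": 0.03}, 0.18),
    "start_y": ("add", {"puzzle": 540.0, "runner": 1200.0, "slicer": 520.0}, 60.0),
    "gap_scale": ("log", {"puzzle": 1.0, "runner": 1.0, "slicer": 1.0}, 0.15),
    "sensor_amp": ("log", {"puzzle": 0.25, "runner": 0.35, "slicer": 0.30}, 0.30),
}
_PARAM_ORDER = tuple(sorted(_PARAM_LINKS))

_GAME_GEOM = {
    "puzzle": dict(med_len=300.0, len_sigma=0.40, dir_probs=(0.25, 0.25, 0.25, 0.25),
                   arc_frac=0.04, sx_frac=1 / 6, sy_sd=180.0, margin=48.0,
                   level_mean=60.0),
    "runner": dict(med_len=350.0, len_sigma=0.35, dir_probs=(0.35, 0.25, 0.20, 0.20),
                   arc_frac=0.04, sx_frac=1 / 8, sy_sd=260.0, margin=48.0,
                   level_mean=45.0),
    "slicer": dict(med_len=600.0, len_sigma=0.35, dir_probs=None,
                   arc_frac=0.10, sx_frac=1 / 5, sy_sd=90.0, margin=40.0,
                   level_mean=50.0),
}
#: unit vectors for (up, down, left, right)
_DIR_VECS = np.array([[0.0, 1.0], [0.0, -1.0], [-1.0, 0.0], [1.0, 0.0]])


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent traits plus the realised per-game swipe parameters."""

    participant_id: str
    z_dep: float
    z_anx: float
    params: dict  # game -> {param: value}


def build_profile(
    participant_id: str,
    z_dep: float,
    z_anx: float,
    config: CohortConfig,
    effects: dict[tuple[str, str], CalibratedEffect],
    rng: np.random.Generator,
) -> ParticipantProfile:
    """Realise one participant's swipe parameters from traits + planted effects."""
    params: dict[str, dict[str, float]] = {}
    for game in config.games:
        gp: dict[str, float] = {}
        for name in _PARAM_ORDER:
            link, bases, scale = _PARAM_LINKS[name]
            eff = effects.get((game, name))
            eps = rng.standard_normal()
            if eff is None:
                u = eps
            else:
                u = eff.w_dep * z_dep + eff.w_anx * z_anx + eff.w_noise * eps
            base = bases[game]
            gp[name] = base * math.exp(scale * u) if link == "log" else base + scale * u
        params[game] = gp
    return ParticipantProfile(participant_id, float(z_dep), float(z_anx), params)


def _masked_var(values: np.ndarray, mask: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Row-wise sample variance of masked (n, k) values; 0 where count < 2."""
    s = (values * mask).sum(axis=1)
    mean = s / counts
    ss = (((values - mean[:, None]) * mask) ** 2).sum(axis=1)
    return np.where(counts > 1, ss / np.maximum(counts - 1, 1), 0.0)


def synthesize_session(
    profile: ParticipantProfile,
    game: str,
    config: CohortConfig,
    rng: np.random.Generator,
) -> GameSession:
    """Generate one full game session of swipes and sensor streams.

    Swipes tile the gameplay window as a renewal process (gap + swipe duration),
    so slower swipers complete fewer swipes. Paths are noisy bowed segments
    sampled at ~60 Hz during contact; puzzle/runner swipes are axis-aligned
    with a stored 4-way direction, slicer swipes are longer free-angle slices
    with direction ``none``. Sensor streams run at ``sensor_rate_hz`` for the
    whole session with participant-specific motion amplitude.
    """
    geom = _GAME_GEOM[game]
    orientation = ORIENTATION_FOR_GAME[game]
    w_px, h_px = default_screen_dims(orientation)
    p = profile.params[game]
    t0, t1 = config.gameplay_window
    target = max(int(config.swipes_per_session[game]), 1)

    m = int(target * 1.7) + 30
    length = np.clip(rng.lognormal(math.log(geom["med_len"]), geom["len_sigma"], m),
                     60.0, 1500.0)
    v_swipe = p["speed"] * rng.lognormal(0.0, config.within_speed_sigma, m)
    dur = np.clip(length / v_swipe, 0.08, 2.5)
    mean_dur = (geom["med_len"] * math.exp(geom["len_sigma"] ** 2 / 2)
                * math.exp(config.within_speed_sigma ** 2) / p["speed"])
    mean_gap = max(0.06, (t1 - t0) / target - mean_dur)
    gaps = p["gap_scale"] * rng.lognormal(math.log(mean_gap) - 0.18, 0.6, m)
    starts = t0 + np.cumsum(gaps + dur) - dur
    n = int(np.searchsorted(starts + dur, t1))
    length, dur, gaps, starts = length[:n], dur[:n], gaps[:n], starts[:n]

    margin = geom["margin"]
    sx = np.clip(rng.normal(w_px / 2, w_px * geom["sx_frac"], n), margin, w_px - margin)
    sy = np.clip(rng.normal(p["start_y"], geom["sy_sd"], n), margin, h_px - margin)
    if geom["dir_probs"] is not None:
        didx = rng.choice(4, size=n, p=geom["dir_probs"])
        base_ang = np.arctan2(_DIR_VECS[didx, 1], _DIR_VECS[didx, 0])
        ang = base_ang + rng.normal(0.0, 0.06, n)
    else:
        ang = rng.uniform(0.0, 2 * math.pi, n)
    ux, uy = np.cos(ang), np.sin(ang)
    ex, ey = sx + ux * length, sy + uy * length
    # scale overlong swipes into the usable rectangle, then shift them inside
    span_x = np.abs(ex - sx)
    span_y = np.abs(ey - sy)
    scale = np.minimum(1.0, np.minimum(
        (w_px - 2 * margin) / np.maximum(span_x, 1e-9),
        (h_px - 2 * margin) / np.maximum(span_y, 1e-9)))
    ex = sx + (ex - sx) * scale
    ey = sy + (ey - sy) * scale
    for s_, e_, size in ((sx, ex, w_px), (sy, ey, h_px)):
        shift = (np.clip(margin - np.minimum(s_, e_), 0, None)
                 - np.clip(np.maximum(s_, e_) - (size - margin), 0, None))
        s_ += shift
        e_ += shift

    npts = np.clip(np.rint(dur * 60.0).astype(int) + 1, 4, 40)
    maxp = int(npts.max()) if n else 4
    j = np.arange(maxp)
    mask = j[None, :] < npts[:, None]
    frac = np.where(mask, j[None, :] / np.maximum(npts[:, None] - 1, 1), 1.0)
    frac = np.minimum(frac, 1.0)
    t_path = frac * dur[:, None]
    eff_len = length * scale
    bow = np.sin(np.pi * frac) * (geom["arc_frac"] * eff_len
                                  * rng.choice([-1.0, 1.0], n))[:, None]
    along = frac * eff_len[:, None]
    x = np.clip(sx[:, None] + ux[:, None] * along + (-uy)[:, None] * bow
                + rng.normal(0.0, 1.5, (n, maxp)), 0.0, w_px)
    y = np.clip(sy[:, None] + uy[:, None] * along + ux[:, None] * bow
                + rng.normal(0.0, 1.5, (n, maxp)), 0.0, h_px)

    press_base = np.clip(p["press_level"] + rng.normal(0.0, 0.03, n), 0.08, 0.92)
    press = np.clip(
        press_base[:, None] + 0.02 * np.sin(np.pi * frac)
        + rng.normal(0.0, 1.0, (n, maxp)) * p["press_jitter"],
        0.005, 0.995)

    seg = np.hypot(np.diff(x, axis=1), np.diff(y, axis=1)) * mask[:, 1:]
    dist = seg.sum(axis=1)
    speed = dist / dur
    counts = npts.astype(float)
    press_mean = (press * mask).sum(axis=1) / counts
    press_var = _masked_var(press, mask, counts)
    kf = np.minimum(5, npts)
    fmask = j[None, :5] < kf[:, None]
    first_var = _masked_var(press[:, :5], fmask, kf.astype(float))
    lidx = np.minimum((npts - kf)[:, None] + np.arange(5)[None, :], maxp - 1)
    last_vals = np.take_along_axis(press, lidx, axis=1)
    last_var = _masked_var(last_vals, fmask, kf.astype(float))
    rows = np.arange(n)
    end_x = x[rows, npts - 1] if n else np.empty(0)
    end_y = y[rows, npts - 1] if n else np.empty(0)
    end_press = press[rows, npts - 1] if n else np.empty(0)

    # level/round anchors: start_time is relative to the most recent load
    level_bounds = [0.0]
    while level_bounds[-1] < t1:
        level_bounds.append(level_bounds[-1]
                            + rng.lognormal(math.log(geom["level_mean"]) - 0.125, 0.5))
    level_starts = np.array(level_bounds[:-1])
    lvl = np.searchsorted(level_starts, starts, side="right") - 1
    start_rel = starts - level_starts[lvl]

    swipes: list[SwipeEvent] = []
    directional = game in DIRECTIONAL_GAMES
    paths = np.stack((t_path, x, y, press), axis=-1) if n else np.empty((0, 4, 4))
    for i in range(n):
        k = int(npts[i])
        path = paths[i, :k]
        if directional:
            dx, dy = end_x[i] - x[i, 0], end_y[i] - y[i, 0]
            direction = ("right" if dx > 0 else "left") if abs(dx) >= abs(dy) \
                else ("up" if dy > 0 else "down")
        else:
            direction = "none"
        swipes.append(SwipeEvent(
            swipe_id=i + 1,
            event_time=float(starts[i]),
            start_time=float(start_rel[i]),
            end_time=float(start_rel[i] + dur[i]),
            start_pos=(float(x[i, 0]), float(y[i, 0])),
            end_pos=(float(end_x[i]), float(end_y[i])),
            path=path,
            start_press=float(press[i, 0]),
            end_press=float(end_press[i]),
            press_mean=float(press_mean[i]),
            start_press_variance=float(first_var[i]),
            end_press_variance=float(last_var[i]),
            press_variance=float(press_var[i]),
            speed=float(speed[i]),
            duration=float(dur[i]),
            distance=float(dist[i]),
            direction=direction,
            time_between_swipes=None if i == 0 else float(gaps[i]),
        ))

    sensors = _synthesize_sensors(p["sensor_amp"], orientation, config, rng)
    return GameSession(
        participant_id=profile.participant_id,
        game=game,
        orientation=orientation,
        screen_dims=(w_px, h_px),
        swipes=swipes,
        sensors=sensors,
        session_limit=config.session_limit,
        gameplay_window=(t0, t1),
    )


_GRAVITY = {"portrait": (0.5, 4.0, 8.9), "landscape": (4.1, 1.3, 8.7)}


def _synthesize_sensors(amp: float, orientation: str, config: CohortConfig,
                        rng: np.random.Generator) -> dict[str, SensorStream]:
    m = max(int(round(config.session_limit * config.sensor_rate_hz)), 1)
    t = (np.arange(m, dtype=np.float32) / np.float32(config.sensor_rate_hz))
    # slow postural sway shared by both streams (the device moves as one body),
    # plus independent wideband noise per stream; float32 is ample for sensors
    freq = rng.uniform(0.15, 0.45, 3)
    phase = rng.uniform(0, 2 * math.pi, 3)
    sway = np.sin(2 * np.pi * t[:, None] * freq[None, :].astype(np.float32)
                  + phase[None, :].astype(np.float32))
    streams = {}
    for name, base, amp_scale in (
        ("accelerometer", np.array(_GRAVITY[orientation], dtype=np.float32), amp),
        ("gyroscope", np.zeros(3, dtype=np.float32), 0.5 * amp),
    ):
        vals = rng.standard_normal((m, 3), dtype=np.float32)
        vals *= np.float32(0.55 * amp_scale)
        vals += np.float32(0.45 * amp_scale) * sway
        vals += base[None, :]
        streams[name] = SensorStream(name, t, vals)
    return streams


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

_AGE_BANDS = (("18-20", 0.50), ("21-30", 0.45), ("31-40", 0.05))
_SEX = (("male", 0.38), ("female", 0.62))
_GAMER = (("nongamer", 0.18), ("casual_gamer", 0.65), ("gamer", 0.17))


def _choice(rng, table, size):
    names = [t[0] for t in table]
    probs = [t[1] for t in table]
    return rng.choice(names, size=size, p=probs)


def generate_cohort(config: CohortConfig) -> tuple[list[GameSession], pd.DataFrame]:
    """Generate the full cohort: sessions for every configured game plus the
    questionnaire table. Fully reproducible from ``config.seed``; the last
    ``unmatched_id_count`` participants' sessions carry device ids absent from
    the questionnaire table (linkage then drops them)."""
    n = config.n_participants
    ss = np.random.SeedSequence(config.seed)
    s_traits, s_demo, s_sessions = ss.spawn(3)
    rng_t = np.random.default_rng(s_traits)
    z_dep = rng_t.standard_normal(n)
    rho = config.trait_correlation
    z_anx = rho * z_dep + math.sqrt(max(1 - rho ** 2, 0.0)) * rng_t.standard_normal(n)
    models = _instrument_models(config)
    gad_items = _items_from_latent(models["GAD7"], z_anx, rng_t)
    phq_items = _items_from_latent(models["PHQ8"], z_dep, rng_t)

    rng_d = np.random.default_rng(s_demo)
    ids = [f"P{i + 1:04d}" for i in range(n)]
    table = {"participant_id": ids}
    for i in range(7):
        table[f"gad7_q{i + 1}"] = gad_items[:, i]
    for i in range(8):
        table[f"phq8_q{i + 1}"] = phq_items[:, i]
    table["age_band"] = _choice(rng_d, _AGE_BANDS, n)
    table["sex"] = _choice(rng_d, _SEX, n)
    table["gamer_identity"] = _choice(rng_d, _GAMER, n)
    questionnaires = pd.DataFrame(table, columns=list(QUESTIONNAIRE_COLUMNS))

    effects = resolve_effects(config)
    part_seeds = s_sessions.spawn(n)
    sessions: list[GameSession] = []
    first_unmatched = n - config.unmatched_id_count
    for i in range(n):
        subs = part_seeds[i].spawn(1 + len(config.games))
        session_id = ids[i] if i < first_unmatched else f"{ids[i]}-dev"
        profile = build_profile(session_id, z_dep[i], z_anx[i], config, effects,
                                np.random.default_rng(subs[0]))
        for k, game in enumerate(config.games):
            sessions.append(synthesize_session(
                profile, game, config, np.random.default_rng(subs[1 + k])))
    return sessions, questionnaires


# ---------------------------------------------------------------------------
# Effect measurement and Monte-Carlo calibration
# ---------------------------------------------------------------------------

def measure_effects(
    config: CohortConfig,
    pairs: Sequence[tuple[str, str, str]],
    n_reps: int,
    seed: int,
    n_participants: int | None = None,
    cleaning: CleaningConfig | None = None,
) -> dict[tuple[str, str, str], np.ndarray]:
    """Recovered Spearman rho per replicate for (game, feature, instrument) pairs.

    Each replicate generates a fresh cohort (only the games named in ``pairs``),
    runs the full cleaning/IQR/aggregation pipeline and rank-correlates the
    named features against the questionnaire totals.
    """
    games = tuple(sorted({g for g, _, _ in pairs}))
    cleaning = cleaning or CleaningConfig()
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, str, str], list[float]] = {tuple(p): [] for p in pairs}
    for _ in range(n_reps):
        cfg = replace(
            config,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
            games=games,
            n_participants=n_participants or config.n_participants,
            unmatched_id_count=0,
        )
        sessions, questionnaires = generate_cohort(cfg)
        scored = score_table(questionnaires)
        totals = {
            inst: pd.Series(scored[f"{inst.lower()}_total"].to_numpy(),
                            index=scored["participant_id"])
            for inst in ("GAD7", "PHQ8")
        }
        for game in games:
            feats = feature_table(
                (s for s in sessions if s.game == game), cleaning)
            for key in out:
                g, feature, inst = key
                if g != game:
                    continue
                x = feats[feature]
                y = totals[inst].loc[x.index]
                out[key].append(spearman(x.to_numpy(), y.to_numpy()).rho)
    return {k: np.asarray(v) for k, v in out.items()}


def calibrate_effect(
    spec: EffectSpec,
    config: CohortConfig,
    *,
    n_reps: int = 50,
    n_participants: int = 78,
    max_iter: int = 4,
    tol: float = 0.02,
    seed: int = 7,
) -> CalibratedEffect:
    """Monte-Carlo refine the attenuation factor for one planted effect.

    Solves loadings analytically, measures the mean recovered rho over
    ``n_reps`` end-to-end replicates, and rescales the attenuation until every
    target of the (game, mechanism) group is within ``tol``. Sibling specs in
    ``config.effects`` sharing the mechanism are calibrated jointly (one swipe
    parameter cannot satisfy two instruments independently otherwise). A zero
    target yields zero loadings without simulation.
    """
    group = {spec.instrument: spec.target_spearman}
    features = {spec.instrument: spec.feature_name}
    for other in config.effects:
        if (other.game, other.mechanism) == (spec.game, spec.mechanism):
            group[other.instrument] = other.target_spearman
            features[other.instrument] = other.feature_name
    if all(t == 0 for t in group.values()):
        return CalibratedEffect(spec.game, spec.mechanism, 0.0, 0.0, 1.0,
                                attenuation=None, achieved={k: 0.0 for k in group})
    lam = config.attenuation.get(
        (spec.game, spec.mechanism),
        ATTENUATION.get((spec.game, spec.mechanism), _DEFAULT_ATTENUATION))
    pairs = [(spec.game, features[inst], inst) for inst in sorted(group)]
    specs = tuple(EffectSpec(spec.game, features[i], i, group[i], spec.mechanism)
                  for i in sorted(group))
    rng = np.random.default_rng(seed)
    result = None
    for _ in range(max_iter):
        result = _solve_loadings(group, config, spec.game, spec.mechanism, lam)
        cfg = replace(config, effects=specs,
                      attenuation={**config.attenuation,
                                   (spec.game, spec.mechanism): lam})
        rhos = measure_effects(cfg, pairs, n_reps,
                               seed=int(rng.integers(0, 2 ** 31 - 1)),
                               n_participants=n_participants)
        achieved = {inst: float(rhos[(spec.game, features[inst], inst)].mean())
                    for inst in sorted(group)}
        result = replace(result, achieved=achieved, attenuation=lam)
        err = max(abs(achieved[i] - group[i]) for i in achieved)
        if err <= tol:
            return result
        ratios = [math.sin(math.pi * achieved[i] / 6) / math.sin(math.pi * group[i] / 6)
                  for i in group if group[i] != 0]
        factor = float(np.clip(np.mean(ratios), 0.3, 2.0))
        lam = 0.3 * lam + 0.7 * lam * factor
        if not 0.05 <= lam <= 1.5:
            raise CalibrationError(
                f"attenuation diverged ({lam:.3f}) calibrating {spec}: target "
                "unattainable given the generator's noise floor")
    return result
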