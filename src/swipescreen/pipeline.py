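"""Pipeline orchestration: simulate -> extract -> screen -> report.

Each stage reads and writes plain files under the run's output directory, so
stages can be re-run independently; a manifest records the SHA-256 of every
artifact written, making reruns verifiable (simulate and extract are bit-
reproducible for a fixed config and seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .cohort import CohortConfig, EffectSpec, generate_cohort
from .features import CleaningConfig, build_catalog, catalog_to_frame, feature_table
from .questionnaires import score_table
from .screen import ScreenConfig, results_to_frame, screen_features, write_report

log = logging.getLogger("swipescreen")

STAGES = ("simulate", "extract", "screen", "report")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """One pipeline run: directories, seed and per-module settings."""

    out_dir: Path = Path("swipescreen_run")
    raw_dir: Path | None = None  # defaults to <out_dir>/raw
    seed: int = 0
    log_level: str = "INFO"
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        self.raw_dir = Path(self.raw_dir) if self.raw_dir else self.out_dir / "raw"


def _build(cls, data: dict, ctx: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise PipelineError(f"unknown {ctx} config keys: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise PipelineError(f"invalid {ctx} config: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run config; sections cleaning/screen/cohort map onto the
    corresponding module configs, every default is overridable by name."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise PipelineError("run config must be a mapping")
    cohort_raw = dict(raw.pop("cohort", {}))
    if "effects" in cohort_raw:
        cohort_raw["effects"] = tuple(
            _build(EffectSpec, dict(e), "effect") for e in cohort_raw["effects"])
    if "games" in cohort_raw:
        cohort_raw["games"] = tuple(cohort_raw["games"])
    if "gameplay_window" in cohort_raw:
        cohort_raw["gameplay_window"] = tuple(cohort_raw["gameplay_window"])
    kwargs = {
        "cleaning": _build(CleaningConfig, dict(raw.pop("cleaning", {})), "cleaning"),
        "screen": _build(ScreenConfig, dict(raw.pop("screen", {})), "screen"),
        "cohort": _build(CohortConfig, cohort_raw, "cohort"),
    }
    for key in ("out_dir", "raw_dir", "seed", "log_level"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise PipelineError(f"unknown top-level config keys: {sorted(raw)}")
    return RunConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(f"stage {stage!r} needs missing artifact: {path}")
    return path


def stage_simulate(config: RunConfig) -> list[Path]:
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    sessions, questionnaires = generate_cohort(cohort_cfg)
    raw = config.raw_dir
    raw.mkdir(parents=True, exist_ok=True)
    written = []
    for s in sessions:
        path = raw / f"{s.participant_id}_{s.game}.json"
        sio.write_session_log(s, path)
        written.append(path)
    qpath = raw / "questionnaires.csv"
    sio.write_questionnaires(questionnaires, qpath)
    written.append(qpath)
    log.info("simulate: wrote %d session logs and questionnaires for n=%d",
             len(sessions), cohort_cfg.n_participants)
    return written


def stage_extract(config: RunConfig) -> list[Path]:
    raw = config.raw_dir
    qpath = _require(raw / "questionnaires.csv", "extract")
    session_paths = sorted(raw.glob("*.json"))
    if not session_paths:
        raise PipelineError(f"stage 'extract' needs session logs under {raw}")
    sessions = [sio.read_session_log(p) for p in session_paths]
    questionnaires = sio.read_questionnaires(qpath)
    records, drop_log = sio.link_records(sessions, questionnaires)
    log.info("extract: linked %d participants (%d ids dropped)",
             len(records), len(drop_log))
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for game in sorted({g for r in records for g in r.sessions}):
        df = feature_table(
            (r.sessions[game] for r in records if game in r.sessions),
            config.cleaning)
        df.insert(0, "game", game)
        frames.append(df.reset_index())
    features = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    fpath = out / "features.csv"
    features.to_csv(fpath, index=False)
    scored = score_table(questionnaires[
        questionnaires["participant_id"].isin([r.participant_id for r in records])])
    spath = out / "questionnaires_scored.csv"
    scored.to_csv(spath, index=False)
    dpath = out / "link_drop_log.csv"
    pd.DataFrame(drop_log, columns=["participant_id", "reason"]).to_csv(dpath, index=False)
    written = [fpath, spath, dpath]
    for game in sorted({g for r in records for g in r.sessions}):
        cpath = out / f"catalog_{game}.csv"
        catalog_to_frame(build_catalog(game)).to_csv(cpath, index=False)
        written.append(cpath)
    return written


def stage_screen(config: RunConfig) -> list[Path]:
    out = config.out_dir
    fpath = _require(out / "features.csv", "screen")
    spath = _require(out / "questionnaires_scored.csv", "screen")
    features = pd.read_csv(fpath, dtype={"participant_id": str})
    scored = pd.read_csv(spath, dtype={"participant_id": str})
    totals = {
        inst: pd.Series(scored[f"{inst.lower()}_total"].to_numpy(),
                        index=scored["participant_id"])
        for inst in ("GAD7", "PHQ8")
    }
    all_results = []
    prune_frames = []
    for game, group in features.groupby("game"):
        table = group.drop(columns=["game"]).set_index("participant_id")
        table = table.dropna(axis=1, how="all")
        results, prune_log = screen_features(table, totals, config.screen,
                                             build_catalog(str(game)))
        log.info("screen[%s]: %d features retained -> %d significant",
                 game, len(table.columns) - len(prune_log), len(results))
        all_results.extend(results)
        prune_log.insert(0, "game", game)
        prune_frames.append(prune_log)
    rpath = out / "results.csv"
    results_to_frame(all_results).to_csv(rpath, index=False)
    ppath = out / "pruning_log.csv"
    pd.concat(prune_frames, ignore_index=True).to_csv(ppath, index=False)
    return [rpath, ppath]


def stage_report(config: RunConfig) -> list[Path]:
    out = config.out_dir
    rpath = _require(out / "results.csv", "report")
    df = pd.read_csv(rpath)
    lines = []
    for (game, inst), group in df.groupby(["game", "instrument"]):
        title = f"{inst} — {game}"
        lines += ["", title, "-" * len(title),
                  f"{'Metric':<42}{'rho':>8}  P value"]
        for _, row in group.iterrows():
            p = row["p_value"]
            ptxt = "<.001" if p < 0.001 else f"{p:.3f}".lstrip("0")
            lines.append(f"{row['feature_name']:<42}{row['rho']:>8.3f}  {ptxt}")
    tpath = out / "report.txt"
    with open(tpath, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines).lstrip("\n") + "\n")
    return [tpath]


_STAGE_FN = {
    "simulate": stage_simulate,
    "extract": stage_extract,
    "screen": stage_screen,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order; return the artifact manifest
    (path -> sha256) and write it to ``<out_dir>/manifest.json``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stages {unknown}; valid: {STAGES}")
    written: list[Path] = []
    for stage in STAGES:
        if stage in stages:
            written.extend(_STAGE_FN[stage](config))
    manifest = {str(p.relative_to(p.anchor) if p.is_absolute() else p): _sha256(p)
                for p in written}
    config.out_dir.mkdir(parents=True, exist_ok=True)
    mpath = config.out_dir / "manifest.json"
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
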