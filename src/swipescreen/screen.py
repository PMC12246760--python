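"""Collinearity pruning and Spearman screening of features against symptom scores.

The screen mirrors a standard exploratory digital-phenotyping analysis: groups
of near-duplicate features (pairwise Pearson |r| >= 0.90) are reduced to one
representative each, then every retained feature is rank-correlated against
the GAD-7 and PHQ-8 totals. P values are uncorrected by default — the screen
is meant to surface candidates for confirmatory follow-up, not to test
prespecified hypotheses — with an optional Benjamini-Hochberg mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureCatalog


class ScreenError(ValueError):
    pass


@dataclass(frozen=True)
class ScreenConfig:
    """Collinearity threshold, significance level and retention preferences."""

    collinearity_threshold: float = 0.90
    alpha: float = 0.05
    correction: str = "none"  # or "bh"
    #: ordered substring classes; a feature is ranked by the first class that
    #: matches it, earlier classes are preferred as group representatives
    retention_priority: tuple[str, ...] = (
        "speed",
        "press:std",
        "press_variance",
        "pos",
        "distance|duration",
    )

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.collinearity_threshold <= 1:
            raise ValueError("collinearity_threshold must be in (0, 1]")
        if self.correction not in ("none", "bh"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass(frozen=True)
class CorrelationResult:
    """One (feature, instrument) Spearman test on the linked cohort."""

    feature_name: str
    instrument: str
    rho: float
    p_value: float
    n: int
    game: Optional[str] = None


class SpearmanResult(NamedTuple):
    rho: float
    p_value: float
    n: int


def pearson_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of a feature table.

    Constant (or insufficiently observed) features yield NaN entries, flagging
    them as undefined rather than silently correlating.
    """
    if len(features) < 3:
        raise ScreenError(f"need >= 3 participants, got {len(features)}")
    return features.corr(method="pearson", min_periods=3)


def _priority_rank(name: str, priority: Sequence[str]) -> int:
    for rank, pat in enumerate(priority):
        for alt in pat.split("|"):
            if ":" in alt:
                base_pat, agg_pat = alt.split(":")
                if base_pat in name and name.endswith("_" + agg_pat):
                    return rank
            elif alt in name:
                return rank
    return len(priority)


def prune_collinear(
    features: pd.DataFrame, config: ScreenConfig | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Reduce groups of collinear features to a single representative each.

    Features linked by |r| >= threshold are grouped by connected components
    (a "pair or group" may chain through intermediates); one representative
    per group is kept, chosen by the retention priority with a lexicographic
    tie-break. Returns the retained names (input column order) and a pruning
    log with one row per dropped feature (dropped, representative, r-to-rep).
    """
    config = config or ScreenConfig()
    corr = pearson_matrix(features)
    cols = list(features.columns)
    idx = {c: i for i, c in enumerate(cols)}
    parent = list(range(len(cols)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    absr = corr.abs().to_numpy()
    n = len(cols)
    for i in range(n):
        for j in range(i + 1, n):
            if absr[i, j] >= config.collinearity_threshold - 1e-12:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for c in cols:
        groups.setdefault(find(idx[c]), []).append(c)
    retained: set[str] = set()
    log_rows = []
    for members in groups.values():
        rep = min(members, key=lambda c: (_priority_rank(c, config.retention_priority), c))
        retained.add(rep)
        for c in members:
            if c != rep:
                log_rows.append((c, rep, float(corr.loc[c, rep])))
    log = pd.DataFrame(log_rows, columns=["dropped_feature", "representative", "r"])
    log = log.sort_values("dropped_feature").reset_index(drop=True)
    return [c for c in cols if c in retained], log


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p by full enumeration (n <= 9 only)."""
    n = len(rx)
    perms = np.array(list(permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        rhos = (ryc @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))


def spearman(
    x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray
) -> SpearmanResult:
    """Spearman rank correlation with mid-rank ties.

    rho is the Pearson correlation of mid-ranks. The two-sided p value uses
    the t approximation with n - 2 df for n > 9 and exact permutation
    enumeration for n <= 9. Pairs with a missing value are dropped. A constant
    input yields ``(nan, nan, n)`` — an undefined result the screen excludes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ScreenError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ScreenError(f"need >= 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return SpearmanResult(math.nan, math.nan, n)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        p = _exact_spearman_p(rx, ry, rho)
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    return SpearmanResult(rho, max(p, 5e-324), n)


def correlate_features(
    features: pd.DataFrame,
    totals: dict[str, pd.Series],
    feature_names: Sequence[str] | None = None,
    game: str | None = None,
) -> list[CorrelationResult]:
    """Spearman-test every feature against every instrument total.

    ``totals`` maps instrument name -> participant-indexed total score series.
    All defined results are returned (no significance filter), in instrument
    then feature order. Undefined (constant-input) tests are skipped.
    """
    names = list(feature_names) if feature_names is not None else list(features.columns)
    out: list[CorrelationResult] = []
    for instrument in sorted(totals):
        t = totals[instrument]
        common = features.index.intersection(t.index)
        f = features.loc[common]
        tv = t.loc[common].to_numpy(dtype=float)
        for name in names:
            res = spearman(f[name].to_numpy(dtype=float), tv)
            if math.isnan(res.rho):
                continue
            out.append(CorrelationResult(name, instrument, res.rho, res.p_value,
                                         res.n, game))
    return out


def screen_features(
    features: pd.DataFrame,
    totals: dict[str, pd.Series],
    config: ScreenConfig | None = None,
    catalog: FeatureCatalog | None = None,
) -> tuple[list[CorrelationResult], pd.DataFrame]:
    """Prune collinear features, test the rest, report significant results.

    Returns the results with p below alpha (uncorrected by default, BH-adjusted
    when configured), sorted by instrument then catalog order, plus the pruning
    log. Raises if fewer than 3 participants are available.
    """
    config = config or ScreenConfig()
    retained, prune_log = prune_collinear(features, config)
    if catalog is not None:
        order = {n: i for i, n in enumerate(catalog.names)}
        retained = sorted(retained, key=lambda n: order.get(n, len(order)))
    results = correlate_features(features, totals, retained,
                                 game=catalog.game if catalog else None)
    if config.correction == "bh":
        ps = np.array([r.p_value for r in results])
        results = [
            CorrelationResult(r.feature_name, r.instrument, r.rho, float(p_adj),
                              r.n, r.game)
            for r, p_adj in zip(results, _bh_adjust(ps))
        ]
    sig = [r for r in results if r.p_value < config.alpha]
    return sig, prune_log


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def results_to_frame(results: Iterable[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.game, r.feature_name, r.instrument, r.rho, r.p_value, r.n)
         for r in results],
        columns=["game", "feature_name", "instrument", "rho", "p_value", "n"],
    )


def _fmt_p(p: float) -> str:
    if p < 0.001:
        return "<.001"
    s = f"{p:.3f}" if p < 0.045 else f"{p:.2f}"
    return s.lstrip("0")


def write_report(
    results: Sequence[CorrelationResult],
    csv_path: str | Path,
    txt_path: str | Path | None = None,
) -> None:
    """Write results as CSV plus (optionally) a human-readable table.

    The text table groups rows by game and instrument with metric / rho / P
    columns, P formatted journal-style (``<.001``, ``.004`` ...). Ordering is
    deterministic: the order of ``results``.
    """
    df = results_to_frame(results)
    df.to_csv(csv_path, index=False)
    if txt_path is None:
        return
    lines = []
    width = max([len(r.feature_name) for r in results], default=20) + 2
    last_group = None
    for r in results:
        group = (r.game, r.instrument)
        if group != last_group:
            title = f"{r.instrument}" + (f" — {r.game}" if r.game else "")
            lines += ["", title, "-" * len(title),
                      f"{'Metric'.ljust(width)}{'rho':>8}  P value"]
            last_group = group
        lines.append(f"{r.feature_name.ljust(width)}{r.rho:>8.3f}  {_fmt_p(r.p_value)}")
    with open(txt_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines).lstrip("\n") + "\n")
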