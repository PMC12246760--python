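"""Scoring of the GAD-7 and PHQ-8 self-report screeners.

Both instruments rate symptom frequency over the past two weeks on a 0 ("not
at all") to 3 ("nearly every day") scale per item. Totals are plain item sums:
GAD-7 has 7 items (total 0-21), PHQ-8 has 8 items (total 0-24); higher totals
mean more severe symptoms.

Severity bands default to the instruments' canonical cutoffs (none 0-4,
mild 5-9, moderate 10-14, severe 15+), with the PHQ "moderately severe" and
"severe" categories collapsed so both instruments use the same four bands.
Cutoffs are configurable because published cohorts do not always state them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

INSTRUMENTS = ("GAD7", "PHQ8")
N_ITEMS = {"GAD7": 7, "PHQ8": 8}
MAX_TOTAL = {"GAD7": 21, "PHQ8": 24}
BANDS = ("none", "mild", "moderate", "severe")
#: lower cutoffs of (mild, moderate, severe)
DEFAULT_CUTOFFS = {"GAD7": (5, 10, 15), "PHQ8": (5, 10, 15)}

ITEM_COLUMNS = {
    "GAD7": [f"gad7_q{i}" for i in range(1, 8)],
    "PHQ8": [f"phq8_q{i}" for i in range(1, 9)],
}


class QuestionnaireError(ValueError):
    pass


def _check_instrument(instrument: str) -> None:
    if instrument not in INSTRUMENTS:
        raise QuestionnaireError(f"unknown instrument {instrument!r}; expected one of {INSTRUMENTS}")


def score_questionnaire(items: Sequence[int], instrument: str) -> int:
    """Sum the item ratings into the instrument total score.

    ``items`` must contain exactly 7 (GAD-7) or 8 (PHQ-8) integer ratings in
    {0, 1, 2, 3}; anything else raises :class:`QuestionnaireError`.
    """
    _check_instrument(instrument)
    items = list(items)
    if len(items) != N_ITEMS[instrument]:
        raise QuestionnaireError(
            f"{instrument} needs {N_ITEMS[instrument]} items, got {len(items)}"
        )
    for i, v in enumerate(items):
        if isinstance(v, bool) or not float(v).is_integer() or not 0 <= int(v) <= 3:
            raise QuestionnaireError(
                f"{instrument} item {i + 1} must be an integer in 0..3, got {v!r}"
            )
    return int(sum(int(v) for v in items))


def severity_band(
    total: int,
    instrument: str,
    cutoffs: dict[str, tuple[int, int, int]] | None = None,
) -> str:
    """Map a total score to its severity band (a nondecreasing step function)."""
    _check_instrument(instrument)
    if not 0 <= total <= MAX_TOTAL[instrument]:
        raise QuestionnaireError(
            f"{instrument} total must be in 0..{MAX_TOTAL[instrument]}, got {total}"
        )
    mild, moderate, severe = (cutoffs or DEFAULT_CUTOFFS)[instrument]
    if total >= severe:
        return "severe"
    if total >= moderate:
        return "moderate"
    if total >= mild:
        return "mild"
    return "none"


@dataclass(frozen=True)
class QuestionnaireResponse:
    instrument: str
    items: tuple[int, ...]
    total: int
    band: str

    @classmethod
    def from_items(cls, items: Sequence[int], instrument: str,
                   cutoffs=None) -> "QuestionnaireResponse":
        total = score_questionnaire(items, instrument)
        return cls(instrument, tuple(int(v) for v in items), total,
                   severity_band(total, instrument, cutoffs))


def score_table(df: pd.DataFrame, cutoffs=None) -> pd.DataFrame:
    """Add ``gad7_total``/``gad7_band`` and ``phq8_total``/``phq8_band`` columns.

    Consumes the questionnaire CSV layout of :mod:`swipescreen.io`; rows are
    validated item by item, so out-of-range ratings raise.
    """
    out = df.copy()
    for instrument in INSTRUMENTS:
        cols = ITEM_COLUMNS[instrument]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise QuestionnaireError(f"missing {instrument} item columns: {missing}")
        totals = [
            score_questionnaire([row[c] for c in cols], instrument)
            for _, row in df.iterrows()
        ]
        key = instrument.lower()
        out[f"{key}_total"] = totals
        out[f"{key}_band"] = [severity_band(t, instrument, cutoffs) for t in totals]
    return out
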