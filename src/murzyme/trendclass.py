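"""Saliency-weighted trend-rule classification of feature profiles.

Each of 28 criteria (5 structural, 5 theoretical, 10 experimental, 8
mechanistic-postulate) carries a per-class trend token — what value the
criterion typically takes for classical enzymes versus murzymes.  A
(possibly partial) profile of answers is scored by awarding each answered
criterion's saliency weight to whichever class's trend it matches; unknown
answers contribute nothing.  The verdict is the class with the larger score,
with a confidence tier derived from the score margin normalised by the total
table weight, so that sparse evidence yields low confidence even when
one-sided.

Trend-token matching rules
--------------------------
``yes``/``no`` (and the ordinal ``low``/``moderate``/``high``) match exactly
that answer.  ``usually-yes``/``usually-no`` match their majority direction;
``some-yes`` matches only a *yes* answer (a *no* is uninformative for that
class) while ``rare`` matches its majority direction *no*.
``sometimes-high`` matches *high*.  ``mixed``, ``sometimes`` and
``need-not-be`` carry no direction: such rows score only toward the class
whose trend is definite.

Weights are three-tier: 2.0 for the four salient criteria (heme presence,
DRS involvement, non-integral stoichiometry, substrate non-selectivity), 1.0
for other definite yes/no trends, 0.5 for soft trends — all editable via the
trend-table CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import pandas as pd

__all__ = [
    "TrendRow",
    "TrendTable",
    "FeatureProfile",
    "RuleVerdict",
    "default_trend_table",
    "load_trend_table",
    "classify_profile",
    "profile_from_binary_row",
    "read_profiles_csv",
]

N_CRITERIA = 28

#: Criteria answered on the low/moderate/high ordinal scale (intermediate
#: molecularity, step count, probability index); all others are yes/no.
ORDINAL_CRITERIA = frozenset({24, 25, 26})

BINARY_ANSWERS = ("yes", "no", "unknown")
ORDINAL_ANSWERS = ("low", "moderate", "high", "unknown")

#: Trend token -> the answer it matches (None: no direction of its own).
_TOKEN_MATCH: dict[str, Optional[str]] = {
    "yes": "yes",
    "no": "no",
    "usually-yes": "yes",
    "usually-no": "no",
    "some-yes": "yes",
    "rare": "no",
    "mixed": None,
    "sometimes": None,
    "need-not-be": None,
    "sometimes-high": "high",
    "low": "low",
    "moderate": "moderate",
    "high": "high",
}

#: Normalised-margin thresholds for the confidence tiers.
CONFIDENCE_HIGH = 0.5
CONFIDENCE_MEDIUM = 0.25


@dataclass(frozen=True)
class TrendRow:
    id: int
    category: str
    feature: str
    classical: str
    murburn: str
    tier: str  # "salient" | "definite" | "soft"
    weight: float

    def __post_init__(self) -> None:
        for token in (self.classical, self.murburn):
            if token not in _TOKEN_MATCH:
                raise ValueError(f"unknown trend token {token!r} in row {self.id}")
        if self.weight <= 0:
            raise ValueError(f"trend weight must be > 0 in row {self.id}")


@dataclass(frozen=True)
class TrendTable:
    rows: tuple[TrendRow, ...]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.rows]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("trend rows must be numbered consecutively from 1")

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, cid: int) -> TrendRow:
        return self.rows[cid - 1]

    @property
    def total_weight(self) -> float:
        return sum(r.weight for r in self.rows)

    def features(self, category: str | None = None) -> list[str]:
        return [r.feature for r in self.rows if category in (None, r.category)]


def load_trend_table(path) -> TrendTable:
    """Load a trend table from a CSV with the packaged file's columns."""
    df = pd.read_csv(path)
    rows = tuple(
        TrendRow(
            id=int(r.id),
            category=str(r.category),
            feature=str(r.feature),
            classical=str(r.classical),
            murburn=str(r.murburn),
            tier=str(r.tier),
            weight=float(r.weight),
        )
        for r in df.itertuples()
    )
    return TrendTable(rows)


def default_trend_table() -> TrendTable:
    """The packaged 28-criterion trend encoding."""
    ref = resources.files("murzyme.data").joinpath("trend_table.csv")
    with resources.as_file(ref) as path:
        return load_trend_table(path)


@dataclass(frozen=True)
class FeatureProfile:
    """Answers to the 28 criteria for one protein/system.

    ``answers`` maps criterion id (1-28) to a value: ``yes``/``no`` for
    binary criteria, ``low``/``moderate``/``high`` for the ordinal ones,
    ``unknown`` anywhere.  All 28 keys must be present (partial knowledge is
    expressed with ``unknown``, not omission).
    """

    answers: Mapping[int, str]
    label: Optional[str] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        keys = set(self.answers)
        expected = set(range(1, N_CRITERIA + 1))
        if keys - expected:
            raise ValueError(f"unknown criterion ids: {sorted(keys - expected)}")
        if expected - keys:
            raise ValueError(f"missing criteria: {sorted(expected - keys)}")
        for cid, value in self.answers.items():
            allowed = ORDINAL_ANSWERS if cid in ORDINAL_CRITERIA else BINARY_ANSWERS
            if value not in allowed:
                raise ValueError(
                    f"criterion {cid}: invalid answer {value!r}, expected one of {allowed}"
                )
        if self.label is not None and self.label not in ("murzyme", "classical"):
            raise ValueError(f"label must be murzyme/classical, got {self.label!r}")

    @classmethod
    def all_unknown(cls, **kw) -> "FeatureProfile":
        return cls({i: "unknown" for i in range(1, N_CRITERIA + 1)}, **kw)


@dataclass(frozen=True)
class RuleVerdict:
    murzyme_score: float
    classical_score: float
    verdict: str  # "murzyme" | "classical" | "indeterminate"
    confidence: str  # "high" | "medium" | "low" | "none"
    coverage: float

    def to_dict(self) -> dict:
        return {
            "murzyme_score": self.murzyme_score,
            "classical_score": self.classical_score,
            "verdict": self.verdict,
            "confidence": self.confidence,
            "coverage": self.coverage,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def classify_profile(
    profile: FeatureProfile, trends: TrendTable | None = None
) -> RuleVerdict:
    """Score a profile against the trend table and return the verdict.

    Each answered criterion adds its row's weight to the class whose trend
    token matches the answer; unknowns add nothing.  Coverage is the answered
    fraction of the total table weight.  The confidence tier comes from the
    score margin over the total weight (>= 0.5 high, >= 0.25 medium, > 0
    low), so both a thin margin and thin coverage depress confidence.
    """
    trends = trends if trends is not None else default_trend_table()
    if len(trends) != len(profile.answers):
        raise ValueError(
            f"profile has {len(profile.answers)} answers but trend table has "
            f"{len(trends)} rows"
        )
    murzyme = classical = answered = 0.0
    for row in trends.rows:
        value = profile.answers[row.id]
        if value == "unknown":
            continue
        answered += row.weight
        if _TOKEN_MATCH[row.classical] == value:
            classical += row.weight
        if _TOKEN_MATCH[row.murburn] == value:
            murzyme += row.weight

    total = trends.total_weight
    coverage = answered / total
    if murzyme > classical:
        verdict = "murzyme"
    elif classical > murzyme:
        verdict = "classical"
    else:
        verdict = "indeterminate"
    if coverage == 0.0:
        verdict = "indeterminate"

    margin = abs(murzyme - classical) / total
    if verdict == "indeterminate":
        confidence = "none"
    elif margin >= CONFIDENCE_HIGH:
        confidence = "high"
    elif margin >= CONFIDENCE_MEDIUM:
        confidence = "medium"
    else:
        confidence = "low"
    return RuleVerdict(
        murzyme_score=murzyme,
        classical_score=classical,
        verdict=verdict,
        confidence=confidence,
        coverage=coverage,
    )


# ---------------------------------------------------------------------------
# Profile I/O helpers
# ---------------------------------------------------------------------------

def profile_from_binary_row(
    values: Mapping[str, int],
    trends: TrendTable | None = None,
    label: Optional[str] = None,
    name: Optional[str] = None,
) -> FeatureProfile:
    """Build a profile from a 0/1-encoded feature mapping (feature name -> bit).

    Features absent from ``values`` are marked unknown; ordinal criteria are
    left unknown (a bare bit cannot express low/moderate/high).
    """
    trends = trends if trends is not None else default_trend_table()
    answers: dict[int, str] = {}
    for row in trends.rows:
        if row.id in ORDINAL_CRITERIA or row.feature not in values:
            answers[row.id] = "unknown"
        else:
            answers[row.id] = "yes" if values[row.feature] else "no"
    return FeatureProfile(answers, label=label, name=name)


def read_profiles_csv(path, trends: TrendTable | None = None) -> list[FeatureProfile]:
    """Read profiles from a delimited table, one system per row.

    Columns are criterion ids (``1``..``28`` or ``c1``..``c28``) or feature
    names from the trend table; optional ``name`` and ``label`` columns.
    Missing criterion columns are a schema error naming the missing criteria;
    empty cells become ``unknown``.
    """
    trends = trends if trends is not None else default_trend_table()
    df = pd.read_csv(path, dtype=str)
    by_feature = {r.feature: r.id for r in trends.rows}
    colmap: dict[str, int] = {}
    for col in df.columns:
        key = col.strip()
        if key in ("name", "label"):
            continue
        if key.lower().startswith("c") and key[1:].isdigit():
            colmap[col] = int(key[1:])
        elif key.isdigit():
            colmap[col] = int(key)
        elif key in by_feature:
            colmap[col] = by_feature[key]
        else:
            raise ValueError(f"unrecognised profile column {col!r}")
    missing = sorted(set(range(1, len(trends) + 1)) - set(colmap.values()))
    if missing:
        raise ValueError(f"profile table is missing criteria: {missing}")

    profiles = []
    for _, r in df.iterrows():
        answers = {}
        for col, cid in colmap.items():
            v = r[col]
            answers[cid] = "unknown" if pd.isna(v) or str(v).strip() == "" else str(v).strip()
        profiles.append(
            FeatureProfile(
                answers,
                label=None if "label" not in df.columns or pd.isna(r.get("label")) else str(r["label"]),
                name=None if "name" not in df.columns or pd.isna(r.get("name")) else str(r["name"]),
            )
        )
    return profiles
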