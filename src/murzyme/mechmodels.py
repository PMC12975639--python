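"""Ockham's-razor screening of competing enzyme mechanistic models.

Two proposals for how a given enzyme (or enzyme system) works — a classical
active-site/transition-state mechanism versus a murburn-type mechanism relying
on diffusible reactive species (DRS) — are each encoded as eight postulate
attributes plus an association/dissociation event scheme.  A parsimony
("relative probability") index is computed for the scheme, and the two models
are compared attribute by attribute; the simpler model on each count earns a
point, and the higher total wins.

The probability index treats every association/dissociation event as a coin
flip (associated 1/2, dissociated 1/2 — binding affinities deliberately
discounted) and every one-of-k partner or route selection as a further 1/k
factor; a strictly serial scheme therefore has index

    P = (1/2)^n_events * prod_i (1/k_i).

Schemes with several independent successful routes can only be *more* probable
than any single route, so for those the serial product is reported as a
flagged lower bound rather than combined by an invented rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from importlib import resources
from typing import Iterable

__all__ = [
    "EventScheme",
    "ProbabilityIndex",
    "MechanisticModel",
    "ComparisonReport",
    "probability_index",
    "compare_models",
    "packaged_systems",
    "load_system",
    "load_system_file",
]

#: The five heme systems shipped as packaged model-pair encodings.
PACKAGED_SYSTEMS = (
    "haloperoxidase",
    "cyclooxygenase",
    "cyp450",
    "oxphos",
    "hemoglobin",
)

#: Comparison attributes where the *lower* (absent/0) value is simpler.
BINARY_ATTRIBUTES = (
    "shape_change",
    "serial",
    "irreducible_complexity",
    "long_range_et",
    "es_complex",
)


@dataclass(frozen=True)
class EventScheme:
    """Association/dissociation event bookkeeping for one mechanistic scheme.

    Parameters
    ----------
    n_events:
        Number of association/dissociation events, each contributing a factor
        of 1/2 (the associated and dissociated states are taken as
        equiprobable).
    selection_factors:
        One factor ``k`` per one-of-k partner or route selection, each
        contributing 1/k.
    parallel_modes:
        Number of independent alternative successful routes; 1 means the
        scheme is strictly serial.  When > 1 the computed index is only a
        floor on the true probability.
    """

    n_events: int = 0
    selection_factors: tuple[int, ...] = ()
    parallel_modes: int = 1

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError(f"n_events must be >= 0, got {self.n_events}")
        object.__setattr__(self, "selection_factors", tuple(self.selection_factors))
        for k in self.selection_factors:
            if int(k) != k or k < 1:
                raise ValueError(f"selection factors must be integers >= 1, got {k}")
        if self.parallel_modes < 1:
            raise ValueError(f"parallel_modes must be >= 1, got {self.parallel_modes}")


@dataclass(frozen=True)
class ProbabilityIndex:
    """Parsimony probability of a scheme; exact rational kept alongside the float."""

    value: float
    is_lower_bound: bool
    exact: Fraction = field(compare=False, default=Fraction(1))

    def __post_init__(self) -> None:
        if not (0.0 < self.value <= 1.0):
            raise ValueError(f"probability index must lie in (0, 1], got {self.value}")

    def __str__(self) -> str:  # mirrors the printed "1/8" / "> 1/16" style
        frac = f"{self.exact}" if self.exact.denominator > 1 else f"{self.exact.numerator}"
        return f"> {frac}" if self.is_lower_bound else frac


def probability_index(scheme: EventScheme) -> ProbabilityIndex:
    """Compute the relative probability index of an event scheme.

    The index is ``(1/2)**n_events`` times ``1/k`` for every one-of-k
    selection.  It does not depend on ``parallel_modes``: extra independent
    routes can only raise the true probability, so for multi-route schemes the
    serial product is returned flagged as a lower bound.  The degenerate empty
    scheme has index 1.
    """
    exact = Fraction(1, 2) ** scheme.n_events
    for k in scheme.selection_factors:
        exact /= k
    return ProbabilityIndex(
        value=float(exact),
        is_lower_bound=scheme.parallel_modes > 1,
        exact=exact,
    )


@dataclass(frozen=True)
class MechanisticModel:
    """One competing mechanism, encoded as the eight postulate attributes.

    Binary attributes take 0 (simpler: feature absent) or 1 (feature
    required).  ``n_steps`` counts the minimal mechanistic steps,
    ``molecularity`` the largest transient species; the probability postulate
    is carried by ``scheme``.
    """

    name: str
    shape_change: int
    serial: int
    n_steps: int
    irreducible_complexity: int
    molecularity: int
    long_range_et: int
    es_complex: int
    scheme: EventScheme

    def __post_init__(self) -> None:
        for attr in BINARY_ATTRIBUTES:
            v = getattr(self, attr)
            if v not in (0, 1):
                raise ValueError(f"{attr} must be 0 or 1, got {v!r}")
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.molecularity < 1:
            raise ValueError(f"molecularity must be >= 1, got {self.molecularity}")

    @property
    def index(self) -> ProbabilityIndex:
        return probability_index(self.scheme)

    @classmethod
    def from_dict(cls, d: dict) -> "MechanisticModel":
        d = dict(d)
        s = d.pop("scheme")
        scheme = EventScheme(
            n_events=s.get("n_events", 0),
            selection_factors=tuple(s.get("selection_factors", ())),
            parallel_modes=s.get("parallel_modes", 1),
        )
        return cls(scheme=scheme, **d)


@dataclass(frozen=True)
class ComparisonReport:
    """Per-attribute award record for one model-pair screening.

    ``awards`` maps each of the eight attribute names to ``"a"``, ``"b"`` or
    ``"tie"``; a model's score is its number of awards (0-8).  The verdict
    names the higher scorer, or ``"tie"``.
    """

    model_a: str
    model_b: str
    score_a: int
    score_b: int
    awards: dict[str, str]
    verdict: str

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _award(attr: str, va, vb) -> str:
    """Lower is simpler for every attribute except the probability index."""
    if attr == "probability_index":
        va, vb = -va, -vb
    if va < vb:
        return "a"
    if vb < va:
        return "b"
    return "tie"


def compare_models(a: MechanisticModel, b: MechanisticModel) -> ComparisonReport:
    """Compare two mechanistic models attribute by attribute.

    For each binary postulate the model *not* requiring the feature gets the
    point; for step count and molecularity the strictly lower value wins; for
    the probability index the strictly higher value wins.  Ties award nothing.
    Higher total score means greater admissibility; equal totals give a
    ``"tie"`` verdict (never broken arbitrarily).
    """
    awards: dict[str, str] = {}
    for attr in BINARY_ATTRIBUTES:
        awards[attr] = _award(attr, getattr(a, attr), getattr(b, attr))
    awards["n_steps"] = _award("n_steps", a.n_steps, b.n_steps)
    awards["molecularity"] = _award("molecularity", a.molecularity, b.molecularity)
    awards["probability_index"] = _award(
        "probability_index", a.index.exact, b.index.exact
    )
    score_a = sum(1 for w in awards.values() if w == "a")
    score_b = sum(1 for w in awards.values() if w == "b")
    if score_a > score_b:
        verdict = "model_a"
    elif score_b > score_a:
        verdict = "model_b"
    else:
        verdict = "tie"
    return ComparisonReport(
        model_a=a.name,
        model_b=b.name,
        score_a=score_a,
        score_b=score_b,
        awards=awards,
        verdict=verdict,
    )


# ---------------------------------------------------------------------------
# Packaged system encodings (model pairs for the five heme systems)
# ---------------------------------------------------------------------------

def packaged_systems() -> tuple[str, ...]:
    """Names of the model-pair encodings shipped with the package."""
    return PACKAGED_SYSTEMS


def _system_payload(name: str) -> dict:
    ref = resources.files("murzyme.data").joinpath(f"{name}.json")
    try:
        return json.loads(ref.read_text())
    except FileNotFoundError:
        raise KeyError(
            f"unknown packaged system {name!r}; available: {PACKAGED_SYSTEMS}"
        ) from None


def load_system(name: str) -> tuple[MechanisticModel, MechanisticModel]:
    """Load a packaged model pair; returns ``(murburn, classical)``."""
    payload = _system_payload(name)
    return (
        MechanisticModel.from_dict(payload["murburn"]),
        MechanisticModel.from_dict(payload["classical"]),
    )


#: Classical control systems (central-dogma machinery) for the label gate.
PACKAGED_CONTROLS = ("control_dna_polymerase", "control_ribosome")


def packaged_controls() -> tuple[str, ...]:
    """Names of the packaged classical-control encodings."""
    return PACKAGED_CONTROLS


def load_control(name: str) -> tuple[MechanisticModel, MechanisticModel, list[str]]:
    """Load a classical control: ``(murburn, classical, classical_assertions)``.

    The murburn block is a deliberately contrived DRS account of a
    high-fidelity process; the assertion list describes the classical
    proposal for consistency screening.
    """
    payload = _system_payload(name)
    return (
        MechanisticModel.from_dict(payload["murburn"]),
        MechanisticModel.from_dict(payload["classical"]),
        list(payload.get("classical_assertions", ())),
    )


def load_system_file(path) -> tuple[MechanisticModel, MechanisticModel]:
    """Load a ``(murburn, classical)`` model pair from a JSON document.

    The document must contain ``"murburn"`` and ``"classical"`` model blocks
    in the same layout as the packaged system files.
    """
    with open(path) as fh:
        payload = json.load(fh)
    return (
        MechanisticModel.from_dict(payload["murburn"]),
        MechanisticModel.from_dict(payload["classical"]),
    )
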