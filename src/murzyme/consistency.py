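"""Internal-consistency screening of classical active-site proposals.

A classical (Michaelis-Menten, active-site/transition-state) proposal for an
enzyme is summarised as a set of assertions drawn from a controlled
vocabulary.  Eight rules flag inadmissible proposals: four *mutual* rules fire
when two jointly-held assertions are logically incompatible (e.g. a sterically
limited active site together with no substrate selectivity), and four
*standalone* rules fire on single assertions that are incompatible with
active-site theory outright (e.g. a catalytic rate above the diffusion limit).

The murburn-type alternative accommodates all interactions as a larger event
set and is deliberately not screened here; combined with the parsimony
comparison this yields the labeling gate: a system is kept classical only if
the classical model both wins the comparison and survives consistency
screening.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional

from .mechmodels import ComparisonReport

__all__ = [
    "Assertion",
    "ConsistencyReport",
    "VOCABULARY",
    "MUTUAL_RULES",
    "STANDALONE_RULES",
    "KCAT_DIFFUSION_LIMIT",
    "check_consistency",
    "gate_label",
    "load_assertions",
]

#: Controlled vocabulary of admissible assertion codes.
VOCABULARY = frozenset(
    {
        "ACTIVE_SITE_ACCESS_LIMITED",
        "NO_SUBSTRATE_SELECTIVITY",
        "NO_PRODUCT_SPECIFICITY",
        "SUBSTRATE_SELECTIVITY",
        "NONINTEGRAL_STOICHIOMETRY",
        "SUBSTRATE_BOUND_AT_ACTIVE_SITE",
        "HIGH_INTERNAL_KIE",
        "KCAT_EXCEEDS_DIFFUSION",
        "SUBSTRATE_LARGER_THAN_SITE",
        "ZEROTH_ORDER_AT_MICROMOLAR_S",
        "KM_LESS_THAN_KD",
    }
)

#: Diffusion limit for bimolecular catalysis, M^-1 s^-1.  A kcat qualifier
#: must exceed this for KCAT_EXCEEDS_DIFFUSION to be admitted.
KCAT_DIFFUSION_LIMIT = 1e9

#: Rules 1-4: pairs of mutually incompatible assertions.
MUTUAL_RULES: dict[int, frozenset[str]] = {
    1: frozenset({"ACTIVE_SITE_ACCESS_LIMITED", "NO_SUBSTRATE_SELECTIVITY"}),
    2: frozenset({"ACTIVE_SITE_ACCESS_LIMITED", "NO_PRODUCT_SPECIFICITY"}),
    3: frozenset({"SUBSTRATE_SELECTIVITY", "NONINTEGRAL_STOICHIOMETRY"}),
    4: frozenset({"SUBSTRATE_BOUND_AT_ACTIVE_SITE", "HIGH_INTERNAL_KIE"}),
}

#: Rules 5-8: assertions inadmissible under active-site theory on their own.
STANDALONE_RULES: dict[int, str] = {
    5: "KCAT_EXCEEDS_DIFFUSION",
    6: "SUBSTRATE_LARGER_THAN_SITE",
    7: "ZEROTH_ORDER_AT_MICROMOLAR_S",
    8: "KM_LESS_THAN_KD",
}


@dataclass(frozen=True)
class Assertion:
    """One assertion about a classical proposal, optionally quantified.

    ``qualifier`` carries a numeric value where one is meaningful — for
    ``KCAT_EXCEEDS_DIFFUSION`` it is the catalytic rate in M^-1 s^-1 and must
    exceed the diffusion limit for the code to be admitted at all.
    """

    code: str
    qualifier: Optional[float] = None

    def __post_init__(self) -> None:
        if self.code not in VOCABULARY:
            raise ValueError(
                f"unknown assertion code {self.code!r}; "
                f"must be one of {sorted(VOCABULARY)}"
            )
        if self.qualifier is not None:
            if self.qualifier < 0:
                raise ValueError("assertion qualifier must be non-negative")
            if (
                self.code == "KCAT_EXCEEDS_DIFFUSION"
                and self.qualifier <= KCAT_DIFFUSION_LIMIT
            ):
                raise ValueError(
                    f"kcat qualifier {self.qualifier:g} does not exceed the "
                    f"diffusion limit {KCAT_DIFFUSION_LIMIT:g} M^-1 s^-1"
                )


@dataclass(frozen=True)
class Violation:
    rule: int
    kind: str  # "mutual" | "standalone"
    codes: tuple[str, ...]


@dataclass(frozen=True)
class ConsistencyReport:
    violations: tuple[Violation, ...]

    @property
    def consistent(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {
            "consistent": self.consistent,
            "violations": [
                {"rule": v.rule, "kind": v.kind, "codes": list(v.codes)}
                for v in self.violations
            ],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def check_consistency(assertions: Iterable[Assertion | str]) -> ConsistencyReport:
    """Screen a set of assertions for internal contradictions.

    Accepts :class:`Assertion` objects or bare code strings.  Set semantics:
    duplicates and ordering are irrelevant.  Unknown codes are rejected.
    """
    codes = frozenset(
        a.code if isinstance(a, Assertion) else Assertion(a).code for a in assertions
    )
    violations: list[Violation] = []
    for rule, pair in MUTUAL_RULES.items():
        if pair <= codes:
            violations.append(Violation(rule, "mutual", tuple(sorted(pair))))
    for rule, code in STANDALONE_RULES.items():
        if code in codes:
            violations.append(Violation(rule, "standalone", (code,)))
    return ConsistencyReport(tuple(violations))


def gate_label(comparison: ComparisonReport, report: ConsistencyReport) -> str:
    """Combined labeling gate for one system.

    ``comparison`` must pit the murburn model as ``model_a`` against the
    classical model as ``model_b``.  A system is labeled ``classical`` only
    when the classical model wins the parsimony comparison *and* its proposal
    is internally consistent; a murburn win or a classical inconsistency is
    each sufficient for ``murzyme``; a tie with a consistent classical
    proposal is ``unresolved``.
    """
    if comparison.verdict == "model_a" or not report.consistent:
        return "murzyme"
    if comparison.verdict == "model_b":
        return "classical"
    return "unresolved"


def load_assertions(path) -> list[Assertion]:
    """Read assertions from a JSON list or a plain-text file of codes.

    JSON entries may be bare code strings or ``{"code": ..., "qualifier": ...}``
    objects; plain text is one code per line, ``#`` comments allowed.
    """
    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if stripped.startswith("["):
        entries = json.loads(text)
        out = []
        for e in entries:
            if isinstance(e, str):
                out.append(Assertion(e))
            else:
                out.append(Assertion(e["code"], e.get("qualifier")))
        return out
    out = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            out.append(Assertion(line))
    return out
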