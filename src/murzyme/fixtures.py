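"""Seeded synthetic data: trend-conformant feature tables and PDB corpora.

Every learning component in this package can be exercised without any
download thanks to two generators:

``gen_feature_table``
    samples 20-feature binary profiles per class from the packaged trend
    table.  Each trend token maps to a class-conditional probability of
    answering *yes*: definite ``yes``/``no`` trends are followed with
    probability 1 by default, ``usually-*`` trends with 0.8, ``some-yes``
    with 0.4, ``rare`` with 0.1, and the direction-free tokens (``mixed``,
    ``sometimes``, ``need-not-be``) are a coin flip.  The default cohort is
    22 murzymes and 17 classical systems (39 rows), mirroring the size of
    curated expert-annotated collections for this problem.

``gen_pdb_corpus``
    writes valid 80-column PDB text files whose HEADER/TITLE/COMPND/KEYWDS
    vocabulary correlates with the class (oxidoreductase-flavoured tokens for
    murzymes, hydrolase/transferase-flavoured for classical enzymes), plus a
    HET record for the heme ligand on every murzyme file.  A configurable
    ``overlap`` fraction makes that share of files draw all descriptive
    tokens from a class-neutral shared vocabulary, which bounds the
    achievable accuracy at roughly ``1 - overlap * P(minority)`` and so keeps
    the classification task honest.  The default corpus holds 200 records
    with the murzyme class in the minority (56 vs 144, ~28%, matching the
    class imbalance typical of annotated structure collections) and
    ``overlap = 0.3``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .featml import FeatureTable
from .pdbtext import LabeledCorpus, extract_text_features
from .trendclass import TrendTable, default_trend_table

__all__ = [
    "FixtureSpec",
    "DEFAULT_ADHERENCE",
    "MURZYME_VOCAB",
    "CLASSICAL_VOCAB",
    "SHARED_VOCAB",
    "gen_feature_table",
    "gen_pdb_corpus",
    "default_corpus_spec",
]

#: Probability that a sampled value follows its class trend, per trend strength.
DEFAULT_ADHERENCE: dict[str, float] = {
    "definite": 1.0,
    "usually": 0.8,
    "some": 0.4,
    "rare": 0.1,
    "mixed": 0.5,
}

MURZYME_VOCAB = (
    "peroxidase", "oxidase", "cytochrome", "heme", "monooxygenase",
    "catalase", "dioxygenase", "oxidoreductase", "superoxide", "reductase",
    "peroxide", "radical", "flavoprotein", "globin",
)

CLASSICAL_VOCAB = (
    "polymerase", "ligase", "protease", "kinase", "isomerase",
    "hydrolase", "transferase", "helicase", "nuclease", "synthetase",
    "ribosome", "phosphatase", "amylase", "lipase",
)

SHARED_VOCAB = (
    "enzyme", "protein", "catalysis", "metabolism", "binding",
    "complex", "structure", "cofactor", "substrate", "reaction",
    "biosynthesis", "regulation",
)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic cohort (feature table or PDB corpus)."""

    n_murzyme: int = 22
    n_classical: int = 17
    seed: int = 0
    adherence: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ADHERENCE))
    include_postulates: bool = False
    # PDB-corpus knobs
    overlap: float = 0.3
    murzyme_vocab: tuple[str, ...] = MURZYME_VOCAB
    classical_vocab: tuple[str, ...] = CLASSICAL_VOCAB
    shared_vocab: tuple[str, ...] = SHARED_VOCAB

    def __post_init__(self) -> None:
        if self.n_murzyme < 1 or self.n_classical < 1:
            raise ValueError("both classes need at least one sample")
        for k, v in self.adherence.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"adherence[{k!r}] must lie in [0, 1], got {v}")
        if not (0.0 <= self.overlap <= 1.0):
            raise ValueError(f"vocabulary overlap must lie in [0, 1], got {self.overlap}")
        for name in ("murzyme_vocab", "classical_vocab", "shared_vocab"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")


def default_corpus_spec(seed: int = 0, **kw) -> FixtureSpec:
    """The default 200-record PDB-corpus spec (56 murzyme / 144 classical)."""
    kw.setdefault("n_murzyme", 56)
    kw.setdefault("n_classical", 144)
    return FixtureSpec(seed=seed, **kw)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def _p_yes(token: str, adherence: dict[str, float]) -> float:
    """Class-conditional probability of a *yes* (or *high*) answer."""
    if token in ("yes", "high"):
        return adherence["definite"]
    if token in ("no", "low", "moderate"):
        return 1.0 - adherence["definite"]
    if token == "usually-yes":
        return adherence["usually"]
    if token == "usually-no":
        return 1.0 - adherence["usually"]
    if token == "some-yes":
        return adherence["some"]
    if token == "rare":
        return adherence["rare"]
    if token == "sometimes-high":
        return adherence["mixed"]
    if token in ("mixed", "sometimes", "need-not-be"):
        return adherence["mixed"]
    raise ValueError(f"unhandled trend token {token!r}")


def gen_feature_table(
    spec: FixtureSpec, trends: TrendTable | None = None
) -> FeatureTable:
    """Sample a labeled binary feature table following the class trends.

    Murzyme rows draw each feature from the murburn trend token's yes-
    probability, classical rows from the classical token's.  With the
    default adherence map every definite trend is followed exactly, so the
    definite rows separate the classes perfectly while soft trends inject
    class-conditional noise.  Deterministic under ``spec.seed``.  Ordinal
    postulate criteria (when included) are binarised as "is the value high?".
    """
    trends = trends if trends is not None else default_trend_table()
    rng = np.random.default_rng(spec.seed)
    rows = trends.rows if spec.include_postulates else trends.rows[:20]
    data: dict[str, list[int]] = {r.feature: [] for r in rows}
    labels: list[str] = []
    for label, n in (("murzyme", spec.n_murzyme), ("classical", spec.n_classical)):
        for _ in range(n):
            labels.append(label)
            for r in rows:
                token = r.murburn if label == "murzyme" else r.classical
                p = _p_yes(token, spec.adherence)
                data[r.feature].append(int(rng.random() < p))
    df = pd.DataFrame(data)
    df["label"] = labels
    return FeatureTable(df)


# ---------------------------------------------------------------------------
# PDB corpora
# ---------------------------------------------------------------------------

def _pdb_line(record: str, body: str, continuation: int = 0) -> str:
    """One 80-column PDB record line."""
    if continuation:
        line = f"{record:<6}  {continuation:>2}{body}"
    else:
        line = f"{record:<6}    {body}"
    return f"{line:<80}"[:80]


def _wrap_record(record: str, body: str, width: int = 60) -> list[str]:
    """Split a long record body across continuation lines at word boundaries."""
    words = body.split()
    chunks: list[str] = []
    current = ""
    for w in words:
        cand = f"{current} {w}".strip()
        if len(cand) > width and current:
            chunks.append(current)
            current = w
        else:
            current = cand
    if current:
        chunks.append(current)
    lines = []
    for i, chunk in enumerate(chunks):
        lines.append(_pdb_line(record, chunk, continuation=i + 1 if i else 0))
    return lines


def _render_pdb(
    entry_id: str, classification: str, title: str, molecules: list[str],
    keywords: list[str], het: Optional[str],
) -> str:
    lines = [
        f"{'HEADER':<6}    {classification.upper():<40}{'01-JAN-20':>9}   {entry_id.upper():<4}"[:80].ljust(80)
    ]
    lines += _wrap_record("TITLE", title.upper())
    compnd_body = "MOL_ID: 1; " + " ".join(
        f"MOLECULE: {m.upper()};" for m in molecules
    ) + " CHAIN: A"
    lines += _wrap_record("COMPND", compnd_body)
    lines += _wrap_record("KEYWDS", ", ".join(k.upper() for k in keywords))
    if het:
        lines.append(f"HET    {het.upper():>3}  A 501      43".ljust(80))
        lines.append(f"HETNAM     {het.upper():>3} PROTOPORPHYRIN IX CONTAINING FE".ljust(80))
    lines.append("END".ljust(80))
    return "\n".join(lines) + "\n"


def gen_pdb_corpus(
    spec: FixtureSpec, out_dir=None
) -> LabeledCorpus:
    """Generate a labeled synthetic PDB-text corpus (synthetic stand-in for a
    curated structure collection).

    Each file's descriptive tokens come from its class vocabulary, except
    that with probability ``spec.overlap`` a file is "generic": all its
    tokens come from the shared vocabulary and only the class-blind records
    remain, making it unclassifiable from text alone.  Every murzyme file
    carries a HET record for the heme ligand (HEM); HET codes are *not* part
    of the cleaned embedding text, so they do not leak the label.  When
    ``out_dir`` is given the files are written as ``<id>.pdb`` alongside a
    ``labels.tsv`` manifest.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    records, labels = [], []
    texts: dict[str, str] = {}
    counters = {"murzyme": 0, "classical": 0}
    plan = ["murzyme"] * spec.n_murzyme + ["classical"] * spec.n_classical
    for label in plan:
        counters[label] += 1
        entry_id = f"{'m' if label == 'murzyme' else 'c'}{counters[label]:03d}"
        class_vocab = spec.murzyme_vocab if label == "murzyme" else spec.classical_vocab
        generic = rng.random() < spec.overlap
        pool = np.asarray(spec.shared_vocab if generic else class_vocab)
        pick = lambda k: [str(w) for w in rng.choice(pool, size=k, replace=False)]

        classification = pick(1)[0]
        title = " ".join(pick(3)) + " from synthetic organism"
        molecules = [" ".join(pick(2))]
        keywords = pick(min(4, len(pool)))
        het = "HEM" if label == "murzyme" else None
        text = _render_pdb(entry_id, classification, title, molecules, keywords, het)
        texts[entry_id] = text
        # roundtrip through the parser so corpus fields always match the files
        records.append(extract_text_features(text))
        labels.append(label)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = []
        for (entry_id, text), label in zip(texts.items(), labels):
            (out_dir / f"{entry_id}.pdb").write_text(text)
            manifest.append(f"{entry_id}\t{label}")
        (out_dir / "labels.tsv").write_text("\n".join(manifest) + "\n")
    return LabeledCorpus(records, labels)
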