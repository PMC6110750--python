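"""Cloze probability of produced sentence endings.

Because the endings are produced spontaneously rather than fixed in advance,
cloze probability is defined post hoc as the share of responses for a
sentence x condition cell that used the *most frequent* ending.  Cells are
classed as high (>= 0.67), medium (0.34-0.66) or low cloze; the printed bands
leave (0.66, 0.67) undefined, and values falling in that gap are assigned to
``medium`` with a logged note.
"""

from __future__ import annotations

import logging
import string
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_PUNCT = str.maketrans("", "", string.punctuation)


def normalize_word(word: str) -> str:
    """Lowercase, strip punctuation and surrounding whitespace."""
    return word.translate(_PUNCT).strip().lower()


@dataclass
class ClozeRecord:
    sentence_id: object
    condition: str
    modal_word: str
    modal_count: int
    total: int
    cloze: float
    cloze_class: str

    def __post_init__(self) -> None:
        if not 0.0 < self.cloze <= 1.0:
            raise ValueError("cloze must lie in (0, 1]")


def cloze_probability(responses, sentence_id=None,
                      condition: str = "") -> ClozeRecord:
    """Modal-ending share of a response list (ties -> lexicographically
    first, logged)."""
    words = [normalize_word(w) for w in responses]
    words = [w for w in words if w]
    if not words:
        raise ValueError("no responses for this sentence/condition")
    counts = Counter(words)
    top = max(counts.values())
    modal_candidates = sorted(w for w, c in counts.items() if c == top)
    if len(modal_candidates) > 1:
        log.info("modal tie among %s; using %r", modal_candidates,
                 modal_candidates[0])
    modal = modal_candidates[0]
    cloze = top / len(words)
    return ClozeRecord(sentence_id, condition, modal, top, len(words),
                       cloze, classify_cloze(cloze))


def classify_cloze(cloze: float) -> str:
    """high for >= 0.67, medium for [0.34, 0.66], low below 0.34.

    Values in the undefined printed gap (0.66, 0.67) are logged and classed
    medium.
    """
    if not 0.0 < cloze <= 1.0:
        raise ValueError("cloze must lie in (0, 1]")
    if cloze >= 0.67:
        return "high"
    if cloze > 0.66:
        log.info("cloze %.4f falls in the undefined (0.66, 0.67) band; "
                 "classing medium", cloze)
        return "medium"
    if cloze >= 0.34:
        return "medium"
    return "low"


def summarize_conditions(records: list[ClozeRecord]) -> pd.DataFrame:
    """Mean/SD/min/max cloze per condition (SD is 0 for a single record)."""
    if not records:
        raise ValueError("no cloze records")
    frame = pd.DataFrame([vars(r) for r in records])
    out = []
    for cond, g in frame.groupby("condition"):
        c = g["cloze"].to_numpy()
        out.append({"condition": cond, "n": c.size, "mean": c.mean(),
                    "sd": c.std(ddof=1) if c.size > 1 else 0.0,
                    "min": c.min(), "max": c.max()})
    return pd.DataFrame(out)


def response_table_records(table: pd.DataFrame) -> list[ClozeRecord]:
    """Cloze records for a long-format response table.

    Expects columns ``sentence``, ``condition``, ``response`` (one row per
    responding subject).
    """
    for col in ("sentence", "condition", "response"):
        if col not in table.columns:
            raise ValueError(f"response table missing column {col!r}")
    return [cloze_probability(g["response"].tolist(), sentence_id=sid,
                              condition=cond)
            for (sid, cond), g in table.groupby(["sentence", "condition"])]


def simulate_response_table(rng: np.random.Generator, n_sentences: int = 40,
                            n_subjects: int = 15,
                            modal_prob_expected: float = 0.8,
                            modal_prob_unexpected: float = 0.15
                            ) -> pd.DataFrame:
    """Synthetic produced-ending table with a known modal probability.

    Each sentence has a designated modal ending produced with the condition's
    probability; other responses are unique filler words, mimicking the
    near-unique endings of the unexpected condition.
    """
    rows = []
    for s in range(n_sentences):
        for cond, p in (("expected", modal_prob_expected),
                        ("unexpected", modal_prob_unexpected)):
            for subj in range(n_subjects):
                if rng.uniform() < p:
                    word = f"modal{s}"
                else:
                    word = f"filler{s}_{cond}_{subj}"
                rows.append({"sentence": s, "condition": cond,
                             "response": word})
    return pd.DataFrame(rows)
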