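"""Survey data preparation: exclusion rules and answer normalization.

Three exclusion criteria are applied in a fixed order — completion time,
manual irrelevance flag, per-question minimum distinct-word count — and each
removed record is attributed to exactly one criterion (the first it fails).
Between the time filter and the word-count filter, the per-question text
fields are aggregated into a single word sequence: concatenated in field
order, tokenized on whitespace, edge punctuation stripped, lowercased, and
repeated words collapsed to their first occurrence.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CleaningConfig",
    "ExclusionLedger",
    "tokenize_field",
    "aggregate_and_dedupe",
    "filter_time",
    "filter_irrelevant",
    "suggest_irrelevant",
    "filter_wordmin",
    "run_pipeline",
]

_PUNCT = string.punctuation


@dataclass(frozen=True)
class CleaningConfig:
    time_cutoff_minutes: float = 5.0
    min_words: int = 3
    n_questions: int = 4
    fields_per_question: int = 10


@dataclass
class ExclusionLedger:
    """Audit trail: every input record is kept or excluded for one reason."""

    initial_n: int
    excluded_time: int
    excluded_irrelevant: int
    excluded_wordmin: int
    final_n: int
    dispositions: pd.DataFrame = field(repr=False)  # id, disposition

    def __post_init__(self) -> None:
        total = self.excluded_time + self.excluded_irrelevant + self.excluded_wordmin + self.final_n
        if total != self.initial_n:
            raise ValueError(f"ledger does not conserve records: {total} != {self.initial_n}")

    @property
    def excluded_total(self) -> int:
        return self.initial_n - self.final_n

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "initial_n": self.initial_n,
            "excluded_time": self.excluded_time,
            "excluded_irrelevant": self.excluded_irrelevant,
            "excluded_wordmin": self.excluded_wordmin,
            "excluded_total": self.excluded_total,
            "final_n": self.final_n,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def tokenize_field(text: str) -> list[str]:
    """Whitespace split, strip edge punctuation, lowercase; drop empty tokens."""
    out = []
    for tok in str(text).split():
        tok = tok.strip(_PUNCT).lower()
        if tok:
            out.append(tok)
    return out


def _question_fields(row, q: int, fields_per_question: int) -> list[str]:
    return [str(row[f"q{q}_f{f}"]) for f in range(1, fields_per_question + 1)]


def aggregate_and_dedupe(record, config: CleaningConfig = CleaningConfig()) -> dict[int, list[str]]:
    """Aggregate one record's fields per question into a deduplicated sequence.

    Field boundaries vanish; repeated words are reduced to their first
    occurrence, preserving relative order.
    """
    sequences: dict[int, list[str]] = {}
    for q in range(1, config.n_questions + 1):
        tokens: list[str] = []
        for fld in _question_fields(record, q, config.fields_per_question):
            tokens.extend(tokenize_field(fld))
        sequences[q] = list(dict.fromkeys(tokens))
    return sequences


def filter_time(
    records: pd.DataFrame, cutoff_minutes: float = 5.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (kept, excluded) by completion time; cutoff inclusive."""
    t = pd.to_numeric(records["time_minutes"])
    if (t < 0).any():
        bad = records.loc[t < 0, "id"].tolist()
        raise ValueError(f"negative completion times for ids {bad}")
    mask = t <= cutoff_minutes
    return records.loc[~mask].copy(), records.loc[mask].copy()


def suggest_irrelevant(records: pd.DataFrame, config: CleaningConfig = CleaningConfig()) -> pd.Series:
    """Heuristic pre-population of irrelevance flags (off by default downstream).

    Flags records whose filled fields all contain one single repeated token —
    the placeholder pattern seen in careless responding.
    """
    out = []
    for _, row in records.iterrows():
        toks: set[str] = set()
        n_filled = 0
        for q in range(1, config.n_questions + 1):
            for fld in _question_fields(row, q, config.fields_per_question):
                ts = tokenize_field(fld)
                if ts:
                    n_filled += 1
                    toks.update(ts)
        out.append(n_filled > 0 and len(toks) == 1)
    return pd.Series(out, index=records.index, name="suggested_irrelevant")


def filter_irrelevant(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split on the manual irrelevance flag."""
    if "irrelevant_flag" not in records.columns:
        raise ValueError("records lack the 'irrelevant_flag' column")
    mask = records["irrelevant_flag"].astype(bool)
    return records.loc[~mask].copy(), records.loc[mask].copy()


def _clean_frame(records: pd.DataFrame, config: CleaningConfig) -> pd.DataFrame:
    """Attach aggregated word sequences and distinct counts per question."""
    out = records.copy()
    for q in range(1, config.n_questions + 1):
        seqs = []
        for _, row in records.iterrows():
            tokens: list[str] = []
            for fld in _question_fields(row, q, config.fields_per_question):
                tokens.extend(tokenize_field(fld))
            seqs.append(" ".join(dict.fromkeys(tokens)))
        out[f"q{q}"] = seqs
        out[f"q{q}_n_words"] = [len(s.split()) if s else 0 for s in seqs]
    return out


def filter_wordmin(
    clean_records: pd.DataFrame, min_words: int = 3, n_questions: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude records with fewer than ``min_words`` distinct words on ANY question."""
    counts = clean_records[[f"q{q}_n_words" for q in range(1, n_questions + 1)]]
    mask = (counts < min_words).any(axis=1)
    return clean_records.loc[~mask].copy(), clean_records.loc[mask].copy()


def run_pipeline(
    records: pd.DataFrame, config: CleaningConfig = CleaningConfig()
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Apply time -> irrelevance -> word-minimum exclusions with a full ledger.

    Returns the clean dataset (one aggregated, deduplicated word sequence per
    question in columns q1..q4, plus carried demographics and GDT items) and
    the exclusion ledger.
    """
    initial_n = len(records)
    kept_t, excl_t = filter_time(records, config.time_cutoff_minutes)
    kept_i, excl_i = filter_irrelevant(kept_t)
    clean = _clean_frame(kept_i, config)
    kept_w, excl_w = filter_wordmin(clean, config.min_words, config.n_questions)

    disp = pd.concat(
        [
            pd.DataFrame({"id": excl_t["id"], "disposition": "excluded_time"}),
            pd.DataFrame({"id": excl_i["id"], "disposition": "excluded_irrelevant"}),
            pd.DataFrame({"id": excl_w["id"], "disposition": "excluded_wordmin"}),
            pd.DataFrame({"id": kept_w["id"], "disposition": "kept"}),
        ],
        ignore_index=True,
    )
    ledger = ExclusionLedger(
        initial_n=initial_n,
        excluded_time=len(excl_t),
        excluded_irrelevant=len(excl_i),
        excluded_wordmin=len(excl_w),
        final_n=len(kept_w),
        dispositions=disp,
    )
    keep_cols = ["id", "time_minutes", "gender", "age"]
    keep_cols += [f"q{q}" for q in range(1, config.n_questions + 1)]
    keep_cols += [f"q{q}_n_words" for q in range(1, config.n_questions + 1)]
    keep_cols += [f"gdt_{i}" for i in range(1, 5)]
    return kept_w[keep_cols].reset_index(drop=True), ledger
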