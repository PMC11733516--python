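"""Leave-one-word-out importance and word-cloud data export.

For each word in one question's vocabulary, the word is deleted from every
respondent's answer to that question, the affected answers are re-encoded,
and the out-of-fold validity correlation is recomputed on the SAME fold
assignment as the baseline.  The performance drop delta = baseline_r −
ablated_r is standardized across the vocabulary into a z-score; words whose
two-sided normal p falls below alpha are flagged as significant drivers.
Holding folds, seeds and the analysis set fixed guarantees that a word's
delta reflects the word, not resampling noise — respondents are NOT
re-excluded even if a deletion drops them below the minimum word count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import Encoder, build_features, encode_answer
from .predict import CVSpec, OOFResult, RidgeSpec, kfold_split, oof_predict, pearson_with_p

__all__ = [
    "AblationResult",
    "WordCloudDatum",
    "vocabulary",
    "word_counts",
    "remove_word",
    "ablation_scan",
    "standardize_and_flag",
    "wordcloud_data",
]


@dataclass
class AblationResult:
    word: str
    question: int
    baseline_r: float
    ablated_r: float
    delta: float
    z: float = float("nan")
    p: float = float("nan")
    significant: bool = False

    def to_dict(self) -> dict:
        return {
            "word": self.word,
            "question": self.question,
            "baseline_r": self.baseline_r,
            "ablated_r": self.ablated_r,
            "delta": self.delta,
            "z": self.z,
            "p": self.p,
            "significant": self.significant,
        }


@dataclass
class WordCloudDatum:
    word: str
    size: float
    bucket: str  # "p<.01", "p<.05", or "ns"
    z: float
    p: float


def word_counts(dataset: pd.DataFrame, question: int) -> Counter:
    """Respondent-level frequency of each word in one question's answers."""
    col = f"q{question}"
    if col not in dataset.columns:
        raise KeyError(f"unknown question q{question}")
    counts: Counter = Counter()
    for seq in dataset[col]:
        counts.update(str(seq).split())
    return counts


def vocabulary(dataset: pd.DataFrame, question: int, min_count: int = 1) -> list[str]:
    """Unique words used in one question's answers, optionally frequency-filtered.

    Order is deterministic: first occurrence across respondents.
    """
    col = f"q{question}"
    if col not in dataset.columns:
        raise KeyError(f"unknown question q{question}")
    counts = word_counts(dataset, question)
    seen: dict[str, None] = {}
    for seq in dataset[col]:
        for w in str(seq).split():
            seen.setdefault(w, None)
    return [w for w in seen if counts[w] >= min_count]


def remove_word(dataset: pd.DataFrame, question: int, word: str) -> pd.DataFrame:
    """Delete one word from every answer to one question; all else untouched."""
    col = f"q{question}"
    out = dataset.copy()
    out[col] = [
        " ".join(w for w in str(seq).split() if w != word) for seq in dataset[col]
    ]
    return out


def _encode_sequences(encoder: Encoder, sequences: list[str]) -> np.ndarray:
    """Encode word sequences; an emptied answer maps to the zero vector."""
    out = np.zeros((len(sequences), encoder.dim))
    for i, seq in enumerate(sequences):
        words = str(seq).split()
        if words:
            out[i] = encode_answer(encoder, words)
    return out


def ablation_scan(
    dataset: pd.DataFrame,
    encoder: Encoder,
    ridge_spec: RidgeSpec,
    cv_spec: CVSpec,
    question: int,
    min_count: int = 1,
) -> list[AblationResult]:
    """Leave-one-word-out scan over one question's vocabulary.

    The baseline model uses that question's features alone; the fold
    assignment is computed once from ``cv_spec`` and reused for every word.
    Only answers containing the word are re-encoded.
    """
    vocab = vocabulary(dataset, question, min_count=min_count)
    if not vocab:
        raise ValueError(f"question q{question} has an empty vocabulary")
    y = dataset[[f"gdt_{i}" for i in range(1, 5)]].to_numpy().sum(axis=1).astype(float)
    base_fm = build_features(dataset, encoder, (question,))
    folds = kfold_split(len(dataset), cv_spec)
    base_oof = oof_predict(base_fm.values, y, ridge_spec, cv_spec, fold_assignment=folds)
    baseline_r, _ = pearson_with_p(base_oof.predictions, y)

    sequences = [str(s) for s in dataset[f"q{question}"].tolist()]
    results = []
    for word in vocab:
        affected = [i for i, seq in enumerate(sequences) if word in seq.split()]
        X = base_fm.values.copy()
        stripped = [
            " ".join(w for w in sequences[i].split() if w != word) for i in affected
        ]
        X[affected] = _encode_sequences(encoder, stripped)
        oof = oof_predict(X, y, ridge_spec, cv_spec, fold_assignment=folds)
        ablated_r, _ = pearson_with_p(oof.predictions, y)
        results.append(
            AblationResult(
                word=word,
                question=question,
                baseline_r=baseline_r,
                ablated_r=ablated_r,
                delta=baseline_r - ablated_r,
            )
        )
    return results


def standardize_and_flag(
    results: list[AblationResult], alpha: float = 0.05
) -> list[AblationResult]:
    """Standardize deltas across words into z-scores and flag significance.

    z_w = (delta_w − mean(delta)) / sd(delta) with the population (n)
    denominator; p is two-sided normal; flagged iff p < alpha (p == alpha is
    not significant).
    """
    if len(results) < 2:
        raise ValueError("need at least 2 words to standardize")
    deltas = np.array([r.delta for r in results])
    sd = deltas.std(ddof=0)
    if sd == 0 or np.ptp(deltas) == 0:
        raise ValueError("all deltas identical; z-scores undefined")
    mean = deltas.mean()
    out = []
    for r, d in zip(results, deltas):
        z = (d - mean) / sd
        p = float(2 * stats.norm.sf(abs(z)))
        out.append(
            AblationResult(
                word=r.word,
                question=r.question,
                baseline_r=r.baseline_r,
                ablated_r=r.ablated_r,
                delta=r.delta,
                z=float(z),
                p=p,
                significant=p < alpha,
            )
        )
    return out


def wordcloud_data(
    results: list[AblationResult], size_range: tuple[float, float] = (10.0, 100.0)
) -> list[WordCloudDatum]:
    """Export renderer-ready word-cloud data: size ∝ z (floored at 0), bucketed p.

    Buckets: "p<.01", "p<.05", "ns"; a p of exactly .05 lands in "ns".
    Ordering by size equals ordering by z.
    """
    lo, hi = size_range
    if hi < lo:
        raise ValueError("size_range must be (low, high) with low <= high")
    zs = np.array([max(r.z, 0.0) for r in results])
    zmax = zs.max() if len(zs) and zs.max() > 0 else 1.0
    out = []
    for r, z in zip(results, zs):
        if r.p < 0.01:
            bucket = "p<.01"
        elif r.p < 0.05:
            bucket = "p<.05"
        else:
            bucket = "ns"
        out.append(
            WordCloudDatum(word=r.word, size=lo + (hi - lo) * z / zmax, bucket=bucket, z=r.z, p=r.p)
        )
    return out
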