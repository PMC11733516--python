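"""Pluggable text encoders and stacked per-question feature matrices.

Each question's word sequence is mapped to a fixed-dimension vector; the
vectors for a chosen subset of questions are concatenated (question blocks
in ascending index order) into one feature matrix per respondent.

Two encoders implement the contract:

* :class:`HashingBowEncoder` — a deterministic bag-of-words embedding in
  which every word hashes to a fixed random unit vector and an answer is the
  (optionally L2-normalized) sum of its word vectors.  It is the default
  path: fully reproducible, no model weights, yet it preserves additive
  lexical signal, which is what a linear ridge reads.
* :class:`TransformerEncoder` — an optional adapter around a Hugging Face
  masked language model (last hidden layer, mean- or first-token pooling),
  for running the pipeline with a contextual sentence embedding.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Encoder",
    "HashingBowEncoder",
    "TransformerEncoder",
    "FeatureMatrix",
    "encode_answer",
    "build_features",
    "CANONICAL_SUBSETS",
]

# The five canonical per-question feature sets, plus the two combinations
# used in subgroup comparisons.
CANONICAL_SUBSETS: tuple[tuple[int, ...], ...] = ((1, 2, 3, 4), (1,), (2,), (3,), (4,))


class Encoder(Protocol):
    dim: int

    def encode(self, words: Sequence[str]) -> np.ndarray: ...

    @property
    def identity(self) -> str: ...


@dataclass
class HashingBowEncoder:
    """Deterministic bag-of-words embedding via seeded random projections.

    Each word deterministically seeds a pseudorandom unit vector in R^dim
    (seed derived from blake2b(word, seed), stable across processes); an
    answer is encoded as the sum of its word vectors, L2-normalized by
    default.  Word order never matters; adding a word adds a fixed increment
    before normalization.
    """

    dim: int = 768
    seed: int = 0
    normalize: bool = True
    _cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def word_vector(self, word: str) -> np.ndarray:
        vec = self._cache.get(word)
        if vec is None:
            digest = hashlib.blake2b(
                f"{self.seed}:{word}".encode(), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "big"))
            vec = rng.standard_normal(self.dim)
            vec /= np.linalg.norm(vec)
            self._cache[word] = vec
        return vec

    def encode(self, words: Sequence[str]) -> np.ndarray:
        if len(words) == 0:
            raise ValueError("cannot encode an empty word sequence")
        total = np.zeros(self.dim)
        for w in words:
            total += self.word_vector(w)
        if self.normalize:
            norm = np.linalg.norm(total)
            if norm > 0:
                total = total / norm
        return total

    @property
    def identity(self) -> str:
        return f"hashing_bow(dim={self.dim}, seed={self.seed}, normalize={self.normalize})"


@dataclass
class TransformerEncoder:
    """Adapter around a Hugging Face masked language model (optional extra).

    Pools the last hidden layer over tokens: ``pooling='mean'`` (default) or
    ``'first'`` (the [CLS] position).  Requires the ``transformer`` extra
    (transformers + torch); import happens lazily so the rest of the package
    works without model weights.
    """

    model_id: str = "allegro/herbert-base-cased"
    pooling: str = "mean"
    dim: int = 768

    def __post_init__(self) -> None:
        if self.pooling not in ("mean", "first"):
            raise ValueError("pooling must be 'mean' or 'first'")
        self._model = None
        self._tokenizer = None

    def _load(self):
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - optional path
            raise ImportError(
                "TransformerEncoder requires the 'transformer' extra "
                "(pip install qcla[transformer])"
            ) from exc
        self._tokenizer = AutoTokenizer.from_pretrained(self.model_id)
        self._model = AutoModel.from_pretrained(self.model_id)
        self._model.eval()

    def encode(self, words: Sequence[str]) -> np.ndarray:  # pragma: no cover - optional path
        if len(words) == 0:
            raise ValueError("cannot encode an empty word sequence")
        if self._model is None:
            self._load()
        import torch

        text = " ".join(words)
        with torch.no_grad():
            inputs = self._tokenizer(text, return_tensors="pt", truncation=True)
            hidden = self._model(**inputs).last_hidden_state[0]
        vec = hidden[0] if self.pooling == "first" else hidden.mean(dim=0)
        return vec.numpy().astype(float)

    @property
    def identity(self) -> str:
        return f"transformer(model={self.model_id}, pooling={self.pooling})"


def encode_answer(encoder: Encoder, word_sequence: Sequence[str]) -> np.ndarray:
    """Encode one answer; pure function of (encoder spec, text)."""
    vec = encoder.encode(word_sequence)
    if vec.shape != (encoder.dim,) or not np.all(np.isfinite(vec)):
        raise ValueError("encoder returned a malformed vector")
    return vec


@dataclass
class FeatureMatrix:
    """n x (|subset| * dim) stacked embeddings, row-aligned with respondent ids."""

    ids: list[str]
    question_subset: tuple[int, ...]
    values: np.ndarray
    encoder_identity: str

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.ids):
            raise ValueError("row count does not match id count")

    def save(self, prefix: str) -> None:
        np.save(f"{prefix}.npy", self.values)
        header = {
            "format_version": 1,
            "ids": self.ids,
            "question_subset": list(self.question_subset),
            "encoder_identity": self.encoder_identity,
            "shape": list(self.values.shape),
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(header, fh)

    @classmethod
    def load(cls, prefix: str) -> "FeatureMatrix":
        with open(f"{prefix}.json") as fh:
            header = json.load(fh)
        values = np.load(f"{prefix}.npy")
        return cls(
            ids=header["ids"],
            question_subset=tuple(header["question_subset"]),
            values=values,
            encoder_identity=header["encoder_identity"],
        )


def build_features(
    dataset: pd.DataFrame, encoder: Encoder, question_subset: Sequence[int]
) -> FeatureMatrix:
    """Stack per-question embeddings for a subset of questions.

    ``dataset`` is a clean dataset with space-joined word sequences in
    columns q1..q4; blocks are ordered by ascending question index whatever
    order the subset is given in.
    """
    subset = tuple(sorted(set(int(q) for q in question_subset)))
    if not subset:
        raise ValueError("question subset must be non-empty")
    for q in subset:
        if f"q{q}" not in dataset.columns:
            raise KeyError(f"unknown question q{q}")
    n = len(dataset)
    values = np.empty((n, len(subset) * encoder.dim))
    for j, q in enumerate(subset):
        col = dataset[f"q{q}"].tolist()
        block = slice(j * encoder.dim, (j + 1) * encoder.dim)
        for i, seq in enumerate(col):
            values[i, block] = encode_answer(encoder, str(seq).split())
    return FeatureMatrix(
        ids=[str(x) for x in dataset["id"].tolist()],
        question_subset=subset,
        values=values,
        encoder_identity=encoder.identity,
    )
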