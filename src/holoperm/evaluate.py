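"""Evaluation harness: multiple-choice synonymy tests and rank correlation
with human word-pair similarity judgments.

A "model" here is anything that maps words to memory vectors: a trained
:class:`~holoperm.encoders.Lexicon`, a fitted
:class:`~holoperm.encoders.SemanticSpace`, or a plain ``dict`` of word →
vector (e.g. loaded from the labeled-vector text format).

OOV policy: a synonymy item whose probe (or every candidate) is out of
vocabulary is flagged unanswerable and scored incorrect; similarity pairs
with an OOV word are dropped, with the number of pairs actually used
reported alongside the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SynonymyItem",
    "SimilarityItem",
    "read_synonymy_tsv",
    "read_similarity_tsv",
    "answer_synonymy_item",
    "score_synonymy_test",
    "correlate_similarity_judgments",
]


@dataclass(frozen=True)
class SynonymyItem:
    """One multiple-choice question: pick the probe's synonym."""

    probe: str
    candidates: tuple[str, ...]
    correct_index: int

    def __post_init__(self) -> None:
        if len(self.candidates) < 2:
            raise ValueError("a synonymy item needs at least 2 candidates")
        if len(set(self.candidates)) != len(self.candidates):
            raise ValueError("candidates must be distinct")
        if not 0 <= self.correct_index < len(self.candidates):
            raise ValueError("correct_index out of range")


@dataclass(frozen=True)
class SimilarityItem:
    """A human-rated word pair (test-specific rating scale)."""

    word_a: str
    word_b: str
    rating: float

    def __post_init__(self) -> None:
        if self.word_a == self.word_b:
            raise ValueError("similarity pairs must contain two distinct words")


def read_synonymy_tsv(path) -> list[SynonymyItem]:
    """``probe<TAB>correct<TAB>distractor...`` — correct always first."""
    items = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if not line.strip():
                    continue
                raise ValueError(f"{path}:{lineno}: need probe, correct, distractors")
            items.append(SynonymyItem(parts[0], tuple(parts[1:]), 0))
    if not items:
        raise ValueError(f"empty synonymy test {path}")
    return items


def read_similarity_tsv(path) -> list[SimilarityItem]:
    """``word_a<TAB>word_b<TAB>rating`` lines."""
    items = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                if not line.strip():
                    continue
                raise ValueError(f"{path}:{lineno}: need word_a, word_b, rating")
            items.append(SimilarityItem(parts[0], parts[1], float(parts[2])))
    if not items:
        raise ValueError(f"empty similarity file {path}")
    return items


def _vector(model, word: str):
    """Memory vector for ``word`` or None if OOV; accepts several model types."""
    if hasattr(model, "memory_vector"):
        return model.memory_vector(word)
    if hasattr(model, "lexicon_"):
        return model.lexicon_.memory_vector(word)
    try:
        return model[word]
    except KeyError:
        return None


def _quiet_cosine(x: np.ndarray, y: np.ndarray) -> float:
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.dot(x, y) / (nx * ny))


def answer_synonymy_item(model, item: SynonymyItem) -> tuple[int, bool]:
    """Choose the candidate most cosine-similar to the probe.

    Returns ``(chosen_index, answerable)``.  OOV candidates never win; if
    the probe or every candidate is OOV the item is unanswerable and
    ``chosen_index`` is -1.  Ties break toward the lowest candidate index.
    """
    probe_vec = _vector(model, item.probe)
    if probe_vec is None:
        return -1, False
    sims = np.full(len(item.candidates), -np.inf)
    for i, cand in enumerate(item.candidates):
        vec = _vector(model, cand)
        if vec is not None:
            sims[i] = _quiet_cosine(probe_vec, vec)
    if not np.isfinite(sims).any():
        return -1, False
    return int(np.argmax(sims)), True


def score_synonymy_test(model, items: Sequence[SynonymyItem]) -> tuple[float, float]:
    """Fraction correct (unanswerable counts as wrong) and fraction answerable."""
    if len(items) == 0:
        raise ValueError("empty synonymy test")
    n_correct = 0
    n_answerable = 0
    for item in items:
        chosen, answerable = answer_synonymy_item(model, item)
        if answerable:
            n_answerable += 1
            if chosen == item.correct_index:
                n_correct += 1
    return n_correct / len(items), n_answerable / len(items)


def correlate_similarity_judgments(
    model, items: Sequence[SimilarityItem]
) -> tuple[float, int]:
    """Spearman rank correlation between model cosines and human ratings.

    Pairs with an OOV word are dropped; returns ``(rho, n_used)``.  Ties
    are handled by average ranks (the scipy default).
    """
    cosines = []
    ratings = []
    for item in items:
        va = _vector(model, item.word_a)
        vb = _vector(model, item.word_b)
        if va is None or vb is None:
            continue
        cosines.append(_quiet_cosine(va, vb))
        ratings.append(item.rating)
    if len(cosines) < 3:
        raise ValueError(
            f"need at least 3 in-vocabulary pairs, got {len(cosines)}"
        )
    rho = stats.spearmanr(cosines, ratings).statistic
    return float(rho), len(cosines)
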