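"""Corpus reading, tokenization, and synthetic fixture generation.

Real corpora are plain UTF-8 text, one document per line, sentences split
on ``.``/``!``/``?``.  The synthetic generator emits a small corpus with
*planted* paradigmatic structure: groups of designated synonyms are sampled
interchangeably into the same sentence templates, so that a working
order/context encoder must recover the groups.  Matching multiple-choice
synonymy and word-pair similarity files are generated from the same ground
truth, which makes end-to-end training and evaluation runnable with no
external data.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Document",
    "tokenize",
    "split_sentences",
    "read_plaintext_corpus",
    "SyntheticCorpusSpec",
    "generate_synthetic_corpus",
    "generate_synthetic_eval_sets",
]

_EDGE_PUNCT = re.compile(r"^\W+|\W+$", re.UNICODE)
_SENT_SPLIT = re.compile(r"[.!?]+(?:\s+|$)")


@dataclass
class Document:
    """A tokenized document: a list of sentences, each a list of tokens."""

    sentences: list[list[str]]


def tokenize(text: str) -> list[str]:
    """Lowercase, split on whitespace, strip edge punctuation, drop empties."""
    out = []
    for raw in text.lower().split():
        tok = _EDGE_PUNCT.sub("", raw)
        if tok:
            out.append(tok)
    return out


def split_sentences(line: str) -> list[str]:
    """Split a document line into sentence strings on ./!/? + whitespace."""
    return [s for s in _SENT_SPLIT.split(line) if s and s.strip()]


def read_plaintext_corpus(path) -> Iterator[Document]:
    """Lazily yield tokenized documents, one per nonblank line of ``path``."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            sentences = [tokenize(s) for s in split_sentences(line)]
            sentences = [s for s in sentences if s]
            if sentences:
                yield Document(sentences)


# ---------------------------------------------------------------------------
# Synthetic corpus with planted synonym groups
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCorpusSpec:
    """Parameters of the planted-synonym corpus generator.

    Synonymy here is purely paradigmatic: members of a group are
    interchangeable fillers of the same sentence templates.  With
    ``template_overlap`` close to 1 synonyms occur almost exclusively in
    shared contexts; at 0 the groups carry no signal.  Ten sentences per
    document mirrors the small-document sampling regime the encoders are
    normally run under.
    """

    n_synonym_groups: int = 16
    group_size: int = 2
    n_filler_words: int = 120
    n_documents: int = 400
    sentences_per_document: int = 10
    sentence_length_range: tuple[int, int] = (5, 9)
    template_overlap: float = 0.9
    templates_per_group: int = 3
    n_shared_templates: int = 40
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.template_overlap <= 1.0:
            raise ValueError("template_overlap must lie in [0, 1]")
        for name in (
            "n_synonym_groups",
            "group_size",
            "n_filler_words",
            "n_documents",
            "sentences_per_document",
            "templates_per_group",
            "n_shared_templates",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.sentence_length_range
        if lo < 2 or hi < lo:
            raise ValueError("sentence_length_range must satisfy 2 <= lo <= hi")
        if self.n_filler_words < hi:
            raise ValueError("vocabulary too small for the sentence length")


def _make_template(
    rng: np.random.Generator, fillers: Sequence[str], lo: int, hi: int
) -> tuple[tuple[str, ...], int]:
    """A template is a fixed filler sentence with one slot position."""
    length = int(rng.integers(lo, hi + 1))
    words = tuple(rng.choice(fillers, size=length - 1, replace=False))
    slot = int(rng.integers(length))
    return words, slot


def _instantiate(template: tuple[tuple[str, ...], int], word: str) -> list[str]:
    words, slot = template
    return list(words[:slot]) + [word] + list(words[slot:])


def generate_synthetic_corpus(
    spec: SyntheticCorpusSpec, corpus_path, truth_path
) -> tuple[Path, Path]:
    """Write a planted-synonym corpus and its ground-truth JSON.

    Every sentence realizes one template with one group member in its slot;
    with probability ``template_overlap`` the template is one of the group's
    own (shared by all members), otherwise a group-neutral one.  The first
    sentences deterministically cycle through every (member, home-template)
    combination so each synonym pair is guaranteed to share at least one
    realized template even in tiny corpora.  Deterministic given
    ``master_seed``.
    """
    rng = np.random.default_rng(spec.master_seed)
    groups = [
        [f"syn{g}_{j}" for j in range(spec.group_size)]
        for g in range(spec.n_synonym_groups)
    ]
    fillers = [f"fill{i}" for i in range(spec.n_filler_words)]
    lo, hi = spec.sentence_length_range

    group_templates = [
        [_make_template(rng, fillers, lo, hi) for _ in range(spec.templates_per_group)]
        for _ in range(spec.n_synonym_groups)
    ]
    shared_templates = [
        _make_template(rng, fillers, lo, hi) for _ in range(spec.n_shared_templates)
    ]

    # guaranteed coverage: each member realized in each of its home templates
    seeded: list[list[str]] = []
    for g, members in enumerate(groups):
        for t in group_templates[g]:
            for w in members:
                seeded.append(_instantiate(t, w))
    rng.shuffle(seeded)

    def random_sentence() -> list[str]:
        g = int(rng.integers(spec.n_synonym_groups))
        w = groups[g][int(rng.integers(spec.group_size))]
        if rng.random() < spec.template_overlap:
            t = group_templates[g][int(rng.integers(spec.templates_per_group))]
        else:
            t = shared_templates[int(rng.integers(spec.n_shared_templates))]
        return _instantiate(t, w)

    corpus_path = Path(corpus_path)
    with open(corpus_path, "w", encoding="utf-8") as fh:
        queue = list(seeded)
        for _ in range(spec.n_documents):
            sents = []
            for _ in range(spec.sentences_per_document):
                sents.append(queue.pop() if queue else random_sentence())
            fh.write(". ".join(" ".join(s) for s in sents) + ".\n")

    truth_path = Path(truth_path)
    truth = {"groups": groups, "fillers": fillers}
    truth_path.write_text(json.dumps(truth, indent=1), encoding="utf-8")
    return corpus_path, truth_path


def load_ground_truth(truth_path) -> dict:
    return json.loads(Path(truth_path).read_text(encoding="utf-8"))


def generate_synthetic_eval_sets(
    ground_truth: dict | str | Path,
    rng_seed: int,
    synonymy_path,
    similarity_path,
    n_distractors: int = 3,
) -> tuple[Path, Path]:
    """Write synonymy (TSV) and similarity (TSV) files from the ground truth.

    Synonymy: each group member is probed once; the correct answer is a
    fellow member, distractors come from other groups.  Similarity: synonym
    pairs receive high ratings and cross-group pairs low ratings on a 0-4
    scale.  Deterministic given ``rng_seed``.
    """
    if not isinstance(ground_truth, dict):
        ground_truth = load_ground_truth(ground_truth)
    groups: list[list[str]] = ground_truth["groups"]
    if len(groups) < n_distractors + 1:
        raise ValueError(
            f"need at least {n_distractors + 1} synonym groups to supply distractors"
        )
    rng = np.random.default_rng(rng_seed)

    synonymy_path = Path(synonymy_path)
    with open(synonymy_path, "w", encoding="utf-8") as fh:
        for g, members in enumerate(groups):
            for j, probe in enumerate(members):
                others = [w for w in members if w != probe]
                correct = others[int(rng.integers(len(others)))]
                other_groups = rng.choice(
                    [h for h in range(len(groups)) if h != g],
                    size=n_distractors,
                    replace=False,
                )
                distractors = [
                    groups[h][int(rng.integers(len(groups[h])))] for h in other_groups
                ]
                fh.write("\t".join([probe, correct, *distractors]) + "\n")

    similarity_path = Path(similarity_path)
    with open(similarity_path, "w", encoding="utf-8") as fh:
        pairs = []
        for members in groups:
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    rating = 3.2 + 0.8 * rng.random()
                    pairs.append((members[a], members[b], rating))
        n_cross = len(pairs)
        for _ in range(n_cross):
            g, h = rng.choice(len(groups), size=2, replace=False)
            a = groups[g][int(rng.integers(len(groups[g])))]
            b = groups[h][int(rng.integers(len(groups[h])))]
            rating = 0.8 * rng.random()
            pairs.append((a, b, rating))
        for a, b, rating in pairs:
            fh.write(f"{a}\t{b}\t{rating:.3f}\n")

    return synonymy_path, similarity_path
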