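"""Order- and context-sensitive semantic space encoders.

Every word keeps a static random *signal* (environmental) vector ``e_w``
and a dynamic *memory* vector ``m_w`` accumulated during a single pass over
a corpus.  Order information binds the signal vectors of a word's
neighbours into its memory vector using one of:

* ``convolution`` — all n-grams (length 2..λ) containing the target are
  circularly convolved left-to-right with a placeholder vector Φ standing
  in for the target, and the bindings are summed into ``m_target``;
* ``random_permutation`` — each neighbour's signal vector is permuted by
  the signed power of a base permutation matching its offset from the
  target (Π for the next word, Π² for the one after, Π⁻¹ for the previous,
  ...), then summed;
* direction-only variants (window ±2) that apply a single transform per
  side: Π⁻¹/Π for permutations, or the non-bijective random-connection
  transform T (before-side only, or T before / T² after).

Context information simply sums the signal vectors of co-occurring words
(the sentence, or a ±2 window), optionally excluding a stop list or the
most frequent words as cues.

The :class:`SemanticSpace` estimator wraps the whole pipeline in the
scikit-learn ``fit``/``transform`` idiom.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .corpus import Document, read_plaintext_corpus, tokenize, split_sentences
from .vectors import (
    GaussianSpec,
    PermutationMap,
    RandomConnectionMap,
    SparseTernarySpec,
    make_permutation,
    make_random_connections,
    make_signal_matrix,
    make_signal_vector,
    rc_transform,
    save_labeled_vectors,
)

__all__ = [
    "EncoderConfig",
    "beagle_config",
    "rpm_config",
    "Lexicon",
    "build_frequency_stats",
    "init_lexicon",
    "update_order_convolution",
    "update_order_rp",
    "update_context",
    "encode_rpm_sentence",
    "train_semantic_model",
    "SemanticSpace",
    "load_stoplist",
    "default_stoplist",
]

OPERATORS = (
    "convolution",
    "random_permutation",
    "random_connection_sim1",
    "random_connection_sim2",
)


@dataclass(frozen=True)
class EncoderConfig:
    """Training parameters for a semantic space.

    ``max_ngram`` is the λ parameter: the longest n-gram bound by the
    convolution operator (and the farthest offset, λ−1, encoded by signed
    permutation powers).  ``context_window`` is either ``"sentence"`` or an
    integer half-window.  ``freq_threshold_n`` omits the n most frequent
    corpus words as cues; ``stoplist`` words are omitted as *context* cues
    only.  The desk-scale default dimensionality is 2,048.
    """

    D: int = 2048
    operator: str = "random_permutation"
    max_ngram: int = 5
    context_window: str | int = "sentence"
    use_order: bool = True
    use_context: bool = False
    direction_only: bool = False
    freq_threshold_n: int = 0
    stoplist: frozenset[str] = frozenset()
    vector_kind: str = "gaussian"
    n_nonzero: int = 4
    perm_style: str = "random"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.operator not in OPERATORS:
            raise ValueError(f"unknown operator {self.operator!r}")
        if self.vector_kind not in ("gaussian", "sparse_ternary"):
            raise ValueError(f"unknown vector kind {self.vector_kind!r}")
        if self.use_order and self.max_ngram < 2:
            raise ValueError("order encoding needs max_ngram >= 2")
        if self.freq_threshold_n < 0:
            raise ValueError("freq_threshold_n must be nonnegative")
        if self.operator.startswith("random_connection") and not self.direction_only:
            raise ValueError("random-connection operators are direction-only")
        object.__setattr__(self, "stoplist", frozenset(self.stoplist))

    def signal_spec(self):
        if self.vector_kind == "gaussian":
            return GaussianSpec(self.D)
        half = self.n_nonzero // 2
        return SparseTernarySpec(self.D, half, self.n_nonzero - half)


def beagle_config(D: int = 1024, **overrides) -> EncoderConfig:
    """Holographic (convolution) encoder defaults: Gaussian signals,
    λ = 5 n-grams, sentence-wide context with a function-word stop list."""
    base = EncoderConfig(
        D=D,
        operator="convolution",
        max_ngram=5,
        context_window="sentence",
        use_order=True,
        use_context=True,
        stoplist=default_stoplist(),
        vector_kind="gaussian",
    )
    return replace(base, **overrides)


def rpm_config(D: int = 2048, **overrides) -> EncoderConfig:
    """Permutation-model defaults: sparse ternary signals (two +1s, two
    −1s), direction-only order with a ±2 window, and the 87 most frequent
    words omitted as cues.  The full-scale model runs at D ≈ 25,000; the
    default here is desk-scale."""
    base = EncoderConfig(
        D=D,
        operator="random_permutation",
        context_window=2,
        use_order=True,
        use_context=True,
        direction_only=True,
        freq_threshold_n=87,
        vector_kind="sparse_ternary",
        n_nonzero=4,
    )
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# Lexicon
# ---------------------------------------------------------------------------


class Lexicon:
    """Per-word signal and memory vectors plus corpus frequency counts."""

    def __init__(
        self,
        words: Sequence[str],
        signal: np.ndarray,
        freq: Mapping[str, int],
        placeholder: np.ndarray,
        perm: PermutationMap,
        rc: RandomConnectionMap,
        excluded_cues: frozenset[str] = frozenset(),
    ):
        self.words = list(words)
        self.vocab = {w: i for i, w in enumerate(self.words)}
        if len(self.vocab) != len(self.words):
            raise ValueError("duplicate words in lexicon")
        self.signal = np.asarray(signal, dtype=float)
        self.memory = np.zeros_like(self.signal)
        self.freq = dict(freq)
        self.placeholder = np.asarray(placeholder, dtype=float)
        self.perm = perm
        self.rc = rc
        self.excluded_cues = frozenset(excluded_cues)
        # permutation powers of every word's signal vector are built lazily
        self._signal_fft: np.ndarray | None = None

    @property
    def D(self) -> int:
        return int(self.signal.shape[1])

    def __contains__(self, word: str) -> bool:
        return word in self.vocab

    def __len__(self) -> int:
        return len(self.words)

    def signal_vector(self, word: str) -> np.ndarray:
        return self.signal[self.vocab[word]]

    def memory_vector(self, word: str) -> np.ndarray | None:
        idx = self.vocab.get(word)
        return None if idx is None else self.memory[idx]

    def signal_fft(self) -> np.ndarray:
        """Cached rFFT of the signal matrix (used by the convolution path)."""
        if self._signal_fft is None:
            self._signal_fft = np.fft.rfft(self.signal, axis=1)
        return self._signal_fft

    def save(self, path) -> None:
        """Export memory vectors in the labeled-vector text format."""
        save_labeled_vectors(path, self.words, self.memory)


def build_frequency_stats(
    corpus: Iterable[Document],
) -> tuple[dict[str, int], list[str]]:
    """Exact token counts and the frequency-ranked word list.

    Rank ties break lexicographically so that "the n most frequent words"
    is a deterministic set.
    """
    counts: Counter[str] = Counter()
    for doc in corpus:
        for sentence in doc.sentences:
            counts.update(sentence)
    if not counts:
        raise ValueError("empty corpus")
    ranked = sorted(counts, key=lambda w: (-counts[w], w))
    return dict(counts), ranked


def init_lexicon(vocab_counts: Mapping[str, int], config: EncoderConfig) -> Lexicon:
    """Draw signal vectors, Φ, the base permutation and the random
    connections; zero all memory vectors.  Deterministic given
    ``config.master_seed``."""
    if not vocab_counts:
        raise ValueError("empty vocabulary")
    words = sorted(vocab_counts)
    spec = config.signal_spec()
    rng = np.random.default_rng([config.master_seed, 0xC0FFEE])
    signal = make_signal_matrix(spec, len(words), rng)
    placeholder = make_signal_vector(spec, rng)
    perm = make_permutation(config.D, config.perm_style, rng)
    rc = make_random_connections(config.D, rng)
    if config.freq_threshold_n:
        _, ranked = (
            dict(vocab_counts),
            sorted(vocab_counts, key=lambda w: (-vocab_counts[w], w)),
        )
        excluded = frozenset(ranked[: config.freq_threshold_n])
    else:
        excluded = frozenset()
    return Lexicon(words, signal, vocab_counts, placeholder, perm, rc, excluded)


# ---------------------------------------------------------------------------
# Update rules
# ---------------------------------------------------------------------------


def update_order_convolution(
    lexicon: Lexicon,
    sentence: Sequence[str],
    target_position: int,
    config: EncoderConfig,
) -> None:
    """Add every n-gram binding (length 2..λ) containing the target.

    Each qualifying contiguous n-gram is convolved left-to-right from the
    signal vectors of its words, with Φ substituted at the target's slot,
    and the result is added to the target's memory vector.  n-grams never
    cross sentence boundaries.  Computed in the frequency domain with
    cumulative prefix/suffix products, one inverse FFT per call.
    """
    L = len(sentence)
    if not 0 <= target_position < L:
        raise IndexError(f"target position {target_position} outside sentence")
    if L < 2:
        return
    lam = config.max_ngram
    t = target_position
    F = lexicon.signal_fft()
    ids = [lexicon.vocab[w] for w in sentence]
    phi_f = np.fft.rfft(lexicon.placeholder)

    # left[a] = product of the a signals immediately before the target
    max_left = min(lam - 1, t)
    max_right = min(lam - 1, L - 1 - t)
    left = [np.ones_like(phi_f)]
    for a in range(1, max_left + 1):
        left.append(left[a - 1] * F[ids[t - a]])
    right = [np.ones_like(phi_f)]
    for b in range(1, max_right + 1):
        right.append(right[b - 1] * F[ids[t + b]])

    acc = np.zeros_like(phi_f)
    for a in range(max_left + 1):
        for b in range(max_right + 1):
            if 1 <= a + b <= lam - 1:
                acc += left[a] * right[b]
    lexicon.memory[ids[t]] += np.fft.irfft(phi_f * acc, n=lexicon.D)


def update_order_rp(
    lexicon: Lexicon,
    sentence: Sequence[str],
    target_position: int,
    config: EncoderConfig,
) -> None:
    """Add Π^j e_u for every neighbour u at signed offset j, 1 ≤ |j| ≤ λ−1.

    Words after the target get positive permutation powers, words before it
    negative powers, so decoding by the matching inverse power is well
    defined on both sides.
    """
    L = len(sentence)
    if not 0 <= target_position < L:
        raise IndexError(f"target position {target_position} outside sentence")
    lam = config.max_ngram
    t = target_position
    perm = lexicon.perm
    # Horner-style accumulation: one permutation application per offset
    cur_f = np.zeros(lexicon.D)
    cur_b = np.zeros(lexicon.D)
    for j in range(lam - 1, 0, -1):
        if t + j < L:
            cur_f = cur_f + lexicon.signal[lexicon.vocab[sentence[t + j]]]
        cur_f = perm.apply(cur_f)
        if t - j >= 0:
            cur_b = cur_b + lexicon.signal[lexicon.vocab[sentence[t - j]]]
        cur_b = perm.apply_inverse(cur_b)
    total = cur_f + cur_b
    lexicon.memory[lexicon.vocab[sentence[t]]] += total


def update_context(
    lexicon: Lexicon,
    unit: Sequence[str],
    target_position: int,
    config: EncoderConfig,
) -> None:
    """Add the sum of signal vectors of the other words in the context unit.

    Stop-list words and the ``freq_threshold_n`` most frequent words are
    skipped as cues; the target itself is never added to its own sum.
    """
    L = len(unit)
    if not 0 <= target_position < L:
        raise IndexError(f"target position {target_position} outside unit")
    acc = np.zeros(lexicon.D)
    for i, w in enumerate(unit):
        if i == target_position:
            continue
        if w in config.stoplist or w in lexicon.excluded_cues:
            continue
        acc += lexicon.signal[lexicon.vocab[w]]
    lexicon.memory[lexicon.vocab[unit[target_position]]] += acc


def encode_rpm_sentence(
    lexicon: Lexicon, sentence: Sequence[str], config: EncoderConfig
) -> None:
    """Direction-only encoding of one sentence, window ±2.

    For each target, the up-to-two cue words on each side are summed and
    transformed once per side: Π⁻¹ (before) and Π (after) for the
    permutation operator; T (before) with no after-transform for the first
    random-connection variant; T (before) and T² (after) for the second.
    Frequency-thresholded words are skipped as cues (their own memory
    vectors are still trained).  Context, when enabled, adds the untransformed
    cue sum over the same window.
    """
    window = 2 if config.context_window == "sentence" else int(config.context_window)
    L = len(sentence)
    perm, rc = lexicon.perm, lexicon.rc
    for t in range(L):
        tid = lexicon.vocab[sentence[t]]
        before = np.zeros(lexicon.D)
        after = np.zeros(lexicon.D)
        n_cues = 0
        for i in range(max(0, t - window), t):
            w = sentence[i]
            if w in lexicon.excluded_cues or w in config.stoplist:
                continue
            before += lexicon.signal[lexicon.vocab[w]]
            n_cues += 1
        for i in range(t + 1, min(L, t + window + 1)):
            w = sentence[i]
            if w in lexicon.excluded_cues or w in config.stoplist:
                continue
            after += lexicon.signal[lexicon.vocab[w]]
            n_cues += 1
        if n_cues == 0:
            continue
        if config.use_order:
            if config.operator == "random_permutation":
                lexicon.memory[tid] += perm.apply_inverse(before) + perm.apply(after)
            elif config.operator == "random_connection_sim1":
                lexicon.memory[tid] += rc_transform(before, rc, 1) + after
            elif config.operator == "random_connection_sim2":
                lexicon.memory[tid] += rc_transform(before, rc, 1) + rc_transform(
                    after, rc, 2
                )
            else:
                raise ValueError(
                    "direction-only encoding needs a permutation or "
                    "random-connection operator"
                )
        if config.use_context:
            lexicon.memory[tid] += before + after


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _as_documents(corpus) -> list[Document]:
    if isinstance(corpus, (str, Path)):
        return list(read_plaintext_corpus(corpus))
    docs = []
    for item in corpus:
        if isinstance(item, Document):
            docs.append(item)
        elif isinstance(item, str):
            sentences = [tokenize(s) for s in split_sentences(item)]
            docs.append(Document([s for s in sentences if s]))
        else:  # already a list of token lists
            docs.append(Document([list(s) for s in item]))
    return docs


def train_semantic_model(corpus, config: EncoderConfig) -> Lexicon:
    """Single-pass training of memory vectors over a corpus.

    ``corpus`` may be a path to a one-document-per-line text file, an
    iterable of raw document strings, or of :class:`Document` /
    token-list-of-lists items.  Deterministic given ``config.master_seed``.
    """
    docs = _as_documents(corpus)
    counts, _ = build_frequency_stats(docs)
    lexicon = init_lexicon(counts, config)
    for doc in docs:
        for sentence in doc.sentences:
            if config.direction_only:
                encode_rpm_sentence(lexicon, sentence, config)
                continue
            for t in range(len(sentence)):
                if config.use_order and len(sentence) >= 2:
                    if config.operator == "convolution":
                        update_order_convolution(lexicon, sentence, t, config)
                    elif config.operator == "random_permutation":
                        update_order_rp(lexicon, sentence, t, config)
                    else:
                        raise ValueError(
                            f"operator {config.operator!r} requires "
                            "direction_only=True"
                        )
                if config.use_context:
                    if config.context_window == "sentence":
                        update_context(lexicon, sentence, t, config)
                    else:
                        w = int(config.context_window)
                        lo = max(0, t - w)
                        update_context(
                            lexicon, sentence[lo : t + w + 1], t - lo, config
                        )
    return lexicon


# ---------------------------------------------------------------------------
# scikit-learn estimator facade
# ---------------------------------------------------------------------------


class SemanticSpace(BaseEstimator):
    """Corpus-trained distributional semantic space (sklearn idiom).

    Parameters mirror :class:`EncoderConfig`.  ``fit`` trains memory
    vectors from documents; ``transform`` maps words to their memory
    vectors, so the estimator drops into sklearn pipelines that expect a
    word-to-vector featurizer.

    Examples
    --------
    >>> model = SemanticSpace(D=256, operator="random_permutation",
    ...                       master_seed=7)
    >>> model.fit(["the cat sat. the dog sat."])
    SemanticSpace(D=256, master_seed=7)
    >>> model.transform(["cat", "dog"]).shape
    (2, 256)
    """

    def __init__(
        self,
        D: int = 2048,
        operator: str = "random_permutation",
        max_ngram: int = 5,
        context_window: str | int = "sentence",
        use_order: bool = True,
        use_context: bool = False,
        direction_only: bool = False,
        freq_threshold_n: int = 0,
        stoplist: frozenset[str] = frozenset(),
        vector_kind: str = "gaussian",
        n_nonzero: int = 4,
        perm_style: str = "random",
        master_seed: int = 0,
    ):
        self.D = D
        self.operator = operator
        self.max_ngram = max_ngram
        self.context_window = context_window
        self.use_order = use_order
        self.use_context = use_context
        self.direction_only = direction_only
        self.freq_threshold_n = freq_threshold_n
        self.stoplist = stoplist
        self.vector_kind = vector_kind
        self.n_nonzero = n_nonzero
        self.perm_style = perm_style
        self.master_seed = master_seed

    def _config(self) -> EncoderConfig:
        return EncoderConfig(
            D=self.D,
            operator=self.operator,
            max_ngram=self.max_ngram,
            context_window=self.context_window,
            use_order=self.use_order,
            use_context=self.use_context,
            direction_only=self.direction_only,
            freq_threshold_n=self.freq_threshold_n,
            stoplist=frozenset(self.stoplist),
            vector_kind=self.vector_kind,
            n_nonzero=self.n_nonzero,
            perm_style=self.perm_style,
            master_seed=self.master_seed,
        )

    def fit(self, X, y=None) -> "SemanticSpace":
        """Train on documents (an iterable of strings/Documents, or a path)."""
        self.lexicon_ = train_semantic_model(X, self._config())
        self.vocabulary_ = dict(self.lexicon_.vocab)
        self.n_features_out_ = self.lexicon_.D
        return self

    def transform(self, words: Sequence[str]) -> np.ndarray:
        """Map words to their (n_words, D) memory-vector matrix."""
        if not hasattr(self, "lexicon_"):
            raise RuntimeError("SemanticSpace is not fitted yet; call fit first")
        out = np.zeros((len(words), self.lexicon_.D))
        for i, w in enumerate(words):
            vec = self.lexicon_.memory_vector(w)
            if vec is None:
                raise KeyError(f"word {w!r} not in the trained vocabulary")
            out[i] = vec
        return out

    def fit_transform(self, X, y=None, words: Sequence[str] | None = None):
        self.fit(X)
        if words is None:
            words = self.lexicon_.words
        return self.transform(words)

    def similarity(self, a: str, b: str) -> float:
        """Cosine between two words' memory vectors."""
        from .vectors import cosine

        va = self.lexicon_.memory_vector(a)
        vb = self.lexicon_.memory_vector(b)
        if va is None or vb is None:
            raise KeyError(f"word {a if va is None else b!r} not in vocabulary")
        return cosine(va, vb)


# ---------------------------------------------------------------------------
# Stop list
# ---------------------------------------------------------------------------


def load_stoplist(path) -> frozenset[str]:
    """One word per line, UTF-8; blank lines ignored."""
    words = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            w = line.strip().lower()
            if w:
                words.add(w)
    return frozenset(words)


def default_stoplist() -> frozenset[str]:
    """The bundled 280-entry English function-word stop list."""
    from importlib.resources import files

    return load_stoplist(files("holoperm.data") / "stoplist_280.txt")
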