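"""Core vector-symbolic primitives.

Signal (environmental) vectors, the two binding operators — circular
convolution with its approximate inverse (correlation), and random
permutation with exact inverses — plus the relaxed random-connection
transform, cosine similarity, and clean-up memory retrieval.

All vectors are plain 1-D ``numpy.ndarray`` of float64.  Randomness always
flows through explicit seeds (an ``int`` or a ``numpy.random.Generator``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GaussianSpec",
    "SparseTernarySpec",
    "make_signal_vector",
    "circular_convolve",
    "involution",
    "correlate",
    "PermutationMap",
    "make_permutation",
    "permute_power",
    "RandomConnectionMap",
    "make_random_connections",
    "rc_transform",
    "cosine",
    "CleanupMemory",
    "cleanup_retrieve",
    "save_labeled_vectors",
    "load_labeled_vectors",
]


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Signal-vector specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianSpec:
    """Dense Gaussian signal vectors: i.i.d. N(0, 1/D) entries.

    With sd = 1/sqrt(D) the expected squared norm of a draw is 1, so
    superpositions of a few signal vectors stay O(1) regardless of D.
    """

    D: int
    sigma: float | None = None  # default 1/sqrt(D)

    def __post_init__(self) -> None:
        if self.D < 2:
            raise ValueError(f"dimensionality must be >= 2, got {self.D}")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def effective_sigma(self) -> float:
        return self.sigma if self.sigma is not None else 1.0 / np.sqrt(self.D)


@dataclass(frozen=True)
class SparseTernarySpec:
    """Sparse ternary ("spatter code") signal vectors.

    Mostly zeros with ``n_plus`` entries of +1 and ``n_minus`` entries of -1
    at uniformly random distinct positions.  Defaults follow the common
    random-indexing choice of two of each.
    """

    D: int
    n_plus: int = 2
    n_minus: int = 2

    def __post_init__(self) -> None:
        if self.D < 2:
            raise ValueError(f"dimensionality must be >= 2, got {self.D}")
        if self.n_plus < 0 or self.n_minus < 0:
            raise ValueError("nonzero counts must be nonnegative")
        if self.n_plus + self.n_minus > self.D:
            raise ValueError(
                f"impossible sparse spec: {self.n_plus}+{self.n_minus} nonzeros "
                f"exceed D={self.D}"
            )


def make_signal_vector(
    spec: GaussianSpec | SparseTernarySpec, rng_seed: int | np.random.Generator
) -> np.ndarray:
    """Draw one signal vector according to ``spec``; deterministic per seed."""
    rng = _as_rng(rng_seed)
    if isinstance(spec, GaussianSpec):
        return rng.normal(0.0, spec.effective_sigma, spec.D)
    if isinstance(spec, SparseTernarySpec):
        v = np.zeros(spec.D)
        pos = rng.choice(spec.D, size=spec.n_plus + spec.n_minus, replace=False)
        v[pos[: spec.n_plus]] = 1.0
        v[pos[spec.n_plus :]] = -1.0
        return v
    raise TypeError(f"unknown signal spec {type(spec).__name__}")


def make_signal_matrix(
    spec: GaussianSpec | SparseTernarySpec, n: int, rng_seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` independent signal vectors as rows of an (n, D) matrix."""
    rng = _as_rng(rng_seed)
    if isinstance(spec, GaussianSpec):
        return rng.normal(0.0, spec.effective_sigma, (n, spec.D))
    return np.stack([make_signal_vector(spec, rng) for _ in range(n)])


# ---------------------------------------------------------------------------
# Circular convolution and correlation
# ---------------------------------------------------------------------------


def _check_same_dim(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")


def circular_convolve(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bind two vectors by circular convolution.

    ``z[i] = sum_j x[j] * y[(i - j) mod D]`` — the modulo-D compression of
    the outer product.  Computed in the frequency domain (O(D log D)); equal
    to the direct sum up to floating error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_same_dim(x, y)
    D = x.shape[0]
    return np.fft.irfft(np.fft.rfft(x) * np.fft.rfft(y), n=D)


def circular_convolve_direct(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """O(D^2) textbook evaluation of the circular-convolution sum.

    Reference implementation used to validate the FFT route.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_same_dim(x, y)
    D = x.shape[0]
    z = np.zeros(D)
    for i in range(D):
        for j in range(D):
            z[i] += x[j] * y[(i - j) % D]
    return z


def involution(x: np.ndarray) -> np.ndarray:
    """Index involution ``x*[i] = x[(-i) mod D]`` (its own inverse)."""
    x = np.asarray(x, dtype=float)
    return np.roll(x[::-1], 1)


def correlate(probe: np.ndarray, trace: np.ndarray) -> np.ndarray:
    """Approximate inverse of convolution (Plate's correlation operator).

    Defined as ``involution(probe) ⊛ trace``.  For ``trace = probe ⊛ y`` the
    result is a noisy approximation of ``y`` whose fidelity grows with D.
    """
    probe = np.asarray(probe, dtype=float)
    trace = np.asarray(trace, dtype=float)
    _check_same_dim(probe, trace)
    D = probe.shape[0]
    # involution in the frequency domain is complex conjugation
    return np.fft.irfft(np.conj(np.fft.rfft(probe)) * np.fft.rfft(trace), n=D)


def deconvolve_exact(probe: np.ndarray, trace: np.ndarray) -> np.ndarray:
    """Exact unbinding by frequency-domain division.

    Solves ``probe ⊛ z = trace`` for ``z``.  Unlike :func:`correlate` this is
    an exact inverse when the trace is a single binding, but it amplifies
    superposition noise without bound wherever the probe has small Fourier
    components, so its retrieval accuracy from crowded traces is erratic.
    """
    probe = np.asarray(probe, dtype=float)
    trace = np.asarray(trace, dtype=float)
    _check_same_dim(probe, trace)
    D = probe.shape[0]
    return np.fft.irfft(np.fft.rfft(trace) / np.fft.rfft(probe), n=D)


# ---------------------------------------------------------------------------
# Permutations and random connections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermutationMap:
    """A bijective coordinate shuffle Π.

    ``target_index[i]`` is the destination of source coordinate ``i``:
    applying the map writes ``out[target_index[i]] = v[i]``.
    """

    target_index: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.target_index, dtype=np.intp)
        object.__setattr__(self, "target_index", t)
        if t.ndim != 1 or t.shape[0] < 2:
            raise ValueError("permutation needs at least 2 coordinates")
        if not np.array_equal(np.sort(t), np.arange(t.shape[0])):
            raise ValueError("target_index is not a bijection")
        # source_index inverts the map: out = v[source_index]
        src = np.empty_like(t)
        src[t] = np.arange(t.shape[0])
        object.__setattr__(self, "_source_index", src)

    @property
    def D(self) -> int:
        return int(self.target_index.shape[0])

    def apply(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if v.shape[-1] != self.D:
            raise ValueError(f"dimension mismatch: {v.shape[-1]} != {self.D}")
        return v[..., self._source_index]

    def apply_inverse(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if v.shape[-1] != self.D:
            raise ValueError(f"dimension mismatch: {v.shape[-1]} != {self.D}")
        return v[..., self.target_index]


def make_permutation(
    D: int, style: str = "random", rng_seed: int | np.random.Generator = 0
) -> PermutationMap:
    """Construct a permutation map.

    ``style='random'`` draws a uniform random bijection; ``style='rotation'``
    maps coordinate i to i+1 (mod D), the cheap special case often used in
    practice.
    """
    if D < 2:
        raise ValueError(f"dimensionality must be >= 2, got {D}")
    if style == "rotation":
        return PermutationMap((np.arange(D) + 1) % D)
    if style == "random":
        rng = _as_rng(rng_seed)
        return PermutationMap(rng.permutation(D))
    raise ValueError(f"unknown permutation style {style!r}")


def permute_power(v: np.ndarray, perm: PermutationMap, n: int) -> np.ndarray:
    """Apply Π^n to ``v`` (negative n uses the exact inverse; n=0 is identity)."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != perm.D:
        raise ValueError(f"dimension mismatch: {v.shape[-1]} != {perm.D}")
    out = v
    if n >= 0:
        for _ in range(n):
            out = perm.apply(out)
    else:
        for _ in range(-n):
            out = perm.apply_inverse(out)
    return out


@dataclass(frozen=True)
class RandomConnectionMap:
    """A permutation-like map without the uniqueness constraint.

    Every source coordinate has exactly one outgoing connection but
    destinations may collide; a destination's value becomes the sum of its
    incoming sources, and destinations with no incoming connection go to
    zero.  Equivalent to multiplication by a 0/1 matrix with one 1 per row.
    """

    target_index: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.target_index, dtype=np.intp)
        object.__setattr__(self, "target_index", t)
        if t.ndim != 1 or t.shape[0] < 2:
            raise ValueError("map needs at least 2 coordinates")
        if t.min() < 0 or t.max() >= t.shape[0]:
            raise ValueError("destinations out of range")

    @property
    def D(self) -> int:
        return int(self.target_index.shape[0])

    def as_matrix(self) -> np.ndarray:
        """Dense 0/1 connection matrix w with w[i, target_index[i]] = 1."""
        w = np.zeros((self.D, self.D))
        w[np.arange(self.D), self.target_index] = 1.0
        return w


def make_random_connections(
    D: int, rng_seed: int | np.random.Generator = 0
) -> RandomConnectionMap:
    """Draw each source's destination uniformly with replacement."""
    if D < 2:
        raise ValueError(f"dimensionality must be >= 2, got {D}")
    rng = _as_rng(rng_seed)
    return RandomConnectionMap(rng.integers(0, D, size=D))


def rc_transform(v: np.ndarray, rc: RandomConnectionMap, n: int = 1) -> np.ndarray:
    """Apply the random-connection transform T (or T^n for n applications)."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != rc.D:
        raise ValueError(f"dimension mismatch: {v.shape[-1]} != {rc.D}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    out = v
    for _ in range(n):
        out = np.bincount(rc.target_index, weights=out, minlength=rc.D).astype(float)
    return out


# ---------------------------------------------------------------------------
# Cosine and clean-up memory
# ---------------------------------------------------------------------------


def cosine(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity; a zero vector yields 0.0 with a warning.

    Degenerate (all-zero) vectors can arise from random-connection
    transforms, so batch experiments must not abort on them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_same_dim(x, y)
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        warnings.warn("cosine of a zero vector is defined as 0", RuntimeWarning)
        return 0.0
    return float(np.dot(x, y) / (nx * ny))


class CleanupMemory:
    """A labeled pool of known vectors matched against by maximal cosine.

    Stores the pool as an (m, D) matrix with precomputed row norms so that
    retrieval is a single matrix-vector product.
    """

    def __init__(self, labels: Sequence, vectors: np.ndarray | Sequence[np.ndarray]):
        self.vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
        self.labels = list(labels)
        if len(self.labels) != self.vectors.shape[0]:
            raise ValueError("labels and vectors differ in length")
        if len(self.labels) == 0:
            raise ValueError("clean-up memory must hold at least one vector")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in clean-up memory")
        self._norms = np.linalg.norm(self.vectors, axis=1)

    @property
    def m(self) -> int:
        return len(self.labels)

    @property
    def D(self) -> int:
        return int(self.vectors.shape[1])

    def cosines(self, query: np.ndarray) -> np.ndarray:
        query = np.asarray(query, dtype=float)
        if query.shape[0] != self.D:
            raise ValueError(f"dimension mismatch: {query.shape[0]} != {self.D}")
        qn = np.linalg.norm(query)
        if qn == 0.0:
            warnings.warn("cosine of a zero vector is defined as 0", RuntimeWarning)
            return np.zeros(self.m)
        with np.errstate(divide="ignore", invalid="ignore"):
            c = (self.vectors @ query) / (self._norms * qn)
        return np.where(self._norms == 0.0, 0.0, c)


def cleanup_retrieve(query: np.ndarray, memory: CleanupMemory):
    """Return ``(label, cosine)`` of the pool member most similar to ``query``.

    Ties break toward the lowest member index, making retrieval
    deterministic.
    """
    c = memory.cosines(query)
    best = int(np.argmax(c))
    return memory.labels[best], float(c[best])


# ---------------------------------------------------------------------------
# Labeled-vector text i/o
# ---------------------------------------------------------------------------


def save_labeled_vectors(path, labels: Sequence[str], vectors: np.ndarray) -> None:
    """Write ``label v1 v2 ... vD`` lines, space-separated UTF-8 text."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if len(labels) != vectors.shape[0]:
        raise ValueError("labels and vectors differ in length")
    with open(path, "w", encoding="utf-8") as fh:
        for label, row in zip(labels, vectors):
            fh.write(str(label) + " " + " ".join(repr(float(x)) for x in row) + "\n")


def load_labeled_vectors(path):
    """Read the labeled-vector text format; returns (labels, (m, D) array)."""
    labels: list[str] = []
    rows: list[np.ndarray] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            labels.append(parts[0])
            rows.append(np.array([float(x) for x in parts[1:]]))
    if not rows:
        raise ValueError(f"no vectors found in {path}")
    return labels, np.stack(rows)
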