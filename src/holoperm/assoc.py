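"""Paired-associate memory traces and the capacity experiment.

Two ways of storing k cue/associate pairs in a single superposed trace:

* convolution: ``M = Σ_i x_i ⊛ y_i`` — decode with the correlation operator.
* random permutation: ``M = Π y_1 + Π² x_1 + Π³ y_2 + Π⁴ x_2 + ...`` — the
  permutation power indexes the position at which an item entered the
  trace, so decoding is a sequential search over inverse powers.

``run_capacity_grid`` sweeps dimensionality × pair count and counts correct
retrievals against a fixed clean-up pool, the protocol used to compare the
storage capacity of the two operators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .vectors import (
    CleanupMemory,
    GaussianSpec,
    PermutationMap,
    SparseTernarySpec,
    cleanup_retrieve,
    correlate,
    cosine,
    deconvolve_exact,
    make_permutation,
    make_signal_matrix,
    permute_power,
)

__all__ = [
    "PairedAssociateTrace",
    "build_conv_trace",
    "retrieve_conv_associate",
    "build_rp_trace",
    "rp_decode",
    "retrieve_rp_associate",
    "CapacityConfig",
    "CapacityResult",
    "run_capacity_grid",
]

DEFAULT_MAX_PAIRS = 14


@dataclass
class PairedAssociateTrace:
    """A superposed memory vector holding k cue/associate pairs."""

    memory: np.ndarray
    scheme: str  # "convolution" | "random_permutation"
    k: int
    perm: PermutationMap | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("a trace stores at least one pair")
        if self.scheme == "random_permutation":
            if self.perm is None:
                raise ValueError("random_permutation trace needs its permutation")
            if self.perm.D != self.memory.shape[0]:
                raise ValueError("permutation dimension mismatch")
        elif self.scheme != "convolution":
            raise ValueError(f"unknown scheme {self.scheme!r}")


def build_conv_trace(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
) -> PairedAssociateTrace:
    """Superpose the circular convolutions of each (x, y) pair."""
    if len(pairs) == 0:
        raise ValueError("cannot build a trace from zero pairs")
    D = len(pairs[0][0])
    acc = np.zeros(D // 2 + 1, dtype=complex)
    for x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape[0] != D or y.shape[0] != D:
            raise ValueError("all pair vectors must share one dimensionality")
        acc += np.fft.rfft(x) * np.fft.rfft(y)
    return PairedAssociateTrace(np.fft.irfft(acc, n=D), "convolution", len(pairs))


def retrieve_conv_associate(
    trace: PairedAssociateTrace,
    probe_y: np.ndarray,
    memory: CleanupMemory,
    decode: str = "correlation",
):
    """Decode the probe's associate, then clean up.

    ``decode='correlation'`` uses the standard approximate inverse;
    ``decode='exact_inverse'`` divides in the frequency domain instead,
    which is noisier from superposed traces (see
    :func:`holoperm.vectors.deconvolve_exact`).  Returns the label of the
    clean-up member most similar to the decoded approximation.
    """
    if trace.scheme != "convolution":
        raise ValueError("trace was not built with convolution")
    if decode == "correlation":
        approx = correlate(probe_y, trace.memory)
    elif decode == "exact_inverse":
        approx = deconvolve_exact(probe_y, trace.memory)
    else:
        raise ValueError(f"unknown decode mode {decode!r}")
    label, _ = cleanup_retrieve(approx, memory)
    return label


def build_rp_trace(
    pairs: Sequence[tuple[np.ndarray, np.ndarray]], perm: PermutationMap
) -> PairedAssociateTrace:
    """Store pairs at successive permutation powers.

    y_i sits at power 2i-1 and its associate x_i at power 2i.  Built by a
    Horner-style recursion (k applications of Π instead of O(k²)).
    """
    if len(pairs) == 0:
        raise ValueError("cannot build a trace from zero pairs")
    # items in power order 1, 2, 3, ...: y1, x1, y2, x2, ...
    items: list[np.ndarray] = []
    for x, y in pairs:
        items.append(np.asarray(y, dtype=float))
        items.append(np.asarray(x, dtype=float))
    acc = np.zeros(perm.D)
    for v in reversed(items):
        if v.shape[0] != perm.D:
            raise ValueError("all pair vectors must share the permutation's D")
        acc = perm.apply(v + acc)
    return PairedAssociateTrace(acc, "random_permutation", len(pairs), perm)


def rp_decode(
    trace: PairedAssociateTrace,
    probe_y: np.ndarray,
    max_pairs: int = DEFAULT_MAX_PAIRS,
):
    """Locate the probe in an RP trace by sequential inverse permutation.

    Computes cosine(Π^{-n} M, probe) for n = 1 .. 2*max_pairs, takes the
    power n* with the highest similarity (ties toward the smallest n), and
    returns ``(n_star, approx)`` where ``approx = Π^{-(n*+1)} M`` is the
    noisy associate estimate.  For a probe stored as y_i the correct power
    is n* = 2i - 1, so one further inverse permutation lands on x_i.
    """
    if trace.scheme != "random_permutation":
        raise ValueError("trace was not built with random permutations")
    probe_y = np.asarray(probe_y, dtype=float)
    perm = trace.perm
    assert perm is not None
    n_max = 2 * max_pairs
    current = trace.memory
    history = []
    sims = np.empty(n_max)
    for n in range(1, n_max + 1):
        current = perm.apply_inverse(current)
        history.append(current)
        sims[n - 1] = cosine(probe_y, current)
    n_star = int(np.argmax(sims)) + 1  # argmax ties break to smallest n
    approx = perm.apply_inverse(history[n_star - 1])
    return n_star, approx


def retrieve_rp_associate(
    trace: PairedAssociateTrace,
    probe_y: np.ndarray,
    memory: CleanupMemory,
    max_pairs: int = DEFAULT_MAX_PAIRS,
):
    """Decode the probe's associate from an RP trace, then clean up."""
    _, approx = rp_decode(trace, probe_y, max_pairs)
    label, _ = cleanup_retrieve(approx, memory)
    return label


# ---------------------------------------------------------------------------
# Capacity experiment
# ---------------------------------------------------------------------------


@dataclass
class CapacityConfig:
    """Grid specification for the paired-associate capacity experiment.

    Defaults follow the standard protocol: a clean-up pool of m = 1,000
    candidate vectors, 500 trials per (D, k) cell, dimensionalities 256 to
    2,048, and 2 to 14 stored pairs (the classical cap on pairs per trace).
    """

    scheme: str = "random_permutation"
    D_grid: tuple[int, ...] = (256, 512, 1024, 2048)
    k_grid: tuple[int, ...] = (2, 4, 6, 8, 10, 12, 14)
    m: int = 1000
    n_trials: int = 500
    vector_kind: str = "gaussian"  # "gaussian" | "sparse_ternary"
    n_nonzero: int = 4  # sparse ternary: total nonzeros, split +1/-1
    perm_style: str = "random"
    master_seed: int = 0
    max_pairs: int = DEFAULT_MAX_PAIRS

    def __post_init__(self) -> None:
        if self.scheme not in ("convolution", "random_permutation"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.vector_kind not in ("gaussian", "sparse_ternary"):
            raise ValueError(f"unknown vector kind {self.vector_kind!r}")
        if not self.D_grid or not self.k_grid:
            raise ValueError("empty grid")
        if self.n_trials < 1 or self.m < 2:
            raise ValueError("need n_trials >= 1 and m >= 2")
        if self.max_pairs < max(self.k_grid):
            raise ValueError("max_pairs must cover the largest k in the grid")
        if self.m < 2 * max(self.k_grid):
            raise ValueError("pool too small to draw distinct pair members")


@dataclass
class CapacityResult:
    """Per-cell retrieval counts plus the cross-cell summary."""

    cells: pd.DataFrame  # columns: scheme, D, k, n_trials, n_correct, accuracy
    summary: dict = field(default_factory=dict)  # {scheme: {"mean":…, "sd":…}}

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def _signal_spec(config: CapacityConfig, D: int):
    if config.vector_kind == "gaussian":
        return GaussianSpec(D)
    half = config.n_nonzero // 2
    return SparseTernarySpec(D, n_plus=half, n_minus=config.n_nonzero - half)


def _run_cell(config: CapacityConfig, D: int, k: int, rng: np.random.Generator) -> int:
    """One (D, k) cell: count correct retrievals over n_trials trials."""
    pool = make_signal_matrix(_signal_spec(config, D), config.m, rng)
    memory = CleanupMemory(list(range(config.m)), pool)
    perm = None
    if config.scheme == "random_permutation":
        perm = make_permutation(D, config.perm_style, rng)
    n_correct = 0
    for _ in range(config.n_trials):
        # x's and y's drawn from the same pool, distinct within a trial
        idx = rng.choice(config.m, size=2 * k, replace=False)
        x_idx, y_idx = idx[:k], idx[k:]
        pairs = [(pool[i], pool[j]) for i, j in zip(x_idx, y_idx)]
        probe = int(rng.integers(k))
        if config.scheme == "convolution":
            trace = build_conv_trace(pairs)
            label = retrieve_conv_associate(trace, pool[y_idx[probe]], memory)
        else:
            trace = build_rp_trace(pairs, perm)
            label = retrieve_rp_associate(
                trace, pool[y_idx[probe]], memory, config.max_pairs
            )
        if label == int(x_idx[probe]):
            n_correct += 1
    return n_correct


def run_capacity_grid(config: CapacityConfig) -> CapacityResult:
    """Run the full D × k grid; bit-reproducible given ``master_seed``.

    Each cell gets an independent random stream derived from the master
    seed and the cell coordinates, so results do not depend on iteration
    order.
    """
    records = []
    scheme_code = 0 if config.scheme == "convolution" else 1
    kind_code = 0 if config.vector_kind == "gaussian" else 1
    for D in config.D_grid:
        for k in config.k_grid:
            rng = np.random.default_rng(
                [config.master_seed, scheme_code, kind_code, D, k]
            )
            n_correct = _run_cell(config, D, k, rng)
            records.append(
                {
                    "scheme": config.scheme,
                    "vector_kind": config.vector_kind,
                    "D": D,
                    "k": k,
                    "n_trials": config.n_trials,
                    "n_correct": n_correct,
                    "accuracy": n_correct / config.n_trials,
                }
            )
    cells = pd.DataFrame.from_records(records)
    summary = {
        config.scheme: {
            "mean": float(cells["n_correct"].mean()),
            "sd": float(cells["n_correct"].std(ddof=1)),
        }
    }
    return CapacityResult(cells, summary)
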