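"""Permutation entropy of EEG signals.

Permutation entropy (PE) summarises a time series by the Shannon entropy of
its ordinal (rank-order) pattern distribution: each delay vector
``(x[t], x[t+tau], ..., x[t+(m-1)tau])`` is mapped to the permutation that
sorts it ascending, and PE is the entropy of the resulting pattern
frequencies, normalised by log(m!) to [0, 1]. Smooth, oscillation-dominated
signals visit few patterns (low PE); broadband irregular activity visits
nearly all of them (PE near 1). Ties are broken by occurrence order (stable
sort), which makes a constant signal map to the identity pattern and PE 0.

Defaults m=3, tau=1 follow common anesthesia-EEG practice; both are
configurable everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .errors import EmptyDataError, InvalidParameterError
from .recording import EpochSet

DEFAULT_M = 3
DEFAULT_TAU = 1


@dataclass
class OrdinalDistribution:
    """Ordinal-pattern counts for one signal at embedding (m, tau).

    ``counts[k]`` is the frequency of ``patterns[k]``, the k-th permutation
    of range(m) in lexicographic order.
    """

    m: int
    tau: int
    counts: np.ndarray

    @property
    def n_windows(self) -> int:
        return int(self.counts.sum())

    @property
    def patterns(self) -> list[tuple[int, ...]]:
        return list(permutations(range(self.m)))


def _pattern_index_table(m: int) -> dict[tuple[int, ...], int]:
    return {p: i for i, p in enumerate(permutations(range(m)))}


def ordinal_patterns(x: np.ndarray, m: int = DEFAULT_M,
                     tau: int = DEFAULT_TAU) -> OrdinalDistribution:
    """Count ordinal patterns of all delay vectors of ``x``.

    A delay vector is mapped to ``argsort`` with a stable sort, so equal
    values rank in order of occurrence.
    """
    x = np.asarray(x, dtype=float).ravel()
    if not 2 <= m <= 6:
        raise InvalidParameterError(f"embedding dimension m must be in [2, 6], got {m}")
    if tau < 1:
        raise InvalidParameterError(f"delay tau must be >= 1, got {tau}")
    span = (m - 1) * tau
    if x.size < span + 1:
        raise EmptyDataError(
            f"signal of length {x.size} too short for m={m}, tau={tau}"
        )
    n_vec = x.size - span
    # embedding matrix (n_vec, m) via stride tricks, then stable argsort rows
    idx = np.arange(n_vec)[:, None] + np.arange(m)[None, :] * tau
    perms = np.argsort(x[idx], axis=1, kind="stable")
    # encode each permutation row as a base-m integer, then look up its
    # lexicographic index
    powers = m ** np.arange(m - 1, -1, -1)
    codes = perms @ powers
    lex = np.array(list(permutations(range(m))), dtype=np.int64)
    lut = np.full(int(m ** m), -1, dtype=np.int64)
    lut[lex @ powers] = np.arange(lex.shape[0])
    counts = np.bincount(lut[codes], minlength=math.factorial(m))
    return OrdinalDistribution(m=m, tau=tau, counts=counts)


def permutation_entropy(dist: OrdinalDistribution, normalize: bool = True) -> float:
    """Shannon entropy of the ordinal-pattern frequencies.

    With ``normalize`` the value is divided by log(m!) and lies in [0, 1].
    """
    total = dist.counts.sum()
    if total == 0:
        raise EmptyDataError("ordinal distribution holds no windows")
    p = dist.counts[dist.counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    if normalize:
        h /= math.log(math.factorial(dist.m))
    return h


def pe_of_signal(x: np.ndarray, m: int = DEFAULT_M, tau: int = DEFAULT_TAU,
                 normalize: bool = True) -> float:
    """Convenience: ordinal_patterns + permutation_entropy in one call."""
    return permutation_entropy(ordinal_patterns(x, m, tau), normalize)


@dataclass
class PETimecourse:
    """Per-window, per-channel normalised PE with a channel-mean track."""

    times: np.ndarray          # window centers, seconds
    values: np.ndarray         # (n_windows, n_channels)
    global_values: np.ndarray  # (n_windows,) channel mean
    phase: str | None = None

    @property
    def mean(self) -> float:
        """Grand mean over windows and channels (one number per recording)."""
        return float(self.values.mean())


def pe_timecourse(epochs: EpochSet, m: int = DEFAULT_M, tau: int = DEFAULT_TAU,
                  phase: str | None = None) -> PETimecourse:
    """Normalised PE per kept epoch per channel.

    The epoch grid is the same 2-s/50% grid used by the connectivity stage,
    so PE and wPLI timecourses stay time-aligned.
    """
    epochs.require_nonempty()
    n_ep, n_ch, _ = epochs.epochs.shape
    values = np.empty((n_ep, n_ch))
    for e in range(n_ep):
        for c in range(n_ch):
            values[e, c] = pe_of_signal(epochs.epochs[e, c], m, tau)
    times = epochs.starts + epochs.window / 2
    return PETimecourse(times=times, values=values,
                        global_values=values.mean(axis=1), phase=phase)


def compare_pe(group_a: np.ndarray, group_b: np.ndarray, phase: str | None = None):
    """Normality-routed two-sample comparison of per-subject PE values.

    Routed through the inference layer (Shapiro-Wilk gate at p >= 0.05 in
    both groups -> Student t; otherwise Mann-Whitney U). Returns a
    :class:`~doceeg.inference.StatResult`; FDR adjustment across the phase
    family is applied by the caller via ``benjamini_hochberg``.
    """
    from . import inference

    group_a = np.asarray(group_a, dtype=float)
    group_b = np.asarray(group_b, dtype=float)
    if group_a.size < 2 or group_b.size < 2:
        raise InvalidParameterError("need at least 2 subjects per group")
    result = inference.routed_two_sample(group_a, group_b)
    result.label = f"PE {phase}" if phase else "PE"
    return result
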