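"""The four-level severity domain and probability vectors over it.

Every latent quantity in the network — the immediate value of a clinical
factor (IF), its cumulated value (CF) and its contextual severity (CS) —
lives on the same ordered four-level domain::

    absent < low < medium < high

``LevelDistribution`` is the probability vector over that domain, stored in
ascending severity order.
"""

from __future__ import annotations

import enum
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateElicitationError

__all__ = [
    "SeverityLevel",
    "LEVEL_NAMES",
    "N_LEVELS",
    "LevelDistribution",
    "counts_to_distribution",
    "roulette_to_distribution",
]

#: tolerance on probability-vector normalization
SUM_TOL = 1e-9


class SeverityLevel(enum.IntEnum):
    """Ordinal severity code; comparison follows clinical ordering."""

    ABSENT = 0
    LOW = 1
    MEDIUM = 2
    HIGH = 3

    @classmethod
    def from_name(cls, name: str) -> "SeverityLevel":
        return cls[name.upper()]

    @property
    def label(self) -> str:
        return self.name.lower()


LEVEL_NAMES = tuple(lvl.label for lvl in SeverityLevel)  # ("absent", "low", "medium", "high")
N_LEVELS = len(LEVEL_NAMES)


class LevelDistribution:
    """A probability vector over the four ordered severity levels.

    Immutable; entries are indexed by :class:`SeverityLevel` (or plain int),
    in ascending order absent..high, and must sum to 1 within ``1e-9``.
    """

    __slots__ = ("_p",)

    def __init__(self, probs: Sequence[float] | np.ndarray):
        p = np.asarray(probs, dtype=float)
        if p.shape != (N_LEVELS,):
            raise ValueError(f"expected {N_LEVELS} probabilities, got shape {p.shape}")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError(f"probabilities outside [0, 1]: {p.tolist()}")
        if abs(float(p.sum()) - 1.0) > SUM_TOL:
            raise ValueError(f"probabilities sum to {p.sum():.12f}, not 1")
        p.setflags(write=False)
        self._p = p

    # -- constructors ------------------------------------------------------
    @classmethod
    def point_mass(cls, level: SeverityLevel | int) -> "LevelDistribution":
        p = np.zeros(N_LEVELS)
        p[int(level)] = 1.0
        return cls(p)

    @classmethod
    def uniform(cls) -> "LevelDistribution":
        return cls(np.full(N_LEVELS, 1.0 / N_LEVELS))

    @classmethod
    def from_counts(cls, counts: Iterable[float]) -> "LevelDistribution":
        return cls(counts_to_distribution(counts))

    @classmethod
    def from_unnormalized(cls, weights: Sequence[float] | np.ndarray) -> "LevelDistribution":
        w = np.asarray(weights, dtype=float)
        total = float(w.sum())
        if total <= 0:
            raise ValueError("total weight must be positive")
        return cls(w / total)

    # -- accessors ---------------------------------------------------------
    @property
    def probs(self) -> np.ndarray:
        """Read-only numpy view, absent..high order."""
        return self._p

    def __getitem__(self, level: SeverityLevel | int) -> float:
        return float(self._p[int(level)])

    def __iter__(self):
        return iter(self._p.tolist())

    def __len__(self) -> int:
        return N_LEVELS

    def mode(self) -> SeverityLevel:
        """Most probable level; ties broken toward lower severity."""
        return SeverityLevel(int(np.argmax(self._p)))

    def cdf(self) -> np.ndarray:
        """Cumulative mass over the ordered levels (ends at 1)."""
        return np.cumsum(self._p)

    def stochastically_leq(self, other: "LevelDistribution", tol: float = 1e-9) -> bool:
        """First-order stochastic dominance: self puts no less mass on low levels.

        ``self <=_st other`` iff CDF_self(k) >= CDF_other(k) for every level k.
        """
        return bool(np.all(self.cdf() >= other.cdf() - tol))

    def as_dict(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(LEVEL_NAMES, self._p)}

    def allclose(self, other: "LevelDistribution", tol: float = 1e-9) -> bool:
        return bool(np.allclose(self._p, other._p, atol=tol, rtol=0.0))

    def __eq__(self, other) -> bool:
        return isinstance(other, LevelDistribution) and bool(np.array_equal(self._p, other._p))

    def __hash__(self):
        return hash(self._p.tobytes())

    def __repr__(self) -> str:
        body = ", ".join(f"{n}={v:.4g}" for n, v in self.as_dict().items())
        return f"LevelDistribution({body})"


def roulette_to_distribution(chips: Iterable[float]) -> np.ndarray:
    """Convert roulette-method ("chips and bins") allocations to probabilities.

    Experts distribute chips across bins; the probability of bin *i* is its
    chip fraction ``chips_i / sum(chips)``. Works for any number of bins.

    Raises
    ------
    DegenerateElicitationError
        If the total number of chips is zero.
    """
    c = np.asarray(list(chips), dtype=float)
    if np.any(c < 0):
        raise ValueError("chip counts must be nonnegative")
    total = float(c.sum())
    if total <= 0:
        raise DegenerateElicitationError("no chips allocated: cannot elicit a distribution")
    return c / total

def counts_to_distribution(counts: Iterable[float]) -> np.ndarray:
    """Convert a per-100-subjects elicitation column to a 4-level distribution.

    Elicitation tables ask "out of 100 subjects at this latent level, how many
    answer each way?"; dividing by the column total turns counts into
    probabilities. Scale-invariant: any positive rescaling of the counts gives
    the same distribution.
    """
    p = roulette_to_distribution(counts)
    if p.shape != (N_LEVELS,):
        raise ValueError(f"expected {N_LEVELS} counts, got {p.shape[0]}")
    return p
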