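"""Membrane composition arithmetic.

Converts target mole fractions into integer per-leaflet lipid counts by
largest-remainder (Hamilton) apportionment, and back.  For the ternary
42/28/30 mol% DyPC/DPPC/cholesterol system at 329 lipids per leaflet this
reproduces the 138/92/99 split used for the simulated phase-prone membranes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["MembraneRecipe", "counts_from_composition", "composition_from_counts"]

_FRACTION_TOL = 1e-9


def counts_from_composition(fractions: Sequence[float], n_per_leaflet: int) -> tuple:
    """Apportion ``n_per_leaflet`` lipids to types by largest remainder.

    Each type first receives ``floor(f * N)`` lipids; the remaining seats go
    to the largest fractional remainders, ties broken in favour of the
    first-listed type.  The result minimises ``sum(|count_i - f_i * N|)``
    over integer vectors summing to N.
    """
    f = np.asarray(fractions, dtype=float)
    if f.ndim != 1 or f.size == 0:
        raise ValueError("fractions must be a non-empty 1-D sequence")
    if (f < 0).any():
        raise ValueError(f"fractions must be non-negative, got {fractions}")
    if abs(f.sum() - 1.0) > _FRACTION_TOL:
        raise ValueError(f"fractions must sum to 1 (got {f.sum():.12g})")
    n = int(n_per_leaflet)
    if n < 1:
        raise ValueError("n_per_leaflet must be >= 1")
    quota = f * n
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = n - counts.sum()
    # stable sort descending on remainder -> ties go to the first-listed type
    order = np.argsort(-remainder, kind="stable")
    counts[order[:short]] += 1
    return tuple(int(c) for c in counts)


def composition_from_counts(counts: Sequence[int]) -> tuple:
    """Mole fractions (and an integer-percent rendering) from counts."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total < 1:
        raise ValueError("counts must sum to at least 1")
    fractions = tuple(float(x) for x in c / total)
    percents = tuple(int(round(100.0 * x)) for x in fractions)
    return fractions, percents


@dataclass(frozen=True)
class MembraneRecipe:
    """Named lipid types with target fractions and integer per-leaflet counts."""

    lipids: tuple
    fractions: tuple
    n_per_leaflet: int
    counts: tuple

    def __post_init__(self):
        if len(self.lipids) != len(self.fractions) or len(self.lipids) != len(self.counts):
            raise ValueError("lipids, fractions and counts must have equal length")
        if sum(self.counts) != self.n_per_leaflet:
            raise ValueError("counts must sum to n_per_leaflet")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_fractions(cls, lipids: Sequence[str], fractions: Sequence[float],
                       n_per_leaflet: int) -> "MembraneRecipe":
        counts = counts_from_composition(fractions, n_per_leaflet)
        return cls(tuple(lipids), tuple(float(f) for f in fractions), int(n_per_leaflet), counts)

    @classmethod
    def from_counts(cls, lipids: Sequence[str], counts: Sequence[int]) -> "MembraneRecipe":
        counts = tuple(int(c) for c in counts)
        fractions, _ = composition_from_counts(counts)
        return cls(tuple(lipids), fractions, sum(counts), counts)

    def actual_fractions(self) -> tuple:
        fractions, _ = composition_from_counts(self.counts)
        return fractions

    def percent_rendering(self) -> dict:
        _, percents = composition_from_counts(self.counts)
        return dict(zip(self.lipids, percents))

    def to_dict(self) -> dict:
        return {
            "lipids": list(self.lipids),
            "fractions": list(self.fractions),
            "n_per_leaflet": self.n_per_leaflet,
            "counts": list(self.counts),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MembraneRecipe":
        return cls(tuple(d["lipids"]), tuple(d["fractions"]), int(d["n_per_leaflet"]),
                   tuple(int(c) for c in d["counts"]))
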