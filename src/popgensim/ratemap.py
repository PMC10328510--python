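"""Piecewise-constant genomic rate maps (crossover rate along a contig)."""

from __future__ import annotations

import numpy as np

__all__ = ["RateMap"]


class RateMap:
    """Per-bp, per-generation rates over half-open intervals of a contig.

    ``breakpoints`` is an ascending integer array starting at 0 and ending
    at the contig length; ``rates[i]`` applies on
    ``[breakpoints[i], breakpoints[i+1])``.
    """

    def __init__(self, breakpoints, rates):
        self.breakpoints = np.asarray(breakpoints, dtype=np.int64)
        self.rates = np.asarray(rates, dtype=float)
        if self.breakpoints.ndim != 1 or self.rates.ndim != 1:
            raise ValueError("breakpoints and rates must be 1-D")
        if len(self.rates) != len(self.breakpoints) - 1:
            raise ValueError("need len(rates) == len(breakpoints) - 1")
        if self.breakpoints[0] != 0:
            raise ValueError("breakpoints must start at 0")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly ascending")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        # cumulative mass at each breakpoint, for O(log k) interval mass
        self._cum = np.concatenate(
            [[0.0], np.cumsum(self.rates * np.diff(self.breakpoints))]
        )

    @classmethod
    def uniform(cls, length: int, rate: float) -> "RateMap":
        return cls([0, int(length)], [float(rate)])

    @property
    def total_length(self) -> int:
        return int(self.breakpoints[-1])

    @property
    def total_mass(self) -> float:
        return float(self._cum[-1])

    def mass(self, left: int, right: int) -> float:
        """Integrated rate over [left, right)."""
        if not (0 <= left <= right <= self.total_length):
            raise ValueError(f"interval [{left}, {right}) out of range")
        return self._cum_at(right) - self._cum_at(left)

    def _cum_at(self, x: int) -> float:
        i = int(np.searchsorted(self.breakpoints, x, side="right")) - 1
        i = min(i, len(self.rates) - 1)
        return float(self._cum[i] + self.rates[i] * (x - self.breakpoints[i]))

    def sample_position(self, left: int, right: int, u: float) -> int:
        """Integer position in [left, right) at cumulative-mass fraction u.

        ``u`` is uniform in [0, 1); positions are chosen with probability
        proportional to the local rate.  Requires positive mass on the
        interval.
        """
        lo = self._cum_at(left)
        hi = self._cum_at(right)
        if hi <= lo:
            raise ValueError("no rate mass on interval")
        target = lo + u * (hi - lo)
        i = int(np.searchsorted(self._cum, target, side="right")) - 1
        i = min(i, len(self.rates) - 1)
        pos = self.breakpoints[i] + (target - self._cum[i]) / self.rates[i]
        return int(min(max(int(pos), left), right - 1))

    def __eq__(self, other):
        return (
            isinstance(other, RateMap)
            and np.array_equal(self.breakpoints, other.breakpoints)
            and np.array_equal(self.rates, other.rates)
        )

    def __repr__(self):
        return f"RateMap({len(self.rates)} intervals, L={self.total_length})"
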