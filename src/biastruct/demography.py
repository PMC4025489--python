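"""Piecewise-constant demographies, effective size, and drift.

A demography is an ordered list of epochs, each a (duration in generations,
diploid size) pair.  Two summaries matter for biased-sampling experiments:

* the long-term effective size, the harmonic mean of the per-generation sizes
  (a population that fluctuates in size drifts like a constant population of
  this size);
* the accumulated drift F = 1 - exp(-sum_i t_i / (2 N_i)), which maps a
  demography onto the dispersion parameter of a Balding-Nichols founder model
  so bottleneck scenarios can be simulated without a coalescent simulator.
"""

from __future__ import annotations

import dataclasses
import math


@dataclasses.dataclass(frozen=True)
class Demography:
    """Ordered epochs of (duration in generations, diploid population size)."""

    epochs: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("demography needs at least one epoch")
        for t, n in self.epochs:
            if t <= 0:
                raise ValueError("epoch durations must be positive")
            if n <= 0:
                raise ValueError("population sizes must be positive")

    @property
    def total_duration(self) -> float:
        return sum(t for t, _ in self.epochs)


def constant_scenario(n: float, duration: float = 1000.0) -> Demography:
    """A single-epoch demography of constant diploid size `n`."""
    return Demography(((duration, n),))


def bottleneck_scenario(alpha: float, n0: float = 10_000.0) -> Demography:
    """Split-then-bottleneck history for the contracted branch.

    The population holds size `n0` for 795 generations after the split, drops
    instantaneously to ``alpha * n0`` for 200 generations, then recovers
    instantaneously to `n0` for the final 5 generations (1000 generations in
    total).  ``alpha = 1`` gives a constant-size history.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if alpha == 1.0:
        return constant_scenario(n0)
    return Demography(((795.0, n0), (200.0, alpha * n0), (5.0, n0)))


def harmonic_mean_ne(demography: Demography) -> float:
    """Long-term effective diploid size: T / sum_i (t_i / N_i)."""
    total = demography.total_duration
    return total / sum(t / n for t, n in demography.epochs)


def demography_to_drift(demography: Demography) -> float:
    """Accumulated drift F = 1 - exp(-sum_i t_i / (2 N_i)), in (0, 1)."""
    rate = sum(t / (2.0 * n) for t, n in demography.epochs)
    return 1.0 - math.exp(-rate)
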