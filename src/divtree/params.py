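"""Model parameters, generation caps and the quadrature time grid.

Conventions
-----------
Time is measured backwards from the moment of observation (observation = 0)
and in units of the cell division rate, i.e. the birth rate is 1 and the
death (plus differentiation) rate is ``q < 1``.  All branch start/end times
``tau`` are therefore non-negative, with ``tau_e < tau_s`` along a branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "ClockParams",
    "GenerationCap",
    "TimeGrid",
    "default_upper_bound",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the division-coupled mutation model.

    Parameters
    ----------
    q : float
        Death rate relative to the birth rate; ``0 <= q < 1`` (supercritical
        growth).  For differentiating cell populations this is the combined
        rate of death and differentiation.
    mu : float
        Mean number of mutations per cell division, ``mu >= 0``.
    rho : float
        Probability that an extant cell is sampled, ``0 < rho <= 1``.
    """

    q: float
    mu: float
    rho: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.q < 1.0):
            raise ValueError(f"q must satisfy 0 <= q < 1, got {self.q!r}")
        if not (self.mu >= 0.0):
            raise ValueError(f"mu must be >= 0, got {self.mu!r}")
        if not (0.0 < self.rho <= 1.0):
            raise ValueError(f"rho must satisfy 0 < rho <= 1, got {self.rho!r}")


@dataclass(frozen=True)
class ClockParams:
    """Parameters of the constant-rate molecular-clock comparison model.

    Identical birth–death population process, but mutations accrue as a
    Poisson process in calendar time at rate ``mu_t`` instead of at divisions.
    """

    q: float
    mu_t: float
    rho: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.q < 1.0):
            raise ValueError(f"q must satisfy 0 <= q < 1, got {self.q!r}")
        if not (self.mu_t >= 0.0):
            raise ValueError(f"mu_t must be >= 0, got {self.mu_t!r}")
        if not (0.0 < self.rho <= 1.0):
            raise ValueError(f"rho must satisfy 0 < rho <= 1, got {self.rho!r}")


@dataclass(frozen=True)
class GenerationCap:
    """Upper truncation ``i_max`` of sums over the hidden generation count."""

    i_max: int = 50

    def __post_init__(self) -> None:
        if self.i_max < 1:
            raise ValueError(f"i_max must be >= 1, got {self.i_max!r}")

    @staticmethod
    def default_for(rho: float) -> "GenerationCap":
        """50 generations suffice under complete sampling; incomplete sampling
        stretches branches, so the cap is raised to 200 when ``rho < 1``."""
        return GenerationCap(50 if rho >= 1.0 else 200)


def default_upper_bound(n_tips: int, params: ModelParams | ClockParams) -> float:
    """Upper truncation of the tree-origin time: ``2 log(n_tips/rho)/(1-q)``.

    This is twice the expected age of a tree grown to ``n_tips/rho`` cells at
    net growth rate ``1-q``; with complete sampling it reduces to
    ``2 log(N)/(1-q)``.
    """
    if n_tips < 2:
        raise ValueError(f"n_tips must be >= 2, got {n_tips!r}")
    return 2.0 * math.log(n_tips / params.rho) / (1.0 - params.q)


@dataclass(frozen=True)
class TimeGrid:
    """Uniform grid on ``[0, upper_bound]`` used for all time quadrature."""

    upper_bound: float
    n_subintervals: int = 1000
    nodes: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (self.upper_bound > 0.0):
            raise ValueError(f"upper_bound must be > 0, got {self.upper_bound!r}")
        if self.n_subintervals < 1:
            raise ValueError("n_subintervals must be >= 1")
        nodes = np.linspace(0.0, self.upper_bound, self.n_subintervals + 1)
        nodes.setflags(write=False)
        object.__setattr__(self, "nodes", nodes)

    @property
    def spacing(self) -> float:
        return self.upper_bound / self.n_subintervals

    @staticmethod
    def for_tree(
        n_tips: int, params: ModelParams | ClockParams, n_subintervals: int = 1000
    ) -> "TimeGrid":
        return TimeGrid(default_upper_bound(n_tips, params), n_subintervals)
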