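"""Closed-form per-branch distributions of the birth–death mutation model.

A reconstructed branch living on the backwards-time window
``[tau_e, tau_s]`` hides ``i`` divisions whose other daughter lineage left
no *sampled* descendant.  Under a constant-rate birth–death process with
relative death rate ``q`` and Bernoulli(``rho``) sampling of extant cells,
``i`` is Poisson with mean

    Lambda = 2 q (tau_s - tau_e) + 2 log[ f(tau_e) / f(tau_s) ],
    f(t)   = (1 - rho - q) e^{-(1-q) t} + rho,

and the joint probability that the focal lineage survives the window while
all ``i`` side clades go unsampled is

    p1(i | tau_s, tau_e) = e^{-(1+q)(tau_s - tau_e)} Lambda^i / i! .

With complete sampling (``rho = 1``) this reduces to the classical
hidden-division distribution with ``f(t) = 1 - q e^{-(1-q) t}``.

Each of the ``i`` divisions — plus the one founding the branch — adds a
Poisson(``mu``) number of mutations, so the branch mutation count is a
compound Poisson variable with variance exceeding the equal-mean Poisson.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .params import GenerationCap, ModelParams

__all__ = [
    "BranchWindow",
    "log_survival_factor",
    "log_generation_mean",
    "p1_generations",
    "sum_p1_over_generations",
    "p0_sampled",
    "p1_sampled",
    "mutations_given_generations",
    "compound_poisson_pmf",
]


@dataclass(frozen=True)
class BranchWindow:
    """Backwards-time window of a branch: starts at ``tau_s``, ends at ``tau_e``."""

    tau_s: float
    tau_e: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau_e <= self.tau_s):
            raise ValueError(
                f"need 0 <= tau_e <= tau_s, got tau_e={self.tau_e!r}, tau_s={self.tau_s!r}"
            )

    @property
    def duration(self) -> float:
        return self.tau_s - self.tau_e


def log_survival_factor(t, q: float, rho: float):
    """``log f(t)`` with ``f(t) = (1-rho-q) e^{-(1-q)t} + rho``.

    ``f`` is the sampling-aware survival factor; it interpolates monotonically
    between ``f(0) = 1-q`` and ``f(inf) = rho`` and is strictly positive for
    valid parameters.
    """
    t = np.asarray(t, dtype=float)
    return np.log(rho + (1.0 - rho - q) * np.exp(-(1.0 - q) * t))


def log_generation_mean(window: BranchWindow, params: ModelParams) -> float:
    """Poisson mean ``Lambda`` of the hidden-division count on a branch."""
    q, rho = params.q, params.rho
    lf_e = float(log_survival_factor(window.tau_e, q, rho))
    lf_s = float(log_survival_factor(window.tau_s, q, rho))
    lam = 2.0 * q * window.duration + 2.0 * (lf_e - lf_s)
    # Lambda >= 0 analytically; clip roundoff on near-degenerate windows.
    return max(lam, 0.0)


def p1_generations(i: int, window: BranchWindow, params: ModelParams) -> float:
    """P(focal lineage survives the window with exactly ``i`` unsampled
    side clades)."""
    if i < 0:
        raise ValueError("i must be >= 0")
    lam = log_generation_mean(window, params)
    log_p = -(1.0 + params.q) * window.duration - gammaln(i + 1.0)
    if lam > 0.0:
        log_p += i * math.log(lam)
    elif i > 0:
        return 0.0
    return math.exp(log_p)


def sum_p1_over_generations(window: BranchWindow, params: ModelParams) -> float:
    """``sum_i p1(i | window)`` in closed form:
    ``exp(-(1+q) duration + Lambda)``.

    This is the probability that the focal lineage survives the window and no
    side clade is sampled, irrespective of how many divisions occurred; it is
    the per-branch population factor of the molecular-clock comparison model.
    """
    lam = log_generation_mean(window, params)
    return math.exp(-(1.0 + params.q) * window.duration + lam)


def p0_sampled(tau, params: ModelParams):
    """Probability that a clade founded ``tau`` ago has *no* sampled
    extant descendant."""
    q, rho = params.q, params.rho
    tau = np.asarray(tau, dtype=float)
    denom = rho + (1.0 - rho - q) * np.exp(-(1.0 - q) * tau)
    out = 1.0 - rho * (1.0 - q) / denom
    return out if out.ndim else float(out)


def p1_sampled(tau, params: ModelParams):
    """Probability that a clade founded ``tau`` ago has exactly *one* sampled
    extant descendant."""
    q, rho = params.q, params.rho
    tau = np.asarray(tau, dtype=float)
    e = np.exp(-(1.0 - q) * tau)
    denom = rho + (1.0 - rho - q) * e
    out = rho * (1.0 - q) ** 2 * e / denom**2
    return out if out.ndim else float(out)


def mutations_given_generations(m: int, i: int, mu: float) -> float:
    """P(m mutations | i hidden divisions) = Poisson(m; (i+1) mu).

    The ``+1`` is the division founding the branch: every branch starts with
    its founder cell replicating its genome.
    """
    if m < 0 or i < 0:
        raise ValueError("m and i must be >= 0")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    mean = (i + 1.0) * mu
    if mean == 0.0:
        return 1.0 if m == 0 else 0.0
    return math.exp(-mean + m * math.log(mean) - gammaln(m + 1.0))


def compound_poisson_pmf(
    m,
    mean_generations: float,
    mu: float,
    include_founder: bool = True,
    cap: GenerationCap | None = None,
) -> np.ndarray | float:
    """Compound Poisson pmf of the branch mutation count.

    ``m ~ Poisson((i + k) mu)`` with ``i ~ Poisson(mean_generations)`` and
    ``k = 1`` if the founding division is included (the likelihood convention)
    else 0 (the convention for comparing against an equal-mean simple
    Poisson with mean ``<i> mu``).
    """
    if mean_generations < 0 or mu < 0:
        raise ValueError("mean_generations and mu must be >= 0")
    cap = cap or GenerationCap(max(50, int(mean_generations + 12 * math.sqrt(mean_generations + 1) + 20)))
    m_arr = np.atleast_1d(np.asarray(m, dtype=np.int64))
    if np.any(m_arr < 0):
        raise ValueError("m must be >= 0")
    k = 1 if include_founder else 0
    i = np.arange(cap.i_max + 1)
    # log Poisson(i; <i>)
    if mean_generations > 0:
        log_pi = -mean_generations + i * math.log(mean_generations) - gammaln(i + 1.0)
    else:
        log_pi = np.full(i.shape, -np.inf)
        log_pi[0] = 0.0
    means = (i + k) * mu  # per-i Poisson mean of m
    with np.errstate(divide="ignore"):
        log_means = np.log(means)
    out = np.empty(m_arr.shape, dtype=float)
    for j, mv in enumerate(m_arr):
        with np.errstate(invalid="ignore"):  # 0 * log(0) in masked entries
            log_pm = np.where(
                means > 0,
                -means + mv * log_means - gammaln(mv + 1.0),
                0.0 if mv == 0 else -np.inf,
            )
        out[j] = math.exp(logsumexp(log_pi + log_pm))
    return out if np.ndim(m) else float(out[0])
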