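"""Independent reference implementations used only by the tests.

Everything here is written directly from the model definitions with plain
numpy/scipy and deliberately shares no code with the package internals: sums
over hidden divisions are explicit truncated loops, and tree likelihoods are
brute-force nested trapezoid quadrature without message caching.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln


def lam_mean(tau_s: float, tau_e: float, q: float, rho: float) -> float:
    """Poisson mean of the hidden-division count (direct transcription)."""
    f_e = (1.0 - rho - q) * math.exp(-(1.0 - q) * tau_e) + rho
    f_s = (1.0 - rho - q) * math.exp(-(1.0 - q) * tau_s) + rho
    return 2.0 * q * (tau_s - tau_e) + 2.0 * math.log(f_e / f_s)


def p1_hidden(i: int, tau_s: float, tau_e: float, q: float, rho: float) -> float:
    lam = lam_mean(tau_s, tau_e, q, rho)
    if lam <= 0.0:
        return math.exp(-(1.0 + q) * (tau_s - tau_e)) if i == 0 else 0.0
    return math.exp(
        -(1.0 + q) * (tau_s - tau_e) + i * math.log(lam) - gammaln(i + 1)
    )


def p_m_given_i(m: int, i: int, mu: float) -> float:
    mean = (i + 1) * mu
    if mean == 0.0:
        return 1.0 if m == 0 else 0.0
    return math.exp(-mean + m * math.log(mean) - gammaln(m + 1))


def branch_sum(m: int, tau_s: float, tau_e: float, q: float, mu: float,
               rho: float, i_max: int) -> float:
    """sum_i P(m|i) p1(i|tau_s, tau_e), explicit truncated loop."""
    return sum(
        p_m_given_i(m, i, mu) * p1_hidden(i, tau_s, tau_e, q, rho)
        for i in range(i_max + 1)
    )


def pendant_vec(m: int, t: np.ndarray, q: float, mu: float, rho: float,
                i_max: int) -> np.ndarray:
    return np.array([rho * branch_sum(m, ts, 0.0, q, mu, rho, i_max) for ts in t])


def _trap_weights(n_nodes: int, h: float) -> np.ndarray:
    w = np.full(n_nodes, h)
    w[[0, -1]] *= 0.5
    return w


def internal_vec(m: int, child_product2: np.ndarray, t: np.ndarray, q: float,
                 mu: float, rho: float, i_max: int) -> np.ndarray:
    """Brute-force internal message: for every tau_s node, trapezoid over the
    end time of the product ``2 * child_a * child_b`` (already multiplied)."""
    h = t[1] - t[0]
    out = np.zeros_like(t)
    for s in range(1, len(t)):
        w = _trap_weights(s + 1, h)
        vals = np.array(
            [branch_sum(m, t[s], t[e], q, mu, rho, i_max) for e in range(s + 1)]
        )
        out[s] = float(np.sum(w * vals * child_product2[: s + 1]))
    return out


def loglik_3leaf(m_in: int, m1: int, m2: int, m3: int, t: np.ndarray,
                 q: float, mu: float, rho: float, i_max: int) -> float:
    """((leaf m1, leaf m2) internal m_in, leaf m3) by nested quadrature."""
    pa = pendant_vec(m1, t, q, mu, rho, i_max)
    pb = pendant_vec(m2, t, q, mu, rho, i_max)
    inner = internal_vec(m_in, 2.0 * pa * pb, t, q, mu, rho, i_max)
    pc = pendant_vec(m3, t, q, mu, rho, i_max)
    w = _trap_weights(len(t), t[1] - t[0])
    return math.log(float(np.sum(w * 2.0 * inner * pc)))


def loglik_4leaf_caterpillar(m_a: int, m_b: int, m1: int, m2: int, m3: int,
                             m4: int, t: np.ndarray, q: float, mu: float,
                             rho: float, i_max: int) -> float:
    """(((m1, m2) m_b, m3) m_a, m4): three nested time integrals."""
    pa = pendant_vec(m1, t, q, mu, rho, i_max)
    pb = pendant_vec(m2, t, q, mu, rho, i_max)
    inner_b = internal_vec(m_b, 2.0 * pa * pb, t, q, mu, rho, i_max)
    p3 = pendant_vec(m3, t, q, mu, rho, i_max)
    inner_a = internal_vec(m_a, 2.0 * inner_b * p3, t, q, mu, rho, i_max)
    p4 = pendant_vec(m4, t, q, mu, rho, i_max)
    w = _trap_weights(len(t), t[1] - t[0])
    return math.log(float(np.sum(w * 2.0 * inner_a * p4)))


def compound_moments(mean_generations: float, mu: float, include_founder: bool,
                     m_max: int = 400, i_max: int = 400):
    """(mean, variance) of the compound branch-mutation pmf by brute-force
    truncated double summation."""
    ms = np.arange(m_max + 1)
    pmf = np.zeros(m_max + 1)
    k = 1 if include_founder else 0
    for i in range(i_max + 1):
        if mean_generations > 0:
            log_pi = -mean_generations + i * math.log(mean_generations) - gammaln(i + 1)
        else:
            log_pi = 0.0 if i == 0 else -np.inf
        pi = math.exp(log_pi)
        if pi < 1e-18 and i > mean_generations:
            break
        mean_m = (i + k) * mu
        if mean_m == 0:
            pm = np.zeros(m_max + 1)
            pm[0] = 1.0
        else:
            pm = np.exp(-mean_m + ms * math.log(mean_m) - gammaln(ms + 1.0))
        pmf += pi * pm
    mean = float(np.sum(ms * pmf))
    var = float(np.sum(ms**2 * pmf)) - mean**2
    return mean, var
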