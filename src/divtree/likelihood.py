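"""Dynamic-programming likelihood of a mutation-annotated tree.

The likelihood integrates over the latent calendar times of all internal
nodes and sums over the hidden divisions along every branch.  Messages

    P(nu | tau_s) = probability of the subtree below branch ``nu`` given the
                    branch starts at backwards time ``tau_s``

are tabulated on a shared uniform time grid and combined in post-order:

* pendant branch with ``m`` mutations (ends in a sampled leaf, ``tau_e = 0``):
      P(nu | tau_s) = rho * sum_i P(m | i) p1(i | tau_s, 0)
* internal branch with children ``nu'``, ``nu''``:
      P(nu | tau_s) = sum_i \\int_0^{tau_s} dtau_e P(m | i) p1(i | tau_s, tau_e)
                        * 2 P(nu' | tau_e) P(nu'' | tau_e)
* root (most recent common ancestor), uniform prior on the origin time
  truncated at the grid upper bound T:
      L = \\int_0^T dtau_s 2 P(nu' | tau_s) P(nu'' | tau_s).

All time integrals use the trapezoidal rule on the grid nodes; messages are
stored in log space with per-branch max-shifts, so trees with thousands of
mutations do not underflow.  Within one evaluation the quadrature kernel
depends on a branch only through its mutation count ``m``; kernels are cached
per distinct ``m``, which makes the cost per internal branch a single
matrix–vector product.

The constant-rate molecular-clock comparison model reuses the same
machinery with the per-branch factor replaced by
``Poisson(m; mu_t * (tau_s - tau_e)) * sum_i p1(i | tau_s, tau_e)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .params import ClockParams, GenerationCap, ModelParams, TimeGrid
from .tree import ReconTree

__all__ = [
    "BranchMessage",
    "LikelihoodEngine",
    "pendant_message",
    "internal_message",
    "tree_log_likelihood",
    "clock_tree_log_likelihood",
    "forest_log_likelihood",
]

_LOG2 = math.log(2.0)


@dataclass
class BranchMessage:
    """``log P(nu | tau)`` tabulated at every grid node."""

    log_values: np.ndarray
    grid: TimeGrid
    branch_id: int | None = None

    def __post_init__(self) -> None:
        self.log_values = np.asarray(self.log_values, dtype=float)
        if self.log_values.shape != self.grid.nodes.shape:
            raise ValueError("message length must match the grid")
        if np.any(np.isnan(self.log_values)) or np.any(self.log_values == np.inf):
            raise ValueError("log message values must be finite or -inf")


class LikelihoodEngine:
    """Tabulated kernels and message passing for one parameter point.

    Parameters are fixed at construction; the engine caches, per distinct
    branch mutation count, the trapezoid-weighted quadrature kernel
    ``K_m[s, e] = w[s, e] * sum_i P(m | i) p1(i | tau_s, tau_e)`` (division
    model) or its molecular-clock analogue.
    """

    def __init__(
        self,
        params: ModelParams | ClockParams,
        grid: TimeGrid,
        cap: GenerationCap | None = None,
    ):
        self.params = params
        self.grid = grid
        self.is_clock = isinstance(params, ClockParams)
        if cap is None:
            cap = GenerationCap.default_for(params.rho)
        self.cap = cap

        q, rho = params.q, params.rho
        t = grid.nodes
        self._t = t
        n = t.size
        # survival factor f(t) = (1-rho-q) e^{-(1-q)t} + rho, and
        # A(t) = 2 q t - 2 log f(t); Lambda(s, e) = A(s) - A(e)
        log_f = np.log(rho + (1.0 - rho - q) * np.exp(-(1.0 - q) * t))
        self._A = 2.0 * q * t - 2.0 * log_f
        self._Lam = self._A[:, None] - self._A[None, :]
        self._Delta = t[:, None] - t[None, :]
        # trapezoid weights for \int_0^{tau_s} ... dtau_e over nodes e <= s
        h = grid.spacing
        w = np.tril(np.full((n, n), h))
        w[:, 0] *= 0.5
        idx = np.arange(n)
        w[idx, idx] *= 0.5
        w[0, 0] = 0.0  # empty integration range at tau_s = 0
        self._trap = w
        self._trap_full = np.full(n, h)
        self._trap_full[[0, -1]] *= 0.5

        self._kernels: dict[int, np.ndarray] = {}
        self._pendants: dict[int, np.ndarray] = {}
        self.kernels_built = 0
        self.messages_computed = 0

    # -- generation-sum coefficients --------------------------------------

    def _division_coeffs(self, m: int) -> np.ndarray:
        """``c_i = P(m | i) = Poisson(m; (i+1) mu)`` for i = 0..i_eff.

        The sum is truncated at the configured cap; when the cap lies far in
        the negligible tail (relative contribution below machine precision)
        it is shortened, which leaves the result unchanged to full precision.
        """
        mu = self.params.mu
        lam_max = float(self._Lam[-1, 0]) if self._Lam.size else 0.0
        z = max(lam_max, 0.0) * math.exp(-min(mu, 700.0))
        i_safe = int(z + 12.0 * math.sqrt(z + 1.0) + m + 30)
        i_eff = min(self.cap.i_max, max(i_safe, 1))
        i = np.arange(i_eff + 1, dtype=float)
        mean = (i + 1.0) * mu
        if mu == 0.0:
            c = np.ones(i_eff + 1) if m == 0 else np.zeros(i_eff + 1)
        else:
            c = np.exp(-mean + m * np.log(mean) - gammaln(m + 1.0))
        return c

    @staticmethod
    def _horner(Lam: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
        """``sum_i coeffs[i] Lam^i / i!`` evaluated stably by Horner."""
        n = len(coeffs) - 1
        out = np.full_like(Lam, coeffs[n])
        for i in range(n, 0, -1):
            out *= Lam
            out /= i
            out += coeffs[i - 1]
        return out

    # -- kernels -----------------------------------------------------------

    def kernel(self, m: int) -> np.ndarray:
        """Trapezoid-weighted internal-branch kernel for mutation count m."""
        m = int(m)
        K = self._kernels.get(m)
        if K is not None:
            return K
        q = self.params.q
        if self.is_clock:
            with np.errstate(divide="ignore", invalid="ignore"):
                if m > 0:
                    log_pm = (
                        m * np.log(self.params.mu_t * self._Delta)
                        - self.params.mu_t * self._Delta
                        - gammaln(m + 1.0)
                    )
                else:
                    log_pm = -self.params.mu_t * self._Delta
                logK = log_pm - (1.0 + q) * self._Delta + self._Lam
                with np.errstate(over="ignore"):
                    K = np.exp(logK)  # upper triangle may overflow; masked below
        else:
            c = self._division_coeffs(m)
            S = self._horner(self._Lam, c)
            with np.errstate(over="ignore", invalid="ignore", under="ignore"):
                K = S * np.exp(-(1.0 + q) * self._Delta)
        # entries above the diagonal are junk (tau_e > tau_s) and the far
        # corner may have over/underflowed; both are masked out here
        K = np.where(np.isfinite(K), K, 0.0)
        K *= self._trap
        np.maximum(K, 0.0, out=K)
        self._kernels[m] = K
        self.kernels_built += 1
        return K

    def log_pendant(self, m: int) -> np.ndarray:
        """``log`` pendant message vector for mutation count m."""
        m = int(m)
        v = self._pendants.get(m)
        if v is not None:
            return v
        q, rho = self.params.q, self.params.rho
        lam0 = self._A - self._A[0]
        np.maximum(lam0, 0.0, out=lam0)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            if self.is_clock:
                if m > 0:
                    log_pm = (
                        m * np.log(self.params.mu_t * self._t)
                        - self.params.mu_t * self._t
                        - gammaln(m + 1.0)
                    )
                else:
                    log_pm = -self.params.mu_t * self._t
                logv = math.log(rho) + log_pm - (1.0 + q) * self._t + lam0
            else:
                c = self._division_coeffs(m)
                S = self._horner(lam0, c)
                logv = math.log(rho) + np.log(S) - (1.0 + q) * self._t
        logv = np.where(np.isnan(logv), -np.inf, logv)
        self._pendants[m] = logv
        return logv

    # -- message passing ---------------------------------------------------

    def internal_log_message(
        self, m: int, log_a: np.ndarray, log_b: np.ndarray
    ) -> np.ndarray:
        """Combine two child messages through a branch with m mutations."""
        lw = log_a + log_b
        shift = float(np.max(lw))
        n = lw.size
        if not np.isfinite(shift):
            return np.full(n, -np.inf)
        W = np.exp(lw - shift)
        val = self.kernel(m) @ (2.0 * W)
        with np.errstate(divide="ignore"):
            return np.log(val) + shift

    def tree_log_likelihood(self, tree: ReconTree) -> float:
        if not tree.is_binary():
            raise ValueError(
                "tree is not binary; normalize multifurcations first "
                "(ReconTree.resolve_polytomies)"
            )
        n = self._t.size
        logmsg = np.empty((tree.n_nodes, n))
        for v in tree.postorder():
            if v == 0:
                continue
            if tree.is_leaf(v):
                logmsg[v] = self.log_pendant(tree.mutations[v])
            else:
                a, b = tree.children[v]
                logmsg[v] = self.internal_log_message(
                    tree.mutations[v], logmsg[a], logmsg[b]
                )
            self.messages_computed += 1
        a, b = tree.children[0]
        lw = logmsg[a] + logmsg[b]
        shift = float(np.max(lw))
        if not np.isfinite(shift):
            return -np.inf
        val = self._trap_full @ (2.0 * np.exp(lw - shift))
        if val <= 0.0:
            return -np.inf
        return math.log(val) + shift

    def messages(self, tree: ReconTree) -> dict[int, BranchMessage]:
        """Per-branch messages for debugging/inspection (node id -> message)."""
        out: dict[int, BranchMessage] = {}
        logmsg: dict[int, np.ndarray] = {}
        for v in tree.postorder():
            if v == 0:
                continue
            if tree.is_leaf(v):
                logmsg[v] = self.log_pendant(tree.mutations[v])
            else:
                a, b = tree.children[v]
                logmsg[v] = self.internal_log_message(
                    tree.mutations[v], logmsg[a], logmsg[b]
                )
            out[v] = BranchMessage(logmsg[v], self.grid, branch_id=v)
        return out


# -- module-level convenience wrappers ------------------------------------


def _make_grid(
    tree_or_trees,
    params,
    grid: TimeGrid | None,
    n_subintervals: int,
    n_tips_for_bound: int | None,
) -> TimeGrid:
    if grid is not None:
        return grid
    if n_tips_for_bound is None:
        trees = tree_or_trees if isinstance(tree_or_trees, (list, tuple)) else [tree_or_trees]
        n_tips_for_bound = sum(t.n_leaves for t in trees)
    return TimeGrid.for_tree(n_tips_for_bound, params, n_subintervals)


def pendant_message(
    m: int,
    grid: TimeGrid,
    params: ModelParams,
    cap: GenerationCap | None = None,
) -> BranchMessage:
    """Message of a branch with ``m`` mutations ending in a sampled leaf."""
    if m < 0:
        raise ValueError("m must be >= 0")
    eng = LikelihoodEngine(params, grid, cap)
    return BranchMessage(eng.log_pendant(m), grid)


def internal_message(
    m: int,
    child_a: BranchMessage,
    child_b: BranchMessage,
    grid: TimeGrid,
    params: ModelParams,
    cap: GenerationCap | None = None,
) -> BranchMessage:
    """Message of an internal branch with ``m`` mutations, integrating over
    the branch end time and combining the two child messages."""
    for c in (child_a, child_b):
        if c.grid.nodes.shape != grid.nodes.shape or not np.allclose(
            c.grid.nodes, grid.nodes
        ):
            raise ValueError("child messages are tabulated on a different grid")
    eng = LikelihoodEngine(params, grid, cap)
    return BranchMessage(
        eng.internal_log_message(m, child_a.log_values, child_b.log_values), grid
    )


def tree_log_likelihood(
    tree: ReconTree,
    params: ModelParams,
    grid: TimeGrid | None = None,
    cap: GenerationCap | None = None,
    n_subintervals: int = 1000,
    n_tips_for_bound: int | None = None,
) -> float:
    """Log-likelihood of the model parameters given one tree.

    If no grid is supplied, one is built on ``[0, 2 log(n_tips/rho)/(1-q)]``
    with ``n_subintervals`` steps (the default numerical settings).
    """
    grid = _make_grid(tree, params, grid, n_subintervals, n_tips_for_bound)
    return LikelihoodEngine(params, grid, cap).tree_log_likelihood(tree)


def clock_tree_log_likelihood(
    tree: ReconTree,
    params: ClockParams,
    grid: TimeGrid | None = None,
    n_subintervals: int = 1000,
    n_tips_for_bound: int | None = None,
) -> float:
    """Log-likelihood under the constant-rate molecular-clock comparison
    model (mutations Poisson in calendar time along branches)."""
    grid = _make_grid(tree, params, grid, n_subintervals, n_tips_for_bound)
    return LikelihoodEngine(params, grid).tree_log_likelihood(tree)


def forest_log_likelihood(
    trees: list[ReconTree],
    params: ModelParams | ClockParams,
    grid: TimeGrid | None = None,
    cap: GenerationCap | None = None,
    n_subintervals: int = 1000,
    n_tips_for_bound: int | None = None,
) -> float:
    """Joint log-likelihood of independent trees (clades) sharing one
    parameter set and one time grid; kernels are shared across trees."""
    grid = _make_grid(trees, params, grid, n_subintervals, n_tips_for_bound)
    eng = LikelihoodEngine(params, grid, cap)
    return float(sum(eng.tree_log_likelihood(t) for t in trees))
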