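"""Maximum-likelihood fitting, likelihood landscapes and the clade
heterogeneity likelihood-ratio test.

Fitting maximizes the (joint) tree log-likelihood over ``(q, mu)`` at fixed
sampling probability ``rho`` — coarse grid scan followed by Nelder–Mead
refinement.  The heterogeneity test compares a homogeneous model (one
``(q, mu)`` shared by all clades) against a model giving one focal clade its
own ``(q_dist, mu_dist)``; twice the log-likelihood gain is asymptotically
chi-squared with 2 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .likelihood import LikelihoodEngine
from .params import ClockParams, GenerationCap, ModelParams, TimeGrid, default_upper_bound
from .tree import ReconTree

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "LRTResult",
    "fit_mle",
    "fit_clock_mle",
    "likelihood_landscape",
    "select_postnatal_clades",
    "heterogeneity_test",
    "bonferroni_select",
]


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    params: ModelParams | ClockParams
    log_likelihood: float
    trace: list[tuple[float, float, float]] = field(default_factory=list)
    settings: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def q(self) -> float:
        return self.params.q

    @property
    def mu(self) -> float:
        return self.params.mu if isinstance(self.params, ModelParams) else self.params.mu_t


@dataclass
class LRTResult:
    """Homogeneous vs one-clade-distinct likelihood-ratio test."""

    focal_clade: int
    homogeneous: FitResult
    main: FitResult
    distinct: FitResult
    lambda_lr: float
    df: int = 2
    p_value: float = float("nan")

    def __post_init__(self) -> None:
        if np.isnan(self.p_value):
            self.p_value = float(chi2.sf(self.lambda_lr, self.df))


def _as_list(trees) -> list[ReconTree]:
    return list(trees) if isinstance(trees, (list, tuple)) else [trees]


def _objective(trees, rho, n_subintervals, i_max, n_tips, clock):
    cls = ClockParams if clock else ModelParams
    cap = None if clock else GenerationCap(i_max)

    def neg_loglik(x):
        q, rate = x
        q = min(max(q, 0.0), 0.999)
        rate = max(rate, 0.0)
        params = cls(q, rate, rho)
        grid = TimeGrid(default_upper_bound(n_tips, params), n_subintervals)
        eng = LikelihoodEngine(params, grid, cap)
        ll = float(sum(eng.tree_log_likelihood(t) for t in trees))
        return -ll

    return neg_loglik


def _fit(
    trees,
    rho: float,
    clock: bool,
    q_bounds=(0.0, 0.98),
    mu_bounds=None,
    n_subintervals: int = 1000,
    i_max: int | None = None,
    coarse_shape: tuple[int, int] = (9, 9),
    n_tips_for_bound: int | None = None,
    xatol: float = 1e-3,
    fatol: float = 1e-4,
    extra_starts: list[tuple[float, float]] | None = None,
) -> FitResult:
    trees = _as_list(trees)
    if not trees:
        raise ValueError("need at least one tree")
    if i_max is None:
        i_max = GenerationCap.default_for(rho).i_max
    n_tips = n_tips_for_bound or sum(t.n_leaves for t in trees)
    if mu_bounds is None:
        # mean mutations per branch bounds the per-division mean from above
        mean_m = float(
            np.mean([t.mutations[1:].mean() for t in trees])
        )
        mu_bounds = (1e-4, max(2.0 * mean_m, 2.0))
    neg = _objective(trees, rho, n_subintervals, i_max, n_tips, clock)

    trace: list[tuple[float, float, float]] = []
    qs = np.linspace(q_bounds[0], q_bounds[1], coarse_shape[0])
    # geometric mu scan bracketing the per-branch mean mutation count
    mean_m = float(np.mean([t.mutations[1:].mean() for t in trees]))
    mu_lo = max(mu_bounds[0], mean_m / 30.0, 1e-3)
    mus = np.geomspace(mu_lo, mu_bounds[1], coarse_shape[1])
    candidates = [(q, mu) for q in qs for mu in mus]
    candidates.extend(extra_starts or [])
    best = None
    for q, mu in candidates:
        ll = -neg((q, mu))
        trace.append((float(q), float(mu), ll))
        if np.isfinite(ll) and (best is None or ll > best[2]):
            best = (float(q), float(mu), ll)
    if best is None:
        raise RuntimeError(
            "log-likelihood is -inf on the entire coarse grid; "
            "check the tree and the sampling probability"
        )
    logger.debug("coarse maximum at q=%.3f mu=%.3f (logL=%.3f)", *best)

    def wrapped(x):
        val = neg(x)
        trace.append((float(x[0]), float(x[1]), -val))
        return val if np.isfinite(val) else 1e300

    # explicit initial simplex with inward steps: robust when the coarse
    # maximum sits on a parameter boundary (scipy's default simplex is
    # degenerate there)
    x0 = np.array(best[:2])
    dq = 0.08 if x0[0] < 0.5 * (q_bounds[0] + q_bounds[1]) else -0.08
    dmu = 0.15 * max(x0[1], 0.1)
    if x0[1] + dmu > mu_bounds[1]:
        dmu = -dmu
    simplex = np.array([x0, x0 + [dq, 0.0], x0 + [0.0, dmu]])
    simplex[:, 0] = np.clip(simplex[:, 0], q_bounds[0], q_bounds[1])
    simplex[:, 1] = np.clip(simplex[:, 1], mu_bounds[0], mu_bounds[1])
    res = minimize(
        wrapped,
        x0=x0,
        method="Nelder-Mead",
        bounds=[q_bounds, mu_bounds],
        options={"xatol": xatol, "fatol": fatol, "maxfev": 400,
                 "initial_simplex": simplex},
    )
    q_hat, mu_hat = float(res.x[0]), float(res.x[1])
    cls = ClockParams if clock else ModelParams
    params = cls(q_hat, mu_hat, rho)
    return FitResult(
        params=params,
        log_likelihood=float(-res.fun),
        trace=trace,
        settings={
            "rho": rho,
            "n_subintervals": n_subintervals,
            "i_max": i_max,
            "n_tips_for_bound": n_tips,
            "q_bounds": tuple(q_bounds),
            "mu_bounds": tuple(mu_bounds),
            "coarse_shape": tuple(coarse_shape),
            "model": "clock" if clock else "division",
        },
        converged=bool(res.success),
    )


def fit_mle(trees, rho: float = 1.0, **kwargs) -> FitResult:
    """Maximum-likelihood ``(q, mu)`` under the division-coupled model."""
    return _fit(trees, rho, clock=False, **kwargs)


def fit_clock_mle(trees, rho: float = 1.0, **kwargs) -> FitResult:
    """Maximum-likelihood ``(q, mu_t)`` under the molecular-clock model."""
    return _fit(trees, rho, clock=True, **kwargs)


def likelihood_landscape(
    trees,
    rho: float,
    q_values,
    mu_values,
    clock: bool = False,
    n_subintervals: int = 1000,
    i_max: int | None = None,
    n_tips_for_bound: int | None = None,
    floor: float | None = None,
) -> np.ndarray:
    """Log-likelihood on the grid ``q_values x mu_values``.

    Returns an array of shape ``(len(q_values), len(mu_values))``; with
    ``floor`` set, values below it are masked to NaN (for display).
    """
    trees = _as_list(trees)
    q_values = np.asarray(q_values, float)
    mu_values = np.asarray(mu_values, float)
    if q_values.size == 0 or mu_values.size == 0:
        raise ValueError("parameter grids must be non-empty")
    if i_max is None:
        i_max = GenerationCap.default_for(rho).i_max
    n_tips = n_tips_for_bound or sum(t.n_leaves for t in trees)
    neg = _objective(trees, rho, n_subintervals, i_max, n_tips, clock)
    out = np.empty((q_values.size, mu_values.size))
    for a, q in enumerate(q_values):
        for b, mu in enumerate(mu_values):
            out[a, b] = -neg((q, mu))
    if floor is not None:
        out = np.where(out < floor, np.nan, out)
    return out


def select_postnatal_clades(
    tree: ReconTree,
    min_root_mutations: int = 100,
    min_leaves: int = 23,
) -> list[int]:
    """Maximal clades arising after birth of the donor.

    Returns the node ids of maximal clades whose root is *strictly more* than
    ``min_root_mutations`` mutations from the tree root and which span at
    least ``min_leaves`` leaves.  Selected clades are disjoint: once a node
    qualifies, its descendants are not considered.
    """
    dist = tree.root_distances()
    nleaves = tree.leaf_counts()
    out: list[int] = []
    stack = [0]
    while stack:
        v = stack.pop()
        if dist[v] > min_root_mutations:
            if not tree.is_leaf(v) and nleaves[v] >= min_leaves:
                out.append(v)
            continue  # descendants of a qualifying/too-small node are skipped
        stack.extend(reversed(tree.children[v]))
    return sorted(out)


def heterogeneity_test(
    clades: list[ReconTree],
    focal: int,
    rho: float = 1.0,
    n_tips_for_bound: int | None = None,
    homogeneous_fit: FitResult | None = None,
    **fit_kwargs,
) -> LRTResult:
    """Likelihood-ratio test for distinct parameters in one clade.

    The homogeneous model shares ``(q, mu)`` across all clades (joint
    likelihood = product over independently analyzed clades).  The
    heterogeneous model gives clade ``focal`` its own ``(q_dist, mu_dist)``
    and the remaining clades ``(q_main, mu_main)``; because the joint
    likelihood factorizes, the two pairs are optimized independently.
    ``lambda_LR = 2 (logL_het - logL_hom)`` is referred to chi-squared with
    two degrees of freedom.
    """
    if len(clades) < 2:
        raise ValueError("need at least two clades")
    if not (0 <= focal < len(clades)):
        raise ValueError(f"focal index {focal} out of range")
    n_tips = n_tips_for_bound or sum(t.n_leaves for t in clades)
    kw = dict(fit_kwargs, n_tips_for_bound=n_tips)
    if homogeneous_fit is None:
        homogeneous_fit = fit_mle(clades, rho, **kw)
    # warm-start both heterogeneous fits at the homogeneous optimum: the
    # heterogeneous model nests the homogeneous one, so lambda_LR >= 0 up to
    # optimizer tolerance by construction
    hom_start = [(homogeneous_fit.params.q, homogeneous_fit.mu)]
    rest = [t for k, t in enumerate(clades) if k != focal]
    fit_main = fit_mle(rest, rho, extra_starts=hom_start, **kw)
    fit_dist = fit_mle([clades[focal]], rho, extra_starts=hom_start, **kw)
    ll_het = fit_main.log_likelihood + fit_dist.log_likelihood
    lam = 2.0 * (ll_het - homogeneous_fit.log_likelihood)
    return LRTResult(
        focal_clade=focal,
        homogeneous=homogeneous_fit,
        main=fit_main,
        distinct=fit_dist,
        lambda_lr=float(lam),
    )


def bonferroni_select(results: list[LRTResult], alpha: float = 0.05) -> list[LRTResult]:
    """Scenarios significant under the Bonferroni-corrected threshold
    ``alpha / len(results)``."""
    if not results:
        return []
    threshold = alpha / len(results)
    return [r for r in results if r.p_value < threshold]
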