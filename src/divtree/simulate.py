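"""Forward birth–death simulation and reconstruction of sampled trees.

The generator realizes exactly the process the likelihood describes: a
population grown from a single cell under per-cell birth rate 1 and death
rate ``q``, stopped the first time it reaches size ``N`` (restarting on
extinction), Bernoulli(``rho``) sampling of the extant cells, reconstruction
of the tree spanning the sampled cells, and Poisson(``(i+1) mu``) mutations
per reconstructed branch, where ``i`` counts the hidden divisions inside the
branch.  It also provides a Monte-Carlo estimator of the hidden-division
distribution used as an independent oracle for the closed forms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .branch_stats import BranchWindow
from .params import ModelParams
from .tree import ReconTree

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "LineageTree",
    "simulate_birth_death",
    "sample_and_reconstruct",
    "assign_mutations",
    "simulate_tree",
    "mc_estimate_p1",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated population."""

    q: float
    mu: float
    rho: float = 1.0
    stop_size: int = 300
    seed: int | None = None
    min_sampled: int = 2

    def __post_init__(self) -> None:
        ModelParams(self.q, self.mu, self.rho)  # bounds check
        if self.stop_size < 2:
            raise ValueError("stop_size must be >= 2")


@dataclass
class LineageTree:
    """Complete genealogy of every cell ever alive.

    Cell 0 is the founder.  ``death_time`` is NaN for cells extant at
    ``stop_time`` and for cells that divided (a dividing cell is replaced by
    its two daughters).  Forward time runs from 0 (founding) upwards.
    """

    parent: np.ndarray
    birth_time: np.ndarray
    death_time: np.ndarray
    n_children: np.ndarray
    extant: np.ndarray
    stop_time: float
    restarts: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.parent)


def simulate_birth_death(
    config: SimConfig, rng: np.random.Generator | None = None
) -> LineageTree:
    """Exact (Gillespie) simulation to first passage at ``stop_size``.

    Populations that go extinct before reaching the stop size are redrawn
    from scratch; the number of restarts is logged and recorded.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    q, N = config.q, config.stop_size
    p_birth = 1.0 / (1.0 + q)
    restarts = 0
    while True:
        parent = [-1]
        birth = [0.0]
        death = [np.nan]
        nchild = [0]
        alive = [0]
        t = 0.0
        while alive and len(alive) < N:
            n = len(alive)
            t += rng.exponential(1.0 / (n * (1.0 + q)))
            j = rng.integers(n)
            cell = alive[j]
            if rng.random() < p_birth:
                for _ in range(2):
                    parent.append(cell)
                    birth.append(t)
                    death.append(np.nan)
                    nchild.append(0)
                nchild[cell] = 2
                alive[j] = len(parent) - 2
                alive.append(len(parent) - 1)
            else:
                death[cell] = t
                alive[j] = alive[-1]
                alive.pop()
        if alive:
            extant = np.zeros(len(parent), dtype=bool)
            extant[alive] = True
            if restarts:
                logger.info("population went extinct %d time(s) before reaching "
                            "size %d; restarted", restarts, N)
            return LineageTree(
                parent=np.array(parent, dtype=np.int64),
                birth_time=np.array(birth),
                death_time=np.array(death),
                n_children=np.array(nchild, dtype=np.int64),
                extant=extant,
                stop_time=t,
                restarts=restarts,
            )
        restarts += 1


def sample_and_reconstruct(
    full: LineageTree,
    rho: float,
    rng: np.random.Generator | int | None = None,
    min_sampled: int = 2,
    max_redraws: int = 10000,
) -> ReconTree:
    """Bernoulli(``rho``) sampling of extant cells and tree reconstruction.

    The returned tree spans the sampled cells with degree-2 nodes suppressed;
    its root is their most recent common ancestor.  Each branch is annotated
    with its calendar duration and its hidden-division count ``i`` (truth
    annotations; mutation counts are all zero until
    :func:`assign_mutations` is called).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    extant_ids = np.flatnonzero(full.extant)
    for redraw in range(max_redraws):
        sampled = extant_ids[rng.random(extant_ids.size) < rho]
        if sampled.size >= min_sampled:
            if redraw:
                logger.info("resampled %d time(s) to obtain >= %d sampled cells",
                            redraw, min_sampled)
            break
    else:
        raise RuntimeError(
            f"could not draw >= {min_sampled} sampled cells in {max_redraws} tries"
        )

    n = full.n_cells
    n_sampled_below = np.zeros(n, dtype=np.int64)
    n_sampled_below[sampled] = 1
    for v in range(n - 1, 0, -1):  # children always have larger index
        n_sampled_below[full.parent[v]] += n_sampled_below[v]
    total = int(n_sampled_below[0])

    children = [[] for _ in range(n)]
    for v in range(1, n):
        children[int(full.parent[v])].append(v)

    # descend to the MRCA: first node whose division separates sampled cells
    mrca = 0
    while True:
        live = [c for c in children[mrca] if n_sampled_below[c] > 0]
        if len(live) != 1:
            break
        mrca = live[0]
    T = full.stop_time

    # the two child branches originate at the MRCA's division
    live_root = [c for c in children[mrca] if n_sampled_below[c] > 0]
    tau_origin = T - full.birth_time[live_root[0]]
    parent_out = [-1]
    tau_s_out = [tau_origin]
    tau_e_out = [tau_origin]
    hidden_out = [0]
    labels_out = [""]
    # stack of (lineage-tree node starting a branch, recon parent index)
    stack = [(c, 0) for c in reversed(live_root)]
    tau_start = {c: T - full.birth_time[c] for c in live_root}
    while stack:
        node, recon_parent = stack.pop()
        tau_s = tau_start[node]
        hidden = 0
        while True:
            live = [c for c in children[node] if n_sampled_below[c] > 0]
            if not live:  # sampled extant cell -> leaf
                parent_out.append(recon_parent)
                tau_s_out.append(tau_s)
                tau_e_out.append(0.0)
                hidden_out.append(hidden)
                labels_out.append(f"c{node}")
                break
            if len(live) == 1:  # hidden division (or pass-through to daughter)
                if len(children[node]) == 2:
                    hidden += 1
                node = live[0]
                continue
            # visible bifurcation ends the branch
            idx = len(parent_out)
            parent_out.append(recon_parent)
            tau_s_out.append(tau_s)
            tau_e_out.append(T - full.birth_time[live[0]])
            hidden_out.append(hidden)
            labels_out.append("")
            for c in reversed(live):
                tau_start[c] = T - full.birth_time[c]
                stack.append((c, idx))
            break

    durations = np.array(tau_s_out) - np.array(tau_e_out)
    tree = ReconTree(
        parent_out,
        [0] * len(parent_out),
        labels=labels_out,
        durations=durations,
        hidden_births=hidden_out,
    )
    assert tree.n_leaves == total
    return tree


def assign_mutations(
    recon: ReconTree, mu: float, rng: np.random.Generator | int | None = None
) -> ReconTree:
    """Draw ``m ~ Poisson((i+1) mu)`` independently on every branch.

    The ``+1`` is the division founding the branch; ``i`` are the hidden
    divisions recorded by the reconstruction.  Mutates ``recon`` in place and
    returns it.
    """
    if recon.hidden_births is None:
        raise ValueError("tree lacks hidden-division annotations")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    m = rng.poisson((recon.hidden_births + 1.0) * mu)
    m[0] = 0  # the root has no stem branch
    recon.mutations = m.astype(np.int64)
    return recon


def simulate_tree(
    config: SimConfig, rng: np.random.Generator | None = None
) -> ReconTree:
    """Full pipeline: grow, sample, reconstruct, mutate. One call, one tree."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    full = simulate_birth_death(config, rng)
    recon = sample_and_reconstruct(full, config.rho, rng, config.min_sampled)
    return assign_mutations(recon, config.mu, rng)


# -- Monte-Carlo oracle ----------------------------------------------------


def _build_mc_kernel():
    import numba

    @numba.njit(cache=False)
    def kernel(n_reps, tau_s, tau_e, q, rho, i_target, seed):  # pragma: no cover
        np.random.seed(seed)
        p_death = q / (1.0 + q)
        scale = 1.0 / (1.0 + q)
        stack = np.empty(131072)
        hits = 0
        for _ in range(n_reps):
            t = tau_s
            n_side = 0
            ok = True
            while True:
                t -= np.random.exponential(scale)
                if t <= tau_e:
                    break
                if np.random.random() < p_death:
                    ok = False
                    break
                n_side += 1
                if n_side > i_target:
                    ok = False
                    break
                # side clade founded at t: require no sampled extant descendant
                sp = 0
                stack[sp] = t
                sp += 1
                sampled = False
                while sp > 0 and not sampled:
                    sp -= 1
                    tc = stack[sp]
                    while True:
                        tc -= np.random.exponential(scale)
                        if tc <= 0.0:
                            if np.random.random() < rho:
                                sampled = True
                            break
                        if np.random.random() < p_death:
                            break
                        if sp >= stack.size:
                            # clade exploded; it all but surely has a
                            # sampled survivor
                            sampled = True
                            break
                        stack[sp] = tc
                        sp += 1
                if sampled:
                    ok = False
                    break
            if ok and n_side == i_target:
                hits += 1
        return hits

    return kernel


_MC_KERNEL = None


def mc_estimate_p1(
    i: int,
    window: BranchWindow,
    params: ModelParams,
    n_reps: int = 1_000_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate (value, standard error) of
    ``p1(i | tau_s, tau_e)`` by forward simulation of a single lineage.

    Each replicate follows one designated lineage from ``tau_s``: at every
    division the simulation continues through one daughter and treats the
    other as a side clade.  A replicate is a hit if the designated cell is
    alive at ``tau_e`` having produced exactly ``i`` side lineages, none of
    which has a sampled extant descendant at time 0.  Because either daughter
    can continue a reconstructed branch through a hidden division, the closed
    form counts ``2^i`` lineage embeddings per such realization, so the
    single-path hit frequency is multiplied by ``2**i``.
    """
    if i < 0:
        raise ValueError("i must be >= 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    global _MC_KERNEL
    if _MC_KERNEL is None:
        _MC_KERNEL = _build_mc_kernel()
    hits = _MC_KERNEL(
        n_reps, window.tau_s, window.tau_e, params.q, params.rho, i, seed
    )
    h = hits / n_reps
    weight = 2.0**i
    se = weight * np.sqrt(max(h * (1.0 - h), 1.0 / n_reps)) / np.sqrt(n_reps)
    return float(weight * h), float(se)
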