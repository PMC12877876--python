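"""scikit-learn-style estimators wrapping the maximum-likelihood fits.

These follow the sklearn estimator contract (``get_params``/``set_params``,
``fit`` returning ``self``, fitted attributes with trailing underscores) so
they compose with sklearn model-selection utilities.  ``X`` is a
:class:`~divtree.tree.ReconTree` or a list of them (independent clades
sharing one parameter set); there is no ``y``.
"""

from __future__ import annotations

from sklearn.base import BaseEstimator

from .inference import _fit
from .likelihood import forest_log_likelihood
from .params import GenerationCap, TimeGrid, default_upper_bound

__all__ = ["DivisionModelMLE", "ClockModelMLE"]


class _BaseMLE(BaseEstimator):
    _clock = False

    def __init__(
        self,
        rho: float = 1.0,
        n_subintervals: int = 1000,
        i_max: int | None = None,
        q_bounds: tuple = (0.0, 0.98),
        mu_bounds: tuple | None = None,
        coarse_shape: tuple = (9, 9),
        n_tips_for_bound: int | None = None,
    ):
        self.rho = rho
        self.n_subintervals = n_subintervals
        self.i_max = i_max
        self.q_bounds = q_bounds
        self.mu_bounds = mu_bounds
        self.coarse_shape = coarse_shape
        self.n_tips_for_bound = n_tips_for_bound

    def fit(self, X, y=None):
        result = _fit(
            X,
            self.rho,
            clock=self._clock,
            q_bounds=self.q_bounds,
            mu_bounds=self.mu_bounds,
            n_subintervals=self.n_subintervals,
            i_max=self.i_max
            if self.i_max is not None
            else GenerationCap.default_for(self.rho).i_max,
            coarse_shape=self.coarse_shape,
            n_tips_for_bound=self.n_tips_for_bound,
        )
        self.result_ = result
        self.q_ = result.params.q
        self.log_likelihood_ = result.log_likelihood
        self.n_trees_ = len(X) if isinstance(X, (list, tuple)) else 1
        return self

    def score(self, X, y=None) -> float:
        """Joint log-likelihood of ``X`` at the fitted parameters."""
        trees = X if isinstance(X, (list, tuple)) else [X]
        params = self.result_.params
        n_tips = self.n_tips_for_bound or sum(t.n_leaves for t in trees)
        grid = TimeGrid(
            default_upper_bound(n_tips, params), self.n_subintervals
        )
        cap = None
        if not self._clock:
            cap = GenerationCap(self.result_.settings["i_max"])
        return forest_log_likelihood(trees, params, grid=grid, cap=cap)


class DivisionModelMLE(_BaseMLE):
    """MLE of ``(q, mu)`` under the division-coupled mutation model.

    Fitted attributes: ``q_`` (relative death rate), ``mu_`` (mutations per
    division), ``log_likelihood_``, ``result_`` (full
    :class:`~divtree.inference.FitResult` with optimizer trace).
    """

    _clock = False

    def fit(self, X, y=None):
        super().fit(X, y)
        self.mu_ = self.result_.params.mu
        return self


class ClockModelMLE(_BaseMLE):
    """MLE of ``(q, mu_t)`` under the constant-rate molecular-clock model
    (mutations Poisson in calendar time; same birth–death population)."""

    _clock = True

    def fit(self, X, y=None):
        super().fit(X, y)
        self.mu_t_ = self.result_.params.mu_t
        return self
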