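"""Scikit-learn style estimator wrapping the MILP structure learner."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .scoring import FLAVORS, DataMatrix

__all__ = ["DiProgLearner"]


class DiProgLearner(BaseEstimator):
    """Exact score-based learner for k-bounded progression networks.

    Fits the maximum-score k-bounded Bayesian network to a binary event
    matrix by enumerating all candidate parent sets of size < k, weighting
    each with the (flavor-constrained) decomposable log-likelihood or BIC
    score, and solving a mixed-integer program for the maximum-weight
    acyclic selection.

    Parameters
    ----------
    k : int, default=3
        Hyperedge size bound: each event may select at most k-1 parents.
    flavor : {'monotone', 'semimonotone', 'general'}, default='monotone'
        CPD constraint. ``monotone`` caps the child probability at
        ``epsilon`` unless every parent event has occurred; ``semimonotone``
        caps it only when no parent has occurred; ``general`` is an
        unconstrained Bayesian network.
    epsilon : float, default=0.2
        Escape probability bound of the progression-network flavors.
    criterion : {'bic', 'loglik'}, default='bic'
        Decomposable structure score.
    prune : bool, default=False
        Drop candidates dominated by a subset of their parents before
        building the program (never changes the optimum).
    time_limit_s, mip_gap : float, optional
        Solver limits; on a time limit the best incumbent is kept.
    seed : int, default=0
        Recorded for provenance; the HiGHS backend is deterministic.

    Attributes
    ----------
    network_ : ProgressionNetwork
        Learned structure with constrained-ML CPDs.
    objective_ : float
        Score of the selected structure.
    status_ : str
        'optimal' or 'incumbent'.
    gap_ : float
        Relative optimality gap (0 when proven optimal).

    Examples
    --------
    >>> from diprog import DiProgLearner, simulate
    >>> net = simulate.random_network(6, 2, "monotone", 0.2, seed=0)
    >>> X = simulate.sample_data(net, 500, seed=1)
    >>> est = DiProgLearner(k=2, flavor="monotone").fit(X)
    >>> est.status_
    'optimal'
    """

    def __init__(
        self,
        k: int = 3,
        flavor: str = "monotone",
        epsilon: float = 0.2,
        criterion: str = "bic",
        prune: bool = False,
        time_limit_s: float | None = None,
        mip_gap: float | None = None,
        seed: int = 0,
    ):
        self.k = k
        self.flavor = flavor
        self.epsilon = epsilon
        self.criterion = criterion
        self.prune = prune
        self.time_limit_s = time_limit_s
        self.mip_gap = mip_gap
        self.seed = seed

    # -- input handling ----------------------------------------------------
    def _as_data(self, X) -> DataMatrix:
        if isinstance(X, DataMatrix):
            return X
        names = None
        if hasattr(X, "columns"):  # DataFrame
            names = [str(c) for c in X.columns]
            X = X.to_numpy()
        return DataMatrix(np.asarray(X), names)

    def fit(self, X, y=None):
        """Learn the network structure and CPDs from a binary matrix.

        ``X`` may be a DataMatrix, a pandas DataFrame (column names become
        event names) or any (m, n) array-like over {0, 1}.
        """
        from .milp import learn

        if self.flavor not in FLAVORS:
            raise ValueError(f"flavor must be one of {FLAVORS}")
        if self.criterion not in ("bic", "loglik"):
            raise ValueError("criterion must be 'bic' or 'loglik'")
        D = self._as_data(X)
        res = learn(
            D,
            k=self.k,
            flavor=self.flavor,
            epsilon=self.epsilon,
            score=self.criterion,
            time_limit_s=self.time_limit_s,
            mip_gap=self.mip_gap,
            seed=self.seed,
            prune=self.prune,
        )
        if res.network is None:
            raise RuntimeError(f"solver returned no solution ({res.status})")
        self.n_features_in_ = D.n
        self.feature_names_in_ = np.asarray(D.event_names, dtype=object)
        self.network_ = res.network
        self.objective_ = res.objective
        self.status_ = res.status
        self.gap_ = res.gap
        self.solve_seconds_ = res.solve_seconds
        return self

    def score_samples_total(self, X) -> float:
        """Joint log-likelihood of new data under the fitted network."""
        self._check_fitted()
        D = self._as_data(X)
        if D.n != self.n_features_in_:
            raise ValueError("feature count differs from the fitted data")
        return self.network_.loglik(D)

    def score(self, X, y=None) -> float:
        """Mean per-observation log-likelihood (higher is better)."""
        D = self._as_data(X)
        return self.score_samples_total(D) / D.m

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise AttributeError("estimator is not fitted; call fit first")
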