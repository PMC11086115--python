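"""Gaussian-process Bayesian optimization of the cascade-forest hyperparameters.

The search space is the integer lattice (n_cascadeRF in 1-10) x
(n_cascadeRFtree in 10-300).  A GP with a Matern-5/2 kernel on inputs
normalised to [0,1]^2 models the 5-fold cross-validated accuracy; proposals
maximise expected improvement over a candidate lattice.  Grid and random
search baselines share the same objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern
from sklearn.model_selection import StratifiedKFold

from .cascade import CascadeForestClassifier


@dataclass(frozen=True)
class SearchSpace:
    """Inclusive integer ranges for the two cascade hyperparameters."""

    n_forests: tuple[int, int] = (1, 10)
    n_trees: tuple[int, int] = (10, 300)
    tree_step: int = 10  # lattice granularity along the tree axis

    def lattice(self) -> np.ndarray:
        """Candidate lattice (10 x 30 by default) as an (m, 2) integer array."""
        a = np.arange(self.n_forests[0], self.n_forests[1] + 1)
        b = np.arange(self.n_trees[0], self.n_trees[1] + 1, self.tree_step)
        return np.array([(i, j) for i in a for j in b], dtype=int)

    def clip(self, x) -> tuple[int, int]:
        return (
            int(np.clip(round(x[0]), *self.n_forests)),
            int(np.clip(round(x[1]), *self.n_trees)),
        )

    def normalize(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        lo = np.array([self.n_forests[0], self.n_trees[0]], dtype=float)
        hi = np.array([self.n_forests[1], self.n_trees[1]], dtype=float)
        span = np.maximum(hi - lo, 1.0)
        return (pts - lo) / span


@dataclass
class BOTrace:
    """Observation history of one optimization run."""

    params: list = field(default_factory=list)        # evaluated (n_forests, n_trees)
    values: list = field(default_factory=list)        # objective at each point
    ei: list = field(default_factory=list)            # EI of each proposed point (nan for init)
    incumbents: list = field(default_factory=list)    # best value after each evaluation
    failures: list = field(default_factory=list)      # points whose objective raised
    seed: int = 0

    @property
    def best(self) -> tuple[tuple[int, int], float]:
        i = int(np.argmax(self.values))
        return self.params[i], self.values[i]

    def record(self, x, value, ei=np.nan) -> None:
        self.params.append(tuple(int(c) for c in x))
        self.values.append(float(value))
        self.ei.append(float(ei))
        best = max(self.values)
        self.incumbents.append(best)

    def to_jsonl(self) -> str:
        import json
        lines = [
            json.dumps({"params": list(p), "value": v, "ei": None if np.isnan(e) else e,
                        "incumbent": inc})
            for p, v, e, inc in zip(self.params, self.values, self.ei, self.incumbents)
        ]
        return "\n".join(lines)


def expected_improvement(mu, sigma, f_best: float, xi: float = 0.0) -> np.ndarray:
    """Closed-form EI for maximisation under a Gaussian posterior.

    ``EI = (mu - f_best - xi) Phi(z) + sigma phi(z)`` with
    ``z = (mu - f_best - xi)/sigma``; degenerates to ``max(0, mu - f_best - xi)``
    where sigma = 0.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    imp = mu - f_best - xi
    out = np.maximum(imp, 0.0)
    pos = sigma > 0
    z = np.divide(imp, sigma, out=np.zeros_like(mu), where=pos)
    ei_pos = imp * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)
    return np.where(pos, ei_pos, out)


def cv_objective(X, y, params: tuple[int, int], k: int = 5, seed: int = 0,
                 cv_folds: int = 3, max_levels: int = 10) -> float:
    """Mean k-fold cross-validated accuracy of a cascade forest at ``params``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_forests, n_trees = int(params[0]), int(params[1])
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs at least k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        clf = CascadeForestClassifier(
            n_forests=n_forests, n_trees=n_trees, cv_folds=cv_folds,
            max_levels=max_levels, random_state=seed,
        ).fit(X[tr], y[tr])
        accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
    return float(np.mean(accs))


def _make_gp(seed: int) -> GaussianProcessRegressor:
    # length scales on the [0,1]-normalised space; the upper bound keeps the
    # posterior from collapsing to a flat function with zero predictive spread
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=[0.3, 0.3], length_scale_bounds=(5e-2, 2.0), nu=2.5)
    return GaussianProcessRegressor(
        kernel=kernel, alpha=1e-6, normalize_y=True,
        n_restarts_optimizer=2, random_state=seed)


def optimize(objective, space: SearchSpace = SearchSpace(), n_iter: int = 50,
             n_init: int = 5, seed: int = 0, xi: float = 1e-3,
             ei_tol: float = 1e-6) -> tuple[tuple[int, int], BOTrace]:
    """GP Bayesian optimization with expected-improvement proposals.

    ``n_init`` random lattice points are evaluated first, then up to
    ``n_iter`` EI-maximising proposals; the run stops early once the best
    attainable EI over unobserved candidates drops below ``ei_tol``.
    Points whose objective raises are recorded as failures and skipped;
    more than 20% failures aborts the run.
    """
    rng = np.random.default_rng(seed)
    trace = BOTrace(seed=seed)
    lattice = space.lattice()
    n_init = min(n_init, len(lattice))

    budget = n_init + n_iter

    def evaluate(x, ei=np.nan) -> bool:
        try:
            val = objective(tuple(int(c) for c in x))
        except Exception:
            trace.failures.append(tuple(int(c) for c in x))
            if len(trace.failures) > 0.2 * budget:
                raise RuntimeError("more than 20% of objective evaluations failed")
            return False
        trace.record(x, val, ei)
        return True

    init_idx = rng.choice(len(lattice), size=n_init, replace=False)
    for i in init_idx:
        evaluate(lattice[i])
    if not trace.values:
        raise RuntimeError("all initial evaluations failed")

    for _ in range(n_iter):
        seen = set(trace.params) | set(trace.failures)
        unseen = np.array([i for i, p in enumerate(map(tuple, lattice)) if p not in seen])
        if unseen.size == 0:
            break
        gp = _make_gp(int(rng.integers(2 ** 31)))
        Xn = space.normalize(np.asarray(trace.params, dtype=float))
        with warnings.catch_warnings():
            # kernel hyperparameters pinned at a bound are acceptable here
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(Xn, np.asarray(trace.values))
        mu, sd = gp.predict(space.normalize(lattice[unseen]), return_std=True)
        ei = expected_improvement(mu, sd, max(trace.values), xi=xi)
        j = int(np.argmax(ei))
        if ei[j] < ei_tol:
            break
        evaluate(lattice[unseen[j]], ei=ei[j])

    return trace.best[0], trace


def search_baselines(objective, space: SearchSpace = SearchSpace(),
                     method: str = "grid", budget: int = 50, seed: int = 0):
    """Grid or random-search baselines over the same lattice.

    Grid walks the lattice in order (capped at ``budget`` evaluations);
    random draws uniform integer points from the full space.  Returns
    ``(best_params, best_value, n_evaluations)``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    if method == "grid":
        pts = space.lattice()[:budget]
    elif method == "random":
        pts = np.column_stack([
            rng.integers(space.n_forests[0], space.n_forests[1] + 1, size=budget),
            rng.integers(space.n_trees[0], space.n_trees[1] + 1, size=budget),
        ])
    else:
        raise ValueError(f"unknown method {method!r}")
    best_x, best_v = None, -np.inf
    for x in pts:
        v = objective(tuple(int(c) for c in x))
        if v > best_v:
            best_x, best_v = tuple(int(c) for c in x), float(v)
    return best_x, best_v, len(pts)
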