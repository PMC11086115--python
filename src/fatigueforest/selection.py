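"""mRMR feature selection: mutual information, greedy ranking, subset sizing.

The ranking criterion is max-relevance-min-redundancy: at each step the
candidate set Q maximises ``Phi = D - R`` with ``D`` the mean feature-label
mutual information over Q and ``R`` the mean pairwise mutual information
among Q.  Mutual information is the plug-in estimate on an equal-frequency
discretisation, which keeps rankings deterministic.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted, validate_data


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning; returns integer codes."""
    x = np.asarray(x, dtype=float)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def _is_discrete(y: np.ndarray) -> bool:
    y = np.asarray(y)
    if y.dtype.kind in "OUSb":
        return True
    vals = np.unique(y)
    return vals.size <= max(2, int(np.sqrt(y.size) / 2)) and np.allclose(vals, np.round(vals))


def default_bins(n: int) -> int:
    """Histogram bin count for n samples: min(10, floor(sqrt(n)))."""
    return max(2, min(10, int(np.floor(np.sqrt(n)))))


def mutual_information(x, y, bins: int | None = None) -> float:
    """Plug-in mutual information estimate in bits.

    Continuous inputs are discretised into equal-frequency bins
    (``min(10, floor(sqrt(n)))`` by default); discrete inputs (labels,
    small-integer codes) are used as-is.  Always non-negative; two constant
    inputs give 0 by convention.
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 10:
        raise ValueError("need at least 10 samples for an MI estimate")
    n = x.size
    b = bins if bins is not None else default_bins(n)
    if b > n:
        raise ValueError(f"bins={b} exceeds sample count {n}")
    xc = _codes(x, b)
    yc = _codes(y, b)
    joint = np.zeros((xc.max() + 1, yc.max() + 1))
    np.add.at(joint, (xc, yc), 1.0)
    joint /= n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


def _codes(v: np.ndarray, bins: int) -> np.ndarray:
    if _is_discrete(v):
        _, codes = np.unique(v, return_inverse=True)
        return codes
    return _discretize(v.astype(float), bins)


class MRMRSelector(SelectorMixin, BaseEstimator):
    """Greedy max-relevance-min-redundancy feature selector.

    Parameters
    ----------
    k : int or None
        Number of top-ranked features kept by :meth:`transform`; ``None``
        keeps all (the full ranking is still computed).
    bins : int or None
        Discretisation bins for the MI estimates; default
        ``min(10, floor(sqrt(n)))``.

    Attributes
    ----------
    ranking_ : ndarray of int
        Feature indices in selection order (best first).
    phi_ : ndarray of float
        The Phi = D - R score of the candidate set at each selection step.
    relevance_ : ndarray of float
        D (mean feature-label MI of the selected set) at each step.
    redundancy_ : ndarray of float
        R (mean pairwise MI among the selected set) at each step.
    """

    def __init__(self, k: int | None = None, bins: int | None = None):
        self.k = k
        self.bins = bins

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_features=2)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("mRMR needs at least 2 classes")
        n, p = X.shape
        b = self.bins if self.bins is not None else default_bins(n)
        if b > n:
            raise ValueError(f"bins={b} exceeds sample count {n}")

        rel = np.array([mutual_information(X[:, j], y, bins=b) for j in range(p)])
        pair = np.full((p, p), np.nan)

        def pair_mi(i, j):
            if np.isnan(pair[i, j]):
                pair[i, j] = pair[j, i] = mutual_information(X[:, i], X[:, j], bins=b)
            return pair[i, j]

        order: list[int] = []
        phi_hist, d_hist, r_hist = [], [], []
        remaining = list(range(p))
        while remaining:
            best_j, best_phi, best_d, best_r = None, -np.inf, 0.0, 0.0
            for j in remaining:
                cand = order + [j]
                d = float(np.mean(rel[cand]))
                if len(cand) > 1:
                    pairs = [pair_mi(a, c) for ai, a in enumerate(cand) for c in cand[ai + 1:]]
                    r = float(np.mean(pairs))
                else:
                    r = 0.0
                phi = d - r
                if phi > best_phi + 1e-12:  # ties broken toward the lower index
                    best_j, best_phi, best_d, best_r = j, phi, d, r
            order.append(best_j)
            remaining.remove(best_j)
            phi_hist.append(best_phi)
            d_hist.append(best_d)
            r_hist.append(best_r)

        self.ranking_ = np.asarray(order)
        self.phi_ = np.asarray(phi_hist)
        self.relevance_ = np.asarray(d_hist)
        self.redundancy_ = np.asarray(r_hist)
        self.n_features_in_ = p
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ranking_")
        k = self.k if self.k is not None else self.ranking_.size
        mask = np.zeros(self.ranking_.size, dtype=bool)
        mask[self.ranking_[:k]] = True
        return mask

    def top(self, k: int) -> np.ndarray:
        """The first k feature indices of the ranking."""
        check_is_fitted(self, "ranking_")
        return self.ranking_[:k]


def mrmr_rank(X, y, bins: int | None = None) -> MRMRSelector:
    """Rank all features with mRMR; returns the fitted selector."""
    return MRMRSelector(bins=bins).fit(X, y)


def optimal_subset_size(X, y, ranking: np.ndarray, classifier_factory, seed: int = 0,
                        max_k: int | None = None, test_size: float = 0.3):
    """Accuracy-vs-k curve over nested top-k feature subsets.

    For k = 1..p, a fresh classifier from ``classifier_factory()`` is trained
    on the top-k ranked features of a fixed stratified split and scored on
    the held-out part.  Returns ``(best_k, accuracy_curve)`` with the
    smallest k taken on ties.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    ranking = np.asarray(ranking)
    if ranking.size != X.shape[1]:
        raise ValueError("ranking must cover all features")
    p = max_k if max_k is not None else X.shape[1]
    idx = np.arange(X.shape[0])
    tr, te = train_test_split(idx, test_size=test_size, stratify=y, random_state=seed)
    curve = np.empty(p)
    for k in range(1, p + 1):
        cols = ranking[:k]
        clf = classifier_factory()
        clf.fit(X[np.ix_(tr, cols)], y[tr])
        curve[k - 1] = float(np.mean(clf.predict(X[np.ix_(te, cols)]) == y[te]))
    best_k = int(np.argmax(curve)) + 1  # argmax returns the first (smallest) maximiser
    return best_k, curve
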