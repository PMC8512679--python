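"""Regression neighbourhood component analysis (NCA) feature selection.

NCA learns one non-negative weight per feature by minimising the
expected leave-one-out regression loss of a soft nearest-neighbour
predictor.  With weighted distance

    d_w(x_i, x_j) = sum_r w_r^2 |x_ir - x_jr|

point j is picked as the neighbour of point i with probability

    p_ij = k(d_w(x_i, x_j)) / sum_{j' != i} k(d_w(x_i, x_j')),
    k(z) = exp(-z / sigma),

and the objective is

    F(w) = 1/n sum_i sum_{j != i} p_ij |y_i - y_j|  +  lambda sum_r w_r^2.

Weights enter squared, so the optimisation is unconstrained; features
are standardised internally before distances are computed.  After the
fit, features whose squared weight exceeds a fraction (default 1%) of
the maximum squared weight are selected.

:class:`NcaFeatureSelector` is a scikit-learn compatible transformer
(``fit`` / ``transform`` / ``get_support``); the module-level
functions expose the raw objective, gradient and selection rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "NcaObjectiveBreakdown",
    "NcaFeatureSelector",
    "nca_objective",
    "nca_gradient",
    "fit_nca",
    "select_features",
]


@dataclass
class NcaObjectiveBreakdown:
    """All intermediate quantities of one objective evaluation."""

    d_w: np.ndarray        # (n, n) pairwise weighted distances
    p_ij: np.ndarray       # (n, n) neighbour probabilities, zero diagonal
    l_i: np.ndarray        # (n,) per-point expected losses
    loss_pair: np.ndarray  # (n, n) |y_i - y_j|
    objective: float


def _prepare(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if len(y) != X.shape[0]:
        raise ValueError("X and y length mismatch")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples (leave-one-out is undefined)")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite entries in X or y")
    return X, y


def _breakdown(w, X, y, sigma):
    n = X.shape[0]
    w2 = np.asarray(w, dtype=float) ** 2
    diff = np.abs(X[:, None, :] - X[None, :, :])        # (n, n, p)
    d_w = diff @ w2                                     # (n, n)
    # softmax over -d/sigma, stabilised by the row-wise minimum distance
    z = -d_w / sigma
    np.fill_diagonal(z, -np.inf)
    z = z - z.max(axis=1, keepdims=True)
    k = np.exp(z)
    p = k / k.sum(axis=1, keepdims=True)
    loss = np.abs(y[:, None] - y[None, :])
    l_i = (p * loss).sum(axis=1)
    return diff, d_w, p, loss, l_i


def nca_objective(w, X, y, sigma: float = 1.0, lambda_reg: float = 0.0) -> NcaObjectiveBreakdown:
    """Evaluate the NCA objective and return the full breakdown."""
    X, y = _prepare(X, y)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    _, d_w, p, loss, l_i = _breakdown(w, X, y, sigma)
    obj = float(l_i.mean() + lambda_reg * np.sum(np.asarray(w, dtype=float) ** 2))
    return NcaObjectiveBreakdown(d_w=d_w, p_ij=p, l_i=l_i, loss_pair=loss, objective=obj)


def nca_gradient(w, X, y, sigma: float = 1.0, lambda_reg: float = 0.0) -> np.ndarray:
    """Analytic gradient of the NCA objective with respect to ``w``."""
    X, y = _prepare(X, y)
    w = np.asarray(w, dtype=float)
    n = X.shape[0]
    diff, _, p, loss, l_i = _breakdown(w, X, y, sigma)
    # dF/dw_r = -(2 w_r / (n sigma)) sum_i [ sum_j p_ij l_ij D_ijr
    #                                        - l_i sum_j p_ij D_ijr ]
    pl = p * loss
    term1 = np.einsum("ij,ijr->r", pl, diff)
    term2 = np.einsum("i,ij,ijr->r", l_i, p, diff)
    grad = -(2.0 * w / (n * sigma)) * (term1 - term2) + 2.0 * lambda_reg * w
    return grad


def select_features(weights_sq: np.ndarray, fraction: float = 0.01) -> np.ndarray:
    """Indices (ascending) of features with w^2 above ``fraction`` of the max."""
    w2 = np.asarray(weights_sq, dtype=float)
    if np.all(w2 == 0):
        raise ValueError("all feature weights are zero; selection is undefined")
    return np.flatnonzero(w2 > fraction * w2.max())


class NcaFeatureSelector(SelectorMixin, BaseEstimator):
    """NCA-based feature selection for regression targets.

    Parameters
    ----------
    sigma : float, default=1.0
        Kernel width of ``k(z) = exp(-z / sigma)``, applied after
        internal standardisation of the features.
    lambda_reg : float or "auto", default="auto"
        Regularisation weight of ``lambda * sum w_r^2``; ``"auto"``
        uses ``1 / n_samples``.
    fraction : float, default=0.01
        Selection threshold as a fraction of the maximal squared
        weight.
    max_iter : int, default=100
        L-BFGS iteration cap.
    tol : float, default=1e-8
        Gradient tolerance of the optimiser.
    random_state : int, default=0
        Reserved for API symmetry; the fit itself is deterministic
        (all-ones initial weights).

    Attributes
    ----------
    weights_ : ndarray of shape (n_features,)
        Fitted (unconstrained) weights; the model uses ``weights_**2``.
    objective_ : float
        Objective value at the optimum.
    converged_ : bool
        Whether the optimiser reported convergence (a failed line
        search is flagged, not raised).
    objective_trace_ : list of float
        Objective value at each accepted iterate (non-increasing).
    """

    def __init__(self, sigma: float = 1.0, lambda_reg="auto", fraction: float = 0.01,
                 max_iter: int = 100, tol: float = 1e-8, random_state: int = 0):
        self.sigma = sigma
        self.lambda_reg = lambda_reg
        self.fraction = fraction
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_samples=2, y_numeric=True)
        X, y = _prepare(X, y)
        lam = 1.0 / X.shape[0] if self.lambda_reg == "auto" else float(self.lambda_reg)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        self.feature_means_ = mu
        self.feature_scales_ = sd
        # The response is standardised as well: sigma and lambda are
        # dimensionless defaults that presume unit-scale data, and the
        # selection must not depend on the units of the target (the
        # pipeline mixes %BW forces with mm centre-of-pressure series).
        y_sd = y.std()
        y = (y - y.mean()) / (y_sd if y_sd > 0 else 1.0)

        trace: list[float] = []
        n = X.shape[0]
        last: dict = {}

        def fun_and_jac(w):
            # one pairwise pass serves both the value and the gradient
            diff, _, p, loss, l_i = _breakdown(w, Xs, y, self.sigma)
            f = float(l_i.mean() + lam * np.sum(w**2))
            pl = p * loss
            term1 = np.einsum("ij,ijr->r", pl, diff)
            term2 = np.einsum("i,ij,ijr->r", l_i, p, diff)
            g = -(2.0 * w / (n * self.sigma)) * (term1 - term2) + 2.0 * lam * w
            last["f"] = f
            return f, g

        w0 = np.ones(X.shape[1])
        res = optimize.minimize(
            fun_and_jac, w0, jac=True, method="L-BFGS-B",
            callback=lambda w: trace.append(last["f"]),
            options={"maxiter": self.max_iter, "gtol": self.tol, "ftol": 1e-12},
        )
        self.weights_ = res.x
        self.objective_ = float(res.fun)
        self.converged_ = bool(res.success)
        self.objective_trace_ = [fun_and_jac(w0)[0], *trace]
        self.lambda_ = lam
        self.n_features_in_ = X.shape[1]
        return self

    @property
    def weights_sq_(self) -> np.ndarray:
        check_is_fitted(self)
        return self.weights_**2

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self)
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[select_features(self.weights_sq_, self.fraction)] = True
        return mask

    def selection_table(self, feature_names=None):
        """Per-feature weights and selection flags as a list of dicts."""
        check_is_fitted(self)
        mask = self._get_support_mask()
        names = feature_names if feature_names is not None else [
            f"x{i}" for i in range(self.n_features_in_)
        ]
        return [
            {"feature": names[i], "weight_sq": float(self.weights_sq_[i]),
             "selected": bool(mask[i])}
            for i in range(self.n_features_in_)
        ]


def fit_nca(X, y, lambda_reg="auto", sigma: float = 1.0, max_iter: int = 100,
            tol: float = 1e-8, seed: int = 0) -> NcaFeatureSelector:
    """Functional wrapper around :class:`NcaFeatureSelector`."""
    return NcaFeatureSelector(
        sigma=sigma, lambda_reg=lambda_reg, max_iter=max_iter, tol=tol, random_state=seed
    ).fit(X, y)
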