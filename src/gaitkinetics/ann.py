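"""Single-hidden-layer feedforward networks for GRF/COP regression.

One independent network is trained per target channel (AP/ML/vertical
ground reaction force in %BW; AP/ML centre of pressure in mm).  The
architecture follows common practice for this estimation task: one
hidden layer with hyperbolic-tangent units and a linear output,
full-batch Levenberg-Marquardt (LM) updates, and a minimum-gradient
stopping rule for generalisation.

LM has no classical learning rate; the tunable "learning rate" is
mapped to the initial damping factor of the LM trust region, which
plays the same role of scaling the first steps.  Hyperparameters are
searched inside a fixed box (2-20 neurons, learning rate 5e-4 to 1,
500-1000 epochs) by seeded Bayesian optimisation (Gaussian-process
surrogate with expected improvement; random search as a documented
fallback) minimising the *worst* fold mean-squared error of a seeded
five-fold cross-validation,

    F_obj = max_k ( sum_n (y_est,k - y_true,k)^2 / N_k ).

:class:`LMRegressor` is scikit-learn compatible (``fit``/``predict``,
``get_params``/``set_params``), so it composes with sklearn tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "HYPERPARAM_BOX",
    "AnnHyperParams",
    "CvFoldResult",
    "LMRegressor",
    "train_ann",
    "predict_ann",
    "cv_objective",
    "tune_hyperparameters",
]

#: Search box: (min, max) for each tunable; neuron count and epochs are integer.
HYPERPARAM_BOX = {
    "n_hidden": (2, 20),
    "learning_rate": (0.0005, 1.0),
    "epochs": (500, 1000),
}


@dataclass(frozen=True)
class AnnHyperParams:
    """Tunable network hyperparameters, constrained to the search box."""

    n_hidden: int
    learning_rate: float   # initial LM damping factor
    epochs: int            # maximum training epochs

    def __post_init__(self) -> None:
        for name, value in (("n_hidden", self.n_hidden),
                            ("learning_rate", self.learning_rate),
                            ("epochs", self.epochs)):
            lo, hi = HYPERPARAM_BOX[name]
            if not (lo <= value <= hi):
                raise ValueError(f"{name}={value} outside the box [{lo}, {hi}]")


@dataclass
class CvFoldResult:
    """Held-out predictions and MSE of one cross-validation fold."""

    k: int
    n_points: int
    y_est: np.ndarray
    y_true: np.ndarray
    fold_mse: float = field(init=False)

    def __post_init__(self) -> None:
        self.fold_mse = float(np.mean((self.y_est - self.y_true) ** 2))


class LMRegressor(RegressorMixin, BaseEstimator):
    """tanh-hidden-layer network trained by Levenberg-Marquardt.

    Parameters
    ----------
    n_hidden : int, default=10
        Hidden-layer width.
    learning_rate : float, default=0.001
        Initial LM damping factor (the tuned "learning rate").
    epochs : int, default=1000
        Maximum number of LM epochs.
    min_grad : float, default=1e-7
        Stop when the infinity norm of the SSE gradient (in the
        internally standardised space) falls below this threshold.
    random_state : int or None, default=None
        Seed of the weight initialisation; fixed seed gives identical
        parameters.

    Attributes
    ----------
    coefs_ : dict with W1, b1, w2, b2 (standardised space)
    stop_reason_ : {"min_grad", "max_epochs", "mu_overflow"}
    n_epochs_ : epochs actually run
    """

    def __init__(self, n_hidden: int = 10, learning_rate: float = 0.001,
                 epochs: int = 1000, min_grad: float = 1e-7,
                 random_state: int | None = None):
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.min_grad = min_grad
        self.random_state = random_state

    # --- internal helpers ---------------------------------------------------

    def _unpack(self, theta: np.ndarray, p: int):
        h = self.n_hidden
        i = 0
        W1 = theta[i:i + h * p].reshape(h, p); i += h * p
        b1 = theta[i:i + h]; i += h
        w2 = theta[i:i + h]; i += h
        b2 = theta[i]
        return W1, b1, w2, b2

    @staticmethod
    def _forward(Xs, W1, b1, w2, b2):
        hid = np.tanh(Xs @ W1.T + b1)
        return hid @ w2 + b2, hid

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if n <= self.n_hidden:
            raise ValueError(
                f"need more samples ({n}) than hidden units ({self.n_hidden})"
            )
        self._x_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self._x_scale = sd
        self._y_mean = float(y.mean())
        ysd = float(y.std())
        self._y_scale = ysd if ysd > 0 else 1.0
        Xs = (X - self._x_mean) / self._x_scale
        ys = (y - self._y_mean) / self._y_scale

        rng = np.random.default_rng(self.random_state)
        h = self.n_hidden
        n_par = h * p + h + h + 1
        theta = rng.uniform(-1, 1, n_par)
        theta[: h * p] *= np.sqrt(3.0 / max(p, 1))

        def sse_and_jac(theta):
            W1, b1, w2, b2 = self._unpack(theta, p)
            yhat, hid = self._forward(Xs, W1, b1, w2, b2)
            r = yhat - ys
            dtanh = (1.0 - hid**2) * w2          # (n, h)
            J = np.empty((n, n_par))
            J[:, : h * p] = (dtanh[:, :, None] * Xs[:, None, :]).reshape(n, h * p)
            J[:, h * p: h * p + h] = dtanh
            J[:, h * p + h: h * p + 2 * h] = hid
            J[:, -1] = 1.0
            return r, J

        mu = float(self.learning_rate)
        r, J = sse_and_jac(theta)
        sse = float(r @ r)
        stop = "max_epochs"
        epoch = 0
        eye = np.eye(n_par)
        for epoch in range(1, self.epochs + 1):
            g = J.T @ r
            if np.max(np.abs(g)) < self.min_grad:
                stop = "min_grad"
                break
            JtJ = J.T @ J
            accepted = False
            for _ in range(30):
                try:
                    delta = np.linalg.solve(JtJ + mu * eye, -g)
                except np.linalg.LinAlgError:
                    mu *= 10.0
                    continue
                cand = theta + delta
                r_new, J_new = sse_and_jac(cand)
                sse_new = float(r_new @ r_new)
                if not np.isfinite(sse_new):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}"
                    )
                if sse_new < sse:
                    theta, r, J, sse = cand, r_new, J_new, sse_new
                    mu = max(mu / 10.0, 1e-12)
                    accepted = True
                    break
                mu *= 10.0
            if not accepted:
                stop = "mu_overflow"
                break

        W1, b1, w2, b2 = self._unpack(theta, p)
        self.coefs_ = {"W1": W1, "b1": b1, "w2": w2, "b2": b2}
        self.stop_reason_ = stop
        self.n_epochs_ = epoch
        self.training_sse_ = sse
        # same expression path as predict(), so predict(train X) is bitwise equal
        self.fitted_values_ = self._predict_scaled(Xs) * self._y_scale + self._y_mean
        return self

    def _predict_scaled(self, Xs):
        c = self.coefs_
        yhat, _ = self._forward(Xs, c["W1"], c["b1"], c["w2"], c["b2"])
        return yhat

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        Xs = (X - self._x_mean) / self._x_scale
        return self._predict_scaled(Xs) * self._y_scale + self._y_mean


def train_ann(X, y, hp: AnnHyperParams, seed: int | None = 0,
              min_grad: float = 1e-7) -> LMRegressor:
    """Train one network with the given hyperparameters (deterministic per seed)."""
    model = LMRegressor(
        n_hidden=int(hp.n_hidden), learning_rate=float(hp.learning_rate),
        epochs=int(hp.epochs), min_grad=min_grad, random_state=seed,
    )
    return model.fit(X, y)


def predict_ann(model: LMRegressor, X) -> np.ndarray:
    """Apply a trained network; raises on feature-count mismatch."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"expected {model.n_features_in_} features, got "
            f"{X.shape[1] if X.ndim == 2 else 'non-2D input'}"
        )
    return model.predict(X)


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(perm, n_folds)]


def cv_objective(hp: AnnHyperParams, X, y, seed: int = 0, n_folds: int = 5,
                 min_grad: float = 1e-7) -> tuple[float, list[CvFoldResult]]:
    """Worst-fold MSE over a seeded random partition of the pooled samples.

    ``F_obj = max_k fold_mse_k``; the folds partition the samples into
    near-equal parts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < n_folds:
        raise ValueError(f"need at least {n_folds} samples, got {len(y)}")
    rng = np.random.default_rng(seed)
    folds: list[CvFoldResult] = []
    for k, idx in enumerate(_fold_indices(len(y), n_folds, rng)):
        mask = np.ones(len(y), dtype=bool)
        mask[idx] = False
        model = train_ann(X[mask], y[mask], hp, seed=seed + k, min_grad=min_grad)
        folds.append(CvFoldResult(k=k, n_points=len(idx),
                                  y_est=model.predict(X[idx]), y_true=y[idx]))
    f_obj = float(max(f.fold_mse for f in folds))
    return f_obj, folds


def _sample_box(u: np.ndarray) -> AnnHyperParams:
    """Map a point of the unit cube to the hyperparameter box (log-scale rate)."""
    lo_h, hi_h = HYPERPARAM_BOX["n_hidden"]
    lo_r, hi_r = HYPERPARAM_BOX["learning_rate"]
    lo_e, hi_e = HYPERPARAM_BOX["epochs"]
    n_hidden = int(np.clip(round(lo_h + u[0] * (hi_h - lo_h)), lo_h, hi_h))
    rate = float(np.exp(np.log(lo_r) + u[1] * (np.log(hi_r) - np.log(lo_r))))
    epochs = int(np.clip(round(lo_e + u[2] * (hi_e - lo_e)), lo_e, hi_e))
    return AnnHyperParams(n_hidden, rate, epochs)


def tune_hyperparameters(X, y, budget: int = 30, seed: int = 0,
                         n_folds: int = 5, min_grad: float = 1e-7,
                         n_init: int | None = None):
    """Bayesian-optimisation search of the hyperparameter box.

    A Gaussian-process surrogate (Matern kernel) is fitted to the
    observed (point, F_obj) pairs in the normalised unit cube and the
    next point maximises expected improvement over 256 seeded
    candidates; the first ``n_init`` points (default: budget // 3,
    at least 4) are random.  If the surrogate fit fails the step
    degrades to random search.  Returns the best hyperparameters, the
    best F_obj, and a log of every evaluation.
    """
    if budget < 10:
        raise ValueError(f"tuning budget must be >= 10, got {budget}")
    rng = np.random.default_rng(seed)
    n_init = max(4, budget // 3) if n_init is None else n_init
    points: list[np.ndarray] = []
    scores: list[float] = []
    log: list[dict] = []

    def evaluate(u: np.ndarray):
        hp = _sample_box(u)
        f_obj, _ = cv_objective(hp, X, y, seed=seed, n_folds=n_folds, min_grad=min_grad)
        points.append(u)
        scores.append(f_obj)
        log.append({"n_hidden": hp.n_hidden, "learning_rate": hp.learning_rate,
                    "epochs": hp.epochs, "f_obj": f_obj})

    for _ in range(min(n_init, budget)):
        evaluate(rng.uniform(size=3))

    from scipy.stats import norm as _norm
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern
    import warnings as _warnings

    while len(scores) < budget:
        cand = rng.uniform(size=(256, 3))
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", category=ConvergenceWarning)
                gp = GaussianProcessRegressor(
                    kernel=Matern(nu=2.5), alpha=1e-8, normalize_y=True,
                    random_state=int(rng.integers(2**31 - 1)),
                )
                gp.fit(np.array(points), np.array(scores))
            mu, sd = gp.predict(cand, return_std=True)
            best = min(scores)
            sd = np.clip(sd, 1e-12, None)
            imp = best - mu
            ei = imp * _norm.cdf(imp / sd) + sd * _norm.pdf(imp / sd)
            u_next = cand[int(np.argmax(ei))]
        except Exception:
            u_next = cand[0]  # random-search fallback
        evaluate(u_next)

    best_i = int(np.argmin(scores))
    return _sample_box(points[best_i]), scores[best_i], log
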