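"""Bayesian-regularized one-hidden-layer network regression.

The model is a classical two-layer network, y = w2' tanh(W1 x + b1) + b2,
fitted by minimizing the regularized objective

    F(theta) = beta * E_D + alpha * E_W,
    E_D = 1/2 sum_i (y_i - f(x_i; theta))^2,   E_W = 1/2 ||theta||^2,

with Levenberg-Marquardt (Gauss-Newton plus adaptive damping) steps

    (beta J'J + (alpha + mu) I) delta = beta J'r - alpha theta,

where J is the Jacobian of the network output w.r.t. the parameters.  The
hyper-parameters alpha, beta are re-estimated after every accepted step by
MacKay's evidence approximation:

    gamma = m - alpha * tr(H^-1),  H = beta J'J + alpha I,
    alpha = gamma / (2 E_W),       beta = (n - gamma) / (2 E_D),

where gamma is the effective number of parameters.  This automatic
regularization keeps small networks from overfitting without a validation
set.  Inputs and the target are standardized internally; predictions are
returned on the original scale.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .errors import DegenerateFitError, SchemaError


class BayesianRegularizedNN:
    """One-hidden-layer tanh network with evidence-based regularization.

    Parameters
    ----------
    n_hidden:
        Number of hidden neurons.
    max_iter:
        Maximum Levenberg-Marquardt iterations.
    tol:
        Relative decrease of the data misfit below which (after two
        consecutive iterations) training stops.
    random_state:
        Seed for the weight initialization.
    """

    def __init__(self, n_hidden: int = 2, max_iter: int = 15,
                 tol: float = 1e-4, random_state: int | None = None):
        self.n_hidden = int(n_hidden)
        self.max_iter = int(max_iter)
        self.tol = float(tol)
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _unpack(self, theta: np.ndarray, p: int):
        h = self.n_hidden
        W1 = theta[: h * p].reshape(h, p)
        b1 = theta[h * p: h * p + h]
        w2 = theta[h * p + h: h * p + 2 * h]
        b2 = theta[-1]
        return W1, b1, w2, b2

    def _forward(self, X: np.ndarray, theta: np.ndarray):
        W1, b1, w2, b2 = self._unpack(theta, X.shape[1])
        Z = np.tanh(X @ W1.T + b1)
        return Z @ w2 + b2, Z

    def _jacobian(self, X: np.ndarray, Z: np.ndarray, theta: np.ndarray):
        n, p = X.shape
        h = self.n_hidden
        _, _, w2, _ = self._unpack(theta, p)
        D = (1.0 - Z * Z) * w2  # n x h, d y / d a_j
        J = np.empty((n, theta.size))
        J[:, : h * p] = (D[:, :, None] * X[:, None, :]).reshape(n, h * p)
        J[:, h * p: h * p + h] = D
        J[:, h * p + h: h * p + 2 * h] = Z
        J[:, -1] = 1.0
        return J

    # -- API ---------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BayesianRegularizedNN":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, p = X.shape
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in training data")
        if np.unique(y).size < 2:
            raise DegenerateFitError("targets are constant")

        self._x_mean = X.mean(axis=0)
        x_sd = X.std(axis=0)
        self._x_sd = np.where(x_sd > 0, x_sd, 1.0)
        self._y_mean = float(y.mean())
        y_sd = float(y.std())
        self._y_sd = y_sd if y_sd > 0 else 1.0
        Xs = (X - self._x_mean) / self._x_sd
        ys = (y - self._y_mean) / self._y_sd

        h = self.n_hidden
        m = h * (p + 1) + h + 1
        rng = np.random.default_rng(self.random_state)
        theta = rng.normal(0.0, 1.0 / np.sqrt(p + 1), size=m)

        alpha, beta = 0.01, 1.0
        mu = 0.005
        eye = np.eye(m)
        J = np.empty((n, m))  # reused across iterations
        J[:, -1] = 1.0
        yhat, Z = self._forward(Xs, theta)
        r = ys - yhat
        e_d = 0.5 * float(r @ r)
        gamma = float(m)
        slow = 0
        for _ in range(self.max_iter):
            if e_d <= 1e-14:  # interpolating fit; nothing left to do
                break
            w2 = theta[h * p + h: h * p + 2 * h]
            D = (1.0 - Z * Z) * w2
            np.einsum("ij,ik->ijk", D, Xs,
                      out=J[:, : h * p].reshape(n, h, p))
            J[:, h * p: h * p + h] = D
            J[:, h * p + h: h * p + 2 * h] = Z
            A = beta * (J.T @ J) + alpha * eye
            g = beta * (J.T @ r) - alpha * theta
            e_w = 0.5 * float(theta @ theta)
            f_cur = beta * e_d + alpha * e_w
            accepted = False
            for _ in range(25):
                try:
                    c = cho_factor(A + mu * eye, lower=True,
                                   check_finite=False)
                    delta = cho_solve(c, g, check_finite=False)
                except np.linalg.LinAlgError:
                    mu *= 10.0
                    continue
                theta_new = theta + delta
                yhat_new, Z_new = self._forward(Xs, theta_new)
                r_new = ys - yhat_new
                e_d_new = 0.5 * float(r_new @ r_new)
                f_new = beta * e_d_new + 0.5 * alpha * float(
                    theta_new @ theta_new)
                if np.isfinite(f_new) and f_new < f_cur:
                    mu = max(mu / 10.0, 1e-12)
                    accepted = True
                    break
                mu *= 10.0
                if mu > 1e10:
                    break
            if not accepted:
                break
            theta, yhat, Z, r = theta_new, yhat_new, Z_new, r_new
            e_d_prev, e_d = e_d, e_d_new
            # evidence re-estimation of the hyper-parameters; geometric
            # damping keeps alpha/beta from oscillating between iterations
            try:
                c = cho_factor(A, lower=True, check_finite=False)
                tr_inv = float(np.trace(cho_solve(c, eye, check_finite=False)))
            except np.linalg.LinAlgError:
                tr_inv = float(np.trace(np.linalg.pinv(A)))
            gamma = m - alpha * tr_inv
            gamma = float(np.clip(gamma, 1e-3, min(m, n - 1e-3)))
            e_w = 0.5 * float(theta @ theta)
            alpha_star = gamma / max(2.0 * e_w, 1e-12)
            beta_star = max(n - gamma, 1e-3) / max(2.0 * e_d, 1e-12)
            alpha = float(np.sqrt(alpha * alpha_star))
            beta = float(np.sqrt(beta * beta_star))
            if abs(e_d_prev - e_d) <= self.tol * max(e_d_prev, 1e-12):
                slow += 1
                if slow >= 2:
                    break
            else:
                slow = 0
        self._theta = theta
        self.n_features_in_ = p
        self.effective_parameters_ = gamma
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "_theta"):
            raise SchemaError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise SchemaError(
                f"expected {self.n_features_in_} feature columns, "
                f"got {X.shape[1] if X.ndim == 2 else 'non-2D input'}")
        Xs = (X - self._x_mean) / self._x_sd
        yhat, _ = self._forward(Xs, self._theta)
        return yhat * self._y_sd + self._y_mean
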